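"""Module-eigengene hub scoring and adjacent-hub ("piggybacking") groups.

Module labels are an input (from an external WGCNA run or the synthetic
generator's planted truth); this module computes the standard WGCNA summary
statistics on top of them. The eigengene of a module is the first principal
component of its z-scored expression across samples. Module membership (MM)
is the Pearson correlation of a gene's profile with its module eigengene;
gene significance (GS) is the Pearson correlation with a binary stage-
indicator trait. A gene is a hub when MM >= 0.6, GS >= 0.5 and the GS
correlation is significant at p < 0.05 (correlations are signed, not
absolute). Hub genes at consecutive chromosome ranks form neighbour groups,
the candidate units of expression piggybacking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GenomeAnnotation, intergenic_spacer
from .duplication import DuplicationCall
from .expression import ExpressionMatrix, STAGES


class HubError(ValueError):
    pass


def module_eigengene(expr: ExpressionMatrix, module_genes: Iterable[str]) -> np.ndarray:
    """First principal component of the module's z-scored expression.

    Returns per-sample scores with unit variance, sign-fixed so the mean
    gene-eigengene correlation is non-negative. Zero-variance gene rows are
    dropped with a warning.
    """
    genes = [g for g in module_genes]
    if not genes:
        raise HubError("empty module")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise HubError(f"module gene(s) not in matrix: {missing[:5]}")
    mat = expr.values.loc[genes].to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance gene row(s)")
        mat = mat[keep]
        sd = sd[keep]
    if mat.shape[0] == 0:
        raise HubError("module has no non-constant genes")
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    # PC1 across samples via SVD of the gene x sample z-matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    corr_sum = 0.0
    for row in z:
        corr_sum += np.corrcoef(row, scores)[0, 1]
    if abs(corr_sum) < 1e-8:
        # balanced anti-correlated module: correlations cancel exactly, so
        # fix the sign by the largest-magnitude score instead
        if scores[np.argmax(np.abs(scores))] < 0:
            scores = -scores
    elif corr_sum < 0:
        scores = -scores
    scores = scores - scores.mean()
    scores = scores / scores.std(ddof=0)
    return scores


@dataclass(frozen=True)
class HubScore:
    gene_id: str
    module: str
    mm: float
    gs: float
    gs_pvalue: float

    @property
    def is_hub(self) -> bool:
        return self.mm >= 0.6 and self.gs >= 0.5 and self.gs_pvalue < 0.05


def hub_select(expr: ExpressionMatrix, modules: Mapping[str, str],
               trait_stage: str, mm_min: float = 0.6, gs_min: float = 0.5,
               gs_alpha: float = 0.05) -> list[HubScore]:
    """Score every module-assigned gene for MM and GS against a stage trait.

    The trait is the binary indicator of ``trait_stage`` over samples; the GS
    p-value is the usual t-test of a Pearson correlation with n-2 degrees of
    freedom (as returned by scipy's pearsonr).
    """
    if trait_stage not in STAGES:
        raise HubError(f"unknown stage {trait_stage!r}")
    if len(expr.samples) < 5:
        raise HubError("need at least 5 samples")
    trait = np.array([1.0 if s.stage == trait_stage else 0.0
                      for s in expr.samples])
    if trait.std() == 0:
        raise HubError("constant trait vector")

    module_ids = sorted({m for m in modules.values()})
    eigengenes = {}
    for mod in module_ids:
        genes = [g for g, m in modules.items() if m == mod]
        eigengenes[mod] = module_eigengene(expr, genes)

    scores: list[HubScore] = []
    for gene in expr.genes:
        mod = modules.get(gene)
        if mod is None:
            continue
        profile = expr.values.loc[gene].to_numpy(dtype=float)
        if profile.std() == 0:
            continue
        mm = float(np.corrcoef(profile, eigengenes[mod])[0, 1])
        gs_r, gs_p = stats.pearsonr(profile, trait)
        scores.append(HubScore(gene, mod, mm, float(gs_r), float(gs_p)))
    return scores


@dataclass
class NeighborGroup:
    chrom: str
    genes: list[str]
    spacers: list[int]
    modes: list[str]

    @property
    def all_non_duplicated(self) -> bool:
        return all(m == "singleton" for m in self.modes)


def neighbor_groups(hubs: Sequence[HubScore], ann: GenomeAnnotation,
                    dup: Sequence[DuplicationCall] | None = None) -> list[NeighborGroup]:
    """Maximal runs (length >= 2) of hub genes at consecutive chromosome ranks.

    Spacers are the intergenic distances between successive members; member
    duplication modes are reported so the non-duplicated observation can be
    checked rather than assumed.
    """
    hub_ids = {h.gene_id for h in hubs if h.is_hub}
    mode_of = {c.gene_id: c.mode for c in dup} if dup else {}
    groups: list[NeighborGroup] = []
    for chrom in ann.chroms:
        run: list = []
        for gene in ann.genes_on(chrom):
            if gene.gene_id in hub_ids:
                run.append(gene)
            else:
                if len(run) >= 2:
                    groups.append(_make_group(chrom, run, mode_of))
                run = []
        if len(run) >= 2:
            groups.append(_make_group(chrom, run, mode_of))
    return groups


def _make_group(chrom: str, run: list, mode_of: Mapping[str, str]) -> NeighborGroup:
    spacers = [intergenic_spacer(a, b) for a, b in zip(run, run[1:])]
    return NeighborGroup(
        chrom=chrom,
        genes=[g.gene_id for g in run],
        spacers=spacers,
        modes=[mode_of.get(g.gene_id, "singleton") for g in run],
    )
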