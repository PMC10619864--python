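"""Planted-truth recovery metrics for synthetic bundles.

These helpers run the analysis stages on a :class:`~thermoss.simulate.SimBundle`
and score the results against the bundle's truth tables: island sensitivity and
false discoveries, duplication-mode recovery, DEG recall / false-positive rate,
the TRD ancestral-vs-novel expression contrast, and the trait-null GS rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import expression as xp
from . import duplication as dup
from . import islands as isl
from . import hubs as hb
from . import kaks
from .simulate import SimBundle, CONTRAST_STAGES


@dataclass
class PipelineResult:
    tpm: xp.ExpressionMatrix
    de: list[xp.DEResult]
    patterns: dict[str, set[str]]
    expressed: set[str]
    blocks: list[dup.CollinearBlock]
    calls: list[dup.DuplicationCall]
    islands_by_contrast: dict[str, list[isl.Island]]


def run_pipeline(bundle: SimBundle, de_method: str = "welch") -> PipelineResult:
    """Run expression -> DEG -> duplication -> island stages in memory.

    ``de_method`` may be "welch", "permutation", or "deseq2" (the canonical
    plug-in table route, backed by pydeseq2).
    """
    tpm = xp.counts_to_tpm(bundle.counts)
    if de_method == "deseq2":
        from .plugins import deseq2_de_table
        table = deseq2_de_table(bundle.counts)
        de = xp.call_degs(tpm, method="plugin", plugin_table=table)
    else:
        de = xp.call_degs(tpm, method=de_method)
    patterns = xp.pattern_sets(de)
    expressed = xp.expressed_genes(tpm)
    blocks = dup.chain_collinear_blocks(bundle.homolog_pairs, bundle.annotation)
    calls = dup.classify_duplicates(
        bundle.homolog_pairs, blocks, bundle.annotation,
        interspecies_anchors=bundle.interspecies_anchors,
    )
    islands_by_contrast = {}
    for stage in CONTRAST_STAGES:
        contrast = f"{stage}vsH0"
        pattern = patterns[f"{stage}UP"] & expressed
        islands_by_contrast[contrast] = isl.scan_islands(
            bundle.annotation, pattern, expressed, de=de, dup=calls,
            contrast=contrast,
        )
    return PipelineResult(tpm, de, patterns, expressed, blocks, calls,
                          islands_by_contrast)


def island_recovery(bundle: SimBundle, result: PipelineResult) -> tuple[float, float]:
    """(sensitivity over planted islands, false islands per chromosome).

    A planted island is recovered when a detected island of its contrast
    overlaps its span on the same chromosome; detected islands overlapping no
    planted island of their contrast are false.
    """
    planted = bundle.truth.islands
    recovered = 0
    false = 0
    for contrast, detected in result.islands_by_contrast.items():
        planted_here = [p for p in planted if p.contrast == contrast]
        for p in planted_here:
            if any(d.chrom == p.chrom and d.start <= p.end and d.end >= p.start
                   for d in detected):
                recovered += 1
        for d in detected:
            if not any(p.chrom == d.chrom and d.start <= p.end and d.end >= p.start
                       for p in planted_here):
                false += 1
    n_planted = len(planted)
    sens = recovered / n_planted if n_planted else float("nan")
    return sens, false / len(bundle.annotation.chroms)


def mode_recovery(bundle: SimBundle, result: PipelineResult,
                  modes: tuple[str, ...] = ("WGD", "TD", "PD")) -> float:
    """Fraction of planted genes of the given modes assigned the planted mode."""
    call_of = {c.gene_id: c.mode for c in result.calls}
    n = hit = 0
    for gene, (mode, _partner, _role) in bundle.truth.dup_modes.items():
        if mode in modes:
            n += 1
            hit += call_of[gene] == mode
    return hit / n if n else float("nan")


def deg_recall_fpr(bundle: SimBundle, result: PipelineResult) -> tuple[float, float]:
    """Recall of planted DE genes and false-positive rate among null genes,
    pooled over the four contrasts."""
    status = {(r.contrast, r.gene_id): r.status for r in result.de}
    affected = bundle.truth.de_effects
    # genes with any planted effect in a contrast's stage (islands, modules)
    # are excluded from the null set for that contrast
    non_null: dict[str, set[str]] = {c: set(a) for c, a in affected.items()}
    for isl_ in bundle.truth.islands:
        non_null.setdefault(isl_.contrast, set()).update(isl_.genes)
    module_genes = set(bundle.truth.modules)
    trd_genes = {g for g, (m, _p, _r) in bundle.truth.dup_modes.items() if m == "TRD"}

    n_pos = n_hit = n_null = n_fp = 0
    for contrast, eff in affected.items():
        for gene, fc in eff.items():
            n_pos += 1
            want = "up" if fc > 0 else "down"
            n_hit += status.get((contrast, gene)) == want
        excluded = non_null.get(contrast, set()) | module_genes | trd_genes
        for gene in bundle.counts.genes:
            if gene in excluded:
                continue
            n_null += 1
            n_fp += status.get((contrast, gene), "ns") != "ns"
    recall = n_hit / n_pos if n_pos else float("nan")
    fpr = n_fp / n_null if n_null else float("nan")
    return recall, fpr


def trd_contrast_report(bundle: SimBundle, result: PipelineResult) -> dict:
    return kaks.trd_expression_contrast(result.calls, result.tpm)


def _log_expr(result: PipelineResult) -> xp.ExpressionMatrix:
    log_tpm = np.log2(result.tpm.values + 1.0)
    return xp.ExpressionMatrix(log_tpm, result.tpm.samples, kind="TPM")


def gs_null_rate(bundle: SimBundle, result: PipelineResult,
                 trait_stage: str = "H1") -> float:
    """Rate at which trait-independent (null-module) genes reach GS >= 0.5."""
    scores = hb.hub_select(_log_expr(result), bundle.truth.modules, trait_stage)
    null_mod = bundle.truth.null_module
    null_scores = [s for s in scores if s.module == null_mod]
    if not null_scores:
        return float("nan")
    return sum(s.gs >= 0.5 for s in null_scores) / len(null_scores)


def heat_module_mm_rate(bundle: SimBundle, result: PipelineResult) -> float:
    """Fraction of planted heat-module genes with MM >= 0.6."""
    scores = hb.hub_select(_log_expr(result), bundle.truth.modules, "H1")
    hub_mod = bundle.truth.hub_module
    mod_scores = [s for s in scores if s.module == hub_mod]
    if not mod_scores:
        return float("nan")
    return sum(s.mm >= 0.6 for s in mod_scores) / len(mod_scores)
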