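"""Expression normalisation, DEG calling and stage pattern sets.

The study design is a heat-stress time course: control H0 and four stress
durations H1/H3/H6/H12 (hours at 42 °C), three biological replicates each.
Counts are normalised to TPM; each stress stage is contrasted against H0 and a
gene is a DEG when its fold change exceeds 2 with p < 0.05 (raw p, mirroring
the source analysis — Benjamini–Hochberg correction is available but off by
default). Pattern sets (H1UP ... H12UP / ...DOWN) collect DEGs per contrast.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("H0", "H1", "H3", "H6", "H12")
CONTRASTS = ("H1vsH0", "H3vsH0", "H6vsH0", "H12vsH0")
#: pseudocount added to mean TPM before the log2 ratio
LOG2FC_PSEUDOCOUNT = 1.0


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ExpressionError(f"unknown stage {self.stage!r}")
        if self.replicate < 1:
            raise ExpressionError("replicate must be >= 1")


def read_design(path: str) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    design = [
        SampleDesign(r.sample_id, r.stage, int(r.replicate))
        for r in df.itertuples()
    ]
    keys = {(d.stage, d.replicate) for d in design}
    if len(keys) != len(design):
        raise ExpressionError("duplicate (stage, replicate) in design")
    return design


def default_design(n_reps: int = 3) -> list[SampleDesign]:
    """The 5-stage x 3-replicate layout of the heat-stress experiment."""
    return [
        SampleDesign(f"{stage}_{rep}", stage, rep)
        for stage in STAGES
        for rep in range(1, n_reps + 1)
    ]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values (counts or TPM) as a DataFrame.

    ``values`` has gene ids as the index and sample ids as columns, ordered as
    in ``samples``. ``gene_lengths`` (bp) is required for kind="counts".
    """

    values: pd.DataFrame
    samples: list[SampleDesign]
    kind: str = "counts"
    gene_lengths: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "TPM"):
            raise ExpressionError(f"bad matrix kind {self.kind!r}")
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            self.values = self.values[sample_ids]
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def stage_columns(self, stage: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.stage == stage]


def read_counts(path: str, design: list[SampleDesign],
                gene_lengths: Mapping[str, float] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, design, kind="counts", gene_lengths=gene_lengths)


def counts_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Length-normalise counts to transcripts per million.

    TPM_gs = (count_gs / length_g) / sum_g(count_gs / length_g) * 1e6 within
    each sample; an all-zero sample column stays all-zero (with a warning).
    """
    if m.kind != "counts":
        raise ExpressionError("counts_to_tpm expects a counts matrix")
    if m.gene_lengths is None:
        raise ExpressionError("gene_lengths required for TPM normalisation")
    missing = [g for g in m.genes if g not in m.gene_lengths]
    if missing:
        raise ExpressionError(f"no length for gene(s): {', '.join(missing[:5])}")
    lengths = np.array([m.gene_lengths[g] for g in m.genes], dtype=float)
    if (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive")
    rate = m.values.to_numpy(dtype=float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn("all-zero sample column(s) left as zeros in TPM")
        colsum[zero_cols] = 1.0
    tpm = rate / colsum * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=m.values.index, columns=m.values.columns),
        m.samples, kind="TPM", gene_lengths=m.gene_lengths,
    )


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    contrast: str
    log2fc: float
    pvalue: float

    @property
    def status(self) -> str:
        """up / down / ns by the fold-change-2, p<0.05 rule."""
        if self.pvalue < 0.05:
            if self.log2fc > 1:
                return "up"
            if self.log2fc < -1:
                return "down"
        return "ns"


def _permutation_p(treated: np.ndarray, control: np.ndarray) -> float:
    """Exact two-sided label-permutation p for the mean difference.

    At 3 vs 3 the grid is k/20 over the C(6,3)=20 label assignments; the
    observed labelling is included, and complementary splits share |stat|, so
    the minimum attainable p is 2/20 = 0.1.
    """
    pooled = np.concatenate([treated, control])
    n_t = len(treated)
    obs = abs(treated.mean() - control.mean())
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_t):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        stat = abs(pooled[sel].mean() - pooled[~sel].mean())
        if stat >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def call_degs(m: ExpressionMatrix, method: str = "welch",
              plugin_table: pd.DataFrame | None = None,
              bh_correct: bool = False) -> list[DEResult]:
    """Call differential expression per contrast (H1/H3/H6/H12 vs H0).

    Internal methods ("welch", "permutation") test log2(TPM+1) per gene; the
    fold change is log2((mean treated TPM + 1)/(mean control TPM + 1)).
    Method "plugin" takes an external table (gene_id, contrast, log2fc,
    pvalue), e.g. exported from a count-model DE analysis.
    """
    if method == "plugin":
        if plugin_table is None:
            raise ExpressionError("plugin method needs a DE table")
        required = {"gene_id", "contrast", "log2fc", "pvalue"}
        if not required <= set(plugin_table.columns):
            raise ExpressionError(
                f"plugin table missing columns: {sorted(required - set(plugin_table.columns))}"
            )
        bad = set(plugin_table["contrast"]) - set(CONTRASTS)
        if bad:
            raise ExpressionError(f"unknown contrast label(s): {sorted(bad)}")
        return [
            DEResult(r.gene_id, r.contrast, float(r.log2fc), float(r.pvalue))
            for r in plugin_table.itertuples()
        ]

    if method not in ("welch", "permutation"):
        raise ExpressionError(f"unknown DE method {method!r}")
    if m.kind != "TPM":
        raise ExpressionError("internal DE methods expect a TPM matrix")

    ctrl_cols = m.stage_columns("H0")
    if len(ctrl_cols) < 2:
        raise ExpressionError("need >=2 H0 replicates")
    tpm = m.values
    log_tpm = np.log2(tpm.to_numpy(dtype=float) + 1.0)
    col_index = {c: i for i, c in enumerate(tpm.columns)}
    ctrl_idx = [col_index[c] for c in ctrl_cols]

    results: list[DEResult] = []
    for contrast in CONTRASTS:
        stage = contrast.split("vs")[0]
        trt_cols = m.stage_columns(stage)
        if len(trt_cols) < 2:
            raise ExpressionError(f"need >=2 replicates for {stage}")
        trt_idx = [col_index[c] for c in trt_cols]
        mean_t = tpm.iloc[:, trt_idx].mean(axis=1).to_numpy()
        mean_c = tpm.iloc[:, ctrl_idx].mean(axis=1).to_numpy()
        c = LOG2FC_PSEUDOCOUNT
        log2fc = np.log2(mean_t + c) - np.log2(mean_c + c)
        if method == "welch":
            with np.errstate(divide="ignore", invalid="ignore"):
                _, pvals = stats.ttest_ind(
                    log_tpm[:, trt_idx], log_tpm[:, ctrl_idx],
                    axis=1, equal_var=False,
                )
            pvals = np.where(np.isnan(pvals), 1.0, pvals)
        else:
            pvals = np.array([
                _permutation_p(log_tpm[i, trt_idx], log_tpm[i, ctrl_idx])
                for i in range(len(tpm))
            ])
        if bh_correct:
            pvals = _bh_adjust(pvals)
        results.extend(
            DEResult(g, contrast, float(fc), float(p))
            for g, fc, p in zip(tpm.index, log2fc, pvals)
        )
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        adj[order[i]] = running
    return adj


def pattern_sets(de: Iterable[DEResult]) -> dict[str, set[str]]:
    """Stage pattern sets H1UP..H12UP / H1DOWN..H12DOWN plus overlap-allowed
    unions ("UP_ANY", "DOWN_ANY"): a gene up at one stage and down at another
    is counted in both unions."""
    sets: dict[str, set[str]] = {}
    for contrast in CONTRASTS:
        stage = contrast.split("vs")[0]
        sets[f"{stage}UP"] = set()
        sets[f"{stage}DOWN"] = set()
    sets["UP_ANY"] = set()
    sets["DOWN_ANY"] = set()
    for r in de:
        stage = r.contrast.split("vs")[0]
        if r.status == "up":
            sets[f"{stage}UP"].add(r.gene_id)
            sets["UP_ANY"].add(r.gene_id)
        elif r.status == "down":
            sets[f"{stage}DOWN"].add(r.gene_id)
            sets["DOWN_ANY"].add(r.gene_id)
    return sets


def deg_genes(de: Iterable[DEResult]) -> set[str]:
    """Genes differentially expressed in one or more contrasts."""
    return {r.gene_id for r in de if r.status != "ns"}


def deg_summary(n_deg: int, n_total: int) -> float:
    """Percentage of DEGs among annotated genes, to 2 decimals."""
    if n_total <= 0:
        raise ExpressionError("n_total must be positive")
    if not 0 <= n_deg <= n_total:
        raise ExpressionError("need 0 <= n_deg <= n_total")
    return round(100.0 * n_deg / n_total, 2)


def expressed_genes(tpm: ExpressionMatrix, mean_tpm_gt: float = 2.0) -> set[str]:
    """Genes with mean TPM above the threshold across all samples (the
    co-expression input filter, also the island denominator)."""
    if tpm.kind != "TPM":
        raise ExpressionError("expressed_genes expects a TPM matrix")
    means = tpm.values.mean(axis=1)
    return set(means.index[means > mean_tpm_gt])
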