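"""Ka/Ks estimation for duplicated gene pairs (Nei–Gojobori 1986).

``align_codons`` pairs two CDS via a global protein alignment and back-maps to
codons; ``ng86`` then estimates Ka (nonsynonymous substitutions per
nonsynonymous site) and Ks (synonymous substitutions per synonymous site) by
the NG86 counting method with Jukes–Cantor multiple-hit correction. Pairs with
Ks > 5 are flagged saturated and excluded from downstream mode summaries, as
synonymous sites are unreliable that deep.

Site counting follows classic NG86: the synonymous fraction of a codon is the
number of synonymous one-step nucleotide changes over the three possible
changes, summed over the three positions and averaged between the two
sequences; N is the complement so S + N = 3 x (aligned codons) exactly.
Multi-hit codons average synonymous/nonsynonymous step counts over all
shortest substitution pathways with equal weights, excluding pathways that
traverse a stop codon; a codon pair whose every pathway hits a stop
contributes sites but no differences.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from scipy import stats

from .duplication import DuplicationCall
from .expression import ExpressionMatrix, STAGES

NUCS = "ACGT"
_CODE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)

SATURATION_KS = 5.0


class KaKsError(ValueError):
    pass


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in _STOPS:
        return None
    return _CODE[codon]


@dataclass
class CodonPairAlignment:
    gene_a: str
    gene_b: str
    codons: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.codons:
            raise KaKsError(
                f"{self.gene_a}/{self.gene_b}: no aligned codons retained"
            )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def _split_codons(cds: str, name: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise KaKsError(f"{name}: CDS length {len(cds)} not divisible by 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def align_codons(cds_a: str, cds_b: str, gene_a: str = "a",
                 gene_b: str = "b") -> CodonPairAlignment:
    """Protein-guided codon pairing of two CDS.

    Both CDS are translated (a single trailing stop codon is allowed and
    trimmed), the proteins are globally aligned (match 1, mismatch -1, gap -2,
    first alignment of the deterministic traceback), the alignment is
    back-mapped to codons and gapped or stop-containing columns are dropped.
    """
    codons_a = _split_codons(cds_a, gene_a)
    codons_b = _split_codons(cds_b, gene_b)
    if codons_a and codons_a[-1] in _STOPS:
        codons_a = codons_a[:-1]
    if codons_b and codons_b[-1] in _STOPS:
        codons_b = codons_b[:-1]
    prot_a = str(Seq("".join(codons_a)).translate())
    prot_b = str(Seq("".join(codons_b)).translate())
    if "*" in prot_a or "*" in prot_b:
        # internal stops: keep the columns out later, align on X placeholders
        prot_a = prot_a.replace("*", "X")
        prot_b = prot_b.replace("*", "X")
    alignment = _ALIGNER.align(prot_a, prot_b)[0]
    pairs: list[tuple[str, str]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            ca, cb = codons_a[i], codons_b[j]
            if ca in _STOPS or cb in _STOPS:
                continue
            if "N" in ca or "N" in cb:
                continue
            pairs.append((ca, cb))
    return CodonPairAlignment(gene_a, gene_b, pairs)


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    ka: float
    ks: float
    ratio: float
    saturated: bool
    mode: str = "n/a"


@lru_cache(maxsize=None)
def syn_fraction_sites(codon: str) -> float:
    """Synonymous site count of a codon: per position, the fraction of the
    three one-step changes that preserve the amino acid."""
    aa = translate_codon(codon)
    if aa is None:
        raise KaKsError(f"stop codon {codon} has no site count")
    s = 0.0
    for pos in range(3):
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if translate_codon(mutant) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts for one codon pair,
    averaged over all stop-free shortest substitution pathways."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    syn_counts: list[float] = []
    non_counts: list[float] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            aa_from, aa_to = translate_codon(current), translate_codon(nxt)
            if aa_to is None or aa_from is None:
                ok = False
                break
            if aa_from == aa_to:
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            syn_counts.append(sd)
            non_counts.append(nd)
    if not syn_counts:
        return (0.0, 0.0)
    return (sum(syn_counts) / len(syn_counts), sum(non_counts) / len(non_counts))


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); inf at p >= 3/4."""
    if p < 0:
        raise KaKsError("proportion must be >= 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(aln: CodonPairAlignment, mode: str = "n/a") -> KaKsResult:
    """NG86 Ka/Ks for one aligned codon pair list."""
    s_a = sum(syn_fraction_sites(ca) for ca, _ in aln.codons)
    s_b = sum(syn_fraction_sites(cb) for _, cb in aln.codons)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(aln.codons) - s_sites
    sd = nd = 0.0
    for ca, cb in aln.codons:
        ds, dn = pathway_differences(ca, cb)
        sd += ds
        nd += dn

    saturated = False
    if s_sites > 0:
        ps = sd / s_sites
        ks = jukes_cantor(ps)
        if not math.isfinite(ks):
            saturated = True
            ks = math.nan
    else:
        ks = math.nan
        if sd > 0:
            saturated = True
    if n_sites > 0:
        pn = nd / n_sites
        ka = jukes_cantor(pn)
        if not math.isfinite(ka):
            saturated = True
            ka = math.nan
    else:
        ka = math.nan
        if nd > 0:
            saturated = True

    if not saturated and not math.isnan(ks) and ks > SATURATION_KS:
        saturated = True
    if math.isnan(ks) or ks == 0.0 or math.isnan(ka):
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsResult(aln.gene_a, aln.gene_b, ka, ks, ratio, saturated, mode)


def kaks_for_pairs(cds: Mapping[str, str], pairing: Iterable[tuple[str, str]],
                   modes: Mapping[frozenset, str] | None = None) -> list[KaKsResult]:
    """Align and estimate Ka/Ks for each (gene_a, gene_b) CDS pair."""
    results = []
    for a, b in pairing:
        aln = align_codons(cds[a], cds[b], a, b)
        mode = "n/a"
        if modes is not None:
            mode = modes.get(frozenset((a, b)), "n/a")
        results.append(ng86(aln, mode))
    return results


def mode_divergence_summary(results: Iterable[KaKsResult]) -> dict:
    """Per-mode Ka/Ks distribution summaries plus pairwise rank-sum tests.

    Saturated pairs (Ks > 5 or correction-inapplicable) are excluded. Modes
    with fewer than 2 usable pairs are omitted with a warning.
    """
    by_mode: dict[str, list[float]] = {}
    for r in results:
        if r.saturated or math.isnan(r.ratio):
            continue
        by_mode.setdefault(r.mode, []).append(r.ratio)
    summaries: dict[str, dict] = {}
    for mode in sorted(by_mode):
        ratios = by_mode[mode]
        if len(ratios) < 2:
            warnings.warn(f"mode {mode}: fewer than 2 unsaturated pairs, omitted")
            continue
        arr = np.asarray(ratios)
        summaries[mode] = {
            "n": len(arr),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }
    tests: dict[tuple[str, str], float] = {}
    modes = sorted(summaries)
    for m1, m2 in itertools.combinations(modes, 2):
        stat = stats.ranksums(by_mode[m1], by_mode[m2])
        tests[(m1, m2)] = float(stat.pvalue)
    return {"summaries": summaries, "tests": tests}


def trd_expression_contrast(calls: Iterable[DuplicationCall],
                            tpm: ExpressionMatrix) -> dict[str, dict]:
    """Per-stage Wilcoxon rank-sum contrast of ancestral vs novel TRD genes.

    Expression per gene and stage is log2(mean TPM across replicates + 1);
    stages with fewer than 2 genes in either role are skipped with a warning.
    """
    ancestral = [c.gene_id for c in calls
                 if c.mode == "TRD" and c.trd_role == "ancestral"]
    novel = [c.gene_id for c in calls if c.mode == "TRD" and c.trd_role == "novel"]
    present = set(tpm.genes)
    ancestral = [g for g in ancestral if g in present]
    novel = [g for g in novel if g in present]
    report: dict[str, dict] = {}
    if not ancestral or not novel:
        return report
    for stage in STAGES:
        cols = tpm.stage_columns(stage)
        stage_mean = tpm.values[cols].mean(axis=1)
        anc = np.log2(stage_mean.loc[ancestral].to_numpy() + 1.0)
        nov = np.log2(stage_mean.loc[novel].to_numpy() + 1.0)
        if len(anc) < 2 or len(nov) < 2:
            warnings.warn(f"stage {stage}: fewer than 2 TRD genes per role, skipped")
            continue
        test = stats.ranksums(anc, nov)
        report[stage] = {
            "n_ancestral": len(anc),
            "n_novel": len(nov),
            "median_ancestral": float(np.median(anc)),
            "median_novel": float(np.median(nov)),
            "pvalue": float(test.pvalue),
        }
    return report
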