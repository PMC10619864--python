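"""Independent brute-force oracles.

Each oracle re-implements an operation in the most literal way possible —
per-position boolean arrays, exhaustive pathway enumeration, direct
eigen-decomposition, literal rule application — sharing no code with the
production implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# literal Nei-Gojobori (1986)


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_ng86(codons_a: list[str], codons_b: list[str]):
    """Literal NG86 on pre-paired codon lists: returns (Ka, Ks, saturated)."""
    assert len(codons_a) == len(codons_b)

    def syn_sites(codon: str) -> float:
        aa = _aa(codon)
        s = 0.0
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1:]
                if _aa(mutant) != "*" and _aa(mutant) == aa:
                    s += 1 / 3
        return s

    S = (sum(map(syn_sites, codons_a)) + sum(map(syn_sites, codons_b))) / 2
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        positions = [i for i in range(3) if ca[i] != cb[i]]
        if not positions:
            continue
        path_syn, path_non = [], []
        for order in itertools.permutations(positions):
            cur, sd, nd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if _aa(nxt) == "*":
                    ok = False
                    break
                if _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                path_syn.append(sd)
                path_non.append(nd)
        if path_syn:
            Sd += sum(path_syn) / len(path_syn)
            Nd += sum(path_non) / len(path_non)

    def jc(p):
        if p >= 0.75:
            return math.inf
        return -0.75 * math.log(1 - 4 * p / 3)

    saturated = False
    ks = jc(Sd / S) if S > 0 else math.nan
    ka = jc(Nd / N) if N > 0 else math.nan
    if not math.isfinite(ks) and not math.isnan(ks):
        ks, saturated = math.nan, True
    if not math.isfinite(ka) and not math.isnan(ka):
        ka, saturated = math.nan, True
    if not math.isnan(ks) and ks > 5.0:
        saturated = True
    return ka, ks, saturated, S, N


# ---------------------------------------------------------------------------
# per-position boolean coverage


def brute_coverage(intervals: list[tuple[int, int]], query_len: int) -> float:
    mask = np.zeros(query_len, dtype=bool)
    for s, e in intervals:
        mask[s - 1:e] = True
    return float(mask.sum()) / query_len


# ---------------------------------------------------------------------------
# literal duplication-mode rules


def brute_classify(genes, pairs, anchor_gene_set, interspecies, proximal_window=10):
    """Apply the WGD > TD > PD > TRD > DSD > singleton rules literally.

    ``genes``: mapping gene_id -> (chrom, rank); ``pairs``: list of
    (gene_a, gene_b, score).
    """
    by_gene = {}
    for a, b, score in pairs:
        by_gene.setdefault(a, []).append((b, score))
        by_gene.setdefault(b, []).append((a, score))

    def rank_dist(g1, g2):
        c1, r1 = genes[g1]
        c2, r2 = genes[g2]
        return abs(r1 - r2) if c1 == c2 else math.inf

    out = {}
    for g in genes:
        partners = by_gene.get(g, [])
        if not partners:
            out[g] = ("singleton", None, "n/a")
            continue
        best = min(partners, key=lambda t: (-t[1], rank_dist(g, t[0]), t[0]))[0]
        if g in anchor_gene_set:
            out[g] = ("WGD", None, "n/a")  # partner not checked by oracle
        elif any(rank_dist(g, p) == 1 for p, _ in partners):
            out[g] = ("TD", None, "n/a")
        elif any(2 <= rank_dist(g, p) <= proximal_window for p, _ in partners):
            out[g] = ("PD", None, "n/a")
        else:
            syn_g = g in anchor_gene_set or g in interspecies
            syn_b = best in anchor_gene_set or best in interspecies
            if syn_g != syn_b:
                out[g] = ("TRD", best, "ancestral" if syn_g else "novel")
            else:
                out[g] = ("DSD", best, "n/a")
    return out


# ---------------------------------------------------------------------------
# direct covariance eigen-decomposition


def brute_eigengene(matrix: np.ndarray) -> np.ndarray:
    """First PC scores of row-standardised ``matrix`` (genes x samples) via
    eigen-decomposition of the sample-by-sample covariance."""
    z = (matrix - matrix.mean(axis=1, keepdims=True)) / matrix.std(axis=1, keepdims=True)
    cov = z.T @ z
    w, v = np.linalg.eigh(cov)
    scores = v[:, np.argmax(w)]
    corr = np.sum([np.corrcoef(row, scores)[0, 1] for row in z])
    if abs(corr) < 1e-8:
        if scores[np.argmax(np.abs(scores))] < 0:
            scores = -scores
    elif corr < 0:
        scores = -scores
    scores = scores - scores.mean()
    return scores / scores.std()


# ---------------------------------------------------------------------------
# every-offset island windows


def brute_qualifying_regions(starts, is_pattern, max_pos, window_bp,
                             min_genes=3, min_fraction=0.6):
    """Union of ALL qualifying windows at every bp offset (not just
    gene-anchored ones), as merged [lo, hi] window regions."""
    starts = np.asarray(starts)
    is_pattern = np.asarray(is_pattern, dtype=bool)
    regions = []
    for s in range(1, max_pos + 1):
        in_win = (starts >= s) & (starts <= s + window_bp - 1)
        n_exp = in_win.sum()
        n_pat = (in_win & is_pattern).sum()
        if n_exp and n_pat >= min_genes and n_pat / n_exp > min_fraction:
            regions.append((s, s + window_bp - 1))
    merged = []
    for lo, hi in regions:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged
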