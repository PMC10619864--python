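"""Duplicated-gene mode classification from homolog pairs and collinearity.

Duplicate genes are sorted into five modes with a fixed precedence:

* WGD — the gene anchors an intra-genomic collinear block (whole-genome
  duplication remnant);
* TD  — tandem duplicate: homolog at the adjacent chromosome rank;
* PD  — proximal duplicate: homolog within a small rank window (default 10);
* TRD — transposed duplicate: exactly one member of the gene's best-scoring
  pair sits at a syntenic (ancestral) locus, the other at a novel locus;
* DSD — dispersed duplicate: any remaining homologous gene;
* singleton — no homolog at all.

Collinear blocks are chained on the gene-rank dot plot by dynamic programming
(score = number of anchors, per-step rank gap bounded on both axes, orientation
same or consistently inverted), a deterministic simplification of MCScanX-style
collinearity. Defaults min_block=5, max_gap=25, proximal_window=10 follow the
DupGen_finder workflow.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GenomeAnnotation

MODES = ("WGD", "TD", "PD", "TRD", "DSD", "singleton")
DUPLICATED_MODES = ("WGD", "TD", "PD", "TRD", "DSD")


class DuplicationError(ValueError):
    pass


@dataclass(frozen=True)
class HomologPair:
    """An unordered homologous gene pair, stored with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DuplicationError(f"self-pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    def other(self, gene_id: str) -> str:
        return self.gene_b if gene_id == self.gene_a else self.gene_a


@dataclass
class CollinearBlock:
    anchors: list[HomologPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.anchors:
            out.add(p.gene_a)
            out.add(p.gene_b)
        return out


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: str
    partner: str | None = None
    trd_role: str = "n/a"  # ancestral | novel | n/a

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DuplicationError(f"bad mode {self.mode!r}")
        if (self.mode == "singleton") != (self.partner is None):
            raise DuplicationError("partner must be None iff singleton")
        if (self.trd_role != "n/a") and self.mode != "TRD":
            raise DuplicationError("trd_role only valid for TRD calls")


def read_pairs(path: str) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t")
    return [HomologPair(r.gene_a, r.gene_b, float(r.score)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# collinear block chaining


def _best_chain(dots: Sequence[tuple[int, int, int]], max_gap: int,
                inverted: bool) -> list[int]:
    """Highest-anchor chain over (x, y, id) dots; returns dot indices.

    x strictly increases; y strictly increases (same) or decreases (inverted);
    per-step gap <= max_gap on both axes. Ties broken toward the leftmost
    chain start, then smallest y, making the result order-independent.
    """
    n = len(dots)
    order = sorted(range(n), key=lambda i: (dots[i][0], dots[i][1]))
    best_len = [1] * n
    prev = [-1] * n
    for oi in range(len(order)):
        i = order[oi]
        xi, yi, _ = dots[i]
        for oj in range(oi):
            j = order[oj]
            xj, yj, _ = dots[j]
            if xj >= xi or xi - xj > max_gap:
                continue
            if inverted:
                if yj <= yi or yj - yi > max_gap:
                    continue
            else:
                if yj >= yi or yi - yj > max_gap:
                    continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -dots[i][0], -dots[i][1]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    chain.reverse()
    return chain


def chain_collinear_blocks(pairs: Iterable[HomologPair], ann: GenomeAnnotation,
                           min_block: int = 5, max_gap: int = 25) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks on the rank dot plot."""
    if min_block < 2:
        raise DuplicationError("min_block must be >= 2")
    by_cpair: dict[tuple[str, str], list[tuple[int, int, HomologPair]]] = defaultdict(list)
    for p in pairs:
        ga, gb = ann.get(p.gene_a), ann.get(p.gene_b)
        if (ga.chrom, ga.rank) <= (gb.chrom, gb.rank):
            key = (ga.chrom, gb.chrom)
            dot = (ga.rank, gb.rank, p)
        else:
            key = (gb.chrom, ga.chrom)
            dot = (gb.rank, ga.rank, p)
        by_cpair[key].append(dot)

    blocks: list[CollinearBlock] = []
    for key in sorted(by_cpair):
        remaining = sorted(by_cpair[key], key=lambda d: (d[0], d[1]))
        while True:
            indexed = [(d[0], d[1], i) for i, d in enumerate(remaining)]
            candidates = []
            for inverted in (False, True):
                chain = _best_chain(indexed, max_gap, inverted)
                if len(chain) >= min_block:
                    start_x = indexed[chain[0]][0]
                    candidates.append((len(chain), -start_x, not inverted, chain, inverted))
            if not candidates:
                break
            _, _, _, chain, inverted = max(candidates)
            # A real intra-chromosomal block has its two copies at disjoint
            # rank intervals; near-diagonal chains of tandem/proximal dots
            # would otherwise masquerade as collinear blocks. Such chains
            # consume their dots but are not emitted.
            valid = True
            if key[0] == key[1]:
                xs = [remaining[i][0] for i in chain]
                ys = [remaining[i][1] for i in chain]
                if not (max(xs) < min(ys) or max(ys) < min(xs)):
                    valid = False
            if valid:
                anchors = [remaining[i][2] for i in chain]
                blocks.append(CollinearBlock(
                    anchors=anchors, chrom_a=key[0], chrom_b=key[1],
                    orientation="inverted" if inverted else "same",
                ))
            used = set(chain)
            remaining = [d for i, d in enumerate(remaining) if i not in used]
    return blocks


def anchor_genes(blocks: Iterable[CollinearBlock]) -> set[str]:
    out: set[str] = set()
    for b in blocks:
        out |= b.genes
    return out


# ---------------------------------------------------------------------------
# mode classification


def _rank_distance(ann: GenomeAnnotation, a: str, b: str) -> float:
    ga, gb = ann.get(a), ann.get(b)
    if ga.chrom != gb.chrom:
        return float("inf")
    return abs(ga.rank - gb.rank)


def _best_pair(gene: str, gene_pairs: Sequence[HomologPair],
               ann: GenomeAnnotation) -> HomologPair:
    """Highest score; ties by smaller rank distance, then partner id."""
    return min(
        gene_pairs,
        key=lambda p: (-p.score, _rank_distance(ann, gene, p.other(gene)),
                       p.other(gene)),
    )


def classify_duplicates(pairs: Iterable[HomologPair], blocks: Iterable[CollinearBlock],
                        ann: GenomeAnnotation, proximal_window: int = 10,
                        interspecies_anchors: set[str] | None = None) -> list[DuplicationCall]:
    """Assign exactly one duplication mode to every annotated gene.

    ``interspecies_anchors`` lists genes with syntenic support against an
    outgroup genome; together with intra-genomic block anchors they define
    the ancestral loci used by the TRD rule.
    """
    interspecies = interspecies_anchors or set()
    anchor_set = anchor_genes(blocks)
    pair_list = list(pairs)
    by_gene: dict[str, list[HomologPair]] = defaultdict(list)
    for p in pair_list:
        for g in (p.gene_a, p.gene_b):
            if g not in ann:
                raise DuplicationError(f"pair references unknown gene {g!r}")
        by_gene[p.gene_a].append(p)
        by_gene[p.gene_b].append(p)

    calls: list[DuplicationCall] = []
    for g in ann.genes:
        gid = g.gene_id
        gene_pairs = by_gene.get(gid, [])
        if not gene_pairs:
            calls.append(DuplicationCall(gid, "singleton"))
            continue
        best = _best_pair(gid, gene_pairs, ann)
        if gid in anchor_set:
            anchor_pairs = [p for p in gene_pairs
                            if p.gene_a in anchor_set and p.gene_b in anchor_set]
            partner_pair = _best_pair(gid, anchor_pairs, ann) if anchor_pairs else best
            calls.append(DuplicationCall(gid, "WGD", partner_pair.other(gid)))
            continue
        same_chrom = [p for p in gene_pairs
                      if _rank_distance(ann, gid, p.other(gid)) == 1]
        if same_chrom:
            calls.append(DuplicationCall(
                gid, "TD", _best_pair(gid, same_chrom, ann).other(gid)))
            continue
        proximal = [p for p in gene_pairs
                    if 2 <= _rank_distance(ann, gid, p.other(gid)) <= proximal_window]
        if proximal:
            calls.append(DuplicationCall(
                gid, "PD", _best_pair(gid, proximal, ann).other(gid)))
            continue
        partner = best.other(gid)
        syn_self = gid in anchor_set or gid in interspecies
        syn_partner = partner in anchor_set or partner in interspecies
        if syn_self != syn_partner:
            role = "ancestral" if syn_self else "novel"
            calls.append(DuplicationCall(gid, "TRD", partner, role))
            continue
        calls.append(DuplicationCall(gid, "DSD", partner))
    return calls


def mode_census(calls: Iterable[DuplicationCall]) -> dict:
    """Per-mode counts, duplicated total and percentage of the genome."""
    counts = {m: 0 for m in MODES}
    n = 0
    for c in calls:
        counts[c.mode] += 1
        n += 1
    return census_from_counts({m: counts[m] for m in DUPLICATED_MODES}, n)


def census_from_counts(mode_counts: Mapping[str, int], n_total: int) -> dict:
    """Census summary from per-mode counts (e.g. a published table row)."""
    duplicated = sum(mode_counts.get(m, 0) for m in DUPLICATED_MODES)
    if n_total <= 0:
        raise DuplicationError("n_total must be positive")
    return {
        "counts": dict(mode_counts),
        "n_total": n_total,
        "duplicated_total": duplicated,
        "duplicated_percent": round(100.0 * duplicated / n_total, 2),
    }
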