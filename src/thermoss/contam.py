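"""Assembly contamination screening by taxon-class interval-union coverage.

For each assembly query sequence, the fraction of its length covered by the
union of alignment hit intervals from non-target (e.g. non-embryophyte)
subjects is computed; a query with non-target coverage strictly greater than
50% is called contaminating and removed. Positions covered by both target and
non-target hits count fully toward non-target coverage (no subtraction; the
convention is recorded in the output metadata). Taxon classing of subjects is
an input column — no taxonomy database is consulted here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

TAXON_CLASSES = ("target", "non_target")

#: outfmt-6 column names, to which a taxon_class column is appended
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class ContamError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    query_len: int
    q_start: int
    q_end: int
    taxon_class: str

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            lo, hi = self.q_end, self.q_start
            object.__setattr__(self, "q_start", lo)
            object.__setattr__(self, "q_end", hi)
        if not 1 <= self.q_start <= self.q_end <= self.query_len:
            raise ContamError(
                f"{self.query_id}: hit [{self.q_start}, {self.q_end}] outside "
                f"[1, {self.query_len}]"
            )
        if self.taxon_class not in TAXON_CLASSES:
            raise ContamError(f"bad taxon_class {self.taxon_class!r}")


@dataclass(frozen=True)
class CoverageVerdict:
    query_id: str
    non_target_coverage: float
    target_coverage: float

    @property
    def verdict(self) -> str:
        return "remove" if self.non_target_coverage > 0.5 else "keep"


def union_coverage(hits: Sequence[HitRecord], class_filter: str) -> float:
    """Fraction of the query covered by the union of hits of one class."""
    if not hits:
        return 0.0
    qids = {h.query_id for h in hits}
    qlens = {h.query_len for h in hits}
    if len(qids) > 1 or len(qlens) > 1:
        raise ContamError("hits must share query_id and query_len")
    query_len = hits[0].query_len
    intervals = sorted(
        (h.q_start, h.q_end) for h in hits if h.taxon_class == class_filter
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in intervals:
        if cur_end is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered / query_len


def screen_queries(hits: Iterable[HitRecord],
                   all_query_lens: dict[str, int] | None = None) -> list[CoverageVerdict]:
    """Keep/remove verdict per query by the strict >50% non-target rule.

    ``all_query_lens`` may list queries with no hits at all; these are kept
    with zero coverage.
    """
    by_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    query_ids = set(by_query)
    if all_query_lens is not None:
        query_ids |= set(all_query_lens)
    verdicts = []
    for qid in sorted(query_ids):
        qhits = by_query.get(qid, [])
        if qhits:
            nt = union_coverage(qhits, "non_target")
            tg = union_coverage(qhits, "target")
        else:
            nt = tg = 0.0
        verdicts.append(CoverageVerdict(qid, nt, tg))
    return verdicts


def read_hits(hits_path: str, query_lens_path: str) -> tuple[list[HitRecord], dict[str, int]]:
    """Read an outfmt-6-style hits TSV (with appended taxon_class column) and
    a query-length sidecar TSV (query_id, query_len)."""
    lens_df = pd.read_csv(query_lens_path, sep="\t")
    query_lens = dict(zip(lens_df["query_id"], lens_df["query_len"].astype(int)))
    cols = list(OUTFMT6_COLUMNS) + ["taxon_class"]
    df = pd.read_csv(hits_path, sep="\t", names=cols, comment="#")
    hits = []
    for r in df.itertuples():
        if r.qseqid not in query_lens:
            raise ContamError(f"no query_len for {r.qseqid!r}")
        hits.append(HitRecord(
            query_id=r.qseqid, query_len=query_lens[r.qseqid],
            q_start=int(r.qstart), q_end=int(r.qend),
            taxon_class=str(r.taxon_class),
        ))
    return hits, query_lens
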