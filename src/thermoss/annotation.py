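"""Gene-level genome annotation: GFF3 IO, chromosome rank order, intergenic spacers.

All coordinates are 1-based inclusive (GFF3 native). Every module downstream —
island scanning, duplication adjacency, neighbour-group spacers — works off the
per-chromosome *rank* order defined here: genes sorted by ascending start, ties
broken by ascending end, then lexicographic gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene locus. ``rank`` is the 0-based index along its chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Ordered gene models plus chromosome lengths.

    Ranks are (re)assigned atomically on construction; the invariant that rank
    strictly increases with start along each chromosome always holds.
    """

    genes: list[GeneModel] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rerank()
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            seen: set[str] = set()
            for g in self.genes:
                if g.gene_id in seen:
                    raise AnnotationError(f"duplicate gene ID {g.gene_id!r}")
                seen.add(g.gene_id)
        for g in self.genes:
            clen = self.chrom_lengths.get(g.chrom)
            if clen is not None and g.end > clen:
                raise AnnotationError(
                    f"gene {g.gene_id} end {g.end} exceeds length {clen} of {g.chrom}"
                )

    def _rerank(self) -> None:
        ordered: list[GeneModel] = []
        for chrom in sorted({g.chrom for g in self.genes}):
            on_chrom = sorted(
                (g for g in self.genes if g.chrom == chrom),
                key=lambda g: (g.start, g.end, g.gene_id),
            )
            for rank, g in enumerate(on_chrom):
                ordered.append(
                    GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand, rank)
                )
        self.genes = ordered

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene {gene_id!r}") from None

    @property
    def chroms(self) -> list[str]:
        return sorted({g.chrom for g in self.genes})

    def genes_on(self, chrom: str) -> list[GeneModel]:
        """Genes on one chromosome in rank order."""
        return sorted(
            (g for g in self.genes if g.chrom == chrom), key=lambda g: g.rank
        )


def read_gff3(path: str) -> GenomeAnnotation:
    """Read gene features from a GFF3 file into a :class:`GenomeAnnotation`.

    Only ``gene`` features are read; each must carry an ``ID`` attribute.
    ``##sequence-region`` pragmas populate chromosome lengths when present.
    """
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
                raise AnnotationError(
                    f"{path}: malformed GFF3 at line {lineno}: expected 9 "
                    "tab-separated fields with numeric start/end"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(
                    f"{path}: malformed GFF3 at line {lineno}: {exc}"
                ) from exc
            if feat.featuretype != "gene":
                continue
            ids = feat.attributes.get("ID")
            if not ids:
                raise AnnotationError(
                    f"{path}: gene feature without ID at line {lineno}"
                )
            genes.append(
                GeneModel(ids[0], feat.seqid, feat.start, feat.end, feat.strand)
            )
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)


def write_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Write genes back out as minimal GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in ann.chroms:
            clen = ann.chrom_lengths.get(chrom)
            if clen is not None:
                fh.write(f"##sequence-region {chrom} 1 {clen}\n")
        for g in ann.genes:
            fh.write(
                f"{g.chrom}\tthermoss\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def intergenic_spacer(a: GeneModel, b: GeneModel) -> int:
    """Bases strictly between two rank-adjacent gene bodies.

    Overlapping gene bodies clamp to 0 (the overlap is logged). Abutting genes
    (b.start == a.end + 1) give 0.
    """
    if a.chrom != b.chrom:
        raise AnnotationError(
            f"{a.gene_id} and {b.gene_id} are on different chromosomes"
        )
    if a.rank + 1 != b.rank:
        raise AnnotationError(
            f"{a.gene_id} (rank {a.rank}) and {b.gene_id} (rank {b.rank}) "
            "are not rank-adjacent"
        )
    spacer = b.start - a.end - 1
    if spacer < 0:
        logger.warning(
            "gene bodies of %s and %s overlap (%d bp); spacer clamped to 0",
            a.gene_id, b.gene_id, -spacer,
        )
        return 0
    return spacer
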