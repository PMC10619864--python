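"""Synthetic multi-chromosome genome with planted truth for every pipeline stage.

The generator emulates the heat-stress study design — a small moss-like genome
with realistic gene spacing, a 5-stage (H0/H1/H3/H6/H12) x 3-replicate
negative-binomial count matrix, duplication events of every mode, physical
islands of co-upregulated genes, a planted heat-responsive co-expression
module, and contaminated assembly scaffolds. Every planted entity is recorded
in a truth table emitted alongside the data; the pipeline never sees the
truth. A single integer seed fully determines the bundle.

Planted islands are compact runs of 4-8 co-upregulated genes flanked by
gene-free buffers of one scan-window length, so that each planted island
satisfies the island definition by construction and recovery measures the
pipeline, not layout luck.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, GenomeAnnotation, write_gff3
from .expression import ExpressionMatrix, SampleDesign, STAGES, default_design
from .duplication import HomologPair
from .kaks import NUCS, translate_codon, _STOPS

CONTRAST_STAGES = ("H1", "H3", "H6", "H12")


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters. Defaults mirror the study design (5 stages x 3
    replicates) at a desk-scale genome."""

    seed: int = 0
    # genome layout
    n_chroms: int = 4
    genes_per_chrom: int = 250
    mean_gene_len: int = 1500
    mean_intergenic: int = 6000
    # islands
    n_planted_islands: int = 5
    island_genes_min: int = 4
    island_genes_max: int = 8
    island_span_bp: int = 40_000
    island_log2fc: float = 3.0
    window_bp: int = 50_000  # buffer length used to isolate planted islands
    # duplication events
    n_tandem: int = 20
    n_proximal: int = 20
    n_block_dup: int = 2
    block_len: int = 8
    n_trd: int = 35
    n_dsd: int = 30
    proximal_max_rank: int = 10
    # expression
    n_reps: int = 3
    de_fraction: float = 0.05
    de_up_share: float = 0.38  # the study saw ~1.6x more down- than upregulated
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = float(np.log(500.0))
    baseline_log_sd: float = 0.8
    trd_novel_expression_ratio: float = 0.25  # ancestral gets 4x the novel copy
    # co-expression modules
    n_heat_module_genes: int = 60
    n_other_module_genes: int = 40
    n_null_module_genes: int = 60
    # Ka/Ks sequence divergence: per-mode (synonymous, nonsynonymous)
    # per-codon mutation probabilities; TD/PD diverge under weaker purifying
    # selection (higher Ka/Ks) than WGD remnants
    cds_codons: int = 100
    codon_divergence: dict = field(default_factory=lambda: {
        "WGD": (0.50, 0.08),
        "TD": (0.30, 0.18),
        "PD": (0.30, 0.15),
        "TRD": (0.40, 0.12),
        "DSD": (0.40, 0.10),
    })
    # contamination screen
    n_queries: int = 20
    n_contaminant_queries: int = 5
    query_len: int = 10_000

    def __post_init__(self) -> None:
        if self.island_genes_min < 3 or self.island_genes_max < self.island_genes_min:
            raise SimulationError("bad island gene-count range")
        if self.n_planted_islands > self.n_chroms * 3:
            raise SimulationError("too many islands for the genome layout")


@dataclass
class PlantedIsland:
    chrom: str
    start: int
    end: int
    genes: list[str]
    contrast: str


@dataclass
class TruthTables:
    """Planted ground truth; emitted next to the data, never consumed by it."""

    islands: list[PlantedIsland] = field(default_factory=list)
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    dup_modes: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    modules: dict[str, str] = field(default_factory=dict)
    hub_module: str = "M1"
    null_module: str = "M3"
    contaminants: set[str] = field(default_factory=set)


@dataclass
class SimBundle:
    config: SimConfig
    annotation: GenomeAnnotation
    design: list[SampleDesign]
    counts: ExpressionMatrix
    homolog_pairs: list[HomologPair]
    interspecies_anchors: set[str]
    cds: dict[str, str]
    cds_pairs: list[tuple[str, str]]
    hits: pd.DataFrame
    query_lens: dict[str, int]
    modules: dict[str, str]
    truth: TruthTables

    def write(self, outdir: str) -> dict[str, str]:
        """Write the whole bundle as plain-text files; returns name -> path."""
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}

        def p(name: str) -> str:
            paths[name] = os.path.join(outdir, name)
            return paths[name]

        write_gff3(self.annotation, p("genome.gff3"))
        records = [SeqRecord(Seq(self.cds[g]), id=g, description="")
                   for g in sorted(self.cds)]
        SeqIO.write(records, p("cds.fasta"), "fasta")
        pd.DataFrame(self.cds_pairs, columns=["gene_a", "gene_b"]).to_csv(
            p("cds_pairs.tsv"), sep="\t", index=False)
        self.counts.values.to_csv(p("counts.tsv"), sep="\t")
        pd.DataFrame(
            [(s.sample_id, s.stage, s.replicate) for s in self.design],
            columns=["sample_id", "stage", "replicate"],
        ).to_csv(p("design.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(h.gene_a, h.gene_b, h.score) for h in self.homolog_pairs],
            columns=["gene_a", "gene_b", "score"],
        ).to_csv(p("homolog_pairs.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(self.interspecies_anchors), columns=["gene_id"],
        ).to_csv(p("interspecies_anchors.tsv"), sep="\t", index=False)
        self.hits.to_csv(p("blast_hits.tsv"), sep="\t", index=False, header=False)
        pd.DataFrame(
            sorted(self.query_lens.items()), columns=["query_id", "query_len"],
        ).to_csv(p("query_lens.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(self.modules.items()), columns=["gene_id", "module"],
        ).to_csv(p("modules.tsv"), sep="\t", index=False)
        # truth tables
        pd.DataFrame(
            [(i.chrom, i.start, i.end, ",".join(i.genes), i.contrast)
             for i in self.truth.islands],
            columns=["chrom", "start", "end", "genes", "contrast"],
        ).to_csv(p("truth_islands.tsv"), sep="\t", index=False)
        de_rows = [
            (contrast, gene, fc)
            for contrast in sorted(self.truth.de_effects)
            for gene, fc in sorted(self.truth.de_effects[contrast].items())
        ]
        pd.DataFrame(de_rows, columns=["contrast", "gene_id", "log2fc"]).to_csv(
            p("truth_de.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(g,) + self.truth.dup_modes[g] for g in sorted(self.truth.dup_modes)],
            columns=["gene_id", "mode", "partner", "trd_role"],
        ).to_csv(p("truth_duplications.tsv"), sep="\t", index=False)
        pd.DataFrame(
            sorted(self.truth.contaminants), columns=["query_id"],
        ).to_csv(p("truth_contaminants.tsv"), sep="\t", index=False)
        return paths

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length for g in self.annotation.genes}


# ---------------------------------------------------------------------------


def _lay_out_genome(cfg: SimConfig, rng: np.random.Generator):
    """Place genes chromosome by chromosome with exponential intergenic gaps;
    island runs are compact and buffered by one window length on both sides."""
    island_sites: list[tuple[int, int, int]] = []  # (chrom_idx, start_gene_idx, k)
    per_chrom_sites: dict[int, list[tuple[int, int]]] = {c: [] for c in range(cfg.n_chroms)}
    for i in range(cfg.n_planted_islands):
        c = i % cfg.n_chroms
        k = int(rng.integers(cfg.island_genes_min, cfg.island_genes_max + 1))
        for _ in range(100):
            start = int(rng.integers(15, cfg.genes_per_chrom - 15 - k))
            if all(abs(start - s) > k + ks + 5 for s, ks in per_chrom_sites[c]):
                per_chrom_sites[c].append((start, k))
                island_sites.append((c, start, k))
                break
        else:
            raise SimulationError("could not place island (layout infeasible)")

    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    island_gene_ids: list[list[str]] = [[] for _ in island_sites]
    for c in range(cfg.n_chroms):
        chrom = f"Chr{c + 1:02d}"
        in_island = {}
        for si, (ci, start, k) in enumerate(island_sites):
            if ci == c:
                for j in range(k):
                    in_island[start + j] = (si, j == 0, j == k - 1)
        pos = 1 + int(rng.integers(100, 2000))
        for i in range(cfg.genes_per_chrom):
            isl = in_island.get(i)
            if isl is not None and isl[1]:  # first island gene: leading buffer
                pos += cfg.window_bp
            if isl is not None:
                length = min(300 + int(rng.exponential(1200)), 2500)
            else:
                length = 300 + int(rng.exponential(cfg.mean_gene_len - 300))
            gid = f"NJ{c + 1:02d}G{(i + 1) * 10:06d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, chrom, pos, pos + length - 1, strand))
            if isl is not None:
                island_gene_ids[isl[0]].append(gid)
            if isl is not None and isl[2]:  # last island gene: trailing buffer
                gap = cfg.window_bp
            elif isl is not None:
                gap = min(100 + int(rng.exponential(1500)), 2800)
            else:
                gap = 100 + int(rng.exponential(cfg.mean_intergenic - 100))
            pos += length + gap
        chrom_lengths[chrom] = pos + 1000
    ann = GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)
    islands = []
    for (c, _start, _k), gids in zip(island_sites, island_gene_ids):
        models = [ann.get(g) for g in gids]
        islands.append(PlantedIsland(
            chrom=f"Chr{c + 1:02d}",
            start=min(m.start for m in models),
            end=max(m.end for m in models),
            genes=gids,
            contrast="",  # assigned later
        ))
        span = islands[-1].end - islands[-1].start + 1
        if span > cfg.island_span_bp:
            raise SimulationError(f"island span {span} exceeds {cfg.island_span_bp}")
    return ann, islands


def _plant_duplications(cfg: SimConfig, rng: np.random.Generator,
                        ann: GenomeAnnotation, used: set[str]):
    """Select disjoint gene sets for each duplication mode."""
    by_chrom = {c: ann.genes_on(c) for c in ann.chroms}
    chroms = ann.chroms
    pairs: list[HomologPair] = []
    anchors: set[str] = set()
    truth: dict[str, tuple[str, str, str]] = {}

    def free_run(chrom: str, length: int) -> list[str] | None:
        genes = by_chrom[chrom]
        for _ in range(200):
            start = int(rng.integers(0, len(genes) - length))
            run = [g.gene_id for g in genes[start:start + length]]
            if all(g not in used for g in run):
                return run
        return None

    def free_gene(chrom: str) -> str | None:
        genes = by_chrom[chrom]
        for _ in range(200):
            g = genes[int(rng.integers(0, len(genes)))].gene_id
            if g not in used:
                return g
        return None

    def add_pair(a: str, b: str, mode: str, roles=("n/a", "n/a")) -> None:
        pairs.append(HomologPair(a, b, float(np.round(rng.uniform(50, 100), 3))))
        used.update((a, b))
        truth[a] = (mode, b, roles[0])
        truth[b] = (mode, a, roles[1])

    for bi in range(cfg.n_block_dup):
        ca = chroms[bi % len(chroms)]
        cb = chroms[(bi + 1) % len(chroms)]
        src = free_run(ca, cfg.block_len)
        tgt = free_run(cb, cfg.block_len)
        if src is None or tgt is None:
            raise SimulationError("no room for a duplicated block")
        for a, b in zip(src, tgt):
            add_pair(a, b, "WGD")
            anchors.update((a, b))

    for _ in range(cfg.n_tandem):
        for _ in range(200):
            c = chroms[int(rng.integers(0, len(chroms)))]
            genes = by_chrom[c]
            r = int(rng.integers(0, len(genes) - 1))
            a, b = genes[r].gene_id, genes[r + 1].gene_id
            if a not in used and b not in used:
                add_pair(a, b, "TD")
                break

    for _ in range(cfg.n_proximal):
        for _ in range(200):
            c = chroms[int(rng.integers(0, len(chroms)))]
            genes = by_chrom[c]
            d = int(rng.integers(2, cfg.proximal_max_rank + 1))
            r = int(rng.integers(0, len(genes) - d))
            a, b = genes[r].gene_id, genes[r + d].gene_id
            if a not in used and b not in used:
                add_pair(a, b, "PD")
                break

    interspecies: set[str] = set()
    for i in range(cfg.n_trd):
        ca = chroms[i % len(chroms)]
        cb = chroms[(i + 1 + int(rng.integers(0, len(chroms) - 1))) % len(chroms)]
        if cb == ca:
            cb = chroms[(i + 1) % len(chroms)]
        anc, nov = free_gene(ca), free_gene(cb)
        if anc is None or nov is None:
            raise SimulationError("no room for a transposed duplication")
        add_pair(anc, nov, "TRD", ("ancestral", "novel"))
        interspecies.add(anc)

    for i in range(cfg.n_dsd):
        ca = chroms[i % len(chroms)]
        cb = chroms[(i + 2) % len(chroms)]
        a, b = free_gene(ca), free_gene(cb)
        if a is None or b is None:
            raise SimulationError("no room for a dispersed duplication")
        add_pair(a, b, "DSD")

    return pairs, anchors, interspecies, truth


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(NUCS[i] for i in rng.integers(0, 4, size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return codons


def _mutate_cds(rng: np.random.Generator, codons: list[str],
                syn_rate: float, nonsyn_rate: float) -> list[str]:
    """Apply per-codon synonymous / nonsynonymous one-step changes."""
    out = []
    for codon in codons:
        new = codon
        if rng.random() < syn_rate:
            aa = translate_codon(new)
            options = []
            for pos in range(3):
                for nt in NUCS:
                    if nt == new[pos]:
                        continue
                    cand = new[:pos] + nt + new[pos + 1:]
                    if cand not in _STOPS and translate_codon(cand) == aa:
                        options.append(cand)
            if options:
                new = options[int(rng.integers(0, len(options)))]
        if rng.random() < nonsyn_rate:
            aa = translate_codon(new)
            options = []
            for pos in range(3):
                for nt in NUCS:
                    if nt == new[pos]:
                        continue
                    cand = new[:pos] + nt + new[pos + 1:]
                    if cand not in _STOPS and translate_codon(cand) != aa:
                        options.append(cand)
            if options:
                new = options[int(rng.integers(0, len(options)))]
        out.append(new)
    return out


def _make_hits(cfg: SimConfig, rng: np.random.Generator):
    """Tabular alignment hits with planted contaminant scaffolds (>50%
    non-target interval-union coverage)."""
    rows = []
    query_lens: dict[str, int] = {}
    contaminants: set[str] = set()
    L = cfg.query_len

    def hit_row(qid, qs, qe, taxon):
        rows.append((
            qid, f"subj{int(rng.integers(1, 1000)):04d}",
            float(np.round(rng.uniform(75, 99), 2)), qe - qs + 1,
            int(rng.integers(0, 50)), int(rng.integers(0, 5)),
            qs, qe, 1, qe - qs + 1,
            float(np.format_float_scientific(10 ** -rng.uniform(6, 50), precision=2)),
            float(np.round(rng.uniform(50, 2000), 1)), taxon,
        ))

    for q in range(cfg.n_queries):
        qid = f"scaffold{q + 1:03d}"
        query_lens[qid] = L
        if q < cfg.n_contaminant_queries:
            contaminants.add(qid)
            cov = rng.uniform(0.55, 0.9)
            covered = int(cov * L)
            n_iv = int(rng.integers(2, 5))
            bounds = sorted(rng.integers(1, covered, size=n_iv - 1).tolist())
            edges = [1] + [int(b) for b in bounds] + [covered]
            for s, e in zip(edges[:-1], edges[1:]):
                if e > s:
                    hit_row(qid, s, min(e + int(rng.integers(0, 50)), L), "non_target")
            for _ in range(int(rng.integers(0, 3))):
                s = int(rng.integers(1, L - 500))
                hit_row(qid, s, s + int(rng.integers(100, 500)), "target")
        else:
            cov = rng.uniform(0.0, 0.4)
            covered = max(int(cov * L), 0)
            if covered > 100:
                s = int(rng.integers(1, L - covered))
                hit_row(qid, s, s + covered - 1, "non_target")
            for _ in range(int(rng.integers(1, 4))):
                s = int(rng.integers(1, L - 1000))
                hit_row(qid, s, s + int(rng.integers(200, 1000)), "target")
    hits = pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore", "taxon_class",
    ])
    return hits, query_lens, contaminants


#: log2 expression effects of the planted heat-responsive module, per stage
HEAT_MODULE_PROFILE = {"H0": 0.0, "H1": 3.0, "H3": 1.5, "H6": 0.75, "H12": 0.0}
#: a second, late-responding module for contrast
LATE_MODULE_PROFILE = {"H0": 0.0, "H1": 0.0, "H3": 0.0, "H6": 1.5, "H12": 3.0}


def simulate(config: SimConfig | None = None) -> SimBundle:
    """Generate the full synthetic bundle from a single seed."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    ann, islands = _lay_out_genome(cfg, rng)
    used: set[str] = {g for isl in islands for g in isl.genes}
    pairs, anchors, interspecies, dup_truth = _plant_duplications(cfg, rng, ann, used)

    # ---- expression roles -------------------------------------------------
    all_genes = [g.gene_id for g in ann.genes]
    trd_novel = {g for g, (m, _p, role) in dup_truth.items()
                 if m == "TRD" and role == "novel"}
    trd_ancestral = {g for g, (m, _p, role) in dup_truth.items()
                     if m == "TRD" and role == "ancestral"}
    island_genes = {g for isl in islands for g in isl.genes}
    reserved = island_genes | trd_novel | trd_ancestral
    pool = [g for g in all_genes if g not in reserved]
    pool_idx = rng.permutation(len(pool))
    pool = [pool[i] for i in pool_idx]

    def take(n: int) -> list[str]:
        taken, rest = pool[:n], pool[n:]
        pool[:] = rest
        return taken

    modules: dict[str, str] = {}
    heat_genes = take(cfg.n_heat_module_genes)
    late_genes = take(cfg.n_other_module_genes)
    null_genes = take(cfg.n_null_module_genes)
    modules.update({g: "M1" for g in heat_genes})
    modules.update({g: "M2" for g in late_genes})
    modules.update({g: "M3" for g in null_genes})

    effects: dict[str, dict[str, float]] = {}

    def add_effect(gene: str, stage: str, log2fc: float) -> None:
        effects.setdefault(gene, {})[stage] = log2fc

    for g in heat_genes:
        for stage, fc in HEAT_MODULE_PROFILE.items():
            if fc:
                add_effect(g, stage, fc)
    for g in late_genes:
        for stage, fc in LATE_MODULE_PROFILE.items():
            if fc:
                add_effect(g, stage, fc)

    de_truth: dict[str, dict[str, float]] = {}
    n_de = int(round(cfg.de_fraction * len(all_genes)))
    for stage in CONTRAST_STAGES:
        contrast = f"{stage}vsH0"
        de_truth[contrast] = {}
        chosen = take(n_de)
        n_up = int(round(cfg.de_up_share * len(chosen)))
        for j, g in enumerate(chosen):
            fc = cfg.planted_log2fc if j < n_up else -cfg.planted_log2fc
            add_effect(g, stage, fc)
            de_truth[contrast][g] = fc

    for isl, stage in zip(islands, (CONTRAST_STAGES * len(islands))):
        isl.contrast = f"{stage}vsH0"
        for g in isl.genes:
            add_effect(g, stage, cfg.island_log2fc)

    # ---- counts -----------------------------------------------------------
    design = default_design(cfg.n_reps)
    baseline = {}
    for g in all_genes:
        baseline[g] = float(rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd))
    for g in trd_novel:
        partner = dup_truth[g][1]
        baseline[g] = baseline[partner] * cfg.trd_novel_expression_ratio
    # Stress-induced module and island genes start from a low basal level
    # (like heat-shock genes at the control stage); this also keeps the
    # per-sample library composition stable, so planted fold changes are
    # realized on the TPM scale instead of being diluted by normalisation.
    de_genes = {g for eff in de_truth.values() for g in eff}
    for g, g_eff in effects.items():
        peak = max(g_eff.values(), default=0.0)
        if g not in de_genes and peak > 0:
            baseline[g] /= 2.0 ** peak

    lengths = {g.gene_id: g.length for g in ann.genes}
    mu = np.empty((len(all_genes), len(design)))
    for i, g in enumerate(all_genes):
        g_eff = effects.get(g, {})
        for j, s in enumerate(design):
            m = baseline[g] * (lengths[g] / 1000.0) * 2.0 ** g_eff.get(s.stage, 0.0)
            mu[i, j] = m
    disp = cfg.nb_dispersion
    counts = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))
    counts_df = pd.DataFrame(counts, index=all_genes,
                             columns=[s.sample_id for s in design])
    matrix = ExpressionMatrix(counts_df, design, kind="counts",
                              gene_lengths=lengths)

    # ---- CDS pairs --------------------------------------------------------
    cds: dict[str, str] = {}
    cds_pairs: list[tuple[str, str]] = []
    for p in pairs:
        mode = dup_truth[p.gene_a][0]
        syn_rate, nonsyn_rate = cfg.codon_divergence[mode]
        ancestral_codons = _random_cds(rng, cfg.cds_codons)
        a_codons = _mutate_cds(rng, ancestral_codons, syn_rate / 2, nonsyn_rate / 2)
        b_codons = _mutate_cds(rng, ancestral_codons, syn_rate / 2, nonsyn_rate / 2)
        cds[p.gene_a] = "".join(a_codons)
        cds[p.gene_b] = "".join(b_codons)
        cds_pairs.append((p.gene_a, p.gene_b))

    hits, query_lens, contaminants = _make_hits(cfg, rng)

    truth = TruthTables(
        islands=islands,
        de_effects=de_truth,
        dup_modes=dup_truth,
        modules=dict(modules),
        contaminants=contaminants,
    )
    return SimBundle(
        config=cfg, annotation=ann, design=design, counts=matrix,
        homolog_pairs=pairs, interspecies_anchors=interspecies,
        cds=cds, cds_pairs=cds_pairs, hits=hits, query_lens=query_lens,
        modules=modules, truth=truth,
    )
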