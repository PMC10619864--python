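import numpy as np
import pytest

from thermoss.duplication import (
    DuplicationError,
    HomologPair,
    census_from_counts,
    chain_collinear_blocks,
    classify_duplicates,
    mode_census,
)
from .conftest import make_annotation
from .oracles import brute_classify


def grid_annotation(n_per_chrom, chroms=("chrA", "chrB"), spacing=10_000):
    spec = []
    for c in chroms:
        for i in range(n_per_chrom):
            spec.append((f"{c}_g{i:03d}", c, 1 + i * spacing, 1 + i * spacing + 1000))
    return make_annotation(spec)


def pair_at(ann, chrom_a, rank_a, chrom_b, rank_b, score=10.0):
    ga = ann.genes_on(chrom_a)[rank_a].gene_id
    gb = ann.genes_on(chrom_b)[rank_b].gene_id
    return HomologPair(ga, gb, score)


class TestChaining:
    def test_five_consecutive_anchors_form_one_block(self):
        ann = grid_annotation(120)
        pairs = [pair_at(ann, "chrA", 10 + i, "chrB", 110 + i)
                 for i in range(5)]
        blocks = chain_collinear_blocks(pairs, ann, min_block=5, max_gap=25)
        assert len(blocks) == 1
        assert len(blocks[0]) == 5 and blocks[0].orientation == "same"

    def test_large_gap_breaks_chain_below_min_block(self):
        ann = grid_annotation(600)
        ranks_b = [110, 111, 500, 113, 114]
        pairs = [pair_at(ann, "chrA", 10 + i, "chrB", rb)
                 for i, rb in enumerate(ranks_b)]
        assert chain_collinear_blocks(pairs, ann, min_block=5, max_gap=25) == []

    def test_inverted_orientation_detected(self):
        ann = grid_annotation(120)
        pairs = [pair_at(ann, "chrA", 10 + i, "chrB", 60 - i) for i in range(6)]
        blocks = chain_collinear_blocks(pairs, ann)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_empty_input_and_config_validation(self):
        ann = grid_annotation(10)
        assert chain_collinear_blocks([], ann) == []
        with pytest.raises(DuplicationError):
            chain_collinear_blocks([], ann, min_block=1)

    def test_intra_chromosomal_block_needs_disjoint_intervals(self):
        # near-diagonal tandem/proximal dots must not chain into a "block"
        ann = grid_annotation(120, chroms=("chrA",))
        diagonal = [pair_at(ann, "chrA", r, "chrA", r + 1) for r in (5, 20, 40, 55, 70)]
        assert chain_collinear_blocks(diagonal, ann) == []
        # a genuine intra-chromosomal block copy at disjoint ranks chains fine
        block = [pair_at(ann, "chrA", 10 + i, "chrA", 80 + i) for i in range(5)]
        assert len(chain_collinear_blocks(block, ann)) == 1


class TestClassification:
    def test_adjacent_and_proximal_rules(self):
        ann = grid_annotation(30, chroms=("chrA",))
        pairs = [
            pair_at(ann, "chrA", 5, "chrA", 6),    # tandem
            pair_at(ann, "chrA", 10, "chrA", 14),  # proximal (delta 4)
            pair_at(ann, "chrA", 20, "chrA", 28),  # proximal (delta 8)
        ]
        calls = {c.gene_id: c for c in classify_duplicates(pairs, [], ann)}
        genes = ann.genes_on("chrA")
        assert calls[genes[5].gene_id].mode == "TD"
        assert calls[genes[6].gene_id].mode == "TD"
        assert calls[genes[10].gene_id].mode == "PD"
        assert calls[genes[28].gene_id].mode == "PD"

    def test_trd_roles_from_interspecies_anchors(self):
        ann = grid_annotation(30)
        p = pair_at(ann, "chrA", 5, "chrB", 20)
        calls = {c.gene_id: c for c in classify_duplicates(
            [p], [], ann, interspecies_anchors={p.gene_a})}
        assert calls[p.gene_a].mode == "TRD"
        assert calls[p.gene_a].trd_role == "ancestral"
        assert calls[p.gene_b].mode == "TRD"
        assert calls[p.gene_b].trd_role == "novel"

    def test_dispersed_when_no_synteny_evidence(self):
        ann = grid_annotation(30)
        p = pair_at(ann, "chrA", 5, "chrB", 20)
        calls = {c.gene_id: c.mode for c in classify_duplicates([p], [], ann)}
        assert calls[p.gene_a] == "DSD" and calls[p.gene_b] == "DSD"

    def test_unknown_gene_in_pair_raises(self):
        ann = grid_annotation(5)
        with pytest.raises(DuplicationError, match="unknown"):
            classify_duplicates([HomologPair("nope1", "nope2")], [], ann)

    def test_partition_and_idempotence(self, bundle, pipeline_result):
        calls = pipeline_result.calls
        assert len(calls) == len(bundle.annotation)
        assert len({c.gene_id for c in calls}) == len(calls)
        again = classify_duplicates(
            bundle.homolog_pairs, pipeline_result.blocks, bundle.annotation,
            interspecies_anchors=bundle.interspecies_anchors)
        assert again == calls

    def test_matches_literal_rule_enumeration_on_small_genomes(self):
        """Production classifier equals the literal rule-by-rule oracle on
        random genomes of <= 50 genes."""
        rng = np.random.default_rng(17)
        for trial in range(25):
            n = int(rng.integers(10, 26))
            ann = grid_annotation(n, chroms=("c1", "c2"))
            gene_ids = [g.gene_id for g in ann.genes]
            pairs = []
            seen = set()
            for _ in range(int(rng.integers(3, 15))):
                a, b = rng.choice(len(gene_ids), size=2, replace=False)
                key = frozenset((gene_ids[a], gene_ids[b]))
                if key in seen:
                    continue
                seen.add(key)
                pairs.append(HomologPair(gene_ids[a], gene_ids[b],
                                         float(rng.integers(1, 100))))
            inter = set(rng.choice(gene_ids, size=3, replace=False))
            blocks = chain_collinear_blocks(pairs, ann, min_block=3, max_gap=25)
            calls = classify_duplicates(pairs, blocks, ann,
                                        interspecies_anchors=inter)
            anchor_set = set()
            for blk in blocks:
                anchor_set |= blk.genes
            oracle = brute_classify(
                {g.gene_id: (g.chrom, g.rank) for g in ann.genes},
                [(p.gene_a, p.gene_b, p.score) for p in pairs],
                anchor_set, inter)
            for c in calls:
                o_mode, _o_partner, o_role = oracle[c.gene_id]
                assert c.mode == o_mode, (trial, c)
                if o_mode == "TRD":
                    assert c.trd_role == o_role


class TestCensus:
    def test_published_mode_counts_sum_and_fraction(self):
        census = census_from_counts(
            {"WGD": 1823, "TD": 1103, "PD": 1382, "TRD": 464, "DSD": 3063},
            n_total=26_898)
        assert census["duplicated_total"] == 7835
        assert census["duplicated_percent"] == 29.13

    def test_all_singletons(self, bundle):
        from thermoss.duplication import DuplicationCall
        calls = [DuplicationCall(g.gene_id, "singleton")
                 for g in bundle.annotation.genes]
        census = mode_census(calls)
        assert census["duplicated_total"] == 0
        assert census["duplicated_percent"] == 0.0
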