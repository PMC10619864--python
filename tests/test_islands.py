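import math

import numpy as np
import pytest

from thermoss.expression import DEResult
from thermoss.islands import (
    Island,
    IslandParams,
    duplicated_percentage,
    scan_islands,
    summarize_islands,
)
from .conftest import make_annotation
from .oracles import brute_qualifying_regions


def six_gene_chromosome():
    # expressed genes at starts 1k, 5k, 9k, 13k, 17k, 45k on one chromosome
    starts = [1000, 5000, 9000, 13_000, 17_000, 45_000]
    return make_annotation([
        (f"g{i}", "chr1", s, s + 500) for i, s in enumerate(starts)
    ])


def test_hand_worked_window_rule():
    ann = six_gene_chromosome()
    expressed = {f"g{i}" for i in range(6)}
    pattern = {"g0", "g1", "g2", "g3"}  # first four upregulated: 4/6 = 66.7%
    islands = scan_islands(ann, pattern, expressed)
    assert len(islands) == 1
    isl = islands[0]
    assert isl.member_pattern_genes == ["g0", "g1", "g2", "g3"]
    assert isl.start == 1000 and isl.end == 13_500


def test_strict_sixty_percent_boundary():
    ann = six_gene_chromosome()
    expressed = {f"g{i}" for i in range(6)}
    assert scan_islands(ann, {"g0", "g1", "g2"}, expressed) == []  # 3/6 = 50%


def test_no_expressed_genes_no_islands():
    ann = six_gene_chromosome()
    assert scan_islands(ann, set(), set()) == []


def test_pattern_gene_outside_annotation_or_expressed_set_rejected():
    ann = six_gene_chromosome()
    with pytest.raises(Exception, match="ghost"):
        scan_islands(ann, {"ghost"}, {"ghost"})
    with pytest.raises(Exception, match="expressed"):
        scan_islands(ann, {"g0"}, {"g1"})


def test_relaxing_fraction_never_loses_windows(bundle, pipeline_result):
    ann = bundle.annotation
    expressed = pipeline_result.expressed
    pattern = pipeline_result.patterns["H1UP"] & expressed
    strict = scan_islands(ann, pattern, expressed,
                          params=IslandParams(min_pattern_fraction=0.60))
    loose = scan_islands(ann, pattern, expressed,
                         params=IslandParams(min_pattern_fraction=0.40))
    strict_members = {g for i in strict for g in i.member_pattern_genes}
    loose_members = {g for i in loose for g in i.member_pattern_genes}
    assert strict_members <= loose_members


def test_islands_disjoint_per_chromosome(pipeline_result):
    for islands in pipeline_result.islands_by_contrast.values():
        by_chrom = {}
        for i in islands:
            by_chrom.setdefault(i.chrom, []).append((i.start, i.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2


def test_gene_anchored_islands_contained_in_every_offset_oracle():
    """Every island from the gene-anchored scan lies inside a region that the
    exhaustive every-bp-offset window evaluation also flags."""
    rng = np.random.default_rng(23)
    window = 5_000
    for _ in range(10):
        n = int(rng.integers(8, 25))
        starts = np.sort(rng.choice(np.arange(500, 40_000, 7), size=n, replace=False))
        spec = [(f"g{i}", "chr1", int(s), int(s) + 3) for i, s in enumerate(starts)]
        ann = make_annotation(spec)
        is_pattern = rng.random(n) < 0.5
        pattern = {f"g{i}" for i in range(n) if is_pattern[i]}
        expressed = {f"g{i}" for i in range(n)}
        islands = scan_islands(ann, pattern, expressed,
                               params=IslandParams(window_bp=window))
        regions = brute_qualifying_regions(starts, is_pattern, 45_000, window)
        for isl in islands:
            assert any(lo <= isl.start and isl.end <= hi + 3
                       for lo, hi in regions), (isl, regions)


def test_summary_arithmetic_on_toy_islands():
    islands = [
        Island("chr1", 1000, 9000, [f"m{i}" for i in range(4)], 5, 2.0, 2.0, 1),
        Island("chr1", 20_000, 30_000, [f"n{i}" for i in range(5)], 6, 3.0, 3.0, 0),
        Island("chr2", 1000, 12_000, [f"o{i}" for i in range(6)], 7, 4.0, 4.0, 2),
    ]
    s = summarize_islands(islands, "H1UP", n_pattern_genes_total=40)
    assert s.n_islands == 3 and s.n_pattern_genes_in_islands == 15
    assert s.mean_genes_per_island == pytest.approx(5.0)
    assert s.max_genes_per_island == 6
    assert s.n_duplicated_in_islands == 3
    assert s.pct_duplicated_in_islands == duplicated_percentage(3, 15)


@pytest.mark.parametrize("n_dup,n_genes,expected", [
    (25, 135, 18.52),   # H1UP island row of the study
    (26, 116, 22.41),   # H6UP island row
])
def test_duplicated_percentage_matches_published_rows(n_dup, n_genes, expected):
    assert duplicated_percentage(n_dup, n_genes) == expected


def test_empty_island_list_summary():
    s = summarize_islands([], "H3UP", n_pattern_genes_total=10)
    assert s.n_islands == 0 and s.n_pattern_genes_in_islands == 0
    assert math.isnan(s.mean_island_size_bp)


def test_member_log2fc_taken_from_contrast():
    ann = six_gene_chromosome()
    expressed = {f"g{i}" for i in range(6)}
    pattern = {"g0", "g1", "g2", "g3"}
    de = [DEResult(f"g{i}", "H1vsH0", 2.0 + i, 0.01) for i in range(4)]
    de += [DEResult(f"g{i}", "H3vsH0", 9.0, 0.01) for i in range(4)]
    islands = scan_islands(ann, pattern, expressed, de=de, contrast="H1vsH0")
    assert islands[0].mean_log2fc == pytest.approx(np.mean([2, 3, 4, 5]))
    assert islands[0].median_log2fc == pytest.approx(3.5)
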