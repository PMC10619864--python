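import math

import numpy as np
import pytest

from thermoss import kaks
from thermoss.duplication import DuplicationCall
from .oracles import brute_ng86

NON_STOP = [c for c in
            ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))
            if c not in {"TAA", "TAG", "TGA"}]


def random_codons(rng, n):
    return [NON_STOP[i] for i in rng.integers(0, len(NON_STOP), size=n)]


class TestAlignment:
    def test_identical_sequences_align_fully(self):
        rng = np.random.default_rng(1)
        cds = "".join(random_codons(rng, 30))
        aln = kaks.align_codons(cds, cds)
        assert len(aln.codons) == 30
        assert all(a == b for a, b in aln.codons)

    def test_internal_codon_deletion_drops_exactly_that_column(self):
        rng = np.random.default_rng(2)
        codons = random_codons(rng, 30)
        cds_a = "".join(codons)
        cds_b = "".join(codons[:14] + codons[15:])
        aln = kaks.align_codons(cds_a, cds_b)
        assert len(aln.codons) == 29
        assert all(a == b for a, b in aln.codons)

    def test_frame_violation_rejected(self):
        with pytest.raises(kaks.KaKsError, match="divisible by 3"):
            kaks.align_codons("ATGAAAT", "ATGAAA")


class TestNG86:
    def test_identical_pair_is_zero_with_undefined_ratio(self):
        rng = np.random.default_rng(3)
        cds = "".join(random_codons(rng, 30))
        res = kaks.ng86(kaks.align_codons(cds, cds))
        assert res.ka == 0 and res.ks == 0
        assert math.isnan(res.ratio) and not res.saturated

    def test_single_synonymous_change_matches_literal_oracle(self):
        rng = np.random.default_rng(7)
        codons = random_codons(rng, 30)
        mutated = list(codons)
        # find a codon with a synonymous third-position variant
        for i, codon in enumerate(codons):
            for nt in "ACGT":
                cand = codon[:2] + nt
                if cand != codon and cand in NON_STOP and \
                        kaks.translate_codon(cand) == kaks.translate_codon(codon):
                    mutated[i] = cand
                    break
            if mutated[i] != codon:
                break
        res = kaks.ng86(kaks.CodonPairAlignment("a", "b", list(zip(codons, mutated))))
        ka_o, ks_o, _, _, _ = brute_ng86(codons, mutated)
        assert res.ka == pytest.approx(ka_o, abs=1e-12) and res.ka == 0
        assert res.ks == pytest.approx(ks_o, abs=1e-12) and res.ks > 0

    def test_sites_conservation_and_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = random_codons(rng, 25), random_codons(rng, 25)
        _, _, _, S, N = brute_ng86(a, b)
        assert S + N == pytest.approx(3 * 25, abs=1e-9)
        r1 = kaks.ng86(kaks.CodonPairAlignment("a", "b", list(zip(a, b))))
        r2 = kaks.ng86(kaks.CodonPairAlignment("b", "a", list(zip(b, a))))
        assert r1.ka == pytest.approx(r2.ka, abs=1e-12, nan_ok=True)
        assert r1.ks == pytest.approx(r2.ks, abs=1e-12, nan_ok=True)
        assert r1.saturated == r2.saturated

    def test_jukes_cantor_small_p_limit_and_saturation(self):
        p = 1e-4
        assert kaks.jukes_cantor(p) / p == pytest.approx(1.0, rel=1e-3)
        assert math.isinf(kaks.jukes_cantor(0.75))

    def test_ks_above_five_flags_saturated(self):
        res = kaks.KaKsResult("a", "b", 0.1, 5.2, 0.1 / 5.2, saturated=True)
        assert res.saturated
        summary = kaks.mode_divergence_summary(
            [res] + [kaks.KaKsResult("c", "d", 0.1, 0.5, 0.2, False, "WGD")] * 3)
        assert "n/a" not in summary["summaries"]  # the saturated pair's mode absent

    def test_matches_brute_force_on_random_pairs(self):
        """Production NG86 equals the literal pathway-enumeration oracle to
        1e-10 on 100 random 30-codon pairs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_codons(rng, 30)
            b = [c if rng.random() < 0.7 else NON_STOP[rng.integers(0, len(NON_STOP))]
                 for c in a]
            res = kaks.ng86(kaks.CodonPairAlignment("a", "b", list(zip(a, b))))
            ka_o, ks_o, sat_o, _, _ = brute_ng86(a, b)
            if math.isnan(ka_o):
                assert math.isnan(res.ka)
            else:
                assert res.ka == pytest.approx(ka_o, abs=1e-10)
            if math.isnan(ks_o):
                assert math.isnan(res.ks)
            else:
                assert res.ks == pytest.approx(ks_o, abs=1e-10)


class TestModeSummaries:
    def test_planted_divergence_ordering_recovered(self, bundle):
        truth_modes = {frozenset((p.gene_a, p.gene_b)): bundle.truth.dup_modes[p.gene_a][0]
                       for p in bundle.homolog_pairs}
        results = kaks.kaks_for_pairs(bundle.cds, bundle.cds_pairs, truth_modes)
        summary = kaks.mode_divergence_summary(results)["summaries"]
        # TD and PD pairs were generated under weaker purifying selection
        assert summary["TD"]["median"] > summary["WGD"]["median"]
        assert summary["PD"]["median"] > summary["WGD"]["median"]

    def test_single_mode_and_degenerate_distributions(self):
        single = [kaks.KaKsResult("a", "b", 0.1, 0.5, 0.2, False, "TD")] * 3
        out = kaks.mode_divergence_summary(single)
        assert list(out["summaries"]) == ["TD"] and out["tests"] == {}
        flat = single + [kaks.KaKsResult("c", "d", 0.1, 0.5, 0.2, False, "PD")] * 3
        out = kaks.mode_divergence_summary(flat)
        assert out["tests"][("PD", "TD")] == pytest.approx(1.0)

    def test_mode_with_single_pair_omitted_with_warning(self):
        results = [
            kaks.KaKsResult("a", "b", 0.1, 0.5, 0.2, False, "TD"),
            kaks.KaKsResult("c", "d", 0.2, 0.5, 0.4, False, "WGD"),
            kaks.KaKsResult("e", "f", 0.25, 0.5, 0.5, False, "WGD"),
        ]
        with pytest.warns(UserWarning, match="TD"):
            out = kaks.mode_divergence_summary(results)
        assert list(out["summaries"]) == ["WGD"]


class TestTRDContrast:
    def test_planted_fourfold_asymmetry_detected_each_stage(self, bundle, pipeline_result):
        report = kaks.trd_expression_contrast(pipeline_result.calls,
                                              pipeline_result.tpm)
        assert set(report) == {"H0", "H1", "H3", "H6", "H12"}
        for stage, row in report.items():
            assert row["n_ancestral"] >= 30 and row["n_novel"] >= 30
            assert row["median_ancestral"] > row["median_novel"]
            assert row["pvalue"] < 0.05

    def test_no_trd_genes_gives_empty_report(self, pipeline_result):
        calls = [DuplicationCall("g", "DSD", "h")]
        assert kaks.trd_expression_contrast(calls, pipeline_result.tpm) == {}
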