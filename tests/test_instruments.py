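import numpy as np
import pandas as pd
import pytest

from targetmr.instruments import (
    attach_pav_flags,
    cis_filter,
    clump,
    compute_f_r2,
    exclude_mhc,
    filter_weak,
    flag_pav,
    gw_filter,
    harmonize,
    select_intragenic,
)
from targetmr.io import GeneAnnotation, LDMatrix, annotate_consequences
from targetmr.mr import ivw
from targetmr.simulate import SimulationConfig, simulate_instrument_set

from conftest import clump_oracle, clump_random_case, make_assoc, make_hset

_assoc = make_assoc


class TestGwFilter:
    def test_strict_threshold_boundary(self):
        df = _assoc([
            ("a", "1", 100, "A", "G", 0.3, 0.1, 0.01, 4.9e-8, 1e5),
            ("b", "1", 200, "A", "G", 0.3, 0.1, 0.01, 5e-8, 1e5),
        ])
        kept = gw_filter(df)
        assert list(kept["variant_id"]) == ["a"]  # p = 5e-8 exactly is out

    def test_empty_input(self):
        assert gw_filter(_assoc([])).empty


class TestClump:
    def test_rule_application(self):
        # A (best p) removes B (r2=0.5) but not C (r2=0.0005)
        df = _assoc([
            ("A", "1", 1_000_000, "A", "G", 0.3, 0.2, 0.01, 1e-10, 1e5),
            ("B", "1", 2_000_000, "A", "G", 0.3, 0.2, 0.01, 1e-9, 1e5),
            ("C", "1", 3_000_000, "A", "G", 0.3, 0.2, 0.01, 1e-8, 1e5),
        ])
        r = np.array([
            [1.0, np.sqrt(0.5), np.sqrt(0.0005)],
            [np.sqrt(0.5), 1.0, 0.0],
            [np.sqrt(0.0005), 0.0, 1.0],
        ])
        ld = LDMatrix(["A", "B", "C"], r)
        kept = clump(df, ld)
        assert list(kept["variant_id"]) == ["A", "C"]

    def test_single_variant(self):
        df = _assoc([("A", "1", 100, "A", "G", 0.3, 0.2, 0.01, 1e-10, 1e5)])
        ld = LDMatrix(["A"], np.eye(1))
        assert list(clump(df, ld)["variant_id"]) == ["A"]

    def test_window_limits_removal(self):
        # linked pair beyond the window survives
        df = _assoc([
            ("A", "1", 1_000_000, "A", "G", 0.3, 0.2, 0.01, 1e-10, 1e5),
            ("B", "1", 20_000_000, "A", "G", 0.3, 0.2, 0.01, 1e-9, 1e5),
        ])
        ld = LDMatrix(["A", "B"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert len(clump(df, ld, window_bp=10_000_000)) == 2

    def test_missing_from_ld_treated_unlinked(self, caplog):
        df = _assoc([
            ("A", "1", 1_000_000, "A", "G", 0.3, 0.2, 0.01, 1e-10, 1e5),
            ("Z", "1", 1_100_000, "A", "G", 0.3, 0.2, 0.01, 1e-9, 1e5),
        ])
        ld = LDMatrix(["A"], np.eye(1))
        with caplog.at_level("WARNING"):
            kept = clump(df, ld)
        assert len(kept) == 2
        assert "unlinked" in caplog.text

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, seed):
        df, ld = clump_random_case(seed)
        for r2_thresh, window in [(0.001, 10_000_000), (0.1, 5_000_000)]:
            kept = clump(df, ld, r2_thresh, window)
            assert sorted(kept["variant_id"]) == clump_oracle(
                df, ld, r2_thresh, window
            )

    @pytest.mark.parametrize("seed", [0, 7])
    def test_invariant_to_row_order(self, seed):
        df, ld = clump_random_case(seed)
        shuffled = df.sample(frac=1.0, random_state=99).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            clump(df, ld).reset_index(drop=True),
            clump(shuffled, ld).reset_index(drop=True),
        )


class TestFR2:
    def test_examples(self):
        f, r2 = compute_f_r2(0.1, 0.01, 1e5)
        assert f == pytest.approx(100.0)
        f0, r20 = compute_f_r2(0.0, 0.05, 1e5)
        assert f0 == 0.0 and r20 == 0.0
        f30, r230 = compute_f_r2(np.sqrt(30) * 0.01, 0.01, 1e5)
        assert r230 == pytest.approx(3.0e-4, rel=1e-3)

    def test_against_individual_level_regression(self, rng):
        # summary-level r2 approximates t^2/(t^2 + n - 2) from an actual
        # regression of phenotype on genotype
        n, maf, b = 5000, 0.3, 0.08
        g = rng.binomial(2, maf, size=n).astype(float)
        y = b * g + rng.standard_normal(n)
        g_c = g - g.mean()
        beta_hat = float(g_c @ y / (g_c @ g_c))
        resid = y - y.mean() - beta_hat * g_c
        se_hat = float(
            np.sqrt(resid @ resid / (n - 2) / (g_c @ g_c))
        )
        _, r2_summary = compute_f_r2(beta_hat, se_hat, n)
        corr = np.corrcoef(g, y)[0, 1]
        assert r2_summary == pytest.approx(corr**2, rel=1e-3)


class TestFilterWeak:
    def test_boundaries_and_empty(self, caplog):
        h = make_hset([0.0999, 0.1, 0.2], [0.0316, 0.0316, 0.01],
                      [0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        # F = (beta/se)^2: 9.99..., 10.01..., 400
        out = filter_weak(h, 10.0)
        assert (out.df["f_stat"] >= 10).all()
        h2 = make_hset([0.01], [0.1], [0.1], [0.1])
        with caplog.at_level("WARNING"):
            empty = filter_weak(h2, 10.0)
        assert empty.k == 0 and "no instruments" in caplog.text

    def test_f10_exactly_kept(self):
        h = make_hset([np.sqrt(10) * 0.01], [0.01], [0.1], [0.1])
        assert filter_weak(h, 10.0).k == 1


class TestMhcAndCis:
    def test_mhc_boundaries(self):
        df = _assoc([
            ("in", "6", 29_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("edge", "6", 28_500_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("out", "6", 34_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("chr1", "1", 29_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
        ])
        kept = exclude_mhc(df)
        assert sorted(kept["variant_id"]) == ["chr1", "out"]

    def test_cis_window(self):
        gene = GeneAnnotation("g", "G", "1", 10_000_000, 10_050_000, "+")
        assert gene.tss == 10_000_000
        df = _assoc([
            ("near", "1", 9_100_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("edge", "1", 11_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("far", "1", 11_000_001, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("trans", "2", 10_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
        ])
        kept = cis_filter(df, gene)
        assert sorted(kept["variant_id"]) == ["edge", "near"]


class TestFlagPav:
    @pytest.fixture
    def consequences(self):
        return annotate_consequences(
            pd.DataFrame(
                {
                    "variant_id": ["pav", "x", "y"],
                    "consequence_term": [
                        "missense_variant", "intron_variant", "intron_variant",
                    ],
                }
            )
        )

    def test_proxy_boundary_strict(self, consequences):
        r_above, r_below = np.sqrt(0.61), np.sqrt(0.59)
        r = np.array([
            [1.0, r_above, r_below],
            [r_above, 1.0, 0.0],
            [r_below, 0.0, 1.0],
        ])
        ld = LDMatrix(["pav", "x", "y"], r)
        flags = flag_pav(["pav", "x", "y"], ld, consequences)
        assert flags.tolist() == [True, True, False]

    def test_without_ld_only_direct(self, consequences):
        flags = flag_pav(["pav", "x"], None, consequences)
        assert flags.tolist() == [True, False]

    def test_flagged_variants_retained_in_set(self, consequences):
        h = make_hset([0.2, 0.2], [0.01, 0.01], [0.1, 0.1], [0.1, 0.1])
        h.df.loc[0, "variant_id"] = "pav"
        out = attach_pav_flags(h, None, consequences)
        assert out.k == 2 and bool(out.df["pav_flag"].iloc[0])


class TestSelectIntragenic:
    @pytest.fixture
    def gene(self):
        return GeneAnnotation("g1", "G1", "1", 1_000_000, 1_100_000, "+")

    def _csq(self, mapping):
        return annotate_consequences(
            pd.DataFrame(
                {
                    "variant_id": list(mapping),
                    "consequence_term": list(mapping.values()),
                }
            )
        )

    def test_priority_rule(self, gene):
        hits = _assoc([
            ("m", "1", 1_000_100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1e5),
            ("i1", "1", 1_000_200, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1e5),
            ("i2", "1", 1_000_300, "A", "G", 0.3, 0.1, 0.01, 1e-11, 1e5),
            ("i3", "1", 1_000_400, "A", "G", 0.3, 0.1, 0.01, 1e-12, 1e5),
        ])
        csq = self._csq({
            "m": "missense_variant", "i1": "intron_variant",
            "i2": "intron_variant", "i3": "intron_variant",
        })
        out = select_intragenic(hits, [gene], csq)
        assert list(out["g1"]["variant_id"]) == ["m"]

    def test_fallback_to_intronic(self, gene):
        hits = _assoc([
            ("i1", "1", 1_000_200, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1e5),
            ("i2", "1", 1_000_300, "A", "G", 0.3, 0.1, 0.01, 1e-11, 1e5),
        ])
        csq = self._csq({"i1": "intron_variant", "i2": "intron_variant"})
        out = select_intragenic(hits, [gene], csq)
        assert sorted(out["g1"]["variant_id"]) == ["i1", "i2"]

    def test_hit_outside_gene_excluded(self, gene):
        hits = _assoc([
            ("out", "1", 1_100_001, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1e5),
        ])
        csq = self._csq({"out": "missense_variant"})
        assert select_intragenic(hits, [gene], csq) == {}


class TestHarmonize:
    def _pair(self, exp_rows, out_rows):
        return _assoc(exp_rows), _assoc(out_rows)

    def test_swapped_alleles_flip(self):
        exp, out = self._pair(
            [("rs1", "1", 100, "A", "G", 0.30, 0.10, 0.01, 1e-9, 1e5)],
            [("rs1", "1", 100, "G", "A", 0.70, -0.05, 0.01, 1e-3, 1e5)],
        )
        h = harmonize(exp, out)
        assert h.df["beta_out"].iloc[0] == pytest.approx(0.05)
        assert h.df["eaf_out"].iloc[0] == pytest.approx(0.30)

    def test_palindromic_ambiguous_dropped(self):
        exp, out = self._pair(
            [("rs1", "1", 100, "A", "T", 0.50, 0.10, 0.01, 1e-9, 1e5)],
            [("rs1", "1", 100, "A", "T", 0.50, 0.05, 0.01, 1e-3, 1e5)],
        )
        h = harmonize(exp, out)
        assert h.k == 0 and h.drop_log["palindromic_ambiguous"] == 1

    def test_palindromic_frequency_alignment(self):
        exp, out = self._pair(
            [("rs1", "1", 100, "A", "T", 0.20, 0.10, 0.01, 1e-9, 1e5)],
            [("rs1", "1", 100, "A", "T", 0.80, 0.05, 0.01, 1e-3, 1e5)],
        )
        h = harmonize(exp, out)
        # frequencies disagree about which allele is minor: strand flip
        assert h.df["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert h.df["eaf_out"].iloc[0] == pytest.approx(0.20)

    def test_incompatible_alleles_dropped(self):
        exp, out = self._pair(
            [("rs1", "1", 100, "A", "G", 0.30, 0.10, 0.01, 1e-9, 1e5)],
            [("rs1", "1", 100, "C", "T", 0.30, 0.05, 0.01, 1e-3, 1e5)],
        )
        h = harmonize(exp, out)
        assert h.k == 0 and h.drop_log["incompatible_alleles"] == 1

    def test_empty_intersection_status(self):
        exp, out = self._pair(
            [("rs1", "1", 100, "A", "G", 0.30, 0.10, 0.01, 1e-9, 1e5)],
            [("rs2", "1", 200, "A", "G", 0.30, 0.05, 0.01, 1e-3, 1e5)],
        )
        h = harmonize(exp, out)
        assert h.k == 0 and h.drop_log["not_in_outcome"] == 1

    def test_involution_safety(self):
        # flipping every outcome record's alleles/sign/EAF leaves the
        # harmonized set unchanged
        pair = simulate_instrument_set(SimulationConfig(n_snps=40, seed=21))
        flipped = pair.outcome.copy()
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        h1 = harmonize(pair.exposure, pair.outcome)
        h2 = harmonize(pair.exposure, flipped)
        pd.testing.assert_frame_equal(h1.df, h2.df)

    def test_harmonized_estimates_match_unflipped_truth_path(self):
        cfg = SimulationConfig(n_snps=40, seed=33)
        flipped = simulate_instrument_set(cfg, flip_alleles=True)
        clean = simulate_instrument_set(cfg, flip_alleles=False)
        res_f, _ = ivw(harmonize(flipped.exposure, flipped.outcome))
        res_c, _ = ivw(clean.to_harmonized())
        assert res_f.estimate == pytest.approx(res_c.estimate, abs=1e-12)
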