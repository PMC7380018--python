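"""RPKM, N50/N90, ddCT fold changes, dilution slopes and Tukey letters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemogene import (
    ddct_fold, dilution_slope, efficiency_from_curve, nxx, rpkm, tukey_letters,
)
from chemogene.quantification import DegenerateVarianceError
from chemogene.synthetic_data import gen_qpcr


class TestRpkm:
    @pytest.mark.parametrize(
        "C,N,L,expected",
        [
            (0, 1_000_000, 500, 0.0),
            (1000, 1000, 1000, 1e6),  # C=N, L=1 kb
            (50, 2e7, 500, 5.0),
        ],
    )
    def test_values(self, C, N, L, expected):
        assert rpkm(C, N, L) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)
        with pytest.raises(ValueError):
            rpkm(10, 0, 500)

    @given(
        st.integers(0, 10**6), st.integers(1, 10**9), st.integers(1, 10**6),
        st.integers(2, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, C, N, L, k):
        """Scaling C and N together leaves RPKM unchanged; scaling L divides it."""
        base = rpkm(C, N, L)
        assert rpkm(k * C, k * N, L) == pytest.approx(base)
        assert rpkm(C, N, k * L) == pytest.approx(base / k)


class TestNxx:
    def test_cumulative_oracle_example(self):
        assert nxx([6, 5, 4, 3, 2], 0.5) == 5

    def test_single_contig(self):
        for f in (0.1, 0.5, 0.9):
            assert nxx([1234], f) == 1234

    def test_matches_cumulative_oracle(self, rng):
        for _ in range(30):
            lengths = rng.integers(100, 30_000, size=int(rng.integers(2, 300)))
            f = float(rng.uniform(0.05, 0.95))
            ordered = np.sort(lengths)[::-1]
            cum, target = 0, f * lengths.sum()
            for l in ordered:
                cum += l
                if cum >= target:
                    expected = int(l)
                    break
            assert nxx(lengths, f) == expected

    def test_monotone_in_fraction(self, rng):
        lengths = rng.integers(100, 10_000, size=100)
        values = [nxx(lengths, f) for f in np.linspace(0.05, 0.95, 19)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nxx([], 0.5)


def _ct_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "tissue", "bio_rep", "tech_rep", "ct"])


class TestDdctFold:
    def test_equal_cts_fold_one(self):
        rows = [
            (g, t, b, 1, 20.0)
            for g in ("x", "ref") for t in ("ant", "body") for b in (1, 2, 3)
        ]
        fc = ddct_fold(_ct_frame(rows), "x", "ant", "ref", "body")
        assert fc.fold == pytest.approx(1.0) and fc.se == pytest.approx(0.0)

    def test_one_cycle_doubling(self):
        rows = [("x", "ant", 1, 1, 19.0), ("x", "ant", 2, 1, 19.0),
                ("x", "body", 1, 1, 20.0), ("x", "body", 2, 1, 20.0),
                ("ref", "ant", 1, 1, 20.0), ("ref", "ant", 2, 1, 20.0),
                ("ref", "body", 1, 1, 20.0), ("ref", "body", 2, 1, 20.0)]
        fc = ddct_fold(_ct_frame(rows), "x", "ant", "ref", "body")
        assert fc.fold == pytest.approx(2.0)

    def test_calibrator_equals_tissue_gives_one(self):
        cts, _ = gen_qpcr({"g": {"ant": 17.0, "body": 1.0}}, noise_sd=0.15, seed=3)
        fc = ddct_fold(cts, "g", "body", "GAPDH", "body")
        assert fc.fold == pytest.approx(1.0)

    def test_noiseless_generator_round_trip(self):
        cts, _ = gen_qpcr({"g": {"ant": 101.0, "body": 1.0}}, noise_sd=0.0)
        fc = ddct_fold(cts, "g", "ant", "GAPDH", "body")
        assert fc.fold == pytest.approx(101.0)

    def test_missing_reference_raises(self):
        rows = [("x", "ant", 1, 1, 19.0), ("x", "body", 1, 1, 20.0)]
        with pytest.raises(KeyError):
            ddct_fold(_ct_frame(rows), "x", "ant", "GAPDH", "body")

    def test_technical_reps_averaged_before_bio_se(self):
        rows = [("x", "ant", b, t, 19.0 + 0.3 * (t - 2)) for b in (1, 2, 3) for t in (1, 2, 3)]
        rows += [("x", "body", b, t, 20.0) for b in (1, 2, 3) for t in (1, 2, 3)]
        rows += [("ref", tt, b, t, 20.0) for tt in ("ant", "body") for b in (1, 2, 3) for t in (1, 2, 3)]
        fc = ddct_fold(_ct_frame(rows), "x", "ant", "ref", "body")
        assert len(fc.folds) == 3  # one fold per biological replicate
        assert fc.fold == pytest.approx(2.0)


class TestDilutionSlope:
    def test_equal_efficiencies_slope_zero(self):
        _, dil = gen_qpcr({"g": {"a": 2.0, "body": 1.0}}, noise_sd=0.0)
        t = dil[dil.gene == "g"].sort_values("dilution")
        r = dil[dil.gene == "GAPDH"].sort_values("dilution")
        slope, ok = dilution_slope(t.dilution, t.ct.values - r.ct.values)
        assert slope == pytest.approx(0.0, abs=1e-12) and ok

    def test_unequal_efficiencies_closed_form(self):
        _, dil = gen_qpcr(
            {"g": {"a": 2.0, "body": 1.0}},
            efficiencies={"g": 1.9, "GAPDH": 2.0}, noise_sd=0.0,
        )
        t = dil[dil.gene == "g"].sort_values("dilution")
        r = dil[dil.gene == "GAPDH"].sort_values("dilution")
        slope, ok = dilution_slope(t.dilution, t.ct.values - r.ct.values)
        expected = 1 / np.log10(1.9) - 1 / np.log10(2.0)
        assert slope == pytest.approx(expected, rel=1e-9)  # ~0.2655
        assert not ok

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            dilution_slope([1, 5], [0.1, 0.2])


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        ct = 20 + x * (-1 / np.log10(2.0))  # slope -3.3219
        eff, ok = efficiency_from_curve(x, ct)
        assert eff == pytest.approx(2.0) and ok

    def test_slope_minus_3_6(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        eff, ok = efficiency_from_curve(x, 20 - 3.6 * x)
        assert eff == pytest.approx(10 ** (1 / 3.6), rel=1e-9)  # ~1.896
        assert not ok

    def test_generator_round_trip(self):
        _, dil = gen_qpcr(
            {"g": {"a": 2.0, "body": 1.0}}, efficiencies={"g": 1.95}, noise_sd=0.0,
        )
        t = dil[dil.gene == "g"].sort_values("dilution")
        eff, ok = efficiency_from_curve(np.log10(1 / t.dilution), t.ct)
        assert eff == pytest.approx(1.95, rel=1e-9) and ok

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            efficiency_from_curve([0, 1, 2], [10, 11, 12])


class TestTukeyLetters:
    def test_extreme_separation(self, rng):
        groups = {
            "ant": 100 + rng.normal(0, 0.01, size=5),
            "body": 1 + rng.normal(0, 0.01, size=5),
        }
        assert tukey_letters(groups) == {"ant": "a", "body": "b"}

    def test_identical_groups_share_letter(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]}
        assert set(tukey_letters(groups).values()) == {"a"}

    def test_degenerate_variance_flagged(self):
        with pytest.raises(DegenerateVarianceError):
            tukey_letters({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_intermediate_group_shares_both_letters(self, rng):
        groups = {
            "hi": 10 + rng.normal(0, 1.0, size=6),
            "mid": 8.5 + rng.normal(0, 1.0, size=6),
            "lo": 0 + rng.normal(0, 1.0, size=6),
        }
        letters = tukey_letters(groups)
        assert letters["hi"] != letters["lo"]

    def test_significance_agrees_with_statsmodels_oracle(self, rng):
        """Pairwise Tukey decisions match statsmodels across simulations."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        agree = total = 0
        for _ in range(150):
            means = rng.uniform(0, 3, size=3)
            data = {
                f"g{i}": rng.normal(means[i], 1.0, size=5) for i in range(3)
            }
            letters = tukey_letters(data)
            values = np.concatenate(list(data.values()))
            labels = np.repeat(list(data), 5)
            res = pairwise_tukeyhsd(values, labels, alpha=0.05)
            for (a, b), reject in zip(
                [("g0", "g1"), ("g0", "g2"), ("g1", "g2")], res.reject
            ):
                ours = not set(letters[a]) & set(letters[b])
                total += 1
                agree += ours == reject
        assert agree / total > 0.95
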