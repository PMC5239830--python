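"""Normalization, dispersion recovery, test calibration, and contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bloodrna.diffabund import (
    ContrastDesign,
    enumerate_contrasts,
    estimate_dispersion,
    nb_test,
    normalize_counts,
    run_contrast,
    run_contrasts,
    upper_quartile_factors,
)
from bloodrna.quantify import EligibilityFilter

LIBS = ["a1", "a2", "a3", "b1", "b2", "b3"]
DESIGN = ContrastDesign("fraction_vs_fraction", tuple(LIBS[:3]), tuple(LIBS[3:]))


def nb_counts(rng, mu, alpha, n_libs):
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        draws = [rng.poisson(mu) for _ in range(n_libs)]
    else:
        r = 1.0 / alpha
        draws = [rng.negative_binomial(r, r / (r + mu)) for _ in range(n_libs)]
    return np.column_stack(draws)


class TestUpperQuartile:
    def test_known_quartiles(self):
        # libraries whose nonzero counts have 75th percentiles 100 and 400
        m = pd.DataFrame({"x": [100, 100, 100, 0], "y": [400, 400, 400, 0]})
        factors = upper_quartile_factors(m)
        assert factors["x"] == pytest.approx(0.5)
        assert factors["y"] == pytest.approx(2.0)

    def test_identical_libraries_unit_factors(self):
        m = pd.DataFrame({"x": [5, 10, 20], "y": [5, 10, 20]})
        assert np.allclose(upper_quartile_factors(m), 1.0)

    def test_geometric_mean_of_factors_is_one(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 1000, size=(50, 6)), columns=LIBS)
        factors = upper_quartile_factors(m)
        assert np.exp(np.log(factors).mean()) == pytest.approx(1.0)

    def test_all_zero_library_rejected_by_name(self):
        m = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            upper_quartile_factors(m)


class TestDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(21)
        mu = rng.lognormal(4, 0.5, 50)
        m = pd.DataFrame(nb_counts(rng, mu, 0.0, 6), columns=LIBS)
        alpha = estimate_dispersion(normalize_counts(m), DESIGN)
        assert np.median(alpha) <= 0.05

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(22)
        mu = rng.lognormal(5, 0.5, 200)
        m = pd.DataFrame(nb_counts(rng, mu, 0.5, 6), columns=LIBS)
        alpha = estimate_dispersion(normalize_counts(m), DESIGN)
        assert 0.2 <= np.median(alpha) <= 1.0

    def test_blind_mode_for_single_library_groups(self):
        rng = np.random.default_rng(23)
        m = pd.DataFrame(nb_counts(rng, np.full(20, 100.0), 0.3, 2),
                         columns=["a", "b"])
        design = ContrastDesign("cohort_vs_cohort", ("a",), ("b",))
        assert design.resolved_dispersion == "blind"
        alpha = estimate_dispersion(normalize_counts(m), design)
        assert np.isfinite(alpha).all() and (alpha > 0).all()


class TestNBTest:
    def test_identical_groups_null(self):
        m = pd.DataFrame(
            np.tile(np.array([[100.0], [200.0], [300.0]]), (1, 6)), columns=LIBS
        )
        res = run_contrast(m, DESIGN, EligibilityFilter(0))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p"] >= 0.99).all()

    def test_large_shift_detected(self):
        """Means 10 vs 1000 with small dispersion at n=3 per group."""
        rng = np.random.default_rng(31)
        a = nb_counts(rng, np.full(20, 10.0), 0.05, 3)
        b = nb_counts(rng, np.full(20, 1000.0), 0.05, 3)
        m = pd.DataFrame(np.column_stack([a, b]), columns=LIBS, dtype=float)
        alpha = pd.Series(0.05, index=m.index)
        res = nb_test(m, alpha, DESIGN)
        assert (res["p"] < 0.01).all()
        assert (res["log2fc"] > 0).all()

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(32)
        m = pd.DataFrame(nb_counts(rng, rng.lognormal(5, 1, 100), 0.2, 6),
                         columns=LIBS)
        flipped = ContrastDesign(DESIGN.mode, DESIGN.group_b, DESIGN.group_a)
        r1 = run_contrast(m, DESIGN, EligibilityFilter(0))
        r2 = run_contrast(m, flipped, EligibilityFilter(0))
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-12)
        assert np.allclose(r1["p"], r2["p"], atol=1e-12)

    def test_bh_matches_brute_force(self):
        """q-values equal the hand-rolled step-up computation."""
        rng = np.random.default_rng(33)
        m = pd.DataFrame(nb_counts(rng, rng.lognormal(5, 1, 80), 0.3, 6),
                         columns=LIBS)
        res = run_contrast(m, DESIGN, EligibilityFilter(0))
        p = res["p"].to_numpy()
        n = len(p)
        order = np.argsort(p)
        brute = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            brute[i] = running
        assert np.allclose(res["q"].to_numpy(), brute)

    def test_ineligible_features_flagged_without_p(self):
        m = pd.DataFrame({lib: [500.0, 1.0] for lib in LIBS}, index=["big", "small"])
        res = run_contrast(m, DESIGN, EligibilityFilter(100)).set_index("feature_id")
        assert bool(res.loc["big", "eligible"]) is True
        assert bool(res.loc["small", "eligible"]) is False
        assert np.isnan(res.loc["small", "p"]) and np.isnan(res.loc["small", "q"])

    def test_one_vs_one_conditional_test(self):
        m = pd.DataFrame({"a": [100.0, 400.0], "b": [100.0, 50.0]},
                         index=["same", "diff"])
        design = ContrastDesign("cohort_vs_cohort", ("a",), ("b",))
        res = nb_test(m, pd.Series(0.1, index=m.index), design).set_index("feature_id")
        assert res.loc["same", "p"] == pytest.approx(1.0)
        assert res.loc["diff", "p"] < 0.05
        assert res.loc["same", "log2fc"] == 0.0

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(34)
        mu = rng.lognormal(5, 1, 1000)
        m = pd.DataFrame(nb_counts(rng, mu, 0.1, 6), columns=LIBS)
        res = run_contrast(m, DESIGN, EligibilityFilter(100))
        rate = (res.loc[res["eligible"], "p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_eightfold_sensitivity(self):
        rng = np.random.default_rng(35)
        n = 1000
        mu = rng.lognormal(5, 1, n)
        planted = rng.choice(n, 100, replace=False)
        mu_b = mu.copy()
        mu_b[planted] *= 8
        m = pd.DataFrame(
            np.column_stack([nb_counts(rng, mu, 0.1, 3), nb_counts(rng, mu_b, 0.1, 3)]),
            columns=LIBS, index=[f"f{i}" for i in range(n)],
        )
        res = run_contrast(m, DESIGN, EligibilityFilter(100)).set_index("feature_id")
        sens = (res.iloc[planted]["q"] < 0.05).mean()
        assert sens >= 0.8


@pytest.fixture(scope="module")
def sheet():
    rows = [
        {"library_id": f"{f}_{c}", "fraction": f, "cohort": c}
        for f in ("I", "II", "III", "IV", "V")
        for c in ("H", "LSCC", "LAC")
    ]
    return pd.DataFrame(rows)


class TestContrastEnumeration:
    def test_ten_plus_ten_contrasts(self, sheet):
        contrasts = enumerate_contrasts(sheet)
        assert len(contrasts) == 20
        modes = pd.Series([c.mode for c in contrasts.values()]).value_counts()
        assert modes["fraction_vs_fraction"] == 10
        assert modes["cohort_vs_cohort"] == 10
        for c in contrasts.values():
            if c.mode == "fraction_vs_fraction":
                assert len(c.group_a) == 3 and c.resolved_dispersion == "per_condition"
            else:
                assert len(c.group_a) == 1 and c.resolved_dispersion == "blind"

    def test_missing_fraction_rejected(self, sheet):
        with pytest.raises(ValueError, match="missing fractions"):
            enumerate_contrasts(sheet[sheet.fraction != "III"])

    def test_run_contrasts_covers_all_eligible_features(self, sheet):
        rng = np.random.default_rng(40)
        libs = list(sheet["library_id"])
        mu = rng.lognormal(4, 1, 60)
        m = pd.DataFrame(nb_counts(rng, mu, 0.2, 15), columns=libs,
                         index=[f"f{i}" for i in range(60)])
        results = run_contrasts(m, sheet, EligibilityFilter(50))
        assert len(results) == 20
        for frame in results.values():
            assert list(frame["feature_id"]) == list(m.index)
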