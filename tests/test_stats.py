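"""Regression, significance, outlier classification and error profiling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from noestar import (
    DynamicsProfile,
    PredictionProfile,
    SequenceRecord,
    classify_outliers,
    composition_enrichment,
    fit_dynamics_regression,
    mean_error_rate,
    pearson_pvalue,
    predict_star_from_probability,
    residue_type_error_profile,
)
from noestar.simulate import SyntheticSpec, generate_dynamics_profile, generate_prediction_profile
from noestar.stats import ABOVE, BELOW, fit_xy
from noestar.transform import compute_nhnoe_star


def t_pvalue_by_quadrature(r: float, n: int) -> float:
    """Independent oracle: two-tailed tail mass of Student's t by numerical
    integration of the density written from its gamma-function form."""
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    norm = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(u):
        return norm * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(density, t, np.inf)
    return 2 * tail


def make_profiles(x, y, aa=None):
    """Wrap paired (probability, star) vectors as profiles; y is rescaled by
    its max so the NHNOE* normalization invariant holds (flags and the
    correlation are invariant to that common rescale)."""
    n = len(x)
    aa = aa if aa is not None else ["A"] * n
    y = np.asarray(y, dtype=float)
    y = y / np.nanmax(y)
    dyn = DynamicsProfile(
        residue_numbers=np.arange(1, n + 1),
        aa=aa,
        noe_raw=np.where(np.array(aa) == "P", np.nan, 0.0),
        nhnoe_star=np.where(np.array(aa) == "P", np.nan, y),
    )
    pred = PredictionProfile(
        residue_numbers=np.arange(1, n + 1),
        values=np.asarray(x, dtype=float),
        predictor_name="toy",
    )
    return pred, dyn


class TestPearsonPvalue:
    @pytest.mark.parametrize(
        "r,n,printed",
        [
            (0.55, 58, "0.000008"),
            (0.54, 58, "0.000012"),
            (0.42, 58, "0.00103"),
            (0.44, 60, "0.000435"),
            (0.49, 60, "0.000071"),
            (0.51, 60, "0.000031"),
            (0.58, 61, "0.000001"),
            (0.58, 60, "0.000001"),
            (0.59, 59, "0.000001"),
        ],
    )
    def test_reported_study_pvalues_recovered_at_printed_precision(self, r, n, printed):
        decimals = len(printed.split(".")[1])
        assert f"{pearson_pvalue(r, n):.{decimals}f}" == printed

    @pytest.mark.parametrize(
        "r,n,printed",
        [(0.53, 61, "0.000014"), (0.48, 62, "0.000065"), (0.43, 62, "0.000524")],
    )
    def test_remaining_study_rows_consistent_with_r_rounding(self, r, n, printed):
        """The tabulated r has two decimals; these printed p-values follow
        from correlations that round to the printed r."""
        from noestar.pipeline import consistent_within_r_rounding

        assert consistent_within_r_rounding(r, n, printed)

    @pytest.mark.parametrize("r,n", [(0.65, 60), (0.66, 59), (0.71, 61)])
    def test_reported_bounds_satisfied(self, r, n):
        assert pearson_pvalue(r, n) <= 1e-6

    def test_zero_correlation_gives_p_one(self):
        assert pearson_pvalue(0.0, 10) == 1.0
        assert pearson_pvalue(0.0, 300) == 1.0

    def test_perfect_correlation_limit(self):
        assert pearson_pvalue(1.0, 10) == 0.0

    @pytest.mark.parametrize("r", [1.2, -0.1])
    def test_domain_errors(self, r):
        with pytest.raises(ValueError):
            pearson_pvalue(r, 10)
        with pytest.raises(ValueError):
            pearson_pvalue(0.5, 2)

    def test_matches_quadrature_oracle_to_6_significant_figures(self):
        for r in np.arange(0.1, 0.95, 0.1):
            for n in (10, 30, 60):
                p = pearson_pvalue(float(r), n)
                oracle = t_pvalue_by_quadrature(float(r), n)
                assert p == pytest.approx(oracle, rel=1e-6)

    def test_monotone_decreasing_in_r_and_n(self):
        rs = np.arange(0.05, 1.0, 0.05)
        ps = [pearson_pvalue(float(r), 30) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ns = [5, 10, 20, 40, 80, 160]
        ps = [pearson_pvalue(0.4, n) for n in ns]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestRegression:
    def test_perfect_negative_line(self):
        x = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        reg = fit_xy(x, 1 - x)
        assert reg.r == pytest.approx(1.0)
        assert reg.sign == -1
        assert reg.p_two_tailed < 1e-3
        assert reg.sigma_resid == pytest.approx(0.0, abs=1e-12)

    def test_six_point_toy_against_normal_equations(self):
        """Closed-form least-squares oracle from the raw sums."""
        x = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        y = np.array([0.9, 0.8, 0.6, 0.5, 0.2, 0.1])
        n = len(x)
        sxx = (x * x).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        syy = (y * y).sum() - y.sum() ** 2 / n
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        r = abs(sxy) / math.sqrt(sxx * syy)
        sse = ((y - slope * x - intercept) ** 2).sum()
        reg = fit_xy(x, y)
        assert reg.slope == pytest.approx(slope)
        assert reg.intercept == pytest.approx(intercept)
        assert reg.r == pytest.approx(r)
        assert reg.sign == -1
        assert reg.sigma_resid == pytest.approx(math.sqrt(sse / (n - 2)))

    def test_pairing_drops_missing_listwise(self, toy_dynamics):
        pred = PredictionProfile(
            residue_numbers=np.arange(1, 11),
            values=np.linspace(0.05, 0.95, 10),
            predictor_name="toy",
        )
        reg = fit_dynamics_regression(pred, toy_dynamics)
        assert reg.n == 8  # two prolines drop out

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(ValueError, match="n = 2"):
            fit_xy(np.array([0.1, 0.2]), np.array([0.3, 0.4]))
        with pytest.raises(ValueError, match="variance"):
            fit_xy(np.array([0.5, 0.5, 0.5]), np.array([0.1, 0.2, 0.3]))

    def test_residuals_sum_to_zero_and_line_passes_through_means(self, rng):
        x = rng.uniform(size=30)
        y = 0.8 - 0.5 * x + rng.normal(0, 0.1, 30)
        reg = fit_xy(x, y)
        resid = y - (reg.slope * x + reg.intercept)
        assert resid.sum() == pytest.approx(0.0, abs=1e-10)
        assert predict_star_from_probability(reg, x.mean()) == pytest.approx(y.mean())

    def test_predict_is_plain_line_evaluation(self):
        from noestar.stats import RegressionResult

        reg = RegressionResult(
            slope=-1.0, intercept=1.0, r=0.9, sign=-1, n=10,
            p_two_tailed=0.001, sigma_resid=0.1,
        )
        assert predict_star_from_probability(reg, 0.94) == pytest.approx(0.06)


class TestClassifyOutliers:
    def _planted_residual_fixture(self):
        """Residuals orthogonal to {1, x} so OLS returns the base line
        exactly and every flag is computable in closed form."""
        n = 22
        x = np.linspace(0.05, 0.95, n)
        pattern = 0.02 * (-1.0) ** np.arange(n)
        pattern[5] = 0.25  # the planted outlier
        basis = np.vstack([np.ones(n), x]).T
        coef, *_ = np.linalg.lstsq(basis, pattern, rcond=None)
        d = pattern - basis @ coef
        y = 0.9 - 0.5 * x + d
        sigma = math.sqrt((d @ d) / (n - 2))
        return x, y, d, sigma

    def test_planted_outlier_flagged_at_k2_and_only_it(self):
        x, y, d, sigma = self._planted_residual_fixture()
        expected = {i + 1 for i in np.flatnonzero(np.abs(d) >= 2 * sigma)}
        assert expected == {6}
        pred, dyn = make_profiles(x, y)
        table = classify_outliers(pred, dyn, k_sigma=2)
        assert set(table["residue"]) == expected
        assert not table.attrs["any_beyond_cap"] is None

    def test_flag_set_matches_residual_oracle_at_k1(self):
        x, y, d, sigma = self._planted_residual_fixture()
        expected = set(np.flatnonzero(np.abs(d) >= sigma) + 1)
        pred, dyn = make_profiles(x, y)
        table = classify_outliers(pred, dyn, k_sigma=1)
        assert set(table["residue"]) == expected

    def test_direction_above_means_predicted_more_disordered(self):
        x, y, d, sigma = self._planted_residual_fixture()
        pred, dyn = make_profiles(x, y)
        table = classify_outliers(pred, dyn, k_sigma=1).set_index("residue")
        # planted residual is positive and the association negative: the
        # probability overcalled disorder relative to the observed star
        assert table.loc[6, "direction"] == ABOVE
        for res, row in table.iterrows():
            observed_above_line = row["observed_star"] > row["predicted_star"]
            assert (row["direction"] == ABOVE) == observed_above_line

    def test_gaussian_residuals_flag_about_one_sigma_tail_mass(self, rng):
        n = 50_000
        x = rng.uniform(size=n)
        y = 0.8 - 0.5 * x + rng.normal(0, 0.08, n)
        pred, dyn = make_profiles(x, y)
        table = classify_outliers(pred, dyn, k_sigma=1)
        fraction = len(table) / n
        assert fraction == pytest.approx(0.3173, abs=0.01)

    def test_zero_sigma_regression_flags_any_deviation(self):
        x = np.array([0.0, 0.3, 0.5, 0.7, 0.9])
        reg = fit_xy(x, 1 - x)  # perfect line, sigma_resid == 0
        # downward bump keeps the max at 1 so the profile is not rescaled
        pred, dyn = make_profiles(x, 1 - x - np.array([0, 0, 0.05, 0, 0]))
        table = classify_outliers(pred, dyn, reg=reg, k_sigma=2)
        assert list(table["residue"]) == [3]
        assert np.isinf(table["residual_sigmas"].iloc[0])

    def test_invalid_k_rejected(self, toy_dynamics):
        pred = PredictionProfile(
            residue_numbers=np.arange(1, 11),
            values=np.linspace(0, 1, 10),
            predictor_name="toy",
        )
        with pytest.raises(ValueError, match="k_sigma"):
            classify_outliers(pred, toy_dynamics, k_sigma=0)


def outlier_row(aa, direction, residue=1, predictor="toy"):
    return {
        "residue": residue, "aa": aa, "predictor": predictor,
        "probability": 0.5, "predicted_star": 0.4, "observed_star": 0.6,
        "residual_sigmas": 1.5, "direction": direction,
    }


class TestErrorProfile:
    def test_counting_oracle_two_sequences(self):
        """2 sequences x 3 L each, 2 flagged L -> 33.3%."""
        seqs = [
            SequenceRecord(identifier="s1", residues="LALALAK"),
            SequenceRecord(identifier="s2", residues="KLLLAAA"),
        ]
        flags = pd.DataFrame(
            [outlier_row("L", BELOW, 1), outlier_row("L", ABOVE, 3)]
        )
        profile = residue_type_error_profile([flags], seqs)
        row = profile.table.loc["L"]
        assert row["count_total"] == 6
        assert row["count_flagged"] == 2
        assert row["relative_percentage"] == pytest.approx(100 * 2 / 6)
        assert row["count_above"] == 1 and row["count_below"] == 1

    def test_no_flags_gives_zero_for_present_types(self):
        seqs = [SequenceRecord(identifier="s", residues="KAKAKA")]
        empty = pd.DataFrame(columns=list(outlier_row("L", ABOVE)))
        profile = residue_type_error_profile([empty], seqs)
        assert profile.table.loc["K", "relative_percentage"] == 0.0
        assert profile.table.loc["A", "relative_percentage"] == 0.0

    def test_absent_type_undefined_not_zero(self):
        seqs = [SequenceRecord(identifier="s", residues="KAKAKA")]
        empty = pd.DataFrame(columns=list(outlier_row("L", ABOVE)))
        profile = residue_type_error_profile([empty], seqs)
        assert np.isnan(profile.table.loc["W", "relative_percentage"])
        assert profile.table.loc["W", "annotation"] == "ABSENT"

    def test_proline_reported_zero_with_not_measurable_flag(self):
        seqs = [SequenceRecord(identifier="s", residues="PAPAKL")]
        empty = pd.DataFrame(columns=list(outlier_row("L", ABOVE)))
        profile = residue_type_error_profile([empty], seqs)
        assert profile.table.loc["P", "relative_percentage"] == 0.0
        assert profile.table.loc["P", "annotation"] == "NOT_MEASURABLE"

    def test_mean_error_rate_single_type(self):
        seqs = [SequenceRecord(identifier="s", residues="LLL")]
        flags = pd.DataFrame([outlier_row("L", ABOVE, r) for r in (1,)])
        profile = residue_type_error_profile([flags], seqs)
        mean, sd, excluded = mean_error_rate(profile)
        assert mean == pytest.approx(100 / 3)
        assert sd == 0.0

    def test_mean_error_rate_two_pass_sd_oracle(self):
        """Types at 10/20/30% -> mean 20, sample sd by an independent
        two-pass computation."""
        seqs = [
            SequenceRecord(
                identifier=f"s{i}", residues="K" * 10 + "A" * 10 + "L" * 10
            )
            for i in range(2)
        ]
        flags = pd.DataFrame(
            [outlier_row("K", ABOVE, r) for r in range(1, 3)]
            + [outlier_row("A", ABOVE, r) for r in range(11, 15)]
            + [outlier_row("L", BELOW, r) for r in range(21, 27)]
        )
        profile = residue_type_error_profile([flags], seqs)
        mean, sd, _ = mean_error_rate(profile)
        values = [10.0, 20.0, 30.0]
        m = sum(values) / 3
        two_pass_sd = math.sqrt(sum((v - m) ** 2 for v in values) / 2)
        assert mean == pytest.approx(20.0)
        assert sd == pytest.approx(two_pass_sd)

    def test_occurrence_exclusion_rule(self):
        # W occurs in only one of the two sequences -> excluded
        seqs = [
            SequenceRecord(identifier="s1", residues="KKKWAA"),
            SequenceRecord(identifier="s2", residues="KKKAAA"),
        ]
        flags = pd.DataFrame([outlier_row("W", ABOVE, 4)])
        profile = residue_type_error_profile([flags], seqs)
        mean, sd, excluded = mean_error_rate(profile)
        assert "W" in excluded
        assert mean == 0.0  # only K and A qualify, neither flagged

    def test_no_qualifying_types_is_an_error(self):
        seqs = [SequenceRecord(identifier="s", residues="PPP")]
        empty = pd.DataFrame(columns=list(outlier_row("L", ABOVE)))
        profile = residue_type_error_profile([empty], seqs)
        with pytest.raises(ValueError, match="qualify"):
            mean_error_rate(profile)


class TestCompositionEnrichment:
    def test_observed_equals_reference_gives_zero(self):
        seqs = [SequenceRecord(identifier="s", residues="KKAALL")]
        ref = {"K": 1 / 3, "A": 1 / 3, "L": 1 / 3}
        out = composition_enrichment(seqs, ref)
        for aa in "KAL":
            assert out[aa] == pytest.approx(0.0)

    def test_ninety_percent_enrichment_arithmetic(self):
        # observed L fraction 0.19 vs reference 0.10 -> +90%
        seqs = [SequenceRecord(identifier="s", residues="L" * 19 + "K" * 81)]
        ref = {"L": 0.10, "K": 0.90}
        out = composition_enrichment(seqs, ref)
        assert out["L"] == pytest.approx(90.0)

    def test_observed_fractions_sum_to_one(self):
        seqs = [SequenceRecord(identifier="s", residues="MEEPQSDPSV")]
        pooled = pd.DataFrame({"s": seqs[0].composition()}).sum(axis=1)
        assert (pooled / pooled.sum()).sum() == pytest.approx(1.0)

    def test_zero_reference_for_observed_type_rejected(self):
        seqs = [SequenceRecord(identifier="s", residues="KKLL")]
        with pytest.raises(ValueError, match="zero"):
            composition_enrichment(seqs, {"K": 0.5, "L": 0.0, "A": 0.5})


class TestPlantedCorrelationRecovery:
    def test_fitted_r_within_fisher_interval_of_planted_rho(self):
        """>= 93% of 500 seeded replicates land in the 95% Fisher-z CI."""
        rho, n_reps = 0.55, 500
        spec = SyntheticSpec(
            length=70,
            bumps=((22, 5.0, 8e-10), (50, 6.0, 5e-10)),
            planted_rho=rho,
            noise_sd=0.10,
            proline_positions=frozenset({4, 8, 12, 13, 27, 34, 36, 47, 58, 60}),
            seed=3,
        )
        dyn = compute_nhnoe_star(generate_dynamics_profile(spec))
        hits = 0
        for k in range(n_reps):
            pred = generate_prediction_profile(dyn, spec, seed_offset=k + 1)
            reg = fit_dynamics_regression(pred, dyn)
            halfwidth = 1.96 / math.sqrt(reg.n - 3)
            if abs(math.atanh(reg.r) - math.atanh(rho)) <= halfwidth:
                hits += 1
        assert hits / n_reps >= 0.93
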