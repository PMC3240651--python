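"""Regression of NHNOE* on disorder probability and its error profiling.

The statistical questions answered here:

* How strongly does a predictor's per-residue disorder probability track
  measured backbone dynamics?  Ordinary least squares of NHNOE* (response)
  on probability, with the Pearson correlation reported as a magnitude (the
  association is negative; the sign is carried separately) and a two-tailed
  p-value from the exact t transform ``t = r*sqrt(n-2)/sqrt(1-r^2)``.

* Which residues does a predictor get wrong?  Residues whose observed
  NHNOE* sits at least k residual standard errors (sigma, df = n-2) from
  the fitted conditional mean are flagged, with a direction: ABOVE means
  the predictor erred toward more disorder than observed, BELOW toward
  more order.

* Which residue *types* are systematically mispredicted?  Flag counts per
  type pooled across proteins and predictors, divided by how often the type
  occurs in the sequence set, as a percentage; plus the mean +/- sd error
  rate over types occurring in every homologue, and composition enrichment
  of the sequence set against a reference amino-acid composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AMINO_ACIDS, DynamicsProfile, PredictionProfile, SequenceRecord

__all__ = [
    "RegressionResult",
    "ErrorProfile",
    "pearson_pvalue",
    "fit_xy",
    "fit_dynamics_regression",
    "predict_star_from_probability",
    "classify_outliers",
    "residue_type_error_profile",
    "mean_error_rate",
    "composition_enrichment",
]

ABOVE = "ABOVE"
BELOW = "BELOW"
NOT_MEASURABLE = "NOT_MEASURABLE"


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit of NHNOE* (y) on disorder probability (x).

    ``r`` is the correlation magnitude in [0, 1] as conventionally tabulated
    for this analysis; ``sign`` (+1/-1) carries the direction of association.
    ``sigma_resid`` is the residual standard error sqrt(SSE/(n-2)) — the
    yardstick for the >=1 sigma misprediction rule.
    """

    slope: float
    intercept: float
    r: float
    sign: int
    n: int
    p_two_tailed: float
    sigma_resid: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not 0 <= self.r <= 1:
            raise ValueError("r is stored as a magnitude in [0, 1]")
        if self.sigma_resid < 0:
            raise ValueError("sigma_resid must be >= 0")

    @property
    def signed_r(self) -> float:
        return self.sign * self.r


def pearson_pvalue(r: float, n: int) -> float:
    """Two-tailed p-value for a Pearson correlation magnitude.

    Uses the exact null relation t = r*sqrt(n-2)/sqrt(1-r^2) with Student's
    t on n-2 degrees of freedom.  Monotone decreasing in both r and n.
    r = 1 returns 0 exactly (the limit case).
    """
    if not 0 <= r <= 1:
        raise ValueError(f"correlation magnitude must be in [0, 1], got {r}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if r == 1:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return 2.0 * float(sps.t.sf(t, n - 2))


def fit_xy(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x for already-paired, complete vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"insufficient data: n = {n} < 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; regression is degenerate")
    fit = sps.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sigma = math.sqrt(float(resid @ resid) / (n - 2))
    r_mag = abs(float(fit.rvalue))
    sign = -1 if fit.rvalue < 0 else 1
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=min(r_mag, 1.0),
        sign=sign,
        n=n,
        p_two_tailed=pearson_pvalue(min(r_mag, 1.0), n),
        sigma_resid=sigma,
    )


def paired_values(
    prediction: PredictionProfile, dynamics: DynamicsProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residue numbers, probabilities and NHNOE* where both sides are present.

    Pairs form only on shared residue numbers with neither value missing, so
    prolines and unassigned residues drop out listwise.
    """
    if dynamics.nhnoe_star is None:
        raise ValueError("dynamics profile has no NHNOE* column; transform first")
    star_by_num = dict(zip(dynamics.residue_numbers, dynamics.nhnoe_star))
    nums, xs, ys = [], [], []
    for num, prob in zip(prediction.residue_numbers, prediction.values):
        star = star_by_num.get(int(num), np.nan)
        if not (np.isnan(prob) or np.isnan(star)):
            nums.append(int(num))
            xs.append(float(prob))
            ys.append(float(star))
    return np.array(nums), np.array(xs), np.array(ys)


def fit_dynamics_regression(
    prediction: PredictionProfile, dynamics: DynamicsProfile
) -> RegressionResult:
    """Regress NHNOE* on one predictor's probabilities for one protein."""
    _, x, y = paired_values(prediction, dynamics)
    return fit_xy(x, y)


def predict_star_from_probability(
    reg: RegressionResult, probability: float | np.ndarray
) -> float | np.ndarray:
    """NHNOE* the fitted line assigns to a disorder probability (unclamped)."""
    return reg.slope * probability + reg.intercept


def classify_outliers(
    prediction: PredictionProfile,
    dynamics: DynamicsProfile,
    reg: RegressionResult | None = None,
    k_sigma: float = 1.0,
    cap_sigma: float = 2.0,
) -> pd.DataFrame:
    """Residues whose observed NHNOE* is >= k sigma from the fitted mean.

    Returns a table with one row per flagged residue: residue number, type,
    predictor, probability, predicted and observed NHNOE*, the residual in
    sigma units, the direction of the error, and whether the residual also
    exceeds ``cap_sigma`` (the conventional outlier cutoff; attrs record
    whether any residue did).

    Direction: under the negative association a positive residual (observed
    star above the line) means the predictor called the residue more
    disordered than the dynamics show — ABOVE; BELOW is the converse.  With
    a positive-slope fit the roles of the residual signs swap.

    When ``sigma_resid`` is exactly zero, any nonzero residual is flagged
    (its sigma multiple is reported as infinity).
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be > 0")
    if reg is None:
        reg = fit_dynamics_regression(prediction, dynamics)
    nums, x, y = paired_values(prediction, dynamics)
    predicted = predict_star_from_probability(reg, x)
    resid = y - predicted
    with np.errstate(divide="ignore"):
        sigmas = np.where(
            resid == 0,
            0.0,
            np.abs(resid) / reg.sigma_resid if reg.sigma_resid > 0 else np.inf,
        )
    flagged = sigmas >= k_sigma
    # residual > 0 reads "more disordered than observed" only when the
    # association (slope) is negative
    more_disordered = resid > 0 if reg.slope < 0 else resid < 0
    aa = {int(n): a for n, a in zip(dynamics.residue_numbers, dynamics.aa)}
    table = pd.DataFrame(
        {
            "residue": nums[flagged],
            "aa": [aa[int(n)] for n in nums[flagged]],
            "predictor": prediction.predictor_name,
            "probability": x[flagged],
            "predicted_star": predicted[flagged],
            "observed_star": y[flagged],
            "residual_sigmas": sigmas[flagged],
            "direction": np.where(more_disordered[flagged], ABOVE, BELOW),
        }
    )
    table.attrs["k_sigma"] = k_sigma
    table.attrs["cap_sigma"] = cap_sigma
    table.attrs["any_beyond_cap"] = bool((sigmas > cap_sigma).any())
    table.attrs["n_pairs"] = int(len(nums))
    return table


@dataclass
class ErrorProfile:
    """Per-residue-type misprediction profile pooled over the sequence set.

    ``table`` is indexed by amino-acid type with columns ``count_flagged``,
    ``count_total``, ``relative_percentage`` (100 * flagged/total),
    ``count_above``, ``count_below`` and ``annotation``.  Types absent from
    the sequences have NaN percentage (undefined, not zero); proline is
    reported as 0 with a NOT_MEASURABLE annotation since its NOE cannot be
    measured at all.
    """

    table: pd.DataFrame
    per_homologue_counts: pd.DataFrame  # types x sequences occurrence counts


def residue_type_error_profile(
    outlier_tables: Iterable[pd.DataFrame],
    sequences: Sequence[SequenceRecord],
) -> ErrorProfile:
    """Pool flagged residues by type and normalize by type occurrence.

    The numerator counts every flag event across proteins and predictors
    (a residue flagged by two predictors counts twice); the denominator is
    the number of occurrences of the type in the sequence set, so the
    percentage measures flags per residue of that type.
    """
    pooled = pd.concat(list(outlier_tables), ignore_index=True)
    counts_by_seq = pd.DataFrame(
        {rec.identifier: rec.composition() for rec in sequences}
    ).reindex(list(AMINO_ACIDS))
    totals = counts_by_seq.sum(axis=1)

    rows = []
    for aa in AMINO_ACIDS:
        flags = pooled[pooled["aa"] == aa]
        n_above = int((flags["direction"] == ABOVE).sum())
        n_below = int((flags["direction"] == BELOW).sum())
        total = int(totals[aa])
        if aa == "P":
            pct, note = 0.0, NOT_MEASURABLE
        elif total == 0:
            pct, note = np.nan, "ABSENT"
        else:
            pct, note = 100.0 * (n_above + n_below) / total, ""
        rows.append(
            {
                "aa": aa,
                "count_flagged": n_above + n_below,
                "count_total": total,
                "relative_percentage": pct,
                "count_above": n_above,
                "count_below": n_below,
                "annotation": note,
            }
        )
    table = pd.DataFrame(rows).set_index("aa")
    return ErrorProfile(table=table, per_homologue_counts=counts_by_seq)


def mean_error_rate(
    profile: ErrorProfile,
    min_per_homologue: int = 1,
    include_not_measurable: bool = False,
) -> tuple[float, float, list[str]]:
    """Mean and sd of per-type error percentages over qualifying types.

    A type qualifies when it occurs at least ``min_per_homologue`` times in
    every sequence of the set.  Proline's structural zero (its NOE is not
    measurable, so it can never be flagged) is excluded by default so the
    summary reflects prediction errors only.  The sd uses the sample (n-1)
    convention.  Returns ``(mean_pct, sd_pct, excluded_types)``.
    """
    counts = profile.per_homologue_counts
    qualifies = (counts >= min_per_homologue).all(axis=1)
    if not include_not_measurable:
        not_measurable = profile.table["annotation"] == NOT_MEASURABLE
        qualifies &= ~not_measurable
    included = profile.table.loc[qualifies, "relative_percentage"].dropna()
    excluded = sorted(set(profile.table.index) - set(included.index))
    if included.empty:
        raise ValueError("no residue types qualify for the error-rate summary")
    mean = float(included.mean())
    sd = float(included.std(ddof=1)) if len(included) > 1 else 0.0
    return mean, sd, excluded


def composition_enrichment(
    sequences: Sequence[SequenceRecord],
    reference_freqs: Mapping[str, float],
) -> pd.Series:
    """Relative difference (%) of pooled composition vs a reference.

    ``100 * (observed_freq / reference_freq - 1)`` per type, with observed
    frequencies pooled over all input sequences.  A type observed in the
    sequences but absent (frequency 0) from the reference is a domain error.
    """
    total_ref = sum(reference_freqs.values())
    if not math.isclose(total_ref, 1.0, abs_tol=0.02):
        raise ValueError(
            f"reference frequencies should sum to ~1, got {total_ref:.4f}"
        )
    pooled = pd.DataFrame(
        {rec.identifier: rec.composition() for rec in sequences}
    ).sum(axis=1)
    observed = pooled / pooled.sum()
    out = {}
    for aa in AMINO_ACIDS:
        ref = reference_freqs.get(aa, 0.0)
        if ref <= 0:
            if observed[aa] > 0:
                raise ValueError(
                    f"reference frequency for {aa!r} is zero but it occurs "
                    "in the sequences"
                )
            out[aa] = np.nan
        else:
            out[aa] = 100.0 * (observed[aa] / ref - 1.0)
    return pd.Series(out, name="relative_difference_pct")
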