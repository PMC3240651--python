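"""The NHNOE* statistic and the 5-residue display smoothing.

NHNOE* rescales raw steady-state NOE ratios onto (0, 1]: each raw value is
antilogged (base 10 by default) and divided by the maximum antilog over the
protein, so 1 marks the least flexible residue and values near 0 the most
flexible.  The transform is monotone, so residue rankings are independent of
the antilog base, and shift-invariant, since adding a constant to every raw
value cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import DynamicsProfile

__all__ = ["TransformConfig", "compute_nhnoe_star", "smooth_profile"]


@dataclass(frozen=True)
class TransformConfig:
    """Knobs of the dynamics transform.

    antilog_base:
        Base of the antilog applied to raw NOE values; any base > 1 yields
        identical residue rankings.  Default 10 (common-log convention).
    smoothing_window:
        Odd window for the centered moving average used in plots/reports.
    smooth_before_regression:
        If true, regressions downstream consume smoothed values; by default
        smoothing is cosmetic only and regressions run per-residue.
    """

    antilog_base: float = 10.0
    smoothing_window: int = 5
    smooth_before_regression: bool = False

    def __post_init__(self) -> None:
        if self.antilog_base <= 0 or self.antilog_base == 1:
            raise ValueError("antilog base must be positive and != 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 1")


def nhnoe_star_values(
    noe_raw: np.ndarray, base: float = 10.0
) -> np.ndarray:
    """NHNOE* for a raw NOE vector (NaN-aware).

    Computed as ``base**(x - max(x))`` so the ratio form never overflows;
    missing entries propagate as NaN.
    """
    raw = np.asarray(noe_raw, dtype=float)
    present = ~np.isnan(raw)
    if not present.any():
        raise ValueError("all NOE values missing; cannot normalize")
    peak = raw[present].max()
    out = np.full_like(raw, np.nan)
    out[present] = np.power(base, raw[present] - peak)
    return out


def compute_nhnoe_star(
    profile: DynamicsProfile, cfg: TransformConfig | None = None
) -> DynamicsProfile:
    """Return a copy of the profile with the nhnoe_star column filled in."""
    cfg = cfg or TransformConfig()
    star = nhnoe_star_values(profile.noe_raw, cfg.antilog_base)
    return replace(profile, nhnoe_star=star)


def smooth_profile(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with truncated terminal windows.

    Missing (NaN) entries are left out of each window's mean; an output
    position is NaN only when every value in its window is missing.  Windows
    shrink at the termini rather than padding, so a constant vector maps to
    itself and every output is a convex combination of inputs.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    x = np.asarray(values, dtype=float)
    half = window // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        chunk = x[max(0, i - half) : i + half + 1]
        good = chunk[~np.isnan(chunk)]
        if good.size:
            out[i] = good.mean()
    return out
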