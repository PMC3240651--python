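"""A windowed-propensity stand-in disorder predictor.

Real disorder predictors (VL-XT, IUPred, VSL2B) are external services with
trained models; this module provides a deliberately simple, self-contained
substitute so the pipeline can run end to end: each residue gets the mean
disorder propensity of a sliding window (9 residues by default, truncated
at the termini), min-max calibrated onto [0, 1].  It reproduces the
qualitative structure the analysis cares about — order-promoting residues
(L, V) pull scores down, disorder-promoting ones (E, P) push them up — and
makes no claim of equivalence to any published predictor.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .io import AMINO_ACIDS, PredictionProfile, SequenceRecord

__all__ = ["PropensityScale", "load_default_scale", "predict_disorder"]


@dataclass(frozen=True)
class PropensityScale:
    """Per-type disorder propensities plus windowing and calibration.

    Higher propensity means more disorder-promoting.  Calibration is the
    min-max map over the scale's achievable window means (attained by
    homopolymers), i.e. a linear rescale from [min propensity, max
    propensity] onto [0, 1].
    """

    values: dict[str, float]
    window: int = 9
    name: str = "propensity"

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        if missing:
            raise ValueError(f"scale is missing residue types: {missing}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")

    def calibrate(self, windowed_mean: np.ndarray) -> np.ndarray:
        lo = min(self.values.values())
        hi = max(self.values.values())
        return (np.asarray(windowed_mean) - lo) / (hi - lo)


def load_default_scale(path: str | Path | None = None) -> PropensityScale:
    """Load the propensity scale shipped with the package (or a user file)."""
    if path is None:
        text = (
            resources.files("noestar.data")
            .joinpath("propensity_scale.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return PropensityScale(
        values={str(k): float(v) for k, v in cfg["propensities"].items()},
        window=int(cfg.get("window", 9)),
        name=str(cfg.get("name", "propensity")),
    )


def predict_disorder(
    seq: SequenceRecord, scale: PropensityScale | None = None
) -> PredictionProfile:
    """Per-residue disorder probabilities for a gap-free sequence."""
    scale = scale or load_default_scale()
    if "-" in seq.residues:
        raise ValueError("predictor needs a gap-free sequence")
    try:
        per_res = np.array([scale.values[aa] for aa in seq.residues])
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from exc
    half = scale.window // 2
    means = np.empty(len(per_res))
    for i in range(len(per_res)):
        means[i] = per_res[max(0, i - half) : i + half + 1].mean()
    return PredictionProfile(
        residue_numbers=seq.residue_numbers(),
        values=np.clip(scale.calibrate(means), 0.0, 1.0),
        predictor_name=scale.name,
        protein=seq,
    )
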