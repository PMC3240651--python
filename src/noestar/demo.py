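"""A self-contained six-homologue study on synthetic data.

Mirrors the structure of the real analysis — six p53TAD-like sequences,
three disorder predictors each, regressions pooled into an error profile —
with every input generated by :mod:`noestar.simulate` and
:mod:`noestar.fixtures`.
"""

from __future__ import annotations

import pandas as pd

from .fixtures import synthetic_family
from .pipeline import ErrorProfileReport, RunConfig, run_correlate, run_error_profile
from .predictor import load_default_scale, predict_disorder
from .simulate import generate_dynamics_profile, generate_prediction_profile, p53tad_like_spec
from .transform import compute_nhnoe_star

PREDICTORS = ("plantedA", "plantedB", "propensity9")


def demo_family_run(
    seed: int = 0,
    planted_rho: float = 0.55,
    noise_sd: float = 0.10,
) -> tuple[RunConfig, pd.DataFrame, ErrorProfileReport]:
    """Simulate and analyse the full homologue family.

    Each homologue gets physics-derived dynamics (transient-helix bumps at
    the MDM2- and RPA70-like regions), two planted-association predictors
    at independent seeds, and the windowed-propensity stand-in predictor.
    Returns the run configuration, the regression table and the pooled
    per-type error profile.
    """
    family = synthetic_family(seed)
    scale = load_default_scale()
    dynamics = {}
    predictions = {}
    for k, seq in enumerate(family):
        spec = p53tad_like_spec(
            length=len(seq),
            seed=seed * 1009 + k,
            planted_rho=planted_rho,
            noise_sd=noise_sd,
        )
        dyn = compute_nhnoe_star(generate_dynamics_profile(spec, seq))
        dynamics[seq.identifier] = dyn
        predictions[(seq.identifier, "plantedA")] = generate_prediction_profile(
            dyn, spec, predictor_name="plantedA", seed_offset=1
        )
        predictions[(seq.identifier, "plantedB")] = generate_prediction_profile(
            dyn, spec, predictor_name="plantedB", seed_offset=2
        )
        predictions[(seq.identifier, scale.name)] = predict_disorder(seq, scale)
    config = RunConfig(
        dynamics=dynamics,
        predictions=predictions,
        sequences={seq.identifier: seq for seq in family},
        seed=seed,
    )
    correlations = run_correlate(config)
    error_report = run_error_profile(config)
    return config, correlations, error_report
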