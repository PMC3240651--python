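"""Synthetic IDP dynamics and disorder-probability profiles.

The generator emulates the data-generating process the analysis assumes,
from the physics up:

1.  A per-residue local rotational correlation-time profile tau(i):
    a baseline in the IDP range (hundreds of picoseconds), exponential
    decay toward a floor at both termini (the polymer end effect), and
    Gaussian "bumps" of elevated tau where transient helical structure
    rigidifies the backbone (for p53TAD-like chains, the MDM2 site near
    residues 15-30 and the RPA70 site near 40-60).

2.  The steady-state 15N{1H} NOE each tau implies, from standard
    single-Lorentzian spectral-density relaxation theory:
    J(w) = (2/5) tau / (1 + (w tau)^2), dipolar cross-relaxation
    sigma_NH = (d^2/4)(6 J(wH+wN) - J(wH-wN)), longitudinal rate
    R1 = (d^2/4)(J(wH-wN) + 3 J(wN) + 6 J(wH+wN)) + c^2 J(wN), and
    NOE = 1 + (gammaH/gammaN) sigma_NH / R1.  The NOE is monotone
    increasing in tau, from about -3.9 in the extreme-narrowing limit to
    a plateau near +0.8 for rigid tumbling at 600 MHz.

3.  A measured profile: the mean of three noisy replicates per residue
    (mirroring triplicate NOE experiments), prolines missing.

4.  A disorder-probability profile with a planted negative linear
    association to NHNOE*: p(i) = clip01(a - b*star(i) + eps), with b
    calibrated from the noise level so the expected correlation magnitude
    hits ``planted_rho``, and the realized noise-free association (which
    clipping can attenuate) reported alongside the target.

Identical seed and spec give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import DynamicsProfile, PredictionProfile, SequenceRecord
from .transform import TransformConfig, compute_nhnoe_star

__all__ = [
    "RelaxationConstants",
    "SyntheticSpec",
    "build_tau_profile",
    "noe_from_tau",
    "generate_dynamics_profile",
    "generate_prediction_profile",
]

MU0 = 4e-7 * math.pi  # vacuum permeability, T m / A
HBAR = 1.054571817e-34  # J s

TAU_MIN_PHYS = 1e-11  # bounds of the physically sensible range, s
TAU_MAX_PHYS = 1e-7


@dataclass(frozen=True)
class RelaxationConstants:
    """Constants of the 15N-1H dipolar/CSA relaxation model.

    gamma_h / gamma_n are the 1H and 15N gyromagnetic ratios (rad/s/T;
    gamma_n is negative, which is what makes the IDP NOE negative at short
    tau), r_nh the N-H bond length and csa_ppm the axially symmetric 15N
    chemical-shift anisotropy.
    """

    gamma_h: float = 2.6752218744e8
    gamma_n: float = -2.7116e7
    r_nh: float = 1.02e-10
    csa_ppm: float = -160.0
    include_csa: bool = True

    def __post_init__(self) -> None:
        if self.gamma_n >= 0:
            raise ValueError("gamma_n must be negative for 15N")

    def omegas(self, field_mhz: float) -> tuple[float, float]:
        """(omega_H, omega_N) in rad/s at a 1H frequency in MHz."""
        w_h = 2 * math.pi * field_mhz * 1e6
        return w_h, w_h * self.gamma_n / self.gamma_h


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one synthetic protein.

    Times are seconds.  ``bumps`` is a list of (center residue, width in
    residues, tau_peak) triples modelling transient-helix rigidification;
    ``planted_rho`` is the target magnitude of the negative association
    between NHNOE* and disorder probability; ``noise_sd`` the Gaussian sd
    added to probabilities; ``noe_noise_sd`` the per-replicate measurement
    noise on the NOE (three replicates are averaged).
    """

    length: int
    tau_baseline: float = 3e-10
    tau_min: float = 1e-10
    terminal_decay_length: float = 5.0
    bumps: tuple[tuple[int, float, float], ...] = ()
    field_mhz: float = 600.0
    planted_rho: float = 0.55
    noise_sd: float = 0.10
    noe_noise_sd: float = 0.05
    seed: int = 0
    proline_positions: frozenset[int] = frozenset()
    constants: RelaxationConstants = field(default_factory=RelaxationConstants)

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("need at least 3 residues")
        for tau in (self.tau_baseline, self.tau_min):
            if not TAU_MIN_PHYS <= tau <= TAU_MAX_PHYS:
                raise ValueError(
                    f"tau {tau:g} s outside [{TAU_MIN_PHYS:g}, {TAU_MAX_PHYS:g}]"
                )
        for center, width, peak in self.bumps:
            if not 1 <= center <= self.length:
                raise ValueError(f"bump center {center} outside 1..{self.length}")
            if width <= 0:
                raise ValueError("bump width must be positive")
            if not TAU_MIN_PHYS <= peak <= TAU_MAX_PHYS:
                raise ValueError(f"bump tau_peak {peak:g} s out of range")
        if not 0 <= self.planted_rho <= 1:
            raise ValueError("planted_rho must be in [0, 1]")
        if self.noise_sd < 0 or self.noe_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")


def p53tad_like_spec(length: int = 70, seed: int = 0, **overrides) -> SyntheticSpec:
    """A spec shaped like a p53TAD construct: transient-helix bumps at the
    MDM2 (15-30) and RPA70 (40-60) binding regions over a flexible chain."""
    defaults = dict(
        length=length,
        bumps=((22, 5.0, 8e-10), (50, 6.0, 5e-10)),
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def build_tau_profile(spec: SyntheticSpec) -> np.ndarray:
    """Per-residue local correlation times implied by a spec.

    The baseline decays exponentially toward ``tau_min`` at each terminus
    over ``terminal_decay_length`` residues; each Gaussian bump contributes
    ``tau_peak * exp(-(i-c)^2 / (2 w^2))`` and profiles combine by maximum,
    so overlapping bumps never exceed the larger peak.
    """
    i = np.arange(1, spec.length + 1, dtype=float)
    if spec.terminal_decay_length > 0:
        dist_to_end = np.minimum(i - 1, spec.length - i)
        base = spec.tau_min + (spec.tau_baseline - spec.tau_min) * (
            1.0 - np.exp(-dist_to_end / spec.terminal_decay_length)
        )
    else:  # decay disabled
        base = np.full(spec.length, spec.tau_baseline)
    tau = base
    for center, width, peak in spec.bumps:
        bump = peak * np.exp(-((i - center) ** 2) / (2.0 * width**2))
        tau = np.maximum(tau, bump)
    return np.clip(tau, TAU_MIN_PHYS, TAU_MAX_PHYS)


def noe_from_tau(
    tau: float | np.ndarray,
    constants: RelaxationConstants | None = None,
    field_mhz: float = 600.0,
) -> float | np.ndarray:
    """Steady-state 15N{1H} NOE for a local correlation time.

    Deterministic, continuous, and monotone increasing in tau across the
    physical range.  With CSA disabled the extreme-narrowing limit is the
    closed form 1 + (gammaH/gammaN)/2 ~= -3.93.
    """
    constants = constants or RelaxationConstants()
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0):
        raise ValueError("tau must be positive")
    w_h, w_n = constants.omegas(field_mhz)

    def j(w: float) -> np.ndarray:
        return 0.4 * tau_arr / (1.0 + (w * tau_arr) ** 2)

    d = (
        MU0
        / (4 * math.pi)
        * HBAR
        * constants.gamma_h
        * constants.gamma_n
        / constants.r_nh**3
    )
    d2 = d * d / 4.0
    c2 = (
        (constants.csa_ppm * 1e-6 * w_n) ** 2 / 3.0
        if constants.include_csa
        else 0.0
    )
    r1 = d2 * (j(w_h - w_n) + 3 * j(w_n) + 6 * j(w_h + w_n)) + c2 * j(w_n)
    sigma_nh = d2 * (6 * j(w_h + w_n) - j(w_h - w_n))
    noe = 1.0 + (constants.gamma_h / constants.gamma_n) * sigma_nh / r1
    return float(noe) if np.isscalar(tau) else noe


N_REPLICATES = 3  # triplicate NOE measurements, averaged


def generate_dynamics_profile(
    spec: SyntheticSpec, sequence: SequenceRecord | None = None
) -> DynamicsProfile:
    """Simulated measured NOE profile: physics + replicate noise + prolines.

    Each residue's raw NOE is the mean of three seeded Gaussian-noise
    replicates around the noiseless value; prolines (from the sequence, or
    ``spec.proline_positions``) are missing.
    """
    if sequence is not None and len(sequence.ungapped()) != spec.length:
        raise ValueError(
            f"sequence length {len(sequence.ungapped())} != spec.length {spec.length}"
        )
    rng = np.random.default_rng(spec.seed)
    tau = build_tau_profile(spec)
    clean = noe_from_tau(tau, spec.constants, spec.field_mhz)
    reps = clean + rng.normal(0.0, spec.noe_noise_sd, (N_REPLICATES, spec.length))
    noe = reps.mean(axis=0) if spec.noe_noise_sd > 0 else np.asarray(clean)

    numbers = np.arange(1, spec.length + 1)
    if sequence is not None:
        aa = list(sequence.ungapped().residues)
        numbers = sequence.residue_numbers()
    else:
        aa = ["G"] * spec.length
        for pos in spec.proline_positions:
            aa[pos - 1] = "P"
    noe = noe.copy()
    noe[[letter == "P" for letter in aa]] = np.nan
    return DynamicsProfile(
        residue_numbers=numbers,
        aa=aa,
        noe_raw=noe,
        protein=sequence,
        metadata={"seed": spec.seed, "tau": tau, "field_mhz": spec.field_mhz},
    )


def _planted_slope(star_sd: float, rho: float, noise_sd: float) -> float:
    """Slope b making corr(star, -b*star + eps) = -rho in expectation."""
    if rho >= 1 or noise_sd == 0:
        # noiseless: any b gives |r| = 1; keep the line inside [0, 1]
        return max(rho, 0.1)
    return rho * noise_sd / (star_sd * math.sqrt(1.0 - rho * rho))


def generate_prediction_profile(
    dynamics: DynamicsProfile,
    spec: SyntheticSpec,
    predictor_name: str = "synthetic",
    seed_offset: int = 1,
) -> PredictionProfile:
    """A disorder-probability profile negatively associated with NHNOE*.

    Requires NHNOE* on the dynamics profile (computed on the fly if
    absent).  Probabilities are ``clip01(a - b*star + eps)`` with ``a``
    centering the line at probability 0.5 and ``b`` calibrated so the
    expected association magnitude is ``spec.planted_rho`` at the spec's
    noise level.  The profile's metadata records the target and the
    realized noise-free association (clipping can attenuate it).
    """
    if dynamics.nhnoe_star is None:
        dynamics = compute_nhnoe_star(dynamics, TransformConfig())
    star = dynamics.nhnoe_star
    present = ~np.isnan(star)
    star_present = star[present]
    star_sd = float(star_present.std(ddof=1))
    b = _planted_slope(star_sd, spec.planted_rho, spec.noise_sd)
    a = 0.5 + b * float(star_present.mean())

    rng = np.random.default_rng(spec.seed + seed_offset)
    eps = rng.normal(0.0, spec.noise_sd, len(star))
    values = np.clip(a - b * star + eps, 0.0, 1.0)
    values[~present] = np.nan

    noise_free = np.clip(a - b * star_present, 0.0, 1.0)
    if noise_free.std() > 0 and star_present.std() > 0:
        realized = float(abs(np.corrcoef(noise_free, star_present)[0, 1]))
    else:
        realized = float("nan")
    # residue numbering must be contiguous for a prediction profile; the
    # planted values exist for every residue, prolines included
    values_full = values.copy()
    return PredictionProfile(
        residue_numbers=dynamics.residue_numbers,
        values=values_full,
        predictor_name=predictor_name,
        protein=dynamics.protein,
        metadata={
            "planted_rho": spec.planted_rho,
            "realized_noise_free_rho": realized,
            "slope_b": b,
            "intercept_a": a,
            "seed": spec.seed + seed_offset,
        },
    )
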