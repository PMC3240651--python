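"""Orchestration of the full analysis: transform -> correlate -> outliers
-> per-type error profile -> reports.

The pipeline is a pure function of its inputs and configuration: repeated
runs on identical inputs produce byte-identical reports, and every output
file carries a header comment with the tool version, a configuration hash
and (for simulations) the seed.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    DynamicsProfile,
    PredictionProfile,
    SequenceRecord,
    read_fasta,
    read_residue_table,
)
from .stats import (
    ErrorProfile,
    classify_outliers,
    fit_dynamics_regression,
    mean_error_rate,
    pearson_pvalue,
    residue_type_error_profile,
)
from .transform import TransformConfig, compute_nhnoe_star, smooth_profile

__all__ = [
    "RunConfig",
    "PairingError",
    "run_correlate",
    "run_outliers",
    "run_error_profile",
    "run_pvalue_check",
    "write_report",
]

logger = logging.getLogger("noestar")


class PairingError(ValueError):
    """Raised when dynamics and prediction inputs cannot be matched."""


@dataclass
class RunConfig:
    """Everything one analysis run needs, already loaded in memory.

    ``dynamics`` maps protein identifier to its dynamics profile;
    ``predictions`` maps (protein identifier, predictor name) to a
    prediction profile.  ``k_sigma`` is the misprediction threshold in
    residual standard errors; ``min_per_homologue`` the occurrence floor
    for a residue type to enter the mean error rate.
    """

    dynamics: dict[str, DynamicsProfile]
    predictions: dict[tuple[str, str], PredictionProfile]
    sequences: dict[str, SequenceRecord] = field(default_factory=dict)
    transform: TransformConfig = field(default_factory=TransformConfig)
    k_sigma: float = 1.0
    cap_sigma: float = 2.0
    min_per_homologue: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")

    def config_hash(self) -> str:
        desc = (
            f"{sorted(self.dynamics)}|{sorted(self.predictions)}|"
            f"{self.transform}|{self.k_sigma}|{self.cap_sigma}|"
            f"{self.min_per_homologue}|{self.seed}"
        )
        return hashlib.sha256(desc.encode()).hexdigest()[:12]


def load_run_config(
    dynamics_paths: Mapping[str, str | Path],
    prediction_paths: Mapping[tuple[str, str], str | Path],
    fasta_path: str | Path | None = None,
    **kwargs,
) -> RunConfig:
    """Build a RunConfig from on-disk per-residue tables and sequences."""
    sequences: dict[str, SequenceRecord] = {}
    if fasta_path is not None:
        sequences = {rec.identifier: rec for rec in read_fasta(fasta_path)}
    dynamics = {
        name: read_residue_table(path, "dynamics", protein=sequences.get(name))
        for name, path in dynamics_paths.items()
    }
    predictions = {
        (protein, predictor): read_residue_table(
            path,
            "prediction",
            protein=sequences.get(protein),
            value_column=None,
        )
        for (protein, predictor), path in prediction_paths.items()
    }
    return RunConfig(
        dynamics=dynamics,
        predictions=predictions,
        sequences=sequences,
        **kwargs,
    )


def _check_pairing(config: RunConfig) -> None:
    orphans = [
        (protein, predictor)
        for protein, predictor in config.predictions
        if protein not in config.dynamics
    ]
    if orphans:
        raise PairingError(
            f"predictions without matching dynamics profiles: {orphans}"
        )
    if not config.predictions:
        raise PairingError("no (protein, predictor) pairings to analyse")


def _prepared_dynamics(config: RunConfig) -> dict[str, DynamicsProfile]:
    """Dynamics with NHNOE* computed (and optionally smoothed) per config."""
    out = {}
    for name, profile in config.dynamics.items():
        prepared = compute_nhnoe_star(profile, config.transform)
        if config.transform.smooth_before_regression:
            smoothed = smooth_profile(
                prepared.nhnoe_star, config.transform.smoothing_window
            )
            # renormalize so the max-equals-one invariant survives smoothing
            smoothed = smoothed / np.nanmax(smoothed)
            prepared = DynamicsProfile(
                residue_numbers=prepared.residue_numbers,
                aa=prepared.aa,
                noe_raw=prepared.noe_raw,
                nhnoe_star=smoothed,
                protein=prepared.protein,
                metadata=prepared.metadata,
            )
        out[name] = prepared
    return out


def run_correlate(config: RunConfig) -> pd.DataFrame:
    """One regression row per (protein, predictor) pairing.

    Columns: protein, predictor, n, r (magnitude), sign, p_two_tailed,
    slope, intercept, sigma_resid; rows sorted by (protein, predictor).
    """
    _check_pairing(config)
    dynamics = _prepared_dynamics(config)
    rows = []
    for (protein, predictor), prediction in sorted(config.predictions.items()):
        reg = fit_dynamics_regression(prediction, dynamics[protein])
        logger.info(
            "correlate %s/%s: n=%d r=%.3f p=%.2e",
            protein,
            predictor,
            reg.n,
            reg.r,
            reg.p_two_tailed,
        )
        rows.append(
            {
                "protein": protein,
                "predictor": predictor,
                "n": reg.n,
                "r": reg.r,
                "sign": reg.sign,
                "p_two_tailed": reg.p_two_tailed,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "sigma_resid": reg.sigma_resid,
            }
        )
    return pd.DataFrame(rows)


def run_outliers(config: RunConfig) -> dict[tuple[str, str], pd.DataFrame]:
    """>= k sigma outlier table per (protein, predictor) pairing."""
    _check_pairing(config)
    dynamics = _prepared_dynamics(config)
    tables = {}
    for (protein, predictor), prediction in sorted(config.predictions.items()):
        table = classify_outliers(
            prediction,
            dynamics[protein],
            k_sigma=config.k_sigma,
            cap_sigma=config.cap_sigma,
        )
        table.insert(0, "protein", protein)
        logger.info(
            "outliers %s/%s: %d of %d pairs flagged at %.2f sigma",
            protein,
            predictor,
            len(table),
            table.attrs["n_pairs"],
            config.k_sigma,
        )
        tables[(protein, predictor)] = table
    return tables


@dataclass
class ErrorProfileReport:
    profile: ErrorProfile
    mean_pct: float
    sd_pct: float
    excluded_types: list[str]


def run_error_profile(config: RunConfig) -> ErrorProfileReport:
    """Pooled per-type misprediction percentages with the mean +/- sd summary."""
    tables = run_outliers(config)
    sequences = list(config.sequences.values())
    if not sequences:
        # fall back to the sequences implied by the dynamics tables
        sequences = [
            SequenceRecord(identifier=name, residues="".join(profile.aa))
            for name, profile in sorted(config.dynamics.items())
        ]
    profile = residue_type_error_profile(tables.values(), sequences)
    mean_pct, sd_pct, excluded = mean_error_rate(
        profile, min_per_homologue=config.min_per_homologue
    )
    return ErrorProfileReport(
        profile=profile, mean_pct=mean_pct, sd_pct=sd_pct, excluded_types=excluded
    )


# ---------------------------------------------------------------------------
# p-value recovery from published (r, n) tables


def _printed_decimals(text: str) -> int:
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1])


def check_printed_pvalue(r: float, n: int, printed: str) -> tuple[float, bool]:
    """Recompute a two-tailed p from (r, n) and compare with its printed form.

    A printed bound "<x" matches when the computed p is <= x.  A plain
    printed value matches when rounding the computed p to the printed number
    of decimals reproduces the printed string, or when the relative
    deviation is <= 10% — the slack a correlation printed at two decimals
    induces on its p-value.
    """
    computed = pearson_pvalue(r, n)
    printed = printed.strip()
    if printed.startswith("<"):
        bound = float(printed[1:])
        if bound == 0:  # "<0.000000" means p vanishes at the printed precision
            bound = 10.0 ** -_printed_decimals(printed[1:])
        return computed, computed <= bound
    target = float(printed)
    decimals = _printed_decimals(printed)
    rounded_match = f"{computed:.{decimals}f}" == printed
    rel_match = target > 0 and abs(computed - target) / target <= 0.10
    return computed, rounded_match or rel_match


def consistent_within_r_rounding(
    r: float, n: int, printed: str, r_decimals: int = 2
) -> bool:
    """Whether some correlation rounding to the printed r reproduces printed p.

    Correlations are tabulated at two decimals, so the unrounded value lies
    anywhere in [r - 0.005, r + 0.005); the printed p is consistent when at
    least one correlation in that interval yields it at the printed
    precision (or satisfies a printed "<x" bound).
    """
    printed = printed.strip()
    half = 0.5 * 10.0**-r_decimals
    for r_try in np.linspace(max(r - half, 0.0), min(r + half, 1.0), 201):
        p = pearson_pvalue(float(r_try), n)
        if printed.startswith("<"):
            bound = float(printed[1:]) or 10.0 ** -_printed_decimals(printed[1:])
            if p <= bound:
                return True
        elif f"{p:.{_printed_decimals(printed)}f}" == printed:
            return True
    return False


def run_pvalue_check(rows: pd.DataFrame) -> pd.DataFrame:
    """Verify printed two-tailed p-values against recomputed ones.

    ``rows`` needs columns r, n, printed_p (strings; bounds as "<x") and any
    label columns, which are carried through.  ``match`` applies the direct
    rule of :func:`check_printed_pvalue`; ``match_r_rounding`` additionally
    accepts rows whose printed p is reproducible from some correlation that
    rounds to the printed r.  Malformed rows are reported with match = NaN
    and the run continues.
    """
    out = rows.copy()
    computed, matches, rounded = [], [], []
    for _, row in rows.iterrows():
        try:
            p, ok = check_printed_pvalue(
                float(row["r"]), int(row["n"]), str(row["printed_p"])
            )
            ok_rounded = ok or consistent_within_r_rounding(
                float(row["r"]), int(row["n"]), str(row["printed_p"])
            )
        except (ValueError, KeyError) as exc:
            logger.warning("pvalue-check row skipped: %s", exc)
            p, ok, ok_rounded = np.nan, np.nan, np.nan
        computed.append(p)
        matches.append(ok)
        rounded.append(ok_rounded)
    out["computed_p"] = computed
    out["match"] = matches
    out["match_r_rounding"] = rounded
    return out


def load_published_correlations() -> pd.DataFrame:
    """The packaged (species, predictor, n, r, printed p) regression table."""
    from importlib import resources

    path = resources.files("noestar.data").joinpath("published_correlations.tsv")
    with resources.as_file(path) as real_path:
        return pd.read_csv(
            real_path, sep="\t", comment="#", dtype={"printed_p": str}
        )


def write_report(
    frame: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write a report TSV with the standard provenance header."""
    buf = _io.StringIO()
    buf.write(f"# noestar {__version__}\n")
    if config is not None:
        buf.write(f"# config {config.config_hash()}\n")
        if config.seed is not None:
            buf.write(f"# seed {config.seed}\n")
    frame.to_csv(buf, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    Path(path).write_text(buf.getvalue())
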