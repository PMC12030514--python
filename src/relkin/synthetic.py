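"""Synthetic dissolution-run generation and the packaged reference profiles.

The generator is the exact inverse of the analysis pipeline: starting from
a known true cumulative-release curve it works out what concentrations a
staged, aliquot-corrected sampling experiment would have measured, maps
them to absorbances through the calibration line, and optionally applies
multiplicative Gaussian readout noise.  A zero-noise run pushed back
through the pipeline therefore reproduces the truth at the sample times to
rounding error, which is the property the pipeline tests lean on.

The packaged fixture table holds the six reported tablet release profiles
(K-1 F-1 ... K-3 F-6) on the observation grid; grid cells that were never
reported remain absent rather than imputed, so the fixtures cannot
manufacture values that were not measured.  The gastric-stage values at
0.5 h and 1 h are unreported; when a fixture profile is used as a truth
curve the generator interpolates monotonically from 0% at t=0, which is
adequate for round-trip testing but carries no evidential weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ValidationError
from .model import TransportParams, cumulative_release_exact
from .pipeline import (
    CalibrationLine,
    DissolutionProfile,
    RawDissolutionRun,
    Sample,
    SamplingProtocol,
)

__all__ = [
    "NoiseModel",
    "DEFAULT_CALIBRATION",
    "FIXTURE_IDS",
    "reference_profiles",
    "fixture_provenance",
    "generate_raw_run",
]

FIXTURE_IDS = ("K-1 F-1", "K-2 F-2", "K-3 F-3", "K-1 F-4", "K-2 F-5", "K-3 F-6")

#: Placeholder identity slope; all downstream quantities are percentages,
#: so the calibration scale cancels between generation and analysis.
DEFAULT_CALIBRATION = CalibrationLine(slope=1.0, intercept=0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise on absorbance readings."""

    relative_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0:
            raise ValidationError("relative_sd must be >= 0")


def _load_fixture_frame() -> pd.DataFrame:
    with resources.files("relkin.data").joinpath("reference_profiles.csv").open() as fh:
        return pd.read_csv(fh)


def reference_profiles() -> Mapping[str, DissolutionProfile]:
    """The six packaged reference tablet profiles, keyed by formulation id.

    Only reported grid cells are present; nothing is imputed.
    """
    df = _load_fixture_frame()
    out = {}
    for fid in FIXTURE_IDS:
        grp = df[df["formulation_id"] == fid].sort_values("time_h")
        out[fid] = DissolutionProfile(
            fid, grp["time_h"].to_numpy(float), grp["cumulative_pct"].to_numpy(float)
        )
    return out


def fixture_provenance() -> pd.DataFrame:
    """Per-cell source notes for the packaged profiles."""
    with resources.files("relkin.data").joinpath("reference_profiles_provenance.csv").open() as fh:
        return pd.read_csv(fh)


def _truth_function(truth, protocol: SamplingProtocol):
    """Return cumulative-% function of time covering the protocol horizon."""
    if isinstance(truth, DissolutionProfile):
        if truth.times_h[-1] < protocol.horizon_h - 1e-9:
            raise ValidationError(
                f"truth profile ends at {truth.times_h[-1]:g} h, before the "
                f"protocol horizon {protocol.horizon_h:g} h"
            )
        t = truth.times_h
        y = truth.cumulative_pct
        if t[0] > 0:  # anchor at (0, 0): nothing released before the run starts
            t = np.concatenate(([0.0], t))
            y = np.concatenate(([0.0], y))
        interp = PchipInterpolator(t, y, extrapolate=False)
        return lambda tt: float(interp(tt))
    if isinstance(truth, tuple) and len(truth) == 2 and isinstance(truth[0], TransportParams):
        params, amplitude = truth
        return lambda tt: float(cumulative_release_exact(tt, params, amplitude))
    raise ValidationError("truth must be a DissolutionProfile or (TransportParams, amplitude)")


def generate_raw_run(
    truth: Union[DissolutionProfile, tuple],
    protocol: SamplingProtocol,
    cal: CalibrationLine = DEFAULT_CALIBRATION,
    noise: NoiseModel = NoiseModel(relative_sd=0.0),
    drug_content_mg: float = 70.0,
    formulation_id: str = "synthetic",
    dilution_factor: float = 1.0,
) -> RawDissolutionRun:
    """Simulate a staged dissolution run from a true cumulative curve.

    Within each stage the vessel concentration at sample k satisfies
    m_k = V * C_k + sum_{i<k} v * C_i, where m_k is the mass released since
    the stage began; solving for C_k inverts the pipeline's correction.
    Absorbances are slope * C / dilution + intercept, with multiplicative
    noise (1 + eps), eps ~ N(0, relative_sd), from the seeded generator.
    """
    pct_of = _truth_function(truth, protocol)
    rng = np.random.default_rng(noise.seed)
    samples = []
    carry_mg = 0.0
    for stage_idx, stage in enumerate(protocol.stages):
        removed_mg = 0.0
        stage_mass = 0.0
        for t in stage.sample_times_h:
            total_mg = pct_of(t) / 100.0 * drug_content_mg
            stage_mass = total_mg - carry_mg
            conc = (stage_mass - removed_mg) / stage.vessel_volume_mL
            conc = max(conc, 0.0)
            absorbance = cal.intercept + cal.slope * conc / dilution_factor
            if noise.relative_sd > 0:
                absorbance *= 1.0 + noise.relative_sd * rng.standard_normal()
            measured_conc = max(
                dilution_factor * (absorbance - cal.intercept) / cal.slope, 0.0
            )
            samples.append(Sample(stage_idx, t, measured_conc, dilution_factor))
            removed_mg += stage.aliquot_volume_mL * conc
        carry_mg += stage_mass
    return RawDissolutionRun(formulation_id, drug_content_mg, tuple(samples))
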