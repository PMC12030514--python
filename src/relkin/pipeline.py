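"""Staged dissolution runs: raw aliquots -> corrected cumulative-release profiles.

A compendial paddle-apparatus run draws small aliquots (e.g. 3 mL from a
900 mL vessel) at scheduled times, replacing each with fresh medium.  The
drug mass carried out by earlier aliquots must be added back when the
cumulative released mass is computed (volume-replacement correction):

    M_k = V_vessel * C_k + sum_{i<k} v_aliquot * C_i        (within a stage)

Two-stage runs (gastric pH 1.2 for 2 h, then a full medium change into
intestinal pH 6.8 until 12 h) are assembled into a single continuous
profile: release accumulated in completed stages carries over.

Profiles are expressed as cumulative percent of the formulation's drug
content; profile statistics (interpolation, time to a release threshold,
and the regulatory f1/f2 difference/similarity factors) operate on the
shape-preserving monotone cubic (PCHIP) interpolant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import (
    DataQualityWarning,
    RangeError,
    ScheduleMismatchError,
    ValidationError,
)

__all__ = [
    "Stage",
    "SamplingProtocol",
    "CalibrationLine",
    "Sample",
    "RawDissolutionRun",
    "DissolutionProfile",
    "tablet_protocol",
    "powder_protocol",
    "trim_protocol",
    "absorbance_to_concentration",
    "cumulative_from_samples",
    "assemble_two_stage",
    "run_pipeline",
    "interpolate_profile",
    "time_to_threshold",
    "similarity_f1_f2",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_raw_run_csv",
    "write_raw_run_csv",
]

_TIME_TOL = 1e-9
MONOTONE_TOL_PCT = 0.5  # measurement-noise allowance on cumulative profiles


@dataclass(frozen=True)
class Stage:
    medium_label: str
    pH: float
    vessel_volume_mL: float
    sample_times_h: tuple
    aliquot_volume_mL: float
    replace_with_fresh: bool = True

    def __post_init__(self):
        times = tuple(float(t) for t in self.sample_times_h)
        if len(times) == 0 or any(b - a <= 0 for a, b in zip(times, times[1:])):
            raise ValidationError("sample_times_h must be nonempty and strictly increasing")
        if not self.aliquot_volume_mL < self.vessel_volume_mL:
            raise ValidationError("aliquot volume must be smaller than vessel volume")
        object.__setattr__(self, "sample_times_h", times)


@dataclass(frozen=True)
class SamplingProtocol:
    stages: tuple
    temperature_C: float = 37.0
    stir_rpm: float = 60.0

    def __post_init__(self):
        stages = tuple(self.stages)
        if not stages:
            raise ValidationError("protocol needs at least one stage")
        for prev, nxt in zip(stages, stages[1:]):
            if nxt.sample_times_h[0] <= prev.sample_times_h[-1]:
                raise ValidationError("stage time ranges must be increasing and non-overlapping")
        object.__setattr__(self, "stages", stages)

    @property
    def horizon_h(self) -> float:
        return self.stages[-1].sample_times_h[-1]

    @property
    def all_times(self) -> np.ndarray:
        return np.concatenate([np.asarray(s.sample_times_h) for s in self.stages])

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": [asdict(s) for s in self.stages],
                "temperature_C": self.temperature_C,
                "stir_rpm": self.stir_rpm,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SamplingProtocol":
        try:
            raw = json.loads(text)
            stages = tuple(Stage(**s) for s in raw["stages"])
            return cls(
                stages=stages,
                temperature_C=raw.get("temperature_C", 37.0),
                stir_rpm=raw.get("stir_rpm", 60.0),
            )
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ValidationError(f"malformed protocol JSON: {exc}") from exc


@dataclass(frozen=True)
class CalibrationLine:
    """Beer-Lambert calibration: absorbance = slope * concentration + intercept."""

    slope: float  # absorbance per mg/mL
    intercept: float = 0.0
    wavelength_nm: float = 233.0

    def __post_init__(self):
        if not self.slope > 0:
            raise ValidationError("calibration slope must be > 0")


@dataclass(frozen=True)
class Sample:
    stage: int
    time_h: float
    concentration_mg_per_mL: float
    dilution_factor: float = 1.0

    def __post_init__(self):
        if self.concentration_mg_per_mL < 0:
            raise ValidationError("concentration must be >= 0")
        if not self.dilution_factor > 0:
            raise ValidationError("dilution factor must be > 0")


@dataclass(frozen=True)
class RawDissolutionRun:
    formulation_id: str
    drug_content_mg: float
    samples: tuple

    def __post_init__(self):
        if not self.drug_content_mg > 0:
            raise ValidationError("drug_content_mg must be > 0")
        object.__setattr__(self, "samples", tuple(self.samples))


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative percent of drug content released vs time."""

    formulation_id: str
    times_h: np.ndarray
    cumulative_pct: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.cumulative_pct, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValidationError("times_h and cumulative_pct must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times_h must be strictly increasing (ties rejected)")
        if np.any(y < -MONOTONE_TOL_PCT) or np.any(np.diff(y) < -MONOTONE_TOL_PCT):
            warnings.warn(
                f"profile {self.formulation_id!r} decreases by more than "
                f"{MONOTONE_TOL_PCT} percentage points between samples",
                DataQualityWarning,
                stacklevel=2,
            )
        if np.any(y > 100.0 + MONOTONE_TOL_PCT):
            warnings.warn(
                f"profile {self.formulation_id!r} exceeds 100% of drug content",
                DataQualityWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "cumulative_pct", y)

    def __len__(self) -> int:
        return self.times_h.size


def tablet_protocol(vessel_volume_mL: float = 900.0, t_max_h: float = 12.0) -> SamplingProtocol:
    """Two-stage tablet schedule: gastric pH 1.2 aliquots at 0.5/1/2 h, full
    medium change, then hourly intestinal pH 6.8 aliquots until t_max_h.

    The vessel volume is not prescribed by the source protocol; 900 mL is
    the compendial Apparatus II convention and is configurable.
    """
    intestinal_times = tuple(float(t) for t in np.arange(3.0, t_max_h + 0.5, 1.0))
    return SamplingProtocol(
        stages=(
            Stage("gastric", 1.2, vessel_volume_mL, (0.5, 1.0, 2.0), 3.0),
            Stage("intestinal", 6.8, vessel_volume_mL, intestinal_times, 3.0),
        ),
        temperature_C=37.0,
        stir_rpm=60.0,
    )


def powder_protocol() -> SamplingProtocol:
    """Single-stage powder schedule: 500 mL pH 6.8, 100 rpm, 3 mL aliquots
    every 5 min for 60 min (12 samples)."""
    times = tuple(round(k * 5.0 / 60.0, 10) for k in range(1, 13))
    return SamplingProtocol(
        stages=(Stage("intestinal", 6.8, 500.0, times, 3.0),),
        temperature_C=37.0,
        stir_rpm=100.0,
    )


def trim_protocol(protocol: SamplingProtocol, t_max_h: float) -> SamplingProtocol:
    """Drop scheduled samples later than t_max_h (and then-empty stages)."""
    stages = []
    for s in protocol.stages:
        kept = tuple(t for t in s.sample_times_h if t <= t_max_h + _TIME_TOL)
        if kept:
            stages.append(
                Stage(s.medium_label, s.pH, s.vessel_volume_mL, kept, s.aliquot_volume_mL,
                      s.replace_with_fresh)
            )
    if not stages:
        raise ValidationError(f"no scheduled samples at or before t={t_max_h} h")
    return SamplingProtocol(tuple(stages), protocol.temperature_C, protocol.stir_rpm)


def absorbance_to_concentration(
    absorbance: float, cal: CalibrationLine, dilution_factor: float = 1.0
) -> float:
    """Vessel concentration (mg/mL) from a diluted aliquot's absorbance."""
    if absorbance < cal.intercept:
        raise ValidationError(
            f"absorbance {absorbance:g} below calibration intercept {cal.intercept:g} "
            "(negative concentration)"
        )
    return dilution_factor * (absorbance - cal.intercept) / cal.slope


def cumulative_from_samples(run: RawDissolutionRun, protocol: SamplingProtocol) -> list:
    """Per-stage cumulative released mass (mg), aliquot-corrected.

    Within each stage, M_k = V_vessel * C_k + sum_{i<k} v_aliquot * C_i.
    """
    per_stage = []
    samples_by_stage = {}
    for s in run.samples:
        samples_by_stage.setdefault(s.stage, []).append(s)
    extra = sorted(set(samples_by_stage) - set(range(len(protocol.stages))))
    if extra:
        raise ScheduleMismatchError(f"run references undefined stage indices {extra}")
    for idx, stage in enumerate(protocol.stages):
        samples = sorted(samples_by_stage.get(idx, []), key=lambda s: s.time_h)
        got = np.array([s.time_h for s in samples])
        want = np.array(stage.sample_times_h)
        if got.size != want.size or np.any(np.abs(got - want) > _TIME_TOL):
            bad = sorted(set(np.round(got, 9)) ^ set(np.round(want, 9)))
            raise ScheduleMismatchError(
                f"stage {idx} ({stage.medium_label}): sample times do not match "
                f"protocol schedule; offending times {bad}",
                offending_times=bad,
            )
        conc = np.array([s.concentration_mg_per_mL for s in samples])
        removed = stage.aliquot_volume_mL * np.concatenate(([0.0], np.cumsum(conc)[:-1]))
        per_stage.append(stage.vessel_volume_mL * conc + removed)
    return per_stage


def assemble_two_stage(stage_masses: Sequence[np.ndarray], run: RawDissolutionRun,
                       protocol: SamplingProtocol) -> DissolutionProfile:
    """Continuous cumulative-percent profile across medium changes.

    Mass released in completed stages carries over into later stages.
    """
    if run.drug_content_mg <= 0:
        raise ValidationError("drug content must be positive")
    times, pct = [], []
    carry = 0.0
    for stage, masses in zip(protocol.stages, stage_masses):
        for t, m in zip(stage.sample_times_h, masses):
            times.append(t)
            pct.append(100.0 * (carry + m) / run.drug_content_mg)
        if len(masses):
            carry += float(masses[-1])
    return DissolutionProfile(run.formulation_id, np.array(times), np.array(pct))


def run_pipeline(run: RawDissolutionRun, protocol: SamplingProtocol) -> DissolutionProfile:
    """Full pipeline: aliquot correction then two-stage assembly."""
    return assemble_two_stage(cumulative_from_samples(run, protocol), run, protocol)


def _interpolant(p: DissolutionProfile) -> PchipInterpolator:
    return PchipInterpolator(p.times_h, p.cumulative_pct, extrapolate=False)


def interpolate_profile(p: DissolutionProfile, t_query):
    """Shape-preserving monotone cubic interpolation; exact at the knots."""
    t_query = np.asarray(t_query, dtype=float)
    if np.any(t_query < p.times_h[0] - _TIME_TOL) or np.any(t_query > p.times_h[-1] + _TIME_TOL):
        raise RangeError(
            f"query outside profile range [{p.times_h[0]:g}, {p.times_h[-1]:g}] h"
        )
    out = _interpolant(p)(np.clip(t_query, p.times_h[0], p.times_h[-1]))
    return out if out.shape else float(out)


def time_to_threshold(p: DissolutionProfile, threshold_pct: float) -> Optional[float]:
    """Earliest time at which the interpolated profile reaches threshold_pct.

    Returns None when the profile never reaches it (the 80% level is the
    pharmacopoeial near-total-release criterion).
    """
    if not 0 < threshold_pct <= 100:
        raise ValidationError("threshold must be in (0, 100]")
    y = p.cumulative_pct
    if y[0] >= threshold_pct:
        return float(p.times_h[0])
    hits = np.nonzero(y >= threshold_pct)[0]
    if hits.size == 0:
        return None
    k = int(hits[0])
    f = _interpolant(p)
    return float(brentq(lambda t: float(f(t)) - threshold_pct,
                        p.times_h[k - 1], p.times_h[k], xtol=1e-10))


def similarity_f1_f2(reference: DissolutionProfile, test: DissolutionProfile):
    """Regulatory profile-comparison factors.

    f1 = 100 * sum|R - T| / sum R  (difference factor, 0 when identical)
    f2 = 50 * log10(100 / sqrt(1 + mean((R - T)^2)))  (similarity factor,
    100 when identical; >= 50 conventionally indicates similarity).

    Profiles are compared on the intersection of their time grids; if that
    has fewer than 3 points, the test profile is interpolated onto the
    reference times inside the overlap.
    """
    rt = np.round(reference.times_h, 9)
    tt = np.round(test.times_h, 9)
    common = np.intersect1d(rt, tt)
    if common.size >= 3:
        r = reference.cumulative_pct[np.isin(rt, common)]
        t = test.cumulative_pct[np.isin(tt, common)]
    else:
        lo = max(reference.times_h[0], test.times_h[0])
        hi = min(reference.times_h[-1], test.times_h[-1])
        keep = (reference.times_h >= lo - _TIME_TOL) & (reference.times_h <= hi + _TIME_TOL)
        if keep.sum() < 3:
            raise ValidationError("fewer than 3 common time points for f1/f2")
        r = reference.cumulative_pct[keep]
        t = np.asarray(interpolate_profile(test, reference.times_h[keep]))
    diff = r - t
    f1 = 100.0 * np.sum(np.abs(diff)) / np.sum(r)
    f2 = 50.0 * np.log10(100.0 / np.sqrt(1.0 + np.mean(diff**2)))
    return float(f1), float(f2)


# ---------------------------------------------------------------------------
# CSV interfaces

def write_profiles_csv(profiles: Sequence[DissolutionProfile], path) -> None:
    rows = [
        {"formulation_id": p.formulation_id, "time_h": t, "cumulative_pct": y}
        for p in profiles
        for t, y in zip(p.times_h, p.cumulative_pct)
    ]
    pd.DataFrame(rows, columns=["formulation_id", "time_h", "cumulative_pct"]).to_csv(
        path, index=False
    )


def read_profiles_csv(path) -> list:
    df = pd.read_csv(path)
    required = {"formulation_id", "time_h", "cumulative_pct"}
    if not required.issubset(df.columns):
        raise ValidationError(f"profile CSV must have columns {sorted(required)}")
    out = []
    for fid, grp in df.groupby("formulation_id", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            DissolutionProfile(str(fid), grp["time_h"].to_numpy(), grp["cumulative_pct"].to_numpy())
        )
    return out


def write_raw_run_csv(run: RawDissolutionRun, path) -> None:
    rows = [
        {
            "formulation_id": run.formulation_id,
            "stage": s.stage,
            "time_h": s.time_h,
            "concentration_mg_per_mL": s.concentration_mg_per_mL,
            "dilution_factor": s.dilution_factor,
        }
        for s in run.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_raw_run_csv(path, drug_content_mg: float) -> list:
    df = pd.read_csv(path)
    required = {"formulation_id", "stage", "time_h", "concentration_mg_per_mL", "dilution_factor"}
    if not required.issubset(df.columns):
        raise ValidationError(f"raw-run CSV must have columns {sorted(required)}")
    runs = []
    for fid, grp in df.groupby("formulation_id", sort=False):
        samples = tuple(
            Sample(int(r.stage), float(r.time_h), float(r.concentration_mg_per_mL),
                   float(r.dilution_factor))
            for r in grp.itertuples()
        )
        runs.append(RawDissolutionRun(str(fid), drug_content_mg, samples))
    return runs
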