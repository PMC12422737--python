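"""Relative-density calibration from radial fluorescence profiles.

Peak amplitude at the patch edge is regressed on growth time per seeding
condition; predicted amplitudes are rescaled by one global linear map so
the reference condition (0.5 ul, OD600 = 10, 1 hr growth) has relative
density 10.  Conditions too dilute for direct fluorescence detection are
extrapolated from a quadratic fit of the line parameters across
OD600 = {0.5, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import FittingError, InputDataError

__all__ = [
    "Condition",
    "RadialProfile",
    "PeakResult",
    "DensityModel",
    "peak_amplitude",
    "fit_amplitude_model",
    "relative_density",
    "read_profiles",
    "write_density_table",
    "REFERENCE_CONDITION",
    "REFERENCE_TIME_HR",
    "REFERENCE_DENSITY",
]

REFERENCE_CONDITION = (10.0, 0.5)   # (OD600, volume_ul)
REFERENCE_TIME_HR = 1.0
REFERENCE_DENSITY = 10.0

Condition = tuple  # (od600: float, volume_ul: float)


class PeakResult(NamedTuple):
    amplitude: float
    edge_radius_um: float
    degenerate: bool      # set for an all-zero profile


@dataclass(frozen=True)
class RadialProfile:
    """One patch's fluorescence intensity along its radius."""

    condition: Condition
    growth_time_hr: float
    radius_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radius_um, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "radius_um", r)
        object.__setattr__(self, "intensity", i)
        if r.size == 0 or r.size != i.size:
            raise InputDataError("radius and intensity must be non-empty, equal length")
        if np.any(np.diff(r) <= 0):
            raise InputDataError("radius bins must be strictly increasing")
        if np.any(i < 0):
            raise InputDataError("intensity must be non-negative")


def peak_amplitude(profile: RadialProfile,
                   annulus_frac: float = 0.05) -> PeakResult:
    """Peak intensity in an annulus around the detected patch edge.

    The edge is located at the steepest negative radial intensity gradient
    at or beyond the profile's maximum (ties break toward larger radius),
    i.e. the outward flank of the edge ring.  The annulus half-width is
    ``annulus_frac`` of the profiled radial extent, at least one bin.  An
    all-zero profile yields amplitude 0 with the ``degenerate`` flag set.
    """
    r = profile.radius_um
    inten = profile.intensity
    if np.all(inten == 0):
        return PeakResult(0.0, float(r[-1]), True)
    if r.size < 2:
        return PeakResult(float(inten[0]), float(r[0]), False)

    grad = np.gradient(inten, r)
    region = np.arange(int(np.argmax(inten)), r.size)
    # steepest drop; ties toward larger radius
    g = grad[region]
    edge_local = region[np.nonzero(g == g.min())[0][-1]]
    edge_r = r[edge_local]

    halfwidth = max(annulus_frac * (r[-1] - r[0]), float(np.min(np.diff(r))))
    mask = np.abs(r - edge_r) <= halfwidth
    return PeakResult(float(inten[mask].max()), float(edge_r), False)


@dataclass
class DensityModel:
    """Per-condition amplitude-vs-time lines plus the global rescaling."""

    lines: dict = field(default_factory=dict)   # condition -> (intercept, slope)
    scale_constant: float = 1.0
    low_density_poly: dict = field(default_factory=dict)  # "intercept"/"slope" -> coeffs
    extrapolated: tuple = ()

    def predicted_amplitude(self, condition: Condition,
                            growth_time_hr: float) -> float:
        cond = _norm_cond(condition)
        if cond not in self.lines:
            raise KeyError(f"unknown condition: {condition!r}")
        b0, b1 = self.lines[cond]
        return b0 + b1 * growth_time_hr


def _norm_cond(condition) -> tuple[float, float]:
    od, vol = condition
    return (float(od), float(vol))


def fit_amplitude_model(profiles: Iterable[RadialProfile],
                        below_detection: Iterable[Condition] = (),
                        reference_condition: Condition = REFERENCE_CONDITION,
                        reference_time_hr: float = REFERENCE_TIME_HR,
                        anchor: float = REFERENCE_DENSITY) -> DensityModel:
    """OLS of peak amplitude on growth time per condition, plus rescaling.

    Conditions listed in ``below_detection`` get their line parameters by
    evaluating a degree-2 polynomial, fit to the directly estimated
    (intercept, slope) pairs of same-volume conditions at OD600
    {0.5, 1, 2}, at the low OD.  The scale constant maps the reference
    condition's predicted amplitude at ``reference_time_hr`` to ``anchor``.
    """
    by_cond: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for prof in profiles:
        amp = peak_amplitude(prof).amplitude
        by_cond.setdefault(_norm_cond(prof.condition), []).append(
            (prof.growth_time_hr, amp))

    model = DensityModel()
    for cond, pts in by_cond.items():
        times = np.array([t for t, _ in pts])
        if np.unique(times).size < 2:
            raise FittingError(
                f"condition {cond}: need >= 2 distinct growth times to fit")
        amps = np.array([a for _, a in pts])
        slope, intercept = np.polyfit(times, amps, 1)
        model.lines[cond] = (float(intercept), float(slope))

    below = tuple(_norm_cond(c) for c in below_detection)
    if below:
        anchors = {0.5, 1.0, 2.0}
        for od_low, vol in below:
            donors = sorted(c for c in model.lines
                            if c[1] == vol and c[0] in anchors)
            if len(donors) < 3:
                raise FittingError(
                    f"condition {(od_low, vol)}: extrapolation needs fitted "
                    f"OD600 {{0.5, 1, 2}} at volume {vol}")
            ods = np.array([c[0] for c in donors])
            b0s = np.array([model.lines[c][0] for c in donors])
            b1s = np.array([model.lines[c][1] for c in donors])
            p0 = np.polyfit(ods, b0s, 2)
            p1 = np.polyfit(ods, b1s, 2)
            model.low_density_poly = {"intercept": p0.tolist(),
                                      "slope": p1.tolist()}
            model.lines[(od_low, vol)] = (float(np.polyval(p0, od_low)),
                                          float(np.polyval(p1, od_low)))
        model.extrapolated = below

    ref = _norm_cond(reference_condition)
    if ref not in model.lines:
        raise FittingError(f"reference condition {ref} absent from calibration data")
    ref_amp = model.predicted_amplitude(ref, reference_time_hr)
    if ref_amp <= 0:
        raise FittingError("reference condition predicts non-positive amplitude")
    model.scale_constant = anchor / ref_amp
    return model


def relative_density(model: DensityModel, condition: Condition,
                     growth_time_hr: float) -> float:
    """Linearly rescaled predicted peak amplitude, clipped at 0 from below."""
    amp = model.predicted_amplitude(condition, growth_time_hr)
    return max(model.scale_constant * amp, 0.0)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_profiles(path) -> list[RadialProfile]:
    """Read a profile table: od600, volume_ul, growth_time_hr, radius_um, intensity."""
    df = pd.read_csv(path)
    out = []
    keys = ["od600", "volume_ul", "growth_time_hr"]
    for (od, vol, t), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("radius_um")
        out.append(RadialProfile((float(od), float(vol)), float(t),
                                 grp["radius_um"].to_numpy(),
                                 grp["intensity"].to_numpy()))
    return out


def write_density_table(model: DensityModel, growth_times_hr, path) -> None:
    rows = []
    for cond in sorted(model.lines):
        for t in growth_times_hr:
            rows.append({"od600": cond[0], "volume_ul": cond[1],
                         "growth_time_hr": t,
                         "relative_density": relative_density(model, cond, t)})
    pd.DataFrame(rows).to_csv(path, index=False)
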