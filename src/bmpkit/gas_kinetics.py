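"""Headspace-to-methane accounting and per-vial performance metrics for
biomethane-potential (BMP) batch assays.

A sealed serum vial ferments a soluble substrate; headspace overpressure is
read with a differential manometer and the CH4 molar fraction with a GC,
after which the headspace is vented back to atmospheric pressure. The
methane produced over each inter-measurement interval is recovered from an
ideal-gas mole balance across the vent events,

    dn_CH4 = [(P_atm + P_HS(t)) * x_CH4(t) - P_atm * x_CH4(t-1)] * V_HS / (R*T),

cumulated over time, and expressed as volume at normal temperature and
pressure (273 K, 101 325 Pa).  Performance metrics derived from the
cumulative curve follow the conventions of ammonium-inhibition BMP assays:
the methane production rate (MPR) is the maximal ordinary-least-squares
slope over 4-6 successive measurements normalised by the vial's volatile
solids, the latency (lag) phase is the onset of a sustained >=20 % rise in
cumulative methane above a detection floor, and the yield is the maximal
cumulative volume per gram of fed soluble COD.

All quantities are SI internally (m^3, Pa, K, mol); the I/O layer converts
from ml/mbar file dialects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
NTP_TEMPERATURE = 273.0  # K, printed convention for "normal" conditions
NTP_PRESSURE = 101_325.0  # Pa

#: Molar volume at NTP in ml per mol (R * 273 / 101325, in m^3, times 1e6).
MOLAR_VOLUME_NTP_ML = GAS_CONSTANT * NTP_TEMPERATURE / NTP_PRESSURE * 1e6

#: Methane equivalent of COD: oxidising 1 mol CH4 consumes 64 g O2.
COD_PER_MOL_CH4_G = 64.0

#: Detection floor equivalent of one GC limit of quantitation, in Nml.
#: Used (together with 0.5 % of the final cumulative volume) to anchor the
#: latency rule, which is otherwise ill-defined at a zero baseline.
DEFAULT_LOQ_NML = 0.1

MODALITIES = ("independent", "successive")


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class VialSpec:
    """Geometry, temperature and loading of one batch vial."""

    vial_id: str
    total_volume: float  # m^3
    headspace_volume: float  # m^3
    temperature: float  # K
    atmospheric_pressure: float  # Pa
    inoculum_vs: float  # g volatile solids in the vial
    fed_scod: float  # g soluble COD fed
    ammonium_level: float  # g N-NH4+ per liter
    modality: str = "independent"
    replicate: int = 1

    def __post_init__(self) -> None:
        _require_finite(
            "VialSpec",
            self.total_volume,
            self.headspace_volume,
            self.temperature,
            self.atmospheric_pressure,
            self.inoculum_vs,
            self.fed_scod,
            self.ammonium_level,
        )
        if not 0 < self.headspace_volume < self.total_volume:
            raise ValueError(
                f"vial {self.vial_id}: headspace volume must lie in "
                f"(0, total_volume); got {self.headspace_volume} of {self.total_volume}"
            )
        if self.temperature <= 0:
            raise ValueError(f"vial {self.vial_id}: temperature must be > 0 K")
        if self.atmospheric_pressure <= 0:
            raise ValueError(f"vial {self.vial_id}: atmospheric pressure must be > 0 Pa")
        if self.inoculum_vs <= 0:
            raise ValueError(f"vial {self.vial_id}: inoculum VS must be > 0 g")
        if self.fed_scod <= 0:
            raise ValueError(f"vial {self.vial_id}: fed sCOD must be > 0 g")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"vial {self.vial_id}: modality must be one of {MODALITIES}"
            )

    @property
    def working_volume_l(self) -> float:
        """Liquid working volume in liters."""
        return (self.total_volume - self.headspace_volume) * 1e3

    @property
    def fed_scod_g_per_l(self) -> float:
        """Fed soluble COD as a concentration in the working volume."""
        return self.fed_scod / self.working_volume_l


@dataclass(frozen=True)
class HeadspaceObservation:
    """One timepoint's manometer overpressure (gauge, before venting) and GC
    CH4 molar fraction."""

    time: float  # days since inoculation
    overpressure: float  # Pa above atmospheric
    ch4_fraction: float  # dimensionless, in [0, 1]
    vial_id: str | None = None

    def __post_init__(self) -> None:
        _require_finite("HeadspaceObservation", self.time, self.overpressure, self.ch4_fraction)
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")
        if not 0.0 <= self.ch4_fraction <= 1.0:
            raise ValueError(f"ch4_fraction must be in [0, 1], got {self.ch4_fraction}")


@dataclass
class MethaneProductionSeries:
    """Per-interval produced moles and cumulative NTP volume for one vial.

    ``interval_moles[0]`` is 0 by convention: the first observation defines
    the zero-production baseline.
    """

    vial_id: str
    times: np.ndarray  # days
    interval_moles: np.ndarray  # mol, aligned with times
    cumulative_ntp_ml: np.ndarray  # Nml, aligned with times

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.interval_moles = np.asarray(self.interval_moles, dtype=float)
        self.cumulative_ntp_ml = np.asarray(self.cumulative_ntp_ml, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"vial {self.vial_id}: times must be strictly increasing")
        n = len(self.times)
        if len(self.interval_moles) != n or len(self.cumulative_ntp_ml) != n:
            raise ValueError(f"vial {self.vial_id}: series arrays must share length")


class LatencyResult(NamedTuple):
    days: float
    onset: bool  # False when no qualifying interval was found


@dataclass
class KineticsSummary:
    """Per-vial performance metrics (the columns of a condition table)."""

    vial_id: str
    mpr: float  # ml CH4 g^-1 VS day^-1
    mpr_window: tuple[int, int]  # (start index, window length)
    latency_days: float
    latency_onset: bool
    yield_ml_per_g_cod: float
    max_cumulative_ml: float
    cod_removal_pct: float | None = None


def interval_methane_moles(
    prev: HeadspaceObservation, curr: HeadspaceObservation, vial: VialSpec
) -> float:
    """Methane produced (mol) between two successive measurements.

    Assumes complete venting to atmospheric pressure after the previous
    measurement, at unchanged gas composition ``prev.ch4_fraction`` -- which
    is exactly what the subtracted ``P_atm * x(t-1)`` term encodes.  May be
    negative for noisy inputs; the caller decides whether to clamp.
    """
    if prev.time >= curr.time:
        raise ValueError(
            f"observations must be time-ordered: {prev.time} >= {curr.time}"
        )
    for obs in (prev, curr):
        if obs.vial_id is not None and obs.vial_id != vial.vial_id:
            raise ValueError(
                f"observation belongs to vial {obs.vial_id!r}, not {vial.vial_id!r}"
            )
        if obs.overpressure <= -vial.atmospheric_pressure:
            raise ValueError(
                f"vial {vial.vial_id}: overpressure {obs.overpressure} Pa implies "
                "negative absolute pressure"
            )
    p_atm = vial.atmospheric_pressure
    return (
        ((p_atm + curr.overpressure) * curr.ch4_fraction - p_atm * prev.ch4_fraction)
        * vial.headspace_volume
        / (GAS_CONSTANT * vial.temperature)
    )


def cumulative_methane(
    observations: Sequence[HeadspaceObservation],
    vial: VialSpec,
    monotone_clamp: bool = False,
) -> MethaneProductionSeries:
    """Decode an ordered observation series into a cumulative methane curve.

    The first observation is the zero-production baseline.  With
    ``monotone_clamp`` (default off) negative per-interval moles, which can
    arise from measurement noise, are clamped to zero before cumulating;
    otherwise the raw running sum is kept, preserving the mole-balance
    formula's output.
    """
    if len(observations) < 2:
        raise ValueError("need at least 2 observations (first is the baseline)")
    times = np.array([o.time for o in observations], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"vial {vial.vial_id}: observation times must be strictly increasing")
    moles = np.zeros(len(observations))
    for i in range(1, len(observations)):
        moles[i] = interval_methane_moles(observations[i - 1], observations[i], vial)
    summed = np.where(moles > 0, moles, 0.0) if monotone_clamp else moles
    cumulative_ml = np.cumsum(summed) * MOLAR_VOLUME_NTP_ML
    return MethaneProductionSeries(
        vial_id=vial.vial_id,
        times=times,
        interval_moles=moles,
        cumulative_ntp_ml=cumulative_ml,
    )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(tc, y - y.mean()) / denom)


def methane_production_rate(
    series: MethaneProductionSeries,
    vial: VialSpec,
    window_sizes: Iterable[int] = (4, 5, 6),
) -> tuple[float, dict]:
    """Maximal linear slope of the cumulative curve over short windows.

    For every contiguous window of each allowed size (4 to 6 successive
    measurements by default) an OLS line of cumulative Nml vs time (days) is
    fitted; the MPR is the maximal slope, normalised by the vial's volatile
    solids.  A negative best slope is reported as 0.
    """
    sizes = sorted(set(int(w) for w in window_sizes))
    if any(w < 2 for w in sizes):
        raise ValueError("window sizes must be >= 2")
    n = len(series.times)
    if n < min(sizes):
        raise ValueError(
            f"MPR needs at least {min(sizes)} observations, got {n}"
        )
    t, y = series.times, series.cumulative_ntp_ml
    best_slope, best_start, best_size = -np.inf, 0, 0
    for w in sizes:
        if w > n:
            continue
        for start in range(n - w + 1):
            slope = _ols_slope(t[start : start + w], y[start : start + w])
            if slope > best_slope:
                best_slope, best_start, best_size = slope, start, w
    mpr = max(best_slope, 0.0) / vial.inoculum_vs
    meta = {
        "start": best_start,
        "size": best_size,
        "slope_nml_per_day": best_slope,
        "window_start_day": float(t[best_start]),
    }
    return mpr, meta


def latency_phase(
    series: MethaneProductionSeries, baseline_floor: float | None = None
) -> LatencyResult:
    """Onset of methane production: the 20 %-increase rule with a floor.

    Returns the start of the earliest interval over which the cumulative
    volume rises by at least 20 % *and* ends above ``baseline_floor``.  A
    literal 20 %-of-previous rule fires on any increase from a zero
    baseline, so the floor (default: max of 0.5 % of the final cumulative
    volume and one GC limit-of-quantitation equivalent) anchors the rule to
    detectable production.  When no interval qualifies, the last observation
    time is returned flagged ``onset=False``.
    """
    cum = series.cumulative_ntp_ml
    if baseline_floor is None:
        baseline_floor = max(0.005 * float(np.max(cum, initial=0.0)), DEFAULT_LOQ_NML)
    if baseline_floor < 0:
        raise ValueError("baseline_floor must be >= 0")
    for i in range(1, len(cum)):
        if cum[i] >= 1.2 * cum[i - 1] and cum[i] >= baseline_floor:
            return LatencyResult(float(series.times[i - 1]), True)
    return LatencyResult(float(series.times[-1]), False)


def methane_yield(series: MethaneProductionSeries, vial: VialSpec) -> float:
    """Maximal cumulative CH4 volume per gram of fed soluble COD."""
    if vial.fed_scod <= 0:
        raise ValueError("fed sCOD must be > 0")
    return float(np.max(series.cumulative_ntp_ml)) / vial.fed_scod


def cod_removal_efficiency(fed: float, residual: float) -> float:
    """COD removal efficiency in percent, 100 * (fed - residual) / fed.

    ``fed`` and ``residual`` must share units (typically g O2 per liter).
    Values are clamped to [0, 100]; a residual above the fed load is
    physically impossible up to measurement error and triggers a warning.
    """
    if fed <= 0:
        raise ValueError(f"fed COD must be > 0, got {fed}")
    if residual < 0:
        raise ValueError(f"residual COD must be >= 0, got {residual}")
    eff = 100.0 * (fed - residual) / fed
    if residual > fed:
        warnings.warn(
            f"residual COD ({residual}) exceeds fed COD ({fed}); clamping efficiency to 0",
            stacklevel=2,
        )
        return 0.0
    return min(eff, 100.0)


def theoretical_bmp() -> float:
    """Stoichiometric methane potential, Nml CH4 per g COD.

    Derived, not hard-coded: 1/64 mol CH4 per g COD times the NTP molar
    volume.  Rounds to 350 at integer precision.
    """
    return MOLAR_VOLUME_NTP_ML / COD_PER_MOL_CH4_G


def summarize_kinetics(
    series: MethaneProductionSeries,
    vial: VialSpec,
    residual_scod_g_per_l: float | None = None,
    baseline_floor: float | None = None,
    window_sizes: Iterable[int] = (4, 5, 6),
) -> KineticsSummary:
    """Compute every per-vial metric from a decoded production series."""
    mpr, meta = methane_production_rate(series, vial, window_sizes)
    lat = latency_phase(series, baseline_floor)
    removal = None
    if residual_scod_g_per_l is not None:
        removal = cod_removal_efficiency(vial.fed_scod_g_per_l, residual_scod_g_per_l)
    return KineticsSummary(
        vial_id=vial.vial_id,
        mpr=mpr,
        mpr_window=(meta["start"], meta["size"]),
        latency_days=lat.days,
        latency_onset=lat.onset,
        yield_ml_per_g_cod=methane_yield(series, vial),
        max_cumulative_ml=float(np.max(series.cumulative_ntp_ml)),
        cod_removal_pct=removal,
    )
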