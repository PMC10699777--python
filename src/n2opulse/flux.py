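"""Chamber flux estimation from recirculating-loop concentration series.

The estimator is the standard static/recirculating chamber approach: an
ordinary least-squares line through the N₂O mole fraction over the last
part of a short closure (a deadband discards the mixing transient), a
two-sided t test on the slope that gates non-significant fluxes to zero,
and an ideal-gas unit conversion from ppb s⁻¹ to ng N m⁻² s⁻¹.  An
open-system δ¹⁵N index (*δ¹⁵N, the mean of the final seconds of the raw
delta stream) summarises tracer arrival without claiming to be an
absolute source signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import ChamberGeometry, M_N2, R_GAS
from .errors import (
    DataError,
    DegenerateDesignError,
    InsufficientDataError,
    MissingChannelError,
)


@dataclass
class ChamberSeries:
    """One chamber closure: time-resolved concentrations inside the loop.

    ``time_s`` is seconds since closure start (strictly increasing);
    ``start_time_s`` locates the closure on the experiment clock so that
    pulse summaries can order closures.
    """

    chamber_id: str
    time_s: np.ndarray
    n2o_ppb: np.ndarray
    co2_ppm: Optional[np.ndarray] = None
    d15n: Optional[np.ndarray] = None
    geometry: Optional[ChamberGeometry] = None
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.n2o_ppb = np.asarray(self.n2o_ppb, dtype=float)
        if self.time_s.size < 2:
            raise DataError(f"chamber {self.chamber_id}: need >= 2 points, got {self.time_s.size}")
        if self.time_s.size != self.n2o_ppb.size:
            raise DataError(f"chamber {self.chamber_id}: time and N2O lengths differ")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0)) + 1
            raise DataError(
                f"chamber {self.chamber_id}: time not strictly increasing at row {idx}"
            )
        if np.any(self.n2o_ppb <= 0):
            raise DataError(f"chamber {self.chamber_id}: non-positive N2O mole fraction")
        for name in ("co2_ppm", "d15n"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != self.time_s.size:
                    raise DataError(f"chamber {self.chamber_id}: {name} length mismatch")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass
class FluxEstimate:
    """OLS fit of one closure plus the gated, unit-converted flux."""

    chamber_id: str
    slope_ppb_s: float
    intercept_ppb: float
    r_squared: float
    p_value: float
    flux_ng_n_m2_s: float
    gated: bool
    window_s: float
    start_time_s: float = 0.0


@dataclass
class PulseSummary:
    """Peak and cumulative emission over a post-wetting window."""

    peak_flux: float                  # ng N m-2 s-1
    time_of_peak_h: float
    cumulative_flux_h: float          # (ng N m-2 s-1) * h
    n_estimates: int
    coverage: float                   # sampled span / requested window
    max_gap_h: float


def convert_flux_units(slope_ppb_s: float, geom: ChamberGeometry) -> float:
    """Convert a concentration slope (ppb s⁻¹) to a flux (ng N m⁻² s⁻¹).

    Ideal gas: the loop holds n = PV/RT moles of air, so a mole-fraction
    change of ``slope × 1e-9`` per second is ``slope × 1e-9 × n`` mol N₂O
    per second, times 28.014 g N per mol N₂O (two N atoms), per collar
    area.  kPa·L = Pa·m³ makes the prefactors cancel with the 1e-9/ng
    scaling, leaving the expression below.
    """
    geom.validate()
    moles = geom.pressure_kpa * geom.system_volume_l / (R_GAS * geom.temperature_k)
    return float(slope_ppb_s) * moles * M_N2 / geom.collar_area_m2


def fit_flux(
    series: ChamberSeries,
    deadband_s: Optional[float] = None,
    alpha: float = 0.05,
    geometry: Optional[ChamberGeometry] = None,
) -> FluxEstimate:
    """Fit the closure's concentration rise and gate by slope significance.

    Points earlier than ``deadband_s`` after closure start are discarded
    (default 30 s, i.e. the last 90 s of a 2-min closure are retained).
    The p-value is the two-sided t test on the OLS slope, identical to
    the test on the Pearson correlation for a simple regression.  If
    ``p > alpha`` the flux is reported as zero with ``gated=True`` while
    slope, R² and p remain reported.
    """
    geom = geometry or series.geometry
    if geom is None:
        raise DataError(f"chamber {series.chamber_id}: no geometry available for unit conversion")
    if deadband_s is None:
        deadband_s = 30.0
    mask = series.time_s >= series.time_s[0] + deadband_s
    t = series.time_s[mask]
    c = series.n2o_ppb[mask]
    if t.size < 3:
        raise InsufficientDataError(
            f"chamber {series.chamber_id}: only {t.size} points after the deadband"
        )
    if np.ptp(t) == 0:
        raise DegenerateDesignError(f"chamber {series.chamber_id}: zero time variance")
    if np.ptp(c) == 0:
        # perfectly flat trace: zero slope, no correlation, always gated
        return FluxEstimate(
            chamber_id=series.chamber_id,
            slope_ppb_s=0.0,
            intercept_ppb=float(c[0]),
            r_squared=0.0,
            p_value=1.0,
            flux_ng_n_m2_s=0.0,
            gated=True,
            window_s=float(t[-1] - t[0]),
            start_time_s=series.start_time_s,
        )
    res = stats.linregress(t, c)
    p = float(res.pvalue)
    gated = bool(p > alpha)
    flux = 0.0 if gated else convert_flux_units(res.slope, geom)
    return FluxEstimate(
        chamber_id=series.chamber_id,
        slope_ppb_s=float(res.slope),
        intercept_ppb=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=p,
        flux_ng_n_m2_s=flux,
        gated=gated,
        window_s=float(t[-1] - t[0]),
        start_time_s=series.start_time_s,
    )


def star_delta15n(series: ChamberSeries, tail_s: float = 10.0) -> float:
    """*δ¹⁵N: mean of the raw delta stream over the final ``tail_s`` seconds.

    This is an open-system index of tracer arrival, diluted by whatever
    ambient N₂O the loop started with — it is deliberately not corrected
    to an absolute source value.
    """
    if series.d15n is None:
        raise MissingChannelError(f"chamber {series.chamber_id}: no delta-15N stream")
    mask = series.time_s >= series.time_s[-1] - tail_s
    if not np.any(mask):
        raise InsufficientDataError(f"chamber {series.chamber_id}: empty {tail_s}-s tail")
    return float(np.mean(series.d15n[mask]))


def summarize_pulse(
    estimates: Sequence[FluxEstimate],
    window_h: float = 24.0,
    t0_s: Optional[float] = None,
) -> PulseSummary:
    """Peak and trapezoidal cumulative emission over a post-wetting window.

    Gated estimates enter as zero flux.  Ties on the peak break to the
    earliest closure.  Because instrument dropouts leave gaps, the summary
    carries a coverage fraction and the largest inter-closure gap instead
    of silently interpolating long holes.
    """
    ests = sorted(estimates, key=lambda e: e.start_time_s)
    if t0_s is None:
        t0_s = ests[0].start_time_s if ests else 0.0
    ests = [e for e in ests if t0_s <= e.start_time_s <= t0_s + window_h * 3600.0]
    if not ests:
        raise InsufficientDataError("no flux estimates inside the summary window")
    times_h = np.array([(e.start_time_s - t0_s) / 3600.0 for e in ests])
    flux = np.array([e.flux_ng_n_m2_s for e in ests])
    i_peak = int(np.argmax(flux))  # argmax takes the first maximum: earliest
    cumulative = float(np.trapezoid(flux, times_h)) if len(ests) > 1 else 0.0
    gaps = np.diff(times_h)
    return PulseSummary(
        peak_flux=float(flux[i_peak]),
        time_of_peak_h=float(times_h[i_peak]),
        cumulative_flux_h=cumulative,
        n_estimates=len(ests),
        coverage=float((times_h[-1] - times_h[0]) / window_h) if window_h > 0 else 0.0,
        max_gap_h=float(gaps.max()) if gaps.size else 0.0,
    )
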