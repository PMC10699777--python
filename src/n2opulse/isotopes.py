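"""N₂O isotopocule arithmetic, calibration, Keeling plots, tracer balance.

δ notation, site preference, per-isotopocule calibration against certified
reference gases (with inverse-concentration and CO₂ dependency terms),
Keeling-plot source signatures, and the atom-fraction mass balance used
with enriched ¹⁵N tracers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import R_15N_AIR, R_18O_VSMOW, ReferenceStandard
from .errors import DataError, DegenerateDesignError

#: Calibrated delta channels and the certified attribute each maps to.
CHANNELS = {"d15n_alpha": "d15n_alpha", "d15n_beta": "d15n_beta", "d18o": "d18o"}


# ---------------------------------------------------------------------------
# delta-scale arithmetic

def ratio_to_delta(r_sample, r_standard) -> float:
    """δ = (R_sample / R_standard − 1) × 1000, in ‰."""
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(r_sample <= 0) or r_standard <= 0:
        raise ValueError("isotope ratios must be > 0")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out

def delta_to_ratio(delta, r_standard) -> float:
    """Exact inverse of :func:`ratio_to_delta`."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000.0):
        raise ValueError("delta must be > -1000 per mil")
    out = r_standard * (1.0 + delta / 1000.0)
    return float(out) if out.ndim == 0 else out


class SitePreference(NamedTuple):
    sp: float        # ‰, central minus terminal N
    bulk: float      # ‰, mean of the two site deltas

def site_preference(d15n_alpha: float, d15n_beta: float) -> SitePreference:
    """SP = δ¹⁵Nα − δ¹⁵Nβ, with δ¹⁵N_bulk = (δ¹⁵Nα + δ¹⁵Nβ)/2 alongside."""
    if not (np.isfinite(d15n_alpha) and np.isfinite(d15n_beta)):
        raise ValueError("site deltas must be finite")
    return SitePreference(
        sp=float(d15n_alpha - d15n_beta),
        bulk=float((d15n_alpha + d15n_beta) / 2.0),
    )


# ---------------------------------------------------------------------------
# readings

@dataclass
class IsotopocouleReading:
    """One N₂O sample: isotopocule ratios and derived delta quantities.

    Internal consistency (SP = α − β, bulk = mean of sites, ratios match
    deltas) is enforced at construction; build instances through
    :meth:`from_deltas` or :meth:`from_ratios`.
    """

    n2o_ppb: float
    r_alpha: float
    r_beta: float
    r_18: float
    d15n_alpha: float
    d15n_beta: float
    d18o: float
    d15n_bulk: float
    sp: float
    co2_ppm: Optional[float] = None
    out_of_range: bool = False

    def __post_init__(self) -> None:
        if min(self.r_alpha, self.r_beta, self.r_18) <= 0:
            raise DataError("isotopocule ratios must be > 0")
        if abs(self.sp - (self.d15n_alpha - self.d15n_beta)) > 1e-9:
            raise DataError("SP inconsistent with site deltas")
        if abs(self.d15n_bulk - (self.d15n_alpha + self.d15n_beta) / 2.0) > 1e-9:
            raise DataError("bulk d15N inconsistent with site deltas")

    @classmethod
    def from_deltas(
        cls,
        n2o_ppb: float,
        d15n_alpha: float,
        d15n_beta: float,
        d18o: float,
        co2_ppm: Optional[float] = None,
        out_of_range: bool = False,
    ) -> "IsotopocouleReading":
        sp = site_preference(d15n_alpha, d15n_beta)
        return cls(
            n2o_ppb=float(n2o_ppb),
            r_alpha=delta_to_ratio(d15n_alpha, R_15N_AIR),
            r_beta=delta_to_ratio(d15n_beta, R_15N_AIR),
            r_18=delta_to_ratio(d18o, R_18O_VSMOW),
            d15n_alpha=float(d15n_alpha),
            d15n_beta=float(d15n_beta),
            d18o=float(d18o),
            d15n_bulk=sp.bulk,
            sp=sp.sp,
            co2_ppm=co2_ppm,
            out_of_range=out_of_range,
        )

    @classmethod
    def from_ratios(
        cls,
        n2o_ppb: float,
        r_alpha: float,
        r_beta: float,
        r_18: float,
        co2_ppm: Optional[float] = None,
    ) -> "IsotopocouleReading":
        return cls.from_deltas(
            n2o_ppb=n2o_ppb,
            d15n_alpha=ratio_to_delta(r_alpha, R_15N_AIR),
            d15n_beta=ratio_to_delta(r_beta, R_15N_AIR),
            d18o=ratio_to_delta(r_18, R_18O_VSMOW),
            co2_ppm=co2_ppm,
        )

    @property
    def point(self) -> tuple[float, float, float]:
        """(SP, δ¹⁵N_bulk, δ¹⁸O) for source partitioning."""
        return (self.sp, self.d15n_bulk, self.d18o)


# ---------------------------------------------------------------------------
# calibration against reference gases

@dataclass
class CalibrationModel:
    """Per-channel linear model: measured ~ true + 1/[N₂O] + [CO₂].

    ``coef[channel]`` holds (intercept, slope_true, coef_inv_n2o, coef_co2).
    The correction inverts the model for the true delta.  The model form is
    deliberately explicit and simple; swap the fit function if an
    instrument needs higher-order terms.
    """

    coef: dict[str, np.ndarray]
    r_squared: dict[str, float]
    validity_ppm: tuple[float, float]

    def correct(self, channel: str, measured: float, n2o_ppm: float, co2_ppm: float) -> float:
        b = self.coef[channel]
        if abs(b[1]) < 1e-12:
            raise DegenerateDesignError(f"calibration for {channel} is not invertible")
        return float((measured - b[0] - b[2] / n2o_ppm - b[3] * co2_ppm) / b[1])

    def in_range(self, n2o_ppm: float) -> bool:
        lo, hi = self.validity_ppm
        return lo <= n2o_ppm <= hi


def fit_calibration(
    runs: pd.DataFrame,
    standards: dict[str, ReferenceStandard],
) -> CalibrationModel:
    """Fit the concentration/CO₂ dependency model from reference-gas runs.

    ``runs`` needs columns ``standard``, ``n2o_ppm``, ``co2_ppm`` and one
    measured column per channel (``d15n_alpha``, ``d15n_beta``, ``d18o``).
    Requires at least two distinct standards (to span true delta) and three
    N₂O concentration levels.
    """
    required = {"standard", "n2o_ppm", "co2_ppm", *CHANNELS}
    missing = required - set(runs.columns)
    if missing:
        raise DataError(f"calibration runs missing columns: {sorted(missing)}")
    if runs["standard"].nunique() < 2:
        raise DegenerateDesignError("need >= 2 reference standards to span true delta")
    if runs["n2o_ppm"].nunique() < 3:
        raise DegenerateDesignError("need >= 3 N2O concentration levels")

    n2o = runs["n2o_ppm"].to_numpy(dtype=float)
    co2 = runs["co2_ppm"].to_numpy(dtype=float)
    coef, r2 = {}, {}
    for channel, attr in CHANNELS.items():
        true = np.array([getattr(standards[s], attr) for s in runs["standard"]])
        X = np.column_stack([np.ones_like(n2o), true, 1.0 / n2o, co2])
        # identify collapsed factors before lstsq hides them
        for j, name in ((1, "true delta"), (2, "1/[N2O]"), (3, "[CO2]")):
            if np.ptp(X[:, j]) == 0:
                raise DegenerateDesignError(f"calibration design has no spread in {name}")
        y = runs[channel].to_numpy(dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise DegenerateDesignError("calibration design matrix is rank deficient")
        resid = y - X @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2[channel] = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        coef[channel] = beta
    return CalibrationModel(
        coef=coef,
        r_squared=r2,
        validity_ppm=(float(n2o.min()), float(n2o.max())),
    )


def apply_calibration(reading: IsotopocouleReading, model: CalibrationModel) -> IsotopocouleReading:
    """Invert the calibration for the true deltas and rebuild the reading.

    Readings outside the calibrated concentration span are still corrected
    (the model extrapolates linearly) but come back flagged.
    """
    n2o_ppm = reading.n2o_ppb / 1000.0
    co2 = reading.co2_ppm if reading.co2_ppm is not None else 0.0
    corrected = {
        ch: model.correct(ch, getattr(reading, ch), n2o_ppm, co2) for ch in CHANNELS
    }
    return IsotopocouleReading.from_deltas(
        n2o_ppb=reading.n2o_ppb,
        d15n_alpha=corrected["d15n_alpha"],
        d15n_beta=corrected["d15n_beta"],
        d18o=corrected["d18o"],
        co2_ppm=reading.co2_ppm,
        out_of_range=not model.in_range(n2o_ppm),
    )


# ---------------------------------------------------------------------------
# Keeling plots

@dataclass
class KeelingResult:
    """Two-source mixing intercept: δ of the added source."""

    intercept: float          # ‰ — the source signature
    slope: float              # ‰ · ppb
    se_intercept: Optional[float]
    r_squared: float
    n: int


def keeling_fit(concentrations_ppb: Sequence[float], deltas: Sequence[float]) -> KeelingResult:
    """OLS of δ against 1/[N₂O]; the intercept is the source signature.

    With exactly two distinct concentrations the line is exact and the
    intercept standard error is undefined (returned as ``None``).
    """
    c = np.asarray(concentrations_ppb, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if c.size != d.size or c.size < 2:
        raise DataError("need matched concentration/delta arrays with >= 2 points")
    if np.any(c <= 0):
        raise DataError("concentrations must be > 0")
    x = 1.0 / c
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all concentrations equal: Keeling design is degenerate")
    if c.size == 2:
        slope = (d[1] - d[0]) / (x[1] - x[0])
        return KeelingResult(
            intercept=float(d[0] - slope * x[0]),
            slope=float(slope),
            se_intercept=None,
            r_squared=1.0,
            n=2,
        )
    res = stats.linregress(x, d)
    return KeelingResult(
        intercept=float(res.intercept),
        slope=float(res.slope),
        se_intercept=float(res.intercept_stderr),
        r_squared=float(res.rvalue) ** 2,
        n=int(c.size),
    )


# ---------------------------------------------------------------------------
# 15N tracer mass balance (atom-fraction scale)

def delta_to_atom_fraction(delta: float, r_standard: float = R_15N_AIR) -> float:
    """x = R/(1+R) with R = R_std (1 + δ/1000).

    Delta-scale arithmetic stops being linear at tracer-level enrichment,
    so two-pool bookkeeping is done on the atom-fraction scale.
    """
    r = delta_to_ratio(delta, r_standard)
    return float(r / (1.0 + r))

def atom_fraction_to_delta(x: float, r_standard: float = R_15N_AIR) -> float:
    """Exact inverse of :func:`delta_to_atom_fraction`."""
    if not (0.0 < x < 1.0):
        raise ValueError("atom fraction must be in (0, 1)")
    r = x / (1.0 - x)
    return ratio_to_delta(r, r_standard)


class TracerFraction(NamedTuple):
    fraction: float      # of N derived from the labelled pool, clipped to [0, 1]
    clipped: bool        # True if the raw mass balance fell outside [0, 1]


def tracer_fraction(
    x_mix: float,
    x_native: float,
    x_tracer: float,
    tol: float = 1e-9,
) -> TracerFraction:
    """Two-pool mass balance: f = (x_mix − x_native)/(x_tracer − x_native).

    All arguments are ¹⁵N atom fractions.  A mixture slightly outside the
    [native, tracer] interval (analytical noise) is clipped and flagged.
    """
    span = x_tracer - x_native
    if abs(span) <= tol:
        raise ValueError("tracer and native pools are isotopically indistinguishable")
    f = (x_mix - x_native) / span
    clipped = bool(f < -tol or f > 1.0 + tol)
    return TracerFraction(fraction=float(np.clip(f, 0.0, 1.0)), clipped=clipped)
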