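"""Synthetic instruments: every input the pipeline consumes, from a seed.

Each generator emulates one measurement chain so the estimators can be
tested without field or laboratory hardware:

* :func:`gen_chamber_series` — a wetting-induced emission pulse sampled by
  an automated chamber (linear rise to a peak within the first hour,
  exponential relaxation back to baseline over a few hours).
* :func:`gen_keeling_series` — two-source mixing of ambient and
  soil-derived N₂O for Keeling-plot recovery.
* :func:`gen_isotopocule_samples` — process endmember mixtures overprinted
  by Rayleigh N₂O reduction, with analytical noise.
* :func:`gen_calibration_runs` — a spectroscopic analyser with known
  concentration/CO₂ dependencies measuring certified reference gases.
* :func:`gen_qpcr_plate` — log-linear standard dilution series with a
  configurable amplification efficiency.

Zero-noise output inverts exactly through the matching estimator; all
randomness flows from each scenario's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ChamberGeometry, ReferenceStandard, RunConfig
from .errors import DegenerateDesignError
from .flux import ChamberSeries, convert_flux_units
from .isotopes import IsotopocouleReading
from .partition import build_endmembers, rayleigh_shift


# ---------------------------------------------------------------------------
# chamber pulses

@dataclass
class PulseScenario:
    """A rewetting emission pulse as seen by a scheduled chamber.

    Defaults describe the stated world of the pulse experiments: peak
    414 ng N m⁻² s⁻¹ half an hour after wetting (the high-emission dryland
    site), decay back to a ~0 baseline within ~4 h, 2-min closures every
    30 min, ~330 ppb ambient N₂O.
    """

    baseline_flux: float = 0.0          # ng N m-2 s-1
    peak_flux: float = 414.0            # ng N m-2 s-1
    time_to_peak_min: float = 30.0
    decay_tau_min: float = 60.0
    closure_interval_min: float = 30.0
    closure_length_s: float = 120.0
    cadence_s: float = 1.0
    duration_min: float = 300.0
    noise_sd_ppb: float = 2.0
    ambient_ppb: float = 330.0
    ambient_delta: float = 0.0          # ‰, of the ambient N2O
    source_delta: Optional[float] = None  # ‰; set to emit a d15n stream
    seed: int = 0

    def validate(self) -> None:
        if not (self.peak_flux >= self.baseline_flux >= 0):
            raise ValueError("need peak >= baseline >= 0")
        if self.decay_tau_min <= 0 or self.time_to_peak_min <= 0:
            raise ValueError("pulse time constants must be > 0")
        if self.noise_sd_ppb < 0:
            raise ValueError("noise sd must be >= 0")


def pulse_flux(t_s, scn: PulseScenario):
    """Flux (ng N m⁻² s⁻¹) at time t after wetting: linear rise then decay.

    The shape is a named, swappable function, not a mechanistic claim.
    """
    t = np.asarray(t_s, dtype=float)
    tp = scn.time_to_peak_min * 60.0
    tau = scn.decay_tau_min * 60.0
    amp = scn.peak_flux - scn.baseline_flux
    rise = t / tp
    decay = np.exp(-(t - tp) / tau)
    out = scn.baseline_flux + amp * np.where(t <= tp, rise, decay)
    return out if out.ndim else float(out)


def gen_chamber_series(
    scn: PulseScenario,
    geom: ChamberGeometry,
    shape: Callable = pulse_flux,
) -> list[ChamberSeries]:
    """Simulate the scheduled closures sampling one pulse.

    Within each 2-min closure the flux is held at its closure-start value,
    so the true concentration slope is exactly the flux passed backwards
    through the unit conversion; iid Gaussian noise is added on top.  With
    a labelled source, the raw δ¹⁵N stream mixes ambient and accumulated
    source N₂O with concentration weights (linear-in-delta).
    """
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    per_ppb = convert_flux_units(1.0, geom)   # flux produced by a 1 ppb/s slope
    series = []
    n_closures = int(scn.duration_min // scn.closure_interval_min) + 1
    t_rel = np.arange(0.0, scn.closure_length_s + 0.5 * scn.cadence_s, scn.cadence_s)
    for k in range(n_closures):
        t0 = k * scn.closure_interval_min * 60.0
        slope = float(shape(t0, scn)) / per_ppb           # ppb s-1
        added = slope * t_rel
        conc = scn.ambient_ppb + added + rng.normal(0.0, scn.noise_sd_ppb, t_rel.size)
        conc = np.maximum(conc, 1e-6)
        d15n = None
        if scn.source_delta is not None:
            total = scn.ambient_ppb + added
            d15n = (
                scn.ambient_ppb * scn.ambient_delta + added * scn.source_delta
            ) / total
        series.append(
            ChamberSeries(
                chamber_id="sim",
                time_s=t_rel.copy(),
                n2o_ppb=conc,
                d15n=d15n,
                geometry=geom,
                start_time_s=t0,
            )
        )
    return series


# ---------------------------------------------------------------------------
# Keeling mixtures

def gen_keeling_series(
    source_delta: float,
    ambient_ppb: float,
    ambient_delta: float,
    added_ppb_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ChamberSeries:
    """Two-source mixing series for Keeling-plot recovery.

    Mixture delta at each point is the concentration-weighted mean of the
    ambient and source deltas (linear-in-delta), which makes δ exactly
    linear in 1/[N₂O] and the Keeling intercept exactly ``source_delta``
    at zero noise.
    """
    added = np.asarray(added_ppb_grid, dtype=float)
    if np.any(added <= 0):
        raise ValueError("added concentrations must be > 0")
    total = ambient_ppb + added
    if np.unique(total).size < 2:
        raise DegenerateDesignError("need >= 2 distinct total concentrations")
    rng = np.random.default_rng(seed)
    delta = (ambient_ppb * ambient_delta + added * source_delta) / total
    delta = delta + rng.normal(0.0, noise_sd, delta.size)
    return ChamberSeries(
        chamber_id="keeling",
        time_s=np.arange(total.size, dtype=float),
        n2o_ppb=total,
        d15n=delta,
    )


# ---------------------------------------------------------------------------
# isotopocule mixtures with reduction overprinting

@dataclass
class MixtureScenario:
    """Process mixing + Rayleigh reduction scenario for isotopocule samples.

    ``fractions`` weight the producing processes (must sum to 1); each
    process contributes a point drawn uniformly inside its
    substrate-corrected endmember box unless ``points`` pins it.  The
    mixed signature is then displaced by reduction at ``f_rem`` and
    observed ``n_samples`` times with iid Gaussian noise per axis.
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: {"bacterial_denitrification": 1.0}
    )
    f_rem: float = 1.0
    noise_sd: float = 0.0              # ‰, per delta axis
    n_samples: int = 6
    n2o_ppb: float = 2000.0
    co2_ppm: Optional[float] = None
    points: Optional[dict[str, tuple[float, float, float]]] = None
    seed: int = 0

    def validate(self) -> None:
        w = np.array(list(self.fractions.values()), dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixing fractions must be >= 0 and sum to 1")
        if not (0.0 < self.f_rem <= 1.0):
            raise ValueError("f_rem must be in (0, 1] (0 makes ln f undefined)")
        if self.noise_sd < 0 or self.n_samples < 1:
            raise ValueError("need noise_sd >= 0 and n_samples >= 1")


def true_mixture_point(scn: MixtureScenario, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """(pre-reduction mixture point, post-reduction true point), both (SP, δ¹⁵N, δ¹⁸O)."""
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    boxes = build_endmembers(cfg.endmembers, cfg.substrates)
    points = {}
    for name in scn.fractions:
        box = boxes[name]   # KeyError -> unknown process, surfaced to caller
        if scn.points is not None and name in scn.points:
            points[name] = np.asarray(scn.points[name], dtype=float)
        else:
            lo = np.array([box.sp[0], box.d15n[0], box.d18o[0]])
            hi = np.array([box.sp[1], box.d15n[1], box.d18o[1]])
            points[name] = rng.uniform(lo, hi)
    mixture = np.sum(
        [w * points[name] for name, w in scn.fractions.items()], axis=0
    )
    shifted = np.array(rayleigh_shift(mixture, cfg.rayleigh, scn.f_rem))
    return mixture, shifted


def gen_isotopocule_samples(
    scn: MixtureScenario,
    cfg: RunConfig,
) -> list[IsotopocouleReading]:
    """Observed isotopocule readings for a mixing + reduction scenario.

    Readings carry isotopocule ratios consistent with their deltas (the
    exact inverse of the delta conversion), so ratio-level code paths see
    the same samples.
    """
    _, truth = true_mixture_point(scn, cfg)
    # child seed: keep point draws and observation noise independent
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed).spawn(1)[0])
    readings = []
    for _ in range(scn.n_samples):
        sp, d15n, d18o = truth + rng.normal(0.0, scn.noise_sd, 3)
        readings.append(
            IsotopocouleReading.from_deltas(
                n2o_ppb=scn.n2o_ppb,
                d15n_alpha=d15n + sp / 2.0,
                d15n_beta=d15n - sp / 2.0,
                d18o=d18o,
                co2_ppm=scn.co2_ppm,
            )
        )
    return readings


# ---------------------------------------------------------------------------
# tracer pools (atom-fraction scale; exact at any enrichment)

def mix_atom_fractions(f_tracer: float, x_native: float, x_tracer: float) -> float:
    """Atom fraction of a two-pool mixture with tracer-derived fraction f."""
    if not (0.0 <= f_tracer <= 1.0):
        raise ValueError("f_tracer must be in [0, 1]")
    return f_tracer * x_tracer + (1.0 - f_tracer) * x_native


# ---------------------------------------------------------------------------
# analyser calibration runs

def gen_calibration_runs(
    standards: dict[str, ReferenceStandard],
    coef: dict[str, Sequence[float]],
    n2o_ppm_levels: Sequence[float] = (0.3, 0.6, 1.0, 2.0, 5.0),
    co2_ppm_levels: Sequence[float] = (330.0, 660.0, 990.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference-gas runs from an instrument with known dependencies.

    ``coef[channel] = (intercept, slope_true, coef_inv_n2o, coef_co2)``:
    measured = b0 + b1·true + b2/[N₂O] + b3·[CO₂] + noise.  The identity
    instrument is ``(0, 1, 0, 0)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, std in standards.items():
        for n2o in n2o_ppm_levels:
            for co2 in co2_ppm_levels:
                row = {"standard": name, "n2o_ppm": float(n2o), "co2_ppm": float(co2)}
                for channel, attr in (
                    ("d15n_alpha", "d15n_alpha"),
                    ("d15n_beta", "d15n_beta"),
                    ("d18o", "d18o"),
                ):
                    b = coef[channel]
                    true = getattr(std, attr)
                    row[channel] = (
                        b[0] + b[1] * true + b[2] / n2o + b[3] * co2
                        + rng.normal(0.0, noise_sd)
                    )
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR plates

@dataclass
class QpcrScenario:
    """A standards-plus-unknowns plate with a known true efficiency.

    Defaults mirror a six-level, ten-fold dilution series run in
    triplicate with an 80% efficient assay.
    """

    standard_copies: tuple[float, ...] = (2e7, 2e6, 2e5, 2e4, 2e3, 2e2)
    efficiency: float = 0.80
    cq_ref: float = 10.0               # Cq at ref_copies
    ref_copies: float = 2e7
    replicates: int = 3
    cq_noise_sd: float = 0.0
    unknown_copies: tuple[float, ...] = (1e5,)
    target: str = "narG"
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.standard_copies, dtype=float)
        if np.any(np.diff(c) >= 0):
            raise ValueError("standard dilution must be strictly decreasing")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")
        if self.replicates < 1 or self.cq_noise_sd < 0:
            raise ValueError("need replicates >= 1 and noise sd >= 0")

    def true_cq(self, copies) -> np.ndarray:
        """Cq = Cq_ref − log10(copies/ref)/log10(1+E)."""
        copies = np.asarray(copies, dtype=float)
        return self.cq_ref - np.log10(copies / self.ref_copies) / np.log10(1.0 + self.efficiency)


def gen_qpcr_plate(scn: QpcrScenario) -> pd.DataFrame:
    """Plate table: columns well, target, sample, role, input_copies, cq."""
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    rows = []
    well = 0
    for level, copies in enumerate(scn.standard_copies):
        cq0 = float(scn.true_cq(copies))
        for rep in range(scn.replicates):
            rows.append({
                "well": f"W{well:03d}", "target": scn.target,
                "sample": f"std{level}", "role": "standard",
                "input_copies": float(copies),
                "cq": cq0 + rng.normal(0.0, scn.cq_noise_sd),
            })
            well += 1
    for u, copies in enumerate(scn.unknown_copies):
        cq0 = float(scn.true_cq(copies))
        for rep in range(scn.replicates):
            rows.append({
                "well": f"W{well:03d}", "target": scn.target,
                "sample": f"unk{u}", "role": "unknown",
                "input_copies": np.nan,
                "cq": cq0 + rng.normal(0.0, scn.cq_noise_sd),
            })
            well += 1
    return pd.DataFrame(rows)
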