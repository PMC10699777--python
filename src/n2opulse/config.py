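"""Run configuration: geometry, windows, tracers, endmembers, standards.

A single :class:`RunConfig` carries everything the pipeline stages need to
know about a run and round-trips through YAML.  Values that the science
fixes (reference isotope ratios, certified standards) ship as documented
defaults; values that depend on the apparatus (system volume, temperature)
are required fields with no silent fallback — :func:`default_config` fills
them with the worked-example apparatus used throughout the docs and tests.

Conventions
-----------
* deltas in per mil (‰), concentrations in ppb (N₂O) / ppm (CO₂),
  temperatures in kelvin, pressures in kPa, volumes in litres.
* δ¹⁵N is referenced to atmospheric N₂ (AIR), δ¹⁸O to VSMOW.
* Site preference SP = δ¹⁵Nα − δ¹⁵Nβ (central minus terminal N).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError

# Reference isotope ratios of the international delta scales.
R_15N_AIR = 0.0036765     # 15N/14N of atmospheric N2
R_18O_VSMOW = 0.0020052   # 18O/16O of Vienna SMOW

# Physical constants.
R_GAS = 8.314462618       # J mol-1 K-1
M_N2 = 28.014             # g of N per mol N2O (two N atoms)

#: Processes the partition module knows about.
PROCESSES = (
    "nitrification",
    "nitrifier_denitrification",
    "bacterial_denitrification",
    "fungal_denitrification",
    "chemodenitrification",
)

_AXES = ("sp", "d15n", "d18o")


def _pair(value: Sequence[float], name: str) -> tuple[float, float]:
    lo, hi = float(value[0]), float(value[1])
    if not (lo <= hi):
        raise ConfigError(f"{name}: range low must be <= high, got ({lo}, {hi})")
    return (lo, hi)


@dataclass
class ChamberGeometry:
    """Geometry and state of the chamber + recirculating loop."""

    collar_diameter_m: float
    system_volume_l: float
    temperature_k: float
    pressure_kpa: float

    @property
    def collar_area_m2(self) -> float:
        return math.pi * self.collar_diameter_m**2 / 4.0

    def validate(self) -> None:
        if self.collar_diameter_m <= 0:
            raise ConfigError("chamber_geometry: collar diameter must be > 0")
        if self.system_volume_l <= 0:
            raise ConfigError("chamber_geometry: system volume must be > 0")
        if self.temperature_k <= 0:
            raise ConfigError("chamber_geometry: temperature must be > 0 K")
        if self.pressure_kpa <= 0:
            raise ConfigError("chamber_geometry: pressure must be > 0")


@dataclass
class FluxWindow:
    """Deadband/fit-span windowing and the significance gate for fluxes."""

    deadband_s: float = 30.0
    fit_span_s: float = 90.0
    alpha: float = 0.05
    episode_gap_s: float = 120.0

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("flux_window: alpha must be in (0, 1)")
        if self.deadband_s < 0 or self.fit_span_s <= 0:
            raise ConfigError("flux_window: windows must be positive")
        if self.episode_gap_s <= 0:
            raise ConfigError("flux_window: episode gap must be > 0")


@dataclass
class TracerConfig:
    """15N atom fractions of the labelled and native N pools."""

    atom_fraction_label: float = 0.02
    atom_fraction_native: Optional[float] = None  # default: natural abundance

    def __post_init__(self) -> None:
        if self.atom_fraction_native is None:
            self.atom_fraction_native = R_15N_AIR / (1.0 + R_15N_AIR)

    def validate(self) -> None:
        for name in ("atom_fraction_label", "atom_fraction_native"):
            x = getattr(self, name)
            if not (0.0 < x < 1.0):
                raise ConfigError(f"tracer: {name} must be in (0, 1)")
        if self.atom_fraction_label == self.atom_fraction_native:
            raise ConfigError("tracer: label and native pools are indistinguishable")


@dataclass
class SubstrateSignatures:
    """Isotopic composition of the substrates feeding N2O production.

    ``d15n_no2`` defaults to the same value as ``d15n_no3`` because field
    measurements often report a combined nitrate + nitrite pool.
    """

    d18o_h2o: Optional[float] = -9.0
    d15n_no3: Optional[float] = 7.2
    d15n_no2: Optional[float] = 7.2
    d15n_nh4: Optional[float] = 0.0


@dataclass
class EndmemberBox:
    """A process's rectangle in (SP, δ¹⁵N, δ¹⁸O) space.

    δ¹⁵N and δ¹⁸O ranges are substrate-relative (literature convention of
    reporting them against the substrate's isotope value); the basis flags
    say which substrate signature translates which axis when building the
    absolute-scale box.  SP is never substrate-shifted.
    """

    process: str
    sp: tuple[float, float]
    d15n: tuple[float, float]
    d18o: tuple[float, float]
    d15n_basis: Optional[str] = None  # one of {"no3", "no2", "nh4", None}
    d18o_basis: Optional[str] = None  # one of {"water", None}

    def __post_init__(self) -> None:
        self.sp = _pair(self.sp, f"endmember {self.process} sp")
        self.d15n = _pair(self.d15n, f"endmember {self.process} d15n")
        self.d18o = _pair(self.d18o, f"endmember {self.process} d18o")

    def validate(self) -> None:
        if self.process not in PROCESSES:
            raise ConfigError(f"endmember process {self.process!r} is not recognized")
        if self.d15n_basis not in (None, "no3", "no2", "nh4"):
            raise ConfigError(f"endmember {self.process}: bad d15n_basis {self.d15n_basis!r}")
        if self.d18o_basis not in (None, "water"):
            raise ConfigError(f"endmember {self.process}: bad d18o_basis {self.d18o_basis!r}")

    def translate(self, dsp: float, d15: float, d18: float) -> "EndmemberBox":
        """Pure translation; widths are conserved exactly."""
        return EndmemberBox(
            process=self.process,
            sp=(self.sp[0] + dsp, self.sp[1] + dsp),
            d15n=(self.d15n[0] + d15, self.d15n[1] + d15),
            d18o=(self.d18o[0] + d18, self.d18o[1] + d18),
            d15n_basis=self.d15n_basis,
            d18o_basis=self.d18o_basis,
        )

    @property
    def ranges(self) -> dict[str, tuple[float, float]]:
        return {"sp": self.sp, "d15n": self.d15n, "d18o": self.d18o}

    def centroid(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in (self.sp, self.d15n, self.d18o)])

    def candidate_points(self) -> np.ndarray:
        """The 8 corners plus the centroid, shape (9, 3)."""
        lows = np.array([self.sp[0], self.d15n[0], self.d18o[0]])
        highs = np.array([self.sp[1], self.d15n[1], self.d18o[1]])
        corners = np.array(
            [[lows[i] if (k >> i) & 1 == 0 else highs[i] for i in range(3)] for k in range(8)]
        )
        return np.vstack([corners, self.centroid()])

    def contains(self, point: Sequence[float]) -> dict[str, bool]:
        """Per-axis membership; NaN axes are reported as False."""
        out = {}
        for axis, value in zip(_AXES, point):
            lo, hi = self.ranges[axis]
            out[axis] = bool(np.isfinite(value) and lo <= value <= hi)
        return out


@dataclass
class RayleighParams:
    """Net isotope effects of N2O -> N2 reduction and the system model.

    Closed system: the N2O pool is produced then progressively consumed,
    so the residual follows delta = delta0 + eps*ln(f).  Open system:
    production and consumption are at steady state and the residual
    follows delta = delta0 - eps*(1 - f).  In both, f is the fraction of
    N2O remaining and negative eps enriches the residual pool.
    """

    eps_sp: float = -5.0
    eps_15: float = -6.6
    eps_18: float = -15.4
    mode: str = "closed"
    eps_sp_range: Optional[tuple[float, float]] = (-8.2, -2.9)
    eps_15_range: Optional[tuple[float, float]] = (-11.6, -1.8)
    eps_18_range: Optional[tuple[float, float]] = (-25.1, -5.1)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([self.eps_sp, self.eps_15, self.eps_18])

    def ranges(self) -> np.ndarray:
        """(3, 2) array of epsilon ranges; a missing range collapses to the point value."""
        out = []
        for eps, rng in (
            (self.eps_sp, self.eps_sp_range),
            (self.eps_15, self.eps_15_range),
            (self.eps_18, self.eps_18_range),
        ):
            out.append((eps, eps) if rng is None else (float(rng[0]), float(rng[1])))
        return np.array(out)

    def validate(self) -> None:
        if self.mode not in ("closed", "open"):
            raise ConfigError(f"rayleigh: mode must be 'closed' or 'open', got {self.mode!r}")
        if not np.all(np.isfinite(self.epsilons)):
            raise ConfigError("rayleigh: epsilon values must be finite")


@dataclass
class ReferenceStandard:
    """A certified N2O isotope reference material."""

    name: str
    d15n_bulk: float
    d15n_alpha: float
    d15n_beta: float
    sp: float
    d18o: float

    def validate(self) -> None:
        # certified SP must agree with alpha - beta to printed rounding
        if abs(self.sp - (self.d15n_alpha - self.d15n_beta)) > 0.02:
            raise ConfigError(
                f"standard {self.name}: certified SP inconsistent with site deltas"
            )


@dataclass
class SoilSampleMeta:
    """Extraction metadata for qPCR copies-per-gram conversion.

    All fields are required: without them results stay in copies per
    reaction rather than assuming volumes the run never declared.
    """

    soil_mass_g: float
    elution_volume_ul: float
    template_volume_ul: float
    dilution_factor: float = 1.0

    def validate(self) -> None:
        for name in ("soil_mass_g", "elution_volume_ul", "template_volume_ul", "dilution_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"qpcr_meta: {name} must be > 0")


@dataclass
class RunConfig:
    chamber_geometry: ChamberGeometry
    flux_window: FluxWindow = field(default_factory=FluxWindow)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    substrates: SubstrateSignatures = field(default_factory=SubstrateSignatures)
    rayleigh: RayleighParams = field(default_factory=RayleighParams)
    endmembers: dict[str, EndmemberBox] = field(default_factory=dict)
    standards: dict[str, ReferenceStandard] = field(default_factory=dict)
    qpcr_meta: Optional[SoilSampleMeta] = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.chamber_geometry.validate()
        self.flux_window.validate()
        self.tracer.validate()
        self.rayleigh.validate()
        for box in self.endmembers.values():
            box.validate()
        for std in self.standards.values():
            std.validate()
        if self.qpcr_meta is not None:
            self.qpcr_meta.validate()
        return self

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        d = plain(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            geom = ChamberGeometry(**d["chamber_geometry"])
        except KeyError as exc:
            raise ConfigError(f"config: missing required section/field {exc}") from exc
        except TypeError as exc:
            raise ConfigError(f"config: chamber_geometry is incomplete ({exc})") from exc
        cfg = cls(
            chamber_geometry=geom,
            flux_window=FluxWindow(**d.get("flux_window", {})),
            tracer=TracerConfig(**d.get("tracer", {})),
            substrates=SubstrateSignatures(**d.get("substrates", {})),
            rayleigh=RayleighParams(**_tupled(d.get("rayleigh", {}))),
            endmembers={
                name: EndmemberBox(
                    process=name,
                    **_tupled({k: v for k, v in spec.items() if k != "process"}),
                )
                for name, spec in d.get("endmembers", {}).items()
            },
            standards={
                name: ReferenceStandard(
                    name=name, **{k: v for k, v in spec.items() if k != "name"}
                )
                for name, spec in d.get("standards", {}).items()
            },
            qpcr_meta=(SoilSampleMeta(**d["qpcr_meta"]) if d.get("qpcr_meta") else None),
            seed=int(d.get("seed", 0)),
        )
        return cfg.validate()

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError("config: file does not contain a mapping")
        return cls.from_dict(d)


def _tupled(spec: dict) -> dict:
    """Convert list-valued range fields back to tuples after YAML parsing."""
    out = {}
    for k, v in spec.items():
        out[k] = tuple(v) if isinstance(v, (list, tuple)) else v
    return out


def default_endmembers() -> dict[str, EndmemberBox]:
    """Literature-compilation endmember boxes, substrate-relative.

    The SP ranges for bacterial denitrification, fungal denitrification and
    chemodenitrification follow the commonly cited compilation values
    (−7.5 to 3.7‰, 27.2 to 39.9‰ and 20.1 to 25.7‰ respectively); the
    remaining boxes are approximate compilation ranges.  All are defaults a
    user is expected to confirm or override for their own system.
    """
    boxes = {
        "nitrification": EndmemberBox(
            "nitrification", sp=(32.6, 38.7), d15n=(-62.0, -45.0), d18o=(23.0, 46.0),
            d15n_basis="nh4", d18o_basis=None,
        ),
        "nitrifier_denitrification": EndmemberBox(
            "nitrifier_denitrification", sp=(-13.6, 1.9), d15n=(-57.0, -34.0),
            d18o=(8.0, 27.0), d15n_basis="nh4", d18o_basis="water",
        ),
        "bacterial_denitrification": EndmemberBox(
            "bacterial_denitrification", sp=(-7.5, 3.7), d15n=(-54.0, -10.0),
            d18o=(13.0, 27.0), d15n_basis="no3", d18o_basis="water",
        ),
        "fungal_denitrification": EndmemberBox(
            "fungal_denitrification", sp=(27.2, 39.9), d15n=(-52.0, -20.0),
            d18o=(30.0, 50.0), d15n_basis="no3", d18o_basis="water",
        ),
        "chemodenitrification": EndmemberBox(
            "chemodenitrification", sp=(20.1, 25.7), d15n=(-35.0, -10.0),
            d18o=(15.0, 46.6), d15n_basis="no2", d18o_basis=None,
        ),
    }
    return boxes


def default_standards() -> dict[str, ReferenceStandard]:
    """USGS 51 and USGS 52 certified N2O reference values (‰)."""
    return {
        "USGS51": ReferenceStandard("USGS51", d15n_bulk=1.32, d15n_alpha=0.48,
                                    d15n_beta=2.15, sp=-1.67, d18o=41.23),
        "USGS52": ReferenceStandard("USGS52", d15n_bulk=0.44, d15n_alpha=13.52,
                                    d15n_beta=-12.64, sp=26.15, d18o=40.64),
    }


def default_config(seed: int = 0) -> RunConfig:
    """A fully populated configuration for the worked-example apparatus.

    Geometry: 20-cm collars on a ~10 L chamber + recirculating loop, run at
    40 °C and 1 atm — representative of an automated soil-chamber system in
    a hot dryland.  Apparatus fields have no package-level fallback when a
    config file is loaded; this constructor is the one place example values
    are supplied.
    """
    return RunConfig(
        chamber_geometry=ChamberGeometry(
            collar_diameter_m=0.20, system_volume_l=10.0,
            temperature_k=313.15, pressure_kpa=101.325,
        ),
        endmembers=default_endmembers(),
        standards=default_standards(),
        seed=seed,
    ).validate()
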