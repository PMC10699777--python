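"""Absolute qPCR quantification from standard curves.

Cq is log-linear in template copies: Cq = intercept + slope·log10(copies),
with amplification efficiency E = 10^(−1/slope) − 1 (E = 1 is perfect
doubling, slope −3.32 cycles per decade).  Unknowns are read off the
fitted line and scaled to copies per gram of soil with explicit
extraction metadata — no volumes are ever assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .config import SoilSampleMeta
from .errors import CurveFailureError, InsufficientDataError


@dataclass
class StandardCurve:
    slope: float                       # cycles per log10 copies, < 0
    intercept: float                   # cycles at 1 copy per reaction
    efficiency: float                  # fraction; 1.0 = perfect doubling
    r_squared: float
    dynamic_range: tuple[float, float]  # copies per reaction spanned by standards

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CurveFailureError(
                f"standard curve slope must be negative, got {self.slope:.3g} "
                "(non-negative slope signals a failed or inhibited run)"
            )
        assert abs(self.efficiency - (10.0 ** (-1.0 / self.slope) - 1.0)) <= 1e-9


def fit_standard_curve(copies: Sequence[float], cq: Sequence[float]) -> StandardCurve:
    """OLS of Cq on log10(input copies) over the dilution series."""
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.size != cq.size:
        raise InsufficientDataError("copies and Cq arrays must have the same length")
    if np.any(copies <= 0):
        raise ValueError("standard input copies must be > 0")
    if np.unique(copies).size < 3:
        raise InsufficientDataError("need >= 3 dilution levels for a standard curve")
    res = stats.linregress(np.log10(copies), cq)
    if res.slope >= 0:
        raise CurveFailureError(
            f"standard curve slope {res.slope:.3g} >= 0: run failed or inhibited"
        )
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
        r_squared=float(res.rvalue) ** 2,
        dynamic_range=(float(copies.min()), float(copies.max())),
    )


class QuantResult(NamedTuple):
    copies_per_reaction: float
    copies_per_g: Optional[float]     # None when no extraction metadata given
    in_range: bool                    # within the curve's dynamic range


def quantify(
    cq: float,
    curve: StandardCurve,
    meta: Optional[SoilSampleMeta] = None,
) -> QuantResult:
    """Copies per reaction (and per gram soil, if metadata is supplied).

    copies_rxn = 10^((Cq − intercept)/slope);
    copies/g = copies_rxn · (elution/template) · dilution / soil mass.
    A Cq outside the standards' dynamic range is quantified anyway but
    flagged, since it extrapolates the curve.
    """
    copies_rxn = float(10.0 ** ((cq - curve.intercept) / curve.slope))
    in_range = curve.dynamic_range[0] <= copies_rxn <= curve.dynamic_range[1]
    per_g = None
    if meta is not None:
        meta.validate()
        per_g = (
            copies_rxn
            * (meta.elution_volume_ul / meta.template_volume_ul)
            * meta.dilution_factor
            / meta.soil_mass_g
        )
    return QuantResult(copies_per_reaction=copies_rxn, copies_per_g=per_g, in_range=in_range)


def quantify_sample(
    cq_replicates: Sequence[float],
    curve: StandardCurve,
    meta: Optional[SoilSampleMeta] = None,
) -> QuantResult:
    """Aggregate technical replicates (mean Cq) before quantification."""
    cq = np.asarray([c for c in cq_replicates if c is not None and np.isfinite(c)], dtype=float)
    if cq.size == 0:
        raise InsufficientDataError("no finite Cq replicates to quantify")
    return quantify(float(cq.mean()), curve, meta)


def detection_call(
    cq_values: Sequence[Optional[float]],
    limit_cycles: float = 40.0,
    min_fraction: float = 0.5,
) -> bool:
    """Detected iff more than ``min_fraction`` of replicates amplify below the limit.

    Non-amplifying replicates are passed as None/NaN.  The default rule is
    a majority of triplicates below 40 cycles.
    """
    if len(cq_values) == 0:
        raise InsufficientDataError("need >= 1 replicate for a detection call")
    amplified = [
        c is not None and np.isfinite(c) and c < limit_cycles for c in cq_values
    ]
    return bool(sum(amplified) / len(amplified) > min_fraction)
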