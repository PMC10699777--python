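"""Endmember mixing and Rayleigh N₂O-reduction source attribution.

The dual-isotope ("map") approach: literature endmember rectangles in
(SP, δ¹⁵N_bulk, δ¹⁸O) space are translated onto the absolute scale using
the measured substrate signatures, and an observation is explained as an
endmember point displaced along the Rayleigh trajectory of N₂O → N₂
reduction.  Attribution minimises the Euclidean residual (‰) over
candidate endmember points and the fraction of N₂O remaining, f.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .config import EndmemberBox, RayleighParams, SubstrateSignatures
from .errors import ConfigError, InsufficientDataError

_AXES = ("sp", "d15n", "d18o")


def build_endmembers(
    boxes: dict[str, EndmemberBox],
    substrates: SubstrateSignatures,
) -> dict[str, EndmemberBox]:
    """Translate substrate-relative boxes onto the absolute delta scale.

    Each axis declared with a substrate basis is shifted by that
    substrate's signature (the signature is *added*, so a −9‰ water moves
    a δ¹⁸O range down).  SP is never shifted.  Translation only: box
    widths are conserved exactly.
    """
    shifts_15 = {"no3": substrates.d15n_no3, "no2": substrates.d15n_no2,
                 "nh4": substrates.d15n_nh4}
    corrected = {}
    for name, box in boxes.items():
        d15 = 0.0
        if box.d15n_basis is not None:
            value = shifts_15.get(box.d15n_basis)
            if value is None:
                raise ConfigError(
                    f"endmember {name}: no substrate d15N value for basis {box.d15n_basis!r}"
                )
            d15 = value
        d18 = 0.0
        if box.d18o_basis is not None:
            if substrates.d18o_h2o is None:
                raise ConfigError(f"endmember {name}: no d18O-H2O value for water basis")
            d18 = substrates.d18o_h2o
        corrected[name] = box.translate(0.0, d15, d18)
    return corrected


def rayleigh_shift(
    start: Sequence[float],
    params: RayleighParams,
    f_rem: float,
) -> tuple[float, float, float]:
    """Displace a (SP, δ¹⁵N, δ¹⁸O) point by partial N₂O reduction.

    Closed system: δ = δ₀ + ε ln f (residual-pool Rayleigh distillation).
    Open system (steady-state supply and partial consumption):
    δ = δ₀ − ε (1 − f), bounded as f → 0.  SP is treated as a delta-like
    coordinate with its own net isotope effect ε_SP.
    """
    if not (0.0 < f_rem <= 1.0):
        raise ValueError(f"f_rem must be in (0, 1], got {f_rem}")
    start = np.asarray(start, dtype=float)
    if params.mode == "closed":
        shifted = start + params.epsilons * np.log(f_rem)
    else:
        shifted = start - params.epsilons * (1.0 - f_rem)
    return (float(shifted[0]), float(shifted[1]), float(shifted[2]))


class FRemaining(NamedTuple):
    f_rem: float
    flagged: bool    # True when the raw inversion fell outside (0, 1]


def invert_f_remaining(
    measured: float,
    start: float,
    epsilon: float,
    mode: str = "closed",
    tol: float = 1e-9,
) -> FRemaining:
    """Invert the Rayleigh displacement on one axis for f.

    Closed: f = exp((measured − start)/ε); open: f = 1 + (measured − start)/ε.
    A result outside (0, 1] beyond tolerance is clipped and flagged rather
    than raised — measurement noise routinely lands just past an endpoint.
    """
    if epsilon == 0:
        raise ValueError("epsilon must be nonzero")
    if mode == "closed":
        f = float(np.exp((measured - start) / epsilon))
    elif mode == "open":
        f = 1.0 + (measured - start) / epsilon
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flagged = bool(f > 1.0 + tol or f <= 0.0)
    return FRemaining(f_rem=float(np.clip(f, np.finfo(float).tiny, 1.0)), flagged=flagged)


@dataclass
class PartitionResult:
    """Best-fitting process and reduction extent for one observation."""

    process: str
    f_rem: float
    residual: float                              # ‰, Euclidean over available axes
    start_point: tuple[float, float, float]      # endmember point used
    weights: dict[str, float]
    membership: dict[str, dict[str, bool]]       # per box, per axis
    axis_residuals: dict[str, float]


def _best_f_and_residual(
    diffs: np.ndarray,
    eps: np.ndarray,
    mode: str,
    f_min: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic minimiser of ||d − shift(f)|| over f for many candidates.

    ``diffs`` is (..., n_axes): measured minus candidate start on the
    available axes.  Both system models displace along the fixed direction
    ε, so the optimal scalar is an orthogonal projection, clipped to the
    admissible f interval.
    """
    denom = float(np.sum(eps**2))
    proj = diffs @ eps / denom
    if mode == "closed":
        lnf = np.clip(proj, np.log(f_min), 0.0)
        f = np.exp(lnf)
        resid = np.linalg.norm(diffs - np.multiply.outer(lnf, eps), axis=-1)
    else:
        u = np.clip(-proj, 0.0, 1.0 - f_min)   # u = 1 - f
        f = 1.0 - u
        resid = np.linalg.norm(diffs + np.multiply.outer(u, eps), axis=-1)
    return f, resid


def classify_point(
    reading: Sequence[Optional[float]],
    boxes: dict[str, EndmemberBox],
    params: RayleighParams,
    f_min: float = 0.01,
    n_grid: int = 200,
) -> PartitionResult:
    """Attribute one (SP, δ¹⁵N, δ¹⁸O) observation to a process + reduction.

    Candidate starting points are each box's corners and centroid; for
    each the residual is minimised over f on a log grid of ``n_grid``
    points in [f_min, 1] and then refined analytically (projection onto
    the ε direction), so a point lying exactly on a trajectory has
    residual zero.  Axes given as None/NaN are dropped from the distance.
    Deterministic for a fixed grid.
    """
    if not boxes:
        raise InsufficientDataError("no endmember boxes supplied")
    point = np.array(
        [np.nan if v is None else float(v) for v in reading], dtype=float
    )
    avail = np.isfinite(point)
    if not np.any(avail):
        raise InsufficientDataError("no isotope axes available in the reading")
    eps = params.epsilons[avail]
    f_grid = np.geomspace(f_min, 1.0, n_grid)
    if params.mode == "closed":
        grid_shift = np.multiply.outer(np.log(f_grid), eps)      # (n_grid, n_axes)
    else:
        grid_shift = np.multiply.outer(-(1.0 - f_grid), eps)

    best = None
    membership = {}
    for name, box in boxes.items():
        membership[name] = {
            axis: ok for axis, ok in box.contains(point).items()
            if avail[_AXES.index(axis)]
        }
        cands = box.candidate_points()[:, avail]                  # (9, n_axes)
        diffs = point[avail][None, :] - cands                     # (9, n_axes)
        # coarse grid: residual for every (candidate, f) pair
        resid_grid = np.linalg.norm(
            diffs[:, None, :] - grid_shift[None, :, :], axis=-1
        )
        # analytic refinement per candidate
        f_ref, resid_ref = _best_f_and_residual(diffs, eps, params.mode, f_min)
        i_c, i_f = np.unravel_index(np.argmin(resid_grid), resid_grid.shape)
        grid_best = (float(resid_grid[i_c, i_f]), float(f_grid[i_f]), int(i_c))
        j = int(np.argmin(resid_ref))
        refined_best = (float(resid_ref[j]), float(f_ref[j]), j)
        cand_best = min(grid_best, refined_best)
        if best is None or cand_best[0] < best[0]:
            full_cands = box.candidate_points()
            best = (*cand_best, name, tuple(full_cands[cand_best[2]]))

    residual, f_best, _, proc, start = best
    # per-axis residual components at the optimum
    if params.mode == "closed":
        pred = np.asarray(start) + params.epsilons * np.log(f_best)
    else:
        pred = np.asarray(start) - params.epsilons * (1.0 - f_best)
    axis_resid = {
        axis: (float(point[i] - pred[i]) if avail[i] else float("nan"))
        for i, axis in enumerate(_AXES)
    }
    return PartitionResult(
        process=proc,
        f_rem=f_best,
        residual=residual,
        start_point=(float(start[0]), float(start[1]), float(start[2])),
        weights={proc: 1.0},
        membership=membership,
        axis_residuals=axis_resid,
    )


@dataclass
class PartitionDistribution:
    """Monte-Carlo spread of the attribution under endmember/ε uncertainty."""

    f_quantiles: dict[float, float]
    process_weights: dict[str, float]
    f_samples: np.ndarray
    process_samples: np.ndarray      # process names, same length as f_samples
    n_draws: int


def partition_uncertainty(
    readings: Sequence[Sequence[Optional[float]]],
    boxes: dict[str, EndmemberBox],
    params: RayleighParams,
    n_draws: int = 500,
    seed: int = 0,
    f_min: float = 0.01,
    quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> PartitionDistribution:
    """Propagate endmember-box and ε ranges through the attribution.

    Each draw samples one point uniformly inside every box and an ε vector
    uniformly inside the configured ranges, then attributes every reading
    analytically (projection onto the drawn ε direction).  Returns process
    frequencies and quantiles of f over draws × readings.  Seeded and
    deterministic.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not boxes:
        raise InsufficientDataError("no endmember boxes supplied")
    rng = np.random.default_rng(seed)
    names = list(boxes)
    eps_ranges = params.ranges()
    eps_draws = rng.uniform(eps_ranges[:, 0], eps_ranges[:, 1], size=(n_draws, 3))
    starts = np.empty((n_draws, len(names), 3))
    for j, name in enumerate(names):
        box = boxes[name]
        lo = np.array([box.sp[0], box.d15n[0], box.d18o[0]])
        hi = np.array([box.sp[1], box.d15n[1], box.d18o[1]])
        starts[:, j, :] = rng.uniform(lo, hi, size=(n_draws, 3))

    all_f, all_proc = [], []
    for reading in readings:
        point = np.array([np.nan if v is None else float(v) for v in reading])
        avail = np.isfinite(point)
        if not np.any(avail):
            raise InsufficientDataError("no isotope axes available in a reading")
        diffs = point[avail][None, None, :] - starts[:, :, avail]   # (draws, proc, axes)
        eps = eps_draws[:, avail]                                   # (draws, axes)
        denom = np.sum(eps**2, axis=-1)                             # (draws,)
        proj = np.einsum("dpa,da->dp", diffs, eps) / denom[:, None]
        if params.mode == "closed":
            lnf = np.clip(proj, np.log(f_min), 0.0)
            f = np.exp(lnf)
            resid = np.linalg.norm(diffs - lnf[:, :, None] * eps[:, None, :], axis=-1)
        else:
            u = np.clip(-proj, 0.0, 1.0 - f_min)
            f = 1.0 - u
            resid = np.linalg.norm(diffs + u[:, :, None] * eps[:, None, :], axis=-1)
        j_best = np.argmin(resid, axis=1)                           # (draws,)
        rows = np.arange(n_draws)
        all_f.append(f[rows, j_best])
        all_proc.append(np.array(names, dtype=object)[j_best])

    f_samples = np.concatenate(all_f)
    proc_samples = np.concatenate(all_proc)
    weights = {name: float(np.mean(proc_samples == name)) for name in names}
    f_q = {float(q): float(np.quantile(f_samples, q)) for q in quantiles}
    return PartitionDistribution(
        f_quantiles=f_q,
        process_weights=weights,
        f_samples=f_samples,
        process_samples=proc_samples,
        n_draws=n_draws,
    )
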