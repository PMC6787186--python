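"""Trajectory estimators: conformational observables, worm-like-chain
persistence-length fit, diffusion/mobility/effective-charge transport
analysis, Manning condensation, and surface-domain occupancy.

Conventions: the persistence length lp is extracted from the exponential
decay of tangent correlations, <cos theta>(N) = exp(-N a / lp), by a
least-squares line through ln C(N) vs N a.  The 1D diffusion constant
follows D = <dX^2>/(2 dt) from the slope of the time-averaged MSD, the
mobility mu = v/E from a through-origin fit of drift velocity against
field, and the effective charge from the Einstein relation
q_eff = kBT mu / D.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .model import KB_EV_PER_K, SurfacePattern, surface_indicator
from .simulate import Trajectory

__all__ = [
    "PersistenceFit",
    "TransportFit",
    "end_to_end",
    "tangent_correlation",
    "fit_persistence_length",
    "mean_spacing",
    "com_series",
    "msd",
    "fit_diffusion_1d",
    "drift_velocity",
    "fit_mobility",
    "effective_charge",
    "screening_fraction",
    "manning_condensed_fraction",
    "domain_occupancy",
    "proximity_count",
]


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a meaningful value."""


@dataclass
class PersistenceFit:
    """Worm-like-chain fit result.

    ``correlation_values`` holds <cos theta> for separations 0..max;
    entry 0 is 1 by definition.  ``lp`` comes from the slope of
    ln C(N) over ``fit_range`` (inclusive bounds in separation N).
    """

    lp: float
    mean_spacing_a: float
    correlation_values: np.ndarray
    fit_range: tuple[int, int]
    slope_stderr: float

    def __post_init__(self) -> None:
        if self.lp <= 0:
            raise ValueError("fitted lp must be positive")


@dataclass
class TransportFit:
    """Transport estimates for a driven/diffusing chain.

    q_eff = kBT*mu/D by construction (in e, with mu in nm²/(ns·V) and D
    in nm²/ns).
    """

    D: float                       # nm^2/ns
    v: float                       # nm/ns (at the largest analyzed field)
    mu: float                      # nm^2/(ns V)
    q_eff: float                   # e
    msd_fit_window: tuple[float, float]    # ns
    drift_fit_window: tuple[float, float]  # ns

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")


# ---------------------------------------------------------------------------
# conformation

def _frames(traj) -> np.ndarray:
    """Accept Trajectory, ChainState, or raw arrays; return (F, n, 2)."""
    if isinstance(traj, Trajectory):
        return traj.positions
    if hasattr(traj, "positions"):
        pos = np.asarray(traj.positions, dtype=float)
    else:
        pos = np.asarray(traj, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    return pos


def end_to_end(state) -> float | np.ndarray:
    """Euclidean distance between the first and last bead (nm); for a
    multi-frame input, one value per frame."""
    pos = _frames(state)
    d = np.linalg.norm(pos[:, -1] - pos[:, 0], axis=1)
    return float(d[0]) if d.size == 1 else d


def mean_spacing(traj) -> float:
    """Mean neighbour-bead distance over all frames and bonds (nm)."""
    pos = _frames(traj)
    d = np.linalg.norm(np.diff(pos, axis=1), axis=2)
    return float(d.mean())


def tangent_correlation(traj, max_sep: int, return_stderr: bool = False,
                        n_batches: int = 20):
    """Average tangent correlation C(N) = <t_i . t_{i+N}> for separations
    N = 0..max_sep, averaged over bead index and frames.

    Zero-length bonds are excluded (with a warning giving the count).
    C(0) = 1 identically.  With ``return_stderr`` the per-separation
    standard error is estimated by batch means over ``n_batches``
    contiguous frame blocks (robust to frame-to-frame correlation), and
    the result is ``(C, stderr)``.
    """
    pos = _frames(traj)
    n_beads = pos.shape[1]
    if max_sep > n_beads - 2:
        raise ValueError(f"max_sep must be <= n_beads - 2 = {n_beads - 2}")
    bonds = np.diff(pos, axis=1)
    norm = np.linalg.norm(bonds, axis=2)
    degenerate = norm == 0.0
    if degenerate.any():
        warnings.warn(
            f"excluded {int(degenerate.sum())} zero-length bonds from "
            "tangent correlations", RuntimeWarning,
        )
        norm = np.where(degenerate, np.nan, norm)
    u = bonds / norm[..., None]
    out = np.empty(max_sep + 1)
    out[0] = 1.0
    per_frame = []
    for sep in range(1, max_sep + 1):
        dots = np.sum(u[:, :-sep] * u[:, sep:], axis=2)
        out[sep] = np.nanmean(dots)
        if return_stderr:
            per_frame.append(np.nanmean(dots, axis=1))
    if not return_stderr:
        return out
    stderr = np.zeros(max_sep + 1)
    n_frames = pos.shape[0]
    nb = max(2, min(n_batches, n_frames))
    edges = np.linspace(0, n_frames, nb + 1, dtype=int)
    for sep in range(1, max_sep + 1):
        series = per_frame[sep - 1]
        batch = np.array([np.nanmean(series[a:b])
                          for a, b in zip(edges[:-1], edges[1:])])
        stderr[sep] = float(np.std(batch, ddof=1) / np.sqrt(nb))
    return out, stderr


def fit_persistence_length(
    correlations: np.ndarray,
    mean_spacing_a: float,
    fit_range: tuple[int, int] = (1, 6),
    stderr: Optional[np.ndarray] = None,
) -> PersistenceFit:
    """Persistence length from ln C(N) = -N a / lp over ``fit_range``
    (inclusive separations N).

    The fit is least squares on ln C(N) vs N*a.  When per-point standard
    errors are supplied (see :func:`tangent_correlation`) the fit is
    inverse-variance weighted, which keeps the poorly determined large-N
    tail of a short chain from dominating the slope.  Non-positive
    correlations cannot enter the log and truncate the range with a
    warning; fewer than two usable points is an estimation error.
    """
    corr = np.asarray(correlations, dtype=float)
    lo, hi = fit_range
    if lo < 1:
        raise ValueError("fit_range must start at separation >= 1")
    hi = min(hi, corr.size - 1)
    seps = np.arange(lo, hi + 1)
    c = corr[lo:hi + 1]
    se = None if stderr is None else np.asarray(stderr, dtype=float)[lo:hi + 1]
    pos_mask = c > 0
    if not pos_mask.all():
        first_bad = int(seps[~pos_mask][0])
        warnings.warn(
            f"non-positive correlation at separation {first_bad}; "
            f"fit range truncated", RuntimeWarning,
        )
        keep = seps < first_bad
        seps, c = seps[keep], c[keep]
        if se is not None:
            se = se[keep]
    if seps.size < 2:
        raise EstimationError("fewer than 2 usable correlation points")
    x = seps * mean_spacing_a
    y = np.log(c)
    if se is None:
        res = stats.linregress(x, y)
        slope, slope_se = res.slope, res.stderr
    else:
        # d(ln C) = dC / C; guard against zero estimated errors
        sig = np.maximum(se / c, 1e-12)
        w = 1.0 / sig**2
        (slope, _), cov = np.polyfit(x, y, 1, w=np.sqrt(w), cov="unscaled")
        slope_se = float(np.sqrt(cov[0, 0]))
    if slope >= 0:
        raise EstimationError(
            f"non-decaying correlations (slope {slope:.3g})"
        )
    return PersistenceFit(
        lp=-1.0 / slope,
        mean_spacing_a=mean_spacing_a,
        correlation_values=corr,
        fit_range=(int(seps[0]), int(seps[-1])),
        slope_stderr=float(slope_se),
    )


# ---------------------------------------------------------------------------
# transport

def com_series(traj, axis: int = 0) -> np.ndarray:
    """Per-frame centre-of-mass coordinate along ``axis`` (nm, unwrapped)."""
    pos = _frames(traj)
    return pos[:, :, axis].mean(axis=1)


def msd(series: np.ndarray, max_lag: Optional[int] = None,
        dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged (all-pairs, windowed) mean squared displacement.

    Parameters
    ----------
    series : 1D coordinate series, uniformly sampled at interval ``dt``.
    max_lag : largest lag in frames (default: 25% of the series length).

    Returns ``(lags, msd)`` with lags in the units of ``dt``; msd(0) = 0.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = max(1, n // 4)
    max_lag = min(max_lag, n - 1)
    out = np.empty(max_lag + 1)
    out[0] = 0.0
    for lag in range(1, max_lag + 1):
        d = x[lag:] - x[:-lag]
        out[lag] = np.mean(d * d)
    return np.arange(max_lag + 1) * dt, out


def fit_diffusion_1d(
    lags: np.ndarray,
    msd_curve: np.ndarray,
    fit_window: Optional[tuple[float, float]] = None,
) -> tuple[float, tuple[float, float]]:
    """1D diffusion constant D = <dX^2>/(2 dt): half the least-squares
    slope of MSD vs lag over ``fit_window`` (intercept free).

    The default window covers the first 25 nonzero lag points.  For pure
    centre-of-mass diffusion (memoryless, no localization noise) the
    statistical error of the slope grows with lag, so the smallest lags
    are the best-determined part of the curve.

    Returns ``(D, window_used)``.
    """
    lags = np.asarray(lags, dtype=float)
    msd_curve = np.asarray(msd_curve, dtype=float)
    if fit_window is None:
        hi_idx = min(25, lags.size - 1)
        fit_window = (lags[1], lags[hi_idx])
    lo, hi = fit_window
    mask = (lags >= lo) & (lags <= hi)
    if mask.sum() < 2:
        raise EstimationError("fit window contains fewer than 2 lags")
    res = stats.linregress(lags[mask], msd_curve[mask])
    if res.slope <= 0:
        raise EstimationError(
            f"non-positive MSD slope {res.slope:.3g}; window {fit_window}, "
            f"{int(mask.sum())} points"
        )
    return float(res.slope / 2.0), (float(lo), float(hi))


def drift_velocity(times: np.ndarray, series: np.ndarray) -> float:
    """Least-squares slope of X(t): the drift velocity in nm/ns."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(series, dtype=float)
    if t.size < 2:
        raise EstimationError("need at least 2 points for a drift fit")
    return float(stats.linregress(t, x).slope)


def fit_mobility(velocities: Sequence[tuple[float, float]]) -> float:
    """Electrophoretic mobility mu (nm²/(ns·V)): through-origin
    least-squares slope of drift velocity v against field E, equivalent
    to v Lx / V.  ``velocities`` is a sequence of (E in V/nm, v in nm/ns)
    pairs; at least one must have E != 0."""
    arr = np.asarray(list(velocities), dtype=float)
    E, v = arr[:, 0], arr[:, 1]
    if not np.any(E != 0):
        raise EstimationError("need at least one nonzero-field point")
    return float(np.sum(v * E) / np.sum(E * E))


def effective_charge(mu: float, D: float, temperature: float = 300.0) -> float:
    """Effective charge q_eff = kBT mu / D from the Einstein relation,
    in units of e (kBT/e is the thermal voltage, 0.025852 V at 300 K)."""
    if D <= 0:
        raise ValueError("D must be positive")
    return KB_EV_PER_K * temperature * mu / D


def screening_fraction(q_eff: float, n_backbone_charges: int = 19) -> float:
    """Fraction of the bare backbone charge that is screened,
    1 - q_eff/n.  A 20-mer carries 19 backbone phosphate charges."""
    if n_backbone_charges <= 0:
        raise ValueError("n_backbone_charges must be positive")
    frac = 1.0 - q_eff / n_backbone_charges
    if frac < 0:
        warnings.warn(
            f"q_eff={q_eff} exceeds the bare charge; screening fraction "
            "clamped to 0", RuntimeWarning,
        )
        return 0.0
    return frac


def manning_condensed_fraction(charge_spacing_b: float,
                               bjerrum_length: float = 0.71) -> float:
    """Manning counterion-condensed fraction max(0, 1 - 1/xi) with
    xi = lB/b.  Defaults to the Bjerrum length of water at 300 K
    (0.71 nm); no condensation below the threshold xi <= 1."""
    if charge_spacing_b <= 0 or bjerrum_length <= 0:
        raise ValueError("spacing and Bjerrum length must be positive")
    xi = bjerrum_length / charge_spacing_b
    return max(0.0, 1.0 - 1.0 / xi)


# ---------------------------------------------------------------------------
# occupancy / proximity

def domain_occupancy(traj, pattern: SurfacePattern) -> np.ndarray:
    """Per-frame bead counts (n_in_A, n_in_B): a bead is in B when the
    surface indicator exceeds 1/2.  Counts sum to n_beads."""
    if pattern.geometry == "uniform":
        raise ValueError("domain occupancy is undefined for a uniform surface")
    pos = _frames(traj)
    n_frames, n_beads, _ = pos.shape
    s = surface_indicator(pos.reshape(-1, 2), pattern).reshape(n_frames, n_beads)
    in_b = (s > 0.5).sum(axis=1)
    return np.stack([n_beads - in_b, in_b], axis=1)


def proximity_count(points_a: np.ndarray, points_b: np.ndarray,
                    cutoff: float = 0.35) -> int:
    """Number of points in ``points_a`` lying within ``cutoff`` (nm) of any
    point in ``points_b`` (each a-point counted once)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    tree = cKDTree(b)
    dist, _ = tree.query(a, k=1, distance_upper_bound=cutoff)
    return int(np.sum(dist <= cutoff))
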