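"""From localization tables to binary 48-bit readouts.

A DNA-PAINT recording reduces to a table of localizations: sub-pixel blink
positions with per-localization uncertainty.  This module picks isolated
origami-sized clusters out of that table, fits each cluster with a rigid
6x8 grid of emitters at 10 nm pitch by maximum likelihood, and thresholds
the fitted per-site intensities into a binary matrix for the decoder.

The likelihood of a cluster treats each localization as drawn from a
48-component Gaussian mixture (one component per lattice site, weight
``I_k``, per-axis variance ``dx_i^2 + dx_g^2`` combining the localization's
own uncertainty with a global registration error) plus a uniform background
over the cluster area, times a Poisson term in the total localization count.
Coordinates are nanometres in image orientation (y grows downward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, spatial

from .layout import ROWS, COLS, rotate180

__all__ = [
    "Cluster",
    "GridFitResult",
    "FitError",
    "gaussian_norm",
    "pick_clusters",
    "fit_grid",
    "binarize",
    "calibrate_threshold",
    "template_match",
]

N_SITES = ROWS * COLS

X, Y, UNC = "x [nm]", "y [nm]", "uncertainty [nm]"


class FitError(RuntimeError):
    """Grid fit did not converge; the cluster should be discarded."""


@dataclass
class Cluster:
    """An isolated candidate origami: localization row indices and counts."""

    members: np.ndarray  # integer row indices into the table
    centroid: tuple[float, float]
    inner_count: int
    band_count: int


@dataclass
class GridFitResult:
    """Maximum-likelihood emitter-grid fit of one cluster."""

    intensities: np.ndarray  # I_k, 48 expected localization counts, >= 0
    x_c: float
    y_c: float
    theta: float  # radians
    dx_g: float  # global registration uncertainty, nm
    background: float  # B, expected background localizations in the cluster
    neg_log_likelihood: float
    n_localizations: int
    converged: bool = True


def gaussian_norm(dx_i: float, dx_g: float) -> float:
    """Normalisation constant ``2 pi (dx_i^2 + dx_g^2)`` of one mixture
    component (a 2-D Gaussian whose per-axis variance is the summed squared
    uncertainty)."""
    return 2.0 * np.pi * (dx_i**2 + dx_g**2)


# ---------------------------------------------------------------------------
# cluster picking
# ---------------------------------------------------------------------------

def pick_clusters(
    table: pd.DataFrame,
    radius: float = 60.0,
    min_count: int = 50,
    band_frac: float = 0.15,
    rng: np.random.Generator | None = None,
    n_seeds: int | None = None,
) -> list[Cluster]:
    """Pick bright, isolated clusters by the radius/annulus rule.

    Random localizations seed candidate clusters; each seed is re-centred
    on the mean of its neighbours within ``radius``, then accepted if the
    inner disc holds more than ``min_count`` localizations while the
    annulus ``radius < r < 2*radius`` holds fewer than ``band_frac`` times
    the inner count.  Accepted clusters closer than ``radius`` to an
    earlier one are duplicates and dropped.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(table) == 0:
        return []
    rng = rng or np.random.default_rng()
    xy = table[[X, Y]].to_numpy(dtype=float)
    tree = spatial.cKDTree(xy)
    n_seeds = n_seeds if n_seeds is not None else max(200, 4 * len(table) // min_count)

    clusters: list[Cluster] = []
    centroids: list[np.ndarray] = []
    seeds = rng.integers(0, len(xy), size=n_seeds)
    for s in seeds:
        centre = xy[s]
        for _ in range(3):  # recentre on the local mean
            idx = tree.query_ball_point(centre, radius)
            if not idx:
                break
            centre = xy[idx].mean(axis=0)
        inner = tree.query_ball_point(centre, radius)
        outer = tree.query_ball_point(centre, 2 * radius)
        inner_count = len(inner)
        band_count = len(outer) - inner_count
        if inner_count <= min_count or band_count >= band_frac * inner_count:
            continue
        if any(np.hypot(*(centre - c)) < radius for c in centroids):
            continue
        centroids.append(centre)
        clusters.append(
            Cluster(
                members=np.asarray(sorted(inner), dtype=np.int64),
                centroid=(float(centre[0]), float(centre[1])),
                inner_count=inner_count,
                band_count=band_count,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# grid fitting
# ---------------------------------------------------------------------------

def _grid_sites(pitch: float) -> np.ndarray:
    r, c = np.mgrid[0:ROWS, 0:COLS]
    x = (c - (COLS - 1) / 2.0) * pitch
    y = (r - (ROWS - 1) / 2.0) * pitch
    return np.column_stack([x.ravel(), y.ravel()])


def _theta_scan(xy: np.ndarray, pitch: float, n_angles: int = 90) -> list[float]:
    """Candidate grid angles from the lattice structure factor.

    Rotating the localizations into a candidate grid frame and summing
    ``exp(2 pi i x / pitch)`` over points gives a translation-invariant
    score that peaks when both axes align with the 10 nm lattice; the
    score is periodic in a quarter turn.  Returns the best angle and, as a
    safeguard against spurious peaks, the best angle at least 10 degrees
    away from it.
    """
    angles = np.linspace(0.0, np.pi / 2, n_angles, endpoint=False)
    cos, sin = np.cos(angles), np.sin(angles)
    # coordinates in the grid frame: R(-theta) @ xy
    gx = xy[:, 0][:, None] * cos[None, :] + xy[:, 1][:, None] * sin[None, :]
    gy = -xy[:, 0][:, None] * sin[None, :] + xy[:, 1][:, None] * cos[None, :]
    w = 2.0 * np.pi / pitch
    score = np.abs(np.exp(1j * w * gx).sum(axis=0)) + np.abs(
        np.exp(1j * w * gy).sum(axis=0)
    )
    best = int(np.argmax(score))
    sep = max(1, int(np.round(np.radians(10) / (np.pi / 2 / n_angles))))
    d = np.minimum(np.abs(np.arange(n_angles) - best),
                   n_angles - np.abs(np.arange(n_angles) - best))
    masked = np.where(d >= sep, score, -np.inf)
    second = int(np.argmax(masked))
    return [float(angles[best]), float(angles[second])]


def _candidate_centres(
    xy: np.ndarray, pitch: float, theta: float
) -> list[tuple[float, float]]:
    """Grid-centre starts consistent with the lattice phase.

    The argument of the structure factor locates the lattice lines modulo
    the pitch; the 6x8 grid centre sits half a pitch off a site along both
    axes.  Because a lopsided bit pattern biases the localization
    centroid, the two nearest phase-consistent points per axis are all
    returned as candidates.
    """
    cos, sin = np.cos(theta), np.sin(theta)
    gx = xy[:, 0] * cos + xy[:, 1] * sin
    gy = -xy[:, 0] * sin + xy[:, 1] * cos
    w = 2.0 * np.pi / pitch
    axis_opts = []
    for g in (gx, gy):
        phase = float(np.angle(np.exp(1j * w * g).sum())) * pitch / (2 * np.pi)
        target = phase + pitch / 2.0
        lo = target + pitch * np.floor((g.mean() - target) / pitch)
        axis_opts.append((lo, lo + pitch))
    out = []
    for cgx in axis_opts[0]:
        for cgy in axis_opts[1]:
            out.append(
                (float(cgx * cos - cgy * sin), float(cgx * sin + cgy * cos))
            )
    return out


def _pose_nll(pose, xy, unc2, area, sites, n) -> float:
    """Likelihood of a candidate pose with histogram-seeded intensities,
    used only to rank initialisation candidates."""
    x0, y0, theta = pose
    cos, sin = np.cos(theta), np.sin(theta)
    rot = np.array([[cos, -sin], [sin, cos]])
    posed = sites @ rot.T + (x0, y0)
    d2 = ((xy[:, None, :] - posed[None, :, :]) ** 2).sum(axis=2)
    I0 = np.bincount(np.argmin(d2, axis=1), minlength=N_SITES).astype(float) + 0.1
    p = np.concatenate([I0, [x0, y0, theta, 4.0, 1.0 + 0.02 * n]])
    return float(_nll(p, xy, unc2, area, sites)[0])


def _nll(params, xy, unc2, area, sites):
    """Negative log likelihood and its gradient.

    With the Poisson term in the total expected count ``T = sum(I) + B``,
    the ``log T`` factors of the per-localization mixture cancel against
    the Poisson mean, leaving ``T - sum_i log(sum_k I_k g_ik + B/A)`` up
    to a parameter-free constant.
    """
    I = params[:N_SITES]
    x_c, y_c, theta, dxg2, B = params[N_SITES:]
    cos, sin = np.cos(theta), np.sin(theta)
    rot = np.array([[cos, -sin], [sin, cos]])
    posed = sites @ rot.T + (x_c, y_c)
    diff = xy[:, None, :] - posed[None, :, :]  # (n, 48, 2)
    d2 = (diff**2).sum(axis=2)
    s2 = (unc2 + dxg2)[:, None]  # per-axis variance of each localization
    g = np.exp(-d2 / (2.0 * s2)) / (2.0 * np.pi * s2)
    num = g @ I + B / area
    num = np.maximum(num, 1e-300)
    f = (I.sum() + B) - np.log(num).sum()

    grad = np.empty_like(params)
    inv_num = 1.0 / num
    grad[:N_SITES] = 1.0 - g.T @ inv_num
    q = (g * I[None, :]) * inv_num[:, None]  # (n, 48)
    qs = q / s2
    grad[N_SITES + 0] = -np.einsum("ik,ik->", qs, diff[:, :, 0])
    grad[N_SITES + 1] = -np.einsum("ik,ik->", qs, diff[:, :, 1])
    dp_dtheta = sites @ np.array([[-sin, cos], [-cos, -sin]])  # R'(theta) s
    proj = diff[:, :, 0] * dp_dtheta[None, :, 0] + diff[:, :, 1] * dp_dtheta[None, :, 1]
    grad[N_SITES + 2] = -np.einsum("ik,ik->", qs, proj)
    grad[N_SITES + 3] = -(q * (d2 / (2.0 * s2**2) - 1.0 / s2)).sum()
    grad[N_SITES + 4] = 1.0 - (inv_num.sum() / area)
    return f, grad


def fit_grid(
    cluster: Cluster,
    table: pd.DataFrame,
    pitch: float = 10.0,
    init: tuple[float, float, float] | None = None,
    theta_starts: Sequence[float] | str = "auto",
    gtol: float = 1e-6,
    max_iter: int = 300,
) -> GridFitResult:
    """Maximum-likelihood fit of the rigid 6x8 emitter grid to a cluster.

    ``theta_starts`` may be a sequence of initial angles (radians) or
    ``"auto"``: the principal axis of the cluster fixes the grid's long
    direction up to a quarter turn, so two starts suffice; the remaining
    180-degree ambiguity is deferred to the orientation marker bits.
    """
    idx = cluster.members
    if len(idx) < 3:
        raise FitError("cluster too small to fit")
    xy = table.iloc[idx][[X, Y]].to_numpy(dtype=float)
    unc2 = table.iloc[idx][UNC].to_numpy(dtype=float) ** 2
    sites = _grid_sites(pitch)
    area = np.pi * (4 * pitch) ** 2  # disc comfortably covering the grid
    # recentre for conditioning: position parameters stay O(10 nm)
    shift = xy.mean(axis=0)
    xy = xy - shift

    n = len(xy)
    if init is not None:
        poses = [(init[0] - shift[0], init[1] - shift[1], init[2])]
    else:
        if theta_starts == "auto":
            thetas = []
            for peak in _theta_scan(xy, pitch):
                # quarter-turn ambiguity: the fit picks 6x8 over 8x6
                thetas.extend((peak, peak + np.pi / 2))
        else:
            thetas = list(theta_starts)
        candidates = [
            (cx, cy, th)
            for th in thetas
            for cx, cy in _candidate_centres(xy, pitch, th)
        ]
        # cheap screen: fixed-pose likelihood with histogram intensities
        scored = sorted(
            (_pose_nll(pose, xy, unc2, area, sites, n), pose)
            for pose in candidates
        )
        poses = [pose for _, pose in scored[:2]]

    best = None
    for x0, y0, theta_i in poses:
        cos, sin = np.cos(theta_i), np.sin(theta_i)
        rot = np.array([[cos, -sin], [sin, cos]])
        posed = sites @ rot.T + (x0, y0)
        # nearest-site histogram seeds the intensities
        d2 = ((xy[:, None, :] - posed[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        I0 = np.bincount(nearest, minlength=N_SITES).astype(float) + 0.1
        p0 = np.concatenate([I0, [x0, y0, theta_i, 4.0, 1.0 + 0.02 * n]])
        bounds = (
            [(0.0, None)] * N_SITES
            + [(x0 - 60, x0 + 60), (y0 - 60, y0 + 60),
               (theta_i - np.pi, theta_i + np.pi), (0.0, 400.0), (0.0, None)]
        )
        res = optimize.minimize(
            _nll, p0, args=(xy, unc2, area, sites), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("grid fit did not converge")
    I = best.x[:N_SITES]
    x_c, y_c, theta, dxg2, B = best.x[N_SITES:]
    return GridFitResult(
        intensities=I,
        x_c=float(x_c + shift[0]),
        y_c=float(y_c + shift[1]),
        theta=float(theta % (2 * np.pi)),
        dx_g=float(np.sqrt(max(dxg2, 0.0))),
        background=float(B),
        neg_log_likelihood=float(best.fun),
        n_localizations=n,
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# binarization and evaluation
# ---------------------------------------------------------------------------

def binarize(fit: GridFitResult, threshold: float) -> np.ndarray:
    """Threshold fitted site intensities into a 6x8 bit matrix (site k maps
    to cell (k // 8, k % 8) of the fitted grid frame)."""
    return (fit.intensities >= threshold).astype(np.uint8).reshape(ROWS, COLS)


def calibrate_threshold(fits: Sequence[GridFitResult]) -> float:
    """Empirical on/off intensity threshold: the valley of the pooled,
    bimodal per-site intensity distribution (two-class Otsu).

    Falls back to half the median (with a warning) when the pooled
    distribution shows no usable second mode.
    """
    if len(fits) < 50:
        raise ValueError("need at least 50 fits to calibrate a threshold")
    pooled = np.concatenate([f.intensities for f in fits])
    thr, separability = _otsu(pooled)
    lo, hi = pooled[pooled < thr], pooled[pooled >= thr]
    # a single Gaussian caps the explained-variance ratio near 2/pi ~ 0.64;
    # well-separated on/off modes push it towards 1
    degenerate = (
        len(lo) < 0.05 * len(pooled)
        or len(hi) < 0.05 * len(pooled)
        or separability < 0.75
    )
    if degenerate:
        warnings.warn(
            "pooled intensity distribution looks unimodal; "
            "falling back to median/2",
            RuntimeWarning,
        )
        return float(np.median(pooled) / 2.0)
    return float(thr)


def _otsu(values: np.ndarray, bins: int = 256) -> tuple[float, float]:
    """Two-class Otsu threshold and the explained-variance ratio at it.

    The between-class variance is flat across an empty valley, so the
    midpoint of the maximal plateau is returned rather than its edge.
    """
    hist, edges = np.histogram(values, bins=bins)
    centres = (edges[:-1] + edges[1:]) / 2
    p = hist.astype(float) / hist.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centres)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    between[~np.isfinite(between)] = -1.0
    top = between.max()
    plateau = np.nonzero(between >= top - 1e-9 * max(top, 1.0))[0]
    cut = int(np.median(plateau))
    total_var = float(((centres - mu_t) ** 2 * p).sum())
    ratio = float(top / total_var) if total_var > 0 else 0.0
    return float(centres[cut]), ratio


def template_match(
    readout: np.ndarray, designs: Sequence[np.ndarray]
) -> tuple[int, int, int]:
    """Best-matching design for a readout, scored over both orientations.

    Returns ``(design_id, false_negatives, false_positives)`` for the
    orientation and design with the fewest total errors (ties broken by
    the lower design id).  Evaluation-only: it requires knowing the
    designs, so it is never part of the data-reading path.
    """
    if len(designs) == 0:
        raise ValueError("designs must be non-empty")
    m = np.asarray(readout, dtype=np.uint8)
    best: tuple[int, int, int] | None = None
    best_err = None
    for did, design in enumerate(designs):
        d = np.asarray(design, dtype=np.uint8)
        for cand in (m, rotate180(m)):
            fn = int(((d == 1) & (cand == 0)).sum())
            fp = int(((d == 0) & (cand == 1)).sum())
            if best_err is None or fn + fp < best_err:
                best_err = fn + fp
                best = (did, fn, fp)
    return best
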