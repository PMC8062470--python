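import numpy as np
import pandas as pd
import pytest

from dnam.layout import rotate180
from dnam.localization import (
    Cluster,
    FitError,
    binarize,
    calibrate_threshold,
    fit_grid,
    gaussian_norm,
    pick_clusters,
    template_match,
    GridFitResult,
)
from dnam.simulator import BlinkConfig, synth_localizations, encode_store


def _table(xy, unc):
    return pd.DataFrame(
        {
            "frame": np.arange(1, len(xy) + 1),
            "x [nm]": xy[:, 0],
            "y [nm]": xy[:, 1],
            "uncertainty [nm]": unc,
        }
    )


def test_gaussian_norm_direct_substitution():
    assert gaussian_norm(3.0, 4.0) == pytest.approx(50 * np.pi)


def test_pick_clusters_empty_table():
    assert pick_clusters(_table(np.empty((0, 2)), np.empty(0))) == []


def test_pick_clusters_two_dense_clusters(rng):
    """Two tight synthetic clusters 500 nm apart in sparse background are
    found, and nothing else."""
    a = rng.normal(0, 10, (200, 2)) + (1000, 1000)
    b = rng.normal(0, 10, (200, 2)) + (1500, 1000)
    bg = rng.uniform(0, 3000, (60, 2))
    xy = np.vstack([a, b, bg])
    tbl = _table(xy, np.full(len(xy), 4.0))
    clusters = pick_clusters(tbl, radius=60, min_count=50, rng=rng)
    assert len(clusters) == 2
    centres = sorted(c.centroid for c in clusters)
    assert np.hypot(centres[0][0] - 1000, centres[0][1] - 1000) < 15
    assert np.hypot(centres[1][0] - 1500, centres[1][1] - 1000) < 15


def test_pick_clusters_band_rule_rejects_crowding(rng):
    """A cluster whose annulus holds >= 15% of the inner count is rejected."""
    inner = rng.normal(0, 10, (200, 2)) + (500, 500)
    ring_angle = rng.uniform(0, 2 * np.pi, 60)
    ring = np.column_stack(
        [500 + 90 * np.cos(ring_angle), 500 + 90 * np.sin(ring_angle)]
    )
    xy = np.vstack([inner, ring])
    tbl = _table(xy, np.full(len(xy), 4.0))
    assert pick_clusters(tbl, radius=60, min_count=50, rng=rng) == []


def _clean_cluster(design, pose, rng, locs_per_site=30, sigma=5.0):
    from dnam.simulator import _grid_sites

    sites = _grid_sites(10.0)
    x0, y0, theta = pose
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    posed = sites @ rot.T + (x0, y0)
    pts, unc = [], []
    for k in np.nonzero(np.asarray(design).ravel())[0]:
        n = rng.poisson(locs_per_site)
        u = np.full(n, sigma)
        pts.append(posed[k] + rng.normal(scale=sigma, size=(n, 2)))
        unc.append(u)
    xy = np.vstack(pts)
    tbl = _table(xy, np.concatenate(unc))
    cl = Cluster(
        members=np.arange(len(xy)),
        centroid=(float(xy[:, 0].mean()), float(xy[:, 1].mean())),
        inner_count=len(xy),
        band_count=0,
    )
    return tbl, cl


def test_fit_grid_recovers_known_pose(reference_store, rng):
    """Noiseless-background cluster at a known pose: centre within 2 nm,
    angle within 2 degrees (up to the grid's half-turn symmetry)."""
    design = reference_store["matrices"][7]
    pose = (250.0, -130.0, 0.6)
    tbl, cl = _clean_cluster(design, pose, rng)
    fit = fit_grid(cl, tbl)
    assert np.hypot(fit.x_c - pose[0], fit.y_c - pose[1]) <= 2.0
    dth = (fit.theta - pose[2]) % np.pi
    assert min(dth, np.pi - dth) <= np.radians(2.0)


def test_fit_grid_rejects_tiny_cluster():
    tbl = _table(np.zeros((2, 2)), np.full(2, 4.0))
    cl = Cluster(members=np.arange(2), centroid=(0, 0), inner_count=2, band_count=0)
    with pytest.raises(FitError):
        fit_grid(cl, tbl)


def test_binarize_semantics_and_monotone(rng):
    I = rng.uniform(0, 40, 48)
    fit = GridFitResult(
        intensities=I, x_c=0, y_c=0, theta=0, dx_g=0, background=0,
        neg_log_likelihood=0.0, n_localizations=100,
    )
    zeros = GridFitResult(
        intensities=np.zeros(48), x_c=0, y_c=0, theta=0, dx_g=0, background=0,
        neg_log_likelihood=0.0, n_localizations=0,
    )
    assert binarize(zeros, 1.0).sum() == 0
    lo, hi = binarize(fit, 10.0), binarize(fit, 25.0)
    assert np.all(hi <= lo)  # raising the threshold never creates a 1


def _fits_from_intensities(rows):
    return [
        GridFitResult(
            intensities=np.asarray(r, dtype=float), x_c=0, y_c=0, theta=0,
            dx_g=0, background=0, neg_log_likelihood=0.0, n_localizations=1,
        )
        for r in rows
    ]


def test_calibrate_threshold_separates_two_modes(rng):
    rows = [
        np.concatenate([rng.normal(2, 0.5, 24), rng.normal(30, 3, 24)])
        for _ in range(60)
    ]
    thr = calibrate_threshold(_fits_from_intensities(rows))
    assert 5 < thr < 25


def test_calibrate_threshold_order_invariant(rng):
    rows = [
        np.concatenate([rng.normal(2, 0.5, 24), rng.normal(30, 3, 24)])
        for _ in range(60)
    ]
    t1 = calibrate_threshold(_fits_from_intensities(rows))
    t2 = calibrate_threshold(_fits_from_intensities(list(reversed(rows))))
    assert t1 == pytest.approx(t2)


def test_calibrate_threshold_unimodal_fallback(rng):
    rows = [rng.normal(10, 1, 48) for _ in range(60)]
    with pytest.warns(RuntimeWarning):
        thr = calibrate_threshold(_fits_from_intensities(rows))
    assert thr == pytest.approx(np.median(np.concatenate(rows)) / 2, rel=0.05)


def test_template_match_identity_and_erasures(reference_store):
    designs = reference_store["matrices"]
    did, fn, fp = template_match(designs[3], designs)
    assert (did, fn, fp) == (3, 0, 0)
    erased = designs[3].copy()
    ones = np.argwhere(erased == 1)[:2]
    for r, c in ones:
        erased[r, c] = 0
    did, fn, fp = template_match(erased, designs)
    assert (did, fn, fp) == (3, 2, 0)


def test_template_match_agrees_with_exhaustive_oracle(reference_store, rng):
    designs = reference_store["matrices"]
    for _ in range(300):
        i = int(rng.integers(0, 15))
        noisy = designs[i].copy()
        for cid in rng.choice(48, 5, replace=False):
            noisy[divmod(int(cid), 8)] ^= 1
        if rng.random() < 0.5:
            noisy = rotate180(noisy)
        got = template_match(noisy, designs)
        # oracle: exhaustive scan over designs and orientations
        best = None
        for did, d in enumerate(designs):
            for cand in (noisy, rotate180(noisy)):
                fn = int(((d == 1) & (cand == 0)).sum())
                fp = int(((d == 0) & (cand == 1)).sum())
                if best is None or fn + fp < best[1] + best[2]:
                    best = (did, fn, fp)
        assert got[1] + got[2] == best[1] + best[2]
        assert got == best
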