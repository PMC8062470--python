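"""Synthetic data generation and in-silico recovery experiments.

This module drives the full encode -> corrupt -> decode -> reassemble
pipeline on simulated data: random messages are fountain-encoded into
origami matrices, noisy copies are produced by flipping bits (emulating
missed and spurious docking sites), every copy is error-corrected, and
the fountain decoder attempts to rebuild the message from the recovered
droplets.  It also synthesises DNA-PAINT localization tables for the
imaging pipeline, and computes the areal-density figures.

Error injection uses an independent per-site corruption process: each
copy's flip count is binomial over the 48 sites with the per-site rate
set by the target mean errors per origami.  Results are reported against
the realized mean, which is how recovery curves are binned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import codec, fountain
from .layout import LayoutSpec, ROWS, COLS, build_simulation_layout

__all__ = [
    "SimConfig",
    "SimResult",
    "BlinkConfig",
    "GroundTruth",
    "random_message",
    "inject_errors",
    "plan_store",
    "encode_store",
    "simulate_recovery",
    "tune_mean_for_copy_success",
    "subsample_decode",
    "origami_count_curve",
    "synth_localizations",
    "areal_density",
]

N_SITES = ROWS * COLS


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Conditions of the in-silico recovery experiment."""

    message_sizes: tuple[int, ...] = tuple(range(160, 12801, 320))
    copies_per_origami: int = 10
    error_means: tuple[float, ...] = tuple(float(f) for f in range(10))
    repetitions: int = 40
    redundancy: float = 1.5
    max_flips: int = codec.DEFAULT_MAX_FLIPS
    max_expansions: int = codec.DEFAULT_MAX_EXPANSIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if min(self.message_sizes) < 1 or self.copies_per_origami < 1:
            raise ValueError("message sizes and copy count must be positive")


@dataclass
class SimResult:
    """Recovery rates per (message size, error level), plus aggregates."""

    table: pd.DataFrame  # columns: message_size, target_mean, realized_mean,
    #                      origami_recovery_rate, message_recovery_rate, reps

    def by_error_level(self) -> pd.DataFrame:
        """Average over message sizes, as recovery-rate curves are reported."""
        g = self.table.groupby("target_mean", as_index=False).agg(
            realized_mean=("realized_mean", "mean"),
            origami_recovery_rate=("origami_recovery_rate", "mean"),
            message_recovery_rate=("message_recovery_rate", "mean"),
        )
        return g

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class BlinkConfig:
    """Conditions of the synthetic DNA-PAINT recording.

    Defaults emulate a 40,000-frame recording with ~3 nM imager: a few
    dozen binding events per docking site, nanometre-scale localization
    precision, sparse uniform background, and imperfect origami (missing
    and spurious sites).
    """

    mean_blinks_per_site: float = 35.0
    sigma_nm: float = 4.0
    background_per_um2: float = 50.0
    site_miss_prob: float = 0.10
    spurious_site_prob: float = 0.02
    field_um: float = 5.0
    origami_density_per_um2: float = 0.4
    min_separation_nm: float = 250.0
    frames: int = 40_000
    pitch_nm: float = 10.0

    def __post_init__(self) -> None:
        for p in (self.site_miss_prob, self.spurious_site_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.background_per_um2 < 0 or self.origami_density_per_um2 < 0:
            raise ValueError("densities must be >= 0")


@dataclass
class GroundTruth:
    """Sidecar emitted with every synthetic recording, for oracle checks."""

    origami: pd.DataFrame  # origami_id, design_id, x_nm, y_nm, theta_rad
    site_bits: np.ndarray  # (n_origami, 48) effective bits after miss/spurious
    loc_origami: np.ndarray  # per localization: origami_id, -1 for background
    loc_site: np.ndarray  # per localization: site index, -1 for background


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def random_message(n_bits: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform i.i.d. message bits."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    return rng.integers(0, 2, size=n_bits, dtype=np.uint8)


def inject_errors(
    matrix: np.ndarray, n_flips: int, rng: np.random.Generator
) -> np.ndarray:
    """Invert exactly ``n_flips`` distinct cells of a 6x8 matrix."""
    if not 0 <= n_flips <= N_SITES:
        raise ValueError(f"n_flips must be in [0, {N_SITES}]")
    out = np.asarray(matrix, dtype=np.uint8).copy()
    cells = rng.choice(N_SITES, size=n_flips, replace=False)
    out[np.unravel_index(cells, out.shape)] ^= 1
    return out


def _flip_counts(
    target_mean: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-copy flip counts for an i.i.d. per-site corruption process with
    the given mean errors per origami."""
    p = min(max(target_mean / N_SITES, 0.0), 1.0)
    return rng.binomial(N_SITES, p, size=n)


# ---------------------------------------------------------------------------
# store planning and encoding
# ---------------------------------------------------------------------------

def plan_store(
    message_bits: int, redundancy: float = 1.5
) -> tuple[LayoutSpec, int, int, int]:
    """Choose the layout for a message: minimal index width such that the
    droplet count (``redundancy * k`` origami) stays addressable.

    Returns ``(layout, k, b, n_droplets)`` where ``b`` is the per-origami
    data width and ``k`` the segment count.
    """
    if message_bits < 1:
        raise ValueError("message_bits must be >= 1")
    payload_bits = 20  # data + index budget of the 48-site layout
    for index_width in range(payload_bits):
        b = payload_bits - index_width
        k = math.ceil(message_bits / b)
        n = math.ceil(redundancy * k)
        if n <= (1 << index_width):
            layout = build_simulation_layout(message_bits, n)
            assert layout.index_width == index_width
            return layout, k, b, n
    raise fountain.EncodingError(
        f"message of {message_bits} bits exceeds the index capacity"
    )


def encode_store(
    message: bytes | np.ndarray,
    seed: int,
    redundancy: float = 1.5,
) -> tuple[LayoutSpec, list[fountain.Droplet], list[np.ndarray], int]:
    """Fountain-encode a message into origami matrices.

    ``message`` may be bytes or a bit array whose length is a multiple of 8.
    Returns ``(layout, droplets, matrices, droplet_seed)``.
    """
    bits = (
        np.unpackbits(np.frombuffer(message, dtype=np.uint8))
        if isinstance(message, (bytes, bytearray))
        else np.asarray(message, dtype=np.uint8)
    )
    layout, k, b, n = plan_store(bits.size)
    msg_bytes = np.packbits(bits).tobytes()
    segments = fountain.segment_message(msg_bytes, b)
    # padding may add a segment beyond the planned k when b does not divide
    # the message; re-plan in that case to keep the index wide enough
    if len(segments) != k:
        k = len(segments)
    droplets, droplet_seed = fountain.make_droplets(segments, n, seed)
    matrices = [codec.encode_matrix(d, layout) for d in droplets]
    return layout, droplets, matrices, droplet_seed


# ---------------------------------------------------------------------------
# recovery simulation
# ---------------------------------------------------------------------------

def _decode_copies(
    matrix: np.ndarray,
    truth: fountain.Droplet,
    layout: LayoutSpec,
    flips: np.ndarray,
    rng: np.random.Generator,
    max_flips: int,
    max_expansions: int,
) -> bool:
    """True iff any noisy copy decodes to the true (index, payload).

    Copies are decoded until the first success; later copies cannot change
    the outcome of any reported quantity.
    """
    for f in flips:
        noisy = inject_errors(matrix, int(f), rng)
        res = codec.decode_matrix(noisy, layout, max_flips, max_expansions)
        if res.ok and res.index == truth.index and res.payload == truth.payload:
            return True
    return False


def simulate_recovery(cfg: SimConfig) -> SimResult:
    """Recovery rates of origami and full messages under injected errors."""
    rows = []
    root = np.random.SeedSequence(cfg.seed)
    for size_i, m_bits in enumerate(cfg.message_sizes):
        for mean_i, target_mean in enumerate(cfg.error_means):
            org_rates = []
            msg_ok = 0
            realized = []
            for rep in range(cfg.repetitions):
                ss = np.random.SeedSequence(
                    [cfg.seed, size_i, mean_i, rep]
                )
                rng = np.random.default_rng(ss)
                enc_seed = int(ss.generate_state(1)[0] >> 1)
                msg_bits = random_message(m_bits, rng)
                pad = (-msg_bits.size) % 8
                padded = np.concatenate([msg_bits, np.zeros(pad, np.uint8)])
                layout, droplets, matrices, _ = encode_store(padded, enc_seed)
                n_segments = len(
                    fountain.segment_message(
                        np.packbits(padded).tobytes(), layout.data_width
                    )
                )
                n_rec = 0
                recovered: list[fountain.Droplet] = []
                total_flips = 0
                for drop, mat in zip(droplets, matrices):
                    flips = _flip_counts(
                        target_mean, cfg.copies_per_origami, rng
                    )
                    total_flips += int(flips.sum())
                    if _decode_copies(
                        mat, drop, layout, flips, rng,
                        cfg.max_flips, cfg.max_expansions,
                    ):
                        n_rec += 1
                        recovered.append(drop)
                org_rates.append(n_rec / len(droplets))
                realized.append(
                    total_flips / (len(droplets) * cfg.copies_per_origami)
                )
                segs = fountain.peel_decode(recovered, n_segments)
                if segs is not None:
                    out = fountain.assemble_message(segs, padded.size)
                    if out == np.packbits(padded).tobytes():
                        msg_ok += 1
            rows.append(
                dict(
                    message_size=m_bits,
                    target_mean=target_mean,
                    realized_mean=float(np.mean(realized)),
                    origami_recovery_rate=float(np.mean(org_rates)),
                    message_recovery_rate=msg_ok / cfg.repetitions,
                    reps=cfg.repetitions,
                )
            )
    return SimResult(table=pd.DataFrame(rows))


def tune_mean_for_copy_success(
    target: float = 0.63,
    *,
    seed: int = 0,
    trials_per_level: int = 300,
    grid: Sequence[float] | None = None,
    max_flips: int = codec.DEFAULT_MAX_FLIPS,
    max_expansions: int = codec.DEFAULT_MAX_EXPANSIONS,
) -> float:
    """Mean errors per origami at which a single noisy copy decodes to its
    true droplet with the target probability.

    Measures per-copy success on the 160-bit reference store over a grid of
    error means and interpolates the monotone success curve at ``target``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0DE]))
    layout, droplets, matrices, _ = encode_store(
        random_message(160, rng).astype(np.uint8), seed
    )
    grid = tuple(grid) if grid is not None else tuple(np.arange(0.0, 9.1, 0.75))
    means, rates = [], []
    for mu in grid:
        ok = 0
        for _ in range(trials_per_level):
            i = int(rng.integers(0, len(matrices)))
            f = int(_flip_counts(mu, 1, rng)[0])
            noisy = inject_errors(matrices[i], f, rng)
            res = codec.decode_matrix(noisy, layout, max_flips, max_expansions)
            if (
                res.ok
                and res.index == droplets[i].index
                and res.payload == droplets[i].payload
            ):
                ok += 1
        means.append(mu)
        rates.append(ok / trials_per_level)
    # enforce monotone decrease, then invert by linear interpolation
    r = np.minimum.accumulate(np.asarray(rates))
    m = np.asarray(means)
    if target >= r[0]:
        return float(m[0])
    if target <= r[-1]:
        return float(m[-1])
    j = int(np.searchsorted(-r, -target))
    f = (r[j - 1] - target) / max(r[j - 1] - r[j], 1e-12)
    return float(m[j - 1] + f * (m[j] - m[j - 1]))


# ---------------------------------------------------------------------------
# droplet subsampling (reader-depth analysis)
# ---------------------------------------------------------------------------

def subsample_decode(
    readouts: Sequence[np.ndarray],
    truths: tuple[LayoutSpec, Sequence[fountain.Droplet]],
    sample_sizes: Sequence[int],
    max_flips_options: Sequence[int] = (9,),
    rng: np.random.Generator | None = None,
    n_resamples: int = 30,
    max_expansions: int = codec.DEFAULT_MAX_EXPANSIONS,
) -> pd.DataFrame:
    """How many unique droplets (and whole messages) random subsamples of
    decoded readouts recover.

    ``truths`` carries the layout and the encoded droplet set, used only to
    run the fountain stage (segment count and membership seed); the decode
    of each readout is blind.  Sample sizes beyond the pool are capped.
    """
    rng = rng or np.random.default_rng()
    layout, droplets = truths
    k = _segment_count(droplets)
    true_segments = fountain.peel_decode(list(droplets), k)
    rows = []
    for max_flips in max_flips_options:
        decoded: list[tuple[int, tuple[int, ...]] | None] = []
        for m in readouts:
            res = codec.decode_matrix(m, layout, max_flips, max_expansions)
            decoded.append((res.index, res.payload) if res.ok else None)
        for size in sample_sizes:
            eff = min(size, len(readouts))
            uniq_counts, msg_ok = [], 0
            for _ in range(n_resamples):
                idx = rng.choice(len(readouts), size=eff, replace=False)
                per_index: dict[int, dict[tuple, int]] = {}
                for i in idx:
                    if decoded[i] is None:
                        continue
                    di, payload = decoded[i]
                    per_index.setdefault(di, {})
                    per_index[di][payload] = per_index[di].get(payload, 0) + 1
                # majority payload per index; ties by payload order
                recovered = [
                    fountain.Droplet(
                        index=di,
                        segment_ids=frozenset(),
                        payload=max(sorted(c), key=lambda p: c[p]),
                    )
                    for di, c in per_index.items()
                ]
                # re-derive membership from the recovered indexes
                by_index = {d.index: d for d in droplets}
                resolved = [
                    fountain.Droplet(
                        index=d.index,
                        segment_ids=by_index[d.index].segment_ids,
                        payload=d.payload,
                    )
                    for d in recovered
                    if d.index in by_index
                ]
                uniq_counts.append(len(resolved))
                try:
                    segs = fountain.peel_decode(resolved, k)
                except fountain.IntegrityError:
                    segs = None
                if segs is not None and true_segments is not None and all(
                    s.payload == t.payload for s, t in zip(segs, true_segments)
                ):
                    msg_ok += 1
            rows.append(
                dict(
                    max_flips=max_flips,
                    sample_size=size,
                    mean_unique_droplets=float(np.mean(uniq_counts)),
                    message_recovery_prob=msg_ok / n_resamples,
                    resamples=n_resamples,
                )
            )
    return pd.DataFrame(rows)


def _segment_count(droplets: Sequence[fountain.Droplet]) -> int:
    return max(max(d.segment_ids) for d in droplets) + 1


# ---------------------------------------------------------------------------
# store-size arithmetic
# ---------------------------------------------------------------------------

def origami_count_curve(
    message_sizes: Iterable[int], redundancy: float = 1.5
) -> pd.DataFrame:
    """Number of origami needed per message size, with and without the
    fountain-code redundancy factor."""
    rows = []
    for m in message_sizes:
        _, k, b, n = plan_store(m, redundancy)
        rows.append(
            dict(
                message_size=m,
                data_bits_per_origami=b,
                origami_without_redundancy=k,
                origami_with_redundancy=n,
            )
        )
    return pd.DataFrame(rows)


def areal_density(pitch_nm: float, data_fraction: float) -> float:
    """Areal information density in Gbit/cm^2, to two significant figures.

    One bit per ``pitch_nm`` x ``pitch_nm`` site; ``data_fraction`` is the
    share of sites carrying payload rather than overhead.
    """
    if pitch_nm <= 0:
        raise ValueError("pitch must be positive")
    if not 0 < data_fraction <= 1:
        raise ValueError("data_fraction must be in (0, 1]")
    gbit_per_cm2 = (1e14 / pitch_nm**2) * data_fraction / 1e9
    if gbit_per_cm2 == 0:
        return 0.0
    exp = math.floor(math.log10(abs(gbit_per_cm2)))
    return float(round(gbit_per_cm2, -exp + 1))


# ---------------------------------------------------------------------------
# synthetic DNA-PAINT recordings
# ---------------------------------------------------------------------------

def _grid_sites(pitch_nm: float) -> np.ndarray:
    """Site coordinates of the 6x8 lattice, centred on the origami origin,
    row-major; y grows downward as in image coordinates."""
    r, c = np.mgrid[0:ROWS, 0:COLS]
    x = (c - (COLS - 1) / 2.0) * pitch_nm
    y = (r - (ROWS - 1) / 2.0) * pitch_nm
    return np.column_stack([x.ravel(), y.ravel()])


def synth_localizations(
    designs: Sequence[np.ndarray],
    cfg: BlinkConfig,
    rng: np.random.Generator,
    copies: int = 1,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthesise a localization table for origami carrying the given designs.

    Each origami is placed at a uniform random position (with a minimum
    pairwise separation so clusters remain isolated) and orientation.
    Sites encoding 1 emit ``Poisson(mean_blinks_per_site)`` localizations
    unless missed; sites encoding 0 may emit spuriously.  Localizations are
    jittered by their own reported uncertainty; a uniform background is
    added.  A ground-truth sidecar for oracle checks accompanies the table.
    """
    field_nm = cfg.field_um * 1e3
    sites = _grid_sites(cfg.pitch_nm)
    n_origami = len(designs) * copies
    margin = 60.0

    positions = []
    attempts = 0
    while len(positions) < n_origami and attempts < 100_000:
        attempts += 1
        cand = rng.uniform(margin, field_nm - margin, size=2)
        if all(
            np.hypot(*(cand - p)) >= cfg.min_separation_nm for p in positions
        ):
            positions.append(cand)
    if len(positions) < n_origami:
        raise ValueError(
            "field too crowded: increase field_um or reduce origami count"
        )

    frames_col, xs, ys, uncs, intens = [], [], [], [], []
    loc_origami, loc_site = [], []
    org_rows = []
    site_bits = np.zeros((n_origami, N_SITES), dtype=np.uint8)
    for oid in range(n_origami):
        design_id = oid % len(designs)
        bits = np.asarray(designs[design_id], dtype=np.uint8).ravel()
        theta = rng.uniform(0, 2 * np.pi)
        x0, y0 = positions[oid]
        org_rows.append(
            dict(origami_id=oid, design_id=design_id, x_nm=x0, y_nm=y0,
                 theta_rad=theta)
        )
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        posed = sites @ rot.T + (x0, y0)
        on = bits.astype(bool)
        on &= rng.random(N_SITES) >= cfg.site_miss_prob
        on |= (~bits.astype(bool)) & (rng.random(N_SITES) < cfg.spurious_site_prob)
        site_bits[oid] = on.astype(np.uint8)
        for k in np.nonzero(on)[0]:
            n_loc = rng.poisson(cfg.mean_blinks_per_site)
            if n_loc == 0:
                continue
            unc = cfg.sigma_nm * rng.uniform(0.7, 1.3, size=n_loc)
            jitter = rng.normal(scale=unc[:, None], size=(n_loc, 2))
            pts = posed[k] + jitter
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
            uncs.append(unc)
            frames_col.append(rng.integers(1, cfg.frames + 1, size=n_loc))
            intens.append(rng.lognormal(np.log(1000.0), 0.3, size=n_loc))
            loc_origami.append(np.full(n_loc, oid))
            loc_site.append(np.full(n_loc, k))

    n_bg = rng.poisson(cfg.background_per_um2 * cfg.field_um**2)
    if n_bg:
        xs.append(rng.uniform(0, field_nm, size=n_bg))
        ys.append(rng.uniform(0, field_nm, size=n_bg))
        uncs.append(cfg.sigma_nm * rng.uniform(0.8, 2.0, size=n_bg))
        frames_col.append(rng.integers(1, cfg.frames + 1, size=n_bg))
        intens.append(rng.lognormal(np.log(600.0), 0.4, size=n_bg))
        loc_origami.append(np.full(n_bg, -1))
        loc_site.append(np.full(n_bg, -1))

    if xs:
        table = pd.DataFrame(
            {
                "frame": np.concatenate(frames_col).astype(np.int64),
                "x [nm]": np.concatenate(xs),
                "y [nm]": np.concatenate(ys),
                "uncertainty [nm]": np.concatenate(uncs),
                "intensity [photon]": np.concatenate(intens),
            }
        )
        truth_loc_o = np.concatenate(loc_origami).astype(np.int64)
        truth_loc_s = np.concatenate(loc_site).astype(np.int64)
    else:
        table = pd.DataFrame(
            {
                "frame": np.array([], dtype=np.int64),
                "x [nm]": [],
                "y [nm]": [],
                "uncertainty [nm]": [],
                "intensity [photon]": [],
            }
        )
        truth_loc_o = np.array([], dtype=np.int64)
        truth_loc_s = np.array([], dtype=np.int64)
    truth = GroundTruth(
        origami=pd.DataFrame(
            org_rows,
            columns=["origami_id", "design_id", "x_nm", "y_nm", "theta_rad"],
        ),
        site_bits=site_bits,
        loc_origami=truth_loc_o,
        loc_site=truth_loc_s,
    )
    return table, truth
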