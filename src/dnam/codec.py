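"""Encoding droplets into 48-bit matrices and correcting read errors.

Encoding writes the droplet payload, its index and the orientation marker
into the message region, then fills the checksum and parity cells from the
constraint graph, producing a matrix with zero constraint mismatches.

Decoding assigns every cell an error weight.  A message cell's weight is
the number of violated checks covering it; a parity/checksum cell's weight
counts covered cells implicated by more than one violated check.  The sum
of weights over the matrix, normalised by the number of satisfied parity
bits, is the overall matrix weight -- zero iff the matrix is consistent,
and invariant under 180-degree rotation.  ``correct_matrix`` runs a
best-first search over single-bit flips of implicated cells, keyed by this
weight, until it reaches a consistent matrix or exhausts its budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _search
from .fountain import Droplet
from .layout import (
    COLS,
    ROWS,
    Cell,
    CellRole,
    LayoutSpec,
    _CHECKSUM_SHIFT,
    rotate180,
)

__all__ = [
    "WeightMatrix",
    "DecodeResult",
    "OrientationError",
    "encode_matrix",
    "cell_weights",
    "overall_weight",
    "correct_matrix",
    "orient_and_extract",
    "decode_matrix",
    "matrix_to_int",
    "int_to_matrix",
]

DEFAULT_MAX_FLIPS = 9
#: search budget (queue pops) per matrix; see docs/methods.md for the choice
DEFAULT_MAX_EXPANSIONS = 10_000


class OrientationError(RuntimeError):
    """Orientation cells match neither the marker nor its rotation."""


def matrix_to_int(matrix: np.ndarray) -> int:
    m = np.asarray(matrix, dtype=np.uint64).ravel()
    return int((m << np.arange(48, dtype=np.uint64)).sum())


def int_to_matrix(bits: int) -> np.ndarray:
    v = (np.uint64(bits) >> np.arange(48, dtype=np.uint64)) & np.uint64(1)
    return v.astype(np.uint8).reshape(ROWS, COLS)


def _cell_id(cell: Cell) -> int:
    return cell[0] * COLS + cell[1]


class _Tables:
    """Layout constraints packed for the bit-level search kernel."""

    def __init__(self, layout: LayoutSpec):
        cons = layout.constraints
        n = len(cons)
        self.cov_mask = np.zeros(n, dtype=np.uint64)
        self.storage = np.zeros(n, dtype=np.int64)
        self.shift = np.zeros(n, dtype=np.int64)
        self.impl_mask = np.zeros(n, dtype=np.uint64)
        # per-cell incremental-update tables
        self.toggle = np.zeros(48, dtype=np.uint64)  # linear mismatch toggles
        self.nonlin = np.zeros(48, dtype=np.uint64)  # checks needing recompute
        self.cover_by_cell = np.zeros(48, dtype=np.uint64)
        self.ncov = np.zeros(48, dtype=np.int64)
        self.parity_mask = np.uint64(0)
        for j, k in enumerate(cons):
            jbit = np.uint64(1) << np.uint64(j)
            for cell in k.covered:
                cid = _cell_id(cell)
                self.cov_mask[j] |= np.uint64(1) << np.uint64(cid)
                self.cover_by_cell[cid] |= jbit
                self.ncov[cid] += 1
                if _CHECKSUM_SHIFT[k.function] == 0:
                    self.toggle[cid] ^= jbit
                else:
                    self.nonlin[cid] |= jbit
            sid = _cell_id(k.cell)
            self.storage[j] = sid
            self.toggle[sid] ^= jbit
            self.shift[j] = _CHECKSUM_SHIFT[k.function]
            self.impl_mask[j] = self.cov_mask[j] | (np.uint64(1) << np.uint64(sid))
            if j < len(layout.parity_constraints):
                self.parity_mask |= jbit
        self.n_parity = len(layout.parity_constraints)
        self.orientation_ids = [_cell_id(c) for c in layout.orientation_cells]
        # densest constraint participation of any single cell (covered or
        # storage): one bit flip can repair at most this many violations
        part = self.ncov.copy()
        for j in range(n):
            part[self.storage[j]] += 1
        self.max_part = int(part.max())


_TABLES_CACHE: dict[tuple, _Tables] = {}


def _tables(layout: LayoutSpec) -> _Tables:
    key = (layout.parity_constraints, layout.checksum_constraints,
           layout.orientation_cells)
    if key not in _TABLES_CACHE:
        _TABLES_CACHE[key] = _Tables(layout)
    return _TABLES_CACHE[key]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_matrix(droplet: Droplet, layout: LayoutSpec) -> np.ndarray:
    """Encode one droplet into a consistent 6x8 bit matrix."""
    if len(droplet.payload) != layout.data_width:
        raise ValueError(
            f"droplet payload is {len(droplet.payload)} bits, "
            f"layout data field is {layout.data_width}"
        )
    if not 0 <= droplet.index < (1 << layout.index_width if layout.index_width else 1):
        raise ValueError(f"droplet index {droplet.index} exceeds the index field")
    m = np.zeros((layout.rows, layout.cols), dtype=np.uint8)
    for cell, bit in zip(layout.orientation_cells, layout.orientation_pattern):
        m[cell] = bit
    for i, cell in enumerate(layout.index_cells):  # big-endian
        m[cell] = (droplet.index >> (layout.index_width - 1 - i)) & 1
    for bit, cell in zip(droplet.payload, layout.data_cells):
        m[cell] = bit
    for k in layout.constraints:  # checksum then parity; order is immaterial
        m[k.cell] = k.evaluate(m)
    return m


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    x: np.ndarray  # per-cell error weight, rows x cols
    matched_parity_count: int

    @property
    def total(self) -> float:
        return float(self.x.sum())


def cell_weights(matrix: np.ndarray, layout: LayoutSpec) -> WeightMatrix:
    """Per-cell error weights from the violated constraints of ``matrix``."""
    m = np.asarray(matrix, dtype=np.uint8)
    violated = [k for k in layout.constraints if k.evaluate(m) != m[k.cell]]
    x = np.zeros((layout.rows, layout.cols), dtype=np.int64)
    for k in violated:
        for cell in k.covered:
            x[cell] += 1
    over1 = x > 1
    for k in layout.constraints:
        x_storage = sum(1 for cell in k.covered if over1[cell])
        x[k.cell] = x_storage
    matched = sum(
        1 for k in layout.parity_constraints if k.evaluate(m) == m[k.cell]
    )
    return WeightMatrix(x=x, matched_parity_count=matched)


def overall_weight(matrix: np.ndarray, layout: LayoutSpec) -> float:
    """Summed cell weights normalised by the matched parity bits
    (``inf`` when no parity bit matches)."""
    w = cell_weights(matrix, layout)
    if w.matched_parity_count == 0:
        return float("inf")
    return w.total / w.matched_parity_count


# ---------------------------------------------------------------------------
# correction and extraction
# ---------------------------------------------------------------------------

@dataclass
class DecodeResult:
    status: str  # "ok" | "fail"
    corrected: np.ndarray | None
    flips: list[Cell] = field(default_factory=list)
    index: int | None = None
    payload: tuple[int, ...] | None = None
    orientation: int | None = None  # degrees: 0 or 180
    expansions: int = 0

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def correct_matrix(
    matrix: np.ndarray,
    layout: LayoutSpec,
    max_flips: int = DEFAULT_MAX_FLIPS,
    max_expansions: int = DEFAULT_MAX_EXPANSIONS,
) -> DecodeResult:
    """Greedy best-first error correction of a noisy matrix.

    Failure (budget exhausted or no consistent matrix reachable within
    ``max_flips``) is reported in ``status``, not raised.
    """
    t = _tables(layout)
    bits = np.uint64(matrix_to_int(matrix))
    ok, corrected_bits, expansions = _search.search_correct(
        bits, t.cov_mask, t.storage, t.shift, t.impl_mask, t.toggle, t.nonlin,
        t.cover_by_cell, t.ncov, t.parity_mask, t.n_parity, t.max_part,
        max_flips, max_expansions,
    )
    if not ok:
        return DecodeResult(status="fail", corrected=None, expansions=int(expansions))
    corrected = int_to_matrix(int(corrected_bits))
    diff = np.argwhere(corrected != np.asarray(matrix, dtype=np.uint8))
    flips = [(int(r), int(c)) for r, c in diff]
    return DecodeResult(
        status="ok", corrected=corrected, flips=flips, expansions=int(expansions)
    )


def orient_and_extract(
    result: DecodeResult, layout: LayoutSpec
) -> tuple[int, tuple[int, ...]]:
    """Resolve the orientation of a corrected matrix and read out
    ``(index, payload)``; raises :class:`OrientationError` when the marker
    cells match neither the pattern nor its rotation."""
    if not result.ok or result.corrected is None:
        raise ValueError("orient_and_extract requires a successful correction")
    m = result.corrected
    read = tuple(int(m[c]) for c in layout.orientation_cells)
    if read == layout.orientation_pattern:
        oriented, orientation = m, 0
    elif read == layout._rotated_orientation_pattern():
        oriented, orientation = rotate180(m), 180
    else:
        raise OrientationError(f"orientation cells read {read}")
    index = 0
    for cell in layout.index_cells:
        index = (index << 1) | int(oriented[cell])
    payload = tuple(int(oriented[cell]) for cell in layout.data_cells)
    result.index = index
    result.payload = payload
    result.orientation = orientation
    return index, payload


def decode_matrix(
    matrix: np.ndarray,
    layout: LayoutSpec,
    max_flips: int = DEFAULT_MAX_FLIPS,
    max_expansions: int = DEFAULT_MAX_EXPANSIONS,
) -> DecodeResult:
    """Correct, orient and extract in one call.

    An unresolvable orientation downgrades the result to ``status="fail"``
    (the origami is discarded), mirroring how a reader must treat it.
    """
    result = correct_matrix(matrix, layout, max_flips, max_expansions)
    if result.ok:
        try:
            orient_and_extract(result, layout)
        except OrientationError:
            return DecodeResult(
                status="fail", corrected=result.corrected,
                flips=result.flips, expansions=result.expansions,
            )
    return result
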