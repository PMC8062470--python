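"""Geometry and constraint graph of the 6x8 origami bit matrix.

A dNAM origami presents 48 addressable docking sites arranged in a 6x8
lattice.  Each site carries one bit and is assigned one of five roles:

* ``data``        -- payload bits of one fountain-code droplet,
* ``index``       -- the droplet index, big-endian,
* ``orientation`` -- a fixed asymmetric marker that distinguishes a matrix
  from its 180-degree rotation,
* ``parity``      -- even-parity (XOR) bits over subsets of the central
  message region, at two granularities (rows/columns and 2x2 blocks),
* ``checksum``    -- modular popcounts of the data+index bits.

The defining property of the layout is that the *constraint graph* -- the
set of (storage cell, covered cell set, function) triples -- is closed
under rotating every address by ``(i, j) -> (rows-1-i, cols-1-j)``.  A
matrix read upside down therefore produces exactly the same error weights,
which lets error correction run before the orientation is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

ROWS = 6
COLS = 8

Cell = tuple[int, int]


class CellRole(str, Enum):
    DATA = "data"
    INDEX = "index"
    ORIENTATION = "orientation"
    CHECKSUM = "checksum"
    PARITY = "parity"


#: function identifiers understood by the codec
F_XOR = "xor"
F_POPCOUNT_MOD4_BIT0 = "popcount_mod4_bit0"  # low bit == even parity
F_POPCOUNT_MOD4_BIT1 = "popcount_mod4_bit1"  # second bit of the popcount

_CHECKSUM_SHIFT = {F_XOR: 0, F_POPCOUNT_MOD4_BIT0: 0, F_POPCOUNT_MOD4_BIT1: 1}


@dataclass(frozen=True)
class Constraint:
    """One stored check bit: ``cell`` holds ``function`` of ``covered``."""

    cell: Cell
    covered: frozenset[Cell]
    function: str

    def evaluate(self, bits: np.ndarray) -> int:
        """Recompute the check bit from a 6x8 0/1 matrix."""
        pop = int(sum(int(bits[r, c]) for (r, c) in self.covered))
        return (pop >> _CHECKSUM_SHIFT[self.function]) & 1


def rotate_cell(cell: Cell, rows: int = ROWS, cols: int = COLS) -> Cell:
    r, c = cell
    return rows - 1 - r, cols - 1 - c


def rotate180(matrix: np.ndarray) -> np.ndarray:
    """Rotate a bit matrix by 180 degrees (an involution)."""
    m = np.asarray(matrix)
    if m.shape != (ROWS, COLS):
        raise ValueError(f"expected a {ROWS}x{COLS} matrix, got shape {m.shape}")
    return m[::-1, ::-1].copy()


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class LayoutSpec:
    """Full description of the 48-cell role map and its constraint graph."""

    rows: int
    cols: int
    orientation_cells: tuple[Cell, ...]
    orientation_pattern: tuple[int, ...]
    index_cells: tuple[Cell, ...]  # big-endian: first cell is the MSB
    data_cells: tuple[Cell, ...]
    parity_constraints: tuple[Constraint, ...]
    checksum_constraints: tuple[Constraint, ...]
    role_map: Mapping[Cell, CellRole] = field(repr=False)

    # -- derived ---------------------------------------------------------
    @property
    def index_width(self) -> int:
        return len(self.index_cells)

    @property
    def data_width(self) -> int:
        return len(self.data_cells)

    @property
    def payload_cells(self) -> tuple[Cell, ...]:
        return self.index_cells + self.data_cells

    @property
    def constraints(self) -> tuple[Constraint, ...]:
        return self.parity_constraints + self.checksum_constraints

    def role_counts(self) -> dict[CellRole, int]:
        counts: dict[CellRole, int] = {role: 0 for role in CellRole}
        for role in self.role_map.values():
            counts[role] += 1
        return counts

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        cells = {(r, c) for r in range(self.rows) for c in range(self.cols)}
        if set(self.role_map) != cells:
            raise LayoutError("role map must assign every cell exactly once")
        n = self.rows * self.cols
        if self.index_width + self.data_width + len(self.orientation_cells) + len(
            self.checksum_constraints
        ) + len(self.parity_constraints) != n:
            raise LayoutError("bit budget does not add up to the cell count")
        storage = [k.cell for k in self.constraints]
        if len(storage) != len(set(storage)):
            raise LayoutError("a parity/checksum cell appears in more than one constraint")
        # closure of the constraint graph under 180-degree rotation
        as_set = {
            (rotate_cell(k.cell, self.rows, self.cols),
             frozenset(rotate_cell(c, self.rows, self.cols) for c in k.covered),
             k.function)
            for k in self.constraints
        }
        if as_set != {(k.cell, k.covered, k.function) for k in self.constraints}:
            raise LayoutError("constraint graph is not closed under 180-degree rotation")
        if self._rotated_orientation_pattern() == self.orientation_pattern:
            raise LayoutError("orientation pattern must differ from its rotation")

    def _rotated_orientation_pattern(self) -> tuple[int, ...]:
        """The pattern read from the orientation cells of a rotated matrix."""
        lookup = dict(zip(self.orientation_cells, self.orientation_pattern))
        return tuple(
            lookup[rotate_cell(c, self.rows, self.cols)] for c in self.orientation_cells
        )

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "role_map": sorted(
                [r, c, role.value] for (r, c), role in self.role_map.items()
            ),
            "constraints": [
                {
                    "parity_cell": list(k.cell),
                    "covered": sorted(list(c) for c in k.covered),
                    "function": k.function,
                }
                for k in self.constraints
            ],
            "orientation": {
                "cells": [list(c) for c in self.orientation_cells],
                "pattern": list(self.orientation_pattern),
            },
            "index_cells": [list(c) for c in self.index_cells],
            "data_cells": [list(c) for c in self.data_cells],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LayoutSpec":
        d = json.loads(text)
        role_map = {(r, c): CellRole(role) for r, c, role in d["role_map"]}
        parity, checksum = [], []
        for k in d["constraints"]:
            con = Constraint(
                cell=tuple(k["parity_cell"]),
                covered=frozenset(tuple(c) for c in k["covered"]),
                function=k["function"],
            )
            (parity if role_map[con.cell] is CellRole.PARITY else checksum).append(con)
        spec = cls(
            rows=d["rows"],
            cols=d["cols"],
            orientation_cells=tuple(tuple(c) for c in d["orientation"]["cells"]),
            orientation_pattern=tuple(d["orientation"]["pattern"]),
            index_cells=tuple(tuple(c) for c in d["index_cells"]),
            data_cells=tuple(tuple(c) for c in d["data_cells"]),
            parity_constraints=tuple(parity),
            checksum_constraints=tuple(checksum),
            role_map=role_map,
        )
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# default geometry
# ---------------------------------------------------------------------------
# message region: the central four columns (24 cells); check region: the two
# outer column pairs.  Both are closed under 180-degree rotation.
_MESSAGE_COLS = (2, 3, 4, 5)

_ORIENTATION_CELLS: tuple[Cell, ...] = ((0, 2), (0, 5), (5, 2), (5, 5))
_ORIENTATION_PATTERN: tuple[int, ...] = (1, 1, 1, 0)

_CHECKSUM_CELLS = {
    # (cell, which half, which popcount bit); rotation maps top<->bottom
    ((2, 0), "top", F_POPCOUNT_MOD4_BIT1),
    ((2, 7), "top", F_POPCOUNT_MOD4_BIT0),
    ((3, 7), "bottom", F_POPCOUNT_MOD4_BIT1),
    ((3, 0), "bottom", F_POPCOUNT_MOD4_BIT0),
}

# The 20 parity bits form ten 180-degree-rotation orbit pairs.  Each entry
# below gives the six covered message-region cells of the orbit representative
# (indexed 0..23, row-major over the message columns) and the storage-cell
# pair: the representative parity lives in the first cell, its rotated twin
# (covering the point-rotated cell set) in the second.  The family is
# 5-regular -- every message cell is covered by exactly five parities -- and
# was optimised by simulated annealing to push up the minimum weight of the
# induced [48,24] code (no nonzero codeword below weight ~6, most above 8)
# while keeping checks sparse enough for the weight-guided search to follow.
_PARITY_ORBITS: tuple[tuple[tuple[int, ...], tuple[Cell, Cell]], ...] = (
    ((6, 7, 11, 18, 19, 20), ((0, 0), (5, 7))),
    ((1, 7, 8, 12, 20, 21), ((1, 0), (4, 7))),
    ((1, 4, 9, 16, 19, 21), ((4, 0), (1, 7))),
    ((4, 6, 8, 10, 15, 22), ((5, 0), (0, 7))),
    ((3, 7, 11, 13, 17, 23), ((0, 1), (5, 6))),
    ((0, 3, 8, 13, 16, 18), ((1, 1), (4, 6))),
    ((0, 2, 9, 12, 19, 23), ((2, 1), (3, 6))),
    ((2, 5, 12, 13, 14, 15), ((3, 1), (2, 6))),
    ((0, 1, 5, 10, 17, 22), ((4, 1), (1, 6))),
    ((2, 9, 14, 17, 18, 20), ((5, 1), (0, 6))),
)

#: message-region cells in row-major order (includes orientation cells)
_MESSAGE_CELLS: tuple[Cell, ...] = tuple(
    (r, c) for r in range(ROWS) for c in _MESSAGE_COLS
)


def _payload_cell_order() -> tuple[Cell, ...]:
    """Data+index cells: the message region minus orientation markers, row-major."""
    return tuple(
        (r, c)
        for r in range(ROWS)
        for c in _MESSAGE_COLS
        if (r, c) not in _ORIENTATION_CELLS
    )


def _build_layout(index_width: int) -> LayoutSpec:
    payload = _payload_cell_order()
    if not 0 <= index_width <= len(payload):
        raise LayoutError(f"index width must be in [0, {len(payload)}]")

    parity = []
    for covered_ids, (cell, twin_cell) in _PARITY_ORBITS:
        covered = frozenset(_MESSAGE_CELLS[m] for m in covered_ids)
        twin = frozenset(_MESSAGE_CELLS[23 - m] for m in covered_ids)
        parity.append(Constraint(cell, covered, F_XOR))
        parity.append(Constraint(twin_cell, twin, F_XOR))

    top_half = frozenset(cell for cell in payload if cell[0] <= 2)
    bottom_half = frozenset(cell for cell in payload if cell[0] >= 3)
    checksum = [
        Constraint(cell, top_half if half == "top" else bottom_half, fn)
        for cell, half, fn in sorted(_CHECKSUM_CELLS)
    ]

    role_map: dict[Cell, CellRole] = {}
    for cell in _ORIENTATION_CELLS:
        role_map[cell] = CellRole.ORIENTATION
    for i, cell in enumerate(payload):
        role_map[cell] = CellRole.INDEX if i < index_width else CellRole.DATA
    for k in parity:
        role_map[k.cell] = CellRole.PARITY
    for k in checksum:
        role_map[k.cell] = CellRole.CHECKSUM
    assert len(role_map) == ROWS * COLS, "roles must cover the grid"

    spec = LayoutSpec(
        rows=ROWS,
        cols=COLS,
        orientation_cells=_ORIENTATION_CELLS,
        orientation_pattern=_ORIENTATION_PATTERN,
        index_cells=payload[:index_width],
        data_cells=payload[index_width:],
        parity_constraints=tuple(parity),
        checksum_constraints=tuple(checksum),
        role_map=role_map,
    )
    spec.validate()
    return spec


def build_default_layout() -> LayoutSpec:
    """The experimental 48-cell layout: 16 data, 4 index, 4 orientation,
    4 checksum and 20 parity bits."""
    return _build_layout(index_width=4)


def build_simulation_layout(message_bits: int, n_droplets: int) -> LayoutSpec:
    """Layout for a simulated store of ``n_droplets`` origami.

    Orientation, checksum and parity budgets are fixed; the remaining 20
    payload bits are split so the index can address every droplet, with the
    minimal index width (hence the widest data field).
    """
    if message_bits < 1:
        raise ValueError("message_bits must be >= 1")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    payload_bits = len(_payload_cell_order())
    if n_droplets > 1 << 16:
        raise LayoutError(f"cannot index {n_droplets} droplets")
    index_width = 0
    while (1 << index_width) < n_droplets:
        index_width += 1
    assert index_width < payload_bits
    return _build_layout(index_width=index_width)


def matrix_from_csv(text: str) -> np.ndarray:
    rows = [line.split(",") for line in text.strip().splitlines()]
    m = np.array([[int(v) for v in row] for row in rows], dtype=np.uint8)
    if m.shape != (ROWS, COLS) or not np.isin(m, (0, 1)).all():
        raise ValueError("matrix CSV must be 6 rows x 8 columns of 0/1")
    return m


def matrix_to_csv(matrix: np.ndarray) -> str:
    m = np.asarray(matrix, dtype=np.uint8)
    return "\n".join(",".join(str(int(v)) for v in row) for row in m) + "\n"
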