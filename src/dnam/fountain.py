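"""Fountain (LT) coding of messages into droplets, and the peeling decoder.

A message of ``n`` bits is cut into ``k`` equal segments; each droplet is
the XOR of ``d`` distinct segments, with ``d`` drawn from the ideal Soliton
distribution ``p(1) = 1/k``, ``p(d) = 1/(d(d-1))`` for ``2 <= d <= k``.
Which segments a droplet combines is a pure function of
``(seed, k, droplet index)``, so a reader that recovers a droplet's index
from an origami can re-derive its membership without side information.

Because each droplet occupies one physically synthesised origami, the
droplet count is fixed up front.  ``make_droplets`` therefore re-draws the
whole set until the peeling decoder succeeds on the full set and on every
subset missing one droplet (single-origami-loss robustness).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Segment",
    "Droplet",
    "segment_message",
    "assemble_message",
    "soliton_degree",
    "droplet_segment_ids",
    "make_droplets",
    "peel_decode",
    "EncodingError",
    "IntegrityError",
]


class EncodingError(RuntimeError):
    pass


class IntegrityError(RuntimeError):
    """Two droplets assert contradictory values for the same segment."""


@dataclass(frozen=True)
class Segment:
    id: int
    payload: tuple[int, ...]  # bits


@dataclass(frozen=True)
class Droplet:
    index: int
    segment_ids: frozenset[int]
    payload: tuple[int, ...]

    @property
    def degree(self) -> int:
        return len(self.segment_ids)


def _to_bits(message: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(message, dtype=np.uint8))


def segment_message(message: bytes, b: int) -> list[Segment]:
    """Split ``message`` into ``ceil(8*len/b)`` segments of ``b`` bits each,
    zero-padding the last."""
    if len(message) == 0:
        raise ValueError("message must be non-empty")
    if b < 1:
        raise ValueError("segment length b must be >= 1")
    bits = _to_bits(message)
    k = -(-bits.size // b)
    padded = np.zeros(k * b, dtype=np.uint8)
    padded[: bits.size] = bits
    return [
        Segment(id=i, payload=tuple(int(v) for v in padded[i * b : (i + 1) * b]))
        for i in range(k)
    ]


def assemble_message(segments: Sequence[Segment], n_bits: int) -> bytes:
    """Concatenate segment payloads (in id order) back into message bytes."""
    ordered = sorted(segments, key=lambda s: s.id)
    bits = np.concatenate([np.array(s.payload, dtype=np.uint8) for s in ordered])
    bits = bits[:n_bits]
    if bits.size % 8:
        raise ValueError("message bit count must be a whole number of bytes")
    return np.packbits(bits).tobytes()


def soliton_degree(k: int, rng: np.random.Generator) -> int:
    """Draw a droplet degree from the ideal Soliton distribution on [1, k]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return 1
    u = rng.random()
    if u <= 1.0 / k:
        return 1
    # invert the CDF  F(d) = 1/k + 1 - 1/d  for d >= 2
    d = int(np.ceil(1.0 / (1.0 + 1.0 / k - u)))
    return min(max(d, 2), k)


def droplet_segment_ids(seed: int, k: int, index: int) -> frozenset[int]:
    """Segment membership of droplet ``index`` -- a pure function of
    ``(seed, k, index)`` shared by encoder and decoder."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, k, index]))
    d = soliton_degree(k, rng)
    ids = rng.choice(k, size=d, replace=False)
    return frozenset(int(i) for i in ids)


def _xor_payload(segments: Sequence[Segment], ids: Iterable[int]) -> tuple[int, ...]:
    acc = None
    by_id = {s.id: np.array(s.payload, dtype=np.uint8) for s in segments}
    for i in ids:
        acc = by_id[i] if acc is None else acc ^ by_id[i]
    return tuple(int(v) for v in acc)


def make_droplets(
    segments: Sequence[Segment],
    n_droplets: int,
    seed: int,
    *,
    require_loss_robust: bool = True,
    max_retries: int = 10_000,
) -> tuple[list[Droplet], int]:
    """Form ``n_droplets`` droplets from ``segments``.

    Returns ``(droplets, set_seed)`` where ``set_seed`` is the seed under
    which the accepted membership mapping was drawn; a decoder re-derives
    membership from ``(set_seed, k, index)``.  The set is re-drawn until the
    full set peels successfully and, if ``require_loss_robust``, every
    subset missing one droplet does too.
    """
    k = len(segments)
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    for attempt in range(max_retries):
        set_seed = int(np.random.SeedSequence([seed, attempt]).generate_state(1)[0] >> 1)
        droplets = [
            Droplet(
                index=i,
                segment_ids=(ids := droplet_segment_ids(set_seed, k, i)),
                payload=_xor_payload(segments, ids),
            )
            for i in range(n_droplets)
        ]
        if peel_decode(droplets, k) is None:
            continue
        if require_loss_robust and n_droplets > k:
            ok = all(
                peel_decode(droplets[:j] + droplets[j + 1 :], k) is not None
                for j in range(n_droplets)
            )
            if not ok:
                continue
        return droplets, set_seed
    raise EncodingError(
        f"no droplet set with the required decodability found in {max_retries} draws"
    )


def peel_decode(droplets: Sequence[Droplet], k: int) -> list[Segment] | None:
    """Peeling (belief-propagation) decoder.

    Repeatedly resolves the lowest-degree droplet: a degree-1 droplet yields
    its segment, which is XOR-reduced out of every droplet that contains it.
    Returns the ``k`` segments on success, ``None`` if no degree-1 droplet
    remains before all segments are known.
    """
    known: dict[int, np.ndarray] = {}
    pending: list[tuple[set[int], np.ndarray]] = []
    for d in droplets:
        ids = set(d.segment_ids)
        payload = np.array(d.payload, dtype=np.uint8)
        for i in list(ids):
            if i in known:
                ids.discard(i)
                payload = payload ^ known[i]
        if not ids:
            if payload.any():  # fully reduced droplet must XOR to zero
                raise IntegrityError(
                    f"droplet {d.index} contradicts already-resolved segments"
                )
            continue
        if len(ids) == 1:
            _learn(known, pending, ids.pop(), payload)
        else:
            pending.append((ids, payload))
    return (
        [Segment(id=i, payload=tuple(int(v) for v in known[i])) for i in sorted(known)]
        if len(known) == k
        else None
    )


def _learn(
    known: dict[int, np.ndarray],
    pending: list[tuple[set[int], np.ndarray]],
    seg_id: int,
    payload: np.ndarray,
) -> None:
    """Record a resolved segment and propagate it through pending droplets."""
    stack = [(seg_id, payload)]
    while stack:
        sid, val = stack.pop()
        if sid in known:
            if not np.array_equal(known[sid], val):
                raise IntegrityError(f"conflicting payloads for segment {sid}")
            continue
        known[sid] = val
        for ids, pay in pending:
            if sid in ids:
                ids.discard(sid)
                pay ^= val
                if len(ids) == 1:
                    stack.append((next(iter(ids)), pay.copy()))
        pending[:] = [(ids, pay) for ids, pay in pending if len(ids) > 1]


def peel_decode_robust(
    droplets: Sequence[Droplet], k: int, max_drop: int = 2
) -> list[Segment] | None:
    """Peeling that tolerates a few corrupt droplets.

    A droplet carrying a wrong payload either blocks decoding or raises an
    integrity conflict; since the code is designed to survive droplet loss,
    the decoder retries after discarding up to ``max_drop`` droplets.
    """
    import itertools as _it

    n = len(droplets)

    def consistency(segs: list[Segment]) -> int:
        by_id = {s.id: np.array(s.payload, dtype=np.uint8) for s in segs}
        ok = 0
        for d in droplets:
            acc = np.zeros(len(d.payload), dtype=np.uint8)
            for i in d.segment_ids:
                acc ^= by_id[i]
            ok += tuple(int(v) for v in acc) == d.payload
        return ok

    for ndrop in range(0, max_drop + 1):
        best: tuple[int, list[Segment]] | None = None
        for keep_out in _it.combinations(range(n), ndrop):
            subset = [d for i, d in enumerate(droplets) if i not in keep_out]
            try:
                segs = peel_decode(subset, k)
            except IntegrityError:
                continue
            if segs is None:
                continue
            score = consistency(segs)
            if best is None or score > best[0]:
                best = (score, segs)
            if score == n:
                break
        if best is not None:
            return best[1]
    return None


def droplets_to_json(droplets: Sequence[Droplet], seed: int, k: int, b: int) -> str:
    def payload_hex(bits: tuple[int, ...]) -> str:
        n = (len(bits) + 3) // 4
        return format(int("".join(map(str, bits)), 2), f"0{n}x") if bits else ""

    return json.dumps(
        {
            "seed": seed,
            "k": k,
            "b": b,
            "droplets": [
                {
                    "index": d.index,
                    "degree": d.degree,
                    "segment_ids": sorted(d.segment_ids),
                    "payload_hex": payload_hex(d.payload),
                }
                for d in droplets
            ],
        },
        indent=1,
    )
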