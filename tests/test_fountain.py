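import itertools

import numpy as np
import pytest

from dnam.fountain import (
    Droplet,
    IntegrityError,
    assemble_message,
    droplet_segment_ids,
    make_droplets,
    peel_decode,
    segment_message,
    soliton_degree,
)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_reference_message_segments_into_ten(reference_store):
    assert len(reference_store["segments"]) == 10
    assert all(len(s.payload) == 16 for s in reference_store["segments"])


def test_single_segment_identity():
    msg = b"\xa5\x0f\x33"
    segs = segment_message(msg, 8 * len(msg))
    assert len(segs) == 1
    assert assemble_message(segs, 8 * len(msg)) == msg


def test_padding_forced_by_ceil():
    segs = segment_message(b"0123456789abc", 16)  # 104 bits -> 7 segments
    assert len(segs) == 7
    assert segs[-1].payload[-8:] == (0,) * 8  # zero pad


def test_empty_message_rejected():
    with pytest.raises(ValueError):
        segment_message(b"", 16)


def test_segment_roundtrip_random(rng):
    for b in (8, 12, 16):
        msg = rng.integers(0, 256, 11, dtype=np.uint8).tobytes()
        segs = segment_message(msg, b)
        assert assemble_message(segs, 8 * len(msg)) == msg


# ---------------------------------------------------------------------------
# Soliton degrees
# ---------------------------------------------------------------------------

def test_soliton_degenerate_and_errors(rng):
    assert all(soliton_degree(1, rng) == 1 for _ in range(20))
    with pytest.raises(ValueError):
        soliton_degree(0, rng)


@pytest.mark.parametrize("k", [4, 10])
def test_soliton_distribution_matches_analytic(k, rng):
    """Empirical degree frequencies agree with p(1)=1/k, p(d)=1/(d(d-1))
    within three standard errors at 1e5 draws."""
    n = 100_000
    draws = np.array([soliton_degree(k, rng) for _ in range(n)])
    probs = {1: 1.0 / k, **{d: 1.0 / (d * (d - 1)) for d in range(2, k + 1)}}
    assert abs(sum(probs.values()) - 1.0) < 1e-12
    for d, p in probs.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs((draws == d).mean() - p) <= 3 * se + 1e-9, f"degree {d}"


# ---------------------------------------------------------------------------
# droplet formation
# ---------------------------------------------------------------------------

def test_droplet_membership_rederivable(reference_store):
    seed = reference_store["droplet_seed"]
    for d in reference_store["droplets"]:
        assert droplet_segment_ids(seed, 10, d.index) == d.segment_ids


def test_droplet_payload_is_xor_of_members(reference_store):
    segs = {s.id: np.array(s.payload, dtype=np.uint8) for s in reference_store["segments"]}
    for d in reference_store["droplets"]:
        acc = np.zeros(16, dtype=np.uint8)
        for i in d.segment_ids:
            acc ^= segs[i]
        assert tuple(int(v) for v in acc) == d.payload


def test_single_segment_store():
    segs = segment_message(b"\x42", 8)
    droplets, _ = make_droplets(segs, 1, seed=0)
    assert droplets[0].degree == 1
    assert droplets[0].payload == segs[0].payload


def test_leave_one_out_decodability_enforced(reference_store):
    droplets = reference_store["droplets"]
    for j in range(len(droplets)):
        subset = droplets[:j] + droplets[j + 1 :]
        assert peel_decode(subset, 10) is not None


# ---------------------------------------------------------------------------
# peeling decoder
# ---------------------------------------------------------------------------

def test_peel_all_degree_one():
    droplets = [
        Droplet(index=i, segment_ids=frozenset([i]), payload=(i & 1,) * 4)
        for i in range(5)
    ]
    segs = peel_decode(droplets, 5)
    assert segs is not None and len(segs) == 5


def test_peel_reports_conflicting_droplets():
    a = Droplet(index=0, segment_ids=frozenset([0]), payload=(0, 0))
    b = Droplet(index=1, segment_ids=frozenset([0]), payload=(1, 0))
    with pytest.raises(IntegrityError):
        peel_decode([a, b], 1)


def test_fewer_droplets_than_segments_never_decode(reference_store):
    # spot-check; the exhaustive scan over all 5005 subsets runs in the
    # acceptance suite
    droplets = reference_store["droplets"]
    rng = np.random.default_rng(7)
    for _ in range(100):
        idx = rng.choice(15, 9, replace=False)
        assert peel_decode([droplets[i] for i in idx], 10) is None


def _gf2_solvable(droplets, k):
    """Gaussian-elimination oracle: is every segment determined?"""
    rows = []
    for d in droplets:
        v = np.zeros(k, dtype=np.uint8)
        v[list(d.segment_ids)] = 1
        rows.append(v)
    m = np.array(rows) if rows else np.zeros((0, k), dtype=np.uint8)
    rank = 0
    m = m.copy()
    for col in range(k):
        piv = None
        for r in range(rank, m.shape[0]):
            if m[r, col]:
                piv = r
                break
        if piv is None:
            return False
        m[[rank, piv]] = m[[piv, rank]]
        for r in range(m.shape[0]):
            if r != rank and m[r, col]:
                m[r] ^= m[rank]
        rank += 1
    return True


def test_peel_success_implies_gf2_solvable(rng):
    """On 200 random small instances, whenever peeling succeeds the
    GF(2) incidence system is solvable, and peel failures never occur on
    systems that peeling should handle (degree-1 chains)."""
    agree = 0
    for _ in range(200):
        k = int(rng.integers(2, 7))
        n = int(rng.integers(k, 11))
        segs = segment_message(bytes(rng.integers(0, 256, k, dtype=np.uint8)), 8)
        droplets = []
        for i in range(n):
            d = int(rng.integers(1, k + 1))
            ids = frozenset(int(x) for x in rng.choice(k, d, replace=False))
            payload = np.zeros(8, dtype=np.uint8)
            for j in ids:
                payload ^= np.array(segs[j].payload, dtype=np.uint8)
            droplets.append(
                Droplet(index=i, segment_ids=ids, payload=tuple(int(v) for v in payload))
            )
        peeled = peel_decode(droplets, k)
        if peeled is not None:
            assert _gf2_solvable(droplets, k)
            assert [tuple(s.payload) for s in peeled] == [s.payload for s in segs]
            agree += 1
    assert agree > 50  # peeling succeeds on a healthy share of instances


def test_roundtrip_many_seeds(rng):
    """Message -> droplets -> peel -> message across segment sizes and seeds."""
    for seed in range(30):
        b = (8, 12, 16)[seed % 3]
        msg = bytes(rng.integers(0, 256, 6, dtype=np.uint8))
        segs = segment_message(msg, b)
        droplets, _ = make_droplets(segs, len(segs) + 3, seed=seed)
        out = peel_decode(droplets, len(segs))
        assert out is not None
        assert assemble_message(out, 8 * len(msg)) == msg
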