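import numpy as np
import pytest

from dnam.codec import (
    OrientationError,
    cell_weights,
    correct_matrix,
    decode_matrix,
    encode_matrix,
    int_to_matrix,
    matrix_to_int,
    orient_and_extract,
    overall_weight,
)
from dnam.fountain import Droplet
from dnam.layout import CellRole, rotate180
from dnam.simulator import inject_errors


def _brute_force_weights(m, layout):
    """Independent re-evaluation of the weight rules, straight from the
    constraint list (oracle for the packed implementation)."""
    violated = [k for k in layout.constraints if k.evaluate(m) != m[k.cell]]
    x = {}
    for r in range(6):
        for c in range(8):
            x[(r, c)] = sum(1 for k in violated if (r, c) in k.covered)
    over1 = {cell for cell, v in x.items() if v > 1}
    for k in layout.constraints:
        x[k.cell] = len(over1 & k.covered)
    matched = sum(1 for k in layout.parity_constraints if k.evaluate(m) == m[k.cell])
    total = sum(x.values())
    return (float("inf") if matched == 0 else total / matched), x, matched


def test_encode_zero_droplet_all_checks_zero(layout):
    d = Droplet(index=0, segment_ids=frozenset([0]), payload=(0,) * 16)
    m = encode_matrix(d, layout)
    for k in layout.constraints:
        assert m[k.cell] == k.evaluate(m)
    # data and index cells are zero; only orientation marker cells are set
    assert m.sum() == sum(layout.orientation_pattern) + sum(
        m[k.cell] for k in layout.constraints
    )


def test_encoded_matrices_are_consistent(reference_store, layout):
    assert len(reference_store["matrices"]) == 15
    for m in reference_store["matrices"]:
        assert overall_weight(m, layout) == 0.0
        assert cell_weights(m, layout).x.sum() == 0


def test_encode_rejects_bad_payload(layout):
    with pytest.raises(ValueError):
        encode_matrix(Droplet(0, frozenset([0]), (0,) * 15), layout)
    with pytest.raises(ValueError):
        encode_matrix(Droplet(16, frozenset([0]), (0,) * 16), layout)


def test_single_flip_weight_equals_violated_coverage(reference_store, layout, rng):
    """Flipping one cell gives that cell a weight equal to the number of
    covering checks that now disagree: every XOR-type check covering it
    flips, while the mod-4 checksum high bit flips only on a carry."""
    m = reference_store["matrices"][2].copy()
    for _ in range(20):
        r, c = int(rng.integers(0, 6)), int(rng.integers(0, 8))
        mm = m.copy()
        mm[r, c] ^= 1
        w = cell_weights(mm, layout)
        covering = [k for k in layout.constraints if (r, c) in k.covered]
        if covering:  # message cell
            violated = sum(1 for k in covering if k.evaluate(mm) != mm[k.cell])
            assert w.x[r, c] == violated
            n_xor_like = sum(1 for k in covering if not k.function.endswith("bit1"))
            assert n_xor_like <= w.x[r, c] <= len(covering)


def test_weights_match_brute_force_oracle(layout, rng):
    for _ in range(150):
        m = rng.integers(0, 2, (6, 8), dtype=np.uint8)
        expected, x_exp, matched_exp = _brute_force_weights(m, layout)
        w = cell_weights(m, layout)
        assert w.matched_parity_count == matched_exp
        for cell, v in x_exp.items():
            assert w.x[cell] == v
        got = overall_weight(m, layout)
        assert got == expected or abs(got - expected) < 1e-12


def test_overall_weight_rotation_invariant(layout, rng):
    for _ in range(1000):
        m = rng.integers(0, 2, (6, 8), dtype=np.uint8)
        a, b = overall_weight(m, layout), overall_weight(rotate180(m), layout)
        assert a == b or abs(a - b) < 1e-12


def test_all_inverted_consistent_matrix_weight_finite(reference_store, layout):
    m = 1 - reference_store["matrices"][0]
    expected, _, _ = _brute_force_weights(m, layout)
    assert overall_weight(m, layout) == pytest.approx(expected)


def test_zero_error_matrix_decodes_unchanged(reference_store, layout):
    for d, m in zip(reference_store["droplets"], reference_store["matrices"]):
        res = correct_matrix(m, layout)
        assert res.ok and res.flips == []
        index, payload = orient_and_extract(res, layout)
        assert (index, payload) == (d.index, d.payload)


def test_rotated_matrix_decodes_to_same_droplet(reference_store, layout):
    for d, m in zip(reference_store["droplets"], reference_store["matrices"]):
        res = decode_matrix(rotate180(m), layout)
        assert res.ok and res.orientation == 180
        assert (res.index, res.payload) == (d.index, d.payload)


def test_index_values_span_store(reference_store):
    assert sorted(d.index for d in reference_store["droplets"]) == list(range(15))


def test_orientation_error_on_garbled_marker(reference_store, layout):
    m = reference_store["matrices"][0].copy()
    res = correct_matrix(m, layout)
    # forge a corrected matrix whose orientation cells match neither pattern
    forged = res.corrected.copy()
    for cell in layout.orientation_cells:
        forged[cell] = 0
    res.corrected = forged
    with pytest.raises(OrientationError):
        orient_and_extract(res, layout)


def test_flip_count_bounded_and_matches_hamming(reference_store, layout, rng):
    m = reference_store["matrices"][4]
    for _ in range(10):
        noisy = inject_errors(m, 3, rng)
        res = correct_matrix(noisy, layout, max_flips=9)
        if res.ok:
            assert len(res.flips) <= 9
            assert (res.corrected != noisy).sum() == len(res.flips)


def test_failure_is_status_not_exception(layout, rng):
    # a random matrix is almost surely uncorrectable within 2 flips
    for _ in range(10):
        m = rng.integers(0, 2, (6, 8), dtype=np.uint8)
        res = correct_matrix(m, layout, max_flips=2, max_expansions=500)
        assert res.status in ("ok", "fail")


def test_decode_success_monotone_in_error_count(reference_store, layout, rng):
    """True-decode rate declines (within noise) as injected errors rise."""
    mats, drops = reference_store["matrices"], reference_store["droplets"]
    rates = []
    for nf in (1, 3, 5, 7):
        ok = 0
        n = 60
        for _ in range(n):
            i = int(rng.integers(0, 15))
            res = decode_matrix(inject_errors(mats[i], nf, rng), layout)
            ok += (
                res.ok
                and res.index == drops[i].index
                and res.payload == drops[i].payload
            )
        rates.append(ok / n)
    assert rates[0] > rates[-1]
    for a, b in zip(rates, rates[1:]):
        assert b <= a + 0.15  # 2-3 SE slack at n=60


def test_matrix_int_packing_roundtrip(rng):
    for _ in range(50):
        m = rng.integers(0, 2, (6, 8), dtype=np.uint8)
        assert np.array_equal(int_to_matrix(matrix_to_int(m)), m)
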