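import numpy as np
import pytest

from symtip import (
    Direction,
    DriverSequence,
    SymmetryReport,
    SystemState,
    TippingPoint,
    Transition,
    compare_to_symmetric,
    detect_tipping,
    total_shift_magnitude,
)


def _make_states(O: np.ndarray, S: np.ndarray) -> list[SystemState]:
    return [SystemState(1.0, 1.0, o, s, 0.3) for o, s in zip(O, S)]


def _drivers(n: int) -> DriverSequence:
    la = np.linspace(-2, 0, n)
    return DriverSequence(10.0**la, 10.0 ** la[::-1], Direction.TOWARD_OXIC)


def _brute_force_tip(O, S):
    """Independent oracle: exhaustive scan over all consecutive pairs."""
    best_i, best = -1, -np.inf
    for i in range(len(O) - 1):
        c = max(abs(np.log10(O[i + 1]) - np.log10(O[i])),
                abs(np.log10(S[i + 1]) - np.log10(S[i])))
        if c > best:
            best_i, best = i, c
    return best_i, best


def test_single_jump_is_located_exactly():
    """O jumps 1 -> 100 between steps 5 and 6, varies <1% elsewhere."""
    n = 12
    O = np.full(n, 1.0) * (1 + 0.005 * np.arange(n))
    S = np.full(n, 50.0) * (1 - 0.002 * np.arange(n))
    O[6:] *= 100.0
    tp = detect_tipping(_make_states(O, S), _drivers(n))
    assert tp is not None
    assert tp.index == 5
    assert tp.transition is Transition.ANOXIC_TO_OXIC
    assert tp.magnitude_O == pytest.approx(2.0, abs=0.01)
    la = np.linspace(-2, 0, n)
    assert tp.location_log10_a_O == pytest.approx((la[5] + la[6]) / 2)


def test_detect_tipping_matches_brute_force_on_random_sequences(rng):
    """Randomized multiplicative walks with an injected jump of random size
    and position; the detector must agree with the exhaustive-scan oracle."""
    for _ in range(200):
        n = int(rng.integers(4, 40))
        O = np.exp(np.cumsum(rng.normal(0, 0.2, n))) * 10
        S = np.exp(np.cumsum(rng.normal(0, 0.2, n))) * 10
        if rng.random() < 0.7:  # inject a jump
            j = int(rng.integers(0, n - 1))
            which = rng.random() < 0.5
            (O if which else S)[j + 1:] *= 10.0 ** rng.uniform(1, 3) * (
                1 if rng.random() < 0.5 else 0.01
            )
        states = _make_states(O, S)
        oracle_i, oracle_c = _brute_force_tip(O, S)
        tp = detect_tipping(states, _drivers(n), no_tipping_floor=0.0)
        assert tp is not None
        assert tp.index == oracle_i
        assert max(tp.magnitude_O, tp.magnitude_S) == pytest.approx(oracle_c)


def test_gentle_sequence_reports_no_tipping():
    n = 20
    O = np.linspace(1, 2, n)
    S = np.linspace(50, 40, n)
    assert detect_tipping(_make_states(O, S), _drivers(n)) is None


def test_no_tipping_floor_threshold():
    n = 6
    O = np.ones(n)
    O[3:] *= 10 ** 0.4  # below the default 0.5 log10 floor
    S = np.full(n, 50.0)
    states = _make_states(O, S)
    assert detect_tipping(states, _drivers(n)) is None
    assert detect_tipping(states, _drivers(n), no_tipping_floor=0.3) is not None


def test_tie_break_prefers_gradient_midpoint():
    n = 9
    O = np.ones(n)
    O[1:] *= 10.0   # jump at index 0
    O[-1] *= 10.0   # identical jump at index 7
    S = np.full(n, 50.0)
    tp = detect_tipping(_make_states(O, S), _drivers(n), no_tipping_floor=0.5)
    assert tp.tied
    # both candidate pairs are equidistant from the midpoint pair: lower wins
    assert tp.index == 0


def test_raw_metric_mode():
    n = 6
    O = np.array([1.0, 1.0, 1.0, 61.0, 61.0, 61.0])
    S = np.full(n, 50.0)
    tp = detect_tipping(_make_states(O, S), _drivers(n), metric="raw", no_tipping_floor=10.0)
    assert tp.index == 2
    assert tp.magnitude_O == pytest.approx(60.0)
    with pytest.raises(ValueError, match="metric"):
        detect_tipping(_make_states(O, S), _drivers(n), metric="sqrt")


def test_total_shift_magnitude_is_sum_of_substrate_magnitudes():
    tp = TippingPoint(Transition.ANOXIC_TO_OXIC, 3, -0.8, 1.2, 0.8)
    assert total_shift_magnitude(tp) == pytest.approx(2.0)
    assert TippingPoint(Transition.ANOXIC_TO_OXIC, 3, -0.8, 0.0, 0.0).total_magnitude == 0.0


def test_compare_to_symmetric_self_comparison_is_null():
    tp_up = TippingPoint(Transition.ANOXIC_TO_OXIC, 3, -0.8, 1.0, 1.2)
    tp_dn = TippingPoint(Transition.OXIC_TO_ANOXIC, 3, -1.2, 1.2, 1.0)
    rep = SymmetryReport(tp_up, tp_dn, magnitude_asymmetry=0.0, bistability_width=0.4)
    out = compare_to_symmetric(rep, rep)
    assert out.location_shift_up == 0.0
    assert out.location_shift_down == 0.0


def test_compare_to_symmetric_with_missing_tipping_point():
    tp_up = TippingPoint(Transition.ANOXIC_TO_OXIC, 3, -0.8, 1.0, 1.2)
    rep = SymmetryReport(tp_up, None)
    ref = SymmetryReport(tp_up, tp_up)
    out = compare_to_symmetric(rep, ref)
    assert out.location_shift_up == 0.0
    assert out.location_shift_down is None
    assert out.to_dict()["tp_oxic_to_anoxic"] is None


def test_detect_tipping_input_contracts():
    states = _make_states(np.array([1.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        detect_tipping(states, _drivers(2))
    with pytest.raises(ValueError):
        detect_tipping(
            _make_states(np.array([1.0, 1.0]), np.array([1.0, 1.0])), _drivers(3)
        )
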