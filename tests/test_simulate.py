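"""Seeded determinism, noiseless limits, and planted-rate recovery."""

import numpy as np
import pandas as pd
import pytest

from polyhyb import (
    ExprSimSpec,
    MarkerSimSpec,
    MsapSimSpec,
    ValidationError,
    call_degs,
    simulate_expression,
    simulate_markers,
    simulate_msap,
)
from polyhyb.additivity import classify_additivity
from polyhyb.markers import classify_alterations
from polyhyb.msap import call_states, transition_counts


def _binomial_3se(rate, n):
    return 3 * np.sqrt(rate * (1 - rate) / n)


def test_marker_spec_validation():
    with pytest.raises(ValidationError):
        MarkerSimSpec(p_common=0.5, p_maternal_only=0.2, p_paternal_only=0.2)
    with pytest.raises(ValidationError):
        MarkerSimSpec(loss_rate_hybridization=1.2)


def test_marker_determinism_and_no_change_limit():
    spec = MarkerSimSpec(n_fragments=500, seed=11)
    m1, t1 = simulate_markers(spec)
    m2, t2 = simulate_markers(spec)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(t1, t2)

    quiet = MarkerSimSpec(
        n_fragments=500,
        loss_rate_hybridization=0.0,
        loss_rate_polyploidization=0.0,
        recovery_rate=0.0,
        novel_rate=0.0,
        seed=11,
    )
    matrix, truth = simulate_markers(quiet)
    union = (matrix["maternal"] | matrix["paternal"]).astype(np.int8)
    assert (matrix["hybrid"] == union).all()
    for j in (1, 2, 3):
        assert (matrix[f"allopolyploid_{j}"] == union).all()
        assert (truth[f"fate_allopolyploid_{j}"] == "none").all()


def test_marker_h_only_rate_recovery():
    """With no recovery, the H-only loss fraction matches the planted
    hybridization loss rate within 3 binomial standard errors."""
    spec = MarkerSimSpec(
        n_fragments=10000,
        loss_rate_hybridization=0.05,
        loss_rate_polyploidization=0.0,
        recovery_rate=0.0,
        novel_rate=0.0,
        n_allopolyploids=1,
        seed=3,
    )
    matrix, _ = simulate_markers(spec)
    records, _ = classify_alterations(matrix, "allopolyploid_1")
    h_only = (records["alteration"] == "H_only").mean()
    assert abs(h_only - 0.05) < _binomial_3se(0.05, 10000)


def test_msap_spec_validation():
    bad_rows = ((0.5, 0.5, 0.0, 0.1),) * 4
    with pytest.raises(ValidationError):
        MsapSimSpec(transition_probs=bad_rows)
    with pytest.raises(ValidationError):
        MsapSimSpec(state_probs=(0.5, 0.5, 0.5, -0.5))


def test_msap_determinism_and_identity_limit():
    spec = MsapSimSpec(n_sites=400, seed=5)
    t1, s1 = simulate_msap(spec)
    t2, s2 = simulate_msap(spec)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(s1, s2)

    identity = tuple(tuple(float(i == j) for j in range(4)) for i in range(4))
    table, truth = simulate_msap(MsapSimSpec(n_sites=400, transition_probs=identity, seed=5))
    lines = ["hybrid"] + [f"allopolyploid_{j}" for j in (1, 2, 3)]
    states = call_states(table, lines)
    pd.testing.assert_frame_equal(states, truth, check_names=False)
    for j in (1, 2, 3):
        assert (states[f"allopolyploid_{j}"] == states["hybrid"]).all()


def test_msap_all_type_one_limit():
    table, _ = simulate_msap(MsapSimSpec(n_sites=100, state_probs=(1, 0, 0, 0), seed=2))
    states = call_states(table, ["hybrid"])
    assert (states["hybrid"] == "I").all()


def test_msap_transition_rate_recovery():
    """A planted II->I transition at rate 0.1 over 5000 sites is recovered
    within 3 binomial standard errors."""
    probs = (
        (1.0, 0.0, 0.0, 0.0),
        (0.1, 0.9, 0.0, 0.0),  # II -> I at 0.1
        (0.0, 0.0, 1.0, 0.0),
        (0.0, 0.0, 0.0, 1.0),
    )
    spec = MsapSimSpec(
        n_sites=5000,
        state_probs=(0.0, 1.0, 0.0, 0.0),
        transition_probs=probs,
        n_allopolyploids=1,
        seed=9,
    )
    table, _ = simulate_msap(spec)
    states = call_states(table, ["hybrid", "allopolyploid_1"])
    counts = transition_counts(states, "hybrid", "allopolyploid_1")
    rate = counts[("II", "I")] / 5000
    assert abs(rate - 0.1) < _binomial_3se(0.1, 5000)


def test_expr_spec_validation():
    with pytest.raises(ValidationError):
        ExprSimSpec(fold=1.5)
    with pytest.raises(ValidationError):
        ExprSimSpec(class_mix=(0.5, 0.5, 0.5, -0.25, -0.25))


def test_expression_determinism():
    spec = ExprSimSpec(n_genes=300, seed=21)
    e1, t1 = simulate_expression(spec)
    e2, t2 = simulate_expression(spec)
    pd.testing.assert_frame_equal(e1.counts, e2.counts)
    pd.testing.assert_frame_equal(t1, t2)


def _recover_classes(expr, truth):
    dm, _ = call_degs(expr, "maternal", "hybrid")
    dp, _ = call_degs(expr, "paternal", "hybrid")
    shared = dm.index.intersection(dp.index)
    fpkm = expr.fpkm
    calls = classify_additivity(
        fpkm.loc[shared, "hybrid"],
        fpkm.loc[shared, "maternal"],
        fpkm.loc[shared, "paternal"],
        dm.loc[shared, "status"] != "not_de",
        dp.loc[shared, "status"] != "not_de",
    )
    return calls, truth.loc[shared]


def test_expression_noiseless_limit_all_additive():
    spec = ExprSimSpec(
        n_genes=400, class_mix=(1, 0, 0, 0, 0), dispersion=0.0, seed=13
    )
    expr, truth = simulate_expression(spec)
    calls, _ = _recover_classes(expr, truth)
    assert (calls["additivity_class"] == "additive").all()


def test_expression_noiseless_limit_recovers_all_classes():
    spec = ExprSimSpec(
        n_genes=1000, class_mix=(0.2, 0.2, 0.2, 0.2, 0.2), dispersion=0.0, seed=13
    )
    expr, truth = simulate_expression(spec)
    calls, truth_shared = _recover_classes(expr, truth)
    assert (calls["additivity_class"] == truth_shared["class"]).all()


def test_expression_class_mix_recovery():
    """Planted mixture (0.6,0.1,0.2,0.05,0.05) at n=5000, fold=4, moderate
    noise is recovered within 3 percentage points per class."""
    mix = (0.6, 0.1, 0.2, 0.05, 0.05)
    spec = ExprSimSpec(n_genes=5000, class_mix=mix, fold=4.0, dispersion=0.05, seed=1)
    expr, truth = simulate_expression(spec)
    calls, _ = _recover_classes(expr, truth)
    recovered = calls["additivity_class"].value_counts(normalize=True)
    for cls, planted in zip(
        ("additive", "transgressive_up", "transgressive_down",
         "maternal_dominant", "paternal_dominant"),
        mix,
    ):
        assert abs(recovered.get(cls, 0.0) - planted) < 0.03
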