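"""FPKM, the Audic-Claverie test, DEG calling, homolog filtering, 2^-ddCT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polyhyb import ValidationError, audic_claverie_p, audic_claverie_pmf, call_degs, ddct, filter_homologs, fpkm
from polyhyb.expression import deg_totals


@pytest.mark.parametrize(
    "count,length,libsize,expected",
    [(10, 1000, 1_000_000, 10.0), (0, 1000, 1_000_000, 0.0), (200, 500, 10_000_000, 40.0)],
)
def test_fpkm_values(count, length, libsize, expected):
    assert fpkm(count, length, libsize) == pytest.approx(expected)


def test_fpkm_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        fpkm(10, 0, 1_000_000)
    with pytest.raises(ValidationError):
        fpkm(10, 1000, 0)


def test_ac_pmf_closed_forms():
    # equal libraries: C(x+y, y) / 2^(x+y+1)
    assert audic_claverie_pmf(5, 0) == pytest.approx(1 / 64, abs=1e-12)
    # doubled library: 2!/(2! * 3^3) = 1/27
    assert audic_claverie_pmf(2, 0, 100, 200) == pytest.approx(1 / 27, abs=1e-12)


def test_ac_two_sided_values():
    assert audic_claverie_p(5, 0) == pytest.approx(0.03125, abs=1e-12)
    assert audic_claverie_p(0, 0, 1_000_000, 1_000_000) == 1.0


def test_ac_pmf_matches_negative_binomial_oracle():
    """p(y|x) is the NB pmf with r = x+1, p = N1/(N1+N2), for three library ratios."""
    n1 = 1_000_000
    for ratio in (0.5, 1.0, 2.0):
        n2 = n1 * ratio
        p_success = n1 / (n1 + n2)
        for x in range(0, 51, 5):
            y = np.arange(0, 200)
            ours = audic_claverie_pmf(np.full_like(y, x), y, n1, n2)
            oracle = stats.nbinom.pmf(y, x + 1, p_success)
            assert np.max(np.abs(ours - oracle)) < 1e-9


def test_ac_pmf_sums_to_one():
    for x in (0, 7, 50):
        for ratio in (0.5, 1.0, 2.0):
            y = np.arange(0, 5000)
            total = audic_claverie_pmf(np.full_like(y, x), y, 1e6, 1e6 * ratio).sum()
            assert total == pytest.approx(1.0, abs=1e-9)


@given(
    x=st.integers(0, 200),
    y=st.integers(0, 200),
    n1=st.floats(1e4, 1e8),
    ratio=st.floats(0.2, 5.0),
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_ac_two_sided_symmetry(x, y, n1, ratio):
    """Swapping the two libraries leaves the two-sided p unchanged."""
    n2 = n1 * ratio
    assert audic_claverie_p(x, y, n1, n2) == pytest.approx(
        audic_claverie_p(y, x, n2, n1), abs=1e-12
    )


def test_ac_rejects_invalid_counts():
    with pytest.raises(ValidationError):
        audic_claverie_p(-1, 3)
    with pytest.raises(ValidationError):
        audic_claverie_pmf(1.5, 3)


def test_call_degs_statuses(small_expression_set):
    table, totals = call_degs(small_expression_set, "maternal", "hybrid")
    # g1: fpkm 10 -> 40, log2 = 2 -> up; g5: 6.25 -> 6.25 -> not_de
    assert table.loc["g1", "status"] == "up"
    assert table.loc["g1", "log2_ratio"] == pytest.approx(2.0, abs=1e-3)
    assert table.loc["g5", "status"] == "not_de"
    # g3: detected only in maternal -> strongly down
    assert table.loc["g3", "status"] == "down"
    assert totals == deg_totals(table["status"])


def test_call_degs_requires_detected_genes(small_expression_set):
    expr = small_expression_set
    empty = expr.counts.copy()
    empty[:] = 0
    with pytest.raises(ValidationError):
        call_degs(
            type(expr)(counts=empty, lengths=expr.lengths, library_sizes=expr.library_sizes),
            "maternal",
            "hybrid",
        )


def test_call_degs_monotone_in_second_sample(small_expression_set):
    """Raising the derived count never moves a gene's call toward 'down'."""
    rank = {"down": 0, "not_de": 1, "up": 2}
    expr = small_expression_set
    previous = None
    for c in (0, 5, 20, 80, 320):
        counts = expr.counts.copy()
        counts.loc["g1", "hybrid"] = c
        table, _ = call_degs(
            type(expr)(counts=counts, lengths=expr.lengths, library_sizes=expr.library_sizes),
            "maternal",
            "hybrid",
        )
        current = rank[table.loc["g1", "status"]]
        if previous is not None:
            assert current >= previous
        previous = current


def test_deg_totals_sum():
    status = pd.Series(["up"] * 2698 + ["down"] * 6438 + ["not_de"] * 5)
    assert deg_totals(status) == {"up": 2698, "down": 6438, "total": 9136}


def _match_frame(rows):
    return pd.DataFrame(
        rows, columns=["query_id", "subject_id", "evalue", "alignment_length", "identity"]
    )


def test_filter_homologs_thresholds_inclusive():
    matches = _match_frame(
        [
            ("q1", "s1", 1e-120, 250, 95.0),  # retained
            ("q2", "s2", 1e-50, 250, 95.0),  # weak e-value
            ("q3", "s3", 9e-100, 200, 90.0),  # exactly on every boundary
            ("q4", "s4", 1e-120, 199, 95.0),  # short alignment
            ("q5", "s5", 1e-120, 250, 89.9),  # low identity
        ]
    )
    kept = filter_homologs(matches)
    assert sorted(kept["query_id"]) == ["q1", "q3"]


def test_filter_homologs_one_to_one_and_order_invariant():
    rows = [
        ("q1", "s1", 1e-150, 300, 95.0),
        ("q1", "s2", 1e-140, 300, 95.0),
        ("q2", "s1", 1e-130, 300, 95.0),
        ("q2", "s2", 1e-120, 400, 95.0),
        ("q3", "s3", 1e-110, 250, 92.0),
    ]
    kept_fwd = filter_homologs(_match_frame(rows))
    kept_rev = filter_homologs(_match_frame(rows[::-1]))
    pairs_fwd = list(zip(kept_fwd["query_id"], kept_fwd["subject_id"]))
    pairs_rev = list(zip(kept_rev["query_id"], kept_rev["subject_id"]))
    assert pairs_fwd == pairs_rev == [("q1", "s1"), ("q2", "s2"), ("q3", "s3")]
    assert kept_fwd["query_id"].is_unique and kept_fwd["subject_id"].is_unique


def test_filter_homologs_reciprocal_best():
    rows = [
        ("q1", "s1", 1e-150, 300, 95.0),
        ("q2", "s1", 1e-140, 300, 95.0),  # q2's best hit s1 belongs to q1
        ("q2", "s2", 1e-130, 300, 95.0),  # so q2 keeps no reciprocal partner
    ]
    kept = filter_homologs(_match_frame(rows), reciprocal=True)
    assert list(zip(kept["query_id"], kept["subject_id"])) == [("q1", "s1")]
    # greedy (non-reciprocal) resolution keeps q2 paired with its next-best hit
    greedy = filter_homologs(_match_frame(rows))
    assert list(zip(greedy["query_id"], greedy["subject_id"])) == [
        ("q1", "s1"),
        ("q2", "s2"),
    ]


@pytest.mark.parametrize(
    "args,expected",
    [
        ((10, 10, 12, 12), 1.0),  # ddCT = 0
        ((12, 10, 11, 10), 0.5),  # sample dCT 2, control dCT 1
        ((8, 10, 10, 10), 4.0),  # ddCT = -2
    ],
)
def test_ddct(args, expected):
    assert ddct(*args) == pytest.approx(expected)


def test_ddct_rejects_nonfinite():
    with pytest.raises(ValidationError):
        ddct(float("nan"), 10, 10, 10)
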