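"""Fragment-origin classification and hybridization/polyploidization typing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from polyhyb import ConfigError, MarkerSimSpec, ValidationError, simulate_markers
from polyhyb.markers import (
    ALTERATION_TYPES,
    alteration_summary,
    classify_alterations,
    classify_fragments,
    collapse_replicates,
    type_from_signature,
)

from conftest import build_marker_matrix_from_counts

# Independent oracle: the nine loss-alteration rows of the published typing
# table, transcribed verbatim as (maternal, paternal, hybrid, allopolyploid).
LOSS_TABLE = {
    (1, 0, 0, 0): "H_only",
    (0, 1, 0, 0): "H_only",
    (1, 1, 0, 0): "H_only",
    (1, 0, 1, 0): "P_only",
    (0, 1, 1, 0): "P_only",
    (1, 1, 1, 0): "P_only",
    (1, 0, 0, 1): "H_P",
    (0, 1, 0, 1): "H_P",
    (1, 1, 0, 1): "H_P",
}


@pytest.mark.parametrize(
    "pattern,expected",
    [((1, 1, 1), "common"), ((1, 0, 1), "maternal_specific"),
     ((0, 1, 1), "paternal_specific"), ((0, 0, 1), "novel")],
)
def test_fragment_class_definitions(pattern, expected):
    mat, pat, hyb = pattern
    matrix = pd.DataFrame(
        {"maternal": [mat], "paternal": [pat], "hybrid": [hyb]},
        index=pd.Index(["f"], name="fragment_id"),
    )
    classes, _ = classify_fragments(matrix)
    assert classes.loc["f"] == expected


def test_published_hybrid_percentages():
    """268/212/146/4 of 630 hybrid fragments give 42.5/33.7/23.2/0.6 percent."""
    matrix = build_marker_matrix_from_counts(268, 212, 146, 4)
    _, summary = classify_fragments(matrix)
    assert summary.loc["total", "count"] == 630
    assert summary["percent"].to_dict() == {
        "common": 42.5,
        "maternal_specific": 33.7,
        "paternal_specific": 23.2,
        "novel": 0.6,
        "total": 100.0,
    }


def test_class_partition_and_percent_sum(tiny_marker_matrix):
    classes, summary = classify_fragments(tiny_marker_matrix)
    hybrid_present = tiny_marker_matrix["hybrid"] == 1
    assert set(classes.index) == set(tiny_marker_matrix.index[hybrid_present])
    body = summary.drop("total")
    assert body["count"].sum() == summary.loc["total", "count"]
    assert abs(body["percent"].sum() - 100.0) <= 0.2


def test_missing_role_column_is_config_error(tiny_marker_matrix):
    with pytest.raises(ConfigError):
        classify_fragments(tiny_marker_matrix.drop(columns="paternal"))


def test_signature_enumeration_matches_published_table():
    """All 16 signatures: 9 loss rows, 3 unaltered, 3 gain cases, 1 unscorable."""
    for sig in itertools.product((0, 1), repeat=4):
        mat, pat, hyb, allo = sig
        if sig == (0, 0, 0, 0):
            with pytest.raises(ValidationError):
                type_from_signature(*sig)
            continue
        alt_type, direction = type_from_signature(*sig)
        if sig in LOSS_TABLE:
            assert (alt_type, direction) == (LOSS_TABLE[sig], "loss")
        elif (mat or pat) and hyb and allo:
            assert (alt_type, direction) == ("none", "none")
        else:  # de novo fragments
            assert direction == "gain"
            expected = {(1, 1): "H_only", (1, 0): "H_P", (0, 1): "P_only"}
            assert alt_type == expected[(hyb, allo)]


def test_classify_alterations_tiny(tiny_marker_matrix):
    records, tally = classify_alterations(tiny_marker_matrix, "allopolyploid_1")
    assert records.loc["f_h_only", ["alteration", "direction"]].tolist() == ["H_only", "loss"]
    assert records.loc["f_p_only", "alteration"] == "P_only"
    assert records.loc["f_h_p", "alteration"] == "H_P"
    assert records.loc["f_novel_kept", ["alteration", "direction"]].tolist() == ["H_only", "gain"]
    assert records.loc["f_novel_lost", ["alteration", "direction"]].tolist() == ["H_P", "gain"]
    assert tally.loc["subtotal", "count"] == 3
    # gains stay out of the loss subtotal
    assert tally.loc["gain:H_only", "count"] == 1
    assert tally.loc["gain:H_P", "count"] == 1


def test_unscorable_row_rejected(tiny_marker_matrix):
    bad = tiny_marker_matrix.copy()
    bad.loc["f_dead"] = [0, 0, 0, 0]
    with pytest.raises(ValidationError):
        classify_alterations(bad, "allopolyploid_1")


def test_alteration_summary_published_shares():
    """Counts (84,4,10) give subtotal 98 and an H-only share of 85.7%;
    (85,6,9) give subtotal 100 and shares 85/6/9."""

    def tally_from_counts(h_only, p_only, h_p):
        return pd.DataFrame(
            {"count": [h_only, p_only, h_p]}, index=list(ALTERATION_TYPES)
        )

    summary = alteration_summary(
        {
            "allopolyploid_2": tally_from_counts(84, 4, 10),
            "allopolyploid_3": tally_from_counts(85, 6, 9),
        }
    )
    assert summary.loc["subtotal", "allopolyploid_2_count"] == 98
    assert summary.loc["H_only", "allopolyploid_2_percent"] == 85.7
    assert summary.loc["subtotal", "allopolyploid_3_count"] == 100
    assert summary.loc["H_only", "allopolyploid_3_percent"] == 85.0
    assert summary.loc["P_only", "allopolyploid_3_percent"] == 6.0
    assert summary.loc["H_P", "allopolyploid_3_percent"] == 9.0


def test_alteration_summary_all_zero_warns():
    tally = pd.DataFrame({"count": [0, 0, 0]}, index=list(ALTERATION_TYPES))
    warnings = []
    summary = alteration_summary({"a1": tally}, warn=warnings.append)
    assert summary["a1_percent"].fillna(0).eq(0).all()
    assert warnings


def test_planted_fates_recovered_exactly():
    spec = MarkerSimSpec(n_fragments=2000, seed=7)
    matrix, truth = simulate_markers(spec)
    for allo in ("allopolyploid_1", "allopolyploid_2", "allopolyploid_3"):
        records, _ = classify_alterations(matrix, allo)
        assert (records["alteration"] == truth[f"fate_{allo}"]).all()


def test_collapse_replicates_majority():
    matrix = pd.DataFrame(
        {"a": [1, 1, 0], "b": [1, 0, 0], "c": [0, 0, 1]},
        index=pd.Index(["f1", "f2", "f3"], name="fragment_id"),
    )
    collapsed = collapse_replicates(matrix, {"line": ["a", "b", "c"]})
    assert collapsed["line"].tolist() == [1, 0, 0]
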