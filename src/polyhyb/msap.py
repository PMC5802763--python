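"""MSAP methylation-state calling and hybrid -> allopolyploid transition typing.

MSAP (methylation-sensitive amplification polymorphism) digests genomic DNA in
parallel with EcoRI+HpaII (H lane) and EcoRI+MspI (M lane). The isoschizomers
HpaII and MspI both cut CCGG but differ in methylation sensitivity, so the
band pattern at a site reports its cytosine-methylation state:

====== ======= ======= ==========================================
state  H lane  M lane  meaning
====== ======= ======= ==========================================
I      1       1       non-methylated
II     0       1       fully methylated (internal C, both strands)
III    1       0       hemi-methylated
U      0       0       absent from both lanes
====== ======= ======= ==========================================

``U`` realizes the absent-both-lanes condition ("type IV" is defined only
relative to a change between lines: a site going to or coming from U).
Transitions between the hybrid and an allopolyploid are assigned a direction
(increase/decrease of methylation) by exhaustive lookup of the ten
directional patterns; II<->III swaps are reported as ``other`` because the
gel pattern does not order them.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import as_binary_array, percent, round_half_away
from .errors import ComputationError, ValidationError

STATES = ("I", "II", "III", "U")

#: (h_lane, m_lane) -> state; a total function on binary pairs.
_LANES_TO_STATE = {(1, 1): "I", (0, 1): "II", (1, 0): "III", (0, 0): "U"}
_STATE_TO_LANES = {v: k for k, v in _LANES_TO_STATE.items()}

#: The ten directional hybrid->allopolyploid patterns. Moves into U from a
#: detected state hide the site (more methylation); moves out of U reveal it.
_DECREASE = {("U", "I"), ("U", "III"), ("U", "II"), ("II", "I"), ("III", "I")}
_INCREASE = {("I", "U"), ("III", "U"), ("II", "U"), ("I", "II"), ("I", "III")}

#: Table row order used for transition summaries (alternating down/up, as the
#: pairs are conventionally listed).
TRANSITION_ORDER = (
    ("U", "I"),
    ("I", "U"),
    ("U", "III"),
    ("III", "U"),
    ("U", "II"),
    ("II", "U"),
    ("II", "I"),
    ("I", "II"),
    ("III", "I"),
    ("I", "III"),
)

__all__ = [
    "STATES",
    "TRANSITION_ORDER",
    "call_state",
    "state_to_lanes",
    "call_states",
    "methylation_level",
    "classify_transition",
    "transition_counts",
    "transition_summary",
]


def call_state(h: int, m: int) -> str:
    """Call the methylation state from the (H lane, M lane) presence pair."""
    h_arr = as_binary_array([h], "h_lane")
    m_arr = as_binary_array([m], "m_lane")
    return _LANES_TO_STATE[(int(h_arr[0]), int(m_arr[0]))]


def state_to_lanes(state: str) -> tuple[int, int]:
    """Inverse of :func:`call_state` (total on the four states)."""
    try:
        return _STATE_TO_LANES[state]
    except KeyError:
        raise ValidationError(f"unknown methylation state {state!r}") from None


def call_states(table: pd.DataFrame, lines: Sequence[str]) -> pd.DataFrame:
    """Call per-site states for each line from a dual-lane table.

    ``table`` must carry ``<line>_H`` and ``<line>_M`` binary columns for every
    requested line; the result is a site x line DataFrame of state labels.
    """
    out = {}
    for line in lines:
        for suffix in ("_H", "_M"):
            if line + suffix not in table.columns:
                raise ValidationError(f"MSAP table lacks column {line + suffix!r}")
        h = as_binary_array(table[line + "_H"], line + "_H")
        m = as_binary_array(table[line + "_M"], line + "_M")
        states = np.select(
            [(h == 1) & (m == 1), (h == 0) & (m == 1), (h == 1) & (m == 0)],
            ["I", "II", "III"],
            default="U",
        )
        out[line] = states
    return pd.DataFrame(out, index=table.index)


def methylation_level(states: pd.Series | Sequence[str]) -> dict:
    """Per-line methylation summary over detected sites.

    Detected sites are those in state I, II or III (U excluded); the
    methylated proportion is (#II + #III) / detected, as a percentage rounded
    to one decimal. Raises if no site is detected.
    """
    s = pd.Series(states)
    counts = s.value_counts()
    n1, n2, n3 = (int(counts.get(k, 0)) for k in ("I", "II", "III"))
    total = n1 + n2 + n3
    if total == 0:
        raise ComputationError("methylation level undefined: no detected sites")
    return {
        "type_I": n1,
        "type_II": n2,
        "type_III": n3,
        "detected": total,
        "methylated_percent": percent(n2 + n3, total),
        "non_methylated_percent": percent(n1, total),
    }


def classify_transition(from_state: str, to_state: str) -> dict:
    """Classify one hybrid -> allopolyploid state change with its direction."""
    for st in (from_state, to_state):
        if st not in STATES:
            raise ValidationError(f"unknown methylation state {st!r}")
    pair = (from_state, to_state)
    if from_state == to_state:
        direction = "none"
    elif pair in _DECREASE:
        direction = "decrease"
    elif pair in _INCREASE:
        direction = "increase"
    else:
        direction = "other"
    return {"from_state": from_state, "to_state": to_state, "direction": direction}


def transition_counts(
    states: pd.DataFrame, hybrid: str, allopolyploid: str
) -> pd.Series:
    """Count sites per (from, to) category for one allopolyploid.

    Sites that are U in both the hybrid and the allopolyploid are never
    observed and are ignored.
    """
    hy = states[hybrid]
    al = states[allopolyploid]
    observed = ~((hy == "U") & (al == "U"))
    pairs = pd.DataFrame(
        {"from_state": hy[observed].to_numpy(), "to_state": al[observed].to_numpy()}
    )
    counts = pairs.value_counts()
    all_pairs = [
        (a, b) for a in STATES for b in STATES if (a, b) != ("U", "U")
    ]
    ordered = list(TRANSITION_ORDER) + [("II", "III"), ("III", "II")]
    ordered += [p for p in all_pairs if p not in ordered]
    idx = pd.MultiIndex.from_tuples(ordered, names=["from_state", "to_state"])
    return counts.reindex(idx, fill_value=0).astype(int)


def transition_summary(
    counts_per_allopolyploid: Mapping[str, pd.Series] | pd.DataFrame,
) -> pd.DataFrame:
    """Mean +/- SE of category counts across allopolyploids, with totals.

    Accepts a mapping (or DataFrame, columns = allopolyploids) of per-category
    site counts, indexed by (from_state, to_state). Rows are the ten
    directional categories in conventional order, then ``other`` pooling
    II<->III, then grand totals: sums of the directional category means for
    increases, decreases, and all changes. SE is the sample SD over
    allopolyploids divided by sqrt(n); 0.0 for a single replicate.
    """
    table = pd.DataFrame(counts_per_allopolyploid)
    if table.shape[1] == 0:
        raise ValidationError("transition_summary requires >=1 allopolyploid")

    def _stats(values: np.ndarray) -> tuple[float, float]:
        mean = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
        return mean, se

    rows = []
    for pair in TRANSITION_ORDER:
        vals = table.loc[pair].to_numpy(dtype=float) if pair in table.index else np.zeros(table.shape[1])
        mean, se = _stats(vals)
        direction = classify_transition(*pair)["direction"]
        rows.append((f"{pair[0]}->{pair[1]}", round_half_away(mean, 2), round_half_away(se, 2), direction))

    other = np.zeros(table.shape[1])
    for pair in (("II", "III"), ("III", "II")):
        if pair in table.index:
            other = other + table.loc[pair].to_numpy(dtype=float)
    mean, se = _stats(other)
    rows.append(("other", round_half_away(mean, 2), round_half_away(se, 2), "other"))

    summary = pd.DataFrame(rows, columns=["category", "mean", "se", "direction"]).set_index(
        "category"
    )
    directional = summary.iloc[: len(TRANSITION_ORDER)]
    inc = float(directional.loc[directional["direction"] == "increase", "mean"].sum())
    dec = float(directional.loc[directional["direction"] == "decrease", "mean"].sum())
    for name, value, direction in (
        ("total_increase", inc, "increase"),
        ("total_decrease", dec, "decrease"),
        ("total_changed", inc + dec, "all"),
    ):
        summary.loc[name] = [round_half_away(value, 2), np.nan, direction]
    return summary
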