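"""Dominant-marker (SRAP/AFLP-style) fragment inheritance typing.

Dominant PCR markers are scored as band presence/absence per line. Given a
fragment x line 0/1 matrix covering a maternal parent, a paternal parent,
their F1 hybrid and one or more derived allopolyploids, this module

* classifies each hybrid-present fragment by parental origin
  (``common`` / ``maternal_specific`` / ``paternal_specific`` / ``novel``), and
* types each altered fragment by the stage at which the alteration arose:

  - ``H_only`` — altered at hybridization and transmitted to the allopolyploid,
  - ``P_only`` — unaltered in the hybrid, altered only at polyploidization,
  - ``H_P``   — altered at hybridization but reverted after polyploidization.

Alterations of parental fragments are losses; fragments absent from both
parents are de novo gains and are typed with the same vocabulary but flagged
``direction="gain"`` and tallied separately from the loss table.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import as_binary_array, percent
from .errors import ConfigError, ValidationError

FRAGMENT_CLASSES = ("common", "maternal_specific", "paternal_specific", "novel")
ALTERATION_TYPES = ("H_only", "P_only", "H_P")

__all__ = [
    "FRAGMENT_CLASSES",
    "ALTERATION_TYPES",
    "collapse_replicates",
    "classify_fragments",
    "classify_alterations",
    "alteration_summary",
    "type_from_signature",
]


def _require_columns(matrix: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in matrix.columns]
    if missing:
        raise ConfigError(f"marker matrix lacks role column(s): {', '.join(missing)}")


def collapse_replicates(
    matrix: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Collapse replicate individuals to one profile per line by majority presence.

    ``groups`` maps the output line name to its replicate column names. Ties
    (possible only with an even replicate count) are called present.
    """
    out = {}
    for line, cols in groups.items():
        _require_columns(matrix, cols)
        calls = as_binary_array(matrix[list(cols)].to_numpy(), f"line {line}")
        out[line] = (calls.mean(axis=1) >= 0.5).astype(np.int8)
    return pd.DataFrame(out, index=matrix.index)


def classify_fragments(
    matrix: pd.DataFrame,
    target_line: str = "hybrid",
    maternal: str = "maternal",
    paternal: str = "paternal",
) -> tuple[pd.Series, pd.DataFrame]:
    """Classify fragments present in ``target_line`` by parental origin.

    Returns ``(classes, summary)``: a per-fragment label Series over the
    target-present fragments, and a summary table with one row per class plus
    a total row, with percentages on the target-line fragment total.
    """
    _require_columns(matrix, [maternal, paternal, target_line])
    mat = as_binary_array(matrix[maternal], maternal)
    pat = as_binary_array(matrix[paternal], paternal)
    tgt = as_binary_array(matrix[target_line], target_line)

    present = tgt == 1
    labels = np.select(
        [
            present & (mat == 1) & (pat == 1),
            present & (mat == 1) & (pat == 0),
            present & (mat == 0) & (pat == 1),
        ],
        ["common", "maternal_specific", "paternal_specific"],
        default="novel",
    )
    classes = pd.Series(labels[present], index=matrix.index[present], name="fragment_class")

    total = int(present.sum())
    counts = classes.value_counts().reindex(FRAGMENT_CLASSES, fill_value=0)
    summary = pd.DataFrame(
        {
            "count": counts.astype(int),
            "percent": [percent(c, total) for c in counts],
        }
    )
    summary.loc["total"] = [total, percent(total, total)]
    summary["count"] = summary["count"].astype(int)
    return classes, summary


def type_from_signature(
    maternal: int, paternal: int, hybrid: int, allopolyploid: int
) -> tuple[str, str]:
    """Map one presence signature to ``(alteration_type, direction)``.

    The mapping is a pure function of the four 0/1 calls. Parental fragments
    (present in >=1 parent) are expected in the hybrid by union inheritance;
    deviations are losses. Fragments absent from both parents are gains.
    A fragment absent everywhere is unscorable.
    """
    for v in (maternal, paternal, hybrid, allopolyploid):
        if v not in (0, 1):
            raise ValidationError(f"presence call must be 0/1, got {v!r}")
    parental = maternal or paternal
    if parental:
        if hybrid and allopolyploid:
            return "none", "none"
        if not hybrid and not allopolyploid:
            return "H_only", "loss"
        if hybrid and not allopolyploid:
            return "P_only", "loss"
        return "H_P", "loss"  # lost in hybrid, recovered in allopolyploid
    # de novo fragments (absent from both parents)
    if hybrid and allopolyploid:
        return "H_only", "gain"  # gained at hybridization, transmitted
    if hybrid and not allopolyploid:
        return "H_P", "gain"  # gained at hybridization, reverted
    if not hybrid and allopolyploid:
        return "P_only", "gain"  # gained only at polyploidization
    raise ValidationError("fragment absent from all four lines is unscorable")


def _pattern(*calls: int) -> str:
    return "".join("+" if c else "-" for c in calls)


def classify_alterations(
    matrix: pd.DataFrame,
    allopolyploid_line: str,
    maternal: str = "maternal",
    paternal: str = "paternal",
    hybrid: str = "hybrid",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type every fragment of one allopolyploid against parents and hybrid.

    Returns ``(records, tally)``. ``records`` has per-fragment columns
    ``pattern`` (the +/- signature ordered maternal, paternal, hybrid,
    allopolyploid), ``alteration`` and ``direction``. ``tally`` is the
    loss-alteration table: one row per (type, pattern) with counts, plus a
    ``subtotal`` row and per-type percentage of the loss subtotal; gains are
    tallied in separate ``gain:`` rows outside the subtotal.
    """
    _require_columns(matrix, [maternal, paternal, hybrid, allopolyploid_line])
    cols = [maternal, paternal, hybrid, allopolyploid_line]
    calls = as_binary_array(matrix[cols].to_numpy(), "marker matrix")
    if (calls.sum(axis=1) == 0).any():
        bad = matrix.index[calls.sum(axis=1) == 0][0]
        raise ValidationError(
            f"fragment {bad!r} absent from all four lines is unscorable"
        )

    types, directions, patterns = [], [], []
    for row in calls:
        t, d = type_from_signature(*row)
        types.append(t)
        directions.append(d)
        patterns.append(_pattern(*row))
    records = pd.DataFrame(
        {"pattern": patterns, "alteration": types, "direction": directions},
        index=matrix.index,
    )

    losses = records[records["direction"] == "loss"]
    gains = records[records["direction"] == "gain"]
    subtotal = len(losses)

    rows: dict[str, list] = {"count": [], "percent": []}
    index = []
    for alt_type in ALTERATION_TYPES:
        of_type = losses[losses["alteration"] == alt_type]
        for pat_sig, n in of_type["pattern"].value_counts().sort_index().items():
            index.append(f"{alt_type}:{pat_sig}")
            rows["count"].append(int(n))
            rows["percent"].append(np.nan)
        index.append(alt_type)
        rows["count"].append(len(of_type))
        rows["percent"].append(percent(len(of_type), subtotal))
    index.append("subtotal")
    rows["count"].append(subtotal)
    rows["percent"].append(percent(subtotal, subtotal))
    for alt_type in ("H_only", "P_only", "H_P"):
        of_type = gains[gains["alteration"] == alt_type]
        if len(of_type):
            index.append(f"gain:{alt_type}")
            rows["count"].append(len(of_type))
            rows["percent"].append(np.nan)
    tally = pd.DataFrame(rows, index=index)
    return records, tally


def alteration_summary(
    tallies: Mapping[str, pd.DataFrame], warn=None
) -> pd.DataFrame:
    """Combine per-allopolyploid tallies into one type x allopolyploid table.

    Percentages use each allopolyploid's own loss subtotal as basis. An empty
    tally (no alterations) yields zero shares and triggers ``warn`` if given.
    """
    if not tallies:
        raise ValidationError("alteration_summary requires at least one tally")
    out = {}
    for name, tally in tallies.items():
        counts = {t: int(tally.loc[t, "count"]) for t in ALTERATION_TYPES}
        subtotal = sum(counts.values())
        if subtotal == 0 and warn is not None:
            warn(f"allopolyploid {name}: no alterations; shares reported as 0")
        out[f"{name}_count"] = pd.Series({**counts, "subtotal": subtotal})
        out[f"{name}_percent"] = pd.Series(
            {
                **{t: percent(c, subtotal) for t, c in counts.items()},
                "subtotal": percent(subtotal, subtotal),
            }
        )
    return pd.DataFrame(out)
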