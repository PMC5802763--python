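"""Midparent additivity, transgressive/dominance classification, and
expression-pattern grouping for a parent/hybrid (or parent/allopolyploid) trio.

A gene expressed additively in a hybrid sits at the midparent value (MPV),
the arithmetic mean of the two parental levels. Genes deviating at least
two-fold from the MPV are non-additive and are further split into

* ``transgressive_up``    — at least two-fold above *both* parents,
* ``transgressive_down``  — at least two-fold below *both* parents,
* ``maternal_dominant``   — statistically indistinguishable from the maternal
  parent while differing from the paternal one,
* ``paternal_dominant``   — the mirror case,
* ``ambiguous``           — non-additive but fitting none of the above.

"Indistinguishable from a parent" is operationalized as *not* differentially
expressed versus that parent under the module's two-fold criterion. Genes are
also partitioned by detection (Venn categories) and by the sign grid of their
DEG calls versus each parent (four clusters / four groups).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import percent
from .errors import ValidationError
from .expression import DEFAULT_EPSILON

logger = logging.getLogger(__name__)

ADDITIVITY_CLASSES = (
    "additive",
    "transgressive_up",
    "transgressive_down",
    "maternal_dominant",
    "paternal_dominant",
    "ambiguous",
)

VENN_CATEGORIES = (
    "shared_all",
    "parents_only",
    "maternal_derived",
    "paternal_derived",
    "maternal_only",
    "paternal_only",
    "derived_novel",
)

#: (direction vs maternal, direction vs paternal) -> cluster/group number.
PATTERN_GRID = {
    ("down", "down"): 1,
    ("down", "up"): 2,
    ("up", "down"): 3,
    ("up", "up"): 4,
}

__all__ = [
    "ADDITIVITY_CLASSES",
    "VENN_CATEGORIES",
    "PATTERN_GRID",
    "partition_expressed",
    "midparent",
    "classify_additivity",
    "additivity_summary",
    "assign_patterns",
]


def partition_expressed(flags: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Partition genes by where they are detected.

    ``flags`` must have boolean-like columns ``maternal``, ``paternal`` and
    ``derived``; rows where all three are false are dropped (such genes are
    not expressed anywhere). Returns per-gene category labels and the counts
    per category.
    """
    for col in ("maternal", "paternal", "derived"):
        if col not in flags.columns:
            raise ValidationError(f"expression flags lack column {col!r}")
    mat = flags["maternal"].astype(bool).to_numpy()
    pat = flags["paternal"].astype(bool).to_numpy()
    der = flags["derived"].astype(bool).to_numpy()
    anywhere = mat | pat | der
    if not anywhere.any():
        raise ValidationError("no gene expressed in any line")
    labels = np.select(
        [
            mat & pat & der,
            mat & pat & ~der,
            mat & ~pat & der,
            ~mat & pat & der,
            mat & ~pat & ~der,
            ~mat & pat & ~der,
            ~mat & ~pat & der,
        ],
        VENN_CATEGORIES,
        default="unexpressed",
    )
    categories = pd.Series(labels[anywhere], index=flags.index[anywhere], name="venn_category")
    counts = categories.value_counts().reindex(VENN_CATEGORIES, fill_value=0)
    return categories, counts


def midparent(maternal_fpkm, paternal_fpkm):
    """Midparent value: the arithmetic mean of the parental expression levels."""
    mat = np.asarray(maternal_fpkm, dtype=float)
    pat = np.asarray(paternal_fpkm, dtype=float)
    if (mat < 0).any() or (pat < 0).any():
        raise ValidationError("expression values must be non-negative")
    out = (mat + pat) / 2.0
    return float(out) if out.ndim == 0 else out


def classify_additivity(
    derived_fpkm,
    maternal_fpkm,
    paternal_fpkm,
    de_vs_maternal,
    de_vs_paternal,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Classify each gene's deviation from parental additivity.

    ``de_vs_maternal``/``de_vs_paternal`` are boolean flags saying whether the
    derived line is differentially expressed versus that parent. Additive
    means ``|log2((derived+eps)/(MPV+eps))| < 1``; the non-additive rules are
    applied in the order transgressive -> dominance -> ambiguous.
    """
    der = np.asarray(derived_fpkm, dtype=float)
    mat = np.asarray(maternal_fpkm, dtype=float)
    pat = np.asarray(paternal_fpkm, dtype=float)
    if (der < 0).any():
        raise ValidationError("expression values must be non-negative")
    de_mat = np.asarray(de_vs_maternal, dtype=bool)
    de_pat = np.asarray(de_vs_paternal, dtype=bool)
    mpv = midparent(mat, pat)
    log2_dev = np.log2((der + epsilon) / (mpv + epsilon))
    labels = np.select(
        [
            np.abs(log2_dev) < 1.0,
            (der >= 2.0 * mat) & (der >= 2.0 * pat),
            (der <= mat / 2.0) & (der <= pat / 2.0),
            de_pat & ~de_mat,
            de_mat & ~de_pat,
        ],
        [
            "additive",
            "transgressive_up",
            "transgressive_down",
            "maternal_dominant",
            "paternal_dominant",
        ],
        default="ambiguous",
    )
    index = (
        derived_fpkm.index
        if isinstance(derived_fpkm, pd.Series)
        else pd.RangeIndex(len(np.atleast_1d(der)))
    )
    return pd.DataFrame(
        {
            "mpv": np.atleast_1d(mpv),
            "log2_dev": np.atleast_1d(log2_dev),
            "additivity_class": np.atleast_1d(labels),
        },
        index=index,
    )


def additivity_summary(calls: pd.DataFrame | pd.Series) -> dict:
    """Counts and percentages per class, with the transgressive/dominance split.

    Percentages are over the classified total, rounded to one decimal. The
    dominance total is maternal + paternal dominant; the transgressive total
    is up + down.
    """
    labels = calls["additivity_class"] if isinstance(calls, pd.DataFrame) else calls
    if len(labels) == 0:
        raise ValidationError("additivity_summary requires >=1 call")
    counts = labels.value_counts().reindex(ADDITIVITY_CLASSES, fill_value=0)
    total = int(counts.sum())
    non_additive = total - int(counts["additive"])
    return {
        "total": total,
        "counts": {k: int(v) for k, v in counts.items()},
        "percent": {k: percent(v, total) for k, v in counts.items()},
        "additive": int(counts["additive"]),
        "additive_percent": percent(counts["additive"], total),
        "non_additive": non_additive,
        "non_additive_percent": percent(non_additive, total),
        "transgressive_total": int(counts["transgressive_up"] + counts["transgressive_down"]),
        "dominance_total": int(counts["maternal_dominant"] + counts["paternal_dominant"]),
    }


def assign_patterns(
    deg_vs_maternal: pd.DataFrame, deg_vs_paternal: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Assign four-cluster / four-group expression patterns from paired DEG calls.

    Both inputs are per-gene DEG tables (from :func:`~polyhyb.expression.call_degs`
    of the derived line versus that parent) carrying ``log2_ratio`` and
    ``status``. Genes DE versus *both* parents get a cluster; genes DE versus
    *either* parent get a group, using the raw ratio sign for the
    non-significant side (a ratio of exactly 0 breaks toward "down" and is
    logged). Genes present in only one table are excluded with a warning.
    """
    shared = deg_vs_maternal.index.intersection(deg_vs_paternal.index)
    dropped = len(deg_vs_maternal.index.union(deg_vs_paternal.index)) - len(shared)
    if dropped:
        logger.warning("%d gene(s) lack one parent comparison; excluded", dropped)
    dm = deg_vs_maternal.loc[shared]
    dp = deg_vs_paternal.loc[shared]

    def _direction(table: pd.DataFrame) -> np.ndarray:
        sig = table["status"].to_numpy()
        raw = np.where(table["log2_ratio"].to_numpy() > 0, "up", "down")
        n_ties = int((table["log2_ratio"].to_numpy() == 0).sum())
        if n_ties:
            logger.info("%d zero log2-ratio tie(s) broke toward 'down'", n_ties)
        return np.where(sig == "not_de", raw, sig)

    vs_mat = _direction(dm)
    vs_pat = _direction(dp)
    de_mat = dm["status"].to_numpy() != "not_de"
    de_pat = dp["status"].to_numpy() != "not_de"
    numbers = np.array([PATTERN_GRID[(m, p)] for m, p in zip(vs_mat, vs_pat)])

    assignment = pd.DataFrame(
        {
            "vs_maternal": vs_mat,
            "vs_paternal": vs_pat,
            "cluster": pd.array(
                np.where(de_mat & de_pat, numbers, np.nan), dtype="Int64"
            ),
            "group": pd.array(
                np.where(de_mat | de_pat, numbers, np.nan), dtype="Int64"
            ),
        },
        index=shared,
    )
    counts = {
        "clusters": {
            k: int((assignment["cluster"] == k).sum()) for k in (1, 2, 3, 4)
        },
        "groups": {k: int((assignment["group"] == k).sum()) for k in (1, 2, 3, 4)},
    }
    counts["clustered_total"] = sum(counts["clusters"].values())
    counts["grouped_total"] = sum(counts["groups"].values())
    return assignment, counts
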