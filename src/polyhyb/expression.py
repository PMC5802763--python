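"""FPKM, the Audic-Claverie digital-expression test, DEG calling, homolog
filtering and qPCR relative-expression math.

The core statistic is the Audic-Claverie test for comparing a read count
between two libraries of known size. Conditional on observing ``x`` reads of a
gene in a library of ``N1`` reads, the count ``y`` in a second library of
``N2`` reads follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

which is a negative-binomial law with ``r = x + 1`` successes and success
probability ``N1/(N1+N2)``. The probability mass is evaluated in log space
(log-gamma) for overflow safety, and the reported p-value is the two-sided
doubled tail, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ValidationError

#: pseudo-FPKM added inside all log2 ratios to guard against log of zero.
DEFAULT_EPSILON = 1e-3
#: |log2 ratio| >= 1, i.e. a two-fold change, is the differential-expression cut.
LOG2_FOLD_CUTOFF = 1.0

#: inclusive homolog-standardization thresholds for cross-line gene pairing.
HOMOLOG_MAX_EVALUE = 9e-100
HOMOLOG_MIN_ALIGN_LENGTH = 200
HOMOLOG_MIN_IDENTITY = 90.0

__all__ = [
    "ExpressionSet",
    "fpkm",
    "audic_claverie_pmf",
    "audic_claverie_p",
    "call_degs",
    "deg_totals",
    "filter_homologs",
    "ddct",
    "DEFAULT_EPSILON",
]


@dataclass
class ExpressionSet:
    """Gene-level counts with the per-sample metadata needed for FPKM.

    counts : DataFrame, genes x samples, non-negative integers
    lengths : Series, gene length in bp (index aligned with counts)
    library_sizes : Series, total mapped reads per sample
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    _fpkm: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        counts = self.counts.to_numpy()
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValidationError("every gene needs a length")
        if (self.lengths <= 0).any():
            raise ValidationError("gene lengths must be positive")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
            raise ValidationError("every sample needs a positive library size")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def fpkm(self) -> pd.DataFrame:
        """Fragments per kilobase per million mapped reads: 1e9*C/(N*L)."""
        if self._fpkm is None:
            self._fpkm = (
                1e9
                * self.counts.div(self.library_sizes, axis=1).div(self.lengths, axis=0)
            )
        return self._fpkm


def fpkm(count, length_bp, library_size):
    """FPKM of a single measurement: ``1e9 * count / (library_size * length_bp)``."""
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (length_bp <= 0).any():
        raise ValidationError("gene length must be positive")
    if (library_size <= 0).any():
        raise ValidationError("library size must be positive")
    if (count < 0).any():
        raise ValidationError("count must be non-negative")
    out = 1e9 * count / (library_size * length_bp)
    return float(out) if out.ndim == 0 else out


def _check_counts(x) -> np.ndarray:
    arr = np.asarray(x)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be non-negative integers")
    return arr.astype(np.int64)


def audic_claverie_pmf(x, y, n1: float = 1.0, n2: float = 1.0):
    """p(y | x): probability of count ``y`` in library 2 given ``x`` in library 1.

    Evaluated through log-gamma so large counts do not overflow. With equal
    library sizes this reduces to ``C(x+y, y) / 2**(x+y+1)``.
    """
    x = _check_counts(x)
    y = _check_counts(y)
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")
    ratio = n2 / n1
    log_pmf = (
        y * math.log(ratio)
        + special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        - (x + y + 1) * math.log1p(ratio)
    )
    out = np.exp(log_pmf)
    return float(out) if out.ndim == 0 else out


def _conditional_tails(x, y, n1: float, n2: float):
    """``(P(Y<=y|x), P(Y>=y|x))`` for the conditional law of library 2 given 1.

    The lower tail is the negative-binomial CDF, computed through the
    regularized incomplete beta function; the upper tail is its complement
    plus the point mass at ``y``.
    """
    p_success = n1 / (n1 + n2)
    pmf = audic_claverie_pmf(x, y, n1, n2)
    lower = special.betainc(x + 1.0, y + 1.0, p_success)  # P(Y <= y)
    upper = 1.0 - lower + pmf  # P(Y >= y)
    return lower, upper


def audic_claverie_p(x, y, n1: float = 1.0, n2: float = 1.0):
    """Two-sided Audic-Claverie p-value: twice the smallest tail, capped at 1.

    The conditional law is evaluated in both directions (count 2 given count
    1, and count 1 given count 2) and the smallest of the four tails is
    doubled, so the result is invariant to which library is named first.
    With equal library sizes this reduces to
    ``min(1, 2*min(P(Y<=y|x), P(Y>=y|x)))``.
    """
    x = _check_counts(x)
    y = _check_counts(y)
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")
    lo_d, up_d = _conditional_tails(x, y, n1, n2)
    lo_s, up_s = _conditional_tails(y, x, n2, n1)
    smallest = np.minimum(np.minimum(lo_d, up_d), np.minimum(lo_s, up_s))
    out = np.minimum(1.0, 2.0 * smallest)
    return float(out) if np.ndim(out) == 0 else out


def call_degs(
    expr: ExpressionSet,
    sample_a: str,
    sample_b: str,
    epsilon: float = DEFAULT_EPSILON,
    p_threshold: float | None = None,
    fdr: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Call differential expression of ``sample_b`` relative to ``sample_a``.

    Only genes detected (count > 0) in at least one of the two samples are
    testable. ``log2_ratio = log2((fpkm_b + eps) / (fpkm_a + eps))``; a gene is
    ``up``/``down`` when ``|log2_ratio| >= 1`` and, if ``p_threshold`` is set,
    its (optionally Benjamini-Hochberg adjusted) Audic-Claverie p-value passes.
    Returns the per-gene table and ``{"up", "down", "total"}`` tallies.
    """
    for s in (sample_a, sample_b):
        if s not in expr.counts.columns:
            raise ValidationError(f"sample {s!r} not in expression set")
    ca = expr.counts[sample_a]
    cb = expr.counts[sample_b]
    testable = (ca > 0) | (cb > 0)
    if not testable.any():
        raise ValidationError(f"no gene detected in either {sample_a} or {sample_b}")

    fa = expr.fpkm.loc[testable, sample_a]
    fb = expr.fpkm.loc[testable, sample_b]
    log2_ratio = np.log2((fb + epsilon) / (fa + epsilon))
    n1 = float(expr.library_sizes[sample_a])
    n2 = float(expr.library_sizes[sample_b])
    p = audic_claverie_p(
        ca[testable].to_numpy(), cb[testable].to_numpy(), n1, n2
    )
    p = np.atleast_1d(p)
    p_eff = p
    if p_threshold is not None and fdr:
        p_eff = stats.false_discovery_control(p, method="bh")

    significant = np.ones(len(p), dtype=bool)
    if p_threshold is not None:
        significant = p_eff <= p_threshold
    status = np.where(
        (log2_ratio >= LOG2_FOLD_CUTOFF) & significant,
        "up",
        np.where((log2_ratio <= -LOG2_FOLD_CUTOFF) & significant, "down", "not_de"),
    )
    table = pd.DataFrame(
        {
            "count_a": ca[testable],
            "count_b": cb[testable],
            "fpkm_a": fa,
            "fpkm_b": fb,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "status": status,
        },
        index=expr.counts.index[testable],
    )
    table.index.name = "gene_id"
    return table, deg_totals(table["status"])


def deg_totals(status: pd.Series) -> dict:
    """Up/down/total tallies of a status vector."""
    up = int((status == "up").sum())
    down = int((status == "down").sum())
    return {"up": up, "down": down, "total": up + down}


def filter_homologs(
    matches: pd.DataFrame,
    max_evalue: float = HOMOLOG_MAX_EVALUE,
    min_align_length: int = HOMOLOG_MIN_ALIGN_LENGTH,
    min_identity: float = HOMOLOG_MIN_IDENTITY,
    reciprocal: bool = False,
) -> pd.DataFrame:
    """Reduce a BLAST match table to a one-to-one cross-line gene pairing.

    A pair is retained iff ``evalue <= max_evalue`` AND ``alignment_length >=
    min_align_length`` AND ``identity >= min_identity`` (thresholds inclusive).
    Retained pairs are resolved to one-to-one greedily by best e-value, then
    longest alignment, then lexicographic ids — so the result is invariant to
    input row order. With ``reciprocal=True`` only pairs that are each other's
    best hit under the same ordering survive.
    """
    required = {"query_id", "subject_id", "evalue", "alignment_length", "identity"}
    missing = required - set(matches.columns)
    if missing:
        raise ValidationError(f"match table lacks column(s): {sorted(missing)}")
    kept = matches[
        (matches["evalue"] <= max_evalue)
        & (matches["alignment_length"] >= min_align_length)
        & (matches["identity"] >= min_identity)
    ]
    kept = kept.sort_values(
        ["evalue", "alignment_length", "query_id", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    if reciprocal:
        best_by_query = kept.drop_duplicates("query_id")
        best_by_subject = kept.drop_duplicates("subject_id")
        pairs = set(zip(best_by_query["query_id"], best_by_query["subject_id"])) & set(
            zip(best_by_subject["query_id"], best_by_subject["subject_id"])
        )
        mask = [
            (q, s) in pairs for q, s in zip(kept["query_id"], kept["subject_id"])
        ]
        kept = kept[mask]
    used_q: set = set()
    used_s: set = set()
    rows = []
    for row in kept.itertuples(index=False):
        if row.query_id in used_q or row.subject_id in used_s:
            continue
        used_q.add(row.query_id)
        used_s.add(row.subject_id)
        rows.append(row)
    return pd.DataFrame(rows, columns=kept.columns).reset_index(drop=True)


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    dCT = CT(target) - CT(reference) within each of sample and control;
    ddCT = dCT(sample) - dCT(control); returns ``2**-ddCT``.
    """
    values = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(math.isfinite(v) for v in values):
        raise ValidationError("CT values must be finite")
    ddct_value = (ct_target_sample - ct_ref_sample) - (
        ct_target_control - ct_ref_control
    )
    return 2.0**-ddct_value
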