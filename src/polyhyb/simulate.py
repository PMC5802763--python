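"""Synthetic parent/hybrid/allopolyploid data with planted, recoverable truth.

Three generators emulate the three assays of a line-series study — dominant
marker profiles, MSAP dual-lane methylation tables, and gene-level RNA-Seq
counts — so that every downstream classifier can be exercised, and its
planted-parameter recovery measured, without any external data.

Defaults mirror the scale and rates of a synthesized Chrysanthemum x
Tanacetum series: ~740 distinct parental marker fragments with a ~13%
hybridization loss rate, ~500 CCGG sites with a mostly-diagonal
hybrid-to-allopolyploid methylation transition matrix, and ~21,000
homolog-paired genes in a roughly 2:1 additive:non-additive mixture with
repression-biased transgressive expression.

All three generators take a single integer seed; independent sub-streams per
generator are derived from ``(seed, stream_id)`` so simulations of different
assays never share randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import ExpressionSet
from .msap import STATES, state_to_lanes

__all__ = [
    "MarkerSimSpec",
    "MsapSimSpec",
    "ExprSimSpec",
    "simulate_markers",
    "simulate_msap",
    "simulate_expression",
    "EXPRESSION_CLASSES",
]

EXPRESSION_CLASSES = (
    "additive",
    "transgressive_up",
    "transgressive_down",
    "maternal_dominant",
    "paternal_dominant",
)

_MARKER_STREAM, _MSAP_STREAM, _EXPR_STREAM = 1, 2, 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class MarkerSimSpec:
    """Marker-fragment simulation parameters.

    ``n_fragments`` distinct parental fragments are assigned an origin
    (present in both parents / maternal only / paternal only). Each is lost in
    the hybrid with ``loss_rate_hybridization``; a hybrid-lost fragment
    reappears in an allopolyploid with ``recovery_rate``, a hybrid-present one
    disappears with ``loss_rate_polyploidization``. De novo fragments (absent
    from both parents, arising in the hybrid) occur at ``novel_rate`` per
    parental fragment and are subject to the same polyploidization loss.
    """

    n_fragments: int = 737
    p_common: float = 0.364
    p_maternal_only: float = 0.349
    p_paternal_only: float = 0.287
    loss_rate_hybridization: float = 0.127
    loss_rate_polyploidization: float = 0.009
    recovery_rate: float = 0.106
    novel_rate: float = 0.005
    n_allopolyploids: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_fragments < 1 or self.n_allopolyploids < 1:
            raise ValidationError("n_fragments and n_allopolyploids must be >= 1")
        for name in (
            "p_common",
            "p_maternal_only",
            "p_paternal_only",
            "loss_rate_hybridization",
            "loss_rate_polyploidization",
            "recovery_rate",
            "novel_rate",
        ):
            _check_prob(name, getattr(self, name))
        total = self.p_common + self.p_maternal_only + self.p_paternal_only
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(f"origin proportions must sum to 1, got {total}")


def simulate_markers(spec: MarkerSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a fragment x line presence matrix plus per-fragment truth.

    Returns ``(matrix, truth)``. ``matrix`` has columns ``maternal``,
    ``paternal``, ``hybrid``, ``allopolyploid_1..k``; ``truth`` records each
    fragment's ``origin``, whether it was lost at hybridization, and its fate
    per allopolyploid (``none`` / ``H_only`` / ``P_only`` / ``H_P``) with the
    gain/loss direction implied by the origin (``novel`` fragments are gains).
    """
    rng = _rng(spec.seed, _MARKER_STREAM)
    n = spec.n_fragments
    origin = rng.choice(
        ["common", "maternal_only", "paternal_only"],
        size=n,
        p=[spec.p_common, spec.p_maternal_only, spec.p_paternal_only],
    )
    n_novel = int(rng.binomial(n, spec.novel_rate))
    origin = np.concatenate([origin, np.repeat("novel", n_novel)])
    total = n + n_novel

    maternal = np.isin(origin, ["common", "maternal_only"]).astype(np.int8)
    paternal = np.isin(origin, ["common", "paternal_only"]).astype(np.int8)
    parental = (maternal | paternal).astype(bool)

    lost_hyb = np.zeros(total, dtype=bool)
    lost_hyb[parental] = rng.random(parental.sum()) < spec.loss_rate_hybridization
    hybrid = np.where(parental, ~lost_hyb, True).astype(np.int8)

    matrix = {"maternal": maternal, "paternal": paternal, "hybrid": hybrid}
    truth = {"origin": origin, "lost_at_hybridization": lost_hyb}
    for j in range(1, spec.n_allopolyploids + 1):
        name = f"allopolyploid_{j}"
        recovered = rng.random(total) < spec.recovery_rate
        lost_poly = rng.random(total) < spec.loss_rate_polyploidization
        in_hybrid = hybrid == 1
        present = np.where(in_hybrid, ~lost_poly, parental & recovered)
        matrix[name] = present.astype(np.int8)
        fate = np.full(total, "none", dtype=object)
        fate[~in_hybrid & ~present] = "H_only"  # altered in hybrid, persists
        fate[~in_hybrid & present] = "H_P"  # altered in hybrid, recovered
        fate[in_hybrid & ~present & parental] = "P_only"  # altered only here
        # novel fragments: present in hybrid is itself the alteration (gain)
        novel = origin == "novel"
        fate[novel & present] = "H_only"
        fate[novel & ~present] = "H_P"
        truth[f"fate_{name}"] = fate

    ids = [f"frag_{i:05d}" for i in range(total)]
    index = pd.Index(ids, name="fragment_id")
    return pd.DataFrame(matrix, index=index), pd.DataFrame(truth, index=index)


@dataclass(frozen=True)
class MsapSimSpec:
    """MSAP site simulation parameters.

    Hybrid states are drawn from ``state_probs`` over (I, II, III, U); each
    allopolyploid's state is drawn from the corresponding row of the 4x4
    stochastic ``transition_probs`` (hybrid state -> allopolyploid state),
    independently per allopolyploid. Defaults reproduce the observed state
    frequencies and a mostly-diagonal transition structure in which moves
    into U (increased methylation) outnumber moves out of it.
    """

    n_sites: int = 500
    state_probs: tuple[float, float, float, float] = (0.404, 0.254, 0.232, 0.110)
    transition_probs: tuple[tuple[float, ...], ...] = (
        (0.850, 0.083, 0.051, 0.016),  # from I
        (0.073, 0.854, 0.000, 0.073),  # from II
        (0.050, 0.000, 0.848, 0.102),  # from III
        (0.051, 0.078, 0.064, 0.807),  # from U
    )
    n_allopolyploids: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1 or self.n_allopolyploids < 1:
            raise ValidationError("n_sites and n_allopolyploids must be >= 1")
        probs = np.asarray(self.state_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or not math.isclose(
            probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValidationError("state_probs must be 4 non-negative values summing to 1")
        matrix = np.asarray(self.transition_probs, dtype=float)
        if matrix.shape != (4, 4) or (matrix < 0).any():
            raise ValidationError("transition_probs must be a non-negative 4x4 matrix")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each transition_probs row must sum to 1")


def simulate_msap(spec: MsapSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an MSAP dual-lane table plus per-site truth states.

    Returns ``(table, truth)``. ``table`` has per line the two binary lane
    columns ``<line>_H`` / ``<line>_M`` implied by the state under the
    standard mapping; ``truth`` holds the planted state per site and line.
    """
    rng = _rng(spec.seed, _MSAP_STREAM)
    state_idx = {s: i for i, s in enumerate(STATES)}
    hybrid = rng.choice(list(STATES), size=spec.n_sites, p=list(spec.state_probs))
    matrix = np.asarray(spec.transition_probs, dtype=float)

    lines = {"hybrid": hybrid}
    for j in range(1, spec.n_allopolyploids + 1):
        rows = matrix[[state_idx[s] for s in hybrid]]
        cumulative = rows.cumsum(axis=1)
        u = rng.random(spec.n_sites)
        chosen = np.minimum((u[:, None] >= cumulative).sum(axis=1), 3)
        lines[f"allopolyploid_{j}"] = np.asarray(STATES)[chosen]

    index = pd.Index([f"site_{i:05d}" for i in range(spec.n_sites)], name="site_id")
    truth = pd.DataFrame(lines, index=index)
    table = {}
    for line, states in lines.items():
        lanes = np.array([state_to_lanes(s) for s in states], dtype=np.int8)
        table[f"{line}_H"] = lanes[:, 0]
        table[f"{line}_M"] = lanes[:, 1]
    return pd.DataFrame(table, index=index), truth


@dataclass(frozen=True)
class ExprSimSpec:
    """Expression simulation parameters.

    Per-gene parental means are lognormal around ``baseline_mean`` (an
    FPKM-scale level). The derived line's mean is planted by class: the MPV
    (additive), ``fold`` x the higher parent (transgressive_up), the lower
    parent / ``fold`` (transgressive_down), or exactly one parent's mean with
    the other parent planted ``2*fold`` higher (dominance; under a two-fold
    midparent rule only dominance toward the lower parent is detectable).
    Counts are negative-binomial with ``variance = mu + dispersion * mu^2``;
    ``dispersion=0`` is the noiseless limit (counts = rounded expectation).
    The default class mixture matches the observed hybrid proportions
    (~65.6% additive, repression-biased transgressive classes).
    """

    n_genes: int = 21056
    class_mix: tuple[float, float, float, float, float] = (
        13811 / 21056,
        618 / 21056,
        3787 / 21056,
        1879 / 21056,
        961 / 21056,
    )
    baseline_mean: float = 20.0
    dispersion: float = 0.05
    fold: float = 4.0
    library_sizes: tuple[float, float, float] = (44_150_000, 45_280_000, 45_240_000)
    gene_length_range: tuple[int, int] = (200, 1500)
    seed: int = 0
    parent_spread_sd: float = 0.4  # lognormal sigma of the parent/parent ratio

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (5,) or (mix < 0).any() or not math.isclose(
            mix.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValidationError("class_mix must be 5 non-negative values summing to 1")
        if self.fold < 2.0:
            raise ValidationError(
                "fold must be >= 2 (planted classes would straddle the two-fold cut)"
            )
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if len(self.library_sizes) != 3 or any(s <= 0 for s in self.library_sizes):
            raise ValidationError("library_sizes must be 3 positive totals")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValidationError("gene_length_range must be a positive interval")


def simulate_expression(spec: ExprSimSpec) -> tuple[ExpressionSet, pd.DataFrame]:
    """Simulate counts for (maternal, paternal, hybrid) plus per-gene truth.

    Returns ``(expression_set, truth)``; ``truth`` carries the planted class
    and the planted per-line mean expression levels (FPKM scale).
    """
    rng = _rng(spec.seed, _EXPR_STREAM)
    n = spec.n_genes
    classes = rng.choice(EXPRESSION_CLASSES, size=n, p=list(spec.class_mix))

    sigma = 0.6
    base = rng.lognormal(mean=math.log(spec.baseline_mean), sigma=sigma, size=n)
    ratio = rng.lognormal(mean=0.0, sigma=spec.parent_spread_sd, size=n)

    maternal = base.copy()
    paternal = base * ratio
    sep = 2.0 * spec.fold  # parental separation planted for dominance genes
    is_md = classes == "maternal_dominant"
    is_pd = classes == "paternal_dominant"
    paternal[is_md] = maternal[is_md] * sep
    maternal[is_pd] = paternal[is_pd] * sep

    mpv = (maternal + paternal) / 2.0
    high = np.maximum(maternal, paternal)
    low = np.minimum(maternal, paternal)
    hybrid = np.select(
        [
            classes == "additive",
            classes == "transgressive_up",
            classes == "transgressive_down",
            is_md,
            is_pd,
        ],
        [mpv, spec.fold * high, low / spec.fold, maternal, paternal],
    )

    lengths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=n
    )
    samples = ("maternal", "paternal", "hybrid")
    lib = dict(zip(samples, spec.library_sizes))
    means = {"maternal": maternal, "paternal": paternal, "hybrid": hybrid}
    counts = {}
    for s in samples:
        mu = means[s] * lengths * lib[s] / 1e9
        if spec.dispersion == 0:
            counts[s] = np.rint(mu).astype(np.int64)
        else:
            r = 1.0 / spec.dispersion
            p = r / (r + mu)
            counts[s] = rng.negative_binomial(r, p)

    index = pd.Index([f"gene_{i:06d}" for i in range(n)], name="gene_id")
    expr = ExpressionSet(
        counts=pd.DataFrame(counts, index=index),
        lengths=pd.Series(lengths, index=index, name="length_bp"),
        library_sizes=pd.Series(lib, name="library_size"),
    )
    truth = pd.DataFrame(
        {
            "class": classes,
            "maternal_mean": maternal,
            "paternal_mean": paternal,
            "hybrid_mean": hybrid,
        },
        index=index,
    )
    return expr, truth
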