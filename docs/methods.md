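# Methods

## Study design and data model

The package analyses a line series of four roles: a maternal parent, a
paternal parent, their F1 hybrid, and k ≥ 1 allopolyploids obtained by
genome doubling of that hybrid. Three data types are consumed, all as
header-bearing TSV tables: dominant-marker presence/absence matrices
(fragment × line, values 0/1), MSAP dual-lane tables (site × line with one
`<line>_H` and one `<line>_M` binary column per line), and gene-level read
counts with per-gene lengths and per-sample library sizes. Replicate
individuals within a line (marker assays are typically run on ~3 plants per
line) can be collapsed to a single profile by majority presence before
classification; ties with an even replicate count are called present.

## Marker inheritance typing

Fragments present in the target line are classified by parental origin from
the (maternal, paternal) presence pair: both → common, maternal only →
maternal-specific, paternal only → paternal-specific, neither → novel.
Percentages use the target line's fragment total, rounded half-away-from-zero
to one decimal (the convention that reproduces published-style tables;
Python's default banker's rounding does not).

Alteration typing is a pure function of the four-call signature
(maternal, paternal, hybrid, allopolyploid). For parental fragments
(present in ≥ 1 parent), the expected state downstream is presence (union
inheritance), and the nine loss signatures map to:

| hybrid | allopolyploid | type |
|---|---|---|
| absent | absent | H-only (hybridization-induced, transmitted) |
| present | absent | P-only (polyploidization-induced) |
| absent | present | H–P (hybridization-induced, reverted) |

Each allopolyploid is typed independently against the single hybrid, and
alteration percentages use that allopolyploid's own loss subtotal. De novo
fragments (absent from both parents) are gains: retained gains are labelled
H-only and reverted gains H–P with `direction="gain"`, and they are tallied
outside the loss table — the published-style subtotal counts losses only,
and no published tally covers gains, so mixing them would change the
denominators. A fragment absent from all four lines is unscorable and
rejected.

## MSAP methylation states and transitions

The HpaII/MspI isoschizomer pair both cut CCGG but respond differently to
cytosine methylation, so the two lane calls identify the state:
(1,1) → I non-methylated, (0,1) → II fully methylated (internal cytosine,
both strands), (1,0) → III hemi-methylated, (0,0) → U (absent from both
lanes). U is modelled as a per-line state rather than a "type IV" label
because absence is only interpretable relative to a change between lines.
The methylation level of a line is (#II + #III) / (#I + #II + #III); U sites
are undetected and excluded from the denominator.

Hybrid → allopolyploid transitions take their direction from an exhaustive
lookup of the ten directional patterns: moves out of U (U→I, U→III, U→II)
and demethylations II→I, III→I are decreases; moves into U (I→U, III→U,
II→U) and methylations I→II, I→III are increases. II↔III swaps have no
defined order on the gel pattern and are reported as `other` rather than
being assigned a direction. Sites that are U in both the hybrid and an
allopolyploid are never observed and are ignored. Per-category summaries
report the mean and the standard error of the mean (sample SD/√n) across
the allopolyploid replicates supplied — the replicate axis is an input, not
a hard-coded n = 3 — and grand totals are sums of the directional category
means.

## Digital expression and additivity

Expression level is FPKM = 10⁹·C/(N·L) with C the gene's read count, N the
sample's total mapped reads and L the gene length in bp. Significance of a
count difference between two libraries uses the Audic–Claverie conditional
law: given x reads in a library of N₁, the count y in a library of N₂ has

p(y|x) = (N₂/N₁)ʸ · (x+y)! / (x!·y!·(1+N₂/N₁)^(x+y+1)),

a negative binomial with r = x+1 and success probability N₁/(N₁+N₂). The
mass is evaluated via log-gamma for overflow safety and the tails via the
regularized incomplete beta function. The reported two-sided p doubles the
smallest of the four tails taken over both conditioning directions (y given
x and x given y), so swapping the two libraries leaves the p-value exactly
unchanged — the conditional tails alone are not swap-symmetric; with equal
library sizes this reduces to the plain doubled conditional tail.

DEG calling uses log₂((FPKM_b + ε)/(FPKM_a + ε)) with ε = 0.001 guarding
zeros; a gene is up/down when |log₂ ratio| ≥ 1 (two-fold). Only genes
detected in at least one sample of the pair are testable. A p-value
threshold (optionally Benjamini–Hochberg adjusted) can be enabled, but the
default criterion is fold-change only, matching the printed criterion of
the summary tables this package mirrors. Cross-line gene spaces come from
BLAST tabular matches filtered by the inclusive thresholds E ≤ 9e−100,
alignment ≥ 200 bp, identity ≥ 90%, resolved to one-to-one greedily by best
e-value, then longest alignment, then lexicographic ids (order-invariant);
reciprocal-best resolution is available as an option. qPCR validation math
is the standard 2^−ΔΔCT.

A gene is additive when its derived-line level is within two-fold of the
midparent value MPV = (maternal + paternal)/2 (same ε inside the log).
Non-additive genes are transgressive up/down when at least two-fold
outside both parents, else dominant toward the parent they are *not* DE
against (DE vs exactly one parent), else ambiguous. "Statistically equal to
one parent" is deliberately operationalized as "not DE under the module's
two-fold criterion"; genes non-additive versus the MPV but DE versus both
or neither parent, without a transgressive margin, stay `ambiguous` rather
than being forced into a named class. Note an arithmetic consequence of the
MPV rule: a derived level equal to the *higher* parent is always within
two-fold of the MPV, so detectable expression dominance is dominance toward
the lower parent — consistent with dominance being observed mostly among
down-regulated genes.

Detection for the Venn partition is FPKM > 0 by default (configurable
`detection_fpkm`); the partition's seven categories are exhaustive and
disjoint over genes expressed anywhere. Pattern clusters (genes DE vs both
parents) and groups (DE vs either) use the sign grid (down,down) → 1,
(down,up) → 2, (up,down) → 3, (up,up) → 4, with the raw log₂-ratio sign
standing in on a non-significant side; an exact zero ratio breaks toward
"down" and is logged.

## Synthetic data

The generators' defaults emulate the study conditions the classifiers
target:

* **Markers** — 737 distinct parental fragments (origin split
  0.364/0.349/0.287 common/maternal-only/paternal-only), hybridization loss
  rate 0.127, recovery rate 0.106, polyploidization loss rate 0.009, de novo
  gain rate 0.005, three allopolyploids. These rates are back-calculated
  from an observed series of ~630 hybrid fragments with ~100 alterations per
  allopolyploid, ~85% of them hybridization-induced.
* **MSAP** — 500 CCGG sites with hybrid state probabilities
  (I, II, III, U) = (0.404, 0.254, 0.232, 0.110) and a mostly-diagonal
  transition matrix whose off-diagonal mass reproduces observed per-category
  transition counts, including the ~2:1 excess of methylation increases
  over decreases after genome doubling.
* **Expression** — 21,056 genes with class mixture
  (additive, transgressive up, transgressive down, maternal dominant,
  paternal dominant) = (0.6559, 0.0293, 0.1799, 0.0892, 0.0456), i.e. the
  observed ≈ 65.6%/34.4% additive split with repression-biased transgression.
  Per-gene baseline levels are lognormal with median 20 FPKM (σ = 0.6);
  parent/parent ratios lognormal (σ = 0.4). The derived mean is the MPV
  (additive), fold × the higher parent (transgressive up), the lower parent
  ÷ fold (transgressive down), or exactly one parent's level with the other
  parent planted 2·fold higher (dominance — planted toward the lower parent
  because, as noted above, dominance toward the higher parent cannot exceed
  the two-fold MPV criterion). Default fold = 4, safely beyond the two-fold
  decision boundary; fold < 2 is rejected because planted classes would
  straddle the criterion. Counts are negative-binomial with
  var = μ + φμ², default φ = 0.05 (moderate bulk RNA-Seq overdispersion);
  φ = 0 is the noiseless limit with counts equal to the rounded expectation,
  which downstream classifiers must recover with zero errors. Library sizes
  default to ~44–45 million reads and gene lengths are uniform on
  200–1500 bp (mean ≈ 850 bp, matching typical de novo unigene lengths).

One integer seed drives a whole simulation; each generator derives its own
`default_rng((seed, stream_id))` sub-stream, so assays are independent but
jointly reproducible. What the generator does *not* emulate: gel scoring
noise and band-size ambiguity, mappability and GC bias, homeolog
cross-mapping between the merged subgenomes, and biological replicate
structure (one library per line, as in the target design). Passing recovery
tests therefore demonstrates correctness of the classification arithmetic
under the stated noise model, not robustness to those real-data artifacts.

## Numerical choices

* Percentages round half-away-from-zero to one decimal.
* Summary means/SEs round to two decimals; SE is 0 for a single replicate.
* ε = 0.001 pseudo-FPKM shared by all log-ratio computations.
* Homolog thresholds are inclusive (≤ / ≥) at the boundary.
* The Audic–Claverie p symmetrizes over conditioning direction (above).
* Pipeline outputs are written with sorted JSON keys; reruns on identical
  inputs are byte-identical.

## Problem sizes used in tests and the acceptance script

Sampling-based checks use 5,000–10,000 items (fragments, sites, genes) with
fixed seeds and 3-binomial-SE / ±3-percentage-point tolerances; these sizes
put the Monte-Carlo error well inside those bands while keeping the whole
suite at a few seconds.

## Known limitations

* Dominant markers cannot distinguish heterozygous from homozygous presence;
  "loss" conflates sequence change, restriction-site change and amplification
  failure.
* MSAP sees only CCGG sites and cannot separate CG from CHG context; the
  absent-both-lanes state is uninformative about which cytosine changed.
* The Audic–Claverie test models technical (Poisson) sampling only; with one
  library per line, biological variance is not estimable, which is why the
  default DEG criterion is the fold-change cut rather than a p threshold.
* The dominance operationalization depends on the DEG criterion; a different
  fold cut moves genes between dominance and ambiguous classes.
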