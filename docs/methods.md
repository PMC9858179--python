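# Methods

## The problem

A near-isogenic line (NIL) panel carries overlapping donor introgressions
("Shongwan Charmi", SC) on one chromosome in a uniform recurrent-parent
background ("Piel de Sapo", PS). Traits are relative abundances of fruit
volatile organic compounds (VOCs) measured on replicate fruits per line.
The questions the pipeline answers are: which traits differ from the
recurrent parent, where on the chromosome the responsible locus (QTL)
lies, and whether each VOC QTL colocalizes with the climacteric-ripening
QTL region (here *ETHQB3.5*, the interval between markers CMPSNP374 and
AI_14-F04, 1.24 Mb on the physical map) — colocalization is read as
ethylene dependence of the volatile.

## Preprocessing

Peak areas are converted to per-sample percentages of the total area
(compositional normalization), zeros — detection-limit censoring — are
replaced by the single minimum non-zero value of the whole matrix, and the
result is log2-transformed. The substitution constant is global, not
per-trait, because the censoring floor is an instrument property; a
per-trait option exists for sensitivity analysis. Normalization precedes
substitution so that the constant lives on the percent scale of the
reported tables.

## Screening and many-to-one comparisons

Each trait is screened by a one-way fixed-effects ANOVA with pedigree as
the factor; p-values are Benjamini–Hochberg adjusted across traits and
traits with adjusted p strictly below 0.05 are retained. Retention and
significance use strict inequalities so ties at the level are excluded
deterministically. A trait whose observations are all identical is
reported as F = 0, p = 1 (uninformative) by convention.

Retained traits are compared line-by-line against the control with a
two-sided Dunnett many-to-one test at level 0.05, using the pooled
within-group variance per trait. With group sizes n_i and control size
n_0, the contrast t statistics follow a multivariate t with df = N − k and
correlation ρ_ij = λ_i λ_j, λ_i = √(n_i/(n_i+n_0)). The adjusted p-value
P(max_i |T_i| ≥ |t_j|) is evaluated through the one-factor representation
T_i = (λ_i Z₀ + √(1−λ_i²) Z_i)/W with W² ~ χ²_df/df: conditioning on
(Z₀, W) the coordinates are independent, so the orthant probability is a
product of normal CDF differences integrated on a Gauss–Hermite (80 nodes,
Z₀) × Gauss–Legendre (48 nodes, W through the χ² quantile transform) grid.
The evaluation is deterministic and accurate to well below the 1e-3
working tolerance; tests cross-check it against `scipy.stats.dunnett`, a
large Monte-Carlo sample of the same multivariate t, the exact pooled
t-test in the single-contrast case, and a family-wise error simulation at
the study's replicate counts (21, 5, 7, 7, 9, 9).

Each Dunnett result is coded as a per-line significance pattern in
{+1, −1, 0}: the sign of the log2 mean difference against the control when
significant, else 0. Box-whisker outliers (beyond 1.5·IQR within a line)
are flagged for reporting only; nothing is removed automatically.

## Substitution mapping

Genotypes are marker-resolved; the interval between two adjacent markers
is a *bin*, whose state for a line is SC or PS when the flanking calls
agree and UNCERTAIN when they disagree (a recombination breakpoint lies
inside) or either call is missing. Coordinates are 1-based inclusive bp;
BED export converts to 0-based half-open.

A bin is *consistent* with a pattern when every significant line covers it
with SC (or UNCERTAIN) sequence and every informative non-significant line
with PS (or UNCERTAIN); all non-zero entries must share one sign, since a
single biallelic locus cannot move a trait in both directions. An all-zero
pattern is vacuously consistent everywhere and is reported as NO_SIGNAL
upstream. Lines may be flagged *lenient* (their non-significant entries
impose no constraint), for lines whose phenotype classification is
unreliable; the packaged reconstruction runs with no lenient lines, which
is what reproduces the published per-trait outcomes exactly (see
"Fixtures" below). Relaxing a line can only grow the consistent set — a
tested monotonicity property.

A call distinguishes the *strong core* — bins whose flank calls satisfy
every constraint exactly — from bins consistent only through uncertainty.
The reported primary interval is the marker-bounded hull of the selected
contiguous consistent run, i.e. the maximal region the data cannot
exclude. Colocalization with the region of interest and the left/right
position class are judged on the strong core (positive-length overlap
required), i.e. the region the data positively support; when a run has no
strong bin the full hull is used. This asymmetry is deliberate: the
maximal interval of a trait significant in every line reaches through the
recombination gap of the non-climacteric recombinant into the region of
interest, but only the core — ending at the region's left flanking
marker — is actually supported, and the published classification treats
such QTLs as independent.

When strict mapping fails (mixed signs or an empty consistent set) and the
dominant-direction fallback is enabled — on by default for compound
classes, off for individual VOCs — the rule is re-run once per sign with
opposite-signed lines excluded. Exactly one mappable sign yields a MAPPED
call in that direction; two mappable signs are two-QTL evidence and the
trait stays NOT_INTERPRETABLE, as does an empty result. Among multiple
consistent runs the ROI-intersecting one is preferred, then the one with
most bins, ties to the leftmost; the others are retained as alternates.
Scenario classes: (i) mapped and colocalizing, (ii) mapped elsewhere,
(iii) not interpretable. Ethylene labels: +1 for (i), −1 for (ii),
unclassified otherwise.

## Correlation network and clustering

The correlation network connects two screened traits when the absolute
Pearson correlation of their log2 profiles strictly exceeds 0.7; groups
are connected components, reported by descending size with ties broken by
the smallest member id. Zero-variance traits are assigned r = 0 against
everything.

Hierarchical clustering uses the distance d = 1 − |r| by default (the
absolute-correlation heatmap convention); d = 1 − r is available by
configuration. The Ward agglomerator is an explicit Lance–Williams
recurrence with total tie-breaking (lowest current node ids), in two
variants: `classic` applies the recurrence to the given distances
(hclust `ward.D` style, the default) and `squared` to squared distances
with square-root heights (`ward.D2`/SciPy style). Which variant and sign
convention the original analysis used is not recoverable, so the default
is asserted against this package's own oracles (a from-scratch centroid
recomputation and, for the squared variant, SciPy), not against published
figures. Cutting the k−1 highest merges yields k clusters (k = 6 by
default, matching the published heatmap). Two-way clustering applies the
same metric to sample profiles; axes too short to correlate over keep
input order under a trivial tree. Dendrograms export to Newick with
branch lengths equal to merge-height differences.

## Synthetic data generator

The generator emulates a NIL metabolite screen: for sample s of line L and
trait t,

    raw_st = 2^( μ_t + β_t·[state(L, b_t) = SC] + γ_t·f_{g_t,s} + ε_st ),

with ε ~ N(0, σ_t²) and per-sample latent factors f ~ N(0, 1) shared
within trait groups (producing correlation blocks), followed by
detection-limit censoring to zero below the q-quantile of the raw marginal
and per-sample compositional normalization. Everything is reproducible
bitwise from one seed; config generation and data generation use separate
seed streams.

Defaults emulate the study design: six lines with replicate counts
(21, 5, 7, 7, 9, 9), 161 traits, baseline μ ~ U(2, 8) log2 units, effect
β = 2 log2 units (a strong mQTL, the regime the published tables show),
σ = 0.5, censoring q = 0.1 (reproducing the many exact-zero cells of the
printed tables), a 0.15 fraction of traits carrying one QTL with balanced
signs, and five latent groups with loading 1 on half the traits. The QTL
fraction is kept a minority deliberately: under compositional
normalization a large mass of strong same-direction effects would shift
every other trait's relative abundance and manufacture spurious patterns;
at 0.15 with balanced signs the induced shift is well below the noise
floor, which is the realistic regime for a screen of this size.

Recovery experiments use a dedicated configuration (no latent blocks, no
censoring, effects only in breakpoint-free bins) so that recovery and
false-map rates measure the screening + mapping chain itself; recovery of
a planted QTL means the trait is MAPPED with the true bin inside the
primary interval. What passing these simulations does *not* show about
real data: effects there are not all equal-sized, censoring is
trait-dependent, correlation arises from shared biosynthetic pathways
rather than Gaussian factors, and line misclassification (the reason the
lenient flag exists) is not modelled.

## Fixtures

The packaged fixtures transcribe the published tables: the 15-marker
chromosome-3 physical map, per-line replicate counts and climacteric
classes, the 110 screened traits' printed means and per-line significance
signs, the 44 published per-trait QTL outcomes, and the published network
groups. The genotype matrix is a synthetic reconstruction (the source
ideogram is graphical): maximal SC blocks per line over the ordered
markers — SC3-5-7 SC through CMPSNP374; SC3-5-8 through MC215; SC3-5-12
from ECM208 onward; SC3-5-13 through AI_06-G01; SC3-5-14 through
AI_14-F04 — chosen as the minimal breakpoint placement that satisfies the
breakpoints stated in the text and reproduces all 44 published outcomes
and none of the 66 unmapped ones. One compound class is flagged
uninterpretable in the fixture, mirroring the published table's underline
convention for classes left unmapped by judgement; the engine's raw call
is still computed and kept.

## Numerical choices and limitations

- Dunnett quadrature: 80×48 Gauss nodes; adjusted p clipped to [0, 1];
  critical values by bisection on the same grid.
- Zero within-group variance: t statistics set to 0 (no evidence), F = 0,
  p = 1 when all observations are identical.
- Ward tie tolerance 1e-12; merge determinism is exact replay.
- Interval lengths in Mb round half-up to 2 decimals.
- The engine has no "position in doubt" state; doubtful placements
  surface as alternate runs and as the gap between the core and the full
  hull.
- Single-QTL model only: epistasis and two-locus architectures appear as
  NOT_INTERPRETABLE, never as multi-QTL calls.
- Problem sizes in the test suite (2000-replicate error simulations,
  20-seed recovery panels of 200 traits, 100-instance clustering oracles)
  are chosen so the full suite completes in a few minutes while keeping
  Monte-Carlo standard errors well inside the asserted tolerances.
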