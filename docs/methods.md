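# Methods

`dermocybe` re-implements, as a tested library, an integrative chemotaxonomic
workflow for dermocyboid *Cortinarius* (subgenus *Dermocybe*): HPLC-DAD
pigment profiling, pigment-group classification, basidiospore morphometrics,
chemo-phylogenetic congruence, and a dichotomous identification key.  This
note records the models, parameter choices and numerical conventions, and
what the synthetic-data generators do and do not emulate.

## Pigment profiles and the level encoding

Fifteen annotated anthraquinones (emodin-1,6-di-glycoside, …, 7,7'-biphyscion;
ids 1–15) serve as semi-quantitative characters.  A chromatogram is processed
as follows:

1. the three detector channels (428, 478, 519 nm, covering yellow to red
   absorbance) are summed pointwise;
2. a rolling-minimum baseline (window: 20 samples) is subtracted — the
   original protocol does not describe baselining, so this conservative
   choice is our own and is configurable (`baseline_window=0` disables it);
   because all simulated peaks share one width, the subtraction rescales all
   peak heights by a common factor and leaves relative heights untouched;
3. local maxima with topographic prominence ≥ 1% of the global maximum are
   detected (`scipy.signal.find_peaks`); peaks below **5%** of the tallest
   peak are discarded (the detection threshold of the original protocol);
   "manual peak addition" is replaced by a user-supplied `forced_apices`
   list;
4. relative heights are expressed in percent of the tallest peak (set to
   100); peaks **< 10%** are *trace* pigments, peaks **≥ 10%** *main*
   pigments.  The protocol's wording ("trace < 10% < main") is silent at
   exactly 10%; we close the upper class (10% → main);
5. peaks are assigned to library compounds whose reference retention time
   lies within `rt_match_tolerance` (default 0.1 min); one compound claims at
   most one peak, nearest apex first.  Libraries with compounds closer than
   twice the tolerance are rejected as unresolvable.  MS/UV–Vis confirmation
   is out of scope, so retention time is the only annotation evidence and the
   default tolerance is deliberately tight.

The packaged reference retention times are synthetic (the source figures
print no numeric axis values): compound *i* elutes at 1.0 + 1.2·*i* minutes.
They are fixed data, used consistently by the simulator and the annotator.
Channel weights split each compound's absorbance across the three channels
according to its colour family (yellow pigments load on 428 nm, red pigments
on 519 nm) and sum to one.

Unassigned peaks are reported as *unknown peaks* with their retention times —
mirroring the unidentified *C. ominosus* pigment near 5.5 min — and excluded
from all distance computations.

## Pigment groups

The four groups (Croceus, Malicorius, Ominosus, Sanguineus) are encoded as a
constraint rule plus curated member list, shipped as data (`groups.json`):

| group | required | forbidden | any-of |
|---|---|---|---|
| Croceus | 11 | 6 | — |
| Malicorius | 6, 11 | — | one of {12, 15} |
| Ominosus | 6, 7, 8 | 11, 14, 15 | — |
| Sanguineus | 7, 13 | 11 | — |

Assignment is two-staged: the constraint filter first, then — among surviving
groups — the nearest group centroid (mean level-weight vector of curated
members) under Bray-Curtis.  The centroid stage is what separates the
Ominosus and Sanguineus groups for the five profiles that satisfy both rule
sets.  With these rules the engine reproduces all fifteen curated
memberships; this 15/15 agreement is asserted in the acceptance tests.

Because published profiles carry only levels, distances operate on a
level-weight scale: absent = 0, trace = 5, main = 55, the midpoints of the
two relative-height bands.  Measured relative quantities are used instead
only when *both* profiles being compared carry them, keeping measured and
encoded profiles commensurable.

## Spore morphometrics

Summaries follow the (min) MV ± sd (max) × (min) MV ± sd (max), Q = mean ± sd
(n) scheme with sample standard deviations (n−1).  Q is computed **per spore**
and then averaged — forced by the convention of reporting Q with its own
standard deviation.  For independent normal length L and width W the
second-order delta method gives

E[L/W] ≈ (μ_L/μ_W)·(1 + σ_W²/μ_W²),

which exceeds the naive ratio of means.  The consistency checker flags
summary rows whose printed Q deviates from this expectation by more than a
tolerance (default 0.02) and rows with min > mean or mean > max.  Two of the
published rows (e.g. *C. malicorius*: printed Q 1.53 against an expectation
of 1.71 from the printed moments) fail this check under any length–width
correlation; the package flags such rows, it does not "correct" them.

Pairwise species comparisons use Welch (unequal-variance) two-sample t-tests;
the original analysis names only a "Bonferroni t-test", so the Welch choice
is ours.  The Bonferroni family is the set of unordered pairs within one
metric (length, width and Q corrected separately); corrected p = min(1, raw ·
#pairs).

The scatter-plot ellipse is a **population coverage** ellipse: sample mean and
covariance with squared Mahalanobis radius equal to the χ²(2 df) quantile at
the coverage level (5.991 at 95%).  The source describes it both as
containing 95% of the measurements (figure caption) and as a confidence
interval (methods); the coverage reading matches the caption and is what the
tests verify empirically (0.95 ± 0.005 at n = 10⁵).

## Congruence analysis

*Distances.*  Pigment matrices use Bray-Curtis, BC(x, y) = 1 − 2Σmin(xᵢ,yᵢ)/
Σ(xᵢ+yᵢ).  "A similar Bray-Curtis matrix from the alignment" is
under-specified, so sequences are one-hot encoded per column over five states
(A, C, G, T, gap); N contributes to no state and any column where either
member of a pair has N is excluded pairwise.  This makes the sequence matrix
commensurable with the pigment matrix under the same dissimilarity, and on
N-free data it provably equals the p-distance with gap as a fifth state
(property-tested on 1000 random alignments).

*Clustering.*  `ward_cluster` implements the Lance-Williams update with Ward
coefficients applied to the dissimilarities **as given** (the classic
"ward.D" behaviour; no squaring), with `ward.D2` available behind a flag.
Ties break deterministically: among equally close pairs, the pair whose
clusters contain the lowest original leaf indices merges first.  The
implementation is checked against a naive O(n³) re-scanning agglomerator on
500 random matrices of up to 7 taxa and against merge heights and topology
frozen from an independent hclust ward.D run on a fixed 6-taxon matrix.

*Mantel test.*  Pearson correlation of strictly-lower-triangle entries after
aligning labels by name; the null permutes rows and columns of one matrix
simultaneously; one-sided p = (1 + #{r_perm ≥ r_obs})/(permutations + 1)
with 999 permutations by default, so the p resolution is exactly 1/1000.
One-sidedness matches the direction of the scientific question (positive
chemistry–phylogeny association).

*Tanglegram entanglement.*  Leaf orders are made canonical (the child whose
subtree holds the smaller minimum leaf index comes first); with positions uᵢ,
vᵢ of each taxon in the two orders, entanglement = Σ(uᵢ−vᵢ)² normalised by
its value under exact reversal, i.e. 0 for identical orders, 1 for reversal.
The exponent 2 and reversal normalisation are our fixed choices; the figure
this mirrors does not define its measure formulaically.

The study's headline Mantel statistic was computed on unpublished
relative-quantity and full-alignment matrices and therefore cannot be
recomputed from printed data.  The package instead verifies the machinery by
calibration: on independent random matrices the Mantel test is approximately
uniform under the null (fraction of p < 0.05 within [0.02, 0.09] over 200
replicates), and on coupled synthetic data with noise-free profiles it
detects the association (p ≤ 0.05) in at least 95 of 100 replicates.

## Identification key

The key is shipped as JSON: 28 couplets, each with exactly two leads, whose
28 terminal leads resolve 26 distinct taxa (*C. huronensis* and
*C. uliginosus* s.l. each terminate two leads; the var. *luteus* lead is
encoded under *C. uliginosus* with a machine-readable qualifier).  The lead
graph is a DAG, not a tree — one couplet is reachable along two routes,
exactly as printed.  Prose predicates were decomposed into a controlled
vocabulary of 17 characters (colours of lamellae, veil, pileus, context,
stipe base and basal mycelium; hosts; habitat; KOH reactions; UV
fluorescence; mean spore length/width in µm).  Quantitative wording such as
"spore diam. mostly > 4.5 µm" becomes a numeric threshold on the mean width.
Taxa printed with an asterisk (not type-confirmed or outside the habitat
scope) carry a flag; the "never detected" annotations are preserved as
qualifiers.

Traversal uses candidate-set semantics: a lead whose predicate is
undecidable under the record's unknowns is followed alongside any satisfied
lead, so partial field observations narrow the candidates monotonically
instead of failing; records contradicting both leads of a couplet report the
blocking couplet.  Each couplet's two leads constrain at least one shared
character with disjoint admissible states, which yields the round-trip
property verified in the tests: conjoining the predicates along any terminal
lead's canonical (breadth-first) path produces a record that identifies
exactly that taxon, for all 28 leads.

## Synthetic-data generators

*Spores* are bivariate normal with the published per-species means and
standard deviations (length–width correlation 0 by default, since no
correlations are published; n = 30 per collection as in the study protocol).
Non-positive draws are resampled rather than renormalising a truncated
normal — at the published coefficients of variation (≤ 0.15) the truncated
mass is negligible (< 10⁻¹⁰).

*Chromatograms* place a Gaussian peak (width sd 0.05 min on a 0.01-min grid
over 0–21 min) at each present pigment's reference retention time.  Main
pigments draw relative heights uniformly in [15, 100] with the tallest
anchored at exactly 100; traces draw uniformly in [6, 9].  The margins keep
every simulated peak above the 5% detection threshold and clear of the 10%
boundary, making the level encoding invertible: at zero noise the full
pipeline recovers all fifteen encoded profiles exactly (an acceptance
property), and it remains stable at realistic noise (a few tenths of a
percent of the tallest peak).

*Coupled data sets* evolve sequences on a star-within-clades topology: a
random root, one ancestor per clade, one branch per taxon, each branch
applying per-site substitution with probability `substitutions_per_site`
(default 0.03 on 600 bp, ITS-like).  Pigment profiles are per-clade templates
on the {0, 5, 55} weight scale whose entries are independently resampled with
probability `pigment_noise`; at noise 1 profiles are independent of the
clades, giving a true null.  Expected Mantel r is non-increasing in the noise
rate (property-tested at three noise levels × 50 replicates).

What the generators do **not** emulate: rate heterogeneity, indel processes
or tree-shaped within-clade structure (distance structure is all the
congruence stage consumes); MS fragmentation, UV–Vis band shapes or
co-elution; measurement-protocol effects on spore sizes.  Green tests
therefore certify the algorithms and their statistical calibration, not the
biological variability of real collections.

## Problem sizes and tolerances

Simulation-based checks use n = 10⁵ spores for moment/Q/ellipse recovery
(Monte-Carlo error well below the ±0.02 and ±0.005 assertion bands), 200
replicates for Mantel null calibration, 100 for the positive control, 500
random matrices for the Ward oracle and 1000 for the p-distance equivalence
— sizes at which the whole suite runs in well under a minute while leaving
the Monte-Carlo bands comfortably narrower than the tolerances asserted.

The reproduction script (`scripts/acceptance.py`) re-simulates the three
published mean-Q values (*C. ominosus* 1.82, *C. huronensis* 1.72,
*C. fervidus* 1.43) from the printed moments at n = 10⁵ with a user-supplied
seed.  Note the delta-method expectations for *C. huronensis* (1.714) and
*C. fervidus* (1.422) sit slightly below the printed values — the printed
moments and printed Q are internally consistent only to about ±0.01 — so the
simulated values reproduce the printed ones within ±0.02 but not exactly.

## Known limitations

- Group rules are distilled from prose; they reproduce the curated
  memberships but are not guaranteed to generalise to unsampled species.
- The level-weight scale (0/5/55) is a stand-in for unpublished quantities;
  distances between encoded profiles are ordinal approximations.
- Key predicates inherit the printed key's looseness; colour states are a
  controlled but coarse vocabulary, and two printed couplets required
  curation choices (documented in the fixture's `text` fields) to keep
  sibling leads mutually exclusive.
- The headline chemistry–phylogeny correlation of the original study is not
  reproducible from printed data; the package validates the machinery by
  simulation instead.
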