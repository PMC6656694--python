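# Methods

## Overview

cytomon implements a standardized mass-cytometry immune-monitoring workflow
as a chain of explicit, individually tested stages:

    raw dual counts → bead normalization → (debarcoding) → arcsinh(x/5)
    → pre-gating → { hierarchical gating | SOM clustering + annotation }
    → frequency tables → coverage / reproducibility / differential abundance

Every stage consumes and produces plain data structures (an events×channels
matrix with channel metadata, TSV tables, FCS files), so intermediate results
can be audited or replaced.

## Intensity model and transforms

Mass-cytometry dual counts are non-negative and approximately log-normal in
their positive component. All analysis happens after the variance-stabilizing
transform x → asinh(x/c) with cofactor c = 5 (the convention for mass
cytometry; flow cytometry typically uses c = 150). For clustering, each
channel is additionally divided by its 99.5th percentile so that channels
contribute comparably to Euclidean distances; percentiles are computed per
sample. The percentile step makes the pipeline only *approximately* invariant
to global sensitivity factors — asinh is log-like above its elbow but linear
below it — which is why drift is corrected on the raw scale by beads rather
than absorbed by the transform. The tests quantify this: a 10% global
sensitivity change moves percentile-normalized intensities by < 0.05 and
never reorders events within a channel.

## Cutoffs

Populations are defined by two per-antigen thresholds on the transformed
scale: a primary cutoff (negative/positive boundary) and a secondary cutoff
(low/high boundary, secondary > primary). `pos`/`neg` clauses compare to the
primary cutoff, `high`/`low` to the secondary one; this two-level scheme is
what makes graded definitions such as CD25^high CD127^low Tregs expressible.
The packaged default table places the primary cutoff at 1.5 and the secondary
at 3.0 arcsinh units for every antibody channel; these are simultaneously the
ground truth of the synthetic generator and the "manual" cutoffs used to gate
it. `estimate_cutoffs` provides a data-driven alternative: the deepest
kernel-density valley between the two largest modes, falling back for
unimodal channels to the 99th percentile of a half-Gaussian fitted below the
mode. It requires ≥ 100 events and is intended for real data where manual
cutoffs are unavailable; the bundled analyses use the known cutoffs.

## Bead normalization

Calibration beads (EQ four-element: Ce140, Eu151, Eu153, Ho165, Lu175) are
identified as events above the bead cutoff in *all* bead channels and below
the DNA cutoff. Beads are grouped into windows of 500 bead events (windows
are defined in events, not seconds, so acquisition pauses do not distort the
fit; the count is configurable). Per window, the correction factor is the
median over bead channels of (global bead median / window median) — a single
scalar per window rather than per-channel slopes, which is simpler and
adequate for the smooth drifts the generator produces; zero-median windows
are dropped with a log message. Factors are linearly interpolated in time and
multiplied into every mass channel (event length and time are untouched).
With fewer than two usable windows, or at least ten beads per window, the
transform degrades to the identity with a warning rather than failing.

## Debarcoding

Samples pooled by k-of-n palladium codes are deconvolved per event: the n
barcode channels are rescaled to [0, 1] within the event, the top-k channel
set is matched against the scheme, and the separation between the k-th and
(k+1)-th rescaled intensity must reach a cutoff (default 0.1, the
conventional debarcoder default). Events whose top-k set matches no code —
including cross-sample doublets, which carry the union pattern — are
unassigned. Distinct equal-weight codes automatically differ in ≥ 2
positions.

## Pre-gating

Sequential filters, each recorded with events in/out: non-beads; DNA⁺ (both
iridium channels above cutoff); singlets (DNA below the doublet boundary and
event length below cutoff); live (cisplatin-low); CD45⁺; CD235ab/CD61⁻
(erythrocytes, platelets). A non-neutrophil rule (exclude
CD16⁺CD14⁻HLA-DR⁻CD11b^high) exists behind a flag for granulocyte-containing
matrices and is a documented package convention, not a published rule; it is
a no-op for PBMC-type samples.

## Hierarchical gating

The gating tree is generated from the same marker-sign definitions that
drive annotation. At each node an event descends only when *exactly one*
child predicate holds; ambiguous or unmatched events stay at the node
("ungated at level"), and sibling overlap above 1% triggers a warning naming
the siblings. The packaged trees are constructed so that sibling predicates
are mutually exclusive (e.g. conventional CD4 memory subsets carry a CD25-low
clause to exclude Tregs). The memory scheme is the conventional CD45RA/CCR7
quadrant (naive RA⁺CCR7⁺, central memory RA⁻CCR7⁺, effector memory RA⁻CCR7⁻,
effector RA⁺CCR7⁻) with CD45RO/CD27 as auxiliary clauses; Tregs default to
CD25^high AND CD127^low AND FoxP3⁺; NKT cells use the invariant-TCR reagent
(clone 6B11) channel. All are config-overridable, since the published
gating figures are not machine-readable and conventions differ between
laboratories.

## SOM clustering and annotation

Events are quantized by a batch SOM on the lineage/subset antigens only
(activation and checkpoint channels are excluded from clustering and
summarized per cluster post hoc). The codebook is initialized by greedy
D²-weighted seeding and refined for 10 epochs with a Gaussian neighborhood
whose radius shrinks from 0.3 to 0.05 grid units. This is a deliberate
departure from classical SOM schedules (quantile-grid initialization, wide
initial neighborhoods): wide neighborhoods average rare, well-separated
modes into their dense neighbors, and the map here is used as a quantizer —
recovering a 0.09%-of-events population requires that it keep a dedicated
node — not as a 2-D visualization. Determinism is guaranteed by the seed
(NumPy PCG64 and scikit-learn's seeded D² sampling).

Codebook vectors are agglomerated by average-linkage hierarchical clustering
(Euclidean) cut at k metaclusters (default grid 10×10, k = 30, matching a
transplant-reconstitution resolution of ~30 subsets). Each metacluster's
median marker profile is scored against every population definition: a
clause matches when the median lies on the required side of the antigen's
cutoff, and the score is the matched fraction of clauses. A metacluster
receives the deepest definition whose entire ancestor chain scores ≥ 0.9
(ties break to the deeper definition, then the larger score, then the
lexicographically first name); below the floor at the root it is Unassigned.
Internal lineages with ≥ 200 events are then recursively subclustered: a
fresh SOM restricted to the lineage's events and to the antigens its subtree
references, with an automatically scaled grid (≈ 8 nodes per candidate
definition, capped at 8×8 and at one node per 10 events) and
k = (#subtree definitions + 5). This mirrors how per-sample automated
annotation platforms resolve maturation subsets within a lineage.

## Statistics

* **Coverage**: per event, the number of antibody channels above their
  primary cutoff; reported as the median and the fraction of cells with ≥ k
  (default 4), optionally stratified by lineage.
* **Replicate agreement**: ordinary least squares of one replicate's
  population frequencies on the other's, pooled over populations and donors,
  on the raw frequency scale; Pearson r and the two-sided slope p-value.
* **Sample dendrograms**: scipy hierarchical clustering (default complete
  linkage, Euclidean) of sample frequency profiles, with a utility to test
  whether replicate pairs merge as sibling leaves.
* **Bootstrap SEM of the median**: the standard deviation of the median over
  1000 resamples with replacement, seeded.
* **Label agreement**: one-vs-rest TP/FP/FN/TN per population between two
  labelings, with precision, recall, F1 and MCC (defined as 0 when any
  marginal factor vanishes), plus macro means.
* **Differential abundance**: per population, counts are modeled as negative
  binomial with a log link, log(sample total) offset and a group indicator.
  The dispersion is a method-of-moments estimate around group means, scaled
  by n/(n−2) for the two fitted means and shrunk halfway toward the cohort
  median dispersion (weight configurable). The group coefficient is Wald
  tested against a t reference with n−2 degrees of freedom; BH FDR is
  applied across populations. The t reference and df correction were fixed
  once by a 1000-replicate null calibration (the test suite re-runs it:
  per-population type-I error at α = 0.05 stays within [0.03, 0.07] on an
  exchangeable null). This is a deliberately self-contained divergence from
  quasi-likelihood F-tests used by count-model packages; its calibration is
  tested, not assumed, and populations with an all-zero group are flagged
  with p = 1 by convention. A group with genuinely heavier-than-median
  dispersion is tested slightly conservatively under shrinkage — the usual
  price of moderated dispersion.

## Synthetic-data generator

The generator exists so the whole pipeline can be exercised with known
truth. Per population, marker intensities are truncated Gaussians on the
arcsinh scale (spread 0.3), placed consistently with the population's sign
profile: negatives at 0.2, positives at primary + 2.0 (= 3.5), high levels
at secondary + 1.4 (= 4.4), and dim levels mid-band (2.25 between the
cutoffs, 1.0 for low-only constraints) — locations are derived from the
lineage table itself, so generator/gating closure holds by construction,
plus curated extras (e.g. CD27 on naive T cells, CD38 on NK cells) that give
every population at least four positive antigens, mirroring the panel's
coverage guarantee. Values are inverse-transformed to raw counts; beads are
high in all five bead metals and DNA-negative; dead cells are
cisplatin-high; doublets are raw sums of two cell events (doubling DNA and
event length); barcoded samples put their k-of-n pattern high. Acquisition
drift is an arbitrary positive multiplicative trajectory over normalized
time applied to all mass channels.

Per-sample frequency variation is logit-normal (sd 0.3 by default), a
moderate inter-sample dispersion typical of frequency-recovery
benchmarking; real reconstitution cohorts show substantially larger
inter-patient spread, under which group medians from a three-donor group are
identifiable only within correspondingly wide tolerances. In the transplant
profile a designated filler population (HLA-DR⁻CD16⁺ cells, the largest
unconstrained compartment) absorbs the renormalization so that every other
population's median frequency is *exactly* its parameter. Two consequences
are worth knowing: (i) the median of a *sum* of independently perturbed
subsets (e.g. total T cells) sits ~2–3% above the sum of subset medians, a
property of logit-normal sums; (ii) the filler's dispersion differs from
the logit-normal populations, so shrinkage tests it slightly conservatively.

The bundled profiles encode the study conditions: a healthy-PBMC sample
(22 leaf populations, 5% beads, 3% dead, 2% doublets) and a 28-sample
transplant cohort (15 donors sampled at days 30/90, 3 donors with GvHD;
40,000 events per sample; lineage medians T 29.0%, monocytes 27.0%, NK
7.1%, B 2.5%) whose group-effect table sets CD27⁻ B cells to 0.44%
(GvHD) vs 3.33% and naive CD4 T cells to 0.09% vs 0.30%. Technical
replicate pairs share a donor's true frequency vector and differ by
per-channel location shifts (sd 0.05 by default) emulating inter-site
staining variation.

What the generator does **not** emulate: mass-spectral physics (ion-cloud
fusion, oxide formation, isotopic spillover), heavy-tailed or zero-inflated
marker distributions, correlated marker noise within cells, batch effects
beyond a global drift, and continuous developmental gradients between
populations. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under a well-specified model, not robustness
to every artifact of instrument data; on real cohorts the gating/annotation
agreement and recovery rates will be lower and cutoffs will need estimation
or manual curation.

## Problem sizes and numerical choices

The bundled analyses use 50,000 events for single-sample QC, 20,000 events
per technical replicate, and 28 × 40,000 events for the cohort — sizes at
which every reported statistic is stable yet the full suite runs in minutes
on one CPU. Frequencies are kept as fractions internally and formatted as
percentages only at the reporting layer; event indexing is 0-based; medians
over even-sized groups are midpoint-interpolated. FCS files are written as
FCS 3.1, list mode, little-endian float32, one DATA segment, with
`Metal_Target` channel names; values are held as float64 in memory.

## Known limitations

* The annotation score is a hard clause-match fraction; a distance-based
  soft score is a natural extension (a flagged mode, not yet implemented).
* Differential abundance uses a Wald t test, not quasi-likelihood F; with
  very small groups (< 3 samples) or extreme dispersion heterogeneity the
  stated calibration band applies only approximately.
* The debarcoder does no Mahalanobis-distance doublet refinement; bead
  removal is by mask only.
* Ellipse/polygon gates are not supported; the packaged trees need only
  thresholds and rectangles.
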