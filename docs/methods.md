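# Methods

## Site annotation

Canonical sites of a miRNA (5'→3', seed = positions 2–8) are defined on the
3'UTR as: 7mer-m8 = reverse complement of positions 2–8; 7mer-A1 = reverse
complement of positions 2–7 followed by an A in the UTR (opposite position
1, regardless of the miRNA's first base); 8mer = 7mer-m8 followed by A. A
locus matching the 8mer pattern is reported once, as 8mer — the site types
are exclusive categories. `N` never matches. The scanner is validated
against a window-by-window brute-force classifier on 1,000 random UTRs.

Coordinates are 0-based half-open throughout, on the transcript (3'UTR)
frame; all intervals are sense-strand and genome liftover is out of scope.
Two intervals are *overlapped* only when they share at least one base;
intervals that merely touch (end == start) have gap 0 but are not
overlapped — the strictest reading of the overlapped category, stated as a
convention because edge cases (touching) are otherwise ambiguous. The
distance statistic d is the minimum edge-to-edge gap to any RBS on the same
UTR, ties broken lexicographically by RBP id; a transcript with no RBS gets
a distinguished no-RBS flag, never an infinite d. The "RBPs within the
flank" count uses the same edge-to-edge gap (the alternative,
center-to-center, is not used anywhere).

Replicate eCLIP-style intervals are merged per (RBP, transcript) as an
interval union (overlapping or touching spans coalesce); single-replicate
intervals are retained and support records the number of distinct
contributing replicates. RBPs are retained only with ≥ 300 3'UTR intervals
and, when an RBP expression table is supplied, expression at or above the
median. Stringency tiers come from the BED name suffix when present,
otherwise by thresholding the BED score at a per-RBP quantile (default: top
50% stringent).

## Confounding features

The four features known to confound distance–efficacy associations are
computed in their simplest defensible forms, each swappable via arguments:

* **local AU content** — unweighted A/U fraction in ±30 nt flanks (site
  excluded), truncated at UTR ends with the denominator equal to the bases
  actually present. A distance-weighted variant (weight 1/position) is
  available but off by default. The 30-nt window is a package default, not
  a claim about any published value.
* **TA (target-site abundance)** — log10(1 + total canonical site count)
  over the supplied transcriptome only; never a built-in reference.
* **SPS (seed-pairing stability)** — additive per-pair duplex energy over
  the seven seed positions against a perfect complement, with
  GC/AU/GU = −3/−2/−1 kcal/mol. Because pairing is perfect, the pair class
  is determined by the seed letter alone, which makes SPS
  permutation-invariant across seed positions — a deliberate simplification
  (no stacking terms).
* **UTR length** — enters all regressions as log10(length); lengths are
  heavy-tailed and the log keeps the linear model sane.

## Regression and per-RBP association

Ordinary least squares with an auto-prepended intercept; two-sided t tests
on n − p degrees of freedom (statsmodels under the hood, with an explicit
rank check that names collinear columns). Residualization subtracts the
fitted confounder model from log2 fold change; residuals are mean-zero and
orthogonal to the design by construction.

Fold changes are repression-negative. On raw d, a positive distance
coefficient therefore means repression weakens with distance — the RBP is
an MT *enhancer*; this sign convention is a tested invariant. The per-RBP
association optionally fits a transformed regressor (the saturating
proximity exp(−d/τ), a decreasing function of d); the enhancer/suppressor
call is adjusted internally so "enhancer" always means stronger repression
at small d. The transform recovers the generative effect size on its own
scale, which is what the parameter-recovery analysis reports. P values are
BH-corrected across RBPs (plain "FDR" is read as Benjamini–Hochberg).

Rank-sum tests use exact enumeration when the combined sample is ≤ 12 with
no ties, otherwise the normal approximation with tie and continuity
corrections. The switch point was chosen so that the approximation error
against full enumeration stays below 0.02 everywhere the approximate branch
is reachable; below the switch the returned p *is* the enumeration value.
KS tests use the asymptotic Kolmogorov distribution. The χ² miRNA selection
(for depletion datasets) calls "highly de-repressed" the top quartile of
fold change — a configurable default, since no published threshold exists —
and skips tables with any expected cell < 1.

The saturation curve is f(n) = 1 − (1−p)^n, the independence model for the
fraction of sites covered by at least one of n RBPs; it is fitted by least
squares on log(1−f), linear in n through the origin. Points with f = 1
carry no information on that scale and are excluded with a warning. The
functional family is a package choice; nothing deeper than independence is
claimed. The co-occurrence test takes the control-site set as explicit
input (a confounder-matched set of sites of non-expressed miRNA families is
a reasonable construction) and BH-corrects across tissues.

## Covariate-balanced sampling

Quartet sampling operationalizes "different d, indistinguishable
confounders": candidates (single-site 3'UTRs with ≥ 1 RBS) are shuffled
under a seed; each unused overlapped candidate greedily collects the first
three unused same-site-type candidates with d > 0 that jointly keep every
confounder's min–max spread within its cutoff; members are assigned to
groups 1–4 by ascending d. Determinism under the seed is the contract;
globally optimal packing is not (greedy first-fit), but on constructed
instances with separated confounder clusters the greedy count equals an
exhaustive packing oracle, which is the tested property.

Cutoffs are chosen to maximize transcripts consumed, with cutoff vectors
whose groups fail verification scored zero. The default optimizer is a
deterministic full-factorial grid (5 log-spaced points per axis — tight
cutoffs matter most, hence log spacing); a Gaussian-process surrogate with
expected-improvement acquisition (scikit-learn) is available as
`optimizer="gp"` for larger budgets. The grid is the default because the
entire pipeline is reproducible under a seed, which a surrogate search
complicates for no benefit at these problem sizes.

Verification runs all pairwise two-sided rank-sum tests on every confounder
and passes only if the minimum p exceeds α = 0.05; on failure, every cutoff
shrinks ×0.8 and sampling retries, up to 10 times. Comparisons with a group
smaller than 3 are skipped and logged.

Count-quintile balancing (groups by bound-RBP count) uses two-sided extreme
trimming: the worst-failing (confounder, group-pair) comparison is found
and the most extreme member dropped from each side of the difference. This
removes between-group shifts without starving the tests of sample size —
an earlier nearest-neighbour matching design passed verification only by
shrinking groups until the tests lost power, which is exactly the failure
mode to avoid. Because between-group balancing cannot touch *within*-group
confounding, an optional decorrelation pass drops the rows contributing
most to any residual pooled count–confounder correlation (default bound
|r| ≤ 0.1).

The composition split bipartitions RBPs by frequency rank (alternating
assignment), assigns each MTS to the side contributing the majority of its
bound RBPs (ties to the smaller side), and stratified-downsamples by count
until the two sides' count histograms agree (χ² p > 0.05). This algorithm
is an invention satisfying the stated endpoint — similar counts, different
composition — as no published procedure exists; the null-calibration test
(exchangeable compositions ⇒ no efficacy difference between sides) is the
guard against the split itself creating signal.

## DMS-seq scoring

Counts are RPM-normalized per replicate, averaged across replicates into
DMS levels, and scored as log2((level + 1) / (denatured level + 1)) — the
1-RPM pseudocount handles zero coverage, on which published procedures are
silent. ΔDMS = in vivo score − in vitro score. Fragment scores average over
A/C positions only (DMS chemistry probes unpaired A/C); mean rather than
sum is the aggregation decision. Fragments are all 100-nt windows at 10-nt
steps that fit inside the UTR. Transcripts below the median expression are
dropped before fragment analyses (low coverage makes unpaired-region calls
unreliable); the quantile uses linear interpolation, so "top 50%" keeps
values strictly above the median for even n. ΔDMS can be normalized by
log10(1 + expression) for count-trend analyses. Per-nucleotide reactivity
compares DMS(+) to DMS(−) RT-stop counts at A/C positions with the same
pseudocount convention.

Fragment groups (NoRBS / Lenient / Stringent, with stringent taking
precedence when both overlap) are balanced on in vitro MFE and expression
by the same trimming machinery as above. The per-fragment MFE used for
balancing is a window sum over a per-transcript pair-energy profile (each
base pair's energy split half onto each partner, from folding the UTR in
non-overlapping 100-nt chunks) — folding every overlapping window exactly
would cost 10× for a covariate whose only role is balance.

## Constrained folding

The engine is a Nussinov-style dynamic program minimizing summed pair
energies (GC/AU/GU = −3/−2/−1 kcal/mol) with minimum hairpin loop 3 and a
set of positions forced unpaired; traceback is deterministic (pairing the
left end beats leaving it unpaired on ties; smallest partner index wins).
The deliberately simple energy model keeps the engine self-contained and
verifiable against exhaustive enumeration of all nested structures
(`enumerate_fold`, an independent exponential-time routine used in tests);
it is not a substitute for nearest-neighbour thermodynamics, and absolute
ΔG values should not be compared against thermodynamic folders. Constraint
monotonicity (forbidding more positions never lowers the MFE) is a tested
invariant. Sequence length is capped at 300 nt by default (O(n³) in pure
numpy-assisted Python).

RBP binding is modeled as forcing the footprint single-stranded (removing
the footprint from the sequence would change coordinates and was rejected);
miRNA binding as the MTS forced unpaired intramolecularly plus a
seed-duplex bonus from the SPS pair table. The ΔG quartet is then ΔG_0
(free), ΔG_RBP (RBS unpaired), ΔG_miR (MTS unpaired + bonus), ΔG_RBP+miR
(union + bonus); overlapping footprints are handled by position-set union.
The accessibility costs ΔG_miR − ΔG_0 and ΔG_RBP+miR − ΔG_RBP are computed
properties, never stored. Note the constrained-fold component satisfies
ΔG_RBP ≥ ΔG_0, but ΔG_miR may exceed ΔG_0 once the duplex bonus is
excluded.

## Synthetic cohorts

The generator has two layers. The *sequence* layer emulates a
single-miRNA-transfection experiment: UTR lengths lognormal (log-mean 6.0,
log-sd 0.5 — median ≈ 400 nt, a deliberately desk-scale 3'UTR), GC fraction
0.45, one implanted canonical site per target transcript (type uniform over
the three), all spontaneous seed matches destroyed by single-base
substitution so sequences remain valid for folding, expression lognormal.
Binding intervals (default 20 RBPs, Poisson(1.5) intervals each, 30 nt
wide) are placed so the realized nearest-interval gap equals a draw from
the configured distance distribution (uniform 0–300 nt by default), with an
overlapped point mass (probability 0.15) in which the nearest interval
straddles the site; extra intervals re-draw if they would land closer than
the realized minimum. Everything is deterministic under the config seed.

The *statistical* layer draws feature rows directly (local AU ~ Beta(2,2),
TA ~ N(2.5, 0.4), SPS ~ N(−14, 2), log10 length ~ N(2.8, 0.25)), emulating
a pooled multi-experiment dataset. This exists because within a
single-miRNA cohort TA and SPS are constants and cannot be estimated in a
regression; identifiability analyses therefore run on this layer, while
annotation and round-trip analyses run on the sequence layer. An optional
tilt correlates every confounder with distance, creating the confounding
that the correction machinery must then remove.

Fold changes follow log2fc = β₀ + β_AU·AU + β_TA·TA + β_SPS·SPS +
β_len·log10len + β_d·exp(−d/τ) + N(0, σ²), with defaults β = (0, −0.5,
0.2, 0.05, 0.1, −1.0), τ = 50 nt, σ = 1. The distance effect enters as a
monotone saturating exponential because only a monotone association is
assumed; β_d < 0 encodes enhancement. Non-target transcripts receive pure
noise.

DMS counts are Poisson at A/C positions only (G/U always zero): the
denatured rate is flat; the in vitro rate is 4× lower at positions paired
in a chunked fold of the UTR; the in vivo rate multiplies the in vitro rate
by (1 + gain·occupancy), occupancy weighting stringent footprints 1.0 and
lenient 0.5, capped at 1; the DMS(−) background is flat and 20× below the
denatured rate. Expected counts at a fully open position default to 50
(gives per-position scores with usable signal-to-noise at two replicates).
With gain 1 and full occupancy, ΔDMS → +1 in expectation, which is the
generator's calibration check.

What the generator does *not* emulate: real seed-match statistics beyond
the implanted/destroyed sites, RBP binding-motif sequence preference,
coverage biases of real DMS-seq libraries, 3'UTR isoform variation, or
translational repression (fold changes are mRNA-level by design). Passing
tests therefore demonstrate the *statistical machinery* is correct and
powered under the assumed data model, not that real data satisfies the
model.

## Analysis problem sizes

The shipped analyses run at desk scale, chosen to keep the full suite and
the acceptance script in the minutes range on one CPU while leaving all
statistical conclusions unambiguous: 2,000 transcripts × 3 seeds for
parameter recovery; 100 null RBP cohorts of 300 rows for calibration;
1,500-candidate cohorts for quartet sampling (the distance-quartet
demonstration uses τ = 150 nt and σ = 0.5 so that all four group means
separate cleanly over the 0–300 nt distance range); 150 transcripts
(median UTR ≈ 250 nt) for the DMS experiment, yielding ≥ 300 balanced
fragments per group; 200 random sequences ≤ 14 nt for folding-oracle
equivalence; a 100 × 400 coverage matrix for the saturation fit.

## Known limitations

* The folding energies are count-like, not thermodynamic; only *relative*
  constrained-vs-free comparisons are meaningful.
* Greedy quartet packing guarantees neither maximal packings nor balanced
  groups on adversarial inputs; verification-plus-shrink is the safeguard.
* The composition-split heuristic and the control-MTS construction for the
  co-occurrence test are package inventions satisfying stated endpoints,
  not published procedures.
* BH is applied across RBPs within one dataset; no hierarchical correction
  across datasets is attempted.
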