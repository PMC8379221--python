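# rbpmt — RNA-binding proteins as modulators of microRNA targeting

Metazoan miRNA targeting (MT) is usually modeled as a ternary interplay of
Argonaute (AGO), the miRNA, and the target mRNA. But human 3'UTRs are
crowded: the ~150 eCLIP-profiled RNA-binding proteins (RBPs) average
~22,000 3'UTR binding sites each, and with >1,500 human RBPs known, tens of
millions of RBP–3'UTR interactions are possible. `rbpmt` implements, as a
tested and reusable pipeline, the quantitative framework for asking whether
an RBP bound near a miRNA target site (MTS) changes how well that site
works — and whether the mechanism is structural: RBP binding melting the
local secondary structure so AGO can reach the site.

It is aimed at regulatory-genomics analysts who have (or simulate)
transcript-space data: 3'UTR FASTA, miRNA FASTA, RBP-binding intervals
(BED6), expression and log2 fold-change tables, and per-position DMS-seq
counts.

## The statistics at the core

* **d<sub>MTS-RBS</sub>** — for a 3'UTR with a single canonical seed site
  (8mer, 7mer-m8 or 7mer-A1), the nucleotide gap between the site and the
  nearest RBP-binding site (RBS); 0 with an `overlapped` flag when they
  share bases.
* **Confounder correction** — log2 fold change is regressed on the four
  known determinants of MT (local AU content, target-site abundance TA,
  seed-pairing stability SPS, 3'UTR length); the residual carries the
  distance signal. Per-RBP associations (`log2fc ~ d + confounders`) are
  t-tested and BH-corrected; β<sub>d</sub> > 0 on raw d means *enhancer*
  (repression weakens as binding moves away).
* **Covariate-balanced quartets** — a non-parametric correction: greedy
  rounds select four same-site-type 3'UTRs (one overlapped, three at
  increasing d) whose confounders all lie within per-feature min–max
  cutoffs; cutoffs are optimized to maximize transcripts consumed and the
  resulting groups verified indistinguishable by pairwise Wilcoxon tests.
* **DMS scores** — DMS level = replicate-mean RPM of per-position counts;
  DMS score = log2(level<sub>sample</sub> / level<sub>denatured</sub>);
  ΔDMS = score<sub>in&nbsp;vivo</sub> − score<sub>in&nbsp;vitro</sub>,
  averaged over A/C positions of 100-nt fragments — a per-fragment measure
  of in-cell structural opening.
* **Constrained-folding accessibility** — a self-contained Nussinov-style
  minimum-free-energy engine (GC/AU/GU = −3/−2/−1 kcal/mol, hairpin loop
  ≥ 3) with positional unpaired constraints gives the ΔG quartet
  (ΔG<sub>0</sub>, ΔG<sub>miR</sub>, ΔG<sub>RBP</sub>,
  ΔG<sub>RBP+miR</sub>): comparing ΔG<sub>RBP+miR</sub> − ΔG<sub>RBP</sub>
  with ΔG<sub>miR</sub> − ΔG<sub>0</sub> quantifies how much a bound RBP
  pre-opens the site for AGO.

A first-class synthetic-data module generates cohorts with exactly this
statistical structure (implanted single sites, controlled distance
distributions, linear confounder models, occupancy-driven DMS opening), so
every stage is testable without external data.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on simulated
data and write tables under `results/`:

```
$ python analysis/01_simulate_cohort.py --seed 1 --n-transcripts 120
wrote 120 transcripts (96 targets), 2985 RBS intervals to results/data

$ python analysis/02_annotate_sites.py
96/120 single-site 3'UTRs; 21 overlapped; median d = 77.5

$ python analysis/03_distance_association.py
distance effect: true -1.0, recovered -0.975 (all enhancer: True); null significant fraction 0.000

$ python analysis/04_matched_groups.py
100 quartets; oracle match 100%; monotone trend: True; g1-vs-g4 p = 7.9e-12

$ python analysis/05_dms_structure.py --n-transcripts 60
mean ΔDMS: NoRBS 0.013 < Lenient 0.201 < Stringent 0.347 (ordered: True); count trend p = 7e-112

$ python analysis/06_fold_accessibility.py --n-transcripts 25
20 fragments; RBP binding lowers the accessibility cost in 70% of them (mean ddG_nomodel -11.45, mean ddG_model -13.15 kcal/mol)

$ python analysis/07_saturation_coverage.py
coverage p-hat = 0.0526; f(1500) = 1.0000; co-occurrence in 4/12 tissues, exclusion in 0
```

Reading these: the generator injected a distance effect of −1 (on the
saturating proximity scale exp(−d/τ)) and the per-RBP regression recovers
−0.975 while calling the RBP an enhancer; with no injected effect nothing is
significant after FDR. The quartet sampler packs as many confounder-balanced
quartets as the exhaustive oracle and reveals a monotone residual
fold-change trend from overlapped (strongest repression) to most distal.
Fragments with stringent binding open up most in vivo (ΔDMS ordering), and
the coverage curve extrapolates to essentially every target site having a
neighboring RBS once 1,500 RBPs are considered.

## Layout

```
src/rbpmt/      io, simulate, annotate, features, stats, matching,
                structure, workflows
analysis/       numbered drivers (simulate → annotate → associate →
                match → dms → fold → saturation)
tests/          pytest suite incl. end-to-end acceptance checks
docs/methods.md model, parameter, and design notes
```
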