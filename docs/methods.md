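# Methods

This note documents the models, parameters and design choices behind
`pidarray`, and what the synthetic cohorts do and do not establish about
real array data.

## Intensity model and genotype calling

Each biallelic probe is measured on two channels (x for the A allele, y for
B). We work in polar coordinates: normalised angle θ = (2/π)·arctan(y/x)
∈ [0, 1] and total intensity R = x + y. Diploid genotypes form three
clusters on the angle axis; the canonical positions are 0.05 (AA), 0.5
(AB), 0.95 (BB).

**Cluster fitting.** Per probe, a three-component 1-D Gaussian mixture is
fitted on θ by EM (20 iterations, canonical initialisation, component order
maintained on the angle axis, spread floor 0.01). EM components carry no
genotype identity, so after fitting: components closer than half the
canonical cluster spacing (0.225) are merged — they describe one cluster
that the mixture split; each observed cluster is then assigned to the
genotype slot whose canonical center it is nearest (minimum-total-distance
assignment over ordered slot combinations); unoccupied slots are imputed at
the canonical centers with the default spread 0.05. Probes with fewer than
10 measurable samples are uncallable. The merge step matters at rare
probes, where a handful of heterozygote points would otherwise be split
across the AB and BB slots and mis-called.

**Primary calling.** A sample is assigned to the nearest cluster on θ with
score 1 − d/h, where d is the distance to the called center and h the
distance from that center to the nearer decision boundary (midpoint to the
adjacent center). Calls with score below 0.15 (a conventional
calling-confidence cutoff magnitude; configurable) become no-calls, as do
unmeasured points (x = y = 0).

**Rare-variant recalling (zCall-style).** At rare probes (minor-cluster
occupancy < 5 samples), no-calls are re-examined against per-channel
thresholds t = mean + z·sd of each homozygote cluster's *null* channel
(z = 7, the cited recalling method's default). Above both thresholds → AB;
above exactly one → the corresponding homozygote; otherwise the no-call
stands. When a homozygote cluster has no carriers (the typical rare-variant
case), its null-channel statistics are imputed from the observed homozygote
cluster's null channel — the two-colour chemistry is symmetric. Recalled
entries are marked (`caller=recalled`) and carry a nominal mid-scale score;
confident primary calls are never altered.

## QC cascade

Order of application (each exclusion records its first failing rule):

1. probe call rate ≥ 97.5%;
2. sample call rate ≥ 97.5% (over retained probes);
3. Hardy-Weinberg exact-test exclusion at P < 1e-4, computed over all
   retained samples (controls + patients) on autosomes, over inferred
   females on X, never on Y. The exact test conditions on the observed
   allele counts and sums the probabilities of all heterozygote counts no
   more probable than the observed one (the standard recurrence
   construction; the suite verifies it against a direct enumeration oracle
   exhaustively for all tables with n ≤ 30). Monomorphic probes return 1.
4. zCall-style recalling on the surviving matrix;
5. post-recall probe then sample call-rate filters at the stricter 98%.

Within a stage probes are filtered before samples (fixed, documented
order). Whether the HWE filter should use controls only is genuinely open;
using the full cohort is the common default and is what we implement.

**Sex inference.** From the X heterozygosity rate: < 0.05 → male, > 0.20 →
female, else ambiguous; at least 50 called X probes required. The rate is
computed over cohort-polymorphic X probes where enough exist (≥ 20),
because monomorphic custom probes carry no sex signal and dilute the female
rate towards the ambiguous band.

## SNV screen

Filter order: pathogenicity (keep `disease_causing`; unannotated probes are
dropped and counted, never silently) → population frequency strictly
< 0.005 (absent frequency treated as 0 and kept) → cohort recurrence (a
probe non-reference in ≥ 2 samples is removed everywhere: recurrence of a
supposedly rare variant indicates probe malfunction) → male X heterozygote
exclusion (male X hom-alt calls are relabelled hemizygous; ambiguous-sex
candidates are kept and flagged) → cluster-quality review.

The cluster-quality step formalises the manual inspection of per-probe
cluster plots: a candidate is excluded when its point lies more than k = 3
effective spreads from the called cluster center, or when its intensity is
a dropout. Two numerical choices matter here:

* the *effective* spread is floored at the canonical width 0.05 — a
  cluster fitted to one or two carriers has no usable spread estimate, and
  flooring prevents the review stage from discarding well-behaved rare
  heterozygotes over a degenerate 0.01 spread;
* "dropout" means below the probe's cohort 5th percentile **and** below
  60% of the probe median. The second condition keeps the rule from
  mechanically pruning the bottom tail of a healthy intensity
  distribution; a percentile alone would discard ~5% of true candidates by
  construction. Borderline points (within one spread of the cutoff, or in
  the 10th-percentile/75%-of-median band) are flagged for review instead.

**Inheritance matching.** Per patient and gene: AD — any non-reference
variant; AR — a homozygote, or two distinct heterozygous variants in the
gene (assumed in trans; phase is unknowable from an array); XL — a
hemizygous male or homozygous female. A patient with any match (or a
retained CNV finding) is counted as a genetic diagnosis.

## CNV screen

LRR = log2(R / median R at the probe across the cohort); BAF interpolates θ
piecewise-linearly between the fitted AA/AB/BB centers onto anchors
0/0.5/1.

**Segmentation.** Per sample and chromosome, binary segmentation on LRR:
recursive splits at the maximal two-sample z statistic of the flanking
means, accepted while the statistic exceeds the normal quantile of the
significance level (5e-6, two-sided). Probe pairs farther apart than 1 Mb
are hard segment breaks. A segment is called when it has ≥ 4 probes, its
mean log2 crosses a class threshold (−0.3 single loss, −1.1 double loss,
0.2 single gain, 0.7 double gain), and the Gaussian p-value of its mean
against the sample's robust noise null (1.4826·MAD of the sample's LRR) is
below 5e-6. The significance level is interpreted per segment.

**Aneuploidy.** A chromosome is called trisomic when its median LRR reaches
50% of the ideal log2(3/2) shift and the heterozygote BAF band splits
towards 1/3 and 2/3; monosomic when the median LRR reaches 50% of
log2(1/2) and the heterozygote band is absent. One criterion without the
other yields an event flagged `discordant`. This automates what is
conventionally read off whole-genome LRR/BAF plots by eye; segment-level
calls on an aneuploid chromosome are reported through the aneuploidy
channel, not as focal CNVs.

**LCSH.** Runs of homozygosity over cohort-polymorphic probes (het rate
≥ 0.05): maximal runs of homozygous calls (|BAF − 0.5| > 0.4), tolerating
one discordant probe per 50 run probes, requiring ≥ 50 probes, ≥ 5 Mb
(conventional ROH-calling magnitudes) and mean LRR inside the normal band
(−0.3, 0.2) — the last condition separates LCSH from deletion, which also
presents as homozygous BAF. X is skipped: hemizygous male X would read as
one chromosome-long run. Per-sample LCSH burden is an indicator of
consanguinity, not a diagnosis.

**CNV filters.** Keep events overlapping a disease-gene locus; drop
heterozygous (single-copy-change) events with *any* overlap of the
known-benign track (0% tolerance), homozygous/double events exempt; drop
events recurring in ≥ 2 samples, where "the same event" means same class
and ≥ 50% reciprocal overlap (the matching rule is ours; none is standard).

## Evaluation

Concordance compares post-QC array genotypes with truth genotypes per call
over custom SNV probes — INDEL probes are excluded because a
sequencing-derived truth frame is only unambiguous for SNVs. Probes with
any disagreement are listed for exclusion from downstream use. For the
non-reference mismatch rate, two denominators are defensible (non-reference
calls, or all compared calls); the report emits both and privileges
neither.

Sensitivity categories partition assessed variants: replicated known / new
confirmed / new unconfirmable / missed for want of a probe / missed because
the probe failed. The sensitivity denominator contains only probe-covered
variants; absent probes are a design limitation, not an assay failure.
Diagnostic yield is patient-level: diagnosed / total. Reproducibility is
reported at patient level (all causal probes of a patient reappear among
the replicate run's post-cascade candidates) and genotype level (discordant
calls over shared post-QC custom probes). Percentages are printed at one
decimal for concordance/replication/validation rates and as integers for
sensitivity and yield, rounding half away from zero.

The cost model is linear and two-armed: screen-then-sequence
(n·array + n·(1 − yield)·NGS) versus sequence-all (n·NGS). Defaults: €40
per array sample, €1,000 per NGS sample.

## Synthetic cohort generator

The generator *is* the study definition; its defaults are the conditions
every end-to-end number is measured under.

* **Cohort**: 95 patients + 56 controls, two runs over the same truth
  (run 2 re-noised; optionally fewer samples). Controls carry truth
  genotypes emulating deep WGS.
* **Genome**: GRCh37 chromosome lengths divided by 10 (autosomes + X).
  Desk-scale probe counts (600 custom in 277 gene loci + 4,000 backbone)
  then give ~13 probes/Mb — the density regime CNV and LCSH calling
  need. The backbone is spaced near-evenly with ±30% jitter (no
  pathological gaps); X is double-weighted, as real arrays carry dense X
  content for sex checks.
* **Genotypes**: backbone allele frequencies ~ U(0.05, 0.95), genotypes
  drawn from HWE (the suite checks this by chi-square); males are
  hemizygous on X. Custom probes are hom-ref except: ~15% common/benign
  probes (frequency-driven genotypes), one planted causal configuration
  per patient matching a gene's inheritance (AD het; AR hom or, with
  probability 0.3, two hets in one gene; XL hemizygous — planted in males
  only, as hemizygous presentation dominates X-linked disease), and
  Poisson(2) incidental rare carrier heterozygotes per sample at autosomal
  AR probes (never at probes used causally). Causal probes are unique per
  patient so the recurrence filter cannot remove them; incidental carriers
  may legitimately recur.
* **Intensities**: per-probe baseline ~ lognormal(log 2000, 0.25) shared
  between runs; per-point total = baseline · (copy/2) · lognormal(0, 0.12);
  copy-0 points carry 5% background at a random angle. Angle = 0.5 +
  (BAF_true − 0.5)·2·0.45 + Gaussian noise: sd 0.04 for heterozygous
  points, 0.15 of that for homozygotes — allelic-fraction noise
  concentrates in heterozygotes, while homozygote clusters sit on channel
  background. This asymmetry is what makes threshold-based recalling
  meaningful at z = 7, exactly as on real arrays. Trisomic heterozygotes
  take allelic fraction 1/3 or 2/3 (AAB/ABB); monosomic sites collapse to
  one allele; LCSH regions force homozygous truth genotypes at normal
  intensity.
* **Failures**: per run, samples fail with probability 0.02 and probes
  with 0.01; failed entries are a 60/40 mix of angle scrambling and
  4× noise inflation plus intensity jitter — enough to sink the call rate
  below the QC thresholds, which is how the QC tests recover exactly the
  planted failures.
* **Determinism**: one seed; all streams are spawned from it in fixed
  order; equal configs are byte-identical.

**What the simulations do not show.** No batch effects, wave artifacts,
GC-content intensity bias, cross-hybridisation (a real array occasionally
reports a neighbouring nucleotide change — candidates are flag-reviewable
but the artifact itself is not modelled), no population structure or
linkage disequilibrium, no INDEL-specific chemistry (INDEL probes are
genotyped like SNVs and only excluded from concordance scope), and planted
causal variants are all probe-covered — so simulated yield and sensitivity
sit far above a real screen's, where probe coverage is the binding
constraint. Passing the suite establishes the pipeline's correctness under
its stated model, not the array's real-world diagnostic performance.

## Problem sizes

End-to-end checks run at: 1,000 probes × 60 samples for the zero-noise
exactness properties; 2,650–4,600 probes × 65–151 samples for noisy
two-run cohorts; 3,150 probes × 24 samples for structural-event recovery;
20 replicate cohorts of 350 probes × 40 samples for the paired recalling
comparison; the exact-HWE/enumeration cross-check is exhaustive for all
genotype tables with n ≤ 30 in the suite (n ≤ 25 in the acceptance
script). These sizes keep every run deterministic and fast while leaving
all rates and thresholds at their defaults.
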