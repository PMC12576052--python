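# Methods

## Model

`qvmeth` estimates the methylation fraction y of a candidate CpG from the
aligned reads covering its ±10-base window. The premise is mechanistic:
5mC alters the nanopore signal enough that the basecaller's confidence
(QVs) and its error pattern change near the site, even after the raw signal
is discarded. The joint distribution of QVs and errors across the 21
window positions is summarized by moment statistics — per-position mean,
covariance, coskewness and cokurtosis of QVs, and the pairwise joint
error-rate tensor over the alphabet {A, C, G, T, deletion} — rather than
used directly, because a full joint distribution is not a workable model
input. The reference 21-mer is appended as a 2-bit-per-base code since
sequence context itself modulates QVs and error rates.

A gradient-boosted tree ensemble (XGBoost, squared-error objective)
regresses the transformed label y′ on the 12 411-dimensional feature
vector. Boosted trees are a natural fit: the feature space is large,
sparse in information, and interactions (e.g. between context bits and
error rates) matter.

### Assumptions

- Reads must *fully* cover the window with aligned or deleted bases; reads
  starting/ending inside it are dropped so the pileup stays rectangular,
  as the moment formulas require.
- All covering reads are pooled regardless of orientation; the feature
  formulas index reads only by j.
- Labels come from an existing per-locus caller at training time; the
  model learns to reproduce those levels from basecall features alone.
- QVs are used as raw Phred integers, with no probability conversion.

## Label transform

y′ = logit(clip(y, α, 1−α)) with α = 10⁻³ ("clip" mode, the default).
A "literal" mode is also provided that maps y = 0 → −α and y = 1 → +α and
applies the plain logit in between. The literal piecewise map sends fully
(un)methylated loci to ±10⁻³ — *interior* values, adjacent to the image of
y ≈ 0.5 — so it is not monotone in y; we treat it as a transcription
artifact of the original description and default to the monotone ε-logit,
keeping the literal form selectable for fidelity. Predictions are mapped
back with the logistic sigmoid and clamped to [0, 1]; the back-transform
is our choice (the inverse was never specified), being the exact inverse
of the clip transform on [α, 1−α].

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank` | 10 | window half-width; 21 loci total |
| `min_depth` | 10 | minimum covering reads per locus (features and labels) |
| `min_score` | 800 | minimum bedMethyl score for a training locus |
| `flag_exclude` | 4079 | SAM flag mask; drops unmapped/secondary/supplementary/duplicate/QC-fail and all paired-end records |
| `deletion_qv` | 0 | QV imputed at deleted positions |
| `sigma_ddof` | 0 | divisor for σ in coskew/cokurt (population sd) |
| `alpha` | 1e-3 | ε of the label transform |
| `eta` / `num_round` / `max_depth` | 0.1 / 1500 / 8 | boosting hyperparameters |
| `seed`, `threads` | 0, 1 | reproducibility controls, recorded in model metadata |

Numerical choices: σ uses divisor n (consistent with the 1/n prefactor of
the third/fourth co-moments; configurable via `sigma_ddof` since the
original definition names only "standard variances"). Co-moment entries
whose σ vanishes are set to 0, not NaN, so constant-QV columns still yield
finite feature vectors. Deleted positions carry base 'D' and QV
`deletion_qv`; reads with 'N' anywhere in the window are excluded whole to
keep the pileup rectangular. Loci whose window crosses a contig edge or
contains a non-ACGT reference base are skipped and counted. The feature
flattening is row-major in the fixed order mean → cov → coskew → cokurt →
error → context, with no triangle compression (coskewness is asymmetric;
uniformity keeps the index arithmetic trivial); a `layout_version` string
embedded in feature tables and model metadata guards train/predict
compatibility. The flag mask 4079 also drops every paired-end record — an
aggressive convention inherited from single-end nanopore practice — so it
is configurable.

## Region aggregation

Two trimming rules summarize per-CpG levels over regions. The range trim
averages values inside [median − v, median + v]; v is implemented
literally as the *sample variance* of the levels (a standard-deviation
half-width is available via `spread='std'`, since "median ± variance"
mixes units and the intended spread measure is ambiguous). The tail trim
drops ⌊f·n⌋ values from each end of the sorted list (f = 0.05 by default)
and reports the mean and sample variance of the rest. Membership is by the
C position of the strand-averaged record in the half-open interval.
Interval intersection (for composite region sets such as H3K4me3 ∩ DNase)
merges per chromosome and sweeps both lists.

## Synthetic data generator

`simulate.SimulationConfig` defines the reference simulation conditions:
400 CpG sites planted ≥ 25 bases apart in a 20 kb uniform-random genome,
true levels drawn from Beta(0.3, 0.3) (bimodal, as genomic CpGs are),
coverage 30, and per-read methylation states Bernoulli(true level).
Methylated reads receive an additive QV shift (−6 Phred at offsets −2..+2)
and additive substitution/deletion probability shifts (+0.05 / +0.03 at
offset 0) inside the window; the additive per-offset effect is the
simplest mechanism that realizes the premise that methylation perturbs QVs
and errors near the site. Baselines are qv ~ N(20, 5) discretized to
[1, 50] and substitution/deletion rates 0.03/0.02 per base — realistic
figures for hac-mode nanopore basecalls. Deletions are sampled before
substitutions. Reads are single-end forward-strand primary alignments with
exact CIGARs (deletions as D runs) written as plain SAM; the loci table
reports the realized methylated-read fraction with score 1000.

What the generator does **not** emulate: signal-level error structure,
homopolymer-specific errors, strand asymmetries, read-length variation,
mapping ambiguity, or any coupling between neighbouring CpGs. Passing the
recovery test therefore shows that the feature extraction and regression
machinery can recover a methylation signal *of the injected form*; it is
not evidence about accuracy on real flowcell data, which depends on the
actual (unknown, basecaller-specific) methylation footprint.

## Verification problem sizes

The test-suite checks every feature formula against independent
nested-loop implementations on 100 random pileups (n ∈ [2, 30]), with the
error tensor required to match exactly. The end-to-end recovery check
trains on 300 simulated sites and evaluates 100 held-out sites with 200
boosting rounds — enough rounds for the held-out correlation to plateau
while keeping a full run (simulation → features → six models → prediction)
under two minutes on one CPU; the same experiment backs
`scripts/acceptance.py`. Under these conditions the all-feature model
reaches a held-out PCC ≈ 0.97, statistically tied with the best single
family (the mean-QV model — expected, since the injected effect is mostly
a mean shift), and region-level range-trimmed means over 5-site blocks
correlate with truth at ≈ 0.91.

## Known limitations

- No pretrained models for real basecaller/flowcell combinations are
  shipped; training data must be produced by a signal-based caller.
- Per-read (single-molecule) calls, 5hmC and non-CpG contexts are out of
  scope, though the framework does not preclude them.
- Insertions between window positions are ignored entirely.
- The boosted ensemble is deterministic only for a fixed seed *and* thread
  count; tests and defaults pin one thread.
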