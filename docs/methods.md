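# Methods

## The composite index

The stress-sensitive gene expression (SSGE) index condenses a k-gene qPCR
panel into one number per animal.  Expression values are first made
direction-aware: for a gene that falls under stress the ratio is
`log2(C/y) + 1`, for a gene that rises it is `log2(y/C) + 1`, where `C` is
the arithmetic mean of the control animals' linear-scale expression for
that gene.  The log2 transform keeps within-group variance roughly
constant across groups; the `+1` centers an at-baseline animal at 1; the
direction flip means every panel gene pulls the index the same way under
stress.  The two ratio forms are mirror images: their sum is exactly 2 for
any (y, C).

Normalization is an **additive per-gene shift** that sets the control-group
mean of each gene's ratio to exactly 1.  The wording "normalized so the
control mean equals unity" admits a multiplicative reading too; the
additive shift was chosen because it preserves between-animal differences
— and therefore Cohen's d and every rank statistic — exactly, which is the
property the downstream analysis depends on.  After the shift, the index is
the unweighted mean of the k normalized ratios; the control-group mean of
the index is 1 to floating-point round-off (tested at 1e-12).  Missing
panel values are hard errors, never imputed: a 6-gene mean cannot absorb
silent dropout.

## Synthetic cohorts and calibration

The generator emulates a seven-group chronic-stress study — control (C),
social isolation (SI), social defeat (SD), grid housing (GH), isolation
defeat (ID), chronic shock (CS) and chronic variable stress (CVS) — with
group sizes 36/18/9/8/8/16/17 (N = 112, matching the omnibus ANOVA's
(6, 105) degrees of freedom).  Per animal and gene, log2 expression is the
gene's control baseline plus the group displacement applied in the gene's
stress direction plus independent Gaussian noise (lognormal on the linear
scale).  Genes are independent with equal noise SD σ, so:

* every gene's expression ratio has mean 1 + Δ and SD σ;
* the k-gene index has SD σ/√k;
* calibrating the index SD to s gives σ = s·√k, and a target effect size d
  needs displacement Δ = d·s (both groups share the index SD s).

Defaults are the study conditions: six-gene index SD s = 0.39, per-group
displacements from the reported d values (SI 1.2, SD 1.5, GH 2.8, ID 2.8,
CS 4.5, CVS 4.9).  The same machinery drives the five-gene modality panel
(displacements only for the isolation-housed SI, GH, ID, CS at d = 0.7,
3.2, 1.6, 3.1) and the CVS-duration experiment (3-week d = 5.3, 1-week
2.9, 1-week + 2-week delay 2.7; group sizes 17/17/9/9 giving the (3, 48)
ANOVA — the per-group split is an assumption, only N = 52 is pinned).
Equal displacement across panel genes is the default; per-gene overrides
exist but no numeric heterogeneity is calibrated because only graphical
evidence is available for it.  Control baselines are plausible adrenal
values in arbitrary rRNA-normalized units; the analysis is scale-free.

What the generator does **not** emulate: gene-gene correlation, per-gene
effect heterogeneity, batch/plate effects, RNA pooling before sequencing,
and circadian structure.  Passing recovery tests therefore show the
pipeline is unbiased under the stated noise model, not that real cohorts
behave this way.

A consequence of the equal-shift, independent-noise model worth knowing:
perfect PC1 separation of control vs high-intensity stress animals (the
zero-overlap property) holds in the *typical* simulated cohort (~3 of 4
cohorts at these group sizes), not in every cohort — boundary animals
occasionally brush the other set's range.  The corresponding test asserts
the median overlap over replicate cohorts is zero rather than demanding it
of a single draw.

## qPCR model and quantification

Simulated wells follow a saturating curve: baseline + plateau·A/(A + K)
with template amount A = expression · template_scale · E^cycle and
efficiency E = 2 (primers are assumed prescreened for near-perfect
doubling; per-primer efficiencies are configurable).  The threshold-
crossing cycle is therefore −log_E(expression) plus a plate-wide constant,
so Cq spacing maps exactly to expression ratios.  Each animal carries
18S/28S reference wells at constant expression 1, so rRNA normalization
returns the simulated values directly.

Quantification: baseline = mean fluorescence of cycles 3–8; threshold
default = 10% of the baseline-subtracted plateau (scale-invariant; an
absolute-fluorescence policy is available); Cq by linear interpolation of
log fluorescence between the flanking cycles; expression =
scale·E^(−Cq); per-sample normalization to the arithmetic mean of the two
rRNA values (the literal reading of "average of 18S and 28S"; geometric
mean available).  Plates run 50 cycles by default so that the faintest
realistic wells still reach their plateau — a max-based plateau estimate
under-reads unsaturated curves, which was the dominant error source at 40
cycles.  With these settings the noise-free round trip recovers expression
within 0.5%, against a 1% contract set by the interpolation error bound at
a 10% threshold.  Wells that never cross are flagged, and the affected
animal is excluded from index computation by the missing-value policy.

## Panel selection

Candidates for the stress panel are the genes significant (BH-adjusted
p ≤ 0.05, NaN treated as not significant) in *both* stress-vs-control
contrasts.  Filters, in order: protein-coding; same fold-change sign in
both contrasts; relative log2FC discrepancy |a−b|/max(|a|,|b|) ≤ 0.5;
control-expression CV ≤ 0.35.  Survivors are ranked by mean |log2FC|, ties
broken lexicographically, top k = 6 taken; the k = 4 panel is by
construction the rank prefix of the k = 6 panel.  The 0.5 and 0.35 cutoffs
are this package's quantification of "reasonably similar" and "relatively
stable" — no published numbers exist — and are configurable.  The modality
panel uses the same machinery on a single CS-vs-CVS contrast at FDR 0.1
with k = 5 and no cross-contrast checks.  Differential-expression testing
itself is out of scope: DE tables are consumed in the DESeq2 output
dialect, and the count prefilter (≥ 10 in every sample) is provided for
the upstream step.

The packaged DE fixture reproduces the published set structure (124 CVS /
196 CS / 44 shared significant genes) and plants the six panel genes as
the largest coherent effects in the shared stratum, alongside decoy
families that each fail exactly one criterion.  The decoys are placed
*inside* the shared stratum — genes outside it never reach selection, so
only there can they exercise the filters.

## Group statistics

Cohen's d uses D_pooled = √((SD₁² + SD₂²)/2) with sample (n−1) SDs —
consistent with the t-tests, and the unweighted form matches the reported
formula.  Post-hoc comparisons are pooled-variance two-sample t-tests of
each group against control (Welch available), BH-corrected within one
experiment's family of group-vs-control tests (the family definition is a
package choice and is recorded in the output).  Groups with n < 2 are
dropped from the family with a warning rather than failing the run.  The
PC1 diagnostic standardizes log2 expression per gene and decomposes the
correlation matrix (genes sit on heterogeneous scales after
normalization); a covariance option exists for variance-weighted use.  At
the study's group sizes the d estimator carries a small upward
small-sample bias (~2–5% at n = 9–17); recovery tests use a ±0.15 band,
which absorbs it without recalibration.

## Problem sizes and determinism

Replicated checks use 200 cohorts for effect-size recovery and subpanel-SD
estimation (Monte-Carlo SE ≈ 0.04 on d), 300–500 cohorts for the type-I
calibration, and 20–30 for PC1 summaries.  All randomness flows from one
master seed through named substreams (CRC-tagged SeedSequence children),
so identical configuration and seed reproduce every table byte-for-byte
and stages can be regenerated in isolation.

## Known limitations

* The real study's threshold-crossing program is unpublished; only the
  round-trip contract (simulate → quantify recovers ratios) is guaranteed,
  not equality with that tool's Cq values.
* Venn counts and panel identities are exact properties of the fixture
  generator, not re-derivations from deposited sequencing data.
* The duration experiment models endpoint magnitudes only; no decay
  dynamics are fitted.
* The index's behavior under correlated gene noise is untested; the √(k/k′)
  subpanel law assumes independence.
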