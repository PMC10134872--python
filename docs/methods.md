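# Methods

This note documents the quantitative models in `viamet`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical conventions. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Viability-PCR arithmetic

**Model.** qPCR amplifies template by a factor (1+E) per cycle, E ∈ (0, 1.2].
A standard curve `Ct = b + m·log10(copies)` links threshold cycle to input
copies, with `E = 10^(−1/m) − 1` (perfect doubling at m = −1/log10 2 ≈
−3.3219). The fraction of amplifiable template removed by a treatment is

    f_removed = 1 − (1+E)^(−ΔCt),  ΔCt = Ct_treated − Ct_control.

**Efficiency default.** `depletion_efficiency` assumes E = 1 unless a
per-assay efficiency is passed. Published removal percentages in this
assay family are consistent with the doubling assumption (a ΔCt of 4.37
yields 95.16% only under 2^(−ΔCt)), and per-assay slopes are rarely
reported; the standard-curve E is an explicit opt-in
(`RunConfig.efficiency_from_curve`).

**Replicates.** Technical replicate Cts are averaged arithmetically in Ct
space before conversion, matching mean ± SEM reporting conventions.
Averaging in copy space (geometric in Ct) is available via
`average_replicate_ct(..., domain="copies")`; the two differ whenever
replicates disagree, and the choice is surfaced rather than hidden.

**Censoring.** The cycler cap is 40 cycles. Wells that never cross threshold
are *censored*: they carry no Ct, convert to zero copies, and in depletion
arithmetic produce a conservative lower bound (plugging the cap in for
`Ct_treated`), flagged `censored_bound`. Censored values never silently
enter means.

**Unit bookkeeping.** Loads (copies per mL saliva / g feces) require an
explicit conversion block — reaction input volume, elution volume, sample
amount, dilution factor (e.g. a 45-fold fecal predilution). The pipeline
refuses to emit per-unit loads without one; there is no defensible universal
default for bench bookkeeping, so it is config-supplied.

**Rounding.** Display percentages use half-up rounding (2 decimals for
depletion, 1 decimal or integer for survival summaries), matching how bench
software prints these figures; all internal arithmetic is full precision.

## Absolute abundance and response classification

Relative compositions are scaled by per-sample loads; column sums of the
absolute table equal the loads by construction (a conservation law the tests
enforce). Spike-in rows are removed and the remainder renormalised before
any diversity or fold-change computation; a spike strain absent from the
table triggers a warning, not an error, because extraction bias can
legitimately make a strain (especially Gram-positive, thick-walled ones)
undetectable by sequencing.

**Shared species** are those detected (abundance > 0 in ≥ 1 control
replicate) in every host of a sample type — "shared" has no standard
definition, so the reference group is configurable (`groups=` argument).

**Fold changes** are control-mean / treated-mean per species, paired by
(host, replicate index) pooled across hosts (n = 9 pairs in the reference
3×3 design; per-host-mean pairing with n = 3 is exposed as `pairing=
"host_mean"` since the pairing unit in published analyses is often
ambiguous). A zero group mean is replaced by a pseudocount — half the
smallest positive value in the table — and flagged; substituting the *mean*
rather than every zero entry keeps the reciprocal identity
fc(A,B)·fc(B,A) = 1 exact whenever no pseudocount fires. No multiple-testing
correction is applied by default (per-species tests are reported as-is);
Benjamini–Hochberg is available via `adjust="bh"`.

**Classification thresholds** come from the fold-change conventions for
these treatments: responsive above 4× (lyPMAxx), 10× (freezing, saliva) or
25× (freezing, feces); resilient below 2.5×; intermediate between. All are
overridable as `(responsive_min, resilient_max)` pairs.

**Wilcoxon signed-rank.** Zero differences are dropped; tied absolute
differences get average ranks. For ≤ 12 nonzero differences the null
distribution of W+ is built by full enumeration of the 2^n sign vectors, so
the two-sided p (doubled smaller tail, capped at 1) is exact even under
ties; above that, a normal approximation with tie and continuity corrections
is used. The enumeration bound of 12 keeps the exact path under 4096
evaluations — instantaneous — while covering every realistic paired design
here (n ≤ 9).

## Diversity layer

Shannon uses natural log (base-2 optional) and Simpson is the Gini–Simpson
complement 1 − Σp², the defaults of the standard ecology software; alpha
diversity is computed on species-level relative abundances without
rarefaction (shotgun-derived compositions, not counts). Bray–Curtis is
Σ|x−y|/Σ(x+y). PCoA is classical (Torgerson) scaling: double-centre −D²/2,
eigendecompose, keep the top nonnegative eigenvalues; negative eigenvalue
mass (non-Euclidean input) is dropped but reported. Axis signs are fixed by
orienting each axis so its largest-magnitude coordinate is positive, making
ordinations reproducible across runs and platforms.

ANOSIM uses R = (mean between-group rank − mean within-group rank)/(M/2)
with M = n(n−1)/2 and average-rank ties, and a label-permutation p-value
p = (1 + #{R_perm ≥ R_obs})/(1 + n_permutations) from a seeded generator —
bit-for-bit reproducible for a fixed seed. Default 999 permutations, so the
smallest attainable p is 0.001. The within- vs between-host comparison uses
the unpaired two-sided rank-sum test, consistent with how unpaired
alpha-diversity contrasts are tested; an all-identical distance set is
degenerate and reported as p = 1 with a flag.

For host-structured designs the ANOSIM grouping used by the pipeline is the
*individual*, since the question of interest is whether personal signatures
survive treatment. An R statistic with Bray–Curtis input is characteristic
of ANOSIM; a PERMANOVA-style pseudo-F analysis is deliberately out of scope.

## The simulator

`generate_study` emulates the reference spike-in design: 3 hosts × 3 groups
(control, lyPMAxx, frozen+lyPMAxx) × 3 technical replicates for saliva and
feces (54 samples), with four exogenous strains — two heat-killed, two live,
one Gram+/Gram− of each — spiked at ~10% of the native load (within the
5–15% band that calibrates quantification without distorting the endogenous
community), in fixed mutual proportions.

Generative chain per sample:

1. **Community.** A shared core of species per sample type (defaults: 102
   saliva, 63 feces) plus ~20 private species per host; log-normal core
   weights (σ = 2) with per-host log-normal perturbation (σ = 0.7);
   per-taxon live fractions from Beta distributions (means 0.64 saliva,
   0.57 feces); total loads log-normal around 10⁹ copies/mL (saliva) and
   10¹¹ copies/g (feces); per-replicate aliquot jitter σ = 0.05.
2. **Treatment maps.** lyPMAxx keeps 60% of live-cell DNA, 5% of
   dead/exposed DNA and 5×10⁻⁴ of host DNA. Freezing moves killed cells
   into the exposed pool with per-taxon survival drawn from per-phylum Beta
   distributions, then lyPMAxx applies. Amplifiable totals can only
   decrease (tested invariant).
3. **qPCR readout.** Ct = curve(copies in reaction) + N(0, 0.15 cycles),
   censored at 40 cycles; triplicate wells; 1 µL of a 50-µL eluate per
   sample unit (template fraction 0.02), which makes the load arithmetic
   exactly invertible by the analysis side's default conversion block.
4. **Sequencing readout.** Multinomial reads (default depth 10⁵) with
   probabilities ∝ copies × genome length × extraction efficiency; host
   reads ∝ host cells × host genome mass (≈10³ × bacterial). Reported
   relative abundances divide read counts by genome length and renormalise
   (taxon-profiler convention), so extraction bias — Gram-positive
   efficiencies drawn lower than Gram-negative, and the Gram+ dead spike
   fixed at 0.01 — propagates into the tables as it does in real data.

**Calibration of defaults.** The defaults were set so the *observables*
match the magnitudes reported for such experiments: pre-treatment saliva
host-read fraction ≈ 0.85 (feces ≈ 0.001) collapsing below 1% after
treatment; post-lyPMAxx loads ≈ 40%/36% of control (saliva/feces), i.e.
roughly 60% of the community dead or injured; frozen-group loads ≈ 35%/6%
of the untreated control. Note the frozen-group figures are *load ratios
against the untreated control*, not cell-survival probabilities: because
~40–45% of the community is already dead before freezing, a frozen saliva
load of 35% of control corresponds to per-cell freeze-thaw survival near
0.83, and the tiny fecal ratios are dominated by residual dead-DNA signal
(5% retention) rather than surviving cells. The per-phylum Betas encode the
qualitative pattern that Proteobacteria suffer most in saliva while
Bacteroidetes/Firmicutes suffer most in feces and Actinobacteria are
relatively spared.

**Randomness contract.** One root seed; every sample draws from an
independent `SeedSequence` substream keyed by (sample type, host, group,
replicate), so enlarging the design never perturbs existing samples.
Identical seed + config give byte-identical outputs (hash-checked).

**What the simulator does not emulate** — and hence what passing recovery
tests do *not* establish about real data: read-level artefacts (errors,
chimeras, mapping ambiguity), 16S copy-number variation per genome (one
copy count per taxon keeps load arithmetic exactly invertible), PCR
amplification bias across cycles, dye dose–response (concentration enters
only as alternative retention presets, not a fitted curve), compositional
correlations between taxa, and temporal/biological replicate structure
beyond log-normal jitter. Recovery results demonstrate estimator
correctness under the stated generative model, not robustness to every
real-world artefact.

## Problem sizes and numerical choices

The test suite and acceptance script run the reference 54-sample design at
sequencing depth 10⁵ and 200 simulate-and-estimate depletion rounds; these
sizes give Monte-Carlo error well inside the asserted tolerances while
keeping a full run in seconds. Tolerances: standard-curve round trips and
PCoA distance reconstruction at 1e-9 (double-precision exact paths);
renormalisation and load conservation at 1e-6 (accumulated float error over
table-sized sums); the depletion-recovery band at ±2 percentage points
around 95% (the ΔCt estimator's noise floor at 0.15-cycle noise and
triplicates is ~0.12 cycles ≈ 0.8 points). Ties in ranks always use
average ranks; degenerate inputs (all-zero compositions, all-zero
differences, identical samples) raise typed errors or return flagged
degenerate results rather than NaNs.

## Known limitations

* Depletion efficiencies above ~99.9% are extrapolations of the
  exponential model; at ΔCt > 10 the treated signal approaches the assay's
  detection limit and the censored-bound path takes over.
* The pseudocount policy makes folds for fully-extinguished species
  threshold-dependent; such species are flagged and should be read as
  "reduced below detection", not as a precise fold.
* `species_fold_change` assumes equal replicate structure between groups;
  unbalanced designs fall back to the intersection of (host, replicate)
  keys.
* ANOSIM p-values are permutation-resolution-limited (min 1/(n_perm+1));
  exact enumeration is feasible only for very small designs and is used in
  the tests as an oracle, not in the pipeline.
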