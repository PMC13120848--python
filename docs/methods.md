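# Methods

This note documents the models, conventions, and numerical choices behind
`dux4kit`, and what the synthetic-data generators do and do not emulate.

## Seed definitions and matching

The seed region of an siRNA guide strand is its 5′-terminal bases 1–8.
Four seed windows are extracted: 8mer = bases 1–8, 7mer_a = 1–7,
7mer_b = 2–8, and 6mer = 2–7. The 6mer window follows the canonical miRNA
seed convention (bases 2–7); because only "bases 1–8" constrains it, the
window is configurable (`1-6`, `2-7`, `3-8`). With the default, every 7mer
window contains the 6mer, so seed-match hits are nested:
8mer ⊆ 7mer_a, 7mer_b ⊆ 6mer (a property test enforces this).

A UTR "match" is an exact occurrence of the seed's DNA reverse complement
on the given sense strand; there is no A1 anchoring, G:U wobble, or
thermodynamic weighting. Overlapping occurrences are counted individually,
but all downstream statistics use the binary per-gene hit flag. `N`
positions never match.

The background gene set is built from simulated siRNAs: uniform i.i.d.
RNA 19-mers (default 10 guides, seed 1020), redrawn whenever a draw's 6mer
seed equals any seed of the siRNA under study, so the background cannot
share the test seed. The background is the union of genes with ≥ 1 6mer
match over the simulated guides — an intersection would usually be empty.

## Off-target statistics

For each seed class, the log₂ fold-change distribution of seed-matched
genes is compared with the background distribution. The effect size is
the Mann–Whitney AUC,

    AUC = [#(x_i < y_j) + ½·#(x_i = y_j)] / (n·m),

oriented so that repression of matched genes (more negative fold-changes)
gives AUC > 0.5. It is computed through the tie-corrected rank formula,
which is exact at any sample size; a signed ECDF-area alternative
(`ecdf_shift_area`, equal to mean(y) − mean(x)) is provided for comparison.
Genes belonging to both the matched and background sets are removed from
the background. Significance uses the two-sided two-sample KS test with
the asymptotic Kolmogorov p-value at effective size nm/(n+m), clamped into
(0, 1]; a degenerate comparison (a seed class with no matched genes) is
reported with NaN statistics rather than raised. "Expressed genes" means
genes surviving the average-log₂CPM ≥ −3 filter.

## Composite scoring

The FSHD composite is 2^(−ΔΔCt) × 100 where ΔCt is the per-well difference
between the mean Ct of the four DUX4-target genes and the mean Ct of the
two housekeeping genes, and ΔΔCt is taken against the *mean* mock ΔCt.
"Average Ct" is the arithmetic mean of raw Ct values. ΔCt is computed per
well and group summaries are mean ± SD across wells; for balanced designs
this is nearly identical to averaging Ct first. Undetermined Cts exclude
the well with a warning by default and raise in strict mode. Two exact
invariants are tested: adding c cycles to every treated target Ct
multiplies the composite by 2^(−c), and adding a constant to *all* Ct
values leaves it unchanged.

Geometric-mean composites over count panels add a configurable floor
(default 0, erroring on zeros; 0.5 is sensible for count data) and scale
to 100 × value / mean(reference group). NanoString-style normalization
applies three sequential steps — per-sample positive-control scaling to
the platform geometric mean, the same over housekeeping probes, then a
per-probe division by the calibrator-sample mean (skipped when no
calibrators are flagged) — and is idempotent. The DUX4 signal is the
arithmetic mean of the three DUX4-specific probes after normalization.

## DE plumbing

Differential-expression tables (log₂FC, p, FDR, average log₂CPM) are
consumed, not produced: moderated statistics and covariate fits are out of
scope. `welch_de` supplies a plain Welch t-test on log₂CPM for synthetic
end-to-end testing only and is not equivalent to a moderated fit on real
data. log₂CPM uses a default pseudocount of 0.5 (0 allowed for exactness
tests; zero counts then map to −inf). FDR is Benjamini–Hochberg.
Threshold strictness is taken literally from the printed inequalities:
log₂FC ≥ 1 (up) / ≤ −1 (down), FDR < 0.05, average log₂CPM < −3
eliminates, panel selection requires TPM > 35 and log₂FC > 1.5 (both
strict). The 87-gene human signature is not shipped; signatures are
user-supplied gene-set files.

## PK/PD fitting

*Half-life.* OLS of ln(concentration) on time over all observations
(a group-mean mode is available); λ = −slope and t½ = ln 2 / λ, reported
only when λ > 0. The conventional printed form "t½ = −0.693/λ with
λ = −slope" is sign-inconsistent for a decaying profile; the implementation
uses the positive-half-life reading. t½ is invariant to rescaling all
concentrations, and the two-point case reduces to the closed form
(t₂−t₁)·ln2 / ln(c₁/c₂).

*Dose-response.* The three-parameter log(inhibitor)-vs-response model
response = bottom + (top − bottom)/(1 + 10^(x − log₁₀EC50)) with
x = log₁₀(concentration) and the Hill slope fixed at −1 (the GraphPad
convention); a variable-slope four-parameter variant sits behind a flag.
Fitting is bounded least squares over 8 deterministic starts (two bottom
guesses × a 4-point log-EC50 grid, top started at max response); the best
residual sum of squares wins, and failure from every start raises with
diagnostics. Responses are percentages of control, so Emax is reported as
100 − bottom. Flat response vectors are rejected ("no decline").

*Standard curves* fit signal vs log₁₀(concentration) and back-interpolate;
out-of-range samples are flagged extrapolated but still quantified.
*Hill binding* fits signal = Bmax·Xʰ/(Kdʰ + Xʰ) by bounded least squares
over a deterministic start grid. *RISC loading* is the plain ratio of
siRNA to miR-16 levels.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of `SimulationConfig`: a fixed seed
yields byte-identical outputs, and every generator returns a ground-truth
registry so recovery can be asserted.

- **UTRs** are i.i.d. uniform nucleotide strings (default 2000 genes,
  lengths uniform on 200–1500 nt), a configurable fraction carrying one
  implanted reverse-complement site of the designated guide's 8mer seed.
  Real UTRs have composition bias and repeats; chance-match rates here
  follow the closed form 1 − (1 − 4⁻⁶)^(L−5) per gene, which a test checks.
- **Counts** are negative binomial with log-normal baseline means
  (defaults: log₂ mean 5 ± 2, dispersion 0.1 — donor-level variability)
  and a planted log₂FC on registry genes in the treated group. The
  end-to-end signature-recovery test instead uses the conditions a
  replicate-well design implies: within-cell-line dispersion 0.005
  (BCV ≈ 0.07), baseline means around 2⁹ counts, and a signature that is a
  small fraction of the transcriptome (100 of 4000 genes). Under those
  conditions ≥ 90% of signature genes are recovered as significantly
  suppressed; with donor-level dispersion and shallow libraries a 4-vs-4
  Welch test cannot reach BH-adjusted significance for most genes, which
  is a real limitation of small-n designs, not of the implementation.
- **Ct tables** emulate sporadic burst-like DUX4-target expression:
  housekeeping Cts ~ N(20, 0.2²), target Cts at baseline 30 minus a
  per-well Bernoulli(0.3) burst of 3 cycles, plus N(0, 0.2²) noise;
  treatment adds a knockdown ΔCt to target genes. Bursts hit both arms,
  so they cancel in mean ΔΔCt but Jensen-inflate the *arithmetic* mean of
  per-well composites symmetrically; knockdown recovery is therefore
  checked on the geometric mean, 2^(−mean ΔΔCt)·100, which returns ~25%
  for a 2-cycle knockdown.
- **Concentration series** are c₀·e^(−λt)·e^ε with ε ~ N(0, CV²), default
  λ = 0.0495/day (t½ ≈ 14 days, matching a >2-week muscle half-life),
  4 time points (7/14/28/56 days) × 5 animals. At CV = 0.2 the fitted
  half-life lands within 10% of truth.
- **Dose-response** draws from the three-parameter curve with defaults
  bottom 5%, top 100%, log₁₀EC50 = −0.5 (0.32 nM, in the sub-nanomolar
  range the assay this mirrors reports), 8 concentrations spanning
  10⁻³–10² nM, 4 replicates, Gaussian noise (default off). The planted
  off-target simulation shifts 200 matched genes by −0.3 log₂FC against
  2000 background genes with null spread sd 0.5 — a typical spread of
  per-gene log₂FC estimates in a small-n design.

Passing tests on these generators demonstrate correctness of the
computations and calibration of the statistics under the stated models;
they do not establish performance on real sequencing data, which has
correlated genes, composition bias, and batch structure none of the
generators produce.

## Problem sizes and runtimes

Default test and acceptance runs use 1000-replicate null calibration at
n = m = 100, 100 planted off-target replicates, 200 noisy dose-response
refits, 500 wells per arm for composite recovery, and 4000-gene expression
experiments — sizes chosen so the whole suite completes in well under a
minute on one CPU while keeping Monte Carlo error far inside the asserted
tolerances.

## Known limitations

- Seed matching is positional and exact; no pairing thermodynamics,
  ORF/5′UTR sites, or transcript-isoform resolution.
- The Welch DE step is plumbing for synthetic tests, not a substitute for
  moderated statistics with covariates.
- The KS p-value is asymptotic; for very small gene sets the exact
  permutation null would differ.
- NanoString calibration implements the per-probe calibrator ratio only;
  plate-level PlexSet specifics beyond that are not modeled.
- Half-life fitting uses all post-dose points; no terminal-phase selection
  or compartmental modeling.
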