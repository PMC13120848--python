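# dux4kit

Quantitative analysis toolkit for the development of DUX4-targeting siRNA
therapeutics in facioscapulohumeral muscular dystrophy (FSHD).

FSHD is caused by aberrant expression of the DUX4 transcription factor in
skeletal muscle. Because DUX4 itself fires in rare, short-lived bursts, its
activity is quantified through downstream DUX4-regulated genes — and an
siRNA drug campaign against *DUX4* needs a set of standard quantitative
procedures around that readout. `dux4kit` implements them as a tested,
reusable library with a CLI:

- **Seed-based off-target profiling** (`dux4kit.seeds`, `dux4kit.offtarget`):
  extract the 6mer/7mer/8mer seeds from guide bases 1–8, scan 3′UTRs for
  reverse-complement seed matches, build a background gene set from
  simulated siRNAs, and compare log₂ fold-change distributions of matched
  vs background genes with a Mann–Whitney AUC effect size and a two-sample
  Kolmogorov–Smirnov test.
- **FSHD composite DUX4-activity score** (`dux4kit.scoring`): from qPCR Ct
  tables,

  ```
  ΔCt  = mean Ct(4 DUX4-target genes) − mean Ct(2 housekeeping genes)
  ΔΔCt = ΔCt(treated) − mean ΔCt(mock)
  composite = 2^(−ΔΔCt) × 100   (% of mock)
  ```

  plus single-gene Livak 2^(−ΔΔCt) relative expression, geometric-mean
  composites over normalized count panels, and NanoString-style
  positive-control / housekeeping / calibrator normalization.
- **DE signature tools** (`dux4kit.de`): log₂CPM, the average-log₂CPM < −3
  low-expression filter, Benjamini–Hochberg FDR, signature concordance
  counting (induced in disease, suppressed by treatment), and
  DUX4-responsive panel selection (TPM > 35, log₂FC > 1.5).
- **PK/PD curves** (`dux4kit.pk`): tissue half-life by ln-linear regression
  (t½ = ln 2 / λ, λ = −slope), the GraphPad-style three-parameter
  log(inhibitor)-vs-response EC50/Emax fit, specific binding with Hill
  slope, stem-loop RT-qPCR standard-curve quantification, and RISC-loading
  ratios relative to miR-16.
- **Synthetic data** (`dux4kit.simulate`): deterministic generators for
  every input — UTR populations with planted seed matches,
  negative-binomial count matrices with planted fold-changes, burst-like
  Ct tables, exponential-decay concentration series, sigmoidal
  dose-response data — each with a ground-truth registry for recovery
  tests.

## Worked example

```python
from dux4kit import guide_from_target_site, extract_seeds, hamming_distance
from dux4kit.reference import HUMAN_TARGET_SITE, CYNO_TARGET_SITE
from dux4kit.pk import fit_log_inhibitor_response_3p
from dux4kit.simulate import SimulationConfig, sim_dose_response

guide = guide_from_target_site(HUMAN_TARGET_SITE, "siDUX4.6")
print("guide:", guide.sequence)
for cls, s in sorted(extract_seeds(guide).seeds.items()):
    print(f"{cls:7s} {s}")
print("human vs cyno mismatches:",
      hamming_distance(HUMAN_TARGET_SITE, CYNO_TARGET_SITE))

dr = sim_dose_response(SimulationConfig(rng_seed=1, dr_noise_sd=3.0))
fit = fit_log_inhibitor_response_3p(dr["concentration"], dr["response"])
print(f"EC50 = {fit.ec50:.3f} nM, Emax = {fit.emax:.1f}%")
```

prints

```
guide: UCCAAACGAGUCUCCGUCG
6mer    CCAAAC
7mer_a  UCCAAAC
7mer_b  CCAAACG
8mer    UCCAAACG
human vs cyno mismatches: 1
EC50 = 0.293 nM, Emax = 93.4%
```

The guide strand is the reverse complement of the 19-nt human DUX4 reporter
target site; its four seed windows all come from guide bases 1–8. The
cynomolgus site differs from the human site by a single nucleotide, which
is why both species respond to the same siRNA. The dose-response fit
recovers a sub-nanomolar EC50 and ~93% maximal knockdown from an 8-point
concentration series (true EC50 0.316 nM, Emax 95% before noise).

A complete synthetic screen — simulate inputs, scan seeds, off-target
statistics, composite scoring — runs as

```bash
dux4kit run --out results/screen --seed 1020
```

and writes TSV reports plus a `summary.json`; identical seeds reproduce
identical files byte for byte.

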