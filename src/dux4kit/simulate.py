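"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of a :class:`SimulationConfig`: the same
seed yields byte-identical outputs, and each generator emits a ground-truth
registry alongside its data so downstream recovery can be asserted.

What is emulated, and how:

* 3'UTR populations as i.i.d. uniform nucleotide strings, a configurable
  fraction carrying an implanted reverse-complement site of a designated
  guide's seed;
* RNA-seq counts as negative-binomial draws with log-normal baseline means
  and a planted log2 fold-change on registry genes in the treated group;
* qPCR Ct tables in which DUX4-target genes fire in a sporadic burst-like
  fashion (a per-well Bernoulli burst lowers target Cts by several cycles)
  on top of Gaussian well noise, with treatment adding a knockdown shift
  in cycles;
* tissue concentration-time series as single-exponential decay with
  log-normal noise, and dose-response data from the three-parameter
  log(inhibitor) curve with Gaussian noise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .pk import _inhibitor_model
from .seeds import GuideStrand, SeedSet, UtrRecord, extract_seeds, seed_to_dna_site
from .scoring import CtTable


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters, with defaults mirroring the study's scales.

    Defaults: a ~2000-gene UTR universe, 10 simulated background siRNAs,
    4-vs-4 expression designs, 4 target + 2 housekeeping qPCR genes, a
    14-day tissue half-life sampled at 4 time points with 5 animals each,
    and an 8-point dose-response with sub-nanomolar EC50.
    """

    rng_seed: int = 1020

    # --- UTR universe ---
    n_genes: int = 2000
    utr_length_min: int = 200
    utr_length_max: int = 1500
    planted_fraction: float = 0.1
    implant_seed_class: str = "8mer"

    # --- expression experiment (negative-binomial counts) ---
    n_samples_per_group: int = 4
    nb_dispersion: float = 0.1
    base_mean_log2_mu: float = 5.0
    base_mean_log2_sd: float = 2.0
    planted_log2fc: float = -1.0

    # --- off-target fold-change null ---
    n_matched_genes: int = 200
    n_background_genes: int = 2000
    offtarget_shift: float = -0.3
    lfc_null_sd: float = 0.5

    # --- Ct table (sporadic burst-like DUX4-target expression) ---
    n_wells_per_group: int = 4
    n_target_genes: int = 4
    n_housekeeping_genes: int = 2
    hk_ct_mean: float = 20.0
    hk_ct_sd: float = 0.2
    target_ct_baseline: float = 30.0
    target_ct_sd: float = 0.2
    burst_prob: float = 0.3
    burst_magnitude: float = 3.0
    knockdown_dct: float = 2.0

    # --- concentration-time series ---
    conc_c0: float = 100.0
    conc_decay_rate: float = 0.0495  # per day; t_half ~ 14 d
    conc_cv: float = 0.2
    conc_timepoints: tuple[float, ...] = (7.0, 14.0, 28.0, 56.0)
    conc_n_per_timepoint: int = 5

    # --- dose-response ---
    dr_bottom: float = 5.0
    dr_top: float = 100.0
    dr_log10_ec50: float = -0.5  # EC50 ~ 0.32 nM
    dr_noise_sd: float = 0.0
    dr_n_concentrations: int = 8
    dr_log10_conc_min: float = -3.0
    dr_log10_conc_max: float = 2.0
    dr_n_replicates: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.conc_decay_rate <= 0:
            raise ValueError("conc_decay_rate must be > 0")
        for name in ("n_genes", "n_samples_per_group", "n_wells_per_group",
                     "conc_n_per_timepoint", "dr_n_concentrations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "conc_timepoints" in data:
            data["conc_timepoints"] = tuple(data["conc_timepoints"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conc_timepoints"] = list(data["conc_timepoints"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def sim_utr_database(
    cfg: SimulationConfig, guide: GuideStrand | None = None
) -> tuple[list[UtrRecord], set[str]]:
    """Random 3'UTR universe with optionally implanted seed-match sites.

    Returns the UTR records and a registry of the gene ids that carry an
    implanted reverse-complement site of ``guide``'s configured seed class.
    With ``planted_fraction`` 0 (or no guide) the registry is empty and
    every match is a chance match.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    site = ""
    if guide is not None and cfg.planted_fraction > 0:
        seed = extract_seeds(guide).seeds[cfg.implant_seed_class]
        site = seed_to_dna_site(seed)
    bases = np.array(list("ACGT"))
    n_planted = int(round(cfg.planted_fraction * cfg.n_genes)) if site else 0
    planted_idx = set(
        rng.choice(cfg.n_genes, size=n_planted, replace=False).tolist()
    )
    records, registry = [], set()
    for i in range(cfg.n_genes):
        length = int(rng.integers(cfg.utr_length_min, cfg.utr_length_max + 1))
        if site and length < len(site):
            raise ValueError("implant site longer than the shortest UTR")
        seq = "".join(rng.choice(bases, size=length))
        gene = f"gene_{i + 1:05d}"
        if i in planted_idx:
            pos = int(rng.integers(0, length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
            registry.add(gene)
        records.append(UtrRecord(gene_id=gene, utr_sequence=seq))
    return records, registry


def sim_expression_experiment(
    cfg: SimulationConfig, planted: set[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix with a planted treated-group shift.

    Returns (counts, true_log2fc): counts is genes x samples with columns
    ``control_1..n`` then ``treated_1..n``; planted genes' treated means
    are scaled by 2**planted_log2fc, all other true fold-changes are 0.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    genes = [f"gene_{i + 1:05d}" for i in range(cfg.n_genes)]
    planted = planted or set()
    mu = 2.0 ** rng.normal(cfg.base_mean_log2_mu, cfg.base_mean_log2_sd, cfg.n_genes)
    true_lfc = pd.Series(
        [cfg.planted_log2fc if g in planted else 0.0 for g in genes],
        index=genes,
        name="true_log2fc",
    )
    mu_treated = mu * 2.0 ** true_lfc.to_numpy()

    def nb(mean):
        r = 1.0 / cfg.nb_dispersion
        cols = np.empty((cfg.n_genes, cfg.n_samples_per_group), dtype=np.int64)
        for j in range(cfg.n_samples_per_group):
            cols[:, j] = rng.negative_binomial(r, r / (r + mean))
        return cols

    counts = pd.DataFrame(
        np.hstack([nb(mu), nb(mu_treated)]),
        index=genes,
        columns=[f"control_{j + 1}" for j in range(cfg.n_samples_per_group)]
        + [f"treated_{j + 1}" for j in range(cfg.n_samples_per_group)],
    )
    return counts, true_lfc


def sim_offtarget_foldchanges(
    cfg: SimulationConfig,
) -> tuple[pd.Series, set[str], set[str]]:
    """Fold-change sets with a planted shift on seed-matched genes.

    Background genes draw log2FC ~ N(0, lfc_null_sd); matched genes draw
    from the same distribution shifted by ``offtarget_shift``.  Returns
    (fold-changes, matched gene ids, background gene ids), disjoint sets.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    matched = [f"hit_{i + 1:05d}" for i in range(cfg.n_matched_genes)]
    background = [f"bg_{i + 1:05d}" for i in range(cfg.n_background_genes)]
    fc = pd.Series(
        np.concatenate(
            [
                rng.normal(cfg.offtarget_shift, cfg.lfc_null_sd, len(matched)),
                rng.normal(0.0, cfg.lfc_null_sd, len(background)),
            ]
        ),
        index=matched + background,
        name="log2fc",
    )
    return fc, set(matched), set(background)


def sim_ct_table(cfg: SimulationConfig) -> CtTable:
    """qPCR Ct table with sporadic burst-like DUX4-target expression.

    Housekeeping Cts ~ Normal(hk_ct_mean, hk_ct_sd^2).  Target Cts start at
    ``target_ct_baseline``; with probability ``burst_prob`` a well's target
    genes drop by ``burst_magnitude`` cycles (a DUX4 expression burst) in
    both arms; treated wells add ``knockdown_dct`` cycles to target genes.
    """
    rng = np.random.default_rng(cfg.rng_seed + 3)
    n = cfg.n_wells_per_group
    targets = [f"TGT{i + 1}" for i in range(cfg.n_target_genes)]
    hks = [f"HK{i + 1}" for i in range(cfg.n_housekeeping_genes)]
    samples, rows, conditions = [], [], []
    for cond, shift in (("mock", 0.0), ("treated", cfg.knockdown_dct)):
        for w in range(n):
            burst = cfg.burst_magnitude * (rng.random() < cfg.burst_prob)
            t_ct = (
                cfg.target_ct_baseline
                - burst
                + shift
                + rng.normal(0.0, cfg.target_ct_sd, len(targets))
            )
            h_ct = rng.normal(cfg.hk_ct_mean, cfg.hk_ct_sd, len(hks))
            samples.append(f"{cond}_{w + 1}")
            conditions.append(cond)
            rows.append(np.concatenate([t_ct, h_ct]))
    ct = pd.DataFrame(rows, index=samples, columns=targets + hks)
    condition = pd.Series(conditions, index=samples, name="condition")
    return CtTable(ct=ct, condition=condition, group=condition.rename("group"))


def sim_conc_time(cfg: SimulationConfig) -> pd.DataFrame:
    """Tissue concentration-time series: exponential decay, log-normal noise.

    c(t) = c0 * exp(-lambda t) * exp(eps), eps ~ N(0, cv^2), sampled at the
    configured time points with ``conc_n_per_timepoint`` animals each.
    """
    rng = np.random.default_rng(cfg.rng_seed + 4)
    rows = []
    for t in cfg.conc_timepoints:
        for a in range(cfg.conc_n_per_timepoint):
            eps = rng.normal(0.0, cfg.conc_cv)
            conc = cfg.conc_c0 * np.exp(-cfg.conc_decay_rate * t) * np.exp(eps)
            rows.append((t, conc, a + 1))
    return pd.DataFrame(rows, columns=["time_days", "concentration", "animal"])


def sim_dose_response(cfg: SimulationConfig) -> pd.DataFrame:
    """Dose-response data from the 3-parameter inhibitor curve plus noise."""
    rng = np.random.default_rng(cfg.rng_seed + 5)
    conc = np.logspace(
        cfg.dr_log10_conc_min, cfg.dr_log10_conc_max, cfg.dr_n_concentrations
    )
    rows = []
    for rep in range(cfg.dr_n_replicates):
        mean = _inhibitor_model(
            np.log10(conc), cfg.dr_bottom, cfg.dr_top, cfg.dr_log10_ec50
        )
        resp = mean + rng.normal(0.0, cfg.dr_noise_sd, conc.size) if cfg.dr_noise_sd > 0 else mean
        for c, r in zip(conc, resp):
            rows.append((c, r, rep + 1))
    return pd.DataFrame(rows, columns=["concentration", "response", "replicate"])
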