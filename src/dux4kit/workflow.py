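"""End-to-end synthetic screen orchestration.

Runs the stages in dependency order — simulate inputs, extract and scan
seeds, off-target statistics against the simulated background, composite
scoring — and writes all reports plus a machine-readable JSON summary.
Identical configuration and seeds produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io, reference
from .de import welch_de
from .offtarget import seed_offtarget_profile
from .scoring import fshd_composite
from .seeds import (
    BackgroundSpec,
    build_simulated_background,
    extract_seeds,
    guide_from_target_site,
    scan_utr_matches,
)
from .simulate import (
    SimulationConfig,
    sim_ct_table,
    sim_expression_experiment,
    sim_utr_database,
)

STAGES = ("simulate", "scan", "offtarget", "composite")


@dataclass
class WorkflowConfig:
    out_dir: str
    rng_seed: int = 1020
    stages: tuple[str, ...] = STAGES
    guide_sequence: str | None = None  # default: complement of the human target site
    six_mer_window: str = "2-7"
    n_simulated_sirnas: int = reference.N_SIMULATED_SIRNAS
    sim: SimulationConfig | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def write_reports(results: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write each result table as TSV; return the manifest of written files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for name, df in results.items():
        path = out / f"{name}.tsv"
        io.write_table(df, path)
        manifest.append(path.name)
    return manifest


def run_workflow(cfg: WorkflowConfig) -> dict:
    """Execute the configured stages; return the machine-readable summary.

    The summary (also written to ``summary.json``) records the parameters,
    the file manifest, and the headline numbers of each stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim or SimulationConfig(rng_seed=cfg.rng_seed)
    guide_seq = cfg.guide_sequence
    if guide_seq is None:
        guide_seq = guide_from_target_site(
            reference.HUMAN_TARGET_SITE, "guide"
        ).sequence
    summary: dict = {
        "parameters": {
            "rng_seed": cfg.rng_seed,
            "stages": list(cfg.stages),
            "guide_sequence": guide_seq,
            "six_mer_window": cfg.six_mer_window,
            "n_simulated_sirnas": cfg.n_simulated_sirnas,
        },
        "stages": {},
    }
    results: dict[str, pd.DataFrame] = {}
    state: dict = {}

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("simulate"):
            stage = "simulate"
            guide = guide_from_target_site(reference.HUMAN_TARGET_SITE, "guide")
            if cfg.guide_sequence is not None:
                from .seeds import GuideStrand

                guide = GuideStrand(id="guide", sequence=cfg.guide_sequence)
            utrs, registry = sim_utr_database(sim, guide)
            io.write_fasta(utrs, out / "utrs.fasta")
            counts, true_lfc = sim_expression_experiment(sim, registry)
            ct_table = sim_ct_table(sim)
            io.write_ct_table(ct_table, out / "ct_table.tsv")
            state.update(
                guide=guide, utrs=utrs, registry=registry, counts=counts,
                ct_table=ct_table,
            )
            summary["stages"]["simulate"] = {
                "n_utrs": len(utrs),
                "n_planted": len(registry),
                "n_count_samples": counts.shape[1],
            }

        if _stage("scan"):
            stage = "scan"
            seeds = extract_seeds(state["guide"], cfg.six_mer_window)
            matches = scan_utr_matches(seeds, state["utrs"])
            results["seed_matches"] = matches
            state["seeds"] = seeds
            state["matches"] = matches
            summary["stages"]["scan"] = {
                cls: int(matches[(matches.seed_class == cls) & matches.hit].shape[0])
                for cls in ("6mer", "7mer_a", "7mer_b", "8mer")
            }

        if _stage("offtarget"):
            stage = "offtarget"
            background = build_simulated_background(
                BackgroundSpec(
                    n_simulated_sirnas=cfg.n_simulated_sirnas,
                    rng_seed=cfg.rng_seed,
                    six_mer_window=cfg.six_mer_window,
                ),
                state["utrs"],
                exclude=state["seeds"],
            )
            counts = state["counts"]
            de = welch_de(
                counts,
                [c for c in counts.columns if c.startswith("treated")],
                [c for c in counts.columns if c.startswith("control")],
            )
            fc = de["log2fc"]
            expressed = set(fc.index)
            matches = state["matches"]
            profile = seed_offtarget_profile(
                fc,
                matches[matches.gene_id.isin(expressed)],
                background & expressed,
            )
            results["offtarget_profile"] = profile
            summary["stages"]["offtarget"] = {
                "n_background": len(background & expressed),
                "auc_6mer": _round(profile.set_index("seed_class").loc["6mer", "auc"]),
                "ks_p_6mer": _round(profile.set_index("seed_class").loc["6mer", "ks_p"]),
            }

        if _stage("composite"):
            stage = "composite"
            comp = fshd_composite(
                state["ct_table"],
                [f"TGT{i + 1}" for i in range(sim.n_target_genes)],
                [f"HK{i + 1}" for i in range(sim.n_housekeeping_genes)],
            )
            results["composite_per_sample"] = comp.per_sample
            results["composite_summary"] = comp.summary
            treated = comp.summary.set_index("group")
            summary["stages"]["composite"] = {
                g: _round(treated.loc[g, "mean"]) for g in treated.index
            }
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise StageError(stage, exc) from exc

    manifest = write_reports(results, out)
    for extra in ("utrs.fasta", "ct_table.tsv"):
        if (out / extra).exists():
            manifest.append(extra)
    summary["manifest"] = sorted(manifest)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _round(x, ndigits: int = 10):
    """Round for byte-stable JSON output."""
    import math

    x = float(x)
    return None if math.isnan(x) else round(x, ndigits)
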