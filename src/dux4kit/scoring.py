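"""Composite DUX4-activity scoring from qPCR Ct tables and NanoString counts.

DUX4 itself is expressed at low, sporadic levels, so DUX4 activity is
measured through downstream DUX4-regulated genes.  The FSHD composite score
integrates four such genes against two housekeeping references:

    dCt  = mean Ct(4 DUX4-target genes) - mean Ct(2 housekeeping genes)
    ddCt = dCt(treated) - mean dCt(mock)
    composite = 2^(-ddCt) * 100  (% of mock)

Also provided: single-gene Livak 2^(-ddCt) relative expression,
geometric-mean composites over normalized count panels (the in vivo
readout), and NanoString-style positive-control / housekeeping / calibrator
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean


@dataclass
class CtTable:
    """Sample x gene cycle-threshold matrix with per-row condition labels.

    ``ct`` rows are wells/samples, columns are genes; NaN marks an
    undetermined Ct (no amplification).  ``condition`` distinguishes
    "treated" from "mock" rows; ``group`` is a free treatment-group label.
    """

    ct: pd.DataFrame
    condition: pd.Series
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.ct.index.equals(self.condition.index):
            raise ValueError("condition labels must be indexed by sample")
        if self.group is not None and not self.ct.index.equals(self.group.index):
            raise ValueError("group labels must be indexed by sample")


@dataclass
class CompositeResult:
    """Per-well composite scores plus group-level summaries."""

    per_sample: pd.DataFrame  # sample, condition, group, delta_ct, delta_delta_ct, composite_percent
    summary: pd.DataFrame     # group, n, mean, sd of composite_percent


def _require_genes(ct: pd.DataFrame, genes: Sequence[str]) -> None:
    missing = [g for g in genes if g not in ct.columns]
    if missing:
        raise KeyError(f"Ct table is missing gene columns {missing}")


def _drop_undetermined(
    ct: pd.DataFrame, genes: Sequence[str], strict: bool
) -> pd.DataFrame:
    bad = ct[list(genes)].isna().any(axis=1)
    if bad.any():
        if strict:
            raise ValueError(
                f"undetermined Ct in required cells for wells {list(ct.index[bad])}"
            )
        warnings.warn(
            f"excluding {int(bad.sum())} well(s) with undetermined Ct",
            stacklevel=3,
        )
    return ct.loc[~bad]


def fshd_composite(
    table: CtTable,
    target_genes: Sequence[str],
    hk_genes: Sequence[str],
    mock_label: str = "mock",
    strict: bool = False,
) -> CompositeResult:
    """FSHD composite DUX4-activity score, per well and per group.

    dCt is computed per well (mean target Ct minus mean housekeeping Ct),
    ddCt against the mean dCt of the mock wells, and the composite as
    2^(-ddCt)*100.  Mock wells are scored too (they average to 100% on the
    log scale by construction).  Wells with an undetermined Ct in a
    required cell are excluded with a warning, or rejected under
    ``strict=True``.
    """
    needed = list(target_genes) + list(hk_genes)
    _require_genes(table.ct, needed)
    ct = _drop_undetermined(table.ct, needed, strict)
    condition = table.condition.loc[ct.index]
    if not (condition == mock_label).any():
        raise ValueError(f"no rows labelled {mock_label!r}")

    delta_ct = ct[list(target_genes)].mean(axis=1) - ct[list(hk_genes)].mean(axis=1)
    reference = delta_ct[condition == mock_label].mean()
    delta_delta_ct = delta_ct - reference
    composite = 100.0 * np.exp2(-delta_delta_ct)

    group = (
        table.group.loc[ct.index]
        if table.group is not None
        else condition.rename("group")
    )
    per_sample = pd.DataFrame(
        {
            "condition": condition,
            "group": group,
            "delta_ct": delta_ct,
            "delta_delta_ct": delta_delta_ct,
            "composite_percent": composite,
        }
    )
    summary = (
        per_sample.groupby("group", sort=True)["composite_percent"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
    )
    return CompositeResult(per_sample=per_sample, summary=summary)


def relative_expression_ddct(
    table: CtTable,
    gene: str,
    reference_gene: str,
    control_group: str,
    strict: bool = False,
) -> pd.Series:
    """Livak 2^(-ddCt) relative expression of one gene vs a reference gene.

    ddCt is taken against the mean dCt of the ``control_group`` rows, so a
    control sample with group-average Cts scores exactly 1.0.
    """
    _require_genes(table.ct, [gene, reference_gene])
    if table.group is None:
        raise ValueError("CtTable has no group labels")
    ct = _drop_undetermined(table.ct, [gene, reference_gene], strict)
    group = table.group.loc[ct.index]
    if not (group == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")
    delta_ct = ct[gene] - ct[reference_gene]
    reference = delta_ct[group == control_group].mean()
    return np.exp2(-(delta_ct - reference)).rename(f"{gene}_rel_expr")


def geometric_mean_composite(
    panel: pd.DataFrame,
    group: pd.Series,
    genes: Sequence[str],
    reference_group: str,
    floor: float = 0.0,
) -> pd.Series:
    """Geometric-mean composite expression, as % of the reference group.

    Per sample, the geometric mean over ``genes`` of (value + floor);
    the composite is 100 * value / mean(reference-group values).  The floor
    guards against zero counts; with floor 0 a zero value is an error.
    """
    _require_genes(panel, genes)
    if not panel.index.equals(group.index):
        raise ValueError("group labels must be indexed by sample")
    if not (group == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    values = panel[list(genes)].to_numpy(dtype=float) + floor
    if (values <= 0).any():
        raise ValueError(
            "non-positive value in geometric mean; raise `floor` or clean input"
        )
    gm = pd.Series(gmean(values, axis=1), index=panel.index)
    ref_mean = gm[group == reference_group].mean()
    return (100.0 * gm / ref_mean).rename("composite_percent")


@dataclass
class NanoStringRun:
    """Raw NanoString-style counts with probe classes and calibrator flags.

    ``counts``: samples x probes raw counts.  ``probe_class`` maps each
    probe to one of {"endogenous", "positive", "housekeeping", "dux4"}.
    ``calibrator``: boolean per-sample flags marking calibrator samples
    (may be all False, in which case the calibrator step is skipped).
    """

    counts: pd.DataFrame
    probe_class: dict[str, str]
    calibrator: pd.Series | None = None

    def __post_init__(self) -> None:
        unknown = set(self.probe_class.values()) - {
            "endogenous", "positive", "housekeeping", "dux4"
        }
        if unknown:
            raise ValueError(f"unknown probe classes {sorted(unknown)}")
        missing = set(self.counts.columns) - set(self.probe_class)
        if missing:
            raise ValueError(f"probes without a class: {sorted(missing)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.probes_of("positive")) < 2:
            raise ValueError("need >= 2 positive-control probes")
        if len(self.probes_of("housekeeping")) < 1:
            raise ValueError("need >= 1 housekeeping probe")
        if self.calibrator is not None and not self.counts.index.equals(
            self.calibrator.index
        ):
            raise ValueError("calibrator flags must be indexed by sample")

    def probes_of(self, cls: str) -> list[str]:
        return [p for p, c in self.probe_class.items() if c == cls and p in self.counts.columns]


@dataclass
class NanoStringResult:
    normalized: pd.DataFrame
    dux4_signal: pd.Series | None  # mean of DUX4-specific probes, or None


def _content_factors(counts: pd.DataFrame, probes: list[str]) -> pd.Series:
    """Per-sample scaling: platform geomean of per-sample geomeans / sample geomean."""
    per_sample = pd.Series(
        gmean(counts[probes].to_numpy(dtype=float), axis=1), index=counts.index
    )
    if (per_sample <= 0).any() or not np.isfinite(per_sample).all():
        raise ValueError("zero or invalid control geometric mean")
    return gmean(per_sample) / per_sample


def nanostring_normalize(run: NanoStringRun) -> NanoStringResult:
    """Three-step normalization: positive controls, housekeeping, calibrators.

    (1) Each sample is scaled so its positive-control geometric mean equals
    the cross-sample (platform) geometric mean; (2) the same construction is
    applied over housekeeping probes; (3) if calibrator samples are flagged,
    every probe is divided by its mean across calibrator samples.  The DUX4
    signal is the arithmetic mean of the "dux4"-class probes after
    normalization.  Applying the procedure to an already-normalized run is
    the identity (all factors 1).
    """
    norm = run.counts.astype(float).copy()
    for cls in ("positive", "housekeeping"):
        factors = _content_factors(norm, run.probes_of(cls))
        norm = norm.mul(factors, axis=0)
    if run.calibrator is not None and run.calibrator.any():
        cal_mean = norm.loc[run.calibrator].mean(axis=0)
        if (cal_mean <= 0).any():
            raise ValueError("zero calibrator mean for some probe")
        norm = norm.div(cal_mean, axis=1)
    dux4_probes = run.probes_of("dux4")
    dux4 = norm[dux4_probes].mean(axis=1).rename("dux4_signal") if dux4_probes else None
    return NanoStringResult(normalized=norm, dux4_signal=dux4)
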