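"""Count normalization, expression filtering, and DUX4-signature concordance.

The differential-expression tables themselves are consumed, not produced
(a moderated-statistics fit is out of scope); :func:`welch_de` offers a
plain Welch t-test on log2CPM as plumbing for synthetic end-to-end tests
and is not equivalent to a moderated fit on real data.

A DeTable is a DataFrame with columns ``log2fc``, ``p_value``, ``fdr``,
``avg_log2cpm`` indexed by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ("log2fc", "p_value", "fdr", "avg_log2cpm")


def log2cpm_matrix(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((c + q) / (lib + 2q) * 1e6).

    ``counts`` is genes x samples with non-negative integer counts.  With
    pseudocount 0, zero counts map to -inf (kept, not raised), which is
    convenient for exactness checks; the default 0.5 keeps values finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have library size > 0")
    with np.errstate(divide="ignore"):
        return np.log2(
            (counts + pseudocount).div(lib + 2 * pseudocount, axis=1) * 1e6
        )


def filter_low_expression(
    log2cpm: pd.DataFrame, threshold: float = -3.0
) -> pd.Index:
    """Genes retained after the low-expression filter.

    A gene is eliminated when its average log2CPM is strictly below the
    threshold (default -3); a row mean exactly at the threshold survives.
    """
    return log2cpm.index[log2cpm.mean(axis=1) >= threshold]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def welch_de(
    counts: pd.DataFrame,
    treated_samples: Sequence[str],
    control_samples: Sequence[str],
    pseudocount: float = 0.5,
    expression_threshold: float = -3.0,
) -> pd.DataFrame:
    """Plumbing two-group DE: Welch t-test on log2CPM, BH-adjusted.

    Applies the low-expression filter before testing.  log2fc is the mean
    log2CPM difference (treated minus control).
    """
    lc = log2cpm_matrix(counts, pseudocount)
    keep = filter_low_expression(lc, expression_threshold)
    lc = lc.loc[keep]
    a = lc[list(treated_samples)].to_numpy()
    b = lc[list(control_samples)].to_numpy()
    t = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(t.pvalue, nan=1.0)  # zero-variance genes: no evidence
    return pd.DataFrame(
        {
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "p_value": p,
            "fdr": bh_fdr(p),
            "avg_log2cpm": lc.mean(axis=1),
        },
        index=keep,
    )


@dataclass
class ConcordanceCounts:
    """Signature concordance between a disease and a treatment contrast."""

    up_in_disease: int
    suppressed: int              # of the up genes, treatment log2fc < 0
    suppressed_significant: int  # of those, treatment fdr < threshold
    down_in_disease: int
    reversed_up: int             # of the down genes, treatment log2fc > 0
    reversed_significant: int


def _check_de(de: pd.DataFrame, name: str) -> None:
    missing = [c for c in ("log2fc", "fdr") if c not in de.columns]
    if missing:
        raise KeyError(f"{name} table is missing columns {missing}")


def signature_concordance(
    disease_de: pd.DataFrame,
    treatment_de: pd.DataFrame,
    signature: Sequence[str] | None = None,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> ConcordanceCounts:
    """Count signature genes induced in disease and reverted by treatment.

    Up-in-disease means disease log2fc >= lfc_threshold with fdr <
    fdr_threshold (printed inequalities taken literally); "suppressed"
    genes additionally have negative treatment log2fc, and "significant"
    ones treatment fdr < fdr_threshold.  Mirrored logic applies to genes
    down in disease (log2fc <= -lfc_threshold).  With ``signature=None``
    the whole shared gene universe is used.
    """
    _check_de(disease_de, "disease")
    _check_de(treatment_de, "treatment")
    universe = disease_de.index.intersection(treatment_de.index)
    if signature is not None:
        universe = universe.intersection(pd.Index(signature))
    d = disease_de.loc[universe]
    t = treatment_de.loc[universe]

    up = (d["log2fc"] >= lfc_threshold) & (d["fdr"] < fdr_threshold)
    suppressed = up & (t["log2fc"] < 0)
    suppressed_sig = suppressed & (t["fdr"] < fdr_threshold)

    down = (d["log2fc"] <= -lfc_threshold) & (d["fdr"] < fdr_threshold)
    rev = down & (t["log2fc"] > 0)
    rev_sig = rev & (t["fdr"] < fdr_threshold)

    return ConcordanceCounts(
        up_in_disease=int(up.sum()),
        suppressed=int(suppressed.sum()),
        suppressed_significant=int(suppressed_sig.sum()),
        down_in_disease=int(down.sum()),
        reversed_up=int(rev.sum()),
        reversed_significant=int(rev_sig.sum()),
    )


def select_dux4_panel(
    tpm: pd.Series,
    de: pd.DataFrame,
    tpm_threshold: float = 35.0,
    lfc_threshold: float = 1.5,
) -> pd.Index:
    """DUX4-responsive panel selection: upregulated, robustly expressed, strong.

    Keeps genes that (i) are upregulated in the disease model (log2fc > 0),
    (ii) have TPM strictly above ``tpm_threshold`` in the disease model and
    (iii) have log2fc strictly above ``lfc_threshold``.
    """
    if "log2fc" not in de.columns:
        raise KeyError("DE table is missing column 'log2fc'")
    shared = tpm.index.intersection(de.index)
    lfc = de.loc[shared, "log2fc"]
    keep = (lfc > 0) & (tpm.loc[shared] > tpm_threshold) & (lfc > lfc_threshold)
    return shared[keep]
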