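"""Distribution-level off-target statistics for seed-matched gene sets.

For each seed length class, the log2 fold-change distribution of the
seed-matched ("bystander") genes is compared with that of a background gene
set (genes carrying 6mer matches of simulated siRNAs).  The effect size is
the Mann-Whitney AUC between the two empirical distributions; significance
comes from the two-sample Kolmogorov-Smirnov test.

Orientation: AUC is the probability that a matched gene's log2FC lies
*below* a background gene's, so siRNA-driven repression of seed-matched
genes yields AUC > 0.5.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .seeds import SEED_CLASSES, hit_genes


def auc_effect_size(x, y) -> float:
    """Mann-Whitney AUC: P(x < y) + 0.5 * P(x = y).

    Computed through the tie-corrected rank formula (exact for any sample
    size).  Equals 0.5 when the two samples are identically distributed and
    1.0 when every ``x`` lies below every ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    # U statistic for y counts pairs with y > x (+0.5 per tie)
    u_y = stats.mannwhitneyu(y, x, alternative="two-sided").statistic
    return float(u_y) / (x.size * y.size)


def ecdf_shift_area(x, y) -> float:
    """Signed area between the two ECDFs, integral of (Fx - Fy) dt.

    Offered as an alternative effect-size reading of "area under the
    curve"; positive when ``x`` is stochastically smaller than ``y``.
    Equals mean(y) - mean(x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.sum((fx - fy)[:-1] * np.diff(grid)))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS test with the asymptotic p approximation.

    Returns (D, p) where D is the supremum ECDF distance and p comes from
    the asymptotic Kolmogorov distribution at effective sample size
    n*m/(n+m); p is clamped into (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    p = float(res.pvalue)
    if np.isnan(p):  # degenerate tiny-sample case: no evidence against the null
        p = 1.0
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return float(res.statistic), p


def seed_offtarget_profile(
    fc: Mapping[str, float] | pd.Series,
    matches: pd.DataFrame,
    background: set[str],
) -> pd.DataFrame:
    """Per-seed-class off-target report: AUC effect size and KS test.

    Parameters
    ----------
    fc
        Gene id -> log2 fold-change for expressed genes.  Must cover every
        gene referenced by ``matches`` and ``background``.
    matches
        Seed-match table from :func:`dux4kit.seeds.scan_utr_matches`.
    background
        Background gene-id set (simulated-siRNA 6mer matches).  Genes that
        are also seed-matched for the class at hand are removed from the
        background before comparison.

    Returns
    -------
    DataFrame with one row per seed class: ``n_matched``, ``n_background``,
    ``auc``, ``ks_d``, ``ks_p``.  A class with no matched (or no remaining
    background) genes is reported with NaN statistics rather than raising.
    """
    fc = pd.Series(dict(fc), dtype=float) if not isinstance(fc, pd.Series) else fc.astype(float)
    if not np.isfinite(fc.to_numpy()).all():
        raise ValueError("fold-change values must be finite")
    referenced = set(matches["gene_id"]) | set(background)
    missing = referenced - set(fc.index)
    if missing:
        raise ValueError(
            f"fold-change table missing {len(missing)} referenced genes "
            f"(e.g. {sorted(missing)[:3]})"
        )
    rows = []
    for cls in SEED_CLASSES:
        matched = hit_genes(matches, cls)
        bg = background - matched
        if not matched or not bg:
            rows.append((cls, len(matched), len(bg), np.nan, np.nan, np.nan))
            continue
        x = fc.loc[sorted(matched)].to_numpy()
        y = fc.loc[sorted(bg)].to_numpy()
        auc = auc_effect_size(x, y)
        d, p = ks_two_sample(x, y)
        rows.append((cls, len(matched), len(bg), auc, d, p))
    return pd.DataFrame(
        rows,
        columns=["seed_class", "n_matched", "n_background", "auc", "ks_d", "ks_p"],
    )


def plot_ecdfs(x, y, ax=None, labels=("seed-matched", "background")):
    """ECDF overlay of the matched vs background fold-change distributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for values, label in zip((x, y), labels):
        v = np.sort(np.asarray(values, dtype=float))
        ax.step(v, np.arange(1, v.size + 1) / v.size, where="post", label=label)
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("cumulative fraction of genes")
    ax.legend()
    return ax
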