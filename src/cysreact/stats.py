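"""Annotation-class enrichment, volcano statistics, fold-change correlation, PCA.

These are the generic statistical readouts of the pipeline: hypergeometric
enrichment of annotation classes among hit proteins (against the background
of all quantified proteins, BH-adjusted across classes); per-feature Welch
t volcano tables with joint p-value / fold-change cutoffs; Pearson
correlation of fold changes between omic layers matched on shared ids; and
complete-case PCA with a top/bottom-k loading report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import AnnotationSet


class StatsError(ValueError):
    """Invalid input to a statistical operation."""


# ---------------------------------------------------------------------------
# Class enrichment
# ---------------------------------------------------------------------------

def class_enrichment(
    hits: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationSet,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each class among the hits.

    ``background`` is the quantified universe (e.g., all proteins bearing at
    least one quantified cysteine); hits must be a subset of it. Returns one
    row per class with counts, odds ratio, one-sided p and BH-adjusted p.
    """
    background = set(background)
    hits = set(hits)
    if not background:
        raise StatsError("empty background")
    if not hits <= background:
        raise StatsError("hits must be a subset of the background")
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for name in annotations.class_names:
        members = annotations.members(name) & background
        k = len(hits & members)
        big_k = len(members)
        # hypergeometric upper tail P(X >= k)
        p = float(sps.hypergeom.sf(k - 1, n_bg, big_k, n_hits))
        a, b = k, n_hits - k
        c, d = big_k - k, (n_bg - big_k) - (n_hits - k)
        if b == 0 or c == 0:
            odds = np.inf if a > 0 and d > 0 else np.nan
        else:
            odds = (a * d) / (b * c) if a * d > 0 or (b * c) > 0 else np.nan
        rows.append(
            {
                "class_name": name,
                "k_hits_in_class": k,
                "n_hits": n_hits,
                "K_class_in_background": big_k,
                "N_background": n_bg,
                "odds_ratio": odds,
                "p_one_sided": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_one_sided"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out


# ---------------------------------------------------------------------------
# Differential (volcano) statistics
# ---------------------------------------------------------------------------

def differential_table(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
) -> pd.DataFrame:
    """Per-feature Welch t volcano table on a features x samples log2 matrix.

    ``log2fc = mean(A) - mean(B)``; the two-sided Welch (unequal-variance) t
    p-value needs at least two observations per group, otherwise p and the
    significance flag are missing while the fold change is reported when
    computable. A feature is ``significant`` when p < ``p_cutoff`` and
    |fold change| > ``fc_cutoff`` (cutoff given on the fold-change scale).
    """
    missing = [s for s in list(group_a) + list(group_b) if s not in matrix.columns]
    if missing:
        raise StatsError(f"samples absent from matrix: {missing}")
    log_fc_cut = np.log2(fc_cutoff)
    rows = []
    a_mat = matrix[list(group_a)].to_numpy(dtype=float)
    b_mat = matrix[list(group_b)].to_numpy(dtype=float)
    for i, feature in enumerate(matrix.index):
        a = a_mat[i][~np.isnan(a_mat[i])]
        b = b_mat[i][~np.isnan(b_mat[i])]
        fc = float(a.mean() - b.mean()) if len(a) and len(b) else np.nan
        if len(a) >= 2 and len(b) >= 2:
            if np.var(a) == 0 and np.var(b) == 0:
                # degenerate Welch: identical constants -> no evidence;
                # different constants -> infinitely strong evidence
                t_stat, p = (0.0, 1.0) if fc == 0 else (np.inf * np.sign(fc), 0.0)
            else:
                t_stat, p = sps.ttest_ind(a, b, equal_var=False)
                t_stat, p = float(t_stat), float(p)
            significant = bool(p < p_cutoff and abs(fc) > log_fc_cut)
        else:
            t_stat, p, significant = np.nan, np.nan, None
        rows.append(
            {
                "feature_id": feature,
                "log2fc": fc,
                "t_statistic": t_stat,
                "p_value": p,
                "n_a": len(a),
                "n_b": len(b),
                "significant": significant,
            }
        )
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if valid.any():
        out.loc[valid, "p_adjusted"] = multipletests(
            out.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# Fold-change correlation between layers
# ---------------------------------------------------------------------------

def fc_correlation(
    layer_a: pd.Series | Dict[str, float],
    layer_b: pd.Series | Dict[str, float],
) -> Dict[str, float]:
    """Pearson r and regression line between two fold-change layers.

    Inputs are id -> log2 fold change maps; the comparison is restricted to
    ids quantified in both layers (inner join). Requires >= 3 matches.
    """
    sa = pd.Series(layer_a, dtype=float).dropna()
    sb = pd.Series(layer_b, dtype=float).dropna()
    common = sa.index.intersection(sb.index)
    if len(common) < 3:
        raise StatsError(f"need >= 3 matched ids, got {len(common)}")
    x = sa.loc[common].to_numpy()
    y = sb.loc[common].to_numpy()
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    return {
        "r": float(r),
        "p_value": float(p),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "n": int(len(common)),
    }


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAReport:
    """Scores (samples x k), loadings (features x k), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    top_loadings: pd.DataFrame
    n_features_used: int


def pca_report(
    matrix: pd.DataFrame,
    n_components: int = 2,
    k_top: int = 5,
    scale: bool = False,
) -> PCAReport:
    """Complete-case PCA of a features x samples log2 matrix.

    Features with any missing value are dropped (only features quantified in
    all samples enter), samples are the observations, and features are
    centered (optionally unit-variance scaled). Components come from the SVD
    of the centered matrix; each component's sign is fixed by making its
    largest-magnitude loading positive. The report lists the ``k_top``
    highest and lowest loadings per component.
    """
    if matrix.shape[1] < 2:
        raise StatsError("need at least 2 samples for PCA")
    complete = matrix.dropna(axis=0, how="any")
    if complete.shape[0] == 0:
        raise StatsError("no complete-case features")
    x = complete.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, len(s))
    # sign convention: largest-|loading| positive
    for j in range(len(s)):
        jmax = int(np.argmax(np.abs(vt[j])))
        if vt[j, jmax] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    n_samples = x.shape[0]
    total_var = float(np.sum(s**2)) / (n_samples - 1)
    var_frac = (s**2 / (n_samples - 1)) / total_var if total_var > 0 else np.zeros_like(s)
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=complete.columns,
        columns=comp_names,
    )
    loadings = pd.DataFrame(
        vt[:n_components].T, index=complete.index, columns=comp_names
    )
    top_rows = []
    for name in comp_names:
        ordered = loadings[name].sort_values(kind="mergesort")
        for feature, value in ordered.tail(k_top).iloc[::-1].items():
            top_rows.append(
                {"component": name, "feature": feature, "loading": value, "end": "top"}
            )
        for feature, value in ordered.head(k_top).items():
            top_rows.append(
                {"component": name, "feature": feature, "loading": value, "end": "bottom"}
            )
    return PCAReport(
        scores=scores,
        loadings=loadings,
        variance_explained=var_frac[:n_components],
        top_loadings=pd.DataFrame(top_rows, columns=["component", "feature", "loading", "end"]),
        n_features_used=complete.shape[0],
    )
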