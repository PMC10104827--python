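"""Module expression activity, rank-AUC scoring, and survival stratification.

The activity statistic standardizes each gene's expression against its own
cross-sample mean, centers it, and averages over a module's genes and a
group's samples:

    S(i,j) = log2( (G(i,j) + pc) / (Gbar(i) + pc) )        (standardize)
    C(i,j) = S(i,j) - Sbar(i)                              (centralize)
    E(x,y) = sum_{i in module x, j in group y} C(i,j) / (g_x * s_y)

Gbar(i) and Sbar(i) are arithmetic means over *all* samples of the matrix,
not per group. Positive E means the module runs above its cross-sample
mean in that group, negative below.

Per-sample module activity for survival use comes either from the mean of
C over module genes or from a rank-based recovery AUC (the AUCell-style
statistic): genes are ranked by descending expression within the sample and
the area under the module-gene recovery curve within the top fraction of
ranks is normalized to [0, 1]. Samples are then split at an activity
quantile (default the median) and compared with a Kaplan-Meier / log-rank
analysis.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


def standardize(G: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Log2 ratio of each sample to the gene's cross-sample mean."""
    if G.shape[1] < 2:
        raise ValueError("need >= 2 samples to standardize")
    gbar = G.mean(axis=1)
    if pseudocount == 0:
        zero = gbar[gbar == 0].index.tolist()
        if zero:
            raise ValueError(f"zero row means with pseudocount 0 for genes: {zero[:10]}")
    S = np.log2(G.add(pseudocount).div(gbar + pseudocount, axis=0))
    if not np.all(np.isfinite(S.to_numpy())):
        raise ValueError("non-finite standardized values")
    return S


def centralize(S: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean standardized value; row means become 0."""
    C = S.sub(S.mean(axis=1), axis=0)
    assert np.all(np.abs(C.mean(axis=1).to_numpy()) < 1e-9), "row means must vanish"
    return C


def module_activity(
    C: pd.DataFrame,
    modules: Mapping[str, set[str]],
    groups: pd.Series,
) -> pd.DataFrame:
    """E(x,y): mean centralized expression of module x in sample group y.

    ``groups`` maps sample_id -> group label and must cover every column of
    C. Module genes absent from the matrix are dropped with a warning; a
    module with no genes in the matrix is an error.
    """
    missing_samples = [s for s in C.columns if s not in groups.index]
    if missing_samples:
        raise ValueError(f"samples without a group: {missing_samples[:5]}")
    group_labels = sorted(groups.loc[C.columns].unique())
    rows = {}
    for name, genes in modules.items():
        present = [g for g in sorted(genes) if g in C.index]
        if not present:
            raise ValueError(f"module {name!r} has no genes in the matrix")
        if len(present) < len(genes):
            warnings.warn(f"module {name!r}: {len(genes) - len(present)} genes absent, dropped")
        sub = C.loc[present]
        rows[name] = {
            y: float(sub.loc[:, groups.loc[C.columns] == y].to_numpy().mean())
            for y in group_labels
        }
    return pd.DataFrame(rows).T[group_labels]


def per_sample_activity(C: pd.DataFrame, module: set[str]) -> pd.Series:
    """Per-sample mean of C over the module's genes (for survival strata)."""
    present = [g for g in sorted(module) if g in C.index]
    if not present:
        raise ValueError("module has no genes in the matrix")
    return C.loc[present].mean(axis=0)


def auc_activity(
    expr_column: pd.Series, module: set[str], top_fraction: float = 0.05
) -> float:
    """Rank-based recovery AUC of a module in one sample, in [0, 1].

    Genes are ranked by descending expression (ties broken by gene label for
    determinism). Within the top ``ceil(top_fraction * n)`` ranks the
    cumulative count of recovered module genes is summed rank by rank and
    normalized by the best achievable curve (all module genes at the very
    top); no module gene in the top block scores 0.
    """
    n = len(expr_column)
    top = math.ceil(top_fraction * n)
    if top < 1:
        raise ValueError("top_fraction too small for the gene universe")
    if len(module) > n:
        raise ValueError("module larger than the gene universe")
    order = sorted(expr_column.index, key=lambda g: (-expr_column[g], g))
    in_mod = np.array([g in module for g in order[:top]])
    cum = np.cumsum(in_mod)
    m_eff = min(len(module), top)
    max_curve = np.minimum(np.arange(1, top + 1), m_eff)
    denom = max_curve.sum()
    return float(cum.sum() / denom) if denom else 0.0


def auc_activity_matrix(
    expr: pd.DataFrame, modules: Mapping[str, set[str]], top_fraction: float = 0.05
) -> pd.DataFrame:
    """auc_activity for every (module, sample)."""
    return pd.DataFrame(
        {
            name: {s: auc_activity(expr[s], genes, top_fraction) for s in expr.columns}
            for name, genes in modules.items()
        }
    ).T


def stratify_survival(
    activity: pd.Series,
    surv: pd.DataFrame,
    cut: float = 0.5,
) -> dict:
    """Split samples at an activity quantile and compare survival.

    Samples with activity <= the ``cut`` quantile (ties at the cut value go
    low) form the low stratum. Returns the strata labels, the two-group
    log-rank chi-square statistic and p-value, and per-stratum Kaplan-Meier
    step tables.
    """
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    common = activity.index.intersection(surv.index)
    if len(common) < 2:
        raise ValueError("too few samples shared between activity and survival")
    a = activity.loc[common]
    s = surv.loc[common]
    if int(s["event"].sum()) < 2:
        raise ValueError("need >= 2 events")
    thresh = float(np.quantile(a.to_numpy(), cut))
    low = a <= thresh
    if low.all() or (~low).all():
        raise ValueError("activity split produced an empty stratum")
    strata = pd.Series(np.where(low, "low", "high"), index=common, name="stratum")
    res = logrank_test(
        s.loc[low, "time"], s.loc[~low, "time"],
        event_observed_A=s.loc[low, "event"], event_observed_B=s.loc[~low, "event"],
    )
    km = {}
    for label in ("low", "high"):
        mask = strata == label
        fitter = KaplanMeierFitter()
        fitter.fit(s.loc[mask, "time"], s.loc[mask, "event"], label=label)
        tbl = fitter.survival_function_.reset_index()
        tbl.columns = ["time", "survival"]
        km[label] = tbl
    return {
        "strata": strata,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "km": km,
        "threshold": thresh,
    }
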