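"""Integration and comparison of CRISPR knockout screens.

Takes MAGeCK-style per-gene summaries (normalized log2 fold change and
negative/positive selection p-values) from two or more screens, partitions
hits into a *common* set (significant under negative selection in every
screen) and a *context-specific* set (significant in at least one but not
all), and provides the supporting comparisons: CPM normalization of sgRNA
count tables, per-sgRNA fold changes, Wilcoxon/rank-sum gene-set tests,
an expressed-gene filter, and pairwise Pearson correlation of screens.

Significance is the raw negative-selection p-value below ``alpha`` (default
0.05) with no multiple-testing correction, matching common practice for
screen intersection; genes absent from a screen count as non-significant
there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TIMEPOINT_PSEUDOCOUNT = 0.5


@dataclass
class GenePartition:
    """Common vs context-specific hit sets across screens."""

    common: set[str]
    context_specific: set[str]
    per_screen_significant: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.common & self.context_specific:
            raise AssertionError("common and context-specific sets must be disjoint")


def normalize_counts(counts: pd.DataFrame, sample_cols: list[str] | None = None) -> pd.DataFrame:
    """Scale each sample column to counts-per-million.

    ``sample_cols`` defaults to every column except sgrna_id/gene_id. The
    0.5 pseudocount is *not* added here — it enters when logs are taken
    (see :func:`sgrna_lfc`).
    """
    out = counts.copy()
    cols = sample_cols or [c for c in counts.columns if c not in ("sgrna_id", "gene_id")]
    for c in cols:
        total = counts[c].sum()
        if total <= 0:
            raise ValueError(f"sample {c!r} has zero total counts")
        out[c] = counts[c] / total * 1e6
    return out


def sgrna_lfc(
    normalized: pd.DataFrame,
    from_cols: list[str],
    to_cols: list[str],
    pseudocount: float = TIMEPOINT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-sgRNA log2 fold change between timepoints.

    LFC = log2(mean CPM over ``to_cols`` + pc) − log2(mean CPM over
    ``from_cols`` + pc). Indexed by sgrna_id when present.
    """
    for c in from_cols + to_cols:
        if c not in normalized.columns:
            raise ValueError(f"missing timepoint column {c!r}")
    a = normalized[from_cols].mean(axis=1)
    b = normalized[to_cols].mean(axis=1)
    lfc = np.log2(b + pseudocount) - np.log2(a + pseudocount)
    if "sgrna_id" in normalized.columns:
        lfc.index = normalized["sgrna_id"]
    return lfc


def compare_gene_sets(
    lfc: pd.Series,
    gene_of: pd.Series,
    set_a: set[str],
    set_b: set[str] | None = None,
    paired: bool = False,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Compare sgRNA fold changes between gene sets.

    With ``set_b=None`` (or ``paired=True`` on equal-length vectors) this is
    a Wilcoxon signed-rank test of set_a's values against zero shift;
    otherwise a two-sample rank-sum (Mann-Whitney) test between the two
    sets' values. Exact enumeration for n <= 25, normal approximation with
    continuity correction beyond.

    Returns (statistic, p).
    """
    va = lfc[gene_of.isin(set_a).to_numpy()].to_numpy(dtype=float)
    if set_b is None or paired:
        vals = va if set_b is None else va - lfc[gene_of.isin(set_b).to_numpy()].to_numpy(dtype=float)
        if len(vals) < 3:
            raise ValueError("need >= 3 sgRNA values for the signed-rank test")
        if np.all(vals == 0):
            warnings.warn("all differences are zero; signed-rank p set to 1")
            return 0.0, 1.0
        no_ties = np.all(vals != 0) and len(np.unique(np.abs(vals))) == len(vals)
        method = "exact" if len(vals) <= 25 and no_ties else "approx"
        res = stats.wilcoxon(vals, alternative=alternative, correction=True, method=method)
        return float(res.statistic), float(res.pvalue)
    vb = lfc[gene_of.isin(set_b).to_numpy()].to_numpy(dtype=float)
    if len(va) < 3 or len(vb) < 3:
        raise ValueError("need >= 3 sgRNA values per set")
    method = "exact" if max(len(va), len(vb)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(va, vb, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def filter_expressed(
    genes: set[str], expr: pd.DataFrame, threshold: float = 0.5
) -> tuple[set[str], set[str]]:
    """Partition genes into expressed (mean > threshold, strictly) and
    low/non-expressed (mean <= threshold, the inclusive boundary).

    Expression units are the caller's (RPKM-like). Genes absent from the
    matrix fall into the low/non-expressed set with a warning.
    """
    mean = expr.mean(axis=1)
    expressed, low = set(), set()
    missing = []
    for g in genes:
        if g not in mean.index:
            missing.append(g)
            low.add(g)
        elif mean[g] > threshold:
            expressed.add(g)
        else:
            low.add(g)
    if missing:
        warnings.warn(f"{len(missing)} genes absent from expression matrix; treated as low/non-expressed")
    return expressed, low


def integrate_screens(tables: list[pd.DataFrame], alpha: float = 0.05) -> GenePartition:
    """Partition genes into common vs context-specific negative-selection hits.

    A gene is significant in a screen iff ``p_neg < alpha`` (strict). The
    common set is the intersection over all screens; context-specific is the
    union minus the common set.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 screens to integrate")
    per_screen: dict[str, set[str]] = {}
    for t in tables:
        sid = str(t["screen_id"].iloc[0]) if "screen_id" in t.columns and len(t) else f"screen{len(per_screen)+1}"
        sig = set(t.loc[t["p_neg"] < alpha, "gene_id"])
        per_screen[sid] = sig
    sets = list(per_screen.values())
    common = set.intersection(*sets) if sets else set()
    union = set.union(*sets) if sets else set()
    return GenePartition(common=common, context_specific=union - common, per_screen_significant=per_screen)


def screen_correlation(tables: list[pd.DataFrame], min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of normalized gene LFCs across screens.

    Computed on genes present in both screens of each pair
    (pairwise-complete). Pairs sharing fewer than ``min_shared`` genes get
    NaN (flagged with a warning) rather than a silent 0.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 screens")
    series = {}
    for t in tables:
        sid = str(t["screen_id"].iloc[0])
        series[sid] = t.set_index("gene_id")["lfc"]
    ids = list(series)
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            shared = series[a].index.intersection(series[b].index)
            if len(shared) < min_shared:
                warnings.warn(f"screens {a}/{b} share only {len(shared)} genes; correlation undefined")
                r = np.nan
            else:
                r = float(np.corrcoef(series[a][shared], series[b][shared])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat
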