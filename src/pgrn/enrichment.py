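"""Per-sample 2-fold over/under-expression calls and hypergeometric
module-enrichment patterns.

For every sample, genes at least ``fold`` times above (or below) their
cross-sample average expression form the over- (under-) expressed sets.
Each module is tested against both sets with an upper-tail hypergeometric
p-value (enrichment, P[X >= k]); if both directions pass ``alpha`` the
smaller p wins, and the signed score is −log2(p) with + for over and − for
under. The same machinery summarizes per-group patterns: for each group the
number of its samples enriched in a direction is tested against the
distribution of enriched samples over all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SampleDEGSets:
    """Per-sample over/under-expressed gene sets and the universe size."""

    over: dict[str, set[str]]
    under: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for s in self.over:
            if self.over[s] & self.under.get(s, set()):
                raise AssertionError(f"sample {s}: over/under sets overlap")


def call_sample_degs(G: pd.DataFrame, fold: float = 2.0) -> SampleDEGSets:
    """Call over/under-expressed genes per sample against the cross-sample mean.

    Over: G(g,j) >= fold * mean(g); under: G(g,j) <= mean(g) / fold (both
    boundaries inclusive — "at least" fold). Genes with zero mean are
    excluded from both sets with a warning.
    """
    if G.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    gbar = G.mean(axis=1)
    zero = gbar == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes with zero mean excluded from DEG calls")
    ok = ~zero
    sub = G.loc[ok]
    m = gbar[ok]
    over_mask = sub.ge(m * fold, axis=0)
    under_mask = sub.le(m / fold, axis=0)
    over = {s: set(sub.index[over_mask[s]]) for s in G.columns}
    under = {s: set(sub.index[under_mask[s]]) for s in G.columns}
    return SampleDEGSets(over=over, under=under, universe=set(G.index[ok]))


def hypergeom_enrich(hit_set: set, module: set, universe_size: int) -> float:
    """Upper-tail hypergeometric enrichment p-value, P[X >= k].

    X ~ Hypergeometric(N=universe_size, K=|module|, n=|hit_set|) and
    k = |hit_set ∩ module|. An empty module returns p = 1 with a warning.
    """
    if not module:
        warnings.warn("empty module; p = 1")
        return 1.0
    k = len(hit_set & module)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(module), len(hit_set)))


def _choose_direction(p_over: float, p_under: float, alpha: float) -> tuple[str, float]:
    """Smaller-p rule; exact ties resolve to 'over'."""
    if p_over < alpha and p_under < alpha:
        return ("over", p_over) if p_over <= p_under else ("under", p_under)
    if p_over < alpha:
        return "over", p_over
    if p_under < alpha:
        return "under", p_under
    return "none", min(p_over, p_under)


def _signed_score(direction: str, p: float) -> float:
    if direction == "none":
        return 0.0
    score = -np.log2(max(p, np.nextafter(0, 1)))
    return score if direction == "over" else -score


def sample_module_pattern(
    degs: SampleDEGSets, modules: Mapping[str, set[str]], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(sample, module) enrichment direction and signed −log2(p) score."""
    n_universe = len(degs.universe)
    rows = []
    for sample in degs.over:
        for name, module in modules.items():
            mod = module & degs.universe
            p_over = hypergeom_enrich(degs.over[sample], mod, n_universe)
            p_under = hypergeom_enrich(degs.under[sample], mod, n_universe)
            direction, p = _choose_direction(p_over, p_under, alpha)
            rows.append((sample, name, direction, p, _signed_score(direction, p)))
    return pd.DataFrame(rows, columns=["sample", "module", "direction", "p", "score"])


def group_pattern(
    cells: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(group, module) enrichment of direction-enriched samples.

    For each module and direction, the population is all samples with their
    total count of direction-enriched samples; the upper-tail hypergeometric
    p asks whether the group holds unexpectedly many of them. Direction by
    the smaller-p rule; score is signed −log2(p).
    """
    missing = [s for s in cells["sample"].unique() if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group: {missing[:5]}")
    samples = list(cells["sample"].unique())
    n_total = len(samples)
    rows = []
    for name, sub in cells.groupby("module", sort=True):
        sub = sub.set_index("sample")
        enriched = {d: set(sub.index[sub["direction"] == d]) for d in ("over", "under")}
        for grp in sorted(groups.loc[samples].unique()):
            members = {s for s in samples if groups[s] == grp}
            ps = {}
            for d in ("over", "under"):
                k = len(members & enriched[d])
                if not enriched[d] or k == 0:
                    ps[d] = 1.0
                else:
                    ps[d] = float(
                        stats.hypergeom.sf(k - 1, n_total, len(enriched[d]), len(members))
                    )
            direction, p = _choose_direction(ps["over"], ps["under"], alpha)
            rows.append((grp, name, direction, p, _signed_score(direction, p)))
    return pd.DataFrame(rows, columns=["group", "module", "direction", "p", "score"])
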