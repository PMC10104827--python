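"""Proximal/distal target assignment and positive-unlabeled refinement.

A sub-class's HDBS are linked to genes two ways: *proximal* targets have an
HDBS interval overlapping the TSS ± 5 kb window; *distal* targets are
reached through a chromatin interaction pair (promoter-capture style) whose
one anchor overlaps an HDBS interval while the other anchor overlaps the
gene's promoter window. The union forms the putative target set, which an
AdaSampling-style positive-unlabeled ensemble then purges of false
positives: putative targets are noisy positives, everything else unlabeled,
and per-gene positive weights are re-estimated over several rounds of
weighted resampling + probabilistic classification. An ensemble of such
runs votes; at prediction threshold 1 only unanimously positive candidates
are retained (the high-precision regime).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .intervals import source_overlap_mask, window_overlap_genes

VOTE_EPS = 1e-9  # float guard for unanimity at threshold 1


@dataclass
class ModuleGeneSet:
    """A module's refined target genes with ensemble provenance."""

    name: str
    genes: set[str]
    vote_fraction: dict[str, float] = field(default_factory=dict)   # candidate -> votes in [0,1]
    mean_probability: dict[str, float] = field(default_factory=dict)
    converged: bool = True


def proximal_targets(
    hdbs: pd.DataFrame, annotation: pd.DataFrame, window: int = 5000
) -> set[str]:
    """Genes whose TSS ± window (half-open ``[tss-w, tss+w)``) overlaps an
    HDBS interval by >= 1 bp; strand-independent."""
    if window <= 0:
        raise ValueError("window must be positive")
    hit = window_overlap_genes(
        hdbs, annotation["chrom"].to_numpy(), annotation["tss"].to_numpy(), window
    )
    return set(annotation.loc[hit, "gene_id"])


def distal_targets(
    hdbs: pd.DataFrame,
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_window: int = 5000,
) -> set[str]:
    """Genes reached through an interaction pair: one anchor overlaps an
    HDBS interval and the *other* anchor overlaps the gene's promoter
    window ``[tss-w, tss+w)``. Both anchor orderings are considered."""
    if pairs.empty:
        raise ValueError("no interaction pairs supplied")
    a1 = pairs.rename(columns={"chrom1": "chrom", "start1": "start", "end1": "end"})[
        ["chrom", "start", "end"]
    ]
    a2 = pairs.rename(columns={"chrom2": "chrom", "start2": "start", "end2": "end"})[
        ["chrom", "start", "end"]
    ]
    hdbs_sorted = hdbs.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    # which pairs have anchor i overlapping any HDBS interval
    hit1 = _anchor_hits_hdbs(a1, hdbs_sorted)
    hit2 = _anchor_hits_hdbs(a2, hdbs_sorted)
    out: set[str] = set()
    chroms = annotation["chrom"].to_numpy()
    tss = annotation["tss"].to_numpy()
    gene = annotation["gene_id"].to_numpy()
    for anchor_hit, other in ((hit1, a2), (hit2, a1)):
        sel = other[anchor_hit]
        if sel.empty:
            continue
        for r in sel.itertuples(index=False):
            m = (chroms == r.chrom) & (r.start < tss + promoter_window) & (r.end > tss - promoter_window)
            out.update(gene[m])
    return out


def _anchor_hits_hdbs(anchors: pd.DataFrame, hdbs_sorted: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(anchors), dtype=bool)
    by_chrom = dict(tuple(hdbs_sorted.groupby("chrom", sort=False)))
    for i, r in enumerate(anchors.itertuples(index=False)):
        sub = by_chrom.get(r.chrom)
        if sub is None:
            continue
        hit[i] = bool(np.any((sub["start"].to_numpy() < r.end) & (sub["end"].to_numpy() > r.start)))
    return hit


def combine_targets(proximal: set[str], distal: set[str], name: str = "") -> pd.DataFrame:
    """Putative target table with per-gene origin (proximal/distal/both)."""
    genes = sorted(proximal | distal)
    origin = [
        "both" if g in proximal and g in distal else ("proximal" if g in proximal else "distal")
        for g in genes
    ]
    return pd.DataFrame({"gene_id": genes, "origin": origin, "module": name or None})


def build_features(
    expr_timecourse: pd.DataFrame | None,
    histone: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concatenate expression-time-course and histone-mark features and
    z-score each over the gene universe.

    Genes missing from one source are imputed to the feature mean (flagged
    via an ``imputed`` boolean column set alongside); zero-variance features
    are dropped with a warning.
    """
    parts = [p for p in (expr_timecourse, histone) if p is not None]
    if not parts:
        raise ValueError("no feature sources supplied")
    universe = parts[0].index
    for p in parts[1:]:
        universe = universe.union(p.index)
    aligned = [p.reindex(universe) for p in parts]
    feats = pd.concat(aligned, axis=1)
    imputed = feats.isna().any(axis=1)
    feats = feats.fillna(feats.mean())
    sd = feats.std(ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping zero-variance features: {list(dead)}")
        feats = feats.drop(columns=dead)
        sd = sd.drop(dead)
    feats = (feats - feats.mean()) / sd
    feats["imputed"] = imputed
    return feats


def _make_classifier(kind: str, seed: int):
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    return LogisticRegression(C=1.0, max_iter=500, random_state=seed)


def adasample_refine(
    candidates: set[str],
    features: pd.DataFrame,
    universe: set[str] | None = None,
    threshold: float = 1.0,
    n_rounds: int = 5,
    n_ensemble: int = 10,
    seed: int = 0,
    name: str = "module",
) -> ModuleGeneSet:
    """AdaSampling-style PU refinement of a putative target set.

    Every candidate starts with positive weight 1, every other gene 0. Each
    round draws a balanced training set — positives from candidates with
    probability proportional to their weight, negatives from non-candidates
    proportional to (1 − weight) — fits a probabilistic classifier, and
    replaces each gene's weight with its predicted positive probability.
    Ensemble members alternate a 5-NN probability estimator and a
    regularized logistic model over distinct seeds; each member casts a
    positive vote for candidates whose final probability is >= 0.5. The
    retained set is the candidates whose vote fraction is >= ``threshold``
    (with a 1e-9 guard, so threshold 1 means unanimity). Candidates only are
    ever retained; the refinement filters, it never adds.
    """
    feat = features.drop(columns=[c for c in ("imputed",) if c in features.columns])
    universe = set(feat.index) if universe is None else universe
    if not candidates <= universe:
        raise ValueError("candidates must be a subset of the universe")
    genes = sorted(universe)
    cand_list = sorted(candidates)
    neg_list = sorted(universe - candidates)
    if len(cand_list) < 10 or len(neg_list) < 10:
        raise ValueError("need >= 10 candidates and >= 10 non-candidates")
    X = feat.loc[genes].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(genes)}
    cand_idx = np.array([idx[g] for g in cand_list])
    neg_idx = np.array([idx[g] for g in neg_list])

    n_train = min(len(cand_idx), len(neg_idx))
    votes = np.zeros(len(cand_idx))
    prob_sum = np.zeros(len(cand_idx))
    converged = True
    root = np.random.SeedSequence([int(seed), 9173])
    for member, child in enumerate(root.spawn(n_ensemble)):
        rng = np.random.default_rng(child)
        kind = "knn" if member % 2 == 0 else "logistic"
        w = np.zeros(len(genes))
        w[cand_idx] = 1.0
        prev = w.copy()
        for _ in range(n_rounds):
            p_pos = w[cand_idx] / w[cand_idx].sum() if w[cand_idx].sum() > 0 else None
            if p_pos is None:
                break
            pos_draw = rng.choice(cand_idx, size=n_train, replace=True, p=p_pos)
            w_neg = 1.0 - w[neg_idx]
            if w_neg.sum() <= 0:
                w_neg = np.ones(len(neg_idx))
            neg_draw = rng.choice(neg_idx, size=n_train, replace=True, p=w_neg / w_neg.sum())
            Xt = np.vstack([X[pos_draw], X[neg_draw]])
            yt = np.concatenate([np.ones(n_train), np.zeros(n_train)])
            clf = _make_classifier(kind, int(rng.integers(2**31)))
            clf.fit(Xt, yt)
            prev = w.copy()
            w = clf.predict_proba(X)[:, list(clf.classes_).index(1.0)]
        # candidate weights still moving > 1e-3 between the last two rounds
        if n_rounds > 1 and np.max(np.abs(w[cand_idx] - prev[cand_idx])) > 1e-3:
            converged = False
        final_prob = w[cand_idx]
        votes += (final_prob >= 0.5).astype(float)
        prob_sum += final_prob
    vote_frac = votes / n_ensemble
    mean_prob = prob_sum / n_ensemble
    keep = vote_frac >= threshold - VOTE_EPS
    return ModuleGeneSet(
        name=name,
        genes={g for g, k in zip(cand_list, keep) if k},
        vote_fraction=dict(zip(cand_list, vote_frac)),
        mean_probability=dict(zip(cand_list, mean_prob)),
        converged=converged,
    )


def module_overlap(modules: list[ModuleGeneSet]) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise intersection counts and per-module exclusive-gene counts."""
    if len(modules) < 2:
        raise ValueError("need >= 2 modules")
    names = [m.name for m in modules]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in modules:
        for b in modules:
            mat.loc[a.name, b.name] = len(a.genes & b.genes)
    excl = pd.Series(
        {m.name: len(m.genes - set().union(*(o.genes for o in modules if o is not m))) for m in modules}
    )
    return mat, excl
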