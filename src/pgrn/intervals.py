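"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)`` (BED convention).
Interval collections are pandas DataFrames with at least the columns
``chrom``, ``start``, ``end``; extra columns pass through where noted.
These few operations (validation, union-merge with gap 0, per-interval
factor-degree counting, window overlap) are deliberately hand-written as
sorted numpy sweeps so that each one can be checked against a brute-force
per-base oracle in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def validate_intervals(df: pd.DataFrame, genome: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Check interval sanity; return the frame sorted by (chrom, start, end).

    Raises ``ValueError`` naming the offending record when ``start >= end``,
    coordinates are negative, the chromosome is undeclared, or an interval
    extends beyond the declared chromosome end.
    """
    if not set(BED_COLUMNS) <= set(df.columns):
        raise ValueError(f"interval frame needs columns {BED_COLUMNS}, got {list(df.columns)}")
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"invalid interval {r['chrom']}:{r['start']}-{r['end']}")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in genome:
                raise ValueError(f"interval on undeclared chromosome {chrom!r}")
            over = sub[sub["end"] > genome[chrom]]
            if len(over):
                r = over.iloc[0]
                raise ValueError(
                    f"interval {r['chrom']}:{r['start']}-{r['end']} beyond chrom end {genome[chrom]}"
                )
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union-merge intervals per chromosome; touching intervals (gap 0) merge.

    Two intervals merge when ``next.start <= current.end + gap``.
    Returns chrom/start/end only, sorted, pairwise non-overlapping.
    """
    if df.empty:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out_c: list[str] = []
    out_s: list[int] = []
    out_e: list[int] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, int(e))
            else:
                out_c.append(chrom)
                out_s.append(cur_s)
                out_e.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_c.append(chrom)
        out_s.append(cur_s)
        out_e.append(cur_e)
    return pd.DataFrame({"chrom": out_c, "start": out_s, "end": out_e})


def _overlap_hits(
    m_starts: np.ndarray, m_ends: np.ndarray, q_starts: np.ndarray, q_ends: np.ndarray
) -> np.ndarray:
    """Boolean mask over disjoint sorted target intervals hit (>=1 bp) by any query."""
    hit = np.zeros(len(m_starts), dtype=bool)
    if len(m_starts) == 0 or len(q_starts) == 0:
        return hit
    lo = np.searchsorted(m_ends, q_starts, side="right")
    hi = np.searchsorted(m_starts, q_ends, side="left")
    for a, b in zip(lo, hi):
        if b > a:
            hit[a:b] = True
    return hit


def count_overlapping_sources(
    merged: pd.DataFrame, sources: Mapping[str, pd.DataFrame]
) -> np.ndarray:
    """For each merged interval, count distinct sources with >=1 bp overlap."""
    counts = np.zeros(len(merged), dtype=int)
    for name, peaks in sources.items():
        counts += source_overlap_mask(merged, peaks).astype(int)
    return counts


def source_overlap_mask(merged: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean per merged interval: does this peak set overlap it by >=1 bp?"""
    mask = np.zeros(len(merged), dtype=bool)
    p_by_chrom = dict(tuple(peaks.groupby("chrom", sort=False)))
    pos = 0
    for chrom, sub in merged.groupby("chrom", sort=False):
        n = len(sub)
        q = p_by_chrom.get(chrom)
        if q is not None and len(q):
            order = np.argsort(q["start"].to_numpy(), kind="mergesort")
            mask[pos : pos + n] = _overlap_hits(
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                q["start"].to_numpy()[order],
                q["end"].to_numpy()[order],
            )
        pos += n
    return mask


def window_overlap_genes(
    intervals: pd.DataFrame,
    gene_chrom: Sequence[str],
    gene_center: Sequence[int],
    window: int,
) -> np.ndarray:
    """Boolean per gene: does any interval overlap ``[center-window, center+window)``?"""
    gene_chrom = np.asarray(gene_chrom)
    gene_center = np.asarray(gene_center, dtype=int)
    out = np.zeros(len(gene_center), dtype=bool)
    by_chrom = dict(tuple(intervals.groupby("chrom", sort=False)))
    for chrom in np.unique(gene_chrom):
        sub = by_chrom.get(chrom)
        if sub is None or not len(sub):
            continue
        sel = gene_chrom == chrom
        centers = gene_center[sel]
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy(), kind="mergesort")]
        # window [c-w, c+w): overlap iff some interval with start < c+w and end > c-w
        hit = np.zeros(len(centers), dtype=bool)
        for s, e in zip(starts, ends):
            hit |= (s < centers + window) & (e > centers - window)
        out[sel] = hit
    return out
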