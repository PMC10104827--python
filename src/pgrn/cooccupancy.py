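"""Factor binding co-occupancy: Z matrix, sub-class clustering, HDBS.

The genome is discretized into fixed-size bins and each factor's peak set
becomes a binary occupancy vector. For two factors occupying m_a and m_b of
N bins with O bins shared, the co-occupancy Z-score standardizes O against
the hypergeometric null of independent random bin assignment:

    E = m_a * m_b / N
    sigma^2 = E * (1 - m_a/N) * (N - m_b) / (N - 1)
    Z = (O - E) / sigma

Factors are clustered into sub-classes by average-linkage hierarchical
clustering on the distance 1 − Pearson(Z row a, Z row b). For one sub-class
of n member factors, the high-degree co-occupancy binding sites (HDBS) are
the union-merged member intervals kept when at least k of the n distinct
members overlap the merged site by >= 1 bp — the k-of-n rule (e.g. 25 of 32
for a CORE-like class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .intervals import merge_intervals, source_overlap_mask, validate_intervals


@dataclass
class BinnedOccupancy:
    """Binary factors × genome-bins occupancy matrix."""

    bin_size: int
    chrom_bins: dict[str, int]              # chrom -> number of bins
    factors: list[str]
    matrix: np.ndarray                      # bool, factors x total bins

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SubClass:
    name: str
    members: list[str]
    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > len(self.members):
            raise ValueError(f"sub-class {self.name}: k={self.k} outside [1, {len(self.members)}]")


def bin_occupancy(
    peaks: Mapping[str, pd.DataFrame], genome: Mapping[str, int], bin_size: int = 1000
) -> BinnedOccupancy:
    """Binarize peak sets over genome bins; a bit is set iff the factor has
    >= 1 bp of peak in the bin (half-open arithmetic)."""
    chrom_bins = {c: int(np.ceil(n / bin_size)) for c, n in genome.items()}
    offsets = {}
    pos = 0
    for c, nb in chrom_bins.items():
        offsets[c] = pos
        pos += nb
    factors = list(peaks)
    mat = np.zeros((len(factors), pos), dtype=bool)
    for i, f in enumerate(factors):
        df = validate_intervals(peaks[f], genome)
        for r in df.itertuples(index=False):
            b0 = r.start // bin_size
            b1 = (r.end - 1) // bin_size  # inclusive last bin touched
            mat[i, offsets[r.chrom] + b0 : offsets[r.chrom] + b1 + 1] = True
    return BinnedOccupancy(bin_size=bin_size, chrom_bins=chrom_bins, factors=factors, matrix=mat)


def cooccupancy_z(occ: BinnedOccupancy) -> pd.DataFrame:
    """Pairwise co-occupancy Z matrix under the hypergeometric bin null.

    Symmetric; the diagonal (a factor against itself) is computed with the
    same formula and is the maximum of each row by construction. A factor
    occupying every bin has sigma = 0; its Z entries are set to 0 with a
    warning.
    """
    m = occ.matrix.astype(float)
    if m.shape[0] < 2:
        raise ValueError("need >= 2 factors")
    counts = m.sum(axis=1)
    if np.any(counts == 0):
        empty = [f for f, c in zip(occ.factors, counts) if c == 0]
        raise ValueError(f"factors with no occupied bins: {empty}")
    n_bins = float(occ.n_bins)
    observed = m @ m.T
    e = np.outer(counts, counts) / n_bins
    var = e * (1.0 - counts[:, None] / n_bins) * (n_bins - counts[None, :]) / (n_bins - 1.0)
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - e) / sigma
    if np.any(sigma == 0):
        warnings.warn("factor occupies all bins; its Z entries set to 0")
        z[sigma == 0] = 0.0
    z = (z + z.T) / 2.0  # enforce exact symmetry against float noise
    return pd.DataFrame(z, index=occ.factors, columns=occ.factors)


def cluster_subclasses(z: pd.DataFrame, n_clusters: int) -> list[SubClass]:
    """Cut an average-linkage tree on d = 1 − Pearson(Z rows) into exactly
    ``n_clusters`` sub-classes.

    Deterministic: scipy's linkage and cut are deterministic given the input,
    and cluster names follow the first member factor in input label order.
    Constant Z rows make the correlation undefined and raise, naming the
    offending factors.
    """
    factors = list(z.index)
    if n_clusters > len(factors):
        raise ValueError("n_clusters exceeds number of factors")
    rows = z.to_numpy(dtype=float)
    sd = rows.std(axis=1)
    bad = [f for f, s in zip(factors, sd) if s == 0]
    if bad:
        raise ValueError(f"constant Z rows (correlation undefined) for factors: {bad}")
    corr = np.corrcoef(rows)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    out = []
    for lab in sorted(set(labels), key=lambda l: min(i for i in range(len(factors)) if labels[i] == l)):
        members = [f for f, l in zip(factors, labels) if l == lab]
        out.append(SubClass(name=f"class_{members[0]}", members=members, k=1))
    return out


def hdbs_extract(peaks: Mapping[str, pd.DataFrame], k: int) -> pd.DataFrame:
    """High-degree co-occupancy binding sites of one sub-class.

    Union-merges all member intervals (touching intervals merge), counts per
    merged site the number of distinct member factors overlapping it by
    >= 1 bp (the site's co-occupancy degree), and keeps sites with degree
    >= k. Empty member peak sets contribute nothing.

    Returns a BED-like frame chrom/start/end/degree.
    """
    n = len(peaks)
    if k > n:
        raise ValueError(f"k={k} exceeds number of member factors {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    nonempty = {f: df for f, df in peaks.items() if len(df)}
    all_peaks = (
        pd.concat(nonempty.values(), ignore_index=True)[["chrom", "start", "end"]]
        if nonempty
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    merged = merge_intervals(all_peaks)
    degree = np.zeros(len(merged), dtype=int)
    for f, df in nonempty.items():
        degree += source_overlap_mask(merged, df).astype(int)
    merged = merged.assign(degree=degree)
    return merged[merged["degree"] >= k].reset_index(drop=True)


def annotate_peaks(intervals: pd.DataFrame, annotation: pd.DataFrame, promoter_dist: int = 3000) -> pd.DataFrame:
    """Categorize intervals by position relative to genes.

    Distance is from the interval midpoint to the nearest TSS, signed by
    that gene's strand (upstream negative). Category priority: promoter
    (|d| <= promoter_dist) > gene body (midpoint within any gene's body
    extent) > distal intergenic.
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    out_rows = []
    ann_by_chrom = dict(tuple(annotation.groupby("chrom", sort=False)))
    for r in intervals.itertuples(index=False):
        mid = (int(r.start) + int(r.end)) // 2
        sub = ann_by_chrom.get(r.chrom)
        if sub is None:
            out_rows.append((r.chrom, r.start, r.end, "distal_intergenic", np.nan, None))
            continue
        tss = sub["tss"].to_numpy()
        d_abs = np.abs(mid - tss)
        i = int(np.argmin(d_abs))  # ties -> first in annotation order
        g = sub.iloc[i]
        signed = mid - int(g["tss"]) if g["strand"] == "+" else int(g["tss"]) - mid
        if abs(signed) <= promoter_dist:
            cat = "promoter"
        else:
            in_body = np.any((sub["body_start"].to_numpy() <= mid) & (mid < sub["body_end"].to_numpy()))
            cat = "gene_body" if in_body else "distal_intergenic"
        out_rows.append((r.chrom, r.start, r.end, cat, int(signed), g["gene_id"]))
    return pd.DataFrame(
        out_rows, columns=["chrom", "start", "end", "category", "tss_distance", "nearest_gene"]
    )


def histone_profile(
    coverage: Mapping[str, Mapping[str, np.ndarray]] | Mapping[str, np.ndarray],
    sites: pd.DataFrame,
    flank: int = 3000,
    bin: int = 50,
) -> pd.DataFrame:
    """Mean coverage profile around site midpoints, per mark.

    ``coverage`` maps mark -> (chrom -> dense per-base array); a single
    chrom->array mapping is treated as one unnamed mark. Windows span
    ±``flank`` around each site midpoint in ``bin``-bp position bins;
    windows running past a chromosome end are zero-filled and still count
    in the denominator.
    """
    if sites.empty:
        raise ValueError("no sites to profile")
    first = next(iter(coverage.values()))
    marks = coverage if isinstance(first, Mapping) else {"coverage": coverage}
    n_bins = (2 * flank) // bin
    centers = np.arange(n_bins) * bin - flank + bin // 2
    rows = {}
    for mark, cov in marks.items():
        acc = np.zeros(n_bins)
        for r in sites.itertuples(index=False):
            mid = (int(r.start) + int(r.end)) // 2
            arr = cov.get(r.chrom)
            window = np.zeros(2 * flank)
            if arr is not None:
                lo, hi = mid - flank, mid + flank
                a, b = max(lo, 0), min(hi, len(arr))
                if b > a:
                    window[a - lo : b - lo] = arr[a:b]
            acc += window.reshape(n_bins, bin).mean(axis=1)
        rows[mark] = acc / len(sites)
    return pd.DataFrame(rows, index=pd.Index(centers, name="position")).T
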