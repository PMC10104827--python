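"""Binning, co-occupancy Z, clustering, HDBS, annotation, profiles."""

import numpy as np
import pandas as pd
import pytest

from pgrn import cooccupancy as co
from pgrn.synth import SimConfig, gen_peaks

from conftest import random_intervals


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------- binning

def test_bin_alignment_and_straddle():
    genome = {"c1": 10_000}
    occ = co.bin_occupancy({"f": bed([("c1", 0, 1000)])}, genome, 1000)
    assert occ.matrix[0].sum() == 1 and occ.matrix[0, 0]
    occ = co.bin_occupancy({"f": bed([("c1", 999, 1001)])}, genome, 1000)
    assert occ.matrix[0, 0] and occ.matrix[0, 1] and occ.matrix[0].sum() == 2


def test_bin_occupancy_matches_per_bin_scan(rng):
    genome = {"c1": 2000, "c2": 2000}
    bin_size = 100
    for _ in range(100):
        df = random_intervals(rng, int(rng.integers(1, 12)), chroms=("c1", "c2"))
        occ = co.bin_occupancy({"f": df}, genome, bin_size)
        expect = np.zeros(occ.n_bins, dtype=bool)
        offsets = {"c1": 0, "c2": 20}
        for c, off in offsets.items():
            for b in range(20):
                lo, hi = b * bin_size, (b + 1) * bin_size
                expect[off + b] = any(
                    r.chrom == c and r.start < hi and r.end > lo
                    for r in df.itertuples(index=False)
                )
        assert np.array_equal(occ.matrix[0], expect)


def test_out_of_bounds_interval_named_in_error():
    with pytest.raises(ValueError, match="c1:0-99999"):
        co.bin_occupancy({"f": bed([("c1", 0, 99_999)])}, {"c1": 10_000}, 1000)


# ---------------------------------------------------------------- Z matrix

def occ_from_bits(bits: dict[str, list[int]], n_bins: int) -> co.BinnedOccupancy:
    mat = np.zeros((len(bits), n_bins), dtype=bool)
    for i, (f, idx) in enumerate(bits.items()):
        mat[i, idx] = True
    return co.BinnedOccupancy(bin_size=1, chrom_bins={"c1": n_bins},
                              factors=list(bits), matrix=mat)


def test_disjoint_factors_negative_z():
    occ = occ_from_bits({"a": [0, 1, 2], "b": [3, 4, 5]}, 10)
    z = co.cooccupancy_z(occ)
    assert z.loc["a", "b"] < 0


def test_diagonal_is_row_maximum():
    rng = np.random.default_rng(8)
    for _ in range(20):
        bits = {f"f{i}": list(rng.choice(50, size=rng.integers(2, 30), replace=False))
                for i in range(5)}
        z = co.cooccupancy_z(occ_from_bits(bits, 50)).to_numpy()
        assert np.allclose(z, z.T)
        assert np.all(np.diag(z) >= z.max(axis=1) - 1e-12)


def test_z_matches_permutation_oracle_small():
    # m_a=5, m_b=8 among N=20 bins with O=4 shared
    occ = occ_from_bits({"a": list(range(5)), "b": [0, 1, 2, 3, 10, 11, 12, 13]}, 20)
    z = co.cooccupancy_z(occ).loc["a", "b"]
    rng = np.random.default_rng(17)
    obs = np.empty(20_000)
    a = np.zeros(20, dtype=bool); a[:5] = True
    for i in range(len(obs)):
        b = np.zeros(20, dtype=bool)
        b[rng.choice(20, size=8, replace=False)] = True
        obs[i] = (a & b).sum()
    z_mc = (4 - obs.mean()) / obs.std(ddof=1)
    assert abs(z - z_mc) < 0.1


def test_full_occupancy_factor_zeroed_with_warning():
    occ = occ_from_bits({"a": list(range(10)), "b": [0, 1]}, 10)
    with pytest.warns(UserWarning, match="all bins"):
        z = co.cooccupancy_z(occ)
    assert z.loc["a", "b"] == 0.0


# ---------------------------------------------------------------- clustering

def test_two_planted_classes_recovered_exactly():
    cfg = SimConfig(seed=21, planted_classes=[("X", 3, 60), ("Y", 3, 60)],
                    n_noise_factors=0, n_background_peaks=10)
    peaks, truth = gen_peaks(cfg)
    occ = co.bin_occupancy(peaks, cfg.genome_dict, cfg.bin_size)
    subs = co.cluster_subclasses(co.cooccupancy_z(occ), 2)
    got = [set(s.members) for s in subs]
    assert {"X_f1", "X_f2", "X_f3"} in got and {"Y_f1", "Y_f2", "Y_f3"} in got


def test_n_clusters_equals_n_factors_gives_singletons():
    occ = occ_from_bits({"a": [0, 1], "b": [5, 6], "c": [2, 9]}, 12)
    subs = co.cluster_subclasses(co.cooccupancy_z(occ), 3)
    assert sorted(len(s.members) for s in subs) == [1, 1, 1]


def test_constant_z_rows_rejected_by_name():
    z = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError, match="a"):
        co.cluster_subclasses(z, 2)


def test_clustering_permutation_equivariant():
    cfg = SimConfig(seed=22, planted_classes=[("X", 3, 60), ("Y", 3, 60)],
                    n_noise_factors=0, n_background_peaks=10)
    peaks, _ = gen_peaks(cfg)
    occ = co.bin_occupancy(peaks, cfg.genome_dict, cfg.bin_size)
    z = co.cooccupancy_z(occ)
    order = ["Y_f2", "X_f1", "Y_f3", "X_f3", "X_f2", "Y_f1"]
    z_perm = z.loc[order, order]
    a = {frozenset(s.members) for s in co.cluster_subclasses(z, 2)}
    b = {frozenset(s.members) for s in co.cluster_subclasses(z_perm, 2)}
    assert a == b


# ---------------------------------------------------------------- HDBS

def test_hdbs_worked_example():
    peaks = {"A": bed([("c1", 0, 100)]), "B": bed([("c1", 50, 150)]),
             "C": bed([("c1", 400, 500)])}
    hd = co.hdbs_extract(peaks, k=2)
    assert hd[["chrom", "start", "end", "degree"]].to_numpy().tolist() == [["c1", 0, 150, 2]]


def test_hdbs_k1_is_plain_merge():
    peaks = {"A": bed([("c1", 0, 100), ("c1", 90, 200)]), "B": bed([("c1", 500, 600)])}
    hd = co.hdbs_extract(peaks, k=1)
    assert hd[["chrom", "start", "end"]].to_numpy().tolist() == [["c1", 0, 200], ["c1", 500, 600]]


def test_hdbs_k_equals_n_identical_sets():
    p = bed([("c1", 10, 60), ("c1", 200, 260)])
    hd = co.hdbs_extract({"A": p, "B": p.copy(), "C": p.copy()}, k=3)
    assert hd[["chrom", "start", "end"]].to_numpy().tolist() == p.to_numpy().tolist()
    assert (hd["degree"] == 3).all()


def test_hdbs_k_above_n_rejected_and_empty_member_allowed():
    peaks = {"A": bed([("c1", 0, 10)]), "B": bed([])}
    with pytest.raises(ValueError, match="exceeds"):
        co.hdbs_extract(peaks, k=3)
    hd = co.hdbs_extract(peaks, k=1)
    assert len(hd) == 1


def hdbs_oracle(peaks: dict[str, pd.DataFrame], k: int, chrom_len=2000) -> list:
    """Brute-force per-base: merged components of the union, then count
    factors with any covered base inside each component."""
    union = np.zeros(chrom_len, dtype=bool)
    covs = {}
    for f, df in peaks.items():
        cov = np.zeros(chrom_len, dtype=bool)
        for r in df.itertuples(index=False):
            cov[r.start:r.end] = True
        covs[f] = cov
        union |= cov
    out = []
    i = 0
    while i < chrom_len:
        if union[i]:
            j = i
            while j < chrom_len and union[j]:
                j += 1
            deg = sum(bool(c[i:j].any()) for c in covs.values())
            if deg >= k:
                out.append(("c1", i, j, deg))
            i = j
        else:
            i += 1
    return out


def test_hdbs_matches_brute_force(rng):
    for _ in range(150):
        peaks = {f"f{i}": random_intervals(rng, int(rng.integers(0, 6)))
                 for i in range(int(rng.integers(2, 5)))}
        k = int(rng.integers(1, len(peaks) + 1))
        got = [tuple(r) for r in co.hdbs_extract(peaks, k).to_numpy()]
        assert got == hdbs_oracle(peaks, k)


def test_hdbs_count_non_increasing_in_k(rng):
    peaks = {f"f{i}": random_intervals(rng, 8) for i in range(4)}
    sizes = [len(co.hdbs_extract(peaks, k)) for k in range(1, 5)]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------- annotation

def ann_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand",
                                       "body_start", "body_end"])


def test_annotate_midpoint_at_tss_is_promoter():
    ann = ann_frame([("g1", "c1", 5000, "+", 5000, 7000)])
    out = co.annotate_peaks(bed([("c1", 4950, 5050)]), ann)
    assert out.loc[0, "category"] == "promoter" and out.loc[0, "tss_distance"] == 0


def test_annotate_3kb_boundary_upstream():
    ann = ann_frame([("g1", "c1", 10_000, "+", 10_000, 12_000)])
    out = co.annotate_peaks(bed([("c1", 6949, 7049)]), ann)  # midpoint 6999, d=-3001
    assert out.loc[0, "tss_distance"] == -3001
    assert out.loc[0, "category"] == "distal_intergenic"
    out = co.annotate_peaks(bed([("c1", 6950, 7050)]), ann)  # midpoint 7000, d=-3000
    assert out.loc[0, "category"] == "promoter"


def test_annotate_nearest_tss_matches_exhaustive_scan(rng):
    tss = sorted(rng.choice(50_000, size=20, replace=False))
    strands = rng.choice(["+", "-"], size=20)
    ann = ann_frame([
        (f"g{i}", "c1", int(t), s, int(t) - (2000 if s == "-" else 0),
         int(t) + (2000 if s == "+" else 0))
        for i, (t, s) in enumerate(zip(tss, strands))
    ])
    ivs = random_intervals(rng, 50, chrom_len=50_000, max_len=200)
    out = co.annotate_peaks(ivs, ann)
    for row, r in zip(out.itertuples(index=False), ivs.itertuples(index=False)):
        mid = (r.start + r.end) // 2
        best = min(abs(mid - t) for t in tss)
        assert abs(row.tss_distance) == best


def test_annotate_empty_annotation_rejected():
    with pytest.raises(ValueError, match="empty"):
        co.annotate_peaks(bed([("c1", 0, 10)]), pd.DataFrame())


# ---------------------------------------------------------------- profiles

def test_profile_constant_coverage_flat():
    cov = {"c1": np.full(20_000, 3.5)}
    sites = bed([("c1", 9_000, 9_200), ("c1", 12_000, 12_100)])
    prof = co.histone_profile({"mark": cov}, sites, flank=3000, bin=50)
    assert np.allclose(prof.loc["mark"].to_numpy(), 3.5)


def test_profile_delta_at_midpoints_center_bin_only():
    cov = {"c1": np.zeros(20_000)}
    sites = bed([("c1", 5_000, 5_100), ("c1", 15_000, 15_100)])
    for r in sites.itertuples(index=False):
        cov["c1"][(r.start + r.end) // 2] = 50.0
    prof = co.histone_profile({"mark": cov}, sites, flank=3000, bin=50).loc["mark"]
    assert prof.loc[25] > 0  # bin holding the midpoint (position offset +25)
    assert (prof.drop(25) == 0).all()


def test_profile_matches_naive_window_average(rng):
    cov = {"c1": rng.random(10_000)}
    sites = random_intervals(rng, 6, chrom_len=9_000, max_len=100)
    flank, width = 1000, 50
    prof = co.histone_profile({"m": cov}, sites, flank=flank, bin=width).loc["m"].to_numpy()
    acc = np.zeros(2 * flank)
    for r in sites.itertuples(index=False):
        mid = (r.start + r.end) // 2
        win = np.zeros(2 * flank)
        lo, hi = mid - flank, mid + flank
        a, b = max(lo, 0), min(hi, 10_000)
        win[a - lo:b - lo] = cov["c1"][a:b]
        acc += win
    expected = (acc / len(sites)).reshape(-1, width).mean(axis=1)
    assert np.allclose(prof, expected)


def test_profile_truncated_window_zero_filled():
    cov = {"c1": np.full(5_000, 2.0)}
    sites = bed([("c1", 0, 100)])  # window extends past chrom start
    prof = co.histone_profile({"m": cov}, sites, flank=3000, bin=50).loc["m"]
    assert prof.iloc[0] == 0.0       # fully out-of-bounds bin
    assert prof.iloc[-1] == 2.0      # fully in-bounds bin
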