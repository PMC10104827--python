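"""Synthetic-data generators: determinism, planted structure, null behaviour."""

import numpy as np
import pandas as pd
import pytest

from pgrn import targets as tg
from pgrn.synth import (
    SimConfig,
    gen_annotation_and_interactions,
    gen_expression,
    gen_histone_features,
    gen_peaks,
    gen_screens,
    gen_survival,
    simulate_all,
)
from pgrn import activity as act


def small_cfg(**kw) -> SimConfig:
    base = dict(seed=5, n_genes=150, n_common_essential=15, n_context_essential=20,
                n_samples_per_group=6)
    base.update(kw)
    return SimConfig(**base)


# ---------------------------------------------------------------- config

def test_config_validation_errors():
    with pytest.raises(ValueError, match="2 screens"):
        SimConfig(n_screens=1)
    with pytest.raises(ValueError, match="declared twice"):
        SimConfig(genome=[("chr1", 1_000_000), ("chr1", 1_000_000)])
    with pytest.raises(ValueError, match="shorter than 10 bins"):
        SimConfig(genome=[("chr1", 5_000)])
    with pytest.raises(ValueError, match="hazard_ratio"):
        SimConfig(hazard_ratio=0.0)


# ---------------------------------------------------------------- screens

def test_screens_same_seed_identical():
    a_tables, a_counts, _ = gen_screens(small_cfg())
    b_tables, b_counts, _ = gen_screens(small_cfg())
    for x, y in zip(a_tables + a_counts, b_tables + b_counts):
        pd.testing.assert_frame_equal(x, y)


def test_planted_common_gene_significant_everywhere():
    tables, _, truth = gen_screens(small_cfg())
    sig_sets = [set(t.loc[t["p_neg"] < 0.05, "gene_id"]) for t in tables]
    inter = set.intersection(*sig_sets)
    # nearly all planted common-essential genes land in every screen's hit set
    recall = len(truth.common_essential & inter) / len(truth.common_essential)
    assert recall >= 0.8


def test_null_screens_nominal_false_positive_rate():
    """Without planted effects, ~5% of genes reach p<0.05 per screen."""
    rates = []
    for seed in range(20):
        cfg = SimConfig(seed=100 + seed, n_genes=120, n_screens=2,
                        n_common_essential=0, n_context_essential=0)
        tables, _, _ = gen_screens(cfg)
        rates.extend((t["p_neg"] < 0.05).mean() for t in tables)
    assert np.mean(rates) <= 0.08


# ---------------------------------------------------------------- peaks

def overlap_count(a: pd.DataFrame, b: pd.DataFrame) -> int:
    n = 0
    for r in a.itertuples(index=False):
        n += any(
            q.chrom == r.chrom and q.start < r.end and q.end > r.start
            for q in b.itertuples(index=False)
        )
    return n


def test_planted_class_cobinding_versus_background():
    cfg = SimConfig(seed=7, planted_classes=[("X", 3, 50), ("Y", 3, 50)],
                    n_noise_factors=0, n_background_peaks=20)
    peaks, truth = gen_peaks(cfg)
    within = overlap_count(peaks["X_f1"], peaks["X_f2"])
    between = overlap_count(peaks["X_f1"], peaks["Y_f1"])
    assert within >= 50
    assert between <= 5  # background-rate collisions only


def test_zero_shared_sites_only_background():
    cfg = SimConfig(seed=7, planted_classes=[("X", 3, 0), ("Y", 3, 0)],
                    n_noise_factors=0, n_background_peaks=20)
    peaks, _ = gen_peaks(cfg)
    assert overlap_count(peaks["X_f1"], peaks["X_f2"]) <= 3


def test_zero_jitter_makes_identical_class_peaks():
    cfg = SimConfig(seed=7, planted_classes=[("X", 3, 30)], n_noise_factors=0,
                    n_background_peaks=0, peak_jitter=0)
    peaks, _ = gen_peaks(cfg)
    pd.testing.assert_frame_equal(peaks["X_f1"], peaks["X_f2"])
    pd.testing.assert_frame_equal(peaks["X_f1"], peaks["X_f3"])


# ------------------------------------------------- annotation/interactions

def test_all_proximal_truth_recoverable_by_proximal_rule():
    cfg = SimConfig(seed=9, fraction_proximal=1.0)
    ann, pairs, truth = gen_annotation_and_interactions(cfg)
    for name, sites in truth.class_sites.items():
        hdbs_like = pd.DataFrame(
            {"chrom": sites["chrom"], "start": sites["center"] - 200, "end": sites["center"] + 200}
        )
        prox = tg.proximal_targets(hdbs_like, ann, window=5000)
        assert truth.true_targets[name] <= prox


def test_all_distal_truth_invisible_to_proximal_rule():
    cfg = SimConfig(seed=9, fraction_proximal=0.0)
    ann, pairs, truth = gen_annotation_and_interactions(cfg)
    for name, sites in truth.class_sites.items():
        hdbs_like = pd.DataFrame(
            {"chrom": sites["chrom"], "start": sites["center"] - 200, "end": sites["center"] + 200}
        )
        prox = tg.proximal_targets(hdbs_like, ann, window=5000)
        assert len(prox & truth.true_targets[name]) == 0
        dist = tg.distal_targets(hdbs_like, pairs, ann, promoter_window=5000)
        assert truth.true_targets[name] <= dist


def test_genome_too_small_to_place_genes():
    with pytest.raises(ValueError, match="too small"):
        gen_annotation_and_interactions(
            SimConfig(n_genes=400, genome=[("chr1", 500_000)])
        )


# ---------------------------------------------------------------- expression

def test_null_expression_gives_zero_module_activity():
    es = []
    for seed in range(5):
        cfg = small_cfg(seed=seed, module_effect={})
        ann, _, truth = gen_annotation_and_interactions(cfg)
        expr, samples, _ = gen_expression(cfg, truth.true_targets)
        C = act.centralize(act.standardize(expr, pseudocount=1))
        E = act.module_activity(C, truth.true_targets, samples.set_index("sample_id")["group"])
        es.append(E.to_numpy())
    es = np.array(es)
    # |E| within 3 standard errors of 0 over seeds
    assert np.all(np.abs(es.mean(axis=0)) < 3 * es.std(axis=0, ddof=1) / np.sqrt(len(es)) + 0.02)


def test_planted_effect_sign():
    cfg = small_cfg(module_effect=None)  # defaults: alternate +2/-2 in G1
    ann, _, truth = gen_annotation_and_interactions(cfg)
    expr, samples, t_expr = gen_expression(cfg, truth.true_targets)
    C = act.centralize(act.standardize(expr, pseudocount=1))
    E = act.module_activity(C, truth.true_targets, samples.set_index("sample_id")["group"])
    for module, by_group in t_expr.group_activity.items():
        for group, eff in by_group.items():
            assert np.sign(E.loc[module, group]) == np.sign(eff)


def test_expression_strictly_positive_and_deterministic():
    cfg = small_cfg()
    ann, _, truth = gen_annotation_and_interactions(cfg)
    a, _, _ = gen_expression(cfg, truth.true_targets)
    b, _, _ = gen_expression(cfg, truth.true_targets)
    assert (a.to_numpy() > 0).all() and np.isfinite(a.to_numpy()).all()
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------- features

def test_contamination_zero_putative_equals_truth():
    cfg = small_cfg(contamination_rate=0.0)
    ann, _, truth = gen_annotation_and_interactions(cfg)
    _, t_feat = gen_histone_features(cfg, truth.true_targets)
    for m in truth.true_targets:
        assert t_feat.putative_targets[m] == truth.true_targets[m]


def test_contamination_fraction_planted():
    for seed in range(5):
        cfg = SimConfig(seed=seed, contamination_rate=0.2)
        ann, _, truth = gen_annotation_and_interactions(cfg)
        _, t_feat = gen_histone_features(cfg, truth.true_targets)
        for m, putative in t_feat.putative_targets.items():
            frac = len(putative - truth.true_targets[m]) / len(putative)
            assert abs(frac - 0.2) <= 0.02


def test_features_deterministic():
    cfg = small_cfg()
    ann, _, truth = gen_annotation_and_interactions(cfg)
    a, _ = gen_histone_features(cfg, truth.true_targets)
    b, _ = gen_histone_features(cfg, truth.true_targets)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------- survival

def test_no_censoring_all_events():
    cfg = small_cfg(censoring_rate=0.0)
    activity = pd.Series(np.linspace(-1, 1, 30), index=[f"s{i}" for i in range(30)])
    surv = gen_survival(cfg, activity)
    assert (surv["event"] == 1).all()
    assert (surv["time"] > 0).all()


def test_survival_rejects_nonpositive_hazard_ratio():
    with pytest.raises(ValueError, match="hazard_ratio"):
        SimConfig(hazard_ratio=-1.0)


# ---------------------------------------------------------------- orchestration

def test_simulate_all_no_orphan_identifiers(std_sim):
    genes = set(std_sim.expression.index)
    for ess in std_sim.truth.essential_genes.values():
        assert ess <= genes
    for t in std_sim.truth.true_targets.values():
        assert t <= genes
    for t in std_sim.truth.putative_targets.values():
        assert t <= genes
    assert set(std_sim.truth.factor_class) == set(std_sim.peaks)
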