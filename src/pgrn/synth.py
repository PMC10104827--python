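"""Synthetic inputs with planted ground truth for the whole pipeline.

Every input the analysis consumes — CRISPR-screen sgRNA counts and gene
summaries, per-factor binding peak sets, a TSS annotation, promoter-capture
style interaction pairs, an expression matrix with grouped samples, per-gene
histone-mark features and a survival table — is generated here with the
planted structure (essential genes, factor classes sharing binding sites,
true module targets, group-wise activity shifts, activity-dependent hazard)
recorded in a :class:`GroundTruth` sidecar so each downstream stage can be
scored against truth.

All randomness flows through one ``numpy.random.Generator`` constructed from
``SimConfig.seed``; the same config yields byte-identical output files.

Default parameter choices mirror the study conditions being emulated:
five knockout screens with 4 sgRNAs per gene and negative-binomial count
noise; factor classes co-binding a common set of sites (the co-occupancy
signal the Z-score clustering must recover); ~40% of class sites proximal
to their target's TSS and the rest connected through chromatin interaction
pairs; 4-fold module expression shifts between sample groups; 20% false
positives among putative targets for the PU-refinement stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

def _default_classes() -> list[tuple[str, int, int]]:
    # (class name, n member factors, n shared sites)
    return [("CORE", 4, 50), ("MYC", 4, 50), ("PRC", 4, 50)]


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the defaults used throughout.

    ``planted_classes`` entries are ``(name, n_factors, n_shared_sites)``;
    ``module_effect`` maps ``(module, group)`` to a log2-scale expression
    shift applied to that module's true targets in that group's samples.
    """

    seed: int = 0
    n_genes: int = 400
    n_screens: int = 5
    planted_classes: list[tuple[str, int, int]] = field(default_factory=_default_classes)
    n_noise_factors: int = 3
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 5_000_000), ("chr2", 5_000_000)]
    )
    bin_size: int = 1000
    peak_width: int = 600  # > 2 * peak_jitter, so co-bound peaks always overlap
    peak_jitter: int | None = None          # None -> bin_size // 4
    n_background_peaks: int = 60
    fraction_proximal: float = 0.4
    n_distractor_pairs: int = 100
    # screens
    n_common_essential: int = 40
    n_context_essential: int = 60
    essential_lfc: float = -2.0
    sgrnas_per_gene: int = 4
    nb_dispersion: float = 0.1
    sgrna_lfc_sd: float = 0.3
    libsize_lognorm_sd: float = 0.1
    # expression
    groups: list[str] = field(default_factory=lambda: ["G1", "G2"])
    n_samples_per_group: int = 20
    module_effect: dict[tuple[str, str], float] | None = None
    expression_noise_sd: float = 0.5
    baseline_log_mean: float = np.log(10.0)
    baseline_log_sd: float = 1.0
    # histone features
    contamination_rate: float = 0.2
    feature_shift: float = 3.0
    feature_noise_sd: float = 1.0
    n_histone_marks: int = 10
    n_expression_timepoints: int = 4
    # survival
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.peak_jitter is None:
            self.peak_jitter = self.bin_size // 4
        if self.module_effect is None:
            # activating modules up in G1, repressed modules down in G1 —
            # alternate signs so both directions are exercised
            eff: dict[tuple[str, str], float] = {}
            for i, (name, _, _) in enumerate(self.planted_classes):
                eff[(name, self.groups[0])] = 2.0 if i % 2 == 0 else -2.0
            self.module_effect = eff
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_screens": self.n_screens,
            "n_samples_per_group": self.n_samples_per_group,
            "sgrnas_per_gene": self.sgrnas_per_gene,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_screens < 2:
            raise ValueError("need at least 2 screens")
        seen: list[tuple[str, int]] = []
        for chrom, length in self.genome:
            if any(c == chrom for c, _ in seen):
                raise ValueError(f"chromosome {chrom!r} declared twice")
            if length < 10 * self.bin_size:
                raise ValueError(f"chromosome {chrom!r} shorter than 10 bins")
            seen.append((chrom, length))
        if not 0 <= self.contamination_rate < 1:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")

    @property
    def genome_dict(self) -> dict[str, int]:
        return dict(self.genome)

    @property
    def class_names(self) -> list[str]:
        return [name for name, _, _ in self.planted_classes]

    def factor_names(self) -> tuple[dict[str, list[str]], list[str]]:
        """Per-class member factor names plus the unclustered noise factors."""
        members = {
            name: [f"{name}_f{i+1}" for i in range(n)] for name, n, _ in self.planted_classes
        }
        noise = [f"noise_f{i+1}" for i in range(self.n_noise_factors)]
        return members, noise

def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


# fixed stream tags so each generator is independent of the others
_T_SCREENS, _T_PEAKS, _T_ANN, _T_EXPR, _T_FEAT, _T_SURV = 11, 22, 33, 44, 55, 66


@dataclass
class GroundTruth:
    """Planted structure recorded for test assertions."""

    essential_genes: dict[str, set[str]] = field(default_factory=dict)   # screen -> genes
    common_essential: set[str] = field(default_factory=set)
    factor_class: dict[str, str] = field(default_factory=dict)           # factor -> class
    class_sites: dict[str, pd.DataFrame] = field(default_factory=dict)   # class -> site table
    true_targets: dict[str, set[str]] = field(default_factory=dict)      # module -> genes
    putative_targets: dict[str, set[str]] = field(default_factory=dict)  # module -> candidates
    group_activity: dict[str, dict[str, float]] = field(default_factory=dict)  # module -> group -> shift

    def to_json_dict(self) -> dict:
        return {
            "essential_genes": {k: sorted(v) for k, v in self.essential_genes.items()},
            "common_essential": sorted(self.common_essential),
            "factor_class": self.factor_class,
            "true_targets": {k: sorted(v) for k, v in self.true_targets.items()},
            "putative_targets": {k: sorted(v) for k, v in self.putative_targets.items()},
            "group_activity": self.group_activity,
        }


def gene_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"g{i+1:0{width}d}" for i in range(cfg.n_genes)]


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson: var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def gen_screens(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[pd.DataFrame], list[pd.DataFrame], GroundTruth]:
    """Simulate knockout screens with planted essential genes.

    Returns per-screen gene tables (``screen_id, gene_id, lfc, p_neg, p_pos``),
    per-screen sgRNA count tables (columns ``t0_r1, t0_r2, t14_r1, t14_r2``)
    and the ground truth. A common subset of genes is essential in every
    screen; context-specific genes are essential in random proper subsets.
    Gene-level p-values come from a one-sample t-test over the per-sgRNA
    log2 count ratios.
    """
    cfg.validate()
    rng = rng or _stream(cfg.seed, _T_SCREENS)
    genes = gene_ids(cfg)
    n = cfg.n_genes
    if cfg.n_common_essential + cfg.n_context_essential > n:
        raise ValueError("more essential genes requested than genes available")

    perm = rng.permutation(n)
    common = [genes[i] for i in perm[: cfg.n_common_essential]]
    context = [genes[i] for i in perm[cfg.n_common_essential : cfg.n_common_essential + cfg.n_context_essential]]

    truth = GroundTruth(common_essential=set(common))
    screen_ids = [f"screen{i+1}" for i in range(cfg.n_screens)]
    # each context gene is essential in a random proper non-empty subset of screens
    context_membership = {}
    for g in context:
        size = int(rng.integers(1, cfg.n_screens))  # 1 .. n_screens-1
        member = rng.choice(cfg.n_screens, size=size, replace=False)
        context_membership[g] = {screen_ids[i] for i in member}
    for sid in screen_ids:
        truth.essential_genes[sid] = set(common) | {
            g for g, s in context_membership.items() if sid in s
        }

    gene_tables, count_tables = [], []
    n_sg = cfg.sgrnas_per_gene
    samples = ["t0_r1", "t0_r2", "t14_r1", "t14_r2"]
    for sid in screen_ids:
        ess = truth.essential_genes[sid]
        gene_shift = np.array([cfg.essential_lfc if g in ess else 0.0 for g in genes])
        # per-sgRNA baseline abundance and true lfc
        abundance = rng.lognormal(np.log(200.0), 0.8, size=(n, n_sg))
        sg_lfc = gene_shift[:, None] + rng.normal(0, cfg.sgrna_lfc_sd, size=(n, n_sg))
        sf = rng.lognormal(0.0, cfg.libsize_lognorm_sd, size=4)
        mu = np.empty((n, n_sg, 4))
        mu[:, :, 0] = abundance * sf[0]
        mu[:, :, 1] = abundance * sf[1]
        mu[:, :, 2] = abundance * 2.0**sg_lfc * sf[2]
        mu[:, :, 3] = abundance * 2.0**sg_lfc * sf[3]
        counts = _nb_draw(rng, mu, cfg.nb_dispersion)

        counts2 = counts.reshape(n * n_sg, 4)
        cpm = counts2 / counts2.sum(axis=0, keepdims=True) * 1e6
        obs_lfc = np.log2(cpm[:, 2:].mean(axis=1) + 0.5) - np.log2(cpm[:, :2].mean(axis=1) + 0.5)
        obs_lfc = obs_lfc.reshape(n, n_sg)

        gene_lfc = obs_lfc.mean(axis=1)
        se = obs_lfc.std(axis=1, ddof=1) / np.sqrt(n_sg)
        se = np.where(se == 0, 1e-12, se)
        t = gene_lfc / se
        p_neg = stats.t.cdf(t, df=n_sg - 1)
        p_pos = stats.t.sf(t, df=n_sg - 1)
        p_neg = np.clip(p_neg, np.nextafter(0, 1), 1.0)
        p_pos = np.clip(p_pos, np.nextafter(0, 1), 1.0)

        gene_tables.append(
            pd.DataFrame(
                {"screen_id": sid, "gene_id": genes, "lfc": gene_lfc, "p_neg": p_neg, "p_pos": p_pos}
            )
        )
        count_tables.append(
            pd.DataFrame(
                {
                    "sgrna_id": [f"{g}_sg{j+1}" for g in genes for j in range(n_sg)],
                    "gene_id": np.repeat(genes, n_sg),
                    **{s: counts2[:, k] for k, s in enumerate(samples)},
                }
            )
        )
    return gene_tables, count_tables, truth


# ---------------------------------------------------------------------------
# annotation, class sites, interactions
# ---------------------------------------------------------------------------

def gen_annotation_and_interactions(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    promoter_window: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Place genes, decide class binding-site locations, and wire interactions.

    Genes (TSSs) are laid out non-overlapping in the proximal territory of
    each chromosome. For every planted class, each shared binding site picks
    a distinct true target gene: with probability ``fraction_proximal`` the
    site center falls inside the target's TSS±(promoter_window−peak margin)
    window, otherwise the site is placed in gene-free distal territory and an
    interaction pair connects it to the target's promoter. Distractor pairs
    link unused distal slots to random promoters.

    Returns (annotation, interaction pairs, truth). The truth carries the
    per-class site tables that :func:`gen_peaks` consumes.
    """
    cfg.validate()
    rng = rng or _stream(cfg.seed, _T_ANN)
    genes = gene_ids(cfg)
    chroms = cfg.genome

    # gene territory = first 55% of each chromosome; distal = last 30%
    spacing = 12_000
    slots: list[tuple[str, int]] = []
    for chrom, length in chroms:
        pos = 10_000
        while pos + spacing < 0.55 * length:
            slots.append((chrom, pos))
            pos += spacing
    if len(slots) < cfg.n_genes:
        raise ValueError(
            f"genome too small to place {cfg.n_genes} genes ({len(slots)} slots available)"
        )
    chosen = rng.choice(len(slots), size=cfg.n_genes, replace=False)
    chosen.sort()
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    body_len = 2000
    rows = []
    for g, idx, strand in zip(genes, chosen, strands):
        chrom, tss = slots[idx]
        if strand == "+":
            rows.append((g, chrom, tss, strand, tss, tss + body_len))
        else:
            rows.append((g, chrom, tss, strand, tss - body_len, tss))
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "body_start", "body_end"])

    # distal slots on a 5 kb grid
    distal_slots = []
    for chrom, length in chroms:
        pos = int(0.70 * length)
        while pos + 5000 < length - 5000:
            distal_slots.append((chrom, pos))
            pos += 5000
    rng.shuffle(distal_slots)
    slot_cursor = 0

    truth = GroundTruth()
    pair_rows = []
    margin = cfg.peak_width // 2 + (cfg.peak_jitter or 0)
    for name, _, n_sites in cfg.planted_classes:
        if n_sites > cfg.n_genes:
            raise ValueError(f"class {name}: more sites than genes to target")
        target_idx = rng.choice(cfg.n_genes, size=n_sites, replace=False)
        site_rows = []
        for ti in target_idx:
            g = ann.iloc[ti]
            proximal = rng.random() < cfg.fraction_proximal
            if proximal:
                off = int(rng.integers(-(promoter_window - margin - 1), promoter_window - margin))
                center = int(g["tss"]) + off
                site_rows.append((g["chrom"], center, g["gene_id"], "proximal"))
            else:
                chrom, center = distal_slots[slot_cursor]
                slot_cursor += 1
                site_rows.append((chrom, center, g["gene_id"], "distal"))
                a1 = (chrom, center - 1000, center + 1000)
                a2 = (g["chrom"], int(g["tss"]) - 2000, int(g["tss"]) + 2000)
                if (a1[0], a1[1]) > (a2[0], a2[1]):
                    a1, a2 = a2, a1
                pair_rows.append(a1 + a2)
        truth.class_sites[name] = pd.DataFrame(
            site_rows, columns=["chrom", "center", "target_gene", "kind"]
        )
        truth.true_targets[name] = set(truth.class_sites[name]["target_gene"])

    # distractors: unused distal slots paired with random promoters
    n_distract = min(cfg.n_distractor_pairs, len(distal_slots) - slot_cursor)
    for k in range(n_distract):
        chrom, center = distal_slots[slot_cursor]
        slot_cursor += 1
        g = ann.iloc[int(rng.integers(cfg.n_genes))]
        a1 = (chrom, center - 1000, center + 1000)
        a2 = (g["chrom"], int(g["tss"]) - 2000, int(g["tss"]) + 2000)
        if (a1[0], a1[1]) > (a2[0], a2[1]):
            a1, a2 = a2, a1
        pair_rows.append(a1 + a2)

    pairs = pd.DataFrame(
        pair_rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )
    return ann, pairs, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def gen_peaks(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    class_sites: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Per-factor peak sets with planted class co-binding.

    Factors of one class share that class's sites (each member's peak is the
    site center plus uniform jitter in ±``peak_jitter``), plus private
    background peaks placed uniformly. When ``class_sites`` is not supplied
    (standalone use), site centers are drawn on a 5 kb grid so classes never
    share sites.
    """
    cfg.validate()
    rng = rng or _stream(cfg.seed, _T_PEAKS)
    genome = cfg.genome_dict
    members, noise_factors = cfg.factor_names()

    if class_sites is None:
        grid = []
        for chrom, length in cfg.genome:
            pos = 5000
            while pos + 5000 < length - 5000:
                grid.append((chrom, pos))
                pos += 5000
        rng.shuffle(grid)
        cursor = 0
        class_sites = {}
        for name, _, n_sites in cfg.planted_classes:
            take = grid[cursor : cursor + n_sites]
            cursor += n_sites
            class_sites = {**class_sites, name: pd.DataFrame(take, columns=["chrom", "center"])}

    half = cfg.peak_width // 2
    jit = cfg.peak_jitter or 0
    peaks: dict[str, pd.DataFrame] = {}
    truth = GroundTruth(class_sites=dict(class_sites))

    def _background(n_peaks: int) -> list[tuple[str, int, int]]:
        out = []
        for _ in range(n_peaks):
            chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
            c = int(rng.integers(half, length - half))
            out.append((chrom, c - half, c + half))
        return out

    for name, _, _ in cfg.planted_classes:
        sites = class_sites[name]
        for f in members[name]:
            truth.factor_class[f] = name
            rows = []
            for r in sites.itertuples(index=False):
                c = int(r.center) + (int(rng.integers(-jit, jit + 1)) if jit else 0)
                lo = max(0, c - half)
                hi = min(genome[r.chrom], c + half)
                rows.append((r.chrom, lo, hi))
            rows += _background(cfg.n_background_peaks)
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            peaks[f] = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
                drop=True
            )
    for f in noise_factors:
        truth.factor_class[f] = "noise"
        df = pd.DataFrame(_background(cfg.n_background_peaks + 50), columns=["chrom", "start", "end"])
        peaks[f] = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return peaks, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    cfg: SimConfig,
    true_targets: Mapping[str, set[str]],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Grouped expression matrix with planted module activity shifts.

    Baseline per-gene expression is log-normal; genes in a module's true
    target set are multiplied by ``2**module_effect[(module, group)]`` in the
    samples of that group; independent log-normal noise on every entry.

    Returns (matrix genes × samples, sample annotation, truth).
    """
    cfg.validate()
    rng = rng or _stream(cfg.seed, _T_EXPR)
    genes = gene_ids(cfg)
    sample_rows = []
    for grp in cfg.groups:
        for i in range(cfg.n_samples_per_group):
            sample_rows.append((f"{grp}_s{i+1}", grp))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "group"])

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    shift = np.zeros((cfg.n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    truth = GroundTruth(true_targets={m: set(t) for m, t in true_targets.items()})
    for (module, group), eff in (cfg.module_effect or {}).items():
        if module not in true_targets:
            continue
        rows = [gene_index[g] for g in true_targets[module] if g in gene_index]
        cols = np.flatnonzero(samples["group"].to_numpy() == group)
        shift[np.ix_(rows, cols)] += eff
        truth.group_activity.setdefault(module, {})[group] = float(eff)
    noise = rng.normal(0.0, cfg.expression_noise_sd, size=shift.shape)
    values = baseline[:, None] * 2.0 ** (shift + noise)
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise AssertionError("expression matrix must be strictly positive and finite")
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples["sample_id"])
    return expr, samples, truth


def gen_expression_closed_form(
    cfg: SimConfig, true_targets: Mapping[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Deterministic no-noise variant (one sample per group, unit baseline).

    Used for closed-form checks of the activity equations: with two groups,
    effect +1 in the active group and no noise, a module's activity works
    out to exactly ±0.5.
    """
    cfg2 = SimConfig(**{**cfg.__dict__, "n_samples_per_group": 1, "expression_noise_sd": 0.0,
                        "baseline_log_sd": 0.0, "baseline_log_mean": 0.0,
                        "module_effect": cfg.module_effect, "peak_jitter": cfg.peak_jitter})
    genes = gene_ids(cfg2)
    samples = pd.DataFrame(
        [(f"{g}_s1", g) for g in cfg2.groups], columns=["sample_id", "group"]
    )
    shift = np.zeros((cfg2.n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    truth = GroundTruth(true_targets={m: set(t) for m, t in true_targets.items()})
    for (module, group), eff in (cfg2.module_effect or {}).items():
        if module not in true_targets:
            continue
        rows = [gene_index[g] for g in true_targets[module] if g in gene_index]
        cols = np.flatnonzero(samples["group"].to_numpy() == group)
        shift[np.ix_(rows, cols)] += eff
        truth.group_activity.setdefault(module, {})[group] = float(eff)
    values = 2.0**shift
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples["sample_id"])
    return expr, samples, truth


# ---------------------------------------------------------------------------
# histone features
# ---------------------------------------------------------------------------

#: marks carrying the activating signal on true targets
_SIGNAL_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1")

_MARK_NAMES = (
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K27me3",
    "H3K9me3", "H3K9ac", "H3K36me3", "H3K79me2", "H4K20me3",
)


def gen_histone_features(
    cfg: SimConfig,
    true_targets: Mapping[str, set[str]],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-gene histone-mark + expression-time-course features, and the
    contaminated putative-positive sets the PU refinement must clean up.

    True targets of any module carry a ``feature_shift`` elevation on the
    active marks and on the expression-time-course features; all other genes
    carry background noise. Each module's putative set is its true targets
    plus enough random non-target genes that a ``contamination_rate``
    fraction of the putative positives are background-only — the planted
    false positives.
    """
    cfg.validate()
    rng = rng or _stream(cfg.seed, _T_FEAT)
    genes = gene_ids(cfg)
    marks = list(_MARK_NAMES[: cfg.n_histone_marks])
    tcols = [f"expr_t{i}" for i in range(cfg.n_expression_timepoints)]
    all_true = set().union(*true_targets.values()) if true_targets else set()
    is_true = np.array([g in all_true for g in genes])

    values = rng.normal(0.0, cfg.feature_noise_sd, size=(cfg.n_genes, len(marks) + len(tcols)))
    signal_cols = [marks.index(m) for m in _SIGNAL_MARKS if m in marks]
    signal_cols += [len(marks) + i for i in range(len(tcols))]
    values[np.ix_(is_true, signal_cols)] += cfg.feature_shift
    feats = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=marks + tcols)

    truth = GroundTruth(true_targets={m: set(t) for m, t in true_targets.items()})
    non_targets = [g for g in genes if g not in all_true]
    for module, targets in true_targets.items():
        n_true = len(targets)
        n_contam = int(round(cfg.contamination_rate / (1 - cfg.contamination_rate) * n_true))
        n_contam = min(n_contam, len(non_targets))
        contam = list(rng.choice(non_targets, size=n_contam, replace=False)) if n_contam else []
        truth.putative_targets[module] = set(targets) | set(contam)
    return feats, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def gen_survival(
    cfg: SimConfig,
    activity: pd.Series,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival times with activity-dependent hazard.

    Hazard is ``h0 * HR`` for samples whose activity z-score is positive and
    ``h0`` otherwise; censoring times are uniform on an interval calibrated
    so roughly ``censoring_rate`` of samples are censored (0 disables it).
    Columns: sample_id, time, event.
    """
    cfg.validate()
    rng = rng or _stream(cfg.seed, _T_SURV)
    a = activity.to_numpy(dtype=float)
    sd = a.std()
    z = (a - a.mean()) / (sd if sd > 0 else 1.0)
    hazard = cfg.baseline_hazard * np.where(z > 0, cfg.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        # censored fraction for T~Exp(h), C~U(0,c) is (1 - exp(-h c)) / (h c);
        # calibrate c on the mean hazard by bisection
        hbar = hazard.mean()

        def frac(c: float) -> float:
            return (1.0 - np.exp(-hbar * c)) / (hbar * c)

        lo_c, hi_c = 1e-6, 1e6
        for _ in range(80):
            mid = np.sqrt(lo_c * hi_c)
            if frac(mid) > cfg.censoring_rate:
                lo_c = mid
            else:
                hi_c = mid
        c_upper = np.sqrt(lo_c * hi_c)
        t_cens = rng.uniform(0, c_upper, size=len(a))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(a), dtype=int)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({"sample_id": activity.index, "time": time, "event": event})


# ---------------------------------------------------------------------------
# orchestration and file output
# ---------------------------------------------------------------------------

@dataclass
class SimData:
    """Everything one simulated study produces, in memory."""

    cfg: SimConfig
    gene_tables: list[pd.DataFrame]
    count_tables: list[pd.DataFrame]
    peaks: dict[str, pd.DataFrame]
    annotation: pd.DataFrame
    interactions: pd.DataFrame
    expression: pd.DataFrame
    sample_annotation: pd.DataFrame
    features: pd.DataFrame
    truth: GroundTruth


def simulate_all(cfg: SimConfig) -> SimData:
    """Run every generator with consistent planted structure."""
    gene_tables, count_tables, t_scr = gen_screens(cfg)
    ann, pairs, t_ann = gen_annotation_and_interactions(cfg)
    peaks, t_peaks = gen_peaks(cfg, class_sites=t_ann.class_sites)
    expr, samples, t_expr = gen_expression(cfg, t_ann.true_targets)
    feats, t_feat = gen_histone_features(cfg, t_ann.true_targets)
    truth = GroundTruth(
        essential_genes=t_scr.essential_genes,
        common_essential=t_scr.common_essential,
        factor_class=t_peaks.factor_class,
        class_sites=t_ann.class_sites,
        true_targets=t_ann.true_targets,
        putative_targets=t_feat.putative_targets,
        group_activity=t_expr.group_activity,
    )
    _check_no_orphans(truth, gene_ids(cfg), list(peaks))
    return SimData(cfg, gene_tables, count_tables, peaks, ann, pairs, expr, samples, feats, truth)


def _check_no_orphans(truth: GroundTruth, genes: list[str], factors: list[str]) -> None:
    """Every planted identifier must reference a generated entity."""
    gene_set, factor_set = set(genes), set(factors)
    for sid, ess in truth.essential_genes.items():
        if not ess <= gene_set:
            raise AssertionError(f"orphan essential genes in {sid}")
    for m, t in truth.true_targets.items():
        if not t <= gene_set:
            raise AssertionError(f"orphan true targets in module {m}")
    for m, t in truth.putative_targets.items():
        if not t <= gene_set:
            raise AssertionError(f"orphan putative targets in module {m}")
    if not set(truth.factor_class) <= factor_set | {"noise"} | factor_set:
        raise AssertionError("orphan factors in factor_class")


def write_simdata(sim: SimData, outdir: str | Path) -> None:
    """Write every generated input in its standard plain-text format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_genome_sizes(sim.cfg.genome_dict, out / "genome.sizes.tsv")
    for gt in sim.gene_tables:
        sid = gt["screen_id"].iloc[0]
        gt.to_csv(out / f"{sid}.gene_summary.tsv", sep="\t", index=False)
    for ct, gt in zip(sim.count_tables, sim.gene_tables):
        sid = gt["screen_id"].iloc[0]
        ct.to_csv(out / f"{sid}.sgrna_counts.tsv", sep="\t", index=False)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    manifest = []
    for f, df in sim.peaks.items():
        path = peaks_dir / f"{f}.bed"
        io.write_bed(df, path)
        manifest.append((f, str(path.relative_to(out))))
    pd.DataFrame(manifest, columns=["factor", "path"]).to_csv(
        out / "peaks.manifest.tsv", sep="\t", index=False
    )
    sim.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    io.write_bedpe(sim.interactions, out / "interactions.bedpe")
    sim.expression.to_csv(out / "expression.tsv", sep="\t")
    sim.sample_annotation.to_csv(out / "samples.tsv", sep="\t", index=False)
    sim.features.to_csv(out / "features.tsv", sep="\t")
    io.write_gmt(sim.truth.true_targets, out / "true_modules.gmt")
    io.write_json(sim.truth.to_json_dict(), out / "ground_truth.json")
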