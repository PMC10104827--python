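"""End-to-end driver: simulate → screens → classes → HDBS → targets →
activity → enrichment → survival, writing every stage's tables.

Each stage delegates to its module; this file only wires them together and
serializes results, so the whole analysis is reproducible from one
:class:`~pgrn.synth.SimConfig`. Output is deterministic: the same config
yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import activity as act
from . import cooccupancy as co
from . import enrichment as en
from . import io
from . import screens as scr
from . import targets as tg
from .synth import SimConfig, SimData, gen_survival, simulate_all, write_simdata


@dataclass
class PipelineResult:
    sim: SimData
    partition: scr.GenePartition
    correlation: pd.DataFrame
    z: pd.DataFrame
    subclasses: list[co.SubClass]
    hdbs: dict[str, pd.DataFrame]
    putative: dict[str, pd.DataFrame]
    modules: dict[str, tg.ModuleGeneSet]
    activity_E: pd.DataFrame
    per_sample: pd.DataFrame
    sample_cells: pd.DataFrame
    group_cells: pd.DataFrame
    survival: dict[str, dict]


def default_k(n_members: int) -> int:
    """k-of-n co-occupancy threshold: ~3/4 of the members (>=1)."""
    return max(1, math.ceil(0.75 * n_members))


def run_pipeline(cfg: SimConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on one simulated study; optionally write all tables."""
    sim = simulate_all(cfg)

    # --- screens ---
    partition = scr.integrate_screens(sim.gene_tables)
    correlation = scr.screen_correlation(sim.gene_tables)

    # --- co-occupancy classes ---
    occ = co.bin_occupancy(sim.peaks, cfg.genome_dict, cfg.bin_size)
    z = co.cooccupancy_z(occ)
    n_clusters = len(cfg.planted_classes) + (1 if cfg.n_noise_factors else 0)
    subclasses = co.cluster_subclasses(z, n_clusters)

    # --- HDBS + targets per planted class (skip the noise cluster) ---
    planted_members, _ = cfg.factor_names()
    hdbs: dict[str, pd.DataFrame] = {}
    putative: dict[str, pd.DataFrame] = {}
    modules: dict[str, tg.ModuleGeneSet] = {}
    expr_cols = [c for c in sim.features.columns if c.startswith("expr_")]
    feats = tg.build_features(sim.features[expr_cols], sim.features.drop(columns=expr_cols))
    for name, members in planted_members.items():
        hd = co.hdbs_extract({f: sim.peaks[f] for f in members}, k=default_k(len(members)))
        hdbs[name] = hd
        prox = tg.proximal_targets(hd, sim.annotation)
        dist = tg.distal_targets(hd, sim.interactions, sim.annotation)
        putative[name] = tg.combine_targets(prox, dist, name)
        cand = set(putative[name]["gene_id"])
        if len(cand) >= 10 and len(set(feats.index) - cand) >= 10:
            modules[name] = tg.adasample_refine(
                cand, feats, threshold=1.0, seed=cfg.seed, name=name
            )
        else:
            modules[name] = tg.ModuleGeneSet(name=name, genes=cand)

    # --- activity + enrichment + survival ---
    groups = sim.sample_annotation.set_index("sample_id")["group"]
    module_sets = {m: ms.genes for m, ms in modules.items() if ms.genes}
    C = act.centralize(act.standardize(sim.expression, pseudocount=1))
    activity_E = act.module_activity(C, module_sets, groups)
    per_sample = pd.DataFrame(
        {m: act.per_sample_activity(C, genes) for m, genes in module_sets.items()}
    )
    degs = en.call_sample_degs(sim.expression)
    cells = en.sample_module_pattern(degs, module_sets)
    group_cells = en.group_pattern(cells, groups)
    survival: dict[str, dict] = {}
    for m in sorted(module_sets):
        a = per_sample[m]
        surv = gen_survival(cfg, a)
        survival[m] = act.stratify_survival(a, surv)

    res = PipelineResult(
        sim, partition, correlation, z, subclasses, hdbs, putative, modules,
        activity_E, per_sample, cells, group_cells, survival,
    )
    if outdir is not None:
        write_pipeline(res, outdir)
    return res


def write_pipeline(res: PipelineResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_simdata(res.sim, out / "inputs")
    io.write_json(
        {
            "common": sorted(res.partition.common),
            "context_specific": sorted(res.partition.context_specific),
            "per_screen": {k: sorted(v) for k, v in res.partition.per_screen_significant.items()},
        },
        out / "screen_partition.json",
    )
    res.correlation.to_csv(out / "screen_correlation.tsv", sep="\t")
    res.z.to_csv(out / "cooccupancy_z.tsv", sep="\t")
    io.write_json(
        {s.name: s.members for s in res.subclasses}, out / "subclasses.json"
    )
    for name, hd in res.hdbs.items():
        io.write_bed(hd, out / f"hdbs_{name}.bed", extra_cols=["degree"])
    for name, put in res.putative.items():
        put.to_csv(out / f"putative_{name}.tsv", sep="\t", index=False)
    io.write_gmt({m: ms.genes for m, ms in res.modules.items()}, out / "modules.gmt")
    prov = pd.concat(
        [
            pd.DataFrame(
                {
                    "module": m,
                    "gene_id": sorted(ms.vote_fraction),
                    "vote_fraction": [ms.vote_fraction[g] for g in sorted(ms.vote_fraction)],
                    "retained": [g in ms.genes for g in sorted(ms.vote_fraction)],
                }
            )
            for m, ms in res.modules.items()
        ],
        ignore_index=True,
    ) if any(ms.vote_fraction for ms in res.modules.values()) else pd.DataFrame()
    prov.to_csv(out / "module_provenance.tsv", sep="\t", index=False)
    res.activity_E.to_csv(out / "module_activity.tsv", sep="\t")
    res.per_sample.to_csv(out / "per_sample_activity.tsv", sep="\t")
    res.sample_cells.to_csv(out / "enrichment_samples.tsv", sep="\t", index=False)
    res.group_cells.to_csv(out / "enrichment_groups.tsv", sep="\t", index=False)
    surv_rows = []
    for m, s in res.survival.items():
        surv_rows.append((m, s["statistic"], s["p"], s["threshold"]))
        for label, tbl in s["km"].items():
            tbl.assign(module=m, stratum=label).to_csv(
                out / f"km_{m}_{label}.tsv", sep="\t", index=False
            )
    pd.DataFrame(surv_rows, columns=["module", "logrank_chi2", "p", "activity_threshold"]).to_csv(
        out / "survival_logrank.tsv", sep="\t", index=False
    )
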