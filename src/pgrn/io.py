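"""Readers and writers for the plain-text formats the pipeline exchanges.

BED / BEDPE / bedGraph / GMT / genome-sizes TSV plus the tabular TSVs
(counts, screen gene summaries, expression, features, survival). Everything
round-trips through pandas; coordinates stay 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"] + [
        f"extra{i}" for i in range(df.shape[1] - 6)
    ]
    return df


def write_bedpe(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom1", "start1", "end1", "chrom2", "start2", "end2"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, set[str] | list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


def read_genome_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_genome_sizes(genome: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame({"chrom": list(genome), "length": list(genome.values())}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str | Path, genome: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base arrays (missing intervals = 0)."""
    cov = {c: np.zeros(n, dtype=float) for c, n in genome.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for r in df.itertuples(index=False):
        cov[r.chrom][r.start : r.end] = r.value
    return cov


def write_bedgraph(cov: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode dense per-base coverage; zero runs are omitted."""
    rows = []
    for chrom, arr in cov.items():
        if len(arr) == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate([[0], change, [len(arr)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            v = arr[s]
            if v != 0:
                rows.append((chrom, int(s), int(e), float(v)))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_mageck_gene_summary(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a MAGeCK-style gene_summary TSV into (gene_id, lfc, p_neg, p_pos).

    ``column_map`` maps our names to the file's column headers; defaults cover
    MAGeCK's ``id``, ``neg|lfc``, ``neg|p-value``, ``pos|p-value``.
    """
    cmap = {"gene_id": "id", "lfc": "neg|lfc", "p_neg": "neg|p-value", "p_pos": "pos|p-value"}
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t")
    out = pd.DataFrame()
    for ours, theirs in cmap.items():
        if theirs in raw.columns:
            out[ours] = raw[theirs]
        elif ours == "p_pos":  # optional
            continue
        else:
            raise ValueError(f"column {theirs!r} not found in {path}")
    return out


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")
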