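"""File formats, configuration and the end-to-end pipeline.

Counts are read either from MatrixMarket coordinate files (genes x cells, with
``<stem>.genes.tsv`` / ``<stem>.cells.tsv`` sidecars listing row and column
ids) or from dense CSV/TSV matrices with gene rows and a header of cell ids.
Group labels come from a two-column TSV/CSV (cell id, group in {0, 1}).

The pipeline mirrors the recommended workflow: filter low-prevalence genes,
bootstrap the model over a factor grid, summarise edges, pick F at the peak of
the differential-edge proportion, and write the differential network plus the
two within-condition networks as TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .inference import bootstrap
from .model import CountDataset, ModelSpec
from .network import EdgeTable, edge_index, select_factors, summarize_edges, \
    summarize_group_edges

logger = logging.getLogger(__name__)

_EDGE_COLUMNS = ["gene1", "gene2", "rho0_hat", "rho1_hat", "theta_hat",
                 "ci_lower", "ci_upper", "approx_p", "significant"]


def _validate_int_matrix(values: np.ndarray, cell_names) -> np.ndarray:
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    bad = ~np.isclose(arr, np.round(arr))
    if bad.any():
        g, i = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer count at gene row {g}, cell {cell_names[i]!r}")
    if (arr < 0).any():
        g, i = np.argwhere(arr < 0)[0]
        raise ValueError(f"negative count at gene row {g}, cell {cell_names[i]!r}")
    return np.round(arr).astype(np.int64)


def read_counts(path: str | Path, fmt: str | None = None,
                transpose: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a counts matrix; returns (counts G x N, gene_ids, cell_ids).

    ``fmt`` is inferred from the suffix when omitted.  ``transpose`` handles
    cells-in-rows input.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "mtx":
        raw = mmread(path)
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        genes_path = path.with_suffix(".genes.tsv")
        cells_path = path.with_suffix(".cells.tsv")
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).to_numpy()
        cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).to_numpy()
        if transpose:
            mat = mat.T
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix is {mat.shape} but sidecars list {len(gene_ids)} genes "
                f"and {len(cell_ids)} cells; pass transpose=True if cells are rows")
        counts = _validate_int_matrix(mat, cell_ids)
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        gene_ids = df.index.astype(str).to_numpy()
        cell_ids = df.columns.astype(str).to_numpy()
        counts = _validate_int_matrix(df.to_numpy(), cell_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    return counts, gene_ids, cell_ids


def write_counts(path: str | Path, dataset: CountDataset, fmt: str | None = None) -> None:
    """Write counts as MatrixMarket (+ id sidecars) or dense CSV/TSV."""
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix.lower(), "tsv")
    if fmt == "mtx":
        mmwrite(str(path), coo_matrix(dataset.counts))
        pd.Series(dataset.gene_ids).to_csv(path.with_suffix(".genes.tsv"),
                                           sep="\t", index=False, header=False)
        pd.Series(dataset.cell_ids).to_csv(path.with_suffix(".cells.tsv"),
                                           sep="\t", index=False, header=False)
    else:
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(dataset.counts, index=dataset.gene_ids,
                     columns=dataset.cell_ids).to_csv(path, sep=sep)


def read_groups(path: str | Path, cell_ids: np.ndarray) -> np.ndarray:
    """Read per-cell group labels (TSV/CSV with columns cell id, group)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.iloc[0, 0] in ("cell_id", "cell"):  # optional header
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))
    missing = [c for c in map(str, cell_ids) if c not in mapping]
    if missing:
        raise ValueError(f"no group label for cells: {missing[:5]}")
    return np.array([mapping[str(c)] for c in cell_ids], dtype=np.int8)


def write_groups(path: str | Path, dataset: CountDataset) -> None:
    pd.DataFrame({"cell_id": dataset.cell_ids, "group": dataset.groups}).to_csv(
        path, sep="\t", index=False, header=False)


def load_dataset(counts_path: str | Path, groups_path: str | Path,
                 fmt: str | None = None, transpose: bool = False) -> CountDataset:
    counts, gene_ids, cell_ids = read_counts(counts_path, fmt, transpose)
    groups = read_groups(groups_path, cell_ids)
    return CountDataset(counts=counts, groups=groups, gene_ids=gene_ids,
                        cell_ids=cell_ids)


def filter_genes(dataset: CountDataset, min_fraction: float = 0.20) -> CountDataset:
    """Keep genes expressed (count > 0) in at least ``min_fraction`` of cells."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    prevalence = np.mean(dataset.counts > 0, axis=1)
    keep = prevalence >= min_fraction
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return CountDataset(counts=dataset.counts[keep], groups=dataset.groups,
                        gene_ids=np.asarray(dataset.gene_ids)[keep],
                        cell_ids=dataset.cell_ids)


def write_edge_table(path: str | Path, table: EdgeTable,
                     gene_ids: np.ndarray | None = None) -> None:
    """Edge TSV: 6 significant digits, stable sort by approx_p then gene pair."""
    df = table.to_frame(gene_ids)
    df = df.sort_values(["approx_p", "gene1", "gene2"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    return df


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; flags mirror these fields one-to-one."""

    counts_path: str
    groups_path: str
    output_dir: str
    variant: str = "SHS"
    factor_grid: tuple[int, ...] = tuple(range(5, 21))
    fixed_F: int | None = None
    M_b: int = 1000
    level_alpha: float = 0.05
    seed: int = 0
    n_workers: int = 1
    min_fraction: float = 0.20
    transpose: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.level_alpha < 1:
            raise ValueError("level_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file whose keys mirror the fields one-to-one."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if "factor_grid" in raw and raw["factor_grid"] is not None:
            raw["factor_grid"] = tuple(raw["factor_grid"])
        return cls(**raw)


def run_pipeline(config: RunConfig, dataset: CountDataset | None = None) -> dict:
    """Filter genes, bootstrap per factor count, select F, write the networks.

    Outputs in ``config.output_dir``: edges_differential.tsv, edges_group0.tsv,
    edges_group1.tsv, factor_selection.tsv and run_log.json (seeds + sizes).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        dataset = load_dataset(config.counts_path, config.groups_path,
                               transpose=config.transpose)
    dataset = filter_genes(dataset, config.min_fraction)
    G = dataset.n_genes
    grid = [config.fixed_F] if config.fixed_F is not None else list(config.factor_grid)

    tables: dict[int, EdgeTable] = {}
    boots = {}
    for F in grid:
        spec = ModelSpec(variant=config.variant, n_factors=F, seed=config.seed)
        boot = bootstrap(dataset, spec, M_b=config.M_b, base_seed=config.seed,
                         n_jobs=config.n_workers)
        tables[F] = summarize_edges(boot.theta_draws, boot.rho0_draws,
                                    boot.rho1_draws, config.level_alpha)
        boots[F] = boot
        logger.info("F=%d: %d/%d significant differential edges", F,
                    tables[F].n_significant, tables[F].n_edges)

    if config.fixed_F is not None:
        chosen_F = config.fixed_F
        sel_df = pd.DataFrame({
            "F": [chosen_F],
            "proportion_differential": [tables[chosen_F].n_significant
                                        / (G * (G - 1) // 2)],
            "chosen": ["fixed"],
        })
    else:
        sel = select_factors(tables, G)
        chosen_F = sel.chosen_F
        sel_df = sel.to_frame()
    sel_df.to_csv(out / "factor_selection.tsv", sep="\t", index=False,
                  float_format="%.6g")

    best = tables[chosen_F]
    boot = boots[chosen_F]
    gene_ids = np.asarray(dataset.gene_ids)
    write_edge_table(out / "edges_differential.tsv", best, gene_ids)
    for t, draws in ((0, boot.rho0_draws), (1, boot.rho1_draws)):
        df = summarize_group_edges(draws, config.level_alpha)
        df["gene1"] = gene_ids[df["gene1"]]
        df["gene2"] = gene_ids[df["gene2"]]
        df.sort_values(["approx_p", "gene1", "gene2"], kind="stable").to_csv(
            out / f"edges_group{t}.tsv", sep="\t", index=False, float_format="%.6g")

    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_genes_after_filter": int(G),
        "n_cells": int(dataset.n_cells),
        "chosen_F": int(chosen_F),
        "replicate_seeds": {int(F): [int(boots[F].base_seed + b)
                                     for b in range(config.M_b)] for F in grid},
        "n_converged": {int(F): int(boots[F].n_converged) for F in grid},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"chosen_F": chosen_F, "edge_table": best, "dataset": dataset,
            "bootstrap": boot, "selection": sel_df}
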