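"""Readers and writers for the package's artifacts, plus the benchmark
driver.

All artifacts are plain delimited text: data matrices and square
weight/adjacency/prior matrices as CSV with a header row, edge lists as
TSV (source, target, weight), and optionally GraphML for graph tools.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import netstats
from .lingam_fit import bilingam
from .simulate import SimulationConfig, generate_study

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_graph",
    "read_module_map",
    "run_benchmark",
    "RunManifest",
]


def read_matrix(path, kind: str = "data") -> pd.DataFrame:
    """Read a delimited matrix with header.

    ``kind='data'`` accepts any numeric n x p table; ``'adjacency'`` and
    ``'prior'`` additionally require a square matrix, and a prior may only
    contain the values {0, -1}.
    """
    if kind not in ("data", "adjacency", "prior"):
        raise ValueError(f"unknown kind {kind!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if kind in ("adjacency", "prior"):
        if df.shape[0] != df.shape[1]:
            raise ValueError(
                f"{kind} matrix in {path} must be square; got {df.shape}"
            )
        if kind == "prior":
            vals = df.to_numpy()
            bad = np.argwhere(~np.isin(vals, (0.0, -1.0)))
            if bad.size:
                r, c = bad[0]
                raise ValueError(
                    f"prior entry at row {df.index[r]}, column {df.columns[c]} "
                    f"is {vals[r, c]}; only 0 and -1 are allowed"
                )
            df = df.astype(np.int8)
    return df


def write_matrix(M: np.ndarray, path, columns: list[str] | None = None) -> None:
    M = np.asarray(M)
    if columns is None:
        columns = [f"V{i+1}" for i in range(M.shape[1])]
    pd.DataFrame(M, columns=columns).to_csv(path, index=False)


def write_graph(
    B: np.ndarray,
    path,
    format: str = "matrix-csv",
    columns: list[str] | None = None,
) -> None:
    """Write a weighted DAG as a matrix CSV, an edge-list TSV (rows in
    lexicographic (source, target) order) or GraphML with a ``weight``
    edge attribute.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    if columns is None:
        columns = [f"V{i+1}" for i in range(p)]
    if format == "matrix-csv":
        write_matrix(B, path, columns)
    elif format == "edgelist-tsv":
        rows = [
            (columns[i], columns[j], B[i, j])
            for i, j in sorted(map(tuple, np.argwhere(B != 0)))
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        G = nx.DiGraph()
        G.add_nodes_from(columns)
        for i, j in np.argwhere(B != 0):
            G.add_edge(columns[i], columns[j], weight=float(B[i, j]))
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_module_map(path) -> dict:
    """Node-to-module table with columns (node, module); node ids may be
    integer indices or names matching the graph's column header."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("module map needs two columns: node, module")
    keys = df.iloc[:, 0]
    try:
        keys = keys.astype(int)
    except (ValueError, TypeError):
        pass
    return dict(zip(keys, df.iloc[:, 1]))


class RunManifest:
    """Reproducibility record: config, seed, durations, digests, version."""

    def __init__(self, config: dict, seed: int | None):
        from . import __version__

        self.data = {
            "version": __version__,
            "seed": seed,
            "config": config,
            "inputs": {},
            "durations_s": {},
        }
        self._t0: dict[str, float] = {}

    def add_input(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.data["inputs"][str(path)] = digest

    def start(self, stage: str) -> None:
        self._t0[stage] = time.monotonic()

    def stop(self, stage: str) -> None:
        self.data["durations_s"][stage] = round(time.monotonic() - self._t0[stage], 3)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str) + "\n")


def _evaluate(B_true_list, B_est_list) -> dict[str, float]:
    tprs, fdrs, shds = [], [], []
    for Bt, Be in zip(B_true_list, B_est_list):
        c = netstats.confusion_counts(Bt, Be)
        tpr, fdr = netstats.tpr_fdr(c)
        tprs.append(tpr)
        fdrs.append(fdr)
        shds.append(netstats.shd(Bt, Be))
    return {
        "TPR": float(np.nanmean(tprs)),
        "FDR": float(np.mean(fdrs)),
        "SHD": float(np.mean(shds)),
    }


def run_benchmark(
    grid: list[dict],
    reps: int = 10,
    methods: tuple[str, ...] = ("bilingam", "psi-lingam"),
    seed: int = 0,
    alpha: float = 0.05,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Simulation benchmark over a grid of scenarios.

    Each grid cell is a dict with keys K, p, N, d.  For every replicate a
    fresh ground-truth family and dataset are generated; each method is
    fit and its group-averaged TPR/FDR/SHD recorded.  Output is a
    long-format frame with one row per cell x replicate x method x metric,
    with the replicate seed logged.
    """
    prior_mode = {"bilingam": "joint", "psi-lingam": "distinct"}
    records = []
    ss = np.random.SeedSequence(seed)
    for cell in grid:
        cell_seeds = ss.spawn(reps)
        for r in range(reps):
            rep_seed = int(cell_seeds[r].generate_state(1)[0] % (2**31))
            cfg = SimulationConfig(
                K=cell["K"], p=cell["p"], N=cell["N"], d=cell["d"], seed=rep_seed
            )
            truth, X_groups = generate_study(cfg)
            for method in methods:
                res = bilingam(
                    X_groups, alpha=alpha, lam=lam, prior=prior_mode[method]
                )
                metrics = _evaluate(truth.B_list, res.B_list)
                for name, value in metrics.items():
                    records.append(
                        {
                            **{k: cell[k] for k in ("K", "p", "N", "d")},
                            "replicate": r,
                            "seed": rep_seed,
                            "method": method,
                            "metric": name,
                            "value": value,
                        }
                    )
    return pd.DataFrame.from_records(records)
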