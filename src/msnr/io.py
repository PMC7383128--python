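"""Readers and writers for the interchange formats.

Adjacency stacks travel either as one HDF5 container (datasets ``/A``,
``/subject_ids``, ``/node_ids``) or as a directory of per-subject
delimited square matrices named ``<subject_id>.tsv`` (plus an optional
``nodes.txt`` listing node ids, one per line).  Covariates, partitions and
coordinates are delimited text.  Subjects are always aligned by ID join,
never by row order; node order is taken from the adjacency container and
partition/coordinate tables are reindexed to it.  Numeric text output uses
17 significant digits so round-trips are exact.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    AdjacencyStack,
    CommunityPartition,
    CovariateTable,
    FitDiagnostics,
    MSNRModel,
    build_membership,
)
from .summaries import NodeCoordinates

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

__all__ = [
    "load_adjacency",
    "save_adjacency",
    "load_covariates",
    "save_covariates",
    "load_partition",
    "load_coordinates",
    "align_subjects",
    "save_model",
    "load_model",
    "read_config",
    "write_config",
    "write_json",
]


def _validate_stack(values: np.ndarray, subject_ids, node_ids, source: str) -> AdjacencyStack:
    asym = np.max(np.abs(values - values.transpose(0, 2, 1)), initial=0.0)
    if asym > 1e-8:
        raise ValueError(f"{source}: asymmetry {asym:.3e} exceeds tolerance 1e-8")
    idx = np.arange(values.shape[1])
    max_diag = np.max(np.abs(values[:, idx, idx]), initial=0.0)
    if max_diag > 0:
        logger.warning("%s: nonzero diagonal (max |%g|) zeroed", source, max_diag)
    return AdjacencyStack(values, subject_ids, node_ids)


def load_adjacency(path) -> AdjacencyStack:
    """Load a stack from an HDF5 container or a directory of text matrices."""
    path = Path(path)
    if path.is_dir():
        nodes_file = path / "nodes.txt"
        node_ids = (
            nodes_file.read_text().split() if nodes_file.exists() else None
        )
        files = sorted(p for p in path.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no .tsv matrices in {path}")
        mats, sids = [], []
        for f in files:
            M = np.loadtxt(f, delimiter="\t", ndmin=2)
            mats.append(M)
            sids.append(f.stem)
        shapes = {m.shape for m in mats}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent matrix shapes across subjects: {shapes}")
        return _validate_stack(np.stack(mats), sids, node_ids, str(path))
    with h5py.File(path, "r") as h5:
        values = np.asarray(h5["A"], dtype=float)
        subject_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["subject_ids"][()]]
        node_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in h5["node_ids"][()]]
    return _validate_stack(values, subject_ids, node_ids, str(path))


def save_adjacency(stack: AdjacencyStack, path, fmt: str = "h5") -> Path:
    """Write a stack as HDF5 (``fmt='h5'``) or a directory of TSVs."""
    path = Path(path)
    if fmt == "h5":
        with h5py.File(path, "w") as h5:
            h5.create_dataset("A", data=stack.values)
            h5.create_dataset("subject_ids", data=np.array(stack.subject_ids, dtype="S"))
            h5.create_dataset("node_ids", data=np.array(stack.node_ids, dtype="S"))
        return path
    if fmt == "dir":
        path.mkdir(parents=True, exist_ok=True)
        (path / "nodes.txt").write_text("\n".join(map(str, stack.node_ids)) + "\n")
        for sid, M in zip(stack.subject_ids, stack.values):
            np.savetxt(path / f"{sid}.tsv", M, delimiter="\t", fmt=FLOAT_FMT)
        return path
    raise ValueError(f"unknown adjacency format: {fmt}")


def load_covariates(path) -> CovariateTable:
    """Delimited text: first column subject_id, remaining numeric columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("covariate table needs subject_id plus >= 1 covariate")
    sids = df.iloc[:, 0].astype(str).to_numpy()
    names = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=float)
    return CovariateTable(raw, sids, names)


def save_covariates(X: CovariateTable, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(X.raw, columns=list(X.covariate_names))
    df.insert(0, "subject_id", X.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def load_partition(path, node_order=None) -> CommunityPartition | dict:
    """Delimited text with columns node_id, community_label.

    With ``node_order`` given (from the adjacency container) the indicator
    matrix is built in that order; otherwise the raw map is returned.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("partition table needs node_id and community_label columns")
    table = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if node_order is None:
        return table
    return build_membership(table, [str(x) for x in node_order])


def save_partition(partition: CommunityPartition, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "node_id": list(partition.node_ids),
            "community_label": [partition.assignment[n] for n in partition.node_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def load_coordinates(path, node_order=None) -> NodeCoordinates:
    """Delimited text with columns node, x, y, z; reindexed to node_order."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 4:
        raise ValueError("coordinate table needs node, x, y, z columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if node_order is not None:
        missing = [n for n in map(str, node_order) if n not in df.index]
        if missing:
            raise KeyError(f"nodes missing coordinates: {missing[:5]}")
        df = df.loc[[str(n) for n in node_order]]
    coords = df.iloc[:, :3].to_numpy(dtype=float)
    return NodeCoordinates(coords, list(df.index))


def align_subjects(A: AdjacencyStack, X: CovariateTable) -> tuple[AdjacencyStack, CovariateTable]:
    """Reorder the covariate table to the adjacency stack's subject order.

    Subjects present on one side only are an error, never a silent drop.
    """
    a_ids = [str(s) for s in A.subject_ids]
    x_ids = [str(s) for s in X.subject_ids]
    missing = sorted(set(a_ids) - set(x_ids))
    extra = sorted(set(x_ids) - set(a_ids))
    if missing or extra:
        raise ValueError(
            f"subject ID mismatch: {len(missing)} without covariates "
            f"(e.g. {missing[:3]}), {len(extra)} without matrices (e.g. {extra[:3]})"
        )
    pos = {s: i for i, s in enumerate(x_ids)}
    order = [pos[s] for s in a_ids]
    return A, X.subset(np.asarray(order))


def save_model(model: MSNRModel, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "theta.tsv", model.theta, delimiter="\t", fmt=FLOAT_FMT)
    names = (
        list(model.covariate_names)
        if model.covariate_names is not None
        else [f"x{f}" for f in range(model.n_covariates)]
    )
    for f, name in enumerate(names):
        np.savetxt(out_dir / f"gamma_{name}.tsv", model.gammas[f], delimiter="\t", fmt=FLOAT_FMT)
    d = model.diagnostics
    meta = {
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "covariate_names": names,
        "x_center": list(map(float, model.x_center)),
        "x_scale": list(map(float, model.x_scale)),
        "node_ids": list(map(str, model.partition.node_ids)),
        "community_labels": list(map(str, model.partition.community_labels)),
        "assignment": {str(k): str(v) for k, v in model.partition.assignment.items()},
        "diagnostics": {
            "objective_trajectory": list(map(float, d.objective_trajectory)),
            "n_iterations": d.n_iterations,
            "converged": bool(d.converged),
            "final_relative_change": float(d.final_relative_change),
            "trace_WtThetaW": float(d.trace_WtThetaW),
        },
    }
    write_json(meta, out_dir / "model.json")
    return out_dir


def load_model(model_dir) -> MSNRModel:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "model.json").read_text())
    theta = np.loadtxt(model_dir / "theta.tsv", delimiter="\t", ndmin=2)
    names = meta["covariate_names"]
    gammas = np.stack(
        [np.loadtxt(model_dir / f"gamma_{n}.tsv", delimiter="\t", ndmin=2) for n in names]
    )
    partition = build_membership(meta["assignment"], meta["node_ids"])
    d = meta["diagnostics"]
    diagnostics = FitDiagnostics(
        objective_trajectory=d["objective_trajectory"],
        n_iterations=d["n_iterations"],
        converged=d["converged"],
        final_relative_change=d["final_relative_change"],
        trace_WtThetaW=d["trace_WtThetaW"],
    )
    return MSNRModel(
        theta=theta,
        gammas=gammas,
        lambda1=float(meta["lambda1"]),
        lambda2=float(meta["lambda2"]),
        partition=partition,
        x_center=np.asarray(meta["x_center"], dtype=float),
        x_scale=np.asarray(meta["x_scale"], dtype=float),
        covariate_names=np.asarray(names),
        diagnostics=diagnostics,
    )


def read_config(path) -> dict:
    """Flat ``key = value`` text config; '#' starts a comment."""
    out: dict = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{line_no}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def write_config(config: dict, path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{k} = {v}\n" for k, v in config.items()))
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
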