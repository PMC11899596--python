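"""File round-tripping for the pipeline's delimited-text artifacts.

Everything the pipeline reads or writes is plain text: parcellation tables
(CSV/TSV), per-subject time series (timepoints x parcels, whitespace/tab
delimited, optional header), phenotype tables (CSV), connectivity matrices
(TSV + JSON sidecar), datasets (edges TSV + phenotype CSV), CPM results
(JSON + predictions TSV), networks (edge-list and node-table TSV) and null
distributions (single-column TSV).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, ParcellatedTimeSeries
from .cpm import CPMResult, SubjectDataset, encode_confounds
from .networks import PredictiveNetwork
from .parcellation import ParcelTable, edge_pairs

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "write_dataset",
    "read_dataset",
    "save_cpm_result",
    "write_null_distribution",
    "write_network",
    "read_network",
    "write_node_table",
    "config_hash",
    "write_provenance",
]


def parcellation_hash(parcels: ParcelTable) -> str:
    payload = json.dumps(
        {"labels": parcels.labels, "groups": parcels.groups}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def read_timeseries(path: str | Path, subject_id: str | None = None) -> ParcellatedTimeSeries:
    """Read a timepoints x parcels table; a non-numeric first row is a header."""
    path = Path(path)
    try:
        values = np.loadtxt(path, ndmin=2)
    except ValueError:
        values = np.loadtxt(path, ndmin=2, skiprows=1)
    return ParcellatedTimeSeries(
        subject_id=subject_id or path.stem, values=values
    )


def write_timeseries(ts: ParcellatedTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.values, fmt="%.10g", delimiter="\t")


def write_matrix(mat: ConnectivityMatrix, path: str | Path, parcels: ParcelTable | None = None) -> None:
    """Matrix as TSV plus a JSON sidecar (subject, kind, parcellation hash)."""
    path = Path(path)
    np.savetxt(path, mat.values, fmt="%.12g", delimiter="\t")
    sidecar = {
        "subject": mat.subject_id,
        "kind": mat.kind,
        "n_parcels": mat.n_parcels,
    }
    if parcels is not None:
        sidecar["parcellation_hash"] = parcellation_hash(parcels)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    values = np.loadtxt(path, ndmin=2)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        return ConnectivityMatrix(
            subject_id=meta["subject"], values=values, kind=meta["kind"]
        )
    return ConnectivityMatrix(subject_id=path.stem, values=values, kind="covariance")


def write_dataset(data: SubjectDataset, out_dir: str | Path) -> None:
    """Dataset as edges.tsv (subject + edge columns) and phenotype.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(data.edges, columns=[f"e{j}" for j in range(data.n_edges)])
    edges.insert(0, "subject", list(data.subject_ids))
    edges.to_csv(out / "edges.tsv", sep="\t", index=False, float_format="%.12g")
    pheno = pd.DataFrame({"subject": list(data.subject_ids), "target": data.target})
    for j, name in enumerate(data.confound_names):
        pheno[name] = data.confounds[:, j]
    pheno["family"] = list(data.family_id)
    pheno.to_csv(out / "phenotype.csv", index=False, float_format="%.12g")


def read_dataset(in_dir: str | Path) -> SubjectDataset:
    in_dir = Path(in_dir)
    edges = pd.read_csv(in_dir / "edges.tsv", sep="\t")
    pheno = pd.read_csv(in_dir / "phenotype.csv")
    if not (edges["subject"].astype(str) == pheno["subject"].astype(str)).all():
        raise ValueError("edges.tsv and phenotype.csv subject order differs")
    conf_cols = [c for c in pheno.columns if c not in ("subject", "target", "family")]
    X, names = (
        (pheno[conf_cols].to_numpy(dtype=float), tuple(conf_cols))
        if conf_cols
        else (np.empty((len(pheno), 0)), ())
    )
    return SubjectDataset(
        subject_ids=tuple(str(s) for s in pheno["subject"]),
        edges=edges.drop(columns="subject").to_numpy(dtype=float),
        target=pheno["target"].to_numpy(dtype=float),
        confounds=X,
        family_id=tuple(str(f) for f in pheno["family"]),
        confound_names=names,
    )


def read_phenotype(
    path: str | Path,
    target: str,
    family: str,
    numeric: tuple[str, ...] = (),
    binary: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, np.ndarray, tuple[str, ...]]:
    """Phenotype CSV -> (table, encoded confound design, design names)."""
    df = pd.read_csv(path)
    for col in (target, family, *numeric, *binary, *categorical):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    X, names = encode_confounds(df, numeric=numeric, binary=binary, categorical=categorical)
    return df, X, names


def save_cpm_result(result: CPMResult, out_dir: str | Path) -> None:
    """CPMResult as result.json (models, params, selections) + predictions.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.12g")
    folds = []
    for rec in result.per_fold:
        folds.append(
            {
                "fold": rec.fold,
                "beta0": rec.model.beta0,
                "beta_pos": rec.model.beta_pos,
                "beta_neg": rec.model.beta_neg,
                "fallback": rec.model.fallback,
                "pos_edges": np.flatnonzero(rec.selection.pos_mask).tolist(),
                "neg_edges": np.flatnonzero(rec.selection.neg_mask).tolist(),
                "pos_r": rec.selection.r[rec.selection.pos_mask].tolist(),
                "neg_r": rec.selection.r[rec.selection.neg_mask].tolist(),
                "test_ids": list(rec.test_ids),
                "excluded_train_ids": list(rec.excluded_train_ids),
                "flags": list(rec.flags),
            }
        )
    payload = {"r_eval": result.r_eval, "params": result.params, "folds": folds}
    (out / "result.json").write_text(json.dumps(payload, indent=2))


def write_null_distribution(null_r: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(null_r, dtype=float), fmt="%.12g")


def write_network(
    net: PredictiveNetwork, parcels: ParcelTable, coi_indices: np.ndarray, path: str | Path
) -> None:
    """Network as an edge list TSV: parcel_i, parcel_j, weight, freq.

    ``coi_indices`` maps the network's edge positions (COI-vector order)
    back to the global edge universe of the parcellation.
    """
    rows, cols = edge_pairs(parcels.n_parcels)
    sel = np.flatnonzero(net.mask)
    gi = np.asarray(coi_indices)[sel]
    df = pd.DataFrame(
        {
            "parcel_i": rows[gi],
            "parcel_j": cols[gi],
            "weight": net.edge_weight[sel],
            "freq": net.edge_freq[sel],
            "coi_index": sel,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_network(path: str | Path, coi_edge_count: int, sign: str | None = None) -> PredictiveNetwork:
    df = pd.read_csv(path, sep="\t")
    if sign is None:  # infer from stored weights (networks are single-signed)
        w = df["weight"].to_numpy(dtype=float)
        sign = "negative" if w.size and (w[w != 0] < 0).all() and (w != 0).any() else "positive"
    freq = np.zeros(coi_edge_count)
    weight = np.zeros(coi_edge_count)
    mask = np.zeros(coi_edge_count, dtype=bool)
    idx = df["coi_index"].to_numpy(dtype=int)
    mask[idx] = True
    freq[idx] = df["freq"].to_numpy(dtype=float)
    weight[idx] = df["weight"].to_numpy(dtype=float)
    return PredictiveNetwork(sign=sign, edge_freq=freq, edge_weight=weight, mask=mask)


def write_node_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_provenance(out_dir: str | Path, command: str, config: dict, seed: int) -> None:
    """JSON record sufficient to re-run and reproduce an output."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "version": __version__,
    }
    (out / f"provenance_{command}.json").write_text(json.dumps(payload, indent=2, default=str))
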