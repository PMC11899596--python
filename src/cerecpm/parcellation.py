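"""Whole-brain parcellation table and connection-of-interest (COI) edge masks.

The parcellation assigns every node (parcel) to one of three groups —
cerebellar, cortical or subcortical — and fixes the edge universe used by
every downstream stage: the row-major upper triangle of the parcel x parcel
matrix, diagonal excluded, 0-based.  The COI mask restricts analysis to
edges with at least one cerebellar endpoint (cerebellocerebral plus,
optionally, intracerebellar connections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("cerebellar", "cortical", "subcortical")
HEMISPHERES = ("left", "right", "midline", "unknown")

__all__ = [
    "GROUPS",
    "HEMISPHERES",
    "ParcelTable",
    "EdgeMask",
    "n_edges",
    "edge_index",
    "edge_pair",
    "edge_pairs",
    "build_coi_mask",
    "build_full_mask",
]


def n_edges(n_parcels: int) -> int:
    """Number of unordered parcel pairs: C(P, 2)."""
    return comb(int(n_parcels), 2)


def edge_index(i: int, j: int, n_parcels: int) -> int:
    """Position of the unordered pair {i, j} in the canonical edge order.

    The canonical order is the row-major upper triangle with the diagonal
    excluded (the order produced by ``numpy.triu_indices(P, 1)``), so the
    mapping is a bijection onto ``0 .. P(P-1)/2 - 1``.

    Raises
    ------
    ValueError
        If ``i == j`` (self-edges are not part of the universe).
    IndexError
        If either id falls outside ``0 .. P-1``.
    """
    P = int(n_parcels)
    i, j = int(i), int(j)
    if not (0 <= i < P and 0 <= j < P):
        raise IndexError(f"parcel ids ({i}, {j}) out of range for P={P}")
    if i == j:
        raise ValueError(f"self-edge ({i}, {i}) is not a valid edge")
    if i > j:
        i, j = j, i
    return i * (2 * P - i - 1) // 2 + (j - i - 1)


def edge_pair(k: int, n_parcels: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: recover the unordered pair {i, j}."""
    P = int(n_parcels)
    k = int(k)
    if not 0 <= k < n_edges(P):
        raise IndexError(f"edge position {k} out of range for P={P}")
    # row i is the largest i with offset(i) <= k, offset(i) = i(2P-i-1)/2
    offsets = np.arange(P - 1) * (2 * P - np.arange(P - 1) - 1) // 2
    i = int(np.searchsorted(offsets, k, side="right") - 1)
    j = k - int(offsets[i]) + i + 1
    return i, j


def edge_pairs(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint arrays (rows, cols) for all edges in canonical order."""
    return np.triu_indices(int(n_parcels), k=1)


@dataclass(frozen=True)
class ParcelTable:
    """Parcel identities, group labels, hemispheres and optional coordinates.

    Parcel ids are implicit and 0-based: row ``p`` of every field describes
    parcel ``p``.  Files using 1-based numbering are accepted through the
    ``one_based`` flag of :meth:`read_csv` / :meth:`from_dataframe`.
    """

    labels: tuple[str, ...]
    groups: tuple[str, ...]
    hemispheres: tuple[str, ...] = field(default=())
    mni_xyz: np.ndarray | None = None  # (P, 3) millimetres, optional

    def __post_init__(self) -> None:
        P = len(self.labels)
        if P < 2:
            raise ValueError("a parcellation needs at least two parcels")
        if len(self.groups) != P:
            raise ValueError("labels and groups must have equal length")
        bad = sorted({g for g in self.groups} - set(GROUPS))
        if bad:
            raise ValueError(f"unknown parcel groups: {bad}; expected one of {GROUPS}")
        if not self.hemispheres:
            object.__setattr__(self, "hemispheres", ("unknown",) * P)
        elif len(self.hemispheres) != P:
            raise ValueError("hemispheres must align with labels")
        bad_h = sorted(set(self.hemispheres) - set(HEMISPHERES))
        if bad_h:
            raise ValueError(f"unknown hemispheres: {bad_h}")
        if self.mni_xyz is not None:
            xyz = np.asarray(self.mni_xyz, dtype=float)
            if xyz.shape != (P, 3):
                raise ValueError("mni_xyz must be (P, 3)")
            object.__setattr__(self, "mni_xyz", xyz)

    @property
    def n_parcels(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_parcels)

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return np.asarray([g == group for g in self.groups], dtype=bool)

    def group_counts(self) -> dict[str, int]:
        return {g: int(self.group_mask(g).sum()) for g in GROUPS}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, one_based: bool = False) -> "ParcelTable":
        """Build from a table with columns id, label, group [, hemisphere, mni_x/y/z]."""
        required = {"id", "label", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        df = df.sort_values("id").reset_index(drop=True)
        ids = df["id"].to_numpy(dtype=int)
        if one_based:
            ids = ids - 1
        P = len(ids)
        if not np.array_equal(ids, np.arange(P)):
            raise ValueError(
                "parcel ids must be contiguous starting at "
                + ("1" if one_based else "0")
            )
        hemis = (
            tuple(str(h) for h in df["hemisphere"])
            if "hemisphere" in df.columns
            else ()
        )
        xyz = None
        if {"mni_x", "mni_y", "mni_z"} <= set(df.columns) and not df["mni_x"].isna().all():
            xyz = df[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
        return cls(
            labels=tuple(str(x) for x in df["label"]),
            groups=tuple(str(g) for g in df["group"]),
            hemispheres=hemis,
            mni_xyz=xyz,
        )

    @classmethod
    def read_csv(cls, path: str | Path, one_based: bool = False) -> "ParcelTable":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        return cls.from_dataframe(pd.read_csv(path, sep=sep), one_based=one_based)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": np.arange(self.n_parcels),
                "label": list(self.labels),
                "group": list(self.groups),
                "hemisphere": list(self.hemispheres),
            }
        )
        if self.mni_xyz is not None:
            df[["mni_x", "mni_y", "mni_z"]] = self.mni_xyz
        return df

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.to_dataframe().to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class EdgeMask:
    """Boolean mask over the canonical edge universe of a parcellation."""

    bits: np.ndarray
    n_parcels: int

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        if bits.ndim != 1 or bits.size != n_edges(self.n_parcels):
            raise ValueError(
                f"mask length {bits.size} != P(P-1)/2 = {n_edges(self.n_parcels)}"
            )
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return self.bits.size

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def edge_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_pairs(self) -> np.ndarray:
        """(n_true, 2) endpoint ids of the masked edges, canonical order."""
        rows, cols = edge_pairs(self.n_parcels)
        return np.column_stack([rows[self.bits], cols[self.bits]])


def build_coi_mask(parcels: ParcelTable, include_intracerebellar: bool = True) -> EdgeMask:
    """Mask of connections of interest: edges with >= 1 cerebellar endpoint.

    With ``include_intracerebellar`` (default, matching the restriction to
    cerebellocerebral *and* cerebellocerebellar connections) edges between
    two cerebellar parcels are kept; otherwise only mixed edges survive.
    """
    cb = parcels.group_mask("cerebellar")
    n_cb = int(cb.sum())
    if n_cb == 0:
        raise ValueError("COI construction requires at least one cerebellar parcel")
    if n_cb == parcels.n_parcels:
        raise ValueError("COI construction requires at least one non-cerebellar parcel")
    rows, cols = edge_pairs(parcels.n_parcels)
    cb_i, cb_j = cb[rows], cb[cols]
    bits = cb_i | cb_j
    if not include_intracerebellar:
        bits &= ~(cb_i & cb_j)
    return EdgeMask(bits=bits, n_parcels=parcels.n_parcels)


def build_full_mask(parcels: ParcelTable) -> EdgeMask:
    """All-true mask: the whole-brain (unrestricted) analysis mode."""
    return EdgeMask(
        bits=np.ones(parcels.n_edges, dtype=bool), n_parcels=parcels.n_parcels
    )
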