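"""Consensus predictive networks, weighted degrees, node ranking, overlaps.

Per-fold edge selections are aggregated into a single positive and a single
negative predictive network (an edge enters the consensus when it was
selected in at least a configurable fraction of folds).  Nodes are then
characterised by their weighted degree — the sum of the weights of all
edges a node is connected by — ranked, and compared across analyses by
mask multiplication (overlap networks) with a hypergeometric or
permutation significance model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cpm import EdgeSelection
from .parcellation import ParcelTable, edge_pairs

__all__ = [
    "PredictiveNetwork",
    "consensus_network",
    "consensus_from_saved",
    "expand_network",
    "network_from_mask",
    "weighted_degree",
    "top_nodes",
    "degree_threshold_nodes",
    "overlap_network",
    "overlap_significance",
    "rank_nodes_over_overlaps",
]

WEIGHT_MODES = ("abs_r", "freq", "unit")


@dataclass(frozen=True)
class PredictiveNetwork:
    """Cross-fold consensus of one sign's edge selections.

    ``edge_freq`` is the fraction of folds selecting each edge,
    ``edge_weight`` the mean nuisance-adjusted r over the folds that
    selected it (0 where never selected), and ``mask`` the consensus at the
    frequency threshold used to build the network.
    """

    sign: str
    edge_freq: np.ndarray
    edge_weight: np.ndarray
    mask: np.ndarray
    freq_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ValueError("sign must be 'positive' or 'negative'")
        f = np.asarray(self.edge_freq, dtype=float)
        w = np.asarray(self.edge_weight, dtype=float)
        mk = np.asarray(self.mask, dtype=bool)
        if not (f.shape == w.shape == mk.shape):
            raise ValueError("edge_freq, edge_weight and mask must align")
        if mk.any():
            if self.sign == "positive" and not np.all(w[mk] > 0):
                raise ValueError("positive network has non-positive masked weights")
            if self.sign == "negative" and not np.all(w[mk] < 0):
                raise ValueError("negative network has non-negative masked weights")
        object.__setattr__(self, "edge_freq", f)
        object.__setattr__(self, "edge_weight", w)
        object.__setattr__(self, "mask", mk)

    @property
    def n_edges_universe(self) -> int:
        return self.mask.size

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def consensus_network(
    per_fold_selections: list[EdgeSelection],
    sign: str,
    freq_threshold: float = 1.0,
) -> PredictiveNetwork:
    """Aggregate per-fold selections of one sign into a consensus network.

    The default threshold 1.0 (edge selected in every fold) is the
    strictest convention; an empty consensus is valid and warned about.
    """
    if not per_fold_selections:
        raise ValueError("need at least one fold selection")
    if not 0.0 < freq_threshold <= 1.0:
        raise ValueError("freq_threshold must lie in (0, 1]")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    masks = np.vstack(
        [s.pos_mask if sign == "positive" else s.neg_mask for s in per_fold_selections]
    )
    rs = np.vstack([s.r for s in per_fold_selections])
    n_sel = masks.sum(axis=0)
    freq = n_sel / masks.shape[0]
    with np.errstate(invalid="ignore"):
        weight = np.where(n_sel > 0, (rs * masks).sum(axis=0) / np.maximum(n_sel, 1), 0.0)
    mask = freq >= freq_threshold - 1e-12
    if not mask.any():
        warnings.warn(
            f"empty {sign} consensus network at threshold {freq_threshold}", stacklevel=2
        )
    return PredictiveNetwork(
        sign=sign,
        edge_freq=freq,
        edge_weight=weight,
        mask=mask,
        freq_threshold=float(freq_threshold),
    )


def network_from_mask(
    mask: np.ndarray, sign: str = "positive", weights: np.ndarray | None = None
) -> PredictiveNetwork:
    """Wrap a bare edge mask (e.g. an overlap mask) as a network.

    Weights default to unit magnitude with the network's sign so degree
    computations on overlap masks count edges.
    """
    mk = np.asarray(mask, dtype=bool)
    if weights is None:
        weights = np.where(mk, 1.0 if sign == "positive" else -1.0, 0.0)
    return PredictiveNetwork(
        sign=sign,
        edge_freq=mk.astype(float),
        edge_weight=np.asarray(weights, dtype=float),
        mask=mk,
        freq_threshold=1.0,
    )


def expand_network(
    net: PredictiveNetwork, coi_indices: np.ndarray, n_edges_total: int
) -> PredictiveNetwork:
    """Lift a COI-vector network onto the full edge universe of a parcellation.

    Positions outside the COI carry zero frequency and weight and stay
    unmasked, so degrees and overlaps computed on the full universe agree
    with the COI-restricted analysis.
    """
    idx = np.asarray(coi_indices, dtype=int)
    if idx.size != net.n_edges_universe:
        raise ValueError("coi_indices length must equal the network's edge count")
    freq = np.zeros(n_edges_total)
    weight = np.zeros(n_edges_total)
    mask = np.zeros(n_edges_total, dtype=bool)
    freq[idx] = net.edge_freq
    weight[idx] = net.edge_weight
    mask[idx] = net.mask
    return PredictiveNetwork(
        sign=net.sign,
        edge_freq=freq,
        edge_weight=weight,
        mask=mask,
        freq_threshold=net.freq_threshold,
    )


def consensus_from_saved(
    folds: list[dict], n_edges: int, sign: str, freq_threshold: float = 1.0
) -> PredictiveNetwork:
    """Rebuild a consensus network from serialized per-fold selections.

    Each fold dict carries ``pos_edges``/``neg_edges`` index lists and the
    matching ``pos_r``/``neg_r`` correlation values (the result.json layout).
    """
    selections = []
    for rec in folds:
        r = np.zeros(n_edges)
        p = np.ones(n_edges)
        pos = np.zeros(n_edges, dtype=bool)
        neg = np.zeros(n_edges, dtype=bool)
        for key_e, key_r, mask in (("pos_edges", "pos_r", pos), ("neg_edges", "neg_r", neg)):
            idx = np.asarray(rec.get(key_e, []), dtype=int)
            mask[idx] = True
            r[idx] = np.asarray(rec.get(key_r, np.zeros(idx.size)), dtype=float)
            p[idx] = 0.0
        selections.append(EdgeSelection(r=r, p=p, pos_mask=pos, neg_mask=neg))
    return consensus_network(selections, sign=sign, freq_threshold=freq_threshold)


def weighted_degree(
    net: PredictiveNetwork,
    parcels: ParcelTable,
    weight_mode: str = "abs_r",
) -> pd.DataFrame:
    """Per-node weighted degree over the network's masked edges.

    ``abs_r`` (default) sums |mean r| so positive and negative networks are
    directly comparable; ``freq`` sums selection frequencies; ``unit``
    counts edges.  Returns a node table (parcel, label, group, hemisphere,
    degree, rank) where rank 1 is the highest degree; ties break by parcel
    id ascending.
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    P = parcels.n_parcels
    if net.n_edges_universe != parcels.n_edges:
        raise ValueError("network edge universe does not match the parcellation")
    if weight_mode == "abs_r":
        w = np.abs(net.edge_weight)
    elif weight_mode == "freq":
        w = net.edge_freq
    else:
        w = np.ones_like(net.edge_weight)
    w = np.where(net.mask, w, 0.0)
    rows, cols = edge_pairs(P)
    degree = np.zeros(P)
    np.add.at(degree, rows, w)
    np.add.at(degree, cols, w)
    order = np.lexsort((np.arange(P), -degree))
    rank = np.empty(P, dtype=int)
    rank[order] = np.arange(1, P + 1)
    return pd.DataFrame(
        {
            "parcel": np.arange(P),
            "label": list(parcels.labels),
            "group": list(parcels.groups),
            "hemisphere": list(parcels.hemispheres),
            "degree": degree,
            "rank": rank,
        }
    )


def top_nodes(
    degrees: pd.DataFrame, group_filter: str | None, fraction: float
) -> pd.DataFrame:
    """Highest-degree nodes of a group, truncated to ceil(fraction * size).

    E.g. fraction 0.05 selects the most relevant 5% of the group's nodes by
    weighted degree.  Ties break by parcel id ascending.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    sub = degrees if group_filter is None else degrees[degrees["group"] == group_filter]
    if sub.empty:
        raise ValueError(f"no nodes in group {group_filter!r}")
    n = int(np.ceil(fraction * len(sub)))
    sub = sub.sort_values(["degree", "parcel"], ascending=[False, True])
    return sub.head(n).reset_index(drop=True)


def degree_threshold_nodes(
    degrees: pd.DataFrame, group_filter: str | None, threshold: float
) -> pd.DataFrame:
    """Nodes of a group with degree >= threshold, sorted descending.

    Supports the practice of picking a cut-off by inspecting the degree
    distribution (e.g. for cerebellar nodes).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    sub = degrees if group_filter is None else degrees[degrees["group"] == group_filter]
    sub = sub[sub["degree"] >= threshold]
    return sub.sort_values(["degree", "parcel"], ascending=[False, True]).reset_index(
        drop=True
    )


def overlap_network(
    a: PredictiveNetwork | np.ndarray, b: PredictiveNetwork | np.ndarray
) -> tuple[np.ndarray, int]:
    """Mask multiplication of two networks: element-wise AND and its count."""
    ma = a.mask if isinstance(a, PredictiveNetwork) else np.asarray(a, dtype=bool)
    mb = b.mask if isinstance(b, PredictiveNetwork) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("networks live on different edge universes")
    inter = ma & mb
    return inter, int(inter.sum())


def overlap_significance(
    a_mask: np.ndarray,
    b_mask: np.ndarray,
    universe_size: int | None = None,
    method: str = "hypergeometric",
    m: int = 10_000,
    seed: int = 0,
) -> float:
    """Tail probability of the observed mask overlap.

    Default model: hypergeometric P(X >= overlap) for |a| draws from a
    universe containing |b| marked edges.  ``method='permutation'``
    shuffles one mask's edge positions ``m`` times instead.  The choice of
    model is the caller's to report; outputs produced by the CLI label it.
    """
    ma = np.asarray(a_mask, dtype=bool)
    mb = np.asarray(b_mask, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError("masks live on different edge universes")
    M = ma.size if universe_size is None else int(universe_size)
    ka, kb = int(ma.sum()), int(mb.sum())
    if ka == 0 or kb == 0:
        raise ValueError("overlap significance undefined for an empty mask")
    obs = int((ma & mb).sum())
    if method == "hypergeometric":
        return float(stats.hypergeom.sf(obs - 1, M, ka, kb))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        idx_b = np.flatnonzero(mb)
        count = 0
        a_idx = np.flatnonzero(ma)
        for _ in range(m):
            perm = rng.permutation(M)[: idx_b.size]
            count += int(np.intersect1d(a_idx, perm, assume_unique=True).size >= obs)
        return count / m
    raise ValueError("method must be 'hypergeometric' or 'permutation'")


def rank_nodes_over_overlaps(degree_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Rank nodes by their weighted degrees averaged over overlap networks.

    Each input is a node table as produced by :func:`weighted_degree`,
    computed on one overlap network; the output averages the degree column
    per node and re-ranks.
    """
    if not degree_tables:
        raise ValueError("need at least one degree table")
    base = degree_tables[0]
    deg = np.zeros(len(base))
    for t in degree_tables:
        if len(t) != len(base) or not np.array_equal(
            t["parcel"].to_numpy(), base["parcel"].to_numpy()
        ):
            raise ValueError("degree tables must cover the same parcels in order")
        deg += t["degree"].to_numpy(dtype=float)
    deg /= len(degree_tables)
    out = base[["parcel", "label", "group", "hemisphere"]].copy()
    out["degree"] = deg
    order = np.lexsort((out["parcel"].to_numpy(), -deg))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out.sort_values("rank").reset_index(drop=True)
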