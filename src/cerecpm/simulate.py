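"""Synthetic connectome generator with planted predictive edges.

Emulates, at desk scale, a cohort in which a continuous trait (think BMI)
linearly shifts the covariance of a handful of connections of interest:
subject covariances are ``Sigma_i = Sigma_0 + effect_size * y_i * (sum of
+1 indicators over planted positive edges - sum over negative edges)``
plus a family-shared COI perturbation, floored to SPD.  BOLD-like time
series are drawn from a zero-mean multivariate normal with ``Sigma_i``;
the observed target adds confound contamination and measurement noise to
the standardized latent trait; families cluster both the trait (via the
intra-class correlation) and the connectome (via the shared perturbation),
which is what makes relative-exclusion leakage demonstrable.

What this does *not* emulate: hemodynamics, temporal autocorrelation,
motion or scanner artifacts — see the methods note for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpm import SubjectDataset, encode_confounds
from .parcellation import ParcelTable, build_coi_mask, edge_pairs
from .connectivity import ParcellatedTimeSeries

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_parcel_table",
    "generate_dataset",
    "recovery_report",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic cohort.

    Defaults define the desk-scale reference condition: 300 subjects in 60
    families of 5, a 44-parcel brain (10 cerebellar, 30 cortical, 4
    subcortical), 200 timepoints, 15 positive and 15 negative planted COI
    edges at a strong covariance effect.
    """

    n_subjects: int = 300
    parcel_counts: tuple[int, int, int] = (10, 30, 4)  # cerebellar, cortical, subcortical
    T: int = 200
    n_pos_edges: int = 15
    n_neg_edges: int = 15
    effect_size: float = 0.12  # covariance shift per unit standardized trait
    noise_sd: float = 0.5  # measurement noise on the observed target
    confound_strength: float = 0.3  # trait-confound correlation / contamination
    n_families: int = 60
    family_trait_icc: float = 0.3  # between-family share of trait variance
    family_edge_sd: float = 0.06  # sd of the family-shared COI covariance perturbation
    base_corr: float = 0.1  # background compound-symmetry correlation
    base_var: float = 2.0  # baseline signal variance (headroom for SPD shifts)
    include_intracerebellar: bool = True
    edge_source: str = "empirical_cov"  # empirical_cov | correlation | true_cov
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects")
        if min(self.parcel_counts) < 0 or self.parcel_counts[0] < 1:
            raise ValueError("need at least one cerebellar parcel")
        if sum(self.parcel_counts) - self.parcel_counts[0] < 1:
            raise ValueError("need at least one non-cerebellar parcel")
        if self.T < 2:
            raise ValueError("need at least 2 timepoints")
        if not 0.0 <= self.family_trait_icc < 1.0:
            raise ValueError("family_trait_icc must lie in [0, 1)")
        if self.n_families < 1 or self.n_families > self.n_subjects:
            raise ValueError("n_families must lie in 1..n_subjects")
        if self.edge_source not in ("empirical_cov", "correlation", "true_cov"):
            raise ValueError("unknown edge_source")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: edge sets (COI-vector indices), trait, families."""

    pos_edges: tuple[int, ...]
    neg_edges: tuple[int, ...]
    trait: np.ndarray
    family: tuple
    coi_edge_count: int = 0

    def __post_init__(self) -> None:
        if set(self.pos_edges) & set(self.neg_edges):
            raise ValueError("positive and negative planted edges must be disjoint")

    @property
    def pos_mask(self) -> np.ndarray:
        m = np.zeros(self.coi_edge_count, dtype=bool)
        m[list(self.pos_edges)] = True
        return m

    @property
    def neg_mask(self) -> np.ndarray:
        m = np.zeros(self.coi_edge_count, dtype=bool)
        m[list(self.neg_edges)] = True
        return m


def make_parcel_table(parcel_counts: tuple[int, int, int]) -> ParcelTable:
    """Synthetic grouped parcellation: cerebellar, then cortical, then subcortical."""
    n_cb, n_ctx, n_sc = parcel_counts
    labels, groups, hemis = [], [], []
    for prefix, group, n in (
        ("CB", "cerebellar", n_cb),
        ("CTX", "cortical", n_ctx),
        ("SC", "subcortical", n_sc),
    ):
        for i in range(n):
            side = "L" if i % 2 == 0 else "R"
            labels.append(f"{prefix}_{side}_{i // 2:02d}")
            groups.append(group)
            hemis.append("left" if side == "L" else "right")
    return ParcelTable(labels=tuple(labels), groups=tuple(groups), hemispheres=tuple(hemis))


def _floor_spd(sigma: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Eigenvalue-floor a symmetric matrix to SPD; reject gross violations."""
    w, V = np.linalg.eigh(sigma)
    lam_max = w[-1]
    if w[0] < -0.1 * lam_max:
        raise ValueError(
            "SPD projection would alter eigenvalues by more than 10% of the "
            "largest; lower effect_size or family_edge_sd"
        )
    if w[0] < floor:
        w = np.maximum(w, floor)
        sigma = (V * w) @ V.T
        sigma = 0.5 * (sigma + sigma.T)
    return sigma


def generate_dataset(
    spec: SyntheticSpec, return_timeseries: bool = False
) -> tuple[SubjectDataset, GroundTruth, list[ParcellatedTimeSeries] | None]:
    """Draw a fully reproducible synthetic cohort from the spec.

    Returns the CPM-ready dataset (COI edge vectors, target, encoded
    confounds, family labels), the planted ground truth, and — on request —
    the raw per-subject time series for exercising the connectivity stage.
    """
    rng = np.random.default_rng(spec.seed)
    parcels = make_parcel_table(spec.parcel_counts)
    P = parcels.n_parcels
    coi = build_coi_mask(parcels, include_intracerebellar=spec.include_intracerebellar)
    coi_idx = coi.edge_indices()
    E = coi.count
    n_planted = spec.n_pos_edges + spec.n_neg_edges
    if n_planted > E:
        raise ValueError(f"cannot plant {n_planted} edges in a COI universe of {E}")

    # planted edges live strictly inside the COI universe
    chosen = rng.choice(E, size=n_planted, replace=False)
    pos_local = np.sort(chosen[: spec.n_pos_edges])
    neg_local = np.sort(chosen[spec.n_pos_edges :])
    rows, cols = edge_pairs(P)
    signal = np.zeros((P, P))
    for local, s in ((pos_local, 1.0), (neg_local, -1.0)):
        gi = coi_idx[local]
        signal[rows[gi], cols[gi]] = s
        signal[cols[gi], rows[gi]] = s

    # family-clustered latent trait (unit variance)
    N = spec.n_subjects
    family = np.arange(N) % spec.n_families
    fam_effect = rng.standard_normal(spec.n_families)
    icc = spec.family_trait_icc
    y = np.sqrt(icc) * fam_effect[family] + np.sqrt(1.0 - icc) * rng.standard_normal(N)
    zy = (y - y.mean()) / y.std()

    # family-shared COI covariance perturbation (the leakage channel)
    fam_pert = np.zeros((spec.n_families, P, P))
    for f in range(spec.n_families):
        vals = rng.normal(0.0, spec.family_edge_sd, size=E)
        W = np.zeros((P, P))
        W[rows[coi_idx], cols[coi_idx]] = vals
        fam_pert[f] = W + W.T

    sigma0 = spec.base_var * (
        (1.0 - spec.base_corr) * np.eye(P) + spec.base_corr * np.ones((P, P))
    )

    edges = np.empty((N, E))
    ts_list: list[ParcellatedTimeSeries] | None = [] if return_timeseries else None
    need_ts = spec.edge_source != "true_cov" or return_timeseries
    for i in range(N):
        sigma = sigma0 + spec.effect_size * zy[i] * signal + fam_pert[family[i]]
        sigma = _floor_spd(sigma)
        if need_ts:
            L = np.linalg.cholesky(sigma)
            X = rng.standard_normal((spec.T, P)) @ L.T
            if return_timeseries:
                ts_list.append(ParcellatedTimeSeries(subject_id=f"sub-{i:04d}", values=X))
        if spec.edge_source == "true_cov":
            edges[i] = sigma[rows[coi_idx], cols[coi_idx]]
        elif spec.edge_source == "empirical_cov":
            Xc = X - X.mean(axis=0)
            S = Xc.T @ Xc / spec.T
            edges[i] = S[rows[coi_idx], cols[coi_idx]]
        else:  # correlation
            C = np.corrcoef(X, rowvar=False)
            edges[i] = C[rows[coi_idx], cols[coi_idx]]

    # confounds: shared latent c correlated with the trait at confound_strength
    rho = spec.confound_strength
    c = rho * zy + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(N)
    lam = 0.7

    def _noisy(latent: np.ndarray) -> np.ndarray:
        return lam * latent + np.sqrt(1 - lam**2) * rng.standard_normal(N)

    gender = np.where(_noisy(c) > 0, "F", "M")
    age = 29.0 + 3.5 * _noisy(c)
    eth_latent = _noisy(c)
    eth = np.asarray(["A", "B", "C"])[
        np.searchsorted(np.quantile(eth_latent, [1 / 3, 2 / 3]), eth_latent)
    ]
    pheno = pd.DataFrame({"gender": gender, "age": age, "ethnicity": eth})
    X_conf, conf_names = encode_confounds(
        pheno, numeric=("age",), binary=("gender",), categorical=("ethnicity",)
    )

    # observed target: trait + confound contamination + noise, in BMI-like units
    sd = X_conf.std(axis=0)
    Xs = (X_conf - X_conf.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    score = Xs.mean(axis=1)
    score = (score - score.mean()) / score.std()
    raw = zy + rho * score + spec.noise_sd * rng.standard_normal(N)
    target = 26.5 + 4.0 * (raw - raw.mean()) / raw.std()

    data = SubjectDataset(
        subject_ids=tuple(f"sub-{i:04d}" for i in range(N)),
        edges=edges,
        target=target,
        confounds=X_conf,
        family_id=tuple(f"fam-{f:03d}" for f in family),
        confound_names=conf_names,
    )
    truth = GroundTruth(
        pos_edges=tuple(int(e) for e in pos_local),
        neg_edges=tuple(int(e) for e in neg_local),
        trait=zy,
        family=tuple(int(f) for f in family),
        coi_edge_count=E,
    )
    return data, truth, ts_list


def recovery_report(
    pos_selected: np.ndarray, neg_selected: np.ndarray, truth: GroundTruth
) -> dict[str, dict[str, float]]:
    """Precision, recall and Jaccard of selected vs planted edges, per sign."""
    if not truth.pos_edges and not truth.neg_edges:
        raise ValueError("ground truth has no planted edges")
    out: dict[str, dict[str, float]] = {}
    for sign, sel_mask, true_set in (
        ("positive", pos_selected, set(truth.pos_edges)),
        ("negative", neg_selected, set(truth.neg_edges)),
    ):
        sel = set(np.flatnonzero(np.asarray(sel_mask, dtype=bool)).tolist())
        tp = len(sel & true_set)
        union = len(sel | true_set)
        out[sign] = {
            "precision": tp / len(sel) if sel else 0.0,
            "recall": tp / len(true_set) if true_set else 0.0,
            "jaccard": tp / union if union else 1.0,
            "n_selected": float(len(sel)),
            "n_true": float(len(true_set)),
        }
    return out
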