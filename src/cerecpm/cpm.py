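"""Connectome-based predictive modeling (CPM) engine.

The protocol, per fold of a k-fold split: (i) hold out a test population;
(ii) in the remaining training population — after removing every training
subject related to a test subject — correlate each edge with the target
while regressing out nuisance variables, and keep edges passing the
selection threshold, split by correlation sign into a positive and a
negative network; (iii) summarise each subject by the summed strength of
the selected edges per network and fit a combined linear model of the
target on the two strengths; (iv) predict the held-out subjects.  After all
folds, every subject has exactly one out-of-fold prediction and the
evaluation statistic is the Pearson correlation of predicted with observed
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectDataset",
    "FoldPlan",
    "EdgeSelection",
    "CPMModel",
    "FoldRecord",
    "CPMResult",
    "encode_confounds",
    "make_folds",
    "exclude_relatives",
    "residualize",
    "edgewise_association",
    "network_strength",
    "fit_combined_glm",
    "predict_from_model",
    "run_cpm",
    "evaluate",
]


@dataclass(frozen=True)
class SubjectDataset:
    """Per-subject COI edge vectors with target, confounds and family labels.

    ``edges`` holds one row per subject, aligned with ``subject_ids``,
    ``target`` (the continuous measure being predicted, e.g. BMI in kg/m2),
    the encoded confound design ``confounds`` (N x q, may have q = 0) and
    ``family_id`` (subjects sharing a label are treated as relatives).
    """

    subject_ids: tuple[str, ...]
    edges: np.ndarray
    target: np.ndarray
    confounds: np.ndarray
    family_id: tuple
    confound_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        E = np.asarray(self.edges, dtype=float)
        y = np.asarray(self.target, dtype=float)
        X = np.asarray(self.confounds, dtype=float)
        if X.ndim == 1:
            X = X.reshape(len(y), -1)
        N = len(self.subject_ids)
        if N < 3:
            raise ValueError("need at least 3 subjects")
        if E.ndim != 2 or E.shape[0] != N or E.shape[1] < 1:
            raise ValueError("edges must be (N, E) with E >= 1, aligned to subjects")
        if y.shape != (N,):
            raise ValueError("target must be length N")
        if X.shape[0] != N:
            raise ValueError("confounds must have N rows")
        if len(self.family_id) != N:
            raise ValueError("family_id must be length N")
        for name, arr in (("edges", E), ("target", y), ("confounds", X)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
        object.__setattr__(self, "edges", E)
        object.__setattr__(self, "target", y)
        object.__setattr__(self, "confounds", X)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "family_id", tuple(self.family_id))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def with_target(self, target: np.ndarray) -> "SubjectDataset":
        """Copy with a replaced target (used by permutation inference)."""
        return replace(self, target=np.asarray(target, dtype=float))


def encode_confounds(
    df: pd.DataFrame,
    numeric: tuple[str, ...] = (),
    binary: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode a phenotype table into a minimal full-rank confound design.

    Numeric columns pass through as floats; binary columns become a single
    0/1 indicator; categorical columns are one-hot encoded with the first
    (sorted) level dropped.  The intercept is *not* included here — model
    code always augments designs with one.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in numeric:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    for c in binary:
        levels = sorted(pd.unique(df[c]).tolist())
        if len(levels) > 2:
            raise ValueError(f"binary confound {c!r} has {len(levels)} levels")
        cols.append((df[c] == levels[-1]).to_numpy(dtype=float))
        names.append(f"{c}[{levels[-1]}]")
    for c in categorical:
        levels = sorted(pd.unique(df[c]).tolist())
        for lev in levels[1:]:
            cols.append((df[c] == lev).to_numpy(dtype=float))
            names.append(f"{c}[{lev}]")
    if not cols:
        return np.empty((len(df), 0)), ()
    return np.column_stack(cols), tuple(names)


@dataclass(frozen=True)
class FoldPlan:
    """Balanced random assignment of N subjects to k test folds."""

    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        sizes = np.bincount(a, minlength=self.k)
        if a.min() < 0 or a.max() >= self.k:
            raise ValueError("fold labels out of range")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")
        object.__setattr__(self, "assignment", a)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(n_subjects: int, k: int, seed: int) -> FoldPlan:
    """Uniformly random balanced k-fold partition, reproducible by seed.

    ``k == n_subjects`` is the leave-one-out limit.
    """
    N, k = int(n_subjects), int(k)
    if not 2 <= k <= N:
        raise ValueError(f"k must satisfy 2 <= k <= N (got k={k}, N={N})")
    rng = np.random.default_rng(seed)
    labels = np.arange(N) % k  # sizes differ by at most 1
    assignment = labels[rng.permutation(N)]
    return FoldPlan(k=k, assignment=assignment, seed=int(seed))


def exclude_relatives(
    train_idx: np.ndarray, test_idx: np.ndarray, family_id
) -> np.ndarray:
    """Drop training subjects sharing a family with any test subject.

    Relatives never predict each other: removal is train-side only, so the
    test fold stays intact and out-of-fold coverage is preserved.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices must be disjoint")
    fams = np.asarray(family_id, dtype=object)
    test_fams = set(fams[test_idx].tolist())
    keep = np.asarray([fams[i] not in test_fams for i in train_idx], dtype=bool)
    filtered = train_idx[keep]
    if filtered.size == 0:
        raise ValueError(
            "family exclusion removed the entire training set; "
            "use larger folds (smaller k) or fewer related subjects per fold"
        )
    return filtered


def _augment(X: np.ndarray, n: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.ones((n, 1))
    if X.ndim == 1:
        X = X.reshape(n, -1)
    return np.column_stack([np.ones(n), X])


def residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of y after OLS on [1 | X]; orthogonal to every column.

    An empty X reduces to mean-centering.  Rank deficiency raises, naming
    the (near-)collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X_aug = _augment(X, len(y))
    Q, R = np.linalg.qr(X_aug)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X_aug.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        raise ValueError(
            f"confound design is rank deficient; collinear column position(s) "
            f"{(bad - 1).tolist()} (0-based, -1 = intercept)"
        )
    return y - Q @ (Q.T @ y)


@dataclass(frozen=True)
class EdgeSelection:
    """Edge-wise nuisance-adjusted correlations and the sign-split masks."""

    r: np.ndarray
    p: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if np.any(self.pos_mask & self.neg_mask):
            raise ValueError("positive and negative masks must be disjoint")


def edgewise_association(
    edges: np.ndarray,
    target: np.ndarray,
    confounds: np.ndarray,
    alpha: float = 0.05,
    residualize_edges: bool = True,
) -> EdgeSelection:
    """Correlate every edge with the target after nuisance regression.

    Both the target and (by default) the edges are residualised on the
    confound design before the Pearson correlation — i.e. a partial
    correlation given the confounds.  Two-sided p-values come from
    ``t = r sqrt(df / (1 - r^2))`` with ``df = N - 2 - q`` degrees of
    freedom, q being the number of confound columns.  Edges passing
    ``p <= alpha`` enter the positive or negative mask according to the
    sign of r.  Constant edge columns get (r=0, p=1) with a warning.
    """
    E = np.asarray(edges, dtype=float)
    y = np.asarray(target, dtype=float)
    X = np.asarray(confounds, dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(y), -1)
    N, n_edges = E.shape
    q = X.shape[1]
    if N <= q + 3:
        raise ValueError(f"need more than q + 3 = {q + 3} training subjects, got {N}")
    X_aug = _augment(X, N)
    Q, _ = np.linalg.qr(X_aug)
    ry = y - Q @ (Q.T @ y)
    if residualize_edges:
        rE = E - Q @ (Q.T @ E)
    else:
        rE = E - E.mean(axis=0)
    sy = np.linalg.norm(ry)
    if sy == 0:
        raise ValueError("target is constant (or fully explained by confounds)")
    se = np.linalg.norm(rE, axis=0)
    scale = np.abs(E).max() if E.size else 1.0
    dead = se <= 1e-12 * max(scale, 1.0) * np.sqrt(N)
    se_safe = np.where(dead, 1.0, se)
    r = (rE.T @ ry) / (se_safe * sy)
    r = np.clip(r, -1.0, 1.0)
    df = N - 2 - q
    t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} constant edge column(s): r set to 0, p to 1",
            stacklevel=2,
        )
        r[dead] = 0.0
        p[dead] = 1.0
    pos = (r > 0) & (p <= alpha)
    neg = (r < 0) & (p <= alpha)
    return EdgeSelection(r=r, p=p, pos_mask=pos, neg_mask=neg, alpha=float(alpha))


def network_strength(edge_vector: np.ndarray, mask: np.ndarray) -> float:
    """Sum of edge values over a selected edge set (0 for an empty mask)."""
    v = np.asarray(edge_vector, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("edge vector and mask must have equal length")
    return float(v[m].sum())


@dataclass(frozen=True)
class CPMModel:
    """Combined linear model of the target on the two network strengths."""

    beta0: float
    beta_pos: float
    beta_neg: float
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    fallback: bool = False  # both masks empty -> predict the training mean

    def __post_init__(self) -> None:
        for b in (self.beta0, self.beta_pos, self.beta_neg):
            if not np.isfinite(b):
                raise ValueError("model coefficients must be finite")


def fit_combined_glm(
    s_pos: np.ndarray,
    s_neg: np.ndarray,
    target: np.ndarray,
    pos_mask: np.ndarray | None = None,
    neg_mask: np.ndarray | None = None,
) -> CPMModel:
    """OLS of the target on [1, S_pos, S_neg].

    A regressor whose mask selected no edges (constant zero strength) is
    dropped and its coefficient recorded as 0; with both masks empty the
    model is flagged as a fallback that predicts the training mean.
    """
    s_pos = np.asarray(s_pos, dtype=float)
    s_neg = np.asarray(s_neg, dtype=float)
    y = np.asarray(target, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 training subjects to fit the model")
    if pos_mask is None:
        pos_mask = np.zeros(0, dtype=bool)
    if neg_mask is None:
        neg_mask = np.zeros(0, dtype=bool)
    use_pos = s_pos.std() > 0
    use_neg = s_neg.std() > 0
    cols = [np.ones(len(y))]
    if use_pos:
        cols.append(s_pos)
    if use_neg:
        cols.append(s_neg)
    if len(cols) == 1:
        return CPMModel(
            beta0=float(y.mean()),
            beta_pos=0.0,
            beta_neg=0.0,
            pos_mask=np.asarray(pos_mask, dtype=bool),
            neg_mask=np.asarray(neg_mask, dtype=bool),
            fallback=True,
        )
    D = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    b_pos = beta[1] if use_pos else 0.0
    b_neg = beta[-1] if use_neg else 0.0
    return CPMModel(
        beta0=float(beta[0]),
        beta_pos=float(b_pos),
        beta_neg=float(b_neg),
        pos_mask=np.asarray(pos_mask, dtype=bool),
        neg_mask=np.asarray(neg_mask, dtype=bool),
    )


def predict_from_model(model: CPMModel, edges: np.ndarray) -> np.ndarray:
    """Apply a fitted fold model to (n, E) edge vectors."""
    E = np.atleast_2d(np.asarray(edges, dtype=float))
    s_pos = E[:, model.pos_mask].sum(axis=1) if model.pos_mask.size else np.zeros(E.shape[0])
    s_neg = E[:, model.neg_mask].sum(axis=1) if model.neg_mask.size else np.zeros(E.shape[0])
    return model.beta0 + model.beta_pos * s_pos + model.beta_neg * s_neg


@dataclass(frozen=True)
class FoldRecord:
    fold: int
    model: CPMModel
    selection: EdgeSelection
    test_ids: tuple[str, ...]
    excluded_train_ids: tuple[str, ...]
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CPMResult:
    """Out-of-fold predictions, per-fold models/selections and evaluation r."""

    subject_ids: tuple[str, ...]
    predictions: np.ndarray
    observed: np.ndarray
    fold_assignment: np.ndarray
    per_fold: tuple[FoldRecord, ...]
    r_eval: float
    params: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": list(self.subject_ids),
                "observed": self.observed,
                "predicted": self.predictions,
                "fold": self.fold_assignment,
            }
        )


def evaluate(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation of predicted with observed values."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 3:
        raise ValueError("predicted and observed must be equal-length vectors (n >= 3)")
    if pred.std() == 0 or obs.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(pred, obs)[0])


def run_cpm(
    data: SubjectDataset,
    k: int = 128,
    alpha: float = 0.05,
    seed: int = 0,
    exclude_family: bool = True,
    residualize_edges: bool = True,
    max_bad_fold_frac: float = 0.1,
) -> CPMResult:
    """Run the full k-fold CPM protocol and evaluate out-of-fold predictions.

    Every subject serves as a test subject exactly once.  A fold whose
    selection is empty falls back to predicting the training mean and is
    flagged; a fold raising an error is also flagged, and the run fails if
    more than ``max_bad_fold_frac`` of folds are unusable.
    """
    N = data.n_subjects
    if k > N:
        warnings.warn(f"k={k} exceeds N={N}; capping at N (leave-one-out)", stacklevel=2)
        k = N
    plan = make_folds(N, k, seed)
    preds = np.full(N, np.nan)
    records: list[FoldRecord] = []
    n_failed = 0
    sid = np.asarray(data.subject_ids, dtype=object)
    for f in range(k):
        test = plan.test_indices(f)
        train = plan.train_indices(f)
        flags: list[str] = []
        excluded: tuple[str, ...] = ()
        try:
            if exclude_family:
                kept = exclude_relatives(train, test, data.family_id)
                excluded = tuple(sid[np.setdiff1d(train, kept)])
                train = kept
            sel = edgewise_association(
                data.edges[train],
                data.target[train],
                data.confounds[train],
                alpha=alpha,
                residualize_edges=residualize_edges,
            )
            s_pos = data.edges[train][:, sel.pos_mask].sum(axis=1)
            s_neg = data.edges[train][:, sel.neg_mask].sum(axis=1)
            model = fit_combined_glm(s_pos, s_neg, data.target[train], sel.pos_mask, sel.neg_mask)
            if model.fallback:
                flags.append("empty-selection:train-mean-fallback")
            preds[test] = predict_from_model(model, data.edges[test])
        except ValueError as exc:
            n_failed += 1
            flags.append(f"fold-error: {exc}")
            preds[test] = data.target[train].mean() if train.size else data.target.mean()
            sel = EdgeSelection(
                r=np.zeros(data.n_edges),
                p=np.ones(data.n_edges),
                pos_mask=np.zeros(data.n_edges, dtype=bool),
                neg_mask=np.zeros(data.n_edges, dtype=bool),
                alpha=alpha,
            )
            model = CPMModel(
                beta0=float(preds[test][0]) if test.size else 0.0,
                beta_pos=0.0,
                beta_neg=0.0,
                pos_mask=sel.pos_mask,
                neg_mask=sel.neg_mask,
                fallback=True,
            )
        records.append(
            FoldRecord(
                fold=f,
                model=model,
                selection=sel,
                test_ids=tuple(sid[test]),
                excluded_train_ids=excluded,
                flags=tuple(flags),
            )
        )
    if n_failed > max_bad_fold_frac * k:
        raise RuntimeError(
            f"{n_failed}/{k} folds failed (limit {max_bad_fold_frac:.0%}); "
            "inspect fold flags"
        )
    assert np.isfinite(preds).all(), "out-of-fold coverage incomplete"
    r_eval = evaluate(preds, data.target)
    return CPMResult(
        subject_ids=data.subject_ids,
        predictions=preds,
        observed=data.target.copy(),
        fold_assignment=plan.assignment.copy(),
        per_fold=tuple(records),
        r_eval=r_eval,
        params={
            "k": int(k),
            "alpha": float(alpha),
            "seed": int(seed),
            "exclude_family": bool(exclude_family),
            "residualize_edges": bool(residualize_edges),
        },
    )
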