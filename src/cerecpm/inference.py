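"""Permutation-based significance for CPM predictions and simple correlations.

The pipeline — not just the final statistic — is permuted: each replicate
shuffles the target and re-runs the complete cross-validated CPM, including
family exclusion and nuisance regression, so the null distribution reflects
every selection step.  P is the plain proportion of null statistics greater
than or equal to the observed one (an optional (b+1)/(m+1) estimator is
available to avoid exact zeros).

Parallel contract: all permutation orders are pre-drawn from the master
seed before any work is dispatched, so results are bit-identical for any
worker count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .cpm import SubjectDataset, make_folds, run_cpm

__all__ = [
    "PermutationResult",
    "permutation_test_cpm",
    "permutation_corr_test",
    "bonferroni",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_r: float
    null_r: np.ndarray
    m: int
    p: float
    seed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if len(self.null_r) != self.m:
            raise ValueError("null distribution length must equal m")


def _proportion_p(count: int, m: int, add_one: bool) -> float:
    return (count + 1) / (m + 1) if add_one else count / m


def permutation_test_cpm(
    data: SubjectDataset,
    m: int,
    seed: int,
    workers: int = 1,
    scope: str = "sample",
    add_one: bool = False,
    **cpm_kwargs,
) -> PermutationResult:
    """Permutation test of the CPM evaluation statistic.

    For each of ``m`` replicates the target vector is shuffled (seeded) and
    the full CPM re-run with identical parameters; ``p`` is the proportion
    of null r values greater than or equal to the observed r.  ``scope``
    chooses between the whole-sample shuffle (default) and shuffling within
    each test fold only (``"within_test"``).  Replicates that fail hard are
    dropped with ``m`` adjusted and logged.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if scope not in ("sample", "within_test"):
        raise ValueError("scope must be 'sample' or 'within_test'")
    observed = run_cpm(data, **cpm_kwargs).r_eval
    rng = np.random.default_rng(seed)
    N = data.n_subjects
    if scope == "sample":
        perms = [rng.permutation(N) for _ in range(m)]
    else:
        # permute targets only within each test fold of the CPM's own plan
        plan = make_folds(N, min(cpm_kwargs.get("k", 128), N), cpm_kwargs.get("seed", 0))
        perms = []
        for _ in range(m):
            perm = np.arange(N)
            for f in range(plan.k):
                idx = plan.test_indices(f)
                perm[idx] = idx[rng.permutation(idx.size)]
            perms.append(perm)

    def one(perm: np.ndarray) -> float:
        try:
            return run_cpm(data.with_target(data.target[perm]), **cpm_kwargs).r_eval
        except (ValueError, RuntimeError) as exc:  # degenerate replicate
            warnings.warn(f"permutation replicate failed: {exc}", stacklevel=2)
            return np.nan

    if workers > 1:
        null = np.asarray(
            Parallel(n_jobs=workers)(delayed(one)(p) for p in perms), dtype=float
        )
    else:
        null = np.asarray([one(p) for p in perms], dtype=float)
    ok = np.isfinite(null)
    n_failed = int((~ok).sum())
    null = null[ok]
    m_eff = int(ok.sum())
    if m_eff == 0:
        raise RuntimeError("every permutation replicate failed")
    count = int((null >= observed).sum())
    return PermutationResult(
        observed_r=float(observed),
        null_r=null,
        m=m_eff,
        p=float(_proportion_p(count, m_eff, add_one)),
        seed=int(seed),
        n_failed=n_failed,
    )


def permutation_corr_test(
    x: np.ndarray, y: np.ndarray, m: int, seed: int, add_one: bool = False
) -> PermutationResult:
    """Two-sided permutation test of a Pearson correlation.

    The null is built by shuffling ``y``; ``p`` counts null replicates with
    ``|r_null| >= |r_obs|``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors (n >= 3)")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    if m < 1:
        raise ValueError("m must be >= 1")
    observed = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)
    null = np.empty(m)
    for i in range(m):
        ys = y[rng.permutation(len(y))]
        yc = ys - ys.mean()
        null[i] = float(xn @ (yc / np.linalg.norm(yc)))
    count = int((np.abs(null) >= abs(observed)).sum())
    return PermutationResult(
        observed_r=observed,
        null_r=null,
        m=m,
        p=float(_proportion_p(count, m, add_one)),
        seed=int(seed),
    )


def bonferroni(p_values: np.ndarray, n_tests: int) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * n_tests)`` element-wise."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests < p.size:
        raise ValueError("n_tests must be at least the number of p-values")
    return np.minimum(1.0, p * n_tests)
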