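"""Fold construction, family exclusion, edge selection, model fit, full runs."""

import numpy as np
import pytest
from scipy import stats

import cerecpm as cc
from cerecpm.cpm import predict_from_model


# ---------------------------------------------------------------- folds

def test_folds_are_balanced_disjoint_and_cover():
    plan = cc.make_folds(8, 4, seed=0)
    sizes = [plan.test_indices(f).size for f in range(4)]
    assert sizes == [2, 2, 2, 2]
    all_test = np.concatenate([plan.test_indices(f) for f in range(4)])
    assert sorted(all_test.tolist()) == list(range(8))


def test_k_equal_n_is_leave_one_out():
    plan = cc.make_folds(5, 5, seed=1)
    assert all(plan.test_indices(f).size == 1 for f in range(5))


def test_folds_deterministic_given_seed():
    a = cc.make_folds(30, 7, seed=42).assignment
    b = cc.make_folds(30, 7, seed=42).assignment
    assert np.array_equal(a, b)
    c = cc.make_folds(30, 7, seed=43).assignment
    assert not np.array_equal(a, c)


def test_folds_reject_bad_k():
    with pytest.raises(ValueError):
        cc.make_folds(5, 6, seed=0)
    with pytest.raises(ValueError):
        cc.make_folds(5, 1, seed=0)


# ---------------------------------------------------- family exclusion

def test_exclude_relatives_basic_and_noop():
    fam = ["f1", "f2", "f3", "f2"]  # B and D are siblings
    kept = cc.exclude_relatives(np.array([0, 1, 2]), np.array([3]), fam)
    assert kept.tolist() == [0, 2]
    fam2 = ["f1", "f2", "f3", "f4"]
    kept2 = cc.exclude_relatives(np.array([0, 1, 2]), np.array([3]), fam2)
    assert kept2.tolist() == [0, 1, 2]


def test_exclude_relatives_matches_pairwise_scan(rng):
    N = 60
    fam = rng.integers(0, 12, size=N)
    test = rng.choice(N, size=8, replace=False)
    train = np.setdiff1d(np.arange(N), test)
    kept = cc.exclude_relatives(train, test, fam)
    # O(N^2) oracle: a train subject survives iff it shares no family with any test subject
    oracle = [i for i in train if all(fam[i] != fam[j] for j in test)]
    assert kept.tolist() == oracle


def test_exclude_relatives_empty_train_raises():
    fam = ["f", "f", "f"]
    with pytest.raises(ValueError, match="larger folds"):
        cc.exclude_relatives(np.array([0, 1]), np.array([2]), fam)


def test_exclude_relatives_requires_disjoint_sets():
    with pytest.raises(ValueError, match="disjoint"):
        cc.exclude_relatives(np.array([0, 1]), np.array([1]), ["a", "b"])


# -------------------------------------------------------- residualize

def test_residualize_confound_column_gives_zero(rng):
    x = rng.standard_normal(30)
    res = cc.residualize(x * 2.0 + 1.0, x.reshape(-1, 1))
    assert np.abs(res).max() < 1e-10


def test_residualize_empty_design_demeans(rng):
    y = rng.standard_normal(20) + 5.0
    res = cc.residualize(y, np.empty((20, 0)))
    assert np.allclose(res, y - y.mean(), atol=1e-12)


def test_residualize_orthogonal_to_design(rng):
    y = rng.standard_normal(50)
    X = rng.standard_normal((50, 3))
    res = cc.residualize(y, X)
    assert np.abs(X.T @ res).max() < 1e-10
    assert abs(res.sum()) < 1e-10  # orthogonal to intercept too


def test_residualize_rank_deficiency_detected(rng):
    x = rng.standard_normal(20)
    X = np.column_stack([x, 2.0 * x])
    with pytest.raises(ValueError, match="rank deficient"):
        cc.residualize(rng.standard_normal(20), X)


# ------------------------------------------------- edgewise association

def test_edge_equal_to_target_lands_in_positive_mask(rng):
    y = rng.standard_normal(30)
    edges = np.column_stack([y, -y, rng.standard_normal(30)])
    sel = cc.edgewise_association(edges, y, np.empty((30, 0)))
    assert sel.pos_mask[0] and sel.r[0] == pytest.approx(1.0)
    assert sel.neg_mask[1] and sel.r[1] == pytest.approx(-1.0)
    assert not (sel.pos_mask & sel.neg_mask).any()


def test_edgewise_matches_per_edge_loop_oracle(rng):
    N, E, q = 50, 40, 3
    edges = rng.standard_normal((N, E))
    y = rng.standard_normal(N)
    X = rng.standard_normal((N, q))
    sel = cc.edgewise_association(edges, y, X)
    X_aug = np.column_stack([np.ones(N), X])
    df = N - 2 - q
    for j in range(E):
        # independent oracle: explicit normal-equation residuals per variable
        def resid(v):
            beta = np.linalg.solve(X_aug.T @ X_aug, X_aug.T @ v)
            return v - X_aug @ beta

        re, ry = resid(edges[:, j]), resid(y)
        r = (re @ ry) / np.sqrt((re @ re) * (ry @ ry))
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
        assert sel.r[j] == pytest.approx(r, abs=1e-10)
        assert sel.p[j] == pytest.approx(p, abs=1e-10)


def test_edgewise_constant_edge_flagged(rng):
    edges = np.column_stack([np.ones(30), rng.standard_normal(30)])
    with pytest.warns(UserWarning, match="constant edge"):
        sel = cc.edgewise_association(edges, rng.standard_normal(30), np.empty((30, 0)))
    assert sel.r[0] == 0.0 and sel.p[0] == 1.0


def test_edgewise_selected_edges_respect_alpha(rng):
    edges = rng.standard_normal((60, 100))
    y = rng.standard_normal(60)
    sel = cc.edgewise_association(edges, y, np.empty((60, 0)), alpha=0.05)
    assert (sel.p[sel.pos_mask] <= 0.05).all()
    assert (sel.p[sel.neg_mask] <= 0.05).all()
    assert (sel.r[sel.pos_mask] > 0).all() and (sel.r[sel.neg_mask] < 0).all()


# ------------------------------------------------- strengths and model

def test_network_strength_examples_and_loop_oracle(rng):
    assert cc.network_strength(np.array([0.5, -0.2, 0.3]), np.array([1, 0, 1], bool)) == pytest.approx(0.8)
    assert cc.network_strength(np.array([1.0, 2.0]), np.zeros(2, bool)) == 0.0
    v = rng.standard_normal(50)
    m = rng.random(50) > 0.5
    assert cc.network_strength(v, m) == pytest.approx(sum(x for x, b in zip(v, m) if b))


def test_glm_noiseless_recovery(rng):
    s_pos = rng.standard_normal(40)
    s_neg = rng.standard_normal(40)
    y = 2.0 + 3.0 * s_pos - 1.0 * s_neg
    model = cc.fit_combined_glm(s_pos, s_neg, y)
    assert model.beta0 == pytest.approx(2.0, abs=1e-10)
    assert model.beta_pos == pytest.approx(3.0, abs=1e-10)
    assert model.beta_neg == pytest.approx(-1.0, abs=1e-10)


def test_glm_matches_normal_equations(rng):
    s_pos = rng.standard_normal(30)
    s_neg = rng.standard_normal(30)
    y = 1.0 + 0.5 * s_pos - 0.2 * s_neg + 0.3 * rng.standard_normal(30)
    model = cc.fit_combined_glm(s_pos, s_neg, y)
    D = np.column_stack([np.ones(30), s_pos, s_neg])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    assert np.allclose([model.beta0, model.beta_pos, model.beta_neg], beta, atol=1e-8)


def test_glm_constant_target_and_empty_masks(rng):
    y = np.full(10, 7.0)
    model = cc.fit_combined_glm(np.zeros(10), np.zeros(10), y)
    assert model.fallback and model.beta0 == 7.0
    pred = predict_from_model(model, rng.standard_normal((3, 0)))
    assert np.allclose(pred, 7.0)


# ------------------------------------------------------------- evaluate

def test_evaluate_identity_and_inverse(rng):
    x = rng.standard_normal(20)
    assert cc.evaluate(x, x) == pytest.approx(1.0)
    assert cc.evaluate(x, -x) == pytest.approx(-1.0)


def test_evaluate_toy_vectors_against_formula():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 1.0, 4.0, 3.0])
    expected = ((a - a.mean()) @ (b - b.mean())) / np.sqrt(
        ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
    )
    assert cc.evaluate(a, b) == pytest.approx(expected, abs=1e-12)


def test_evaluate_rejects_constant_input():
    with pytest.raises(ValueError, match="constant"):
        cc.evaluate(np.ones(5), np.arange(5.0))


# ------------------------------------------------------------- run_cpm

def test_run_cpm_out_of_fold_coverage_and_hygiene(default_run):
    data, _, result = default_run
    # every subject predicted exactly once: union of test folds covers all
    all_test = [s for rec in result.per_fold for s in rec.test_ids]
    assert sorted(all_test) == sorted(data.subject_ids)
    assert np.isfinite(result.predictions).all()
    # family hygiene: no excluded id shares a fold with itself; and no test
    # family remains among the subjects the fold trained on
    fam = dict(zip(data.subject_ids, data.family_id))
    idx = {s: i for i, s in enumerate(data.subject_ids)}
    for rec in result.per_fold:
        test_fams = {fam[s] for s in rec.test_ids}
        test_idx = {idx[s] for s in rec.test_ids}
        excluded = set(rec.excluded_train_ids)
        for s in data.subject_ids:
            if s in excluded or idx[s] in test_idx:
                continue
            # s was available to training: must not be related to the fold's tests
            if fam[s] in test_fams:
                raise AssertionError(f"relative {s} left in training of fold {rec.fold}")


def test_run_cpm_selection_consistency(default_run):
    _, _, result = default_run
    for rec in result.per_fold:
        sel = rec.selection
        assert not (sel.pos_mask & sel.neg_mask).any()
        assert (sel.p[sel.pos_mask | sel.neg_mask] <= sel.alpha + 1e-15).all()


def test_run_cpm_recovers_planted_signal(default_run):
    data, truth, result = default_run
    assert result.r_eval > 0.5
    union_pos = np.zeros(data.n_edges, bool)
    union_neg = np.zeros(data.n_edges, bool)
    for rec in result.per_fold:
        union_pos |= rec.selection.pos_mask
        union_neg |= rec.selection.neg_mask
    assert union_pos[list(truth.pos_edges)].all()
    assert union_neg[list(truth.neg_edges)].all()


def test_run_cpm_deterministic(small_cohort):
    data, _ = small_cohort
    a = cc.run_cpm(data, k=5, seed=11)
    b = cc.run_cpm(data, k=5, seed=11)
    assert np.array_equal(a.predictions, b.predictions)
    assert a.r_eval == b.r_eval
    for ra, rb in zip(a.per_fold, b.per_fold):
        assert np.array_equal(ra.selection.pos_mask, rb.selection.pos_mask)
        assert np.array_equal(ra.selection.r, rb.selection.r)


def test_run_cpm_null_centred_near_zero():
    """With no planted signal, evaluation r over many seeds centres on 0."""
    rs = []
    for seed in range(50):
        spec = cc.SyntheticSpec(
            n_subjects=60,
            parcel_counts=(4, 8, 2),
            T=60,
            n_pos_edges=2,
            n_neg_edges=2,
            effect_size=0.0,
            family_edge_sd=0.0,
            n_families=60,
            seed=seed,
        )
        data, _, _ = cc.generate_dataset(spec)
        rs.append(cc.run_cpm(data, k=5, seed=seed).r_eval)
    rs = np.asarray(rs)
    se = rs.std(ddof=1) / np.sqrt(len(rs))
    assert abs(rs.mean()) < 3 * se + 1e-9


def test_run_cpm_caps_k_at_n(small_cohort):
    data, _ = small_cohort
    with pytest.warns(UserWarning, match="capping"):
        result = cc.run_cpm(data, k=10_000, seed=0)
    assert result.params["k"] == data.n_subjects


def test_encode_confounds_minimal_full_rank():
    import pandas as pd

    df = pd.DataFrame(
        {
            "age": [20.0, 30.0, 40.0, 50.0, 25.0, 35.0],
            "gender": ["M", "F", "F", "M", "F", "M"],
            "ethnicity": ["A", "B", "C", "A", "C", "B"],
        }
    )
    X, names = cc.encode_confounds(df, numeric=("age",), binary=("gender",), categorical=("ethnicity",))
    assert X.shape == (6, 4)  # age + gender + 2 ethnicity dummies
    assert names == ("age", "gender[M]", "ethnicity[B]", "ethnicity[C]")
    assert np.linalg.matrix_rank(np.column_stack([np.ones(6), X])) == 5
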