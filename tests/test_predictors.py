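"""Scorer formulas against hand-evaluated values and exhaustive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ehrvec.predictors import (CFClassifier, DecayedLogisticBaseline,
                               PDESClassifier, PDPSClassifier,
                               build_similarity_matrix, cf_score,
                               lr_baseline_fit, lr_baseline_score,
                               pdes_score, pdps_score, project_patient,
                               temporal_factor)

from _helpers import make_seq, toy_model


# ---------------------------------------------------------- temporal factor

@pytest.mark.parametrize("lam,t,expected", [
    (0.0, 1000.0, 1.0),
    (np.log(2), 1.0, 0.5),
    (0.01, 100.0, np.exp(-1.0)),
])
def test_temporal_factor_analytic(lam, t, expected):
    assert temporal_factor(t, lam) == pytest.approx(expected, rel=1e-12)


def test_temporal_factor_rejects_bad_inputs():
    with pytest.raises(ValueError):
        temporal_factor(-1.0, 0.1)
    with pytest.raises(ValueError):
        temporal_factor(1.0, -0.1)


@settings(deadline=None, derandomize=True)
@given(st.floats(0, 500.0), st.floats(0, 1.0))
def test_temporal_factor_in_unit_interval(t, lam):
    assert 0.0 < temporal_factor(t, lam) <= 1.0


# --------------------------------------------------------------- projection

def test_projection_unweighted_sum():
    m = toy_model({"a": [1.0, 0.0], "b": [0.0, 1.0]})
    p = project_patient(make_seq(["a", "b"], [5.0, 0.0]), m, lam=0.0)
    np.testing.assert_allclose(p.vector, [1.0, 1.0])
    assert p.weight_sum == 2.0


def test_projection_single_event_halved():
    m = toy_model({"a": [2.0, 0.0]})
    p = project_patient(make_seq(["a"], [1.0]), m, lam=np.log(2))
    np.testing.assert_allclose(p.vector, [1.0, 0.0])


def test_projection_order_invariant():
    m = toy_model({"a": [1.0, 2.0], "b": [3.0, -1.0], "c": [0.5, 0.5]})
    s1 = make_seq(["a", "b", "c"], [9.0, 4.0, 0.0])
    s2 = make_seq(["c", "a", "b"], [0.0, 9.0, 4.0])
    p1 = project_patient(s1, m, lam=0.05)
    p2 = project_patient(s2, m, lam=0.05)
    np.testing.assert_allclose(p1.vector, p2.vector)
    assert p1.weight_sum == pytest.approx(p2.weight_sum)


def test_projection_counts_and_rejects_oov():
    m = toy_model({"a": [1.0, 0.0]})
    p = project_patient(make_seq(["a", "zzz"], [1.0, 0.0]), m)
    assert p.n_oov == 1
    with pytest.raises(ValueError, match="out of vocabulary"):
        project_patient(make_seq(["zzz"], [0.0]), m)


def test_weight_sum_equals_length_when_lambda_zero():
    m = toy_model({"a": [1.0, 1.0]})
    p = project_patient(make_seq(["a"] * 7, np.arange(7.0)), m, lam=0.0)
    assert p.weight_sum == 7.0


# --------------------------------------------------------------------- PDPS

def test_pdps_identity_history():
    m = toy_model({"d_x": [0.3, -0.7]})
    assert pdps_score(make_seq(["d_x"], [0.0]), "d_x", m) == pytest.approx(1.0)


def test_pdps_hand_evaluated_two_event_history():
    m = toy_model({"a": [1.0, 0.0], "b": [0.0, 1.0], "d_x": [1.0, 1.0]})
    lam = np.log(2)
    seq = make_seq(["a", "b"], [1.0, 0.0])
    # projection = 0.5*(1,0) + 1*(0,1) = (0.5, 1)
    expected = np.dot([0.5, 1.0], [1.0, 1.0]) / (np.linalg.norm([0.5, 1.0]) * np.sqrt(2))
    assert pdps_score(seq, "d_x", m, lam) == pytest.approx(expected, rel=1e-12)


def test_pdps_invariant_to_common_rescaling():
    m = toy_model({"a": [1.0, 0.3], "b": [-0.2, 1.0], "d_x": [0.5, 0.5]})
    seq = make_seq(["a", "b"], [3.0, 0.0])
    base = pdps_score(seq, "d_x", m, lam=0.01)
    m.vectors_ *= 7.5
    assert pdps_score(seq, "d_x", m, lam=0.01) == pytest.approx(base, rel=1e-12)


def test_pdps_separates_planted_positives(small_sequences):
    from ehrvec.embedding import build_corpus, train_embeddings
    seqs, truth = small_sequences
    m = train_embeddings(build_corpus(seqs), size=32, window=10, epochs=5, seed=2)
    targets = sorted({"d_" + d for d in truth.assignments.diagnosis.unique()}
                     & set(m.vocab_))
    for d in targets:
        pos = [pdps_score(s, d, m) for s in seqs if d in s.label_diagnoses]
        neg = [pdps_score(s, d, m) for s in seqs if d not in s.label_diagnoses]
        assert np.mean(pos) > np.mean(neg), d


# -------------------------------------------------------- similarity matrix

def test_similarity_matrix_diagonal_and_clipping():
    m = toy_model({"a": [1.0, 0.0], "b": [-1.0, 0.0], "d_x": [1.0, 0.0],
                   "d_y": [0.0, 1.0]})
    S = build_similarity_matrix(m, ["d_x", "d_y"], clip_negative=False)
    assert S.values[S.token_index["d_x"], S.target_index["d_x"]] == pytest.approx(1.0)
    assert S.values[S.token_index["a"], S.target_index["d_y"]] == pytest.approx(0.0)
    assert S.values[S.token_index["b"], S.target_index["d_x"]] == pytest.approx(-1.0)
    Sc = build_similarity_matrix(m, ["d_x", "d_y"], clip_negative=True)
    diff = S.values != Sc.values
    assert np.all(S.values[diff] < 0)           # clipping touches only negatives
    assert np.all(Sc.values >= 0)


def test_similarity_matrix_rejects_oov_target():
    m = toy_model({"a": [1.0, 0.0]})
    with pytest.raises(KeyError):
        build_similarity_matrix(m, ["d_missing"])


# --------------------------------------------------------------------- PDES

def _pdes_fixture():
    return toy_model({"a": [1.0, 0.0], "b": [0.0, 1.0],
                      "d_x": [0.6, 0.8], "d_y": [1.0, 0.0]})


def test_pdes_single_event_sigma_cancels():
    m = _pdes_fixture()
    S = build_similarity_matrix(m, ["d_x"])
    # S[a, d_x] = 0.6; any decay cancels with sigma
    for lam in (0.0, 0.3, 5.0):
        assert pdes_score(make_seq(["a"], [10.0]), "d_x", S, lam) == \
            pytest.approx(0.6, rel=1e-12)


def test_pdes_weighted_mean_of_two_events():
    m = _pdes_fixture()
    S = build_similarity_matrix(m, ["d_x"])
    # S[a,d_x]=0.6, S[b,d_x]=0.8; lam=0 -> plain mean
    got = pdes_score(make_seq(["a", "b"], [5.0, 0.0]), "d_x", S, 0.0)
    assert got == pytest.approx(0.7, rel=1e-12)


def test_pdes_limit_large_lambda_keeps_latest_event():
    m = _pdes_fixture()
    S = build_similarity_matrix(m, ["d_x"])
    # late event (t_c=0) has S=0.6 (token a); old event has S=0.8 (token b)
    got = pdes_score(make_seq(["b", "a"], [1e6, 0.0]), "d_x", S, lam=50.0)
    assert got == pytest.approx(0.6, abs=1e-9)


def test_pdes_invariant_to_duplicating_history():
    m = _pdes_fixture()
    S = build_similarity_matrix(m, ["d_x"])
    s1 = make_seq(["a", "b"], [4.0, 0.0])
    s2 = make_seq(["a", "a", "b", "b"], [4.0, 4.0, 0.0, 0.0])
    for lam in (0.0, 0.1):
        assert pdes_score(s1, "d_x", S, lam) == \
            pytest.approx(pdes_score(s2, "d_x", S, lam), rel=1e-12)


def test_pdes_all_oov_history_rejected():
    m = _pdes_fixture()
    S = build_similarity_matrix(m, ["d_x"])
    with pytest.raises(ValueError):
        pdes_score(make_seq(["zzz"], [0.0]), "d_x", S)


# ----------------------------------------------------------------------- CF

def test_cf_two_neighbor_hand_vote():
    # cosines with the test projection: 0.8 (has d), 0.2 (does not)
    test_v = np.array([1.0, 0.0])
    n1 = np.array([0.8, 0.6])       # cos = 0.8
    n2 = np.array([0.2, np.sqrt(1 - 0.04)])  # cos = 0.2
    train = [(n1, frozenset({"d_x"})), (n2, frozenset())]
    assert cf_score(test_v, "d_x", train) == pytest.approx(0.8, rel=1e-9)


def test_cf_unanimous_vote_is_one():
    train = [(np.array([1.0, 0.1]), frozenset({"d_x"})),
             (np.array([0.9, -0.1]), frozenset({"d_x"}))]
    assert cf_score(np.array([1.0, 0.0]), "d_x", train) == pytest.approx(1.0)


def test_cf_negative_neighbors_floored_to_zero():
    train = [(np.array([-1.0, 0.0]), frozenset({"d_x"}))]
    assert cf_score(np.array([1.0, 0.0]), "d_x", train) == 0.0


def test_cf_all_k_equals_brute_force():
    rng = np.random.default_rng(3)
    train = [(rng.normal(size=4),
              frozenset({"d_x"} if rng.random() < 0.4 else set()))
             for _ in range(100)]
    v = rng.normal(size=4)
    got = cf_score(v, "d_x", train, k=None)
    w = np.array([max(0.0, float(np.dot(v, p) / (np.linalg.norm(v) * np.linalg.norm(p))))
                  for p, _ in train])
    brute = w[[i for i, (_, l) in enumerate(train) if "d_x" in l]].sum() / w.sum()
    assert got == pytest.approx(brute, rel=1e-12)


def test_cf_empty_training_set_rejected():
    with pytest.raises(ValueError):
        cf_score(np.array([1.0]), "d_x", [])


def test_cf_small_k_restricts_neighborhood():
    train = [(np.array([1.0, 0.0]), frozenset({"d_x"})),
             (np.array([0.0, 1.0]), frozenset())]
    # k=1 keeps only the most similar neighbor, which has d_x
    assert cf_score(np.array([1.0, 0.1]), "d_x", train, k=1) == pytest.approx(1.0)


# ------------------------------------------------------------------ LR

def test_lr_features_are_counts_when_lambda_zero():
    clf = DecayedLogisticBaseline(lam=0.0, targets=["d_x"])
    seqs = [make_seq(["a", "a", "b"], [2.0, 1.0, 0.0], labels=["d_x"], pid="P0"),
            make_seq(["b"], [0.0], labels=[], pid="P1")]
    clf.targets_ = ["d_x"]
    clf.vocabulary_ = ["a", "b"]
    clf._feat_index = {"a": 0, "b": 1}
    np.testing.assert_allclose(clf._features(seqs), [[2.0, 1.0], [0.0, 1.0]])


def test_lr_separable_toy_reaches_perfect_training_accuracy():
    pos = [make_seq(["a", "a"], [1.0, 0.0], labels=["d_x"], pid=f"P{i}")
           for i in range(4)]
    neg = [make_seq(["b", "b"], [1.0, 0.0], labels=[], pid=f"Q{i}")
           for i in range(4)]
    clf = DecayedLogisticBaseline(lam=0.0, targets=["d_x"]).fit(pos + neg)
    scores = clf.decision_function(pos + neg)[:, 0]
    pred = scores >= 0.5
    assert list(pred) == [True] * 4 + [False] * 4


def test_lr_single_class_warns_and_returns_constant():
    seqs = [make_seq(["a"], [0.0], labels=["d_x"], pid=f"P{i}") for i in range(3)]
    with pytest.warns(RuntimeWarning, match="single-class"):
        clf = DecayedLogisticBaseline(targets=["d_x"]).fit(seqs)
    assert np.all(clf.decision_function(seqs)[:, 0] == 1.0)


def test_lr_functional_wrappers():
    pos = [make_seq(["a"], [0.0], labels=["d_x"], pid=f"P{i}") for i in range(3)]
    neg = [make_seq(["b"], [0.0], labels=[], pid=f"Q{i}") for i in range(3)]
    scorer = lr_baseline_fit(pos + neg, "d_x", lam=0.0)
    assert lr_baseline_score(scorer, pos[0]) > lr_baseline_score(scorer, neg[0])


# ------------------------------------------------------------- estimators

def test_estimators_are_sklearn_parametrized():
    clf = PDPSClassifier(lam=0.25)
    assert clf.get_params()["lam"] == 0.25
    clf.set_params(lam=0.5)
    assert clf.lam == 0.5


def test_classifiers_agree_with_functional_scorers(small_sequences):
    from ehrvec.embedding import build_corpus, train_embeddings
    seqs, truth = small_sequences
    m = train_embeddings(build_corpus(seqs), size=16, window=5, epochs=3, seed=4)
    targets = sorted({"d_" + d for d in truth.assignments.diagnosis.unique()}
                     & set(m.vocab_))[:3]
    lam = 0.01
    pdps = PDPSClassifier(embedding=m, lam=lam, targets=targets).fit(seqs[:50])
    pdes = PDESClassifier(embedding=m, lam=lam, targets=targets).fit(seqs[:50])
    cf = CFClassifier(embedding=m, lam=lam, targets=targets).fit(seqs[:50])
    sub = seqs[50:60]
    Mp = pdps.decision_function(sub)
    Me = pdes.decision_function(sub)
    Mc = cf.decision_function(sub)
    train_projs = [(project_patient(s, m, lam).vector, s.label_diagnoses)
                   for s in seqs[:50]]
    for i, s in enumerate(sub):
        for j, d in enumerate(targets):
            assert Mp[i, j] == pytest.approx(pdps_score(s, d, m, lam), rel=1e-9)
            assert Me[i, j] == pytest.approx(
                pdes_score(s, d, pdes.similarity_matrix_, lam), rel=1e-9)
            assert Mc[i, j] == pytest.approx(
                cf_score(project_patient(s, m, lam), d, train_projs), rel=1e-9)
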