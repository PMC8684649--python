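"""ROC curve, AUC (vs exhaustive pair counting and sklearn), Youden scan
(vs brute force) and the DeLong paired test (vs bootstrap)."""

import numpy as np
import pandas as pd
import pytest

from munophen.roc import (DEFAULT_DELONG_PAIRS, RocError, auc_mann_whitney,
                          auc_trapezoid, delong_auc_variance, delong_test,
                          roc_points, roc_summary, run_roc_table,
                          youden_cutoff)


def brute_force_auc(scores, labels):
    """Oracle: (#concordant + 0.5 #tied) / (n1 * n0) by full enumeration."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    conc = sum(p > q for p in pos for q in neg)
    tied = sum(p == q for p in pos for q in neg)
    return (conc + 0.5 * tied) / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Oracle: evaluate every observed threshold with the >= rule; the
    smallest cutoff within 1e-12 of the maximal J wins (contract tie rule)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    points = []
    for c in sorted(set(s)):
        sens = float(np.mean(s[y == 1] >= c))
        spec = float(np.mean(s[y == 0] < c))
        points.append((float(c), sens, spec, sens + spec - 1))
    jmax = max(p[3] for p in points)
    for p in points:
        if p[3] >= jmax - 1e-12:
            return p


def test_perfect_separation_staircase():
    pts = roc_points([1, 2, 3, 4], [0, 0, 1, 1])
    assert auc_trapezoid(pts) == 1.0
    assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]


def test_all_tied_scores_give_diagonal():
    pts = roc_points([5, 5, 5, 5], [0, 1, 0, 1])
    assert pts.tolist() == [[0, 0], [1, 1]]
    assert auc_trapezoid(pts) == 0.5


def test_five_point_mixed_case_matches_pair_counting():
    scores, labels = [3, 1, 2, 4, 2], [1, 0, 0, 1, 1]
    expected = brute_force_auc(scores, labels)
    assert auc_trapezoid(roc_points(scores, labels)) == pytest.approx(expected, abs=1e-15)
    assert auc_mann_whitney(scores, labels) == pytest.approx(expected, abs=1e-15)


def test_one_class_errors():
    with pytest.raises(RocError):
        roc_points([1, 2, 3], [1, 1, 1])


def test_curve_monotone_and_auc_identity(rng):
    for _ in range(200):
        n = int(rng.integers(4, 13))
        scores = rng.integers(0, 6, n).astype(float)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        pts = roc_points(scores, labels)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        auc = auc_trapezoid(pts)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(auc_mann_whitney(scores, labels), abs=1e-12)


def test_score_sign_reversal_maps_auc(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    labels[:2] = [0, 1]
    a = auc_trapezoid(roc_points(scores, labels))
    b = auc_trapezoid(roc_points(-scores, labels))
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.normal(size=300) + rng.integers(0, 2, 300)
    labels = rng.integers(0, 2, 300)
    labels[:2] = [0, 1]
    assert auc_trapezoid(roc_points(scores, labels)) == \
        pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_youden_perfect_separation():
    cutoff, sens, spec, j = youden_cutoff([1, 2, 8, 9], [0, 0, 1, 1])
    assert (cutoff, sens, spec, j) == (8.0, 1.0, 1.0, 1.0)


def test_youden_six_point_fixture_matches_brute_force():
    scores = [0.2, 0.4, 0.4, 0.6, 0.7, 0.9]
    labels = [0, 0, 1, 0, 1, 1]
    assert youden_cutoff(scores, labels) == pytest.approx(
        brute_force_youden(scores, labels))


def test_youden_ties_broken_by_smallest_cutoff():
    # J = 0.5 at both cutoffs 2 and 4; the smaller must win
    scores = [1, 2, 3, 4]
    labels = [0, 1, 0, 1]
    cutoff, *_ = youden_cutoff(scores, labels)
    assert cutoff == brute_force_youden(scores, labels)[0]
    assert cutoff == 2.0


def test_youden_random_instances_match_brute_force(rng):
    for _ in range(200):
        n = int(rng.integers(4, 13))
        scores = rng.integers(0, 6, n).astype(float)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert youden_cutoff(scores, labels) == pytest.approx(
            brute_force_youden(scores, labels), abs=1e-12)


def test_delong_self_comparison_is_degenerate(rng):
    s = rng.normal(size=50)
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    res = delong_test(s, s, y)
    assert (res.z, res.p_value) == (0.0, 1.0)
    assert res.degenerate_variance


def test_delong_symmetry(rng):
    a = rng.normal(size=80)
    b = rng.normal(size=80) + 0.3
    y = rng.integers(0, 2, 80)
    y[:2] = [0, 1]
    r1 = delong_test(a, b, y)
    r2 = delong_test(b, a, y)
    assert r1.z == pytest.approx(-r2.z, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def test_delong_maximal_contrast():
    scores = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
    labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    res = delong_test(scores, -scores, labels)
    assert res.auc_a == 1.0 and res.auc_b == 0.0
    assert res.p_value < 0.05


def test_delong_variance_close_to_bootstrap(rng):
    """DeLong variance of the paired AUC difference versus a subject-level
    bootstrap on n = 30."""
    n = 30
    y = np.r_[np.ones(15, int), np.zeros(15, int)]
    a = rng.normal(size=n) + 0.9 * y
    b = 0.6 * a + rng.normal(size=n) * 0.8 + 0.5 * y

    from munophen.roc import _placements
    va = _placements(a, y)
    vb = _placements(b, y)
    s10 = np.cov(np.vstack([va[0], vb[0]]), ddof=1)
    s01 = np.cov(np.vstack([va[1], vb[1]]), ddof=1)
    var_delong = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 15 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / 15

    reps = 4000
    boot = np.empty(reps)
    kept = 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.min() == yy.max():
            continue
        boot[kept] = auc_mann_whitney(a[idx], yy) - auc_mann_whitney(b[idx], yy)
        kept += 1
    var_boot = boot[:kept].var(ddof=1)
    assert var_delong == pytest.approx(var_boot, rel=0.3)


def test_roc_summary_invariants(rng):
    s = rng.normal(size=100) + rng.integers(0, 2, 100)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    res = roc_summary(s, y, index_name="x")
    assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1
    assert res.youden == pytest.approx(res.sensitivity + res.specificity - 1)


def test_run_roc_table_composition(rng):
    """The assembled stratified table must equal independently composed
    per-operation results on a 20-row fixture."""
    n = 20
    df = pd.DataFrame({
        "sex": ["male"] * 10 + ["female"] * 10,
        "muno": [0, 1] * 10,
        "vai": rng.normal(size=n) + np.tile([0, 1.2], 10),
        "lap": rng.normal(size=n),
    })
    t3, t4, curves = run_roc_table(df, ["vai", "lap"], pairs=[("vai", "lap")])
    assert len(t3) == 4 and len(t4) == 2
    for stratum in ("male", "female"):
        sub = df[df["sex"] == stratum]
        expected = roc_summary(sub["vai"].to_numpy(), sub["muno"].to_numpy(),
                               index_name="vai", stratum=stratum)
        got = t3[(t3["stratum"] == stratum) & (t3["index_name"] == "vai")].iloc[0]
        assert got["auc"] == pytest.approx(expected.auc)
        assert got["cutoff"] == pytest.approx(expected.cutoff)
        ref = delong_test(sub["vai"].to_numpy(), sub["lap"].to_numpy(),
                          sub["muno"].to_numpy())
        got4 = t4[t4["stratum"] == stratum].iloc[0]
        assert got4["z"] == pytest.approx(ref.z)
        assert got4["p_value"] == pytest.approx(ref.p_value)
    assert ("male", "vai") in curves


def test_identical_index_columns_give_p_one(rng):
    s = rng.normal(size=40)
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    df = pd.DataFrame({"sex": ["male"] * 40, "muno": y, "a": s, "b": s})
    _, t4, _ = run_roc_table(df, ["a", "b"], pairs=[("a", "b")])
    assert t4["p_value"].iloc[0] == 1.0


def test_single_class_stratum_skipped(rng, caplog):
    df = pd.DataFrame({
        "sex": ["male"] * 10 + ["female"] * 10,
        "muno": [0, 1] * 5 + [1] * 10,
        "vai": rng.normal(size=20),
    })
    with caplog.at_level("WARNING", logger="munophen"):
        t3, _, _ = run_roc_table(df, ["vai"], pairs=[])
    assert set(t3["stratum"]) == {"male"}
    assert "skipped" in caplog.text
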