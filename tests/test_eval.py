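"""Cross-validation harness, Wilcoxon signed-rank test, aggregation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from semgshift.evaluate import (
    FoldResult,
    TrainConfig,
    aggregate_report,
    featurize_subject,
    kfold_split,
    train_fold,
    wilcoxon_paired,
)
from semgshift.grid import make_grid
from semgshift.net import ModelConfig
from semgshift.perturb import DamageConfig
from semgshift.synth import SubjectProfile


# -- k-fold ------------------------------------------------------------------


def test_kfold_sizes_and_stratification():
    labels = np.repeat(np.arange(9), 480)  # 4,320 frame labels
    folds = kfold_split(labels, 4, seed=0)
    assert len(folds) == 4
    seen = []
    for tr, te in folds:
        assert len(te) == 1080 and len(tr) == 3240
        assert set(tr).isdisjoint(te)
        counts = np.bincount(labels[te], minlength=9)
        assert (counts == 120).all()
        seen.extend(te.tolist())
    assert sorted(seen) == list(range(4320))


def test_kfold_determinism_and_validation():
    labels = np.repeat([0, 1], 20)
    a = kfold_split(labels, 4, seed=3)
    b = kfold_split(labels, 4, seed=3)
    for (tr1, te1), (tr2, te2) in zip(a, b):
        np.testing.assert_array_equal(te1, te2)
    with pytest.raises(ValueError):
        kfold_split(labels, 1, seed=0)
    with pytest.raises(ValueError):
        kfold_split(labels, 100, seed=0)


def test_kfold_group_by_trial_keeps_trials_together():
    labels = np.repeat(np.arange(3), 8 * 30)
    trials = np.repeat(np.arange(24), 30)
    folds = kfold_split(labels, 4, seed=1, groups=trials)
    for tr, te in folds:
        assert set(trials[tr]).isdisjoint(trials[te])
        counts = np.bincount(labels[te], minlength=3)
        assert (counts == 2 * 30).all()  # 2 trials per gesture per fold


# -- training ----------------------------------------------------------------


def test_train_fold_confusion_identity():
    rng = np.random.default_rng(0)
    x = rng.random((80, 4, 4)).astype(np.float32)
    y = np.tile(np.arange(2), 40)
    cfg = ModelConfig(input_shape=(4, 4), n_classes=2, conv_channels=(4, 6, 8), se_reduction=4, hidden_units=(8, 8, 4), seed=0)
    res = train_fold(cfg, TrainConfig(epochs=2, batch_size=32, seed=0), (x[:60], y[:60]), (x[60:], y[60:]))
    assert res.confusion.sum() == 20
    assert res.accuracy == pytest.approx(np.trace(res.confusion) / res.confusion.sum())
    np.testing.assert_array_equal(res.confusion.sum(axis=1), np.bincount(y[60:], minlength=2))


def test_train_fold_shape_mismatch():
    x = np.zeros((10, 4, 4), dtype=np.float32)
    y = np.zeros(10, dtype=int)
    cfg = ModelConfig(input_shape=(3, 3), n_classes=2, conv_channels=(4, 6, 8), se_reduction=4, hidden_units=(8, 8, 4))
    with pytest.raises(ValueError):
        train_fold(cfg, TrainConfig(epochs=1), (x, y), (x, y))


def test_se_gate_learns_to_downweight_damaged_inputs():
    """After training on data with damaged channels, the mean attention gate
    on damage-bearing images does not exceed the gate on clean images."""
    prof = SubjectProfile(grid=make_grid(4, 6), n_gestures=3, n_repetitions=4, seed=13)
    dmg = DamageConfig(channels=(3, 16), noise_seed=2)
    x_dmg, _, y, _, shape = featurize_subject(prof, damage_cfg=dmg)
    x_clean, _, _, _, _ = featurize_subject(prof)
    cfg = ModelConfig(input_shape=shape, n_classes=3, seed=13)
    _, model = train_fold(
        cfg, TrainConfig(epochs=5, batch_size=64, seed=13), (x_dmg, y), (x_dmg, y), return_model=True
    )
    gate_dmg = model.se_gate(x_dmg[:180]).mean()
    gate_clean = model.se_gate(x_clean[:180]).mean()
    assert gate_dmg <= gate_clean + 0.02


# -- Wilcoxon ----------------------------------------------------------------


def _enumeration_oracle(a, b):
    """Brute force: full 2^n sign-flip distribution of min(W+, W-)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_small = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= w_small:
            count += 1
    return w_small, min(1.0, 2.0 * count / 2**n)


def test_wilcoxon_constant_offset_exact_p():
    b = np.arange(10.0)
    stat, p = wilcoxon_paired(b + 0.5, b)
    assert stat == 0.0
    assert p == pytest.approx(2 * 2**-10)


def test_wilcoxon_degenerate_and_symmetry():
    a = np.arange(8.0)
    with pytest.raises(ValueError):
        wilcoxon_paired(a, a)
    with pytest.raises(ValueError):
        wilcoxon_paired(a[:3], a[:3] + 1)
    rng = np.random.default_rng(5)
    x = rng.normal(size=12)
    y = x + rng.normal(size=12)
    s1, p1 = wilcoxon_paired(x, y)
    s2, p2 = wilcoxon_paired(y, x)
    assert p1 == p2 and s1 == s2


@pytest.mark.parametrize("n", [5, 7, 9, 12])
def test_wilcoxon_matches_enumeration_on_integer_data(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        a = rng.integers(0, 6, n).astype(float)
        b = rng.integers(0, 6, n).astype(float)
        if np.all(a == b):
            continue
        stat, p = wilcoxon_paired(a, b)
        stat_o, p_o = _enumeration_oracle(a, b)
        assert stat == stat_o
        assert p == pytest.approx(p_o, abs=1e-12)


def test_wilcoxon_matches_scipy_exact_on_tie_free_data():
    rng = np.random.default_rng(2)
    for n in (8, 15, 25):
        a = rng.normal(size=n)
        b = a + rng.normal(size=n)
        stat, p = wilcoxon_paired(a, b)
        ref = stats.wilcoxon(a, b, zero_method="wilcox", method="exact")
        assert stat == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_normal_approximation_regime():
    rng = np.random.default_rng(3)
    a = rng.normal(size=60)
    b = a + 0.3 + rng.normal(size=60)
    _, p = wilcoxon_paired(a, b)
    ref = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method="approx")
    assert p == pytest.approx(ref.pvalue, abs=5e-3)


# -- aggregation -------------------------------------------------------------


def _fold(acc, fold=0, direction=None, damage=False, subject=0, n_classes=2):
    conf = np.array([[int(acc * 10), 10 - int(acc * 10)], [0, 10]])
    return FoldResult(fold_index=fold, accuracy=acc, confusion=conf, direction=direction, damage=damage, subject=subject)


def test_aggregate_single_result_sd_zero():
    rep = aggregate_report([_fold(0.9)])
    assert rep.table.loc[0, "sd_accuracy"] == 0.0
    assert rep.table.loc[0, "n"] == 1


def test_aggregate_mean_and_sample_sd():
    rep = aggregate_report([_fold(0.9), _fold(0.7, fold=1)])
    assert rep.table.loc[0, "mean_accuracy"] == pytest.approx(0.8)
    assert rep.table.loc[0, "sd_accuracy"] == pytest.approx(0.1414213562, rel=1e-6)


def test_aggregate_pooled_confusion_rows_normalized():
    rep = aggregate_report([_fold(0.8), _fold(0.6, fold=1), _fold(0.5, direction="inwards")])
    for conf in rep.confusions.values():
        np.testing.assert_allclose(conf.sum(axis=1), 1.0)
    assert set(rep.confusions) == {"baseline", "inwards"}
    with pytest.raises(ValueError):
        aggregate_report([])
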