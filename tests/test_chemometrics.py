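import numpy as np
import pytest

import specfinger as sf
from specfinger.errors import DegenerateInputError


# ---------------------------------------------------------------------------
# splitting

def test_split_sizes_80_20(cohort):
    cfg = sf.ModelConfig(split_seed=11)
    train, val = split = sf.split_dataset(cohort, cfg)
    assert train.labels.count("FM") == 40 and train.labels.count("LC") == 40
    assert val.labels.count("FM") == 10 and val.labels.count("LC") == 10
    assert set(train.sample_ids).isdisjoint(val.sample_ids)


def test_split_deterministic(cohort):
    cfg = sf.ModelConfig(split_seed=11)
    t1, v1 = sf.split_dataset(cohort, cfg)
    t2, v2 = sf.split_dataset(cohort, cfg)
    assert t1.sample_ids == t2.sample_ids and v1.sample_ids == v2.sample_ids


def test_split_half_of_four(tiny_cohort):
    cfg = sf.ModelConfig(split_fraction=0.5, split_seed=0)
    train, val = sf.split_dataset(tiny_cohort, cfg)
    for ds in (train, val):
        assert ds.labels.count("FM") == 2 and ds.labels.count("LC") == 2


# ---------------------------------------------------------------------------
# OSC

def test_osc_scores_orthogonal_to_response(cohort):
    pipe = sf.preprocess_pipeline(cohort, sf.PreprocessConfig())
    y = cohort.y
    model, Xc = sf.osc_fit(pipe.matrix, y, n_osc=2)
    yc = y - y.mean()
    for comp in model.components:
        t = comp.score
        assert abs(t @ yc) / (np.linalg.norm(t) * np.linalg.norm(yc)) < 1e-8
        # raw-y orthogonality holds too because scores have zero mean
        assert abs(t @ y) / (np.linalg.norm(t) * np.linalg.norm(y)) < 1e-8


def test_osc_two_column_closed_form():
    """X = [y, z] with z orthogonal to y: OSC must zero the z column only."""
    rng = np.random.default_rng(0)
    y = np.array([1.0, 1, 1, 2, 2, 2])
    yc = y - y.mean()
    z = rng.normal(size=6)
    z -= z @ yc / (yc @ yc) * yc
    z -= z.mean()
    X = np.column_stack([yc, z])
    model, Xc = sf.osc_fit(X, y, n_osc=1)
    np.testing.assert_allclose(Xc[:, 1], 0.0, atol=1e-10)
    np.testing.assert_allclose(Xc[:, 0], yc, atol=1e-10)


def test_osc_removes_nothing_when_x_proportional_to_y():
    """Every column proportional to y: nothing orthogonal exists to remove."""
    y = np.array([1.0, 1, 1, 2, 2, 2])
    yc = y - y.mean()
    X = np.outer(yc, np.array([1.0, -2.0, 0.5]))
    model, Xc = sf.osc_fit(X, y, n_osc=1)
    assert model.removed_variance == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(Xc, X, atol=1e-12)


def test_osc_apply_consistent_with_fit(cohort):
    pipe = sf.preprocess_pipeline(cohort, sf.PreprocessConfig())
    model, Xc = sf.osc_fit(pipe.matrix, cohort.y, n_osc=1)
    np.testing.assert_allclose(sf.osc_apply(model, pipe.matrix), Xc, atol=1e-10)


def test_osc_apply_zero_and_duplicate_rows(cohort):
    pipe = sf.preprocess_pipeline(cohort, sf.PreprocessConfig())
    model, Xc = sf.osc_fit(pipe.matrix, cohort.y, n_osc=1)
    zero = np.zeros((2, pipe.matrix.shape[1]))
    np.testing.assert_array_equal(sf.osc_apply(model, zero), zero)
    np.testing.assert_allclose(sf.osc_apply(model, pipe.matrix[:3]), Xc[:3], atol=1e-10)


def test_osc_reduces_nuisance_dominated_error(profiles):
    """Cross-validated error with OSC never degrades on nuisance-laden data."""
    import dataclasses

    strong = dataclasses.replace(profiles["FM"], nuisance=sf.NuisanceSpec(center=1600.0, fwhm=120.0, score_sd=2.0))
    strong_lc = dataclasses.replace(profiles["LC"], nuisance=sf.NuisanceSpec(center=1600.0, fwhm=120.0, score_sd=2.0))
    cfg = sf.SimulationConfig(n_per_class=12, seed=13)
    ds = sf.simulate_cohort([strong, strong_lc], cfg)
    pre = sf.PreprocessConfig()
    cv_with = sf.loocv(ds, pre, sf.ModelConfig(n_osc=1))
    cv_without = sf.loocv(ds, pre, sf.ModelConfig(n_osc=0))
    assert cv_with.secv <= cv_without.secv + 1e-9


# ---------------------------------------------------------------------------
# PLS-DA

def test_pls_first_weight_proportional_to_xty():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(3, 2))
    X -= X.mean(axis=0)
    y = np.array([-1.0, 0.0, 1.0])
    model = sf.plsda_fit(X, y, n_lv=1)
    w_direct = X.T @ (y - y.mean())
    w_direct /= np.linalg.norm(w_direct)
    np.testing.assert_allclose(np.abs(model.weights[:, 0]), np.abs(w_direct), atol=1e-12)
    # with 1 LV the regression vector is collinear with w1
    cosine = model.b @ model.weights[:, 0] / np.linalg.norm(model.b)
    assert abs(abs(cosine) - 1.0) < 1e-12


def test_pls_constant_response_rejected():
    X = np.random.default_rng(0).normal(size=(5, 3))
    with pytest.raises(DegenerateInputError):
        sf.plsda_fit(X - X.mean(axis=0), np.ones(5))


def test_full_rank_pls_equals_ols():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 3))
    X -= X.mean(axis=0)
    y = rng.normal(size=8) + 1.5
    model = sf.plsda_fit(X, y, n_lv=3)
    beta, *_ = np.linalg.lstsq(X, y - y.mean(), rcond=None)
    fitted_ols = X @ beta + y.mean()
    np.testing.assert_allclose(model.fitted, fitted_ols, atol=1e-8)


def test_training_predictions_reproduce_nipals_fit(cohort):
    model = sf.DiscriminantModel.fit(cohort, sf.PreprocessConfig(), sf.ModelConfig())
    X = sf.osc_apply(model.osc, model.pipeline.matrix)
    y_hat, _ = sf.plsda_predict(model.pls, X)
    np.testing.assert_allclose(y_hat, model.pls.fitted, atol=1e-10)


def test_predict_tie_goes_to_lc():
    model = sf.PLSDAModel(
        weights=np.ones((1, 1)), scores=np.ones((2, 1)), x_loadings=np.ones((1, 1)),
        y_loadings=np.ones(1), b=np.array([1.0]), intercept=1.5,
        explained_x_variance=np.array([100.0]), fitted=np.array([1.0, 2.0]),
    )
    y_hat, labels = sf.plsda_predict(model, np.array([[0.0]]))
    assert y_hat[0] == 1.5 and labels[0] == "LC"


def test_mean_spectrum_predicts_mean_response(cohort):
    model = sf.DiscriminantModel.fit(cohort, sf.PreprocessConfig(), sf.ModelConfig())
    Xc = sf.osc_apply(model.osc, model.pipeline.matrix)
    y_hat, _ = sf.plsda_predict(model.pls, Xc.mean(axis=0, keepdims=True))
    assert y_hat[0] == pytest.approx(cohort.y.mean(), abs=1e-10)


def test_regression_vector_extrema_near_discriminating_bands(cohort):
    """The classifier's coefficient vector is dominated by the FM/LC bands."""
    model = sf.DiscriminantModel.fit(cohort, sf.PreprocessConfig(), sf.ModelConfig())
    wn = model.pipeline.wavenumbers
    top = wn[np.argsort(-np.abs(model.pls.b))[:2]]
    for w in top:
        assert np.min(np.abs(w - np.array([1565.0, 1581.0, 1588.0]))) <= 10.0


# ---------------------------------------------------------------------------
# LOOCV

def _oracle_loocv(ds, region, n_osc=1):
    """Independent re-implementation via closed forms (1 OSC, 1 LV)."""
    from scipy.signal import savgol_filter

    grid = ds.wavenumbers
    step = float(np.median(np.abs(np.diff(grid))))
    M = ds.absorbance / np.linalg.norm(ds.absorbance, axis=1, keepdims=True)
    M = savgol_filter(M, 5, 2, axis=1, mode="interp")
    M = savgol_filter(M, 7, 2, deriv=2, delta=step, axis=1, mode="interp")
    mask = (grid >= region[0]) & (grid <= region[1])
    Z = M[:, mask]
    y = ds.y
    n = len(ds)
    preds = np.empty(n)
    for i in range(n):
        tr = [j for j in range(n) if j != i]
        Xt = Z[tr] - Z[tr].mean(axis=0)
        yt = y[tr]
        yc = yt - yt.mean()
        Xi = Z[i] - Z[tr].mean(axis=0)
        for _ in range(n_osc):
            s = Xt.T @ yc
            P = np.eye(Xt.shape[1]) - np.outer(s, s) / (s @ s)
            # dominant eigenvector of P X^T X P
            Msym = P @ Xt.T @ Xt @ P
            vals, vecs = np.linalg.eigh(Msym)
            w = vecs[:, -1]
            t = Xt @ w
            p = Xt.T @ t / (t @ t)
            Xt = Xt - np.outer(t, p)
            Xi = Xi - (Xi @ w) * p
        w1 = Xt.T @ yc
        w1 /= np.linalg.norm(w1)
        t1 = Xt @ w1
        q1 = yc @ t1 / (t1 @ t1)
        p1 = Xt.T @ t1 / (t1 @ t1)
        b = w1 * (q1 / (p1 @ w1))
        preds[i] = Xi @ b + yt.mean()
    return preds


def test_loocv_matches_independent_oracle(tiny_cohort):
    pre = sf.PreprocessConfig()
    report = sf.loocv(tiny_cohort, pre, sf.ModelConfig(n_osc=1, n_lv=1))
    oracle = _oracle_loocv(tiny_cohort, pre.region, n_osc=1)
    np.testing.assert_allclose(report.y_hat, oracle, atol=1e-8)


def test_loocv_never_sees_heldout_label(tiny_cohort):
    pre = sf.PreprocessConfig()
    base = sf.loocv(tiny_cohort, pre, sf.ModelConfig())
    flipped = sf.SpectralDataset(
        tiny_cohort.wavenumbers.copy(), tiny_cohort.absorbance.copy(),
        list(tiny_cohort.sample_ids),
        ["LC" if i == 0 else lab for i, lab in enumerate(tiny_cohort.labels)],
    )
    perturbed = sf.loocv(flipped, pre, sf.ModelConfig())
    # prediction of sample 0 is identical; only its residual bookkeeping moves
    assert perturbed.y_hat[0] == pytest.approx(base.y_hat[0], abs=1e-12)


def test_separated_classes_classify_perfectly(tiny_cohort):
    report = sf.loocv(tiny_cohort, sf.PreprocessConfig(), sf.ModelConfig())
    assert report.misclassifications == 0


def test_rcv_permutation_null_shows_no_positive_signal(profiles):
    """Label permutation destroys the CV prediction/response correlation.

    Leakage of the held-out sample into any fitted statistic would shift the
    null Rcv distribution positive; leave-one-out prediction is instead known
    to be slightly *anti*-correlated with the response under the null at
    small n (removing a sample moves the training mean away from it), so the
    assertion is one-sided around zero.
    """
    cfg = sf.SimulationConfig(n_per_class=5, seed=21)
    ds = sf.simulate_cohort([profiles["FM"], profiles["LC"]], cfg)
    rng = np.random.default_rng(0)
    rcvs = []
    for _ in range(40):
        labels = list(ds.labels)
        rng.shuffle(labels)
        if len(set(labels[:5])) == 1:  # keep both classes in both halves
            continue
        shuffled = sf.SpectralDataset(ds.wavenumbers.copy(), ds.absorbance.copy(),
                                      list(ds.sample_ids), labels)
        rcvs.append(sf.loocv(shuffled, sf.PreprocessConfig(), sf.ModelConfig()).rcv)
    assert np.mean(rcvs) < 0.1
    assert np.mean(rcvs) > -0.8


# ---------------------------------------------------------------------------
# external validation

def test_validation_identical_to_training_recovers_training_rmse(tiny_cohort):
    model = sf.DiscriminantModel.fit(tiny_cohort, sf.PreprocessConfig(), sf.ModelConfig())
    ev = sf.external_validate(model, tiny_cohort)
    train_rmse = float(np.sqrt(np.mean((model.pls.fitted - tiny_cohort.y) ** 2)))
    assert ev.sep == pytest.approx(train_rmse, abs=1e-10)


def test_confusion_arithmetic():
    """2 false positives on a 10+10 set give 80% specificity."""
    y_hat = np.array([1.0] * 10 + [1.0, 1.0] + [2.0] * 8)
    labels = ["FM"] * 10 + ["LC"] * 10
    pos = [lab == "FM" for lab in labels]
    pred_pos = y_hat < 1.5
    tp = sum(p and q for p, q in zip(pos, pred_pos))
    tn = sum((not p) and (not q) for p, q in zip(pos, pred_pos))
    fp = sum((not p) and q for p, q in zip(pos, pred_pos))
    fn = sum(p and (not q) for p, q in zip(pos, pred_pos))
    assert (tp, tn, fp, fn) == (10, 8, 2, 0)
    assert 100.0 * tn / (tn + fp) == pytest.approx(80.0)
    assert 100.0 * (tp + tn) / 20 == pytest.approx(90.0)


def test_metrics_invariant_to_sample_order(cohort):
    cfg = sf.ModelConfig(split_seed=11)
    train, val = sf.split_dataset(cohort, cfg)
    model = sf.DiscriminantModel.fit(train, sf.PreprocessConfig(), cfg)
    ev1 = sf.external_validate(model, val)
    perm = np.random.default_rng(5).permutation(len(val))
    ev2 = sf.external_validate(model, val.subset(perm))
    assert ev1.accuracy == ev2.accuracy
    assert ev1.sensitivity == ev2.sensitivity
    assert ev1.specificity == ev2.specificity
    assert (ev1.tp, ev1.tn, ev1.fp, ev1.fn) == (ev2.tp, ev2.tn, ev2.fp, ev2.fn)


# ---------------------------------------------------------------------------
# ROC

def _auc_bruteforce(scores, labels, positive="P"):
    pos = [s for s, lab in zip(scores, labels) if lab == positive]
    neg = [s for s, lab in zip(scores, labels) if lab != positive]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_examples():
    assert sf.roc([1, 2, 3, 4], ["LC", "LC", "FM", "FM"]).auc == pytest.approx(1.0)
    assert sf.roc([1, 2, 3, 4], ["LC", "FM", "LC", "FM"]).auc == pytest.approx(0.75)
    assert sf.roc([1, 1, 1, 1], ["LC", "LC", "FM", "FM"]).auc == pytest.approx(0.5)


def test_roc_auc_equals_pairwise_concordance():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(4, 12))
        scores = np.round(rng.normal(size=n), 1)  # rounding provokes ties
        labels = ["P" if v else "N" for v in rng.integers(0, 2, n)]
        if len(set(labels)) < 2:
            continue
        curve = sf.roc(scores, labels, positive_class="P")
        assert curve.auc == pytest.approx(_auc_bruteforce(scores, labels), abs=1e-12)


def test_roc_direction_less_flips_orientation():
    scores = [1.0, 1.1, 1.9, 2.0]
    labels = ["FM", "FM", "LC", "LC"]
    assert sf.roc(scores, labels, "FM", direction="less").auc == pytest.approx(1.0)
    assert sf.roc(scores, labels, "FM", direction="greater").auc == pytest.approx(0.0)


def test_roc_curve_monotone(cohort):
    cfg = sf.ModelConfig(split_seed=11)
    train, val = sf.split_dataset(cohort, cfg)
    model = sf.DiscriminantModel.fit(train, sf.PreprocessConfig(), cfg)
    ev = sf.external_validate(model, val)
    curve = sf.roc(ev.y_hat, val.labels, "FM", direction="less")
    assert np.all(np.diff(curve.tpr) >= 0) and np.all(np.diff(curve.fpr) >= 0)
    assert 0.0 <= curve.auc <= 1.0


def test_roc_single_class_rejected():
    with pytest.raises(DegenerateInputError):
        sf.roc([1.0, 2.0], ["FM", "FM"])


def test_roc_against_sklearn_oracle():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    scores = rng.normal(size=30)
    truth = rng.integers(0, 2, 30)
    if len(set(truth)) < 2:
        truth[0] = 1 - truth[0]
    labels = ["P" if t else "N" for t in truth]
    curve = sf.roc(scores, labels, positive_class="P")
    assert curve.auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)
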