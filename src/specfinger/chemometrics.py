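"""Orthogonal signal correction, NIPALS PLS-DA, validation and ROC.

The discriminant chain regresses pretreated spectra X onto a dummy-coded
class response (FM = 1, LC = 2).  One or more OSC components are removed
first: each component is a score/loading pair (t, p) with t = Xw chosen to
carry maximal spectral variance while being *exactly* orthogonal to the
response, so deflating X by t p^T strips structured inter-individual
variance that cannot help the classification.  The weight w is constrained
to the orthogonal complement of s = X^T y_c (the dominant singular pair of
the projected matrix), which guarantees y^T t = 0 to machine precision and
makes applying the filter to the training matrix reproduce the fit exactly.

PLS-DA is standard NIPALS PLS1: latent variables maximize X-y covariance;
the regression vector is b = W (P^T W)^{-1} q and predictions are
y_hat = X_new b + y_bar.  Class assignment thresholds y_hat at the midpoint
1.5 (ties go to LC).  Validation follows common chemometrics reporting:
SECV/SEP are root-mean-square residuals with denominator n, Rcv is the
Pearson correlation of cross-validated predictions with the class codes,
R^2 its square on the external set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateInputError, GridError
from .io import LABEL_CODES, SpectralDataset
from .preprocess import PreprocessConfig, FittedPipeline, preprocess_pipeline


@dataclass(frozen=True)
class ModelConfig:
    n_osc: int = 1
    n_lv: int = 1
    class_threshold: float = 1.5
    positive_class: str = "FM"
    split_fraction: float = 0.8
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_osc < 0:
            raise ConfigError("n_osc must be >= 0")
        if self.n_lv < 1:
            raise ConfigError("n_lv must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must be in (0, 1)")
        if self.positive_class not in LABEL_CODES:
            raise ConfigError(f"unknown positive_class {self.positive_class!r}")


# ---------------------------------------------------------------------------
# dataset splitting

def split_dataset(dataset: SpectralDataset, config: ModelConfig) -> tuple[SpectralDataset, SpectralDataset]:
    """Stratified random train/validation split, deterministic per seed.

    Per class, round(split_fraction * n_class) samples go to training; the
    two sets are disjoint and preserve the dataset's sample order within
    each set.
    """
    rng = np.random.default_rng(config.split_seed)
    classes = list(dict.fromkeys(dataset.labels))  # first-appearance order
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in classes:
        idx = np.array([i for i, lab in enumerate(dataset.labels) if lab == cls])
        if idx.size < 2:
            raise DegenerateInputError(f"class {cls!r} has fewer than 2 samples; cannot split")
        n_tr = int(round(config.split_fraction * idx.size))
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[:n_tr]])
        val_idx.extend(idx[perm[n_tr:]])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(val_idx))


# ---------------------------------------------------------------------------
# orthogonal signal correction

@dataclass
class OSCComponent:
    weight: np.ndarray   # spectral space, unit norm, exactly orthogonal to X^T y_c
    loading: np.ndarray  # spectral space
    score: np.ndarray    # training sample space
    removed_variance: float  # fraction of the incoming X sum of squares


@dataclass
class OSCModel:
    components: list[OSCComponent] = field(default_factory=list)

    @property
    def removed_variance(self) -> float:
        return float(sum(c.removed_variance for c in self.components))


def _osc_component(X: np.ndarray, y_c: np.ndarray) -> OSCComponent:
    s = X.T @ y_c
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise DegenerateInputError("response carries no signal in X (X^T y = 0)")
    s = s / s_norm

    # dominant singular pair of X restricted to the orthogonal complement of
    # s: its right vector w lies in range(P_s), so t = Xw is exactly
    # orthogonal to the response
    Xp = X - np.outer(X @ s, s)
    u, sv, vt = np.linalg.svd(Xp, full_matrices=False)
    ss_x = np.sum(X * X)
    if sv[0] ** 2 <= 1e-24 * ss_x:
        # every direction of X is response-correlated: a null component that
        # removes nothing (identity deflation)
        w = np.zeros(X.shape[1])
        w[int(np.argmin(np.abs(s)))] = 1.0
        w -= s * (s @ w)
        w /= np.linalg.norm(w)
        return OSCComponent(weight=w, loading=np.zeros(X.shape[1]),
                            score=np.zeros(X.shape[0]), removed_variance=0.0)
    w = vt[0]
    w -= s * (s @ w)  # exact re-projection against float residue
    w /= np.linalg.norm(w)
    if w[int(np.argmax(np.abs(w)))] < 0:  # deterministic sign
        w = -w
    t = X @ w  # w unit norm => this is X w / (w^T w)
    p = X.T @ t / (t @ t)
    removed = float((t @ t) * (p @ p) / ss_x)
    return OSCComponent(weight=w, loading=p, score=t, removed_variance=removed)


def osc_fit(X: np.ndarray, y: np.ndarray, n_osc: int = 1) -> tuple[OSCModel, np.ndarray]:
    """Fit ``n_osc`` OSC components on a column-centered matrix.

    Returns the model and the corrected matrix X - sum_k t_k p_k^T.  Scores
    are exactly orthogonal to the (centered) response by construction.
    """
    X = np.asarray(X, float).copy()
    y = np.asarray(y, float)
    if np.unique(y).size < 2:
        raise DegenerateInputError("response must take >= 2 distinct values")
    y_c = y - y.mean()
    model = OSCModel()
    for _ in range(n_osc):
        comp = _osc_component(X, y_c)
        X = X - np.outer(comp.score, comp.loading)
        model.components.append(comp)
    return model, X


def osc_apply(model: OSCModel, X_new: np.ndarray) -> np.ndarray:
    """Filter new (training-mean-centered) samples with a fitted OSC model.

    Uses only the stored weights and loadings: t_new = X_new w / (w^T w).
    """
    X = np.asarray(X_new, float).copy()
    for comp in model.components:
        if X.shape[1] != comp.weight.size:
            raise GridError("X_new width does not match the fitted OSC model")
        t = X @ comp.weight / (comp.weight @ comp.weight)
        X = X - np.outer(t, comp.loading)
    return X


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class PLSDAModel:
    weights: np.ndarray      # (p, n_lv)
    scores: np.ndarray       # (n, n_lv) training scores
    x_loadings: np.ndarray   # (p, n_lv)
    y_loadings: np.ndarray   # (n_lv,)
    b: np.ndarray            # regression vector, spectral space
    intercept: float         # training mean of y
    explained_x_variance: np.ndarray  # % of X sum of squares per LV
    fitted: np.ndarray       # training y_hat


def plsda_fit(X: np.ndarray, y: np.ndarray, n_lv: int = 1) -> PLSDAModel:
    """NIPALS PLS1 on centered (and OSC-corrected) X against class codes y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.unique(y).size < 2:
        raise DegenerateInputError("response must take >= 2 distinct values")
    ss_x = np.sum(X * X)
    if ss_x == 0:
        raise DegenerateInputError("X has zero variance")
    Xd = X.copy()
    yd = y - y.mean()
    W, T, P, Q, expl = [], [], [], [], []
    for _ in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise DegenerateInputError("no covariance left for further latent variables")
        w /= nw
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = (yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w); T.append(t); P.append(p); Q.append(q)
        expl.append(100.0 * tt * (p @ p) / ss_x)
    Wm = np.array(W).T
    Pm = np.array(P).T
    Qv = np.array(Q)
    b = Wm @ np.linalg.solve(Pm.T @ Wm, Qv)
    fitted = X @ b + y.mean()
    return PLSDAModel(Wm, np.array(T).T, Pm, Qv, b, float(y.mean()), np.array(expl), fitted)


def plsda_predict(model: PLSDAModel, X_new: np.ndarray,
                  threshold: float = 1.5) -> tuple[np.ndarray, list[str]]:
    """Continuous predictions and hard class assignments.

    y_hat = X_new b + intercept on the 1-2 class-code scale; FM if
    y_hat < threshold else LC (ties assigned LC).
    """
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.b.size:
        raise GridError("X_new width does not match the fitted PLS model")
    y_hat = X_new @ model.b + model.intercept
    labels = ["FM" if v < threshold else "LC" for v in y_hat]
    return y_hat, labels


# ---------------------------------------------------------------------------
# the full discriminant chain

@dataclass
class DiscriminantModel:
    """Preprocessing + OSC + PLS-DA fitted on one training set."""

    pipeline: FittedPipeline
    osc: OSCModel
    pls: PLSDAModel
    config: ModelConfig

    @classmethod
    def fit(cls, train: SpectralDataset, pre_config: PreprocessConfig,
            model_config: ModelConfig) -> "DiscriminantModel":
        pipe = preprocess_pipeline(train, pre_config)
        y = train.y
        osc, Xc = osc_fit(pipe.matrix, y, model_config.n_osc) if model_config.n_osc else (OSCModel(), pipe.matrix)
        pls = plsda_fit(Xc, y, model_config.n_lv)
        return cls(pipe, osc, pls, model_config)

    def predict(self, dataset: SpectralDataset) -> tuple[np.ndarray, list[str]]:
        X = self.pipeline.transform(dataset)
        X = osc_apply(self.osc, X)
        return plsda_predict(self.pls, X, self.config.class_threshold)


# ---------------------------------------------------------------------------
# validation reports

@dataclass
class CVReport:
    secv: float
    rcv: float
    misclassifications: int
    y_hat: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    predicted_labels: list[str]


@dataclass
class EVReport:
    sep: float
    r2: float
    sensitivity: float  # %
    specificity: float  # %
    accuracy: float     # %
    tp: int
    tn: int
    fp: int
    fn: int
    y_hat: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    predicted_labels: list[str]


def loocv(train: SpectralDataset, pre_config: PreprocessConfig,
          model_config: ModelConfig) -> CVReport:
    """Leave-one-out cross-validation re-estimating the *entire* chain.

    Each fold refits the centering means, the OSC filter and the PLS model on
    the n-1 remaining raw spectra, so the held-out sample never influences
    any fitted statistic.
    """
    n = len(train)
    if n < 3:
        raise DegenerateInputError("LOOCV needs at least 3 samples")
    y_hat = np.empty(n)
    labels: list[str] = []
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        model = DiscriminantModel.fit(train.subset(rest), pre_config, model_config)
        pred, lab = model.predict(train.subset([i]))
        y_hat[i] = pred[0]
        labels.append(lab[0])
    y = train.y
    secv = float(np.sqrt(np.mean((y_hat - y) ** 2)))
    rcv = float(np.corrcoef(y_hat, y)[0, 1])
    mis = sum(lab != true for lab, true in zip(labels, train.labels))
    return CVReport(secv, rcv, mis, y_hat, y, list(train.sample_ids), labels)


def external_validate(model: DiscriminantModel, validation: SpectralDataset) -> EVReport:
    """Predict a held-out set and report SEP, R^2 and the confusion metrics."""
    if len(validation) == 0:
        raise DegenerateInputError("validation set is empty")
    y_hat, labels = model.predict(validation)
    y = validation.y
    sep = float(np.sqrt(np.mean((y_hat - y) ** 2)))
    r = np.corrcoef(y_hat, y)[0, 1] if np.unique(y).size > 1 else np.nan
    pos = model.config.positive_class
    tp = sum(p == pos and t == pos for p, t in zip(labels, validation.labels))
    tn = sum(p != pos and t != pos for p, t in zip(labels, validation.labels))
    fp = sum(p == pos and t != pos for p, t in zip(labels, validation.labels))
    fn = sum(p != pos and t == pos for p, t in zip(labels, validation.labels))
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / len(validation)
    return EVReport(sep, float(r**2), sens, spec, acc, tp, tn, fp, fn,
                    y_hat, y, list(validation.sample_ids), labels)


# ---------------------------------------------------------------------------
# ROC

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc(scores, labels, positive_class: str = "FM", direction: str = "greater") -> ROCCurve:
    """Empirical ROC curve and trapezoidal AUC.

    ``direction`` states which way the score points at the positive class:
    "greater" declares a sample positive when score >= threshold (the usual
    convention), "less" when score <= threshold (class-code predictions,
    where the FM code 1 sits *below* the LC code 2).  The trapezoidal AUC
    equals the Mann-Whitney pairwise concordance with ties counted 1/2.
    """
    s = np.asarray(scores, float)
    pos_mask = np.array([lab == positive_class for lab in labels])
    if pos_mask.all() or not pos_mask.any():
        raise DegenerateInputError("ROC needs both classes present")
    if direction == "less":
        s = -s
    elif direction != "greater":
        raise ConfigError(f"unknown direction {direction!r}")
    order = np.argsort(-s, kind="stable")
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    n_pos = pos_mask.sum()
    n_neg = (~pos_mask).sum()
    tpr = np.array([(pos_mask & (s >= th)).sum() / n_pos for th in thresholds])
    fpr = np.array([(~pos_mask & (s >= th)).sum() / n_neg for th in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    # exact tie handling: trapezoid over ties already counts them 1/2
    return ROCCurve(thresholds, tpr, fpr, auc)
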