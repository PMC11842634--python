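"""ErrP detection: xDAWN spatial filtering, Riemannian tangent-space
features, and the cross-validated evaluation protocols.

The detector is the classical xDAWN + Riemannian-geometry stack:

1. **xDAWN** estimates, per class, the evoked response prototype and the
   spatial filters maximizing the ratio of evoked signal power to total
   signal power, via a generalized symmetric eigenproblem.  With
   non-overlapping fixed-length epochs the least-squares evoked estimate
   reduces to the class-mean epoch.
2. **Augmented covariances**: each epoch is stacked with the filtered class
   prototypes ("super-trial"); its shrunken covariance matrix is a symmetric
   positive-definite (SPD) feature capturing both spatial structure and
   similarity to the prototypes.
3. **Tangent space**: SPD matrices live on a Riemannian manifold; they are
   projected to the tangent space at their affine-invariant Riemannian mean,
   yielding Euclidean vectors suitable for a linear model.
4. **Elastic-net logistic regression** classifies the tangent vectors.

Classes are imbalanced roughly 4:1 (non-error:error), so performance is
reported as balanced accuracy, 100 * (TPR + TNR) / 2.

All estimators follow sklearn conventions (fit/transform, trailing
underscore for fitted attributes) and compose in a Pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.covariance import LedoitWolf
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import BANDS, ELECTRODES, bandpass_filter, select_electrodes
from .simulate import SessionData

__all__ = [
    "XdawnFilter", "XdawnCovariances", "TangentSpace",
    "make_errp_classifier", "balanced_accuracy", "CVProtocol",
    "per_user_cv", "zero_shot_generalization", "spatio_spectral_sweep",
    "AccuracyTable", "mean_riemann",
]


# ---------------------------------------------------------------------------
# SPD matrix helpers (eigendecomposition-based matrix functions)

def _eigh_fun(C: np.ndarray, fun) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    return (vecs * fun(vals)) @ vecs.T


def _sqrtm(C: np.ndarray) -> np.ndarray:
    return _eigh_fun(C, np.sqrt)


def _invsqrtm(C: np.ndarray) -> np.ndarray:
    return _eigh_fun(C, lambda v: 1.0 / np.sqrt(v))


def _logm(C: np.ndarray) -> np.ndarray:
    return _eigh_fun(C, np.log)


def _expm(S: np.ndarray) -> np.ndarray:
    return _eigh_fun(S, np.exp)


def mean_riemann(covs: np.ndarray, tol: float = 1e-10,
                 max_iter: int = 100) -> np.ndarray:
    """Affine-invariant Riemannian mean of SPD matrices.

    Fixed-point iteration: starting from the arithmetic mean M, repeatedly
    set ``M <- M^1/2 exp(mean_i log(M^-1/2 C_i M^-1/2)) M^1/2`` until the
    tangent-space mean has negligible Frobenius norm.
    """
    covs = np.asarray(covs, dtype=float)
    M = covs.mean(axis=0)
    for _ in range(max_iter):
        M_isq, M_sq = _invsqrtm(M), _sqrtm(M)
        T = np.mean([_logm(M_isq @ C @ M_isq) for C in covs], axis=0)
        M = M_sq @ _expm(T) @ M_sq
        if np.linalg.norm(T) < tol:
            break
    return M


def _check_spd(C: np.ndarray, name: str = "covariance") -> None:
    vals = np.linalg.eigvalsh(C)
    if vals.min() <= 0:
        raise ValueError(f"{name} is not positive-definite "
                         f"(min eigenvalue {vals.min():.3g})")


# ---------------------------------------------------------------------------
# xDAWN

class XdawnFilter(BaseEstimator, TransformerMixin):
    """Per-class xDAWN spatial filters for epoched data.

    For each class the evoked prototype is the class-mean epoch (the
    least-squares estimate for non-overlapping windows); the filters solve
    the generalized eigenproblem ``Sigma_evoked w = lambda Sigma_total w``
    and are kept unit-norm.  ``transform`` applies all classes' filters,
    returning epochs of shape (n_trials, n_classes * n_filters, n_samples).

    Attributes
    ----------
    classes_ : ndarray of the class labels seen in fit.
    filters_ : (n_classes * n_filters, n_channels) stacked filters.
    patterns_ : matching spatial patterns (columns of Sigma_total @ W).
    evokeds_ : (n_classes, n_channels, n_samples) class prototypes.
    """

    def __init__(self, n_filters: int = 4, reg: float = 1e-9):
        self.n_filters = n_filters
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("expected trials x channels x samples")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("xDAWN requires at least two classes")
        n, c, s = X.shape
        cov_total = np.einsum("ncs,nds->cd", X, X) / (n * s)
        cov_total += self.reg * np.trace(cov_total) / c * np.eye(c)
        nf = min(self.n_filters, c)
        filters, patterns, evokeds = [], [], []
        for k in self.classes_:
            P = X[y == k].mean(axis=0)
            cov_evoked = P @ P.T / s
            vals, vecs = linalg.eigh(cov_evoked, cov_total)
            order = np.argsort(vals)[::-1][:nf]
            W = vecs[:, order]
            W = W / np.linalg.norm(W, axis=0, keepdims=True)
            filters.append(W.T)
            A = cov_total @ W
            patterns.append((A / np.linalg.norm(A, axis=0, keepdims=True)).T)
            evokeds.append(P)
        self.n_filters_ = nf
        self.filters_ = np.concatenate(filters, axis=0)
        self.patterns_ = np.concatenate(patterns, axis=0)
        self.evokeds_ = np.stack(evokeds)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.einsum("fc,ncs->nfs", self.filters_, X)


class XdawnCovariances(BaseEstimator, TransformerMixin):
    """xDAWN-augmented shrunken epoch covariances (SPD features).

    Each epoch is stacked with the per-class filtered prototypes and the
    covariance of the stack is estimated with Ledoit-Wolf shrinkage toward
    scaled identity, guaranteeing positive-definiteness at the 16-ish
    dimensions of the augmented super-trials.
    """

    def __init__(self, n_filters: int = 4):
        self.n_filters = n_filters

    def fit(self, X, y):
        self.xdawn_ = XdawnFilter(n_filters=self.n_filters).fit(X, y)
        nf = self.xdawn_.n_filters_
        protos = []
        for i, _ in enumerate(self.xdawn_.classes_):
            Wk = self.xdawn_.filters_[i * nf:(i + 1) * nf]
            protos.append(Wk @ self.xdawn_.evokeds_[i])
        self.prototypes_ = np.concatenate(protos, axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        filtered = self.xdawn_.transform(X)
        covs = []
        lw = LedoitWolf(assume_centered=True)
        for epoch in filtered:
            Z = np.concatenate([self.prototypes_, epoch], axis=0)
            C = lw.fit(Z.T).covariance_
            _check_spd(C, "shrunken augmented covariance")
            covs.append(C)
        return np.stack(covs)


class TangentSpace(BaseEstimator, TransformerMixin):
    """Project SPD matrices to the tangent space at their Riemannian mean.

    ``transform`` maps C to ``upper(log(M^-1/2 C M^-1/2))`` where M is the
    affine-invariant mean of the training covariances and ``upper`` takes
    the diagonal plus sqrt(2)-weighted off-diagonal upper triangle, so the
    Euclidean norm of the vector equals the Riemannian distance to M.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = mean_riemann(X)
        self.whitener_ = _invsqrtm(self.mean_)
        d = X.shape[1]
        self._iu = np.triu_indices(d)
        weights = np.full((d, d), np.sqrt(2.0))
        np.fill_diagonal(weights, 1.0)
        self._weights = weights[self._iu]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = []
        for C in X:
            S = _logm(self.whitener_ @ C @ self.whitener_)
            out.append(S[self._iu] * self._weights)
        return np.stack(out)

    def inverse_transform(self, V):
        V = np.asarray(V, dtype=float)
        d = self.mean_.shape[0]
        sqrt_mean = _sqrtm(self.mean_)
        out = []
        for v in V:
            S = np.zeros((d, d))
            S[self._iu] = v / self._weights
            S = S + S.T - np.diag(np.diag(S))
            out.append(sqrt_mean @ _expm(S) @ sqrt_mean)
        return np.stack(out)


def make_errp_classifier(n_filters: int = 4, seed: int | None = 0,
                         inner_cv: bool = True) -> Pipeline:
    """The full detection pipeline: xDAWN covariances -> tangent space ->
    standardization -> elastic-net logistic regression.

    ``inner_cv=True`` selects the regularization strength by inner 3-fold
    cross-validation (mixing parameter fixed at 0.5); ``inner_cv=False``
    uses a fixed strength, trading a little accuracy for speed.
    """
    if inner_cv:
        head = LogisticRegressionCV(
            Cs=[0.05, 0.5, 5.0], cv=3, l1_ratios=[0.5], solver="saga",
            max_iter=3000, random_state=seed)
    else:
        head = LogisticRegression(
            C=1.0, l1_ratio=0.5, solver="saga", max_iter=3000,
            random_state=seed)
    return Pipeline([
        ("cov", XdawnCovariances(n_filters=n_filters)),
        ("tangent", TangentSpace()),
        ("scale", StandardScaler()),
        ("logreg", head),
    ])


def balanced_accuracy(labels, predictions) -> float:
    """100 * (TPR + TNR) / 2; robust to the ~4:1 class imbalance."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return 100.0 * balanced_accuracy_score(labels, predictions)


# ---------------------------------------------------------------------------
# Evaluation protocols

@dataclass(frozen=True)
class CVProtocol:
    """Cross-validation protocol: stratified ``folds``-fold CV repeated
    ``repetitions`` times per user (20 runs at the 5 x 4 defaults), the whole
    procedure repeated ``outer_repeats`` times for a mean and sd."""

    folds: int = 5
    repetitions: int = 4
    outer_repeats: int = 10
    mode: str = "per_user_cv"
    pooled_ratio: tuple[int, int, int] = (50, 25, 25)
    seed: int = 0

    @property
    def runs_per_user(self) -> int:
        return self.folds * self.repetitions


def _fit_score(clf, X, y, train, test) -> float:
    model = clone(clf)
    model.fit(X[train], y[train])
    return balanced_accuracy(y[test], model.predict(X[test]))


def per_user_cv(session: SessionData, protocol: CVProtocol = CVProtocol(),
                clf: Pipeline | None = None
                ) -> tuple[float, float, np.ndarray]:
    """Within-user repeated stratified CV balanced accuracy.

    Returns (mean, sd, per-outer-repeat accuracies); each outer repeat is
    the mean over ``folds x repetitions`` runs with freshly seeded folds.
    """
    if clf is None:
        clf = make_errp_classifier(seed=protocol.seed)
    X, y = session.epochs, session.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < protocol.folds:
        raise ValueError(
            f"minority class has {counts.min()} trials; cannot build "
            f"{protocol.folds} stratified folds")
    seeds = np.random.SeedSequence(protocol.seed).spawn(
        protocol.outer_repeats)
    outer = np.empty(protocol.outer_repeats)
    for i in range(protocol.outer_repeats):
        rs = int(seeds[i].generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        rskf = RepeatedStratifiedKFold(n_splits=protocol.folds,
                                       n_repeats=protocol.repetitions,
                                       random_state=rs)
        accs = [_fit_score(clf, X, y, tr, te)
                for tr, te in rskf.split(X, y)]
        outer[i] = np.mean(accs)
    return float(outer.mean()), float(outer.std()), outer


def zero_shot_generalization(cohort: list[SessionData], mode: str = "one_v_one",
                             protocol: CVProtocol = CVProtocol(),
                             clf: Pipeline | None = None,
                             preprocess: bool = True
                             ) -> tuple[float, float, np.ndarray]:
    """Cross-user transfer accuracy without target-user training data.

    ``one_v_one``: train on one user, test on another, over all ordered
    pairs.  ``one_v_rest``: train on all users but one, test on the held-out
    user.  Data is broadband-filtered (F1) on the full montage (E1) unless
    ``preprocess=False``.  Returns (mean, sd over outer repeats, outer
    values).
    """
    if len(cohort) < 2:
        raise ValueError("generalization needs at least two users")
    if mode not in ("one_v_one", "one_v_rest"):
        raise ValueError(f"unknown mode {mode!r}")
    if preprocess:
        cohort = [bandpass_filter(select_electrodes(s, ELECTRODES["E1"]),
                                  BANDS["F1"]) for s in cohort]
    seeds = np.random.SeedSequence(protocol.seed).spawn(
        protocol.outer_repeats)
    outer = np.empty(protocol.outer_repeats)
    for rep in range(protocol.outer_repeats):
        rs = int(seeds[rep].generate_state(1, dtype=np.uint32)[0]
                 % (2 ** 31))
        model = clf if clf is not None else make_errp_classifier(seed=rs)
        accs = []
        for j, test_session in enumerate(cohort):
            if mode == "one_v_one":
                train_sets = [cohort[i] for i in range(len(cohort)) if i != j]
                for train_session in train_sets:
                    m = clone(model)
                    m.fit(train_session.epochs, train_session.labels)
                    accs.append(balanced_accuracy(
                        test_session.labels,
                        m.predict(test_session.epochs)))
            else:
                rest = [s for i, s in enumerate(cohort) if i != j]
                X = np.concatenate([s.epochs for s in rest])
                y = np.concatenate([s.labels for s in rest])
                m = clone(model)
                m.fit(X, y)
                accs.append(balanced_accuracy(
                    test_session.labels, m.predict(test_session.epochs)))
        outer[rep] = np.mean(accs)
    return float(outer.mean()), float(outer.std()), outer


@dataclass
class AccuracyTable:
    """Mean +/- sd balanced accuracy (%) for the nine spatio-spectral cells."""

    dataset_tag: str
    model_tag: str
    cells: dict[str, tuple[float, float]]

    def as_dataframe(self):
        import pandas as pd
        rows = [{"cell": c, "mean": m, "sd": s}
                for c, (m, s) in self.cells.items()]
        return pd.DataFrame(rows)

    def format_text(self) -> str:
        header = ["Dataset", "Model"] + list(self.cells)
        values = [self.dataset_tag, self.model_tag] + [
            f"{m:.2f} ± {s:.2f}" for m, s in self.cells.values()]
        widths = [max(len(h), len(v)) for h, v in zip(header, values)]
        line = "  ".join(h.ljust(w) for h, w in zip(header, widths))
        vals = "  ".join(v.ljust(w) for v, w in zip(values, widths))
        return line + "\n" + vals


def spatio_spectral_sweep(cohort: list[SessionData],
                          grid=None,
                          protocol: CVProtocol = CVProtocol(),
                          clf: Pipeline | None = None,
                          dataset_tag: str = "synthetic",
                          model_tag: str = "xDAWN+RG") -> AccuracyTable:
    """Per-user CV accuracy for every (electrode, band) cell of the grid.

    For each cell, every session is channel-subset and band-passed, then
    evaluated with :func:`per_user_cv`; user accuracies are averaged per
    outer repeat and the cell reports mean +/- sd over outer repeats.
    """
    from .preprocess import spatio_spectral_grid
    if grid is None:
        grid = spatio_spectral_grid()
    cells: dict[str, tuple[float, float]] = {}
    for electrode, band in grid:
        per_user_outers = []
        for session in cohort:
            prepared = bandpass_filter(select_electrodes(session, electrode),
                                       band)
            _, _, outer = per_user_cv(prepared, protocol, clf=clf)
            per_user_outers.append(outer)
        dataset_outer = np.mean(per_user_outers, axis=0)
        cells[f"{electrode.name}{band.name}"] = (
            float(dataset_outer.mean()), float(dataset_outer.std()))
    return AccuracyTable(dataset_tag=dataset_tag, model_tag=model_tag,
                        cells=cells)
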