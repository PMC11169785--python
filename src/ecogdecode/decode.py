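"""Buffered temporal cross-validation and shared-covariance LDA.

The decoding protocol mirrors standard practice for long naturalistic
recordings:

* bins are ordered in time and split into ``n_folds`` contiguous folds
  (default 7); for each test fold, any fold within ``buffer_folds``
  (default 1) of it on either side is excluded from training, so slow
  autocorrelation cannot leak state information across the split;
* within every fold, training and test sets are separately balanced by
  random downsampling to the minority class;
* training and test sets are z-scored independently (sample SD,
  ddof=1), removing slow drifts and per-electrode scale;
* an equal-covariance LDA is fitted: per-class means plus one pooled
  within-class covariance (with a small ridge for conditioning), so
  the class-mean difference is the only discriminative parameter.

Per (ROI, band) evaluation returns one :class:`FoldOutcome` per fold:
the test accuracy and the fitted class-mean difference (first class
minus second, per electrode and averaged over electrodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureTable
from .roimap import RoiAssignment, roi_feature_slice

__all__ = [
    "FoldScheme",
    "LdaModel",
    "FoldOutcome",
    "make_folds",
    "balance_classes",
    "zscore_split",
    "fit_lda_shared",
    "predict_lda",
    "evaluate_feature",
    "evaluate_multiclass",
    "incremental_roi_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldScheme:
    """Temporally ordered contiguous folds with a train/test buffer."""

    n_folds: int
    fold_of_bin: np.ndarray
    buffer_folds: int = 1

    @property
    def n_bins(self) -> int:
        return self.fold_of_bin.size

    def train_folds(self, test_fold: int) -> list[int]:
        """Folds usable for training when ``test_fold`` is held out."""
        return [k for k in range(self.n_folds)
                if abs(k - test_fold) > self.buffer_folds]

    def split(self, test_fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_rows, test_rows) into the kept-bin axis."""
        train = np.flatnonzero(np.isin(self.fold_of_bin,
                                       self.train_folds(test_fold)))
        test = np.flatnonzero(self.fold_of_bin == test_fold)
        return train, test


@dataclass(frozen=True)
class LdaModel:
    """Equal-covariance linear discriminant model."""

    classes: tuple[str, ...]
    class_means: np.ndarray          # (n_classes, n_features), z-units
    shared_cov: np.ndarray           # (n_features, n_features)
    priors: np.ndarray               # (n_classes,)

    def mean_difference(self) -> np.ndarray:
        """Per-feature difference of fitted means, first class minus
        second (two-class models only)."""
        if len(self.classes) != 2:
            raise ValueError("mean difference is defined for 2-class models")
        return self.class_means[0] - self.class_means[1]


@dataclass(frozen=True)
class FoldOutcome:
    """Result of one cross-validation fold."""

    fold: int
    accuracy: float
    n_test: int
    mean_diff: np.ndarray | None = None       # per-feature, class A - class B
    mean_diff_scalar: float | None = None     # averaged over features


def make_folds(n_bins: int, n_folds: int = 7, buffer_folds: int = 1) -> FoldScheme:
    """Contiguous temporal folds with sizes differing by at most one."""
    if n_bins < n_folds * 2:
        raise ValueError(f"{n_bins} bins is too few for {n_folds} folds")
    sizes = np.full(n_folds, n_bins // n_folds)
    sizes[:n_bins % n_folds] += 1
    fold_of_bin = np.repeat(np.arange(n_folds), sizes)
    scheme = FoldScheme(n_folds=n_folds, fold_of_bin=fold_of_bin,
                        buffer_folds=buffer_folds)
    for k in range(n_folds):
        if not scheme.train_folds(k):
            raise ValueError(
                f"buffer_folds={buffer_folds} leaves no training data for "
                f"fold {k}")
    return scheme


def balance_classes(bin_indices: np.ndarray, labels: np.ndarray,
                    seed: int | np.random.Generator,
                    classes=None) -> np.ndarray:
    """Downsample each class to the minority count.

    Removal is by uniform random subsampling without replacement;
    output preserves temporal order.  When ``classes`` is given, every
    listed class must be present.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.Generator(np.random.SFC64(np.random.SeedSequence(seed)))
    bin_indices = np.asarray(bin_indices)
    labs = np.asarray(labels, dtype=object)
    if classes is None:
        classes = sorted(set(labs.tolist()), key=str)
    else:
        classes = list(classes)
    counts = {c: int((labs == c).sum()) for c in classes}
    absent = [str(c) for c, n in counts.items() if n == 0]
    if absent or not classes:
        raise ValueError(f"cannot balance: class(es) absent: {absent}")
    n_min = min(counts.values())
    keep: list[np.ndarray] = []
    for c in classes:
        rows = np.flatnonzero(labs == c)
        if rows.size > n_min:
            rows = rng.choice(rows, size=n_min, replace=False)
        keep.append(rows)
    sel = np.sort(np.concatenate(keep))
    return bin_indices[sel]


def zscore_split(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize train and test independently (each with its own
    per-feature mean and sample SD).  Constant features map to zero."""
    out = []
    for X in (train, test):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("z-scoring needs at least 2 rows per set")
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        bad = sd == 0
        if bad.any():
            logger.warning("%d constant feature(s) set to zero in z-scoring",
                           int(bad.sum()))
            sd = np.where(bad, 1.0, sd)
        Z = (X - mu) / sd
        Z[:, bad] = 0.0
        out.append(Z)
    return out[0], out[1]


def fit_lda_shared(train_z: np.ndarray, labels: np.ndarray,
                   ridge: float = 1e-3,
                   classes: tuple[str, ...] | None = None) -> LdaModel:
    """Fit per-class means and one pooled within-class covariance.

    The covariance is shared across classes by construction; a ridge
    ``ridge * I`` guarantees invertibility (features are z-scored, so
    unit scale).  Priors are uniform (balanced input expected).
    """
    X = np.asarray(train_z, dtype=float)
    labs = np.asarray(labels, dtype=object)
    if classes is None:
        classes = tuple(sorted(set(labs.tolist()), key=str))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    means = np.empty((len(classes), p))
    scatter = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xc = X[labs == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} needs more than 1 training row")
        means[i] = Xc.mean(axis=0)
        d = Xc - means[i]
        scatter += d.T @ d
    cov = scatter / (n - len(classes))
    cov = cov + ridge * np.eye(p)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular even after the ridge; increase "
            "the ridge parameter") from exc
    priors = np.full(len(classes), 1.0 / len(classes))
    return LdaModel(classes=tuple(classes), class_means=means,
                    shared_cov=cov, priors=priors)


def predict_lda(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Classify rows by the linear discriminant score.

    score_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log prior_c;
    ties go to the first class in model order.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError("feature dimension does not match the model")
    Sinv_mu = np.linalg.solve(model.shared_cov, model.class_means.T)  # p x k
    scores = X @ Sinv_mu
    scores -= 0.5 * np.sum(model.class_means.T * Sinv_mu, axis=0)
    scores += np.log(model.priors)
    idx = np.argmax(scores, axis=1)  # argmax returns the first max: tie-break
    return np.array([model.classes[i] for i in idx], dtype=object)


def _fold_seed(base: np.random.SeedSequence | int, *key: int) -> np.random.Generator:
    ss = base if isinstance(base, np.random.SeedSequence) \
        else np.random.SeedSequence(base)
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(key))
    return np.random.Generator(np.random.SFC64(child))


def _run_folds(X: np.ndarray, labels: np.ndarray, scheme: FoldScheme,
               classes: tuple[str, ...], seed, ridge: float = 1e-3,
               train_rows_map=None) -> list[FoldOutcome]:
    """Shared fold loop: balance -> z-score -> fit -> predict."""
    outcomes: list[FoldOutcome] = []
    for k in range(scheme.n_folds):
        train, test = scheme.split(k)
        if train_rows_map is not None:
            train = train_rows_map(k, train)
        train = train[np.isin(labels[train], classes)]
        test = test[np.isin(labels[test], classes)]
        if train.size == 0 or test.size == 0:
            logger.warning("fold %d empty after masking; skipped", k)
            continue
        rng = _fold_seed(seed, k)
        try:
            train = balance_classes(train, labels[train], rng, classes=classes)
            test = balance_classes(test, labels[test], rng, classes=classes)
        except ValueError as exc:
            logger.warning("fold %d skipped: %s", k, exc)
            continue
        if train.size < 4 or test.size < 2:
            logger.warning("fold %d too small after balancing; skipped", k)
            continue
        train_z, test_z = zscore_split(X[train], X[test])
        model = fit_lda_shared(train_z, labels[train], ridge=ridge,
                               classes=classes)
        pred = predict_lda(model, test_z)
        acc = float(np.mean(pred == labels[test]))
        if len(classes) == 2:
            md = model.mean_difference()
            outcomes.append(FoldOutcome(fold=k, accuracy=acc, n_test=test.size,
                                        mean_diff=md,
                                        mean_diff_scalar=float(md.mean())))
        else:
            outcomes.append(FoldOutcome(fold=k, accuracy=acc, n_test=test.size))
    return outcomes


def evaluate_feature(table: FeatureTable, assignment: RoiAssignment,
                     roi: str, band: str, scheme: FoldScheme,
                     class_pair: tuple[str, str], seed,
                     ridge: float = 1e-3) -> list[FoldOutcome]:
    """Buffered-CV LDA accuracy and mean difference for one (ROI, band).

    ``mean_diff`` follows the convention first class of ``class_pair``
    minus the second (per electrode; ``mean_diff_scalar`` averages over
    the ROI's electrodes).
    """
    X, labels = roi_feature_slice(table, assignment, roi, band)
    if scheme.n_bins != X.shape[0]:
        raise ValueError("fold scheme does not match the kept-bin count")
    return _run_folds(X, labels, scheme, tuple(class_pair), seed, ridge)


def _all_roi_matrix(table: FeatureTable, assignment: RoiAssignment,
                    band: str, rois=None) -> tuple[np.ndarray, np.ndarray]:
    rois = list(assignment.retained_rois) if rois is None else list(rois)
    mats, labels = [], None
    for roi in rois:
        X, labels = roi_feature_slice(table, assignment, roi, band)
        mats.append(X)
    return np.hstack(mats), labels


def evaluate_multiclass(table: FeatureTable, assignment: RoiAssignment,
                        bands, scheme: FoldScheme, classes, seed,
                        ridge: float = 1e-3) -> dict[str, list[FoldOutcome]]:
    """Per-band multiclass decoding using all retained-ROI electrodes.

    Balancing downsamples every class to the smallest class count; with
    two classes this reduces to the two-class protocol.
    """
    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    out: dict[str, list[FoldOutcome]] = {}
    for band in bands:
        name = band if isinstance(band, str) else band.name
        X, labels = _all_roi_matrix(table, assignment, name)
        out[name] = _run_folds(X, labels, scheme, classes, seed, ridge)
    return out


def incremental_roi_curve(table: FeatureTable, assignment: RoiAssignment,
                          band: str, scheme: FoldScheme,
                          class_pair: tuple[str, str], seed,
                          ridge: float = 1e-3) -> list[tuple[int, float]]:
    """Test accuracy as electrodes from the top-1, top-2, ... ROIs are
    concatenated.

    ROIs are ranked on a validation set: within each test fold's
    training partition, the training fold most distant in time from
    the test fold is held out, single-ROI models are trained on the
    remainder and scored on it, and ranks use the validation accuracy
    averaged over folds.  The reported curve is the buffered test-fold
    accuracy (validation fold excluded from training), averaged over
    folds, for each prefix of the ranking.
    """
    rois = list(assignment.retained_rois)
    if len(rois) < 2:
        if len(rois) == 1:
            outc = evaluate_feature(table, assignment, rois[0], band, scheme,
                                    class_pair, seed, ridge)
            return [(1, float(np.mean([o.accuracy for o in outc])))]
        raise ValueError("need at least one retained ROI")
    if scheme.n_folds < 3:
        raise ValueError("validation + test requires at least 3 folds")
    classes = tuple(class_pair)

    # per-fold validation fold: the training fold farthest from the test fold
    val_fold = {}
    for k in range(scheme.n_folds):
        tf = scheme.train_folds(k)
        if len(tf) < 2:
            raise ValueError("buffer leaves no room for a validation fold")
        val_fold[k] = max(tf, key=lambda f: abs(f - k))

    def train_minus_val(k, train):
        return train[scheme.fold_of_bin[train] != val_fold[k]]

    # rank ROIs by mean validation accuracy of single-ROI models
    val_acc = {}
    for roi in rois:
        X, labels = roi_feature_slice(table, assignment, roi, band)
        accs = []
        for k in range(scheme.n_folds):
            train, _ = scheme.split(k)
            vrows = train[scheme.fold_of_bin[train] == val_fold[k]]
            trows = train_minus_val(k, train)
            trows = trows[np.isin(labels[trows], classes)]
            vrows = vrows[np.isin(labels[vrows], classes)]
            if trows.size < 4 or vrows.size < 2:
                continue
            rng = _fold_seed(seed, k, 101)
            try:
                trows = balance_classes(trows, labels[trows], rng)
                vrows = balance_classes(vrows, labels[vrows], rng)
            except ValueError:
                continue
            if trows.size < 4 or vrows.size < 2:
                continue
            tz, vz = zscore_split(X[trows], X[vrows])
            model = fit_lda_shared(tz, labels[trows], ridge=ridge,
                                   classes=classes)
            accs.append(float(np.mean(predict_lda(model, vz) == labels[vrows])))
        val_acc[roi] = float(np.mean(accs)) if accs else 0.0
    ranking = sorted(rois, key=lambda r: (-val_acc[r], rois.index(r)))

    curve: list[tuple[int, float]] = []
    for m in range(1, len(ranking) + 1):
        X, labels = _all_roi_matrix(table, assignment, band, ranking[:m])
        outcomes = _run_folds(X, labels, scheme, classes, seed, ridge,
                              train_rows_map=train_minus_val)
        acc = float(np.mean([o.accuracy for o in outcomes])) if outcomes else np.nan
        curve.append((m, acc))
    return curve
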