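"""Linear-SVM multivariate pattern analysis of DC z-maps.

Each subject's in-mask map is one point in voxel space; a soft-margin
linear SVM (C defaults to 1) separates patients from controls.  The
cross-validation scheme holds out one subject from *each* group per fold
(``folds = min(n_patients, n_controls)``, deterministic subject-order
pairing), metrics are computed from the pooled held-out predictions, AUC
from the pooled decision values via the rank (Mann-Whitney) formulation,
and significance comes from whole-sample label permutations that re-run
the full cross-validation (add-one p convention).

The trained whole-sample weight vector is mapped back to voxel space;
the voxels carrying the top fraction of |weight| (default 20%) localize
the discriminative pattern, optionally summarized per region of a
user-supplied integer label image as percent of total |weight|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .errors import InputError
from .images import VolumeMap

PATIENT_LABEL, CONTROL_LABEL = 1, 0


@dataclass
class FeatureMatrix:
    """Subjects-by-voxels feature matrix with class labels.

    Column order is the C scan order of the mask (the same deterministic
    ordering the connectome module uses), recorded in ``voxel_index``.
    """

    x: np.ndarray               # (n_subjects, n_voxels)
    y: np.ndarray               # (n_subjects,) 1 = patient, 0 = control
    voxel_index: np.ndarray     # (n_voxels,) flat indices into the grid
    grid_shape: tuple = ()
    affine: np.ndarray | None = None
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.x.ndim != 2 or self.x.shape[0] != self.y.size:
            raise InputError("feature matrix and labels are inconsistent")
        if np.isnan(self.x).any():
            raise InputError("feature matrix contains NaN inside the mask")
        if set(np.unique(self.y)) - {0, 1}:
            raise InputError("labels must be 0 (control) / 1 (patient)")


@dataclass
class CrossValResult:
    predictions: np.ndarray      # pooled held-out predicted labels
    decision_values: np.ndarray  # pooled signed decision values (patient > 0)
    true_labels: np.ndarray
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    accuracy: float = 0.0        # percent
    sensitivity: float = 0.0     # percent
    specificity: float = 0.0     # percent
    auc: float = 0.0
    n_folds: int = 0

    def metrics(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc,
                "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Accuracy / sensitivity / specificity (percent) from confusion counts."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise InputError(f"{name} must be >= 0, got {v}")
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be represented")
    return {
        "accuracy": 100.0 * (tp + tn) / (n_pos + n_neg),
        "sensitivity": 100.0 * tp / n_pos,
        "specificity": 100.0 * tn / n_neg,
    }


def build_feature_matrix(maps, mask: np.ndarray, labels,
                         subject_ids=None) -> FeatureMatrix:
    """Stack per-subject maps into (subjects, in-mask voxels)."""
    mask = np.asarray(mask, dtype=bool)
    flat_idx = np.flatnonzero(mask.ravel())
    rows = []
    for m in maps:
        if m.grid_shape != mask.shape:
            raise InputError("map grid does not match mask")
        rows.append(m.data.ravel()[flat_idx])
    y = np.asarray([PATIENT_LABEL if l in (1, "patient") else CONTROL_LABEL
                    for l in labels])
    if y.sum() == 0 or y.sum() == y.size:
        raise InputError("labels must cover both classes")
    return FeatureMatrix(x=np.vstack(rows), y=y, voxel_index=flat_idx,
                         grid_shape=mask.shape,
                         affine=None if not len(maps) else maps[0].affine,
                         subject_ids=list(subject_ids) if subject_ids is not None else [])


def roc_auc(decision_values, labels) -> float:
    """AUC via the rank (Mann-Whitney) formulation; ties count 0.5."""
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks implement the tie convention
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def _fit_svm(x, y, c):
    clf = SVC(kernel="linear", C=c)
    clf.fit(x, y)
    return clf


def _decision_patient_positive(clf, x) -> np.ndarray:
    dec = clf.decision_function(x)
    # sklearn orients the decision function toward classes_[1]
    return dec if clf.classes_[1] == PATIENT_LABEL else -dec


def loocv_classify(features: FeatureMatrix, svm_c: float = 1.0, *,
                   pair_folds: bool = True, standardize: bool = False,
                   labels=None, pair_rng=None) -> CrossValResult:
    """Leave-one-(per-group)-out cross-validation of the linear SVM.

    With ``pair_folds`` (default) fold k removes the k-th patient and the
    k-th control in subject order and tests both; the non-default variant
    leaves a single subject out per fold.  ``pair_rng`` optionally
    shuffles the within-group pairing order (seeded) instead of using
    subject order.  ``labels`` overrides the stored labels (used by the
    permutation test).
    """
    x = features.x
    y = features.y if labels is None else np.asarray(labels, dtype=int)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if pair_rng is not None:
        gen = np.random.default_rng(pair_rng)
        idx_pos = gen.permutation(idx_pos)
        idx_neg = gen.permutation(idx_neg)
    if idx_pos.size < 3 or idx_neg.size < 3:
        raise InputError("need >= 3 subjects per group for cross-validation")

    folds = []
    if pair_folds:
        for k in range(min(idx_pos.size, idx_neg.size)):
            folds.append(np.array([idx_pos[k], idx_neg[k]]))
    else:
        folds = [np.array([i]) for i in range(y.size)]

    n = y.size
    preds = np.empty(n, dtype=int)
    decs = np.empty(n, dtype=float)
    tested = np.zeros(n, dtype=bool)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise InputError("a training fold lost one class entirely")
        x_train, x_test = x[train], x[test]
        if standardize:
            mu = x_train.mean(axis=0)
            sd = x_train.std(axis=0)
            sd[sd == 0] = 1.0
            x_train = (x_train - mu) / sd
            x_test = (x_test - mu) / sd
        clf = _fit_svm(x_train, y_train, svm_c)
        dec = _decision_patient_positive(clf, x_test)
        preds[test] = (dec > 0).astype(int)
        decs[test] = dec
        tested[test] = True

    preds, decs, y_t = preds[tested], decs[tested], y[tested]
    tp = int(((preds == 1) & (y_t == 1)).sum())
    fn = int(((preds == 0) & (y_t == 1)).sum())
    tn = int(((preds == 0) & (y_t == 0)).sum())
    fp = int(((preds == 1) & (y_t == 0)).sum())
    m = confusion_metrics(tp, fn, tn, fp)
    return CrossValResult(
        predictions=preds, decision_values=decs, true_labels=y_t,
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=m["accuracy"], sensitivity=m["sensitivity"],
        specificity=m["specificity"], auc=roc_auc(decs, y_t),
        n_folds=len(folds),
    )


def permutation_test(features: FeatureMatrix, n_permutations: int,
                     rng=None, svm_c: float = 1.0, *,
                     metrics=("accuracy", "sensitivity", "specificity", "auc"),
                     pair_folds: bool = True,
                     observed: CrossValResult | None = None) -> dict:
    """Whole-sample label-permutation significance of the CV metrics.

    Each repetition permutes the labels over all subjects and re-runs the
    full cross-validation; p = (#{null >= observed} + 1)/(B + 1).
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    rng = np.random.default_rng(rng)
    if observed is None:
        observed = loocv_classify(features, svm_c, pair_folds=pair_folds)
    obs = observed.metrics()
    null = {m: np.empty(n_permutations) for m in metrics}
    for b in range(n_permutations):
        y_perm = rng.permutation(features.y)
        res = loocv_classify(features, svm_c, pair_folds=pair_folds, labels=y_perm)
        got = res.metrics()
        for m in metrics:
            null[m][b] = got[m]
    p = {m: float((np.sum(null[m] >= obs[m]) + 1) / (n_permutations + 1))
         for m in metrics}
    return {"p": p, "observed": obs, "null": null, "n_permutations": n_permutations}


@dataclass
class WeightMap:
    weights: np.ndarray          # per in-mask voxel, signed
    voxel_index: np.ndarray
    grid_shape: tuple
    affine: np.ndarray | None
    top_fraction: float
    top_mask_flat: np.ndarray    # flat indices of the top-|weight| voxels
    region_summary: pd.DataFrame | None = None

    def to_volume(self) -> VolumeMap:
        data = np.full(self.grid_shape, np.nan)
        data.ravel()[self.voxel_index] = self.weights
        return VolumeMap(data=data, affine=self.affine, kind="weight")

    def top_mask(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=bool)
        out.ravel()[self.top_mask_flat] = True
        return out


def weight_map(features: FeatureMatrix, top_fraction: float = 0.20,
               svm_c: float = 1.0, *, label_image: np.ndarray | None = None,
               label_names: dict | None = None,
               region_summary: bool = False) -> WeightMap:
    """Whole-sample SVM weight vector mapped back to voxel space.

    ``top_fraction`` selects round(fraction * V) voxels with the largest
    |weight| (ties -> smaller linear voxel index).  With a label image,
    summarizes percent of total |weight| per region.
    """
    if not (0 < top_fraction <= 1):
        raise InputError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    clf = _fit_svm(features.x, features.y, svm_c)
    w = np.asarray(clf.coef_).ravel()
    if clf.classes_[1] != PATIENT_LABEL:
        w = -w
    n_top = int(round(top_fraction * w.size))
    n_top = max(n_top, 1)
    order = np.lexsort((features.voxel_index, -np.abs(w)))
    top_local = order[:n_top]
    top_flat = features.voxel_index[top_local]

    summary = None
    if region_summary:
        if label_image is None:
            raise InputError("region summary requested but no label image supplied")
        label_image = np.asarray(label_image)
        if label_image.shape != tuple(features.grid_shape):
            raise InputError("label image grid does not match feature grid")
        lab_flat = label_image.ravel()[features.voxel_index]
        abs_w = np.abs(w)
        covered = lab_flat > 0
        total = abs_w[covered].sum()
        rows = []
        for lab in np.unique(lab_flat[covered]):
            s = abs_w[lab_flat == lab].sum()
            name = (label_names or {}).get(int(lab), str(int(lab)))
            rows.append({"label": int(lab), "region": name,
                         "weight_percent": 100.0 * s / total if total > 0 else 0.0})
        summary = pd.DataFrame(rows).sort_values("weight_percent", ascending=False,
                                                 ignore_index=True)
    return WeightMap(weights=w, voxel_index=features.voxel_index,
                     grid_shape=tuple(features.grid_shape), affine=features.affine,
                     top_fraction=top_fraction, top_mask_flat=top_flat,
                     region_summary=summary)
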