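"""Cohort statistics and ALλ/ATTR typing on MDIC-filtered imaging data.

Regions of interest (ROI) are the high-intensity pixels of the m/z 968.55
reference image. Their spectra are exported as per-pixel feature vectors
over the 19-target panel, each intensity divided by the pixel's total ion
current (TIC). Group differences per target are tested with a two-tailed
Mann–Whitney U test, Bonferroni-corrected over the panel. Cases are typed
ALλ vs ATTR with an RBF-kernel SVM (k(x,y) = exp(−‖x−y‖²/(2σ²)), σ = 2,
C = 10) under stratified fourfold cross-validation, using per-case median
feature vectors — pixels are the statistical unit for the U test, cases for
the classifier, because the diagnosis is made per case.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .mdic_filter import IonImage
from .msi_core import (
    FilterTolerances,
    IMSDataset,
    SIGNIFICANT_MASSES,
    TargetPeptide,
    round_half_away,
)

__all__ = [
    "RoiExport",
    "StatResult",
    "SvmResult",
    "select_roi",
    "export_tic_normalized",
    "mannwhitney_panel",
    "svm_type_cases",
    "confusion_metrics",
]

LABEL_ATTR = "ATTR"
LABEL_AL = "ALλ"


@dataclass
class RoiExport:
    """TIC-normalized panel intensities of one case's ROI pixels.

    ``matrix`` is (n_pixels × n_targets); columns follow ``feature_mz``.
    Every row sums to at most 1 (the targets are a subset of each pixel's
    total ion current).
    """

    case_id: str
    label: str
    pixels: list[tuple[int, int]]
    feature_mz: list[float]
    matrix: np.ndarray

    def median_features(self, features: list[float] | None = None) -> np.ndarray:
        cols = self._columns(features)
        return np.median(self.matrix[:, cols], axis=0)

    def _columns(self, features: list[float] | None) -> list[int]:
        if features is None:
            return list(range(len(self.feature_mz)))
        cols = []
        for f in features:
            match = [i for i, mz in enumerate(self.feature_mz) if abs(mz - f) < 5e-3]
            if not match:
                raise KeyError(f"feature m/z {f} not in export")
            cols.append(match[0])
        return cols


@dataclass
class StatResult:
    """Per-target Mann–Whitney outcomes with Bonferroni correction."""

    table: pd.DataFrame  # columns: protein, theo_mz, U, p, significant, testable
    alpha: float = 0.05
    n_tests: int = 19

    @property
    def significant_masses(self) -> list[float]:
        sig = self.table[self.table["significant"]]
        return list(sig["theo_mz"])


@dataclass
class SvmResult:
    """Cross-validated RBF-SVM typing result."""

    features: list[float]
    sigma: float
    C: float
    folds: int
    seed: int
    confusion: dict  # true_attr, false_all, true_all, false_attr
    metrics: dict  # sensitivity, specificity, ppv_attr, ppv_all (percent)
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_roi(ref_img: IonImage, quantile: float = 0.8) -> np.ndarray:
    """Mask of reference-image pixels strictly above the given quantile of
    the nonzero intensities.

    Guaranteed non-empty whenever any nonzero pixel exists (falls back to
    the argmax pixel for degenerate, e.g. constant, images). An all-zero
    image yields an empty mask with a warning.
    """
    if not (0.0 <= quantile < 1.0):
        raise ValueError("quantile must lie in [0, 1)")
    values = np.where(ref_img.mask, ref_img.values, 0.0)
    nonzero = values[values > 0]
    mask = np.zeros_like(values, dtype=bool)
    if nonzero.size == 0:
        warnings.warn("reference image is all zero; empty ROI")
        return mask
    cut = float(np.quantile(nonzero, quantile))
    mask = values > cut
    if not mask.any():
        warnings.warn("degenerate reference image; ROI fell back to argmax pixel")
        idx = np.unravel_index(int(np.argmax(values)), values.shape)
        mask[idx] = True
    return mask


def export_tic_normalized(
    ds: IMSDataset,
    mask: np.ndarray,
    panel: list[TargetPeptide],
    tol: FilterTolerances | None = None,
) -> RoiExport:
    """Per-ROI-pixel TIC-normalized intensities of every panel target.

    *ds* must be the picked dataset with raw counts (before base-peak
    normalization): the TIC is the sum of all picked-peak intensities in the
    pixel. A target's intensity sums peaks inside the M tolerance and, where
    the target has a reference drift, the D tolerance. Pixels with zero TIC
    are excluded with a warning.
    """
    if tol is None:
        tol = FilterTolerances()
    feature_mz = [t.theo_mz for t in panel]
    pixels: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    for s in ds.spectra:
        if not mask[s.y, s.x]:
            continue
        tic = float(s.intensity.sum())
        if tic <= 0:
            warnings.warn(f"pixel ({s.x},{s.y}): zero TIC, excluded from export")
            continue
        feats = np.zeros(len(panel))
        mz = s.mz
        drift = s.drift.astype(np.float64)
        inten = s.intensity.astype(np.float64)
        for i, t in enumerate(panel):
            sel = np.abs(mz - t.theo_mz) <= t.theo_mz * tol.max_ppm * 1e-6
            if t.ref_drift is not None:
                sel &= np.abs(drift - t.ref_drift) <= tol.max_drift_err
            if sel.any():
                feats[i] = float(inten[sel].sum()) / tic
        pixels.append((s.x, s.y))
        rows.append(feats)
    matrix = np.vstack(rows) if rows else np.empty((0, len(panel)))
    return RoiExport(
        case_id=str(ds.metadata.get("case_id", "")),
        label=str(ds.metadata.get("label", "")),
        pixels=pixels,
        feature_mz=feature_mz,
        matrix=matrix,
    )


def mannwhitney_panel(
    group_a: list[RoiExport],
    group_b: list[RoiExport],
    alpha: float = 0.05,
    panel: list[TargetPeptide] | None = None,
) -> StatResult:
    """Two-tailed Mann–Whitney U per target on pooled ROI pixels.

    Significance is declared at the Bonferroni level alpha / n_targets. A
    target constant across both groups is untestable and reported with
    p = 1.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    feature_mz = group_a[0].feature_mz
    mat_a = np.vstack([e.matrix for e in group_a])
    mat_b = np.vstack([e.matrix for e in group_b])
    n_tests = len(feature_mz)
    proteins = {t.theo_mz: t.protein for t in panel} if panel else {}
    rows = []
    for i, mz in enumerate(feature_mz):
        x, y = mat_a[:, i], mat_b[:, i]
        if np.ptp(np.concatenate([x, y])) == 0.0:
            rows.append({"protein": proteins.get(mz, ""), "theo_mz": mz,
                         "U": float(len(x) * len(y)) / 2.0, "p": 1.0,
                         "significant": False, "testable": False})
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        p = float(res.pvalue)
        rows.append({"protein": proteins.get(mz, ""), "theo_mz": mz,
                     "U": float(res.statistic), "p": p,
                     "significant": bool(p < alpha / n_tests), "testable": True})
    return StatResult(table=pd.DataFrame(rows), alpha=alpha, n_tests=n_tests)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Diagnostic metrics from a 2×2 confusion matrix, as percentages
    rounded to one decimal (ties away from zero).

    With ATTR as the positive class: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), ppv_pos = TP/(TP+FP), ppv_neg = TN/(TN+FN).
    Undefined ratios (zero denominator) are reported as NaN.
    """
    for v in (tp, fn, tn, fp):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be non-negative integers")

    def pct(num: int, den: int) -> float:
        if den == 0:
            return float("nan")
        return round_half_away(100.0 * num / den, 1)

    return {
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv_pos": pct(tp, tp + fp),
        "ppv_neg": pct(tn, tn + fn),
    }


def svm_type_cases(
    cases: list[RoiExport],
    labels: dict[str, str] | None = None,
    features: list[float] | None = None,
    sigma: float = 2.0,
    C: float = 10.0,
    folds: int = 4,
    seed: int = 0,
    z_score: bool = True,
) -> SvmResult:
    """Type cases as ALλ vs ATTR with a cross-validated RBF SVM.

    Each case enters as the median TIC-normalized intensity of the chosen
    feature masses over its ROI pixels (default: the six masses with
    significant ALλ/ATTR intensity differences). Features are z-scored
    before the kernel by default: TIC-normalized intensities have magnitude
    ~0.01–0.1, so with σ = 2 the unscaled RBF kernel is numerically constant
    (exp(−‖x−y‖²/8) ≈ 1 for every pair) and the classifier degenerates to a
    majority vote; standardization puts pairwise distances on the scale the
    kernel width expects. Folds are stratified by class and derived from
    *seed* after sorting cases by id, so the result does not depend on input
    order. The confusion matrix aggregates the held-out predictions of all
    folds.
    """
    if features is None:
        features = list(SIGNIFICANT_MASSES)
    if labels is None:
        labels = {c.case_id: c.label for c in cases}
    cases = sorted(cases, key=lambda c: c.case_id)
    y = np.array([labels[c.case_id] for c in cases])
    classes = set(y)
    if classes != {LABEL_AL, LABEL_ATTR}:
        raise ValueError(f"expected labels {{{LABEL_AL}, {LABEL_ATTR}}}, got {sorted(classes)}")
    for cls in (LABEL_AL, LABEL_ATTR):
        n_cls = int((y == cls).sum())
        if n_cls < folds:
            raise ValueError(
                f"class {cls} has {n_cls} cases but {folds} folds requested; "
                "use fewer folds"
            )
    X = np.vstack([c.median_features(features) for c in cases])
    if z_score:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    gamma = 1.0 / (2.0 * sigma**2)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for train, test in skf.split(X, y):
        clf = SVC(kernel="rbf", gamma=gamma, C=C)
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])

    true_attr = int(np.sum((y == LABEL_ATTR) & (pred == LABEL_ATTR)))
    false_all = int(np.sum((y == LABEL_ATTR) & (pred == LABEL_AL)))
    true_all = int(np.sum((y == LABEL_AL) & (pred == LABEL_AL)))
    false_attr = int(np.sum((y == LABEL_AL) & (pred == LABEL_ATTR)))
    m = confusion_metrics(true_attr, false_all, true_all, false_attr)
    return SvmResult(
        features=features,
        sigma=sigma,
        C=C,
        folds=folds,
        seed=seed,
        confusion={
            "true_attr": true_attr,
            "false_all": false_all,
            "true_all": true_all,
            "false_attr": false_attr,
        },
        metrics={
            "sensitivity": m["sensitivity"],
            "specificity": m["specificity"],
            "ppv_attr": m["ppv_pos"],
            "ppv_all": m["ppv_neg"],
        },
        predictions=pd.DataFrame(
            {"case_id": [c.case_id for c in cases], "label": y, "predicted": pred}
        ),
    )
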