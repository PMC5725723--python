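"""The MDIC peptide filter: Mass accuracy, Drift time, Image Correlation.

A tryptic peptide of the target panel counts as *detected* in a case when
three criteria hold simultaneously:

* M — the intensity-weighted mean observed m/z lies within ``max_ppm`` of
  the theoretical mass (default 30 ppm);
* D — the intensity-weighted mean observed drift bin lies within
  ``max_drift_err`` bins of the peptide's reference drift (default 2.5);
* IC — the Pearson correlation R between the peptide's ion image and the
  reference image of the ApoE peptide at m/z 968.55 is at least ``min_ic``
  (default 0.75).

The reference peptide anchors the whole filter: a case is called
amyloid-positive exactly when m/z 968.55 itself passes M and D (its IC
against itself is 1 by definition). Without the reference peak no other
target is evaluated.

Reference drift bins are not universal constants; they are calibrated from a
derivation cohort by averaging observed drifts of targets that pass M and IC
(:func:`calibrate_ref_drifts`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .msi_core import (
    FilterTolerances,
    IMSDataset,
    REFERENCE_MZ,
    TargetPeptide,
    round_half_away,
)

__all__ = [
    "IonImage",
    "DetectionRecord",
    "CaseCall",
    "build_ion_image",
    "pearson_image_correlation",
    "calibrate_ref_drifts",
    "apply_mdic",
    "detection_frequency",
    "rank_masses_by_correlation",
    "detections_frame",
]


@dataclass
class IonImage:
    """2-D map of summed peak intensity inside one m/z (× drift) window.

    ``mask`` flags acquired pixels; unacquired pixels are distinct from
    measured zeros and are excluded from correlations.
    """

    values: np.ndarray
    mask: np.ndarray
    target_mz: float
    mz_tol_ppm: float
    drift_center: float | None = None
    drift_tol: float | None = None

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.values, delimiter="\t", fmt="%.6g")

    def to_png(self, path, cmap: str = "viridis") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        shown = np.where(self.mask, self.values, np.nan)
        im = ax.imshow(shown, cmap=cmap, origin="upper", interpolation="nearest")
        ax.set_title(f"m/z {self.target_mz:.2f}")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


@dataclass
class DetectionRecord:
    """Per-case outcome of the MDIC filter for one target peptide."""

    target: TargetPeptide
    obs_mz: float
    mass_err_ppm: float
    obs_drift: float
    drift_err: float
    pearson_r: float
    pass_m: bool
    pass_d: bool
    pass_ic: bool

    @property
    def detected(self) -> bool:
        return self.pass_m and self.pass_d and self.pass_ic


@dataclass
class CaseCall:
    """Amyloid-presence call of one case."""

    case_id: str
    reference_ok: bool
    detections: list[DetectionRecord] = field(default_factory=list)

    @property
    def amyloid_positive(self) -> bool:
        # presence of the m/z 968.55 reference peptide IS the calling criterion
        return self.reference_ok

    @property
    def signature(self) -> set[float]:
        return {r.target.theo_mz for r in self.detections if r.detected}


class _FlatView:
    """Cached concatenated peak arrays of a dataset, for windowed queries."""

    def __init__(self, ds: IMSDataset):
        self.ds = ds
        xs, ys, mz, drift, inten, offsets = ds.flat_arrays()
        self.xs, self.ys = xs, ys
        self.mz = mz
        self.drift = drift.astype(np.float64)
        self.inten = inten.astype(np.float64)
        self.pix = np.repeat(np.arange(len(ds.spectra)), np.diff(offsets))

    def window(self, mz_center: float, ppm_tol: float,
               drift_center: float | None, drift_tol: float | None) -> np.ndarray:
        half = mz_center * ppm_tol * 1e-6
        sel = np.abs(self.mz - mz_center) <= half
        if drift_center is not None and drift_tol is not None:
            sel &= np.abs(self.drift - drift_center) <= drift_tol
        return sel

    def pixel_support(self, sel: np.ndarray) -> float:
        """Fraction of acquired pixels holding at least one selected peak."""
        n_spec = len(self.ds.spectra)
        if n_spec == 0:
            return 0.0
        return len(np.unique(self.pix[sel])) / n_spec


def build_ion_image(
    ds: IMSDataset,
    target_mz: float,
    mz_tol_ppm: float,
    drift_center: float | None = None,
    drift_tol: float | None = None,
    _flat: "_FlatView | None" = None,
) -> IonImage:
    """Sum, per pixel, intensities of peaks inside the target window.

    A peak matches when its signed ppm error relative to *target_mz* is
    within ``±mz_tol_ppm`` and, if *drift_center* is given, its drift bin is
    within ``±drift_tol`` of it. Pixels with no match are 0; when
    *drift_center* is None the drift constraint is skipped (mass-only image).
    """
    if mz_tol_ppm <= 0:
        raise ValueError("mz_tol_ppm must be > 0")
    if drift_center is not None and (drift_tol is None or drift_tol <= 0):
        raise ValueError("drift_tol must be > 0 when drift_center is given")
    flat = _flat if _flat is not None else _FlatView(ds)
    sel = flat.window(target_mz, mz_tol_ppm, drift_center, drift_tol)
    values = np.zeros((ds.height, ds.width), dtype=np.float64)
    np.add.at(values, (flat.ys[flat.pix[sel]], flat.xs[flat.pix[sel]]), flat.inten[sel])
    return IonImage(
        values=values,
        mask=ds.acquired_mask(),
        target_mz=target_mz,
        mz_tol_ppm=mz_tol_ppm,
        drift_center=drift_center,
        drift_tol=drift_tol,
    )


def pearson_image_correlation(a: IonImage, b: IonImage) -> float:
    """Pearson product-moment R over the union of acquired pixels.

    Zeros are informative (absence of signal colocalizes too) and are
    included. Returns NaN if either image has zero variance.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("ion images have different grids")
    sel = a.mask | b.mask
    x = a.values[sel]
    y = b.values[sel]
    if x.size < 2 or float(np.var(x)) == 0.0 or float(np.var(y)) == 0.0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def _weighted_obs(flat: _FlatView, sel: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted mean (m/z, drift) over selected peaks."""
    w = flat.inten[sel]
    total = float(w.sum())
    if total <= 0:
        # unweighted fallback for degenerate all-zero windows
        return float(flat.mz[sel].mean()), float(flat.drift[sel].mean())
    return (
        float((flat.mz[sel] * w).sum() / total),
        float((flat.drift[sel] * w).sum() / total),
    )


def calibrate_ref_drifts(
    cases: list[IMSDataset],
    panel: list[TargetPeptide],
    tol: FilterTolerances | None = None,
    ref_mz: float = REFERENCE_MZ,
    min_pixel_support: float = 0.01,
) -> list[TargetPeptide]:
    """Derive per-target reference drift bins from a derivation cohort.

    For every case and target, the observed drift (intensity-weighted mean
    over peaks within the mass tolerance, no drift constraint) is collected
    whenever the target passes the M criterion and its mass-only ion image
    correlates with the mass-only reference image at R ≥ ``min_ic``. The
    reference drift is the plain mean of these observations; targets never
    observed keep ``ref_drift`` unset.

    ``min_pixel_support`` guards the averages against stray near-isobaric
    noise: a genuine tissue peptide appears in a sizeable share of pixels,
    while a chance decoy occupies a handful, and for the reference peptide —
    whose image correlation with itself is tautologically 1 — such a decoy
    would otherwise bias the drift reference unchecked.
    """
    if tol is None:
        tol = FilterTolerances()
    if not cases:
        raise ValueError("need at least one derivation case")
    collected: dict[int, list[float]] = {i: [] for i in range(len(panel))}
    for ds in cases:
        flat = _FlatView(ds)
        ref_img = build_ion_image(ds, ref_mz, tol.max_ppm, _flat=flat)
        for i, t in enumerate(panel):
            sel = flat.window(t.theo_mz, tol.max_ppm, None, None)
            if not sel.any() or flat.pixel_support(sel) < min_pixel_support:
                continue
            obs_mz, obs_drift = _weighted_obs(flat, sel)
            err_ppm = (obs_mz - t.theo_mz) / t.theo_mz * 1e6
            if abs(err_ppm) > tol.max_ppm:
                continue
            if abs(t.theo_mz - ref_mz) < 5e-3:
                r = 1.0
            else:
                img = build_ion_image(ds, t.theo_mz, tol.max_ppm, _flat=flat)
                r = pearson_image_correlation(img, ref_img)
            if not math.isnan(r) and r >= tol.min_ic:
                collected[i].append(obs_drift)
    out = []
    for i, t in enumerate(panel):
        obs = collected[i]
        if obs:
            out.append(replace(t, ref_drift=float(np.mean(obs))))
        else:
            warnings.warn(
                f"target {t.protein} m/z {t.theo_mz}: never observed during "
                "drift calibration; ref_drift left unset"
            )
            out.append(replace(t))
    return out


def apply_mdic(
    ds: IMSDataset,
    panel: list[TargetPeptide],
    tol: FilterTolerances | None = None,
    ref_mz: float = REFERENCE_MZ,
    search_factor: float = 2.0,
    min_pixel_support: float = 0.01,
) -> CaseCall:
    """Run the three-criterion filter on one preprocessed case.

    Candidate peaks for each target are gathered inside a widened search
    window (``search_factor`` × the M and D tolerances) so that signed errors
    can be measured before the pass/fail decision; the pass flags themselves
    use the unwidened tolerances. A target without a calibrated reference
    drift cannot satisfy all three criteria and is reported undetected.

    A target only counts as a candidate when its matches cover at least
    ``min_pixel_support`` of the acquired pixels: a tissue peptide emits in
    most pixels, a chance near-isobaric decoy in a handful, and for the
    reference peptide — whose own image-correlation criterion is
    tautological — a stray decoy would otherwise suffice to call a case
    amyloid-positive.
    """
    if tol is None:
        tol = FilterTolerances()
    ref_candidates = [t for t in panel if abs(t.theo_mz - ref_mz) < 5e-3]
    if not ref_candidates:
        raise ValueError(f"panel does not contain the reference mass {ref_mz}")
    ref_t = ref_candidates[0]
    if ref_t.ref_drift is None:
        raise ValueError("reference peptide has no calibrated ref_drift")

    case_id = str(ds.metadata.get("case_id", ""))
    flat = _FlatView(ds)

    ref_rec = _score_target(flat, ref_t, tol, search_factor, min_pixel_support,
                            pearson_r=1.0, pass_ic=True)
    reference_ok = ref_rec is not None and ref_rec.pass_m and ref_rec.pass_d
    if not reference_ok:
        return CaseCall(case_id=case_id, reference_ok=False, detections=[])

    ref_img = build_ion_image(
        ds, ref_t.theo_mz, tol.max_ppm,
        drift_center=ref_t.ref_drift, drift_tol=tol.max_drift_err, _flat=flat,
    )

    detections = [ref_rec]
    for t in panel:
        if t is ref_t:
            continue
        rec = _score_target(flat, t, tol, search_factor, min_pixel_support)
        if rec is None:
            detections.append(
                DetectionRecord(
                    target=t, obs_mz=float("nan"), mass_err_ppm=float("nan"),
                    obs_drift=float("nan"), drift_err=float("nan"),
                    pearson_r=float("nan"),
                    pass_m=False, pass_d=False, pass_ic=False,
                )
            )
            continue
        img = build_ion_image(
            ds, t.theo_mz, tol.max_ppm,
            drift_center=t.ref_drift, drift_tol=tol.max_drift_err
            if t.ref_drift is not None else None, _flat=flat,
        )
        r = pearson_image_correlation(img, ref_img)
        rec.pearson_r = r
        rec.pass_ic = (not math.isnan(r)) and r >= tol.min_ic
        detections.append(rec)
    return CaseCall(case_id=case_id, reference_ok=True, detections=detections)


def _score_target(
    flat: _FlatView,
    t: TargetPeptide,
    tol: FilterTolerances,
    search_factor: float,
    min_pixel_support: float = 0.0,
    pearson_r: float = float("nan"),
    pass_ic: bool = False,
) -> DetectionRecord | None:
    """Measure M and D errors for one target; None when no candidate peak
    falls inside the widened search window (or too few pixels hold one)."""
    if t.ref_drift is not None:
        sel = flat.window(t.theo_mz, tol.max_ppm * search_factor,
                          t.ref_drift, tol.max_drift_err * search_factor)
    else:
        sel = flat.window(t.theo_mz, tol.max_ppm * search_factor, None, None)
    if not sel.any() or flat.pixel_support(sel) < min_pixel_support:
        return None
    obs_mz, obs_drift = _weighted_obs(flat, sel)
    mass_err = (obs_mz - t.theo_mz) / t.theo_mz * 1e6
    if t.ref_drift is not None:
        drift_err = obs_drift - t.ref_drift
        pass_d = abs(drift_err) <= tol.max_drift_err
    else:
        drift_err = float("nan")
        pass_d = False
    return DetectionRecord(
        target=t,
        obs_mz=obs_mz,
        mass_err_ppm=mass_err,
        obs_drift=obs_drift,
        drift_err=drift_err,
        pearson_r=pearson_r,
        pass_m=abs(mass_err) <= tol.max_ppm,
        pass_d=pass_d,
        pass_ic=pass_ic,
    )


def detections_frame(call: CaseCall) -> pd.DataFrame:
    """Tabulate a case's detection records (one row per panel target)."""
    rows = [
        {
            "case_id": call.case_id,
            "protein": r.target.protein,
            "theo_mz": r.target.theo_mz,
            "obs_mz": r.obs_mz,
            "mass_err_ppm": r.mass_err_ppm,
            "obs_drift": r.obs_drift,
            "drift_err": r.drift_err,
            "pearson_r": r.pearson_r,
            "pass_m": r.pass_m,
            "pass_d": r.pass_d,
            "pass_ic": r.pass_ic,
            "detected": r.detected,
        }
        for r in call.detections
    ]
    return pd.DataFrame(rows)


def detection_frequency(
    calls: list[CaseCall],
    grouping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Detection-frequency table: per target and group, n_D / n and percent.

    The percentage n_D/n_group × 100 is rounded to the nearest integer with
    ties away from zero (62/66 → 94, 31/32 → 97). Cases whose reference
    peptide failed contribute to n but detect nothing. Empty groups are
    omitted with a warning.
    """
    if not calls:
        raise ValueError("need at least one case call")
    if grouping is None:
        grouping = {c.case_id: "all" for c in calls}
    groups: dict[str, list[CaseCall]] = {}
    for c in calls:
        g = grouping.get(c.case_id)
        if g is None:
            warnings.warn(f"case {c.case_id} missing from grouping; omitted")
            continue
        groups.setdefault(g, []).append(c)

    targets: dict[float, TargetPeptide] = {}
    for c in calls:
        for r in c.detections:
            targets.setdefault(r.target.theo_mz, r.target)

    rows = []
    for g, members in groups.items():
        if not members:
            warnings.warn(f"group {g!r} empty; omitted")
            continue
        n = len(members)
        for mz in sorted(targets):
            n_d = sum(1 for c in members if mz in c.signature)
            rows.append(
                {
                    "group": g,
                    "protein": targets[mz].protein,
                    "theo_mz": mz,
                    "n_detected": n_d,
                    "n_cases": n,
                    "percent": int(round_half_away(100.0 * n_d / n)),
                }
            )
    return pd.DataFrame(rows)


def rank_masses_by_correlation(
    ds: IMSDataset,
    ref_img: IonImage,
    mz_tol_ppm: float = 30.0,
    min_pixels: int = 3,
) -> pd.DataFrame:
    """Untargeted convenience: rank every picked m/z by its image R against
    the reference image. A screening aid, not a validated discovery method."""
    flat = _FlatView(ds)
    if flat.mz.size == 0:
        return pd.DataFrame(columns=["mz", "pearson_r", "n_pixels"])
    order = np.argsort(flat.mz)
    mzs = flat.mz[order]
    # greedy grouping of the sorted mass axis into ppm-wide bins
    groups: list[tuple[float, np.ndarray]] = []
    start = 0
    for i in range(1, len(mzs) + 1):
        if i == len(mzs) or (mzs[i] - mzs[start]) / mzs[start] * 1e6 > 2 * mz_tol_ppm:
            groups.append((float(np.median(mzs[start:i])), order[start:i]))
            start = i
    rows = []
    for center, idx in groups:
        if idx.size < min_pixels:
            continue
        img = build_ion_image(ds, center, mz_tol_ppm, _flat=flat)
        r = pearson_image_correlation(img, ref_img)
        rows.append({"mz": center, "pearson_r": r, "n_pixels": int(idx.size)})
    df = pd.DataFrame(rows)
    return df.sort_values("pearson_r", ascending=False, ignore_index=True) if len(df) else df
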