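"""Ground-truthed synthetic ion-mobility MSI cases.

The generator emulates the statistical situation the MDIC filter assumes:
amyloid-associated tryptic peptides are spatially enriched in deposit
regions and therefore colocalize with the m/z 968.55 reference peptide,
while decoy ions scatter uniformly over the mass range and carry no spatial
structure. A case is one rectangular tissue grid (default 64×64 pixels,
200 drift bins) whose deposit is a union of random discs. Per case:

* each panel target is independently present with a class-specific
  probability (the published per-class detection frequencies, see
  ``DETECTION_COUNTS``); controls carry no panel targets at all;
* a present target emits one centroid per pixel: m/z perturbed by a global
  calibration offset (+25 ppm) plus N(0, 8 ppm) noise, drift N(target mean,
  0.8 bins) rounded to a bin, intensity log-normal (median 100 counts inside
  the deposit, 10-fold lower outside);
* ATTR cases scale the six discriminating masses by a 2× intensity ratio —
  the class difference is an intensity effect, not presence alone;
* every pixel carries the CHCA matrix lock-mass peak at m/z 825.101 (median
  500 counts — as on real tissue, the matrix cluster dominates each pixel's
  base peak, so base-peak normalization does not erase deposit contrast) and
  30 uniform decoy centroids (median 8 counts, mostly below the 10-count
  picking threshold).

Intensities are raw "counts" so the picker's intensity threshold is
meaningful. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msi_core import (
    DEFAULT_N_DRIFT_BINS,
    DEFAULT_PIXEL_SIZE_UM,
    IMSDataset,
    LOCK_MASS_MZ,
    PixelSpectrum,
    SIGNIFICANT_MASSES,
    TargetPeptide,
    default_target_panel,
    write_dataset,
)

__all__ = [
    "DETECTION_COUNTS",
    "GeneratorConfig",
    "GroundTruth",
    "generate_case",
    "generate_cohort",
    "iter_cohort",
    "default_panel_probs",
    "default_drift_means",
]

#: Published per-class detection counts of the 19 targets in the validation
#: cohort: m/z -> (n_D all of 66, n_D ALλ of 32, n_D ATTR of 34). These are
#: the generator's default presence probabilities (per-class count / n).
DETECTION_COUNTS: dict[float, tuple[int, int, int]] = {
    948.53: (22, 16, 6),
    968.55: (62, 31, 31),
    1497.80: (48, 23, 25),
    764.45: (29, 8, 21),
    1156.60: (11, 0, 11),
    1406.67: (60, 30, 30),
    1811.89: (51, 20, 31),
    887.51: (29, 12, 17),
    1314.68: (56, 27, 29),
    1422.65: (56, 29, 27),
    1503.84: (17, 10, 7),
    1646.82: (36, 18, 18),
    1666.78: (37, 20, 17),
    781.43: (53, 28, 25),
    1031.52: (42, 25, 17),
    1301.65: (60, 30, 30),
    1612.82: (10, 4, 6),
    1670.79: (11, 6, 5),
    1366.76: (36, 10, 26),
}

N_AL_CASES = 32
N_ATTR_CASES = 34
N_CONTROL_CASES = 31

LABEL_AL = "ALλ"
LABEL_ATTR = "ATTR"
LABEL_CONTROL = "control"


def default_panel_probs() -> dict[float, tuple[float, float]]:
    """Per-target (p_ALλ, p_ATTR) presence probabilities."""
    return {
        mz: (n_al / N_AL_CASES, n_attr / N_ATTR_CASES)
        for mz, (_, n_al, n_attr) in DETECTION_COUNTS.items()
    }


def default_drift_means() -> dict[float, float]:
    """Reference drift bins of the synthetic targets, spread over 40–160 in
    panel order. Synthetic stand-ins, not measured values."""
    panel = default_target_panel()
    means = np.linspace(40.0, 160.0, len(panel))
    return {t.theo_mz: float(m) for t, m in zip(panel, means)}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort (see module docstring)."""

    width: int = 64
    height: int = 64
    n_drift_bins: int = DEFAULT_N_DRIFT_BINS
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    # deposit geometry: discs added until the covered fraction is reached
    n_blobs: int = 6
    blob_radius: tuple[float, float] = (3.0, 8.0)
    deposit_fraction: float = 0.15
    # presence and intensity model
    panel_probs: dict[float, tuple[float, float]] = field(default_factory=default_panel_probs)
    deposit_log_mu: float = math.log(100.0)  # in-deposit median counts
    log_sigma: float = 0.35
    contrast: float = 10.0  # deposit / background intensity ratio
    effect_sizes: dict[float, float] = field(
        default_factory=lambda: {mz: 2.0 for mz in SIGNIFICANT_MASSES}
    )  # ATTR/ALλ mean-intensity ratio; unlisted targets get 1.0
    # mass and drift errors
    mass_error_sd: float = 8.0  # ppm
    calibration_offset: float = 25.0  # global ppm shift
    drift_sd: float = 0.8  # bins
    target_drift_means: dict[float, float] = field(default_factory=default_drift_means)
    # nuisance signals
    decoys_per_pixel: int = 30
    decoy_mz_range: tuple[float, float] = (700.0, 2000.0)
    decoy_log_mu: float = math.log(8.0)
    decoy_log_sigma: float = 0.5
    lock_mz: float = LOCK_MASS_MZ
    lock_log_mu: float = math.log(500.0)
    lock_log_sigma: float = 0.3
    lock_drift: float = 30.0
    lock_drift_sd: float = 0.5

    def __post_init__(self) -> None:
        for p_al, p_attr in self.panel_probs.values():
            if not (0.0 <= p_al <= 1.0 and 0.0 <= p_attr <= 1.0):
                raise ValueError("presence probabilities must lie in [0, 1]")
        if not (0.0 < self.deposit_fraction <= 0.5):
            raise ValueError("deposit_fraction must lie in (0, 0.5]")
        if min(self.mass_error_sd, self.drift_sd, self.log_sigma) <= 0:
            raise ValueError("noise standard deviations must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually emitted for one case."""

    label: str
    seed: int
    deposit_mask: np.ndarray  # (height, width) bool
    present: dict[float, bool]
    drift_means: dict[float, float]
    calibration_offset: float
    contrast: float

    def to_jsonable(self) -> dict:
        return {
            "label": self.label,
            "seed": self.seed,
            "deposit_pixels": [
                [int(x), int(y)] for y, x in zip(*np.nonzero(self.deposit_mask))
            ],
            "present": {str(mz): bool(v) for mz, v in self.present.items()},
            "drift_means": {str(mz): float(v) for mz, v in self.drift_means.items()},
            "calibration_offset": self.calibration_offset,
            "contrast": self.contrast,
        }


def _draw_deposit_mask(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:cfg.height, 0:cfg.width]
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    n_target = cfg.deposit_fraction * cfg.width * cfg.height
    n_discs = 0
    while (mask.sum() < n_target and n_discs < 100) or n_discs < cfg.n_blobs:
        cx = rng.uniform(0, cfg.width)
        cy = rng.uniform(0, cfg.height)
        r = rng.uniform(*cfg.blob_radius)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        n_discs += 1
    if not mask.any():  # degenerate geometry guard
        mask[cfg.height // 2, cfg.width // 2] = True
    return mask


def generate_case(
    cfg: GeneratorConfig,
    label: str,
    seed: int,
    case_id: str | None = None,
) -> tuple[IMSDataset, GroundTruth]:
    """Generate one synthetic case with its ground truth.

    ``label`` is one of ``"ALλ"``, ``"ATTR"`` or ``"control"``. Controls
    carry no panel targets. Identical (cfg, label, seed) triples produce
    identical datasets.
    """
    if label not in (LABEL_AL, LABEL_ATTR, LABEL_CONTROL):
        raise ValueError(f"unknown class label {label!r}")
    rng = np.random.default_rng(seed)
    n_pix = cfg.width * cfg.height
    mask = _draw_deposit_mask(cfg, rng)
    in_deposit = mask.ravel()  # pixel index = y * width + x

    present: dict[float, bool] = {}
    for mz, (p_al, p_attr) in cfg.panel_probs.items():
        if label == LABEL_CONTROL:
            present[mz] = False
        else:
            p = p_al if label == LABEL_AL else p_attr
            present[mz] = bool(rng.random() < p)

    pix_chunks: list[np.ndarray] = []
    mz_chunks: list[np.ndarray] = []
    drift_chunks: list[np.ndarray] = []
    int_chunks: list[np.ndarray] = []
    all_pix = np.arange(n_pix)

    def emit(pix, mz_arr, drift_arr, int_arr):
        pix_chunks.append(pix)
        mz_chunks.append(mz_arr)
        drift_chunks.append(np.clip(drift_arr, 0, cfg.n_drift_bins - 1).astype(np.int32))
        int_chunks.append(int_arr)

    # panel targets: one centroid per pixel, deposit-enriched intensity
    for mz, is_present in present.items():
        if not is_present:
            continue
        err_ppm = cfg.calibration_offset + rng.normal(0.0, cfg.mass_error_sd, n_pix)
        obs_mz = mz * (1.0 + err_ppm * 1e-6)
        drift = np.floor(
            rng.normal(cfg.target_drift_means[mz], cfg.drift_sd, n_pix) + 0.5
        )
        scale = cfg.effect_sizes.get(mz, 1.0) if label == LABEL_ATTR else 1.0
        inten = rng.lognormal(cfg.deposit_log_mu + math.log(scale), cfg.log_sigma, n_pix)
        inten[~in_deposit] /= cfg.contrast
        emit(all_pix, obs_mz, drift, inten)

    # lock-mass peak in every pixel, same calibration offset
    lock_err = cfg.calibration_offset + rng.normal(0.0, cfg.mass_error_sd, n_pix)
    emit(
        all_pix,
        cfg.lock_mz * (1.0 + lock_err * 1e-6),
        np.floor(rng.normal(cfg.lock_drift, cfg.lock_drift_sd, n_pix) + 0.5),
        rng.lognormal(cfg.lock_log_mu, cfg.lock_log_sigma, n_pix),
    )

    # decoys: spatially unstructured
    n_decoy = n_pix * cfg.decoys_per_pixel
    if n_decoy:
        emit(
            np.repeat(all_pix, cfg.decoys_per_pixel),
            rng.uniform(*cfg.decoy_mz_range, n_decoy),
            rng.integers(0, cfg.n_drift_bins, n_decoy).astype(np.float64),
            rng.lognormal(cfg.decoy_log_mu, cfg.decoy_log_sigma, n_decoy),
        )

    pix = np.concatenate(pix_chunks)
    mz_all = np.concatenate(mz_chunks)
    drift_all = np.concatenate(drift_chunks)
    int_all = np.concatenate(int_chunks).astype(np.float32)
    order = np.lexsort((drift_all, mz_all, pix))
    pix, mz_all, drift_all, int_all = pix[order], mz_all[order], drift_all[order], int_all[order]
    bounds = np.searchsorted(pix, np.arange(n_pix + 1))

    spectra = [
        PixelSpectrum(
            x=p % cfg.width,
            y=p // cfg.width,
            mz=mz_all[bounds[p]:bounds[p + 1]],
            drift=drift_all[bounds[p]:bounds[p + 1]],
            intensity=int_all[bounds[p]:bounds[p + 1]],
        )
        for p in range(n_pix)
    ]
    ds = IMSDataset(
        width=cfg.width,
        height=cfg.height,
        spectra=spectra,
        pixel_size=cfg.pixel_size,
        n_drift_bins=cfg.n_drift_bins,
        metadata={
            "case_id": case_id or f"{label}-{seed}",
            "label": label,
            "organ": "heart",
            "seed": str(seed),
        },
    )
    gt = GroundTruth(
        label=label,
        seed=seed,
        deposit_mask=mask,
        present=present,
        drift_means=dict(cfg.target_drift_means),
        calibration_offset=cfg.calibration_offset,
        contrast=cfg.contrast,
    )
    return ds, gt


def _case_seed(master_seed: int, index: int) -> int:
    """Deterministic per-case seed below 2**31."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def _cohort_plan(n_al: int, n_attr: int, n_control: int) -> list[tuple[str, str]]:
    plan = [(f"AL-{i + 1:03d}", LABEL_AL) for i in range(n_al)]
    plan += [(f"ATTR-{i + 1:03d}", LABEL_ATTR) for i in range(n_attr)]
    plan += [(f"CTRL-{i + 1:03d}", LABEL_CONTROL) for i in range(n_control)]
    return plan


def iter_cohort(
    cfg: GeneratorConfig,
    n_al: int = N_AL_CASES,
    n_attr: int = N_ATTR_CASES,
    n_control: int = N_CONTROL_CASES,
    seed: int = 0,
):
    """Lazily yield (case_id, label, dataset, ground_truth) for a cohort.

    Per-case seeds derive deterministically from the master seed, so a case
    can be regenerated in isolation.
    """
    for index, (case_id, label) in enumerate(_cohort_plan(n_al, n_attr, n_control)):
        ds, gt = generate_case(cfg, label, _case_seed(seed, index), case_id=case_id)
        yield case_id, label, ds, gt


def generate_cohort(
    cfg: GeneratorConfig,
    out_dir: str | os.PathLike,
    n_al: int = N_AL_CASES,
    n_attr: int = N_ATTR_CASES,
    n_control: int = N_CONTROL_CASES,
    seed: int = 0,
    fmt: str = "cache",
) -> pd.DataFrame:
    """Write a full synthetic cohort to disk.

    Emits one dataset file per case (imzML or cache), a ``manifest.csv``
    (case_id, path, label, seed) and a ``ground_truth.json``. Returns the
    manifest. Defaults mirror the validation-cohort design: 32 ALλ + 34 ATTR
    + 31 controls = 97 heart samples.
    """
    if fmt not in ("imzml", "cache"):
        raise ValueError(f"unknown format {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    ext = ".imzML" if fmt == "imzml" else ".h5"
    rows = []
    truths = {}
    for index, (case_id, label) in enumerate(_cohort_plan(n_al, n_attr, n_control)):
        case_seed = _case_seed(seed, index)
        ds, gt = generate_case(cfg, label, case_seed, case_id=case_id)
        path = os.path.join(out_dir, case_id + ext)
        write_dataset(ds, path, format=fmt)
        rows.append({"case_id": case_id, "path": path, "label": label, "seed": case_seed})
        truths[case_id] = gt.to_jsonable()
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truths, fh)
    return manifest


def calibration_panel(cfg: GeneratorConfig) -> list[TargetPeptide]:
    """The default panel with the generator's TRUE drift means filled in.

    A synthetic stand-in for an externally measured drift-reference table;
    use :func:`amylofilter.mdic_filter.calibrate_ref_drifts` for the
    data-driven route.
    """
    panel = default_target_panel()
    for t in panel:
        t.ref_drift = cfg.target_drift_means[t.theo_mz]
    return panel
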