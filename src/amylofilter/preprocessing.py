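"""Spectrum normalization, lock-mass recalibration and 3-D peak picking.

The picker is a deterministic, intensity-descending greedy clustering of
centroid events in the m/z × drift plane, parameterised like the vendor
pipeline it emulates (m/z window 0.1 Da, intensity threshold 10 counts,
drift window 5 bins, accepted IMS peak width 2–10 bins, 3000 most intense
signals retained dataset-wide). A "signal" is an m/z × drift species of the
whole dataset, not a single pixel's peak: keeping the 3000 most intense
signals keeps each survivor's complete ion image. Within one pixel, the most
intense
unassigned event seeds a cluster that absorbs every unassigned event within
±mz_window/2 in m/z and ±drift_window in drift; the cluster's m/z and drift
are intensity-weighted means (drift rounded back to a bin) and its intensity
is the member sum. Ties in seeding order are broken by (lower m/z, lower
drift) so the result is unique. The inner loop is JIT-compiled with numba.

Lock-mass recalibration estimates ONE multiplicative factor per dataset from
the median observed position of the matrix-cluster peak across pixels; it is
applied to raw centroids before picking so pixels losing their lock peak to
the dataset-wide top-N cut cannot starve the estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .msi_core import IMSDataset, LOCK_MASS_MZ, PixelSpectrum

__all__ = [
    "PickingParams",
    "normalize_base_peak",
    "normalize_dataset",
    "recalibrate_lockmass",
    "pick_peaks",
    "preprocess_dataset",
]


@dataclass
class PickingParams:
    """Parameters of the greedy 3-D peak picker.

    mz_window
        full merging window in m/z (Da); members lie within ±mz_window/2 of
        the seed.
    intensity_threshold
        minimum apex (seed) intensity in counts for a cluster to survive.
    drift_window
        merging half-window along the drift axis (bins).
    ims_peak_width_min / ims_peak_width_max
        accepted drift extent (occupied-bin span) of a multi-event cluster;
        single-event clusters have no measurable extent and bypass the check.
    top_n
        number of distinct signals (dataset-wide m/z × drift species) kept,
        ranked by their summed intensity over all pixels; every per-pixel
        cluster of a retained signal survives, so the signal's ion image
        stays intact.
    """

    mz_window: float = 0.1
    intensity_threshold: float = 10.0
    drift_window: float = 5.0
    ims_peak_width_min: int = 2
    ims_peak_width_max: int = 10
    top_n: int = 3000

    def __post_init__(self) -> None:
        if min(self.mz_window, self.intensity_threshold, self.drift_window,
               self.ims_peak_width_min, self.ims_peak_width_max) <= 0:
            raise ValueError("all picking parameters must be strictly positive")
        if self.ims_peak_width_min > self.ims_peak_width_max:
            raise ValueError("ims_peak_width_min must be <= ims_peak_width_max")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def normalize_base_peak(spec: PixelSpectrum) -> PixelSpectrum:
    """Divide a pixel's intensities by its base peak (most intense peak).

    The maximum becomes exactly 1.0; relative intensities are preserved.
    An empty spectrum is returned unchanged with a warning.
    """
    if len(spec) == 0:
        warnings.warn(f"pixel ({spec.x},{spec.y}): empty spectrum, not normalized")
        return spec
    base = float(spec.intensity.max())
    if base <= 0:
        warnings.warn(f"pixel ({spec.x},{spec.y}): zero base peak, not normalized")
        return spec
    return PixelSpectrum(
        x=spec.x, y=spec.y, mz=spec.mz.copy(), drift=spec.drift.copy(),
        intensity=(spec.intensity.astype(np.float64) / base).astype(np.float32),
    )


def normalize_dataset(ds: IMSDataset) -> IMSDataset:
    """Base-peak normalization applied per pixel across the dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spectra = [normalize_base_peak(s) for s in ds.spectra]
    return replace(ds, spectra=spectra, metadata=dict(ds.metadata, normalized="base_peak"))


def recalibrate_lockmass(
    ds: IMSDataset,
    lock_mz: float = LOCK_MASS_MZ,
    search_ppm: float = 100.0,
) -> IMSDataset:
    """Single-point multiplicative mass recalibration against a lock mass.

    Per pixel, the peak nearest to *lock_mz* within *search_ppm* is taken as
    the observed lock position; the dataset-wide median of those positions
    defines the correction factor ``lock_mz / median`` applied to every
    peak's m/z. If fewer than half the pixels contain a lock peak the
    dataset is returned uncorrected with a warning.
    """
    tol = lock_mz * search_ppm * 1e-6
    observed: list[float] = []
    for s in ds.spectra:
        if len(s) == 0:
            continue
        i = int(np.searchsorted(s.mz, lock_mz))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(s):
                d = abs(s.mz[j] - lock_mz)
                if d <= tol and (best is None or d < best[0]):
                    best = (d, float(s.mz[j]))
        if best is not None:
            observed.append(best[1])
    n_pixels = len(ds.spectra)
    if n_pixels == 0 or len(observed) < 0.5 * n_pixels:
        warnings.warn(
            f"lock mass {lock_mz} found in {len(observed)}/{n_pixels} pixels "
            "(<50%); dataset returned uncorrected"
        )
        return ds
    factor = lock_mz / float(np.median(observed))
    spectra = [
        PixelSpectrum(x=s.x, y=s.y, mz=s.mz * factor, drift=s.drift.copy(),
                      intensity=s.intensity.copy())
        for s in ds.spectra
    ]
    meta = dict(ds.metadata, lockmass_factor=factor)
    return replace(ds, spectra=spectra, metadata=meta)


@njit(cache=True)
def _greedy_signal_kernel(mz, drift, seed_order, half_mz, drift_win):  # pragma: no cover - jit
    """Group clusters (sorted ascending by mz) into dataset-wide signals.

    Seeds are visited in descending-intensity order; a seed claims every
    unassigned cluster within ±half_mz and ±drift_win of it. Returns the
    signal id per cluster and the seed cluster of each signal.
    """
    n = mz.shape[0]
    signal_id = np.full(n, -1, dtype=np.int64)
    seeds = np.empty(n, dtype=np.int64)
    n_sig = 0
    for k in range(n):
        s = seed_order[k]
        if signal_id[s] >= 0:
            continue
        lo = np.searchsorted(mz, mz[s] - half_mz)
        hi = np.searchsorted(mz, mz[s] + half_mz, side="right")
        for j in range(lo, hi):
            if signal_id[j] < 0 and abs(drift[j] - drift[s]) <= drift_win:
                signal_id[j] = n_sig
        seeds[n_sig] = s
        n_sig += 1
    return signal_id, seeds[:n_sig]


@njit(cache=True)
def _greedy_cluster_kernel(mz, drift, inten, offsets, half_mz, drift_win,
                           threshold, wmin, wmax):  # pragma: no cover - jit
    n_events = mz.shape[0]
    out_pix = np.empty(n_events, dtype=np.int64)
    out_mz = np.empty(n_events, dtype=np.float64)
    out_drift = np.empty(n_events, dtype=np.int32)
    out_int = np.empty(n_events, dtype=np.float64)
    assigned = np.zeros(n_events, dtype=np.uint8)
    n_out = 0
    for p in range(offsets.shape[0] - 1):
        a, b = offsets[p], offsets[p + 1]
        # events are pre-sorted within the pixel by (-intensity, mz, drift)
        for i in range(a, b):
            if assigned[i]:
                continue
            seed_mz = mz[i]
            seed_drift = drift[i]
            s_int = 0.0
            s_mzw = 0.0
            s_drw = 0.0
            dmin = seed_drift
            dmax = seed_drift
            nmem = 0
            for j in range(a, b):
                if assigned[j]:
                    continue
                if abs(mz[j] - seed_mz) <= half_mz and abs(drift[j] - seed_drift) <= drift_win:
                    assigned[j] = 1
                    w = inten[j]
                    s_int += w
                    s_mzw += mz[j] * w
                    s_drw += drift[j] * w
                    if drift[j] < dmin:
                        dmin = drift[j]
                    if drift[j] > dmax:
                        dmax = drift[j]
                    nmem += 1
            apex = inten[i]
            if apex < threshold:
                continue
            if nmem >= 2:
                extent = dmax - dmin + 1
                if extent < wmin or extent > wmax:
                    continue
            out_pix[n_out] = p
            out_mz[n_out] = s_mzw / s_int if s_int > 0 else seed_mz
            out_drift[n_out] = np.int32(np.floor(s_drw / s_int + 0.5)) if s_int > 0 else np.int32(seed_drift)
            out_int[n_out] = s_int
            n_out += 1
    return out_pix[:n_out], out_mz[:n_out], out_drift[:n_out], out_int[:n_out]


def pick_peaks(raw: IMSDataset, params: PickingParams | None = None) -> IMSDataset:
    """Cluster centroid events into picked peaks (see module docstring).

    Operates on raw counts; apply base-peak normalization afterwards — an
    intensity threshold in counts is meaningless on normalized data.
    """
    if params is None:
        params = PickingParams()
    xs, ys, mz, drift, inten, offsets = raw.flat_arrays()
    inten64 = inten.astype(np.float64)
    drift64 = drift.astype(np.float64)

    if mz.size:
        # seed order within each pixel: descending intensity, ties by
        # (lower m/z, lower drift); pixel index is the primary key so the
        # per-pixel offsets stay valid
        pix_idx = np.repeat(np.arange(len(raw.spectra)), np.diff(offsets))
        order = np.lexsort((drift64, mz, -inten64, pix_idx))
        mz_s, drift_s, int_s = mz[order], drift64[order], inten64[order]
    else:
        mz_s, drift_s, int_s = mz, drift64, inten64

    cpix, cmz, cdrift, cint = _greedy_cluster_kernel(
        mz_s, drift_s, int_s, offsets,
        params.mz_window / 2.0, float(params.drift_window),
        float(params.intensity_threshold),
        int(params.ims_peak_width_min), int(params.ims_peak_width_max),
    )

    # retain the top_n most intense SIGNALS (dataset-wide m/z × drift
    # species, grouped with the same windows); each surviving signal keeps
    # all of its per-pixel clusters so ion images stay intact
    if len(cmz):
        by_mz = np.argsort(cmz, kind="stable")
        cpix, cmz, cdrift, cint = cpix[by_mz], cmz[by_mz], cdrift[by_mz], cint[by_mz]
        cdrift_f = cdrift.astype(np.float64)
        seed_order = np.lexsort((cdrift_f, cmz, -cint))
        signal_id, seeds = _greedy_signal_kernel(
            cmz, cdrift_f, seed_order,
            params.mz_window / 2.0, float(params.drift_window),
        )
        if len(seeds) > params.top_n:
            totals = np.bincount(signal_id, weights=cint, minlength=len(seeds))
            rank = np.lexsort((cdrift_f[seeds], cmz[seeds], -totals))
            keep_signals = np.zeros(len(seeds), dtype=bool)
            keep_signals[rank[: params.top_n]] = True
            sel = keep_signals[signal_id]
            cpix, cmz, cdrift, cint = cpix[sel], cmz[sel], cdrift[sel], cint[sel]

    spectra: list[PixelSpectrum] = []
    by_pixel = np.argsort(cpix, kind="stable")
    cpix, cmz, cdrift, cint = cpix[by_pixel], cmz[by_pixel], cdrift[by_pixel], cint[by_pixel]
    bounds = np.searchsorted(cpix, np.arange(len(raw.spectra) + 1))
    for p in range(len(raw.spectra)):
        a, b = bounds[p], bounds[p + 1]
        spectra.append(
            PixelSpectrum(x=int(xs[p]), y=int(ys[p]), mz=cmz[a:b],
                          drift=cdrift[a:b], intensity=cint[a:b].astype(np.float32))
        )
    return replace(raw, spectra=spectra, metadata=dict(raw.metadata, picked="greedy3d"))


def preprocess_dataset(
    raw: IMSDataset,
    params: PickingParams | None = None,
    lock_mz: float = LOCK_MASS_MZ,
    search_ppm: float = 100.0,
    normalize: bool = True,
) -> IMSDataset:
    """Full preprocessing chain: recalibrate → pick → (optionally) normalize.

    With ``normalize=False`` the picked dataset keeps raw counts, as needed
    for total-ion-current exports.
    """
    ds = recalibrate_lockmass(raw, lock_mz=lock_mz, search_ppm=search_ppm)
    ds = pick_peaks(ds, params)
    if normalize:
        ds = normalize_dataset(ds)
    return ds
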