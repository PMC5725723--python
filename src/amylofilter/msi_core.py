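"""Domain types and I/O for ion-mobility MALDI mass spectrometry imaging.

The in-memory model is a pixel-indexed collection of centroided peak lists.
Each peak carries an m/z (Th), an integer drift-time bin, and an intensity
(counts, or a unitless value after normalization). Peaks within a pixel are
kept sorted by (m/z, drift) and stored as parallel NumPy arrays for speed;
the :class:`Peak` named tuple is a convenience view for element access.

Two on-disk formats are supported:

* imzML 1.1 (processed mode) + .ibd, with the drift-bin array encoded as a
  per-spectrum userParam (``"drift bins"``, space-separated integers) — the
  m/z and intensity arrays go through :mod:`pyimzml`;
* a single-file HDF5 cache with flat concatenated peak arrays, which is much
  faster for repeated access.

imzML pixel coordinates are 1-based; everything internal is 0-based, and the
imzML reader/writer is the only place the conversion happens.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Peak",
    "PixelSpectrum",
    "IMSDataset",
    "TargetPeptide",
    "FilterTolerances",
    "FormatError",
    "PanelError",
    "DEFAULT_N_DRIFT_BINS",
    "DEFAULT_PIXEL_SIZE_UM",
    "LOCK_MASS_MZ",
    "REFERENCE_MZ",
    "SIGNIFICANT_MASSES",
    "default_target_panel",
    "load_target_panel",
    "save_target_panel",
    "read_dataset",
    "write_dataset",
    "round_half_away",
]

#: SYNAPT-style mobility axis length (drift bins per spectrum).
DEFAULT_N_DRIFT_BINS = 200
#: Spatial resolution of the acquisitions this model targets (µm).
DEFAULT_PIXEL_SIZE_UM = 200.0
#: CHCA matrix-cluster signal used for single-point recalibration (Th).
LOCK_MASS_MZ = 825.101
#: ApoE tryptic peptide anchoring the colocalization filter (Th).
REFERENCE_MZ = 968.55
#: Panel masses with significantly different intensity between ALλ and ATTR,
#: used as default SVM features.
SIGNIFICANT_MASSES = (764.45, 1156.60, 1406.67, 1811.89, 1422.65, 1366.76)

COMMON_COMPONENT = "common_component"
AMYLOIDOGENIC = "amyloidogenic"

# (protein, theoretical [M+H]+ m/z). ApoE/SAP/VTN are co-deposited "common
# components" of amyloid; ApoAI/SAA/TTR are fibril-forming proteins.
_DEFAULT_PANEL_ROWS: tuple[tuple[str, float], ...] = (
    ("ApoE", 948.53),
    ("ApoE", 968.55),
    ("ApoE", 1497.80),
    ("SAP", 764.45),
    ("SAP", 1156.60),
    ("SAP", 1406.67),
    ("SAP", 1811.89),
    ("VTN", 887.51),
    ("VTN", 1314.68),
    ("VTN", 1422.65),
    ("VTN", 1503.84),
    ("VTN", 1646.82),
    ("VTN", 1666.78),
    ("ApoAI", 781.43),
    ("ApoAI", 1031.52),
    ("ApoAI", 1301.65),
    ("SAA", 1612.82),
    ("SAA", 1670.79),
    ("TTR", 1366.76),
)

_AMYLOIDOGENIC_PROTEINS = frozenset({"ApoAI", "SAA", "TTR"})

_DRIFT_PARAM_NAME = "drift bins"
_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the expected layout."""


class PanelError(ValueError):
    """Raised when a target-panel definition is invalid."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of the reported
    percentages, e.g. 93.75 → 93.8)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


class Peak(NamedTuple):
    """A single centroided detection in the m/z × drift plane."""

    mz: float
    drift: int
    intensity: float


@dataclass
class PixelSpectrum:
    """Centroid peak list of one pixel, sorted ascending by (m/z, drift)."""

    x: int
    y: int
    mz: np.ndarray
    drift: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.drift = np.asarray(self.drift, dtype=np.int32)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if not (self.mz.shape == self.drift.shape == self.intensity.shape):
            raise ValueError("mz, drift and intensity must have equal length")
        if self.mz.size and not _is_sorted(self.mz, self.drift):
            order = np.lexsort((self.drift, self.mz))
            self.mz = self.mz[order]
            self.drift = self.drift[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [
            Peak(float(m), int(d), float(i))
            for m, d, i in zip(self.mz, self.drift, self.intensity)
        ]

    def validate(self, n_drift_bins: int) -> None:
        if self.mz.size == 0:
            return
        if np.any(self.mz <= 0):
            raise ValueError(f"pixel ({self.x},{self.y}): non-positive m/z")
        if np.any((self.drift < 0) | (self.drift >= n_drift_bins)):
            raise ValueError(f"pixel ({self.x},{self.y}): drift bin out of range")
        if np.any(self.intensity < 0):
            raise ValueError(f"pixel ({self.x},{self.y}): negative intensity")


def _is_sorted(mz: np.ndarray, drift: np.ndarray) -> bool:
    if mz.size < 2:
        return True
    dm = np.diff(mz)
    if np.any(dm < 0):
        return False
    ties = dm == 0
    return not np.any(ties & (np.diff(drift) < 0))


@dataclass
class IMSDataset:
    """A rectangular-grid imaging dataset of per-pixel centroid peak lists.

    ``spectra`` need not cover the full ``width × height`` grid (tissue masks
    leave pixels unacquired), but coordinates must be unique and in bounds.
    ``metadata`` carries free-form strings (case id, organ, class label).
    """

    width: int
    height: int
    spectra: list[PixelSpectrum]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    n_drift_bins: int = DEFAULT_N_DRIFT_BINS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_drift_bins < 1:
            raise ValueError("n_drift_bins must be >= 1")
        if len(self.spectra) > self.width * self.height:
            raise ValueError("more spectra than grid pixels")

    def validate(self) -> None:
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            if not (0 <= s.x < self.width and 0 <= s.y < self.height):
                raise ValueError(f"pixel ({s.x},{s.y}) outside {self.width}x{self.height} grid")
            if (s.x, s.y) in seen:
                raise ValueError(f"duplicate pixel ({s.x},{s.y})")
            seen.add((s.x, s.y))
            s.validate(self.n_drift_bins)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def n_peaks(self) -> int:
        return sum(len(s) for s in self.spectra)

    def acquired_mask(self) -> np.ndarray:
        """Boolean (height × width) mask of acquired pixels."""
        mask = np.zeros((self.height, self.width), dtype=bool)
        for s in self.spectra:
            mask[s.y, s.x] = True
        return mask

    def flat_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated (x, y, mz, drift, intensity, offsets) view.

        ``offsets`` has ``len(spectra) + 1`` entries delimiting each pixel's
        slice of the peak arrays.
        """
        n = len(self.spectra)
        xs = np.fromiter((s.x for s in self.spectra), dtype=np.int32, count=n)
        ys = np.fromiter((s.y for s in self.spectra), dtype=np.int32, count=n)
        counts = np.fromiter((len(s) for s in self.spectra), dtype=np.int64, count=n)
        offsets = np.concatenate(([0], np.cumsum(counts)))
        if n:
            mz = np.concatenate([s.mz for s in self.spectra])
            drift = np.concatenate([s.drift for s in self.spectra])
            inten = np.concatenate([s.intensity for s in self.spectra])
        else:
            mz = np.empty(0)
            drift = np.empty(0, dtype=np.int32)
            inten = np.empty(0, dtype=np.float32)
        return xs, ys, mz, drift, inten, offsets


@dataclass
class TargetPeptide:
    """One entry of the tryptic-peptide target panel.

    ``ref_drift`` is the reference drift bin of the peptide; it may be unset
    (None) before calibration, in which case the drift criterion cannot be
    evaluated for this target. Fractional values are allowed because the
    reference is an average over cases.
    """

    protein: str
    theo_mz: float
    ref_drift: float | None = None
    role: str = COMMON_COMPONENT

    def __post_init__(self) -> None:
        if not self.protein:
            raise PanelError("protein symbol must be non-empty")
        if self.theo_mz <= 0:
            raise PanelError(f"non-positive theoretical m/z for {self.protein}")


@dataclass
class FilterTolerances:
    """The three MDIC thresholds: mass accuracy (ppm), drift time (bins) and
    minimum image correlation (Pearson R)."""

    max_ppm: float = 30.0
    max_drift_err: float = 2.5
    min_ic: float = 0.75

    def __post_init__(self) -> None:
        if self.max_ppm <= 0:
            raise ValueError("max_ppm must be > 0")
        if self.max_drift_err < 0:
            raise ValueError("max_drift_err must be >= 0")
        if not (-1.0 <= self.min_ic <= 1.0):
            raise ValueError("min_ic must lie in [-1, 1]")


def default_target_panel() -> list[TargetPeptide]:
    """The 19-peptide six-protein panel, with unset reference drifts."""
    return [
        TargetPeptide(
            protein=p,
            theo_mz=mz,
            ref_drift=None,
            role=AMYLOIDOGENIC if p in _AMYLOIDOGENIC_PROTEINS else COMMON_COMPONENT,
        )
        for p, mz in _DEFAULT_PANEL_ROWS
    ]


def _validate_panel(panel: Sequence[TargetPeptide]) -> list[TargetPeptide]:
    mzs = sorted(t.theo_mz for t in panel)
    for a, b in zip(mzs, mzs[1:]):
        if b - a < 1e-3:
            raise PanelError(f"duplicate target m/z within 1 mDa: {a} vs {b}")
    return list(panel)


def load_target_panel(path: str | os.PathLike) -> list[TargetPeptide]:
    """Load a panel from CSV (columns ``protein,theo_mz,ref_drift``), or the
    built-in 19-peptide panel when *path* is the string ``"default"``."""
    if isinstance(path, str) and path == "default":
        return default_target_panel()
    import pandas as pd

    df = pd.read_csv(path, dtype={"protein": str})
    missing = {"protein", "theo_mz"} - set(df.columns)
    if missing:
        raise PanelError(f"panel CSV missing columns: {sorted(missing)}")
    panel: list[TargetPeptide] = []
    for _, row in df.iterrows():
        try:
            mz = float(row["theo_mz"])
        except (TypeError, ValueError) as exc:
            raise PanelError(f"non-numeric theo_mz: {row['theo_mz']!r}") from exc
        ref = row.get("ref_drift")
        ref_drift = None if ref is None or (isinstance(ref, float) and math.isnan(ref)) else float(ref)
        role = row.get("role")
        if not isinstance(role, str) or not role:
            role = AMYLOIDOGENIC if row["protein"] in _AMYLOIDOGENIC_PROTEINS else COMMON_COMPONENT
        panel.append(TargetPeptide(protein=str(row["protein"]), theo_mz=mz, ref_drift=ref_drift, role=role))
    return _validate_panel(panel)


def save_target_panel(panel: Sequence[TargetPeptide], path: str | os.PathLike) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "protein": [t.protein for t in panel],
            "theo_mz": [t.theo_mz for t in panel],
            "ref_drift": [t.ref_drift for t in panel],
            "role": [t.role for t in panel],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(ds: IMSDataset, path: str | os.PathLike, format: str = "auto") -> None:
    """Write *ds* to imzML(+ibd) or to the HDF5 cache format.

    m/z is stored at 64-bit, intensity at 32-bit float; drift bins as
    integers (lossless round trip for all three fields).
    """
    fmt = _resolve_format(path, format)
    if fmt == "imzml":
        _write_imzml(ds, path)
    else:
        _write_cache(ds, path)


def read_dataset(path: str | os.PathLike, format: str = "auto") -> IMSDataset:
    """Read a dataset written by :func:`write_dataset`."""
    fmt = _resolve_format(path, format)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if fmt == "imzml":
        return _read_imzml(path)
    return _read_cache(path)


def _resolve_format(path: str | os.PathLike, format: str) -> str:
    if format != "auto":
        if format not in ("imzml", "cache"):
            raise ValueError(f"unknown format {format!r}")
        return format
    return "imzml" if str(path).lower().endswith(".imzml") else "cache"


def _xml_safe(value) -> str:
    from xml.sax.saxutils import escape

    # pyimzml writes userParam values verbatim into XML attributes
    return escape(str(value), {'"': "&quot;", "'": "&apos;"})


def _write_imzml(ds: IMSDataset, path: str | os.PathLike) -> None:
    from pyimzml.ImzMLWriter import ImzMLWriter

    meta = dict(ds.metadata)
    meta["_width"] = ds.width
    meta["_height"] = ds.height
    meta["_pixel_size"] = ds.pixel_size
    meta["_n_drift_bins"] = ds.n_drift_bins
    meta_params = [
        {"name": f"meta:{_xml_safe(k)}", "value": _xml_safe(v)}
        for k, v in meta.items()
    ]
    with ImzMLWriter(str(path), mode="processed", intensity_dtype=np.float32) as writer:
        for s in ds.spectra:
            if len(s) == 0:
                # pyimzml cannot encode zero-length arrays: write a
                # placeholder peak the reader strips again
                writer.addSpectrum(
                    np.array([1.0]), np.array([0.0], dtype=np.float32),
                    (int(s.x) + 1, int(s.y) + 1, 1),
                    userParams=[
                        {"name": _DRIFT_PARAM_NAME, "value": "0"},
                        {"name": "placeholder", "value": "1"},
                    ] + meta_params,
                )
                continue
            drift_str = " ".join(str(int(d)) for d in s.drift)
            params = [{"name": _DRIFT_PARAM_NAME, "value": drift_str}] + meta_params
            # imzML is 1-based in both pixel coordinates
            writer.addSpectrum(
                s.mz.astype(np.float64),
                s.intensity.astype(np.float32),
                (int(s.x) + 1, int(s.y) + 1, 1),
                userParams=params,
            )
        if not ds.spectra:
            # pyimzml cannot emit a spectrum-free file either; keep a
            # sentinel spectrum at (1,1) that the reader drops entirely.
            writer.addSpectrum(
                np.array([1.0]), np.array([0.0], dtype=np.float32), (1, 1, 1),
                userParams=[
                    {"name": _DRIFT_PARAM_NAME, "value": "0"},
                    {"name": "placeholder", "value": "1"},
                    {"name": "meta:_empty_sentinel", "value": "1"},
                ] + meta_params,
            )


def _iter_imzml_user_params(path: str | os.PathLike):
    """Yield, per spectrum in document order, the dict of userParams."""
    from lxml import etree

    for _, el in etree.iterparse(str(path), tag=_MZML_NS + "spectrum"):
        params = {
            u.get("name"): u.get("value")
            for u in el.iter(_MZML_NS + "userParam")
        }
        yield params
        el.clear()


def _read_imzml(path: str | os.PathLike) -> IMSDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(str(path))[0] + ".ibd"
    if not os.path.exists(ibd):
        raise IOError(f"missing binary file for {path}: {ibd}")

    parser = ImzMLParser(str(path))
    user_params = list(_iter_imzml_user_params(path))
    if len(user_params) != len(parser.coordinates):
        raise FormatError("spectrum count mismatch between XML and index")

    meta: dict = {}
    sentinel = False
    spectra: list[PixelSpectrum] = []
    max_x = max_y = 0
    for i, coord in enumerate(parser.coordinates):
        params = user_params[i]
        for key, value in params.items():
            if key.startswith("meta:"):
                meta.setdefault(key[5:], value)
        if params.get("meta:_empty_sentinel") == "1":
            sentinel = True
            continue
        if _DRIFT_PARAM_NAME not in params:
            raise FormatError(
                f"spectrum at imzML pixel {tuple(coord[:2])} has no drift-bin array"
            )
        if params.get("placeholder") == "1":
            mzs = np.empty(0)
            intensities = np.empty(0, dtype=np.float32)
            drift_str = ""
        else:
            mzs, intensities = parser.getspectrum(i)
            drift_str = params[_DRIFT_PARAM_NAME]
        drift = (
            np.array(drift_str.split(), dtype=np.int32)
            if drift_str
            else np.empty(0, np.int32)
        )
        if drift.size != len(mzs):
            raise FormatError(
                f"drift array length mismatch at imzML pixel {tuple(coord[:2])}"
            )
        x, y = int(coord[0]) - 1, int(coord[1]) - 1  # 1-based -> 0-based
        spectra.append(PixelSpectrum(x=x, y=y, mz=np.asarray(mzs), drift=drift, intensity=np.asarray(intensities)))
        max_x = max(max_x, x)
        max_y = max(max_y, y)

    meta.pop("_empty_sentinel", None)
    if sentinel:
        spectra = []
    width = int(meta.pop("_width", max_x + 1))
    height = int(meta.pop("_height", max_y + 1))
    pixel_size = float(meta.pop("_pixel_size", DEFAULT_PIXEL_SIZE_UM))
    n_drift_bins = int(meta.pop("_n_drift_bins", DEFAULT_N_DRIFT_BINS))
    return IMSDataset(
        width=width,
        height=height,
        spectra=spectra,
        pixel_size=pixel_size,
        n_drift_bins=n_drift_bins,
        metadata=meta,
    )


def _write_cache(ds: IMSDataset, path: str | os.PathLike) -> None:
    import h5py

    xs, ys, mz, drift, inten, offsets = ds.flat_arrays()
    try:
        f = h5py.File(str(path), "w")
    except OSError as exc:
        raise IOError(f"cannot write cache file {path}: {exc}") from exc
    with f:
        f.attrs["width"] = ds.width
        f.attrs["height"] = ds.height
        f.attrs["pixel_size"] = ds.pixel_size
        f.attrs["n_drift_bins"] = ds.n_drift_bins
        f.attrs["metadata"] = json.dumps(ds.metadata)
        f.create_dataset("pixel_x", data=xs)
        f.create_dataset("pixel_y", data=ys)
        f.create_dataset("offsets", data=offsets)
        f.create_dataset("mz", data=mz.astype(np.float64))
        f.create_dataset("drift", data=drift.astype(np.int32))
        f.create_dataset("intensity", data=inten.astype(np.float32))


def _read_cache(path: str | os.PathLike) -> IMSDataset:
    import h5py

    with h5py.File(str(path), "r") as f:
        required = {"pixel_x", "pixel_y", "offsets", "mz", "drift", "intensity"}
        if not required <= set(f.keys()):
            raise FormatError(f"{path}: not an amylofilter cache file")
        xs = f["pixel_x"][:]
        ys = f["pixel_y"][:]
        offsets = f["offsets"][:]
        mz = f["mz"][:]
        drift = f["drift"][:]
        inten = f["intensity"][:]
        spectra = [
            PixelSpectrum(
                x=int(xs[i]),
                y=int(ys[i]),
                mz=mz[offsets[i]:offsets[i + 1]],
                drift=drift[offsets[i]:offsets[i + 1]],
                intensity=inten[offsets[i]:offsets[i + 1]],
            )
            for i in range(len(xs))
        ]
        return IMSDataset(
            width=int(f.attrs["width"]),
            height=int(f.attrs["height"]),
            spectra=spectra,
            pixel_size=float(f.attrs["pixel_size"]),
            n_drift_bins=int(f.attrs["n_drift_bins"]),
            metadata=json.loads(f.attrs["metadata"]),
        )
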