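"""Volumetric feature extraction: smoothed gray-matter ROI means and pALFF.

Two per-ROI imaging features feed the mediation pipeline:

* **GMV** — the mean of a (segmented, already-normalized) gray-matter map
  over each atlas ROI, after isotropic Gaussian smoothing (8 mm FWHM by
  default).
* **pALFF** — partial amplitude of low-frequency fluctuations: per voxel,
  the ratio of spectral power inside a low-frequency band (0.01-0.08 Hz) to
  the power over the whole detectable range up to the Nyquist frequency
  1/(2 TR), normalized by the mean raw ratio within the brain mask.

"Power" is the squared FFT magnitude of the (optionally linearly detrended)
series on a rectangular-window periodogram; an ``amplitude`` toggle switches
to the |FFT| variant used by classic ALFF implementations.  Band edges are
inclusive on the FFT's natural frequency grid; no interpolation between
bins.  Smoothing applies to gray-matter maps only; pALFF is computed on
unsmoothed series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import detrend as _linear_detrend

__all__ = [
    "Volume3D",
    "Volume4D",
    "AtlasVolume",
    "PalffConfig",
    "nyquist",
    "gaussian_smooth",
    "roi_aggregate",
    "periodogram",
    "compute_palff",
    "extract_gmv_table",
    "extract_palff_table",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # approx 2.3548


def _default_affine(voxel_mm: float = 3.0) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return aff


@dataclass
class Volume3D:
    """A 3D volume with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "Volume3D":
        img = nib.load(path)
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)


@dataclass
class Volume4D:
    """A 3D + time series with its affine and repetition time (s)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)
    tr: float = 1.65

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.shape[3] < 8:
            raise ValueError("need >= 8 time points for spectral estimation")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = img.header.get_zooms()
        img.header.set_zooms((*zooms[:3], self.tr))
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, tr: float | None = None) -> "Volume4D":
        img = nib.load(path)
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, tr=tr)


@dataclass
class AtlasVolume:
    """Integer-labeled parcellation; 0 is background.

    ``label_map`` maps each nonzero label to (ROI name, hemisphere "L"/"R").
    """

    data: np.ndarray
    label_map: dict[int, tuple[str, str]]
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int32)
        present = set(np.unique(self.data)) - {0}
        unmapped = present - set(self.label_map)
        if unmapped:
            raise ValueError(f"labels present in volume but not in label_map: {sorted(unmapped)}")

    @property
    def name_to_label(self) -> dict[str, int]:
        return {name: lab for lab, (name, _h) in self.label_map.items()}

    def hemisphere(self, name: str) -> str:
        for _lab, (nm, hemi) in self.label_map.items():
            if nm == name:
                return hemi
        raise KeyError(name)

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), path)


@dataclass(frozen=True)
class PalffConfig:
    """Spectral-ratio settings for pALFF."""

    band_low: float = 0.01
    band_high: float = 0.08
    detrend: bool = True
    exclude_dc: bool = True
    amplitude: bool = False  # sum |FFT| instead of |FFT|^2

    def validate(self, tr: float) -> None:
        if not 0.0 <= self.band_low < self.band_high:
            raise ValueError("need 0 <= band_low < band_high")
        if self.band_high > nyquist(tr) + 1e-12:
            raise ValueError(
                f"band_high {self.band_high} Hz exceeds Nyquist {nyquist(tr):.4g} Hz at TR {tr}"
            )


def nyquist(tr: float) -> float:
    """Highest detectable frequency (Hz) at repetition time ``tr`` seconds."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return 1.0 / (2.0 * tr)


def gaussian_smooth(vol: Volume3D, fwhm: float) -> Volume3D:
    """Isotropic Gaussian blur specified as FWHM in mm.

    Per-axis sigma in voxels is fwhm / (voxel size * 2*sqrt(2 ln 2));
    anisotropic voxels are handled per axis.  fwhm=0 is the identity.
    Boundaries use nearest-edge replication, so constant volumes stay
    constant everywhere.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return Volume3D(vol.data.copy(), vol.affine.copy())
    sigma_vox = fwhm / (_FWHM_TO_SIGMA * vol.voxel_size)
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma=sigma_vox, mode="nearest")
    return Volume3D(out, vol.affine.copy())


def roi_aggregate(
    vol: Volume3D,
    atlas: AtlasVolume,
    labels: list[int] | list[str] | None = None,
) -> pd.Series:
    """Arithmetic mean of the volume over each requested atlas ROI.

    ``labels`` may be integer labels or ROI names; None means every label in
    the atlas map.  Raises if a requested label has no voxels, naming it.
    """
    if vol.data.shape != atlas.data.shape:
        raise ValueError(
            f"volume grid {vol.data.shape} does not match atlas grid {atlas.data.shape}"
        )
    if labels is None:
        labels = sorted(atlas.label_map)
    labels = list(labels)
    if not labels:
        raise ValueError("empty ROI selection")
    name_to_label = atlas.name_to_label
    ints: list[int] = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in name_to_label:
                raise KeyError(f"ROI name {lab!r} not in atlas label_map")
            ints.append(name_to_label[lab])
        else:
            if int(lab) not in atlas.label_map:
                raise KeyError(f"label {lab} not in atlas label_map")
            ints.append(int(lab))
    present = set(np.unique(atlas.data))
    absent = [atlas.label_map[i][0] for i in ints if i not in present]
    if absent:
        raise ValueError(f"atlas volume contains no voxels for ROI(s): {absent}")
    means = ndimage.mean(vol.data.astype(float), labels=atlas.data, index=ints)
    names = [atlas.label_map[i][0] for i in ints]
    return pd.Series(np.asarray(means, dtype=float), index=names, name="roi_mean")


def periodogram(ts: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram.

    Returns (frequencies, power) where power sums the two-sided spectrum
    into non-negative frequencies (|FFT|^2 / n, doubled for interior bins),
    so that total power including DC equals the time-domain sum of squares
    (Parseval).  Accepts a 1D series or a (V, T) stack.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    F = np.fft.rfft(ts, axis=-1)
    power = np.abs(F) ** 2 / n
    weights = np.full(F.shape[-1], 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin is not duplicated
    power = power * weights
    freqs = np.fft.rfftfreq(n, d=tr)
    return freqs, power


def _raw_ratio(ts: np.ndarray, tr: float, cfg: PalffConfig) -> np.ndarray:
    """Band power / total detectable power per series; 0 for all-zero series."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if cfg.detrend:
        ts = _linear_detrend(ts, axis=-1, type="linear")
    freqs, power = periodogram(ts, tr)
    if cfg.amplitude:
        power = np.sqrt(power)
    in_band = (freqs >= cfg.band_low - 1e-12) & (freqs <= cfg.band_high + 1e-12)
    denom_bins = freqs > 0 if cfg.exclude_dc else freqs >= 0
    if cfg.exclude_dc:
        in_band &= freqs > 0
    num = power[:, in_band].sum(axis=1)
    den = power[:, denom_bins].sum(axis=1)
    ratio = np.zeros(ts.shape[0])
    ok = den > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} time series had zero total power; raw ratio set to 0",
            RuntimeWarning,
        )
    ratio[ok] = num[ok] / den[ok]
    return ratio


def compute_palff(
    bold: Volume4D, mask: Volume3D, cfg: PalffConfig | None = None
) -> Volume3D:
    """pALFF map: per-voxel band-power ratio, normalized by the mask mean.

    Out-of-mask voxels are set to 0.  The mean of the returned map over the
    mask is exactly 1 (up to floating point).
    """
    cfg = cfg or PalffConfig()
    cfg.validate(bold.tr)
    m = np.asarray(mask.data) > 0
    if m.shape != bold.data.shape[:3]:
        raise ValueError("mask grid does not match BOLD grid")
    if not m.any():
        raise ValueError("empty brain mask")
    ts = bold.data[m]  # (V, T)
    ratio = _raw_ratio(ts, bold.tr, cfg)
    mean_ratio = ratio.mean()
    if mean_ratio <= 0:
        raise ValueError("mean raw ratio within mask is zero; cannot normalize")
    out = np.zeros(bold.data.shape[:3])
    out[m] = ratio / mean_ratio
    return Volume3D(out, np.asarray(bold.affine).copy())


# ---------------------------------------------------------------------------
# per-participant feature tables


def extract_gmv_table(
    volumes: dict[str, Volume3D],
    atlas: AtlasVolume,
    fwhm: float = 8.0,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Participant x ROI table of smoothed gray-matter ROI means."""
    rows = {}
    for pid, vol in volumes.items():
        rows[pid] = roi_aggregate(gaussian_smooth(vol, fwhm), atlas, labels)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df


def extract_palff_table(
    bolds: dict[str, Volume4D],
    mask: Volume3D,
    atlas: AtlasVolume,
    cfg: PalffConfig | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Participant x ROI table of mean normalized pALFF per ROI."""
    rows = {}
    for pid, bold in bolds.items():
        rows[pid] = roi_aggregate(compute_palff(bold, mask, cfg), atlas, labels)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df
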