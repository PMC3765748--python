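"""Resting-state BOLD preprocessing on already-aligned 4D volumes.

The chain mirrors the standard hub-connectivity preprocessing for
resting-state fMRI: drop non-steady-state volumes, remove per-voxel linear
trends, low-pass filter at 0.08 Hz, regress nine nuisance series (six
motion parameters plus whole-brain / white-matter / CSF means), smooth with
a 4 mm FWHM Gaussian and downsample to a 4 mm isotropic analysis grid.
Head-motion estimation and template registration are out of scope: inputs
are assumed aligned, with motion supplied only as nuisance regressors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, signal

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493  # sigma = FWHM / (2*sqrt(2*ln 2))

NUISANCE_COLUMNS = [
    "mot1", "mot2", "mot3", "mot4", "mot5", "mot6", "global", "wm", "csf",
]


class PreprocessError(ValueError):
    pass


@dataclass
class VoxelTimeSeriesMatrix:
    """In-mask voxel-by-time BOLD matrix with its grid geometry.

    ``data`` has one row per True voxel of ``mask`` (C order), ``affine``
    maps voxel indices to world mm, ``tr_s`` is the repetition time.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    tr_s: float
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("data must be 2D (voxels x time)")
        if self.data.shape[0] != int(self.mask.sum()):
            raise PreprocessError(
                f"row count {self.data.shape[0]} != mask voxel count {int(self.mask.sum())}"
            )
        if self.tr_s <= 0:
            raise PreprocessError("tr_s must be positive")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise PreprocessError("affine is singular")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    def to_volume(self, values: Optional[np.ndarray] = None, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values (default: frame 0) back into the 3D grid."""
        v = self.data[:, 0] if values is None else np.asarray(values)
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = v
        return vol


@dataclass
class PreprocessConfig:
    """Stage parameters, defaulting to the study's published pipeline."""

    drop_k: int = 4
    detrend: bool = True
    cutoff_hz: Optional[float] = 0.08
    filter_kind: str = "butterworth"  # or "fft"
    regress_nuisance: bool = True
    fwhm_mm: float = 4.0
    target_mm: Optional[float] = 4.0
    resample_method: str = "trilinear"  # or "block_mean"
    mask_source: str = "auto"  # "auto" or "provided"
    mask_threshold: float = 0.10  # fraction of robust max for the auto mask

    @classmethod
    def disabled(cls) -> "PreprocessConfig":
        """A pass-through configuration (every stage off)."""
        return cls(drop_k=0, detrend=False, cutoff_hz=None,
                   regress_nuisance=False, fwhm_mm=0.0, target_mm=None)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def _as_array4d(img):
    if isinstance(img, nib.spatialimages.SpatialImage):
        data = np.asanyarray(img.dataobj)
        return data, img.affine
    raise PreprocessError("expected a nibabel spatial image")


def drop_initial_volumes(img: nib.Nifti1Image, k: int) -> nib.Nifti1Image:
    """Remove the first ``k`` frames (non-steady-state volumes)."""
    data, affine = _as_array4d(img)
    if data.ndim != 4:
        raise PreprocessError("expected a 4D image")
    if k < 0:
        raise PreprocessError("k must be non-negative")
    if k >= data.shape[3]:
        raise PreprocessError(
            f"cannot drop {k} of {data.shape[3]} frames: nothing would remain"
        )
    if k == 0:
        return img
    return nib.Nifti1Image(data[..., k:], affine, img.header)


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove per-row least-squares linear trends (intercept + slope*t).

    Residuals are exactly orthogonal to [1, t]. Accepts a (voxels, time)
    array; a VoxelTimeSeriesMatrix is handled by :func:`run_preprocess`.
    """
    X = np.asarray(ts, dtype=float)
    if X.ndim == 1:
        return detrend_linear(X[None, :])[0]
    n_t = X.shape[1]
    if n_t < 3:
        raise PreprocessError("detrending requires at least 3 timepoints")
    t = np.arange(n_t, dtype=float)
    t = t - t.mean()
    slope = (X @ t) / (t @ t)
    resid = X - X.mean(axis=1, keepdims=True) - slope[:, None] * t[None, :]
    return resid


def lowpass_filter(
    ts: np.ndarray,
    tr_s: float,
    cutoff_hz: float = 0.08,
    kind: str = "butterworth",
) -> np.ndarray:
    """Zero-phase low-pass filter along the time axis.

    ``butterworth`` applies a 4th-order Butterworth forward and backward
    (zero phase, doubled attenuation); ``fft`` zeroes all frequency bins
    strictly above the cutoff (ideal brick-wall response).
    """
    X = np.asarray(ts, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    nyquist = 0.5 / tr_s
    if not 0 < cutoff_hz < nyquist:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.4g} Hz)"
        )
    if kind == "butterworth":
        b, a = signal.butter(4, cutoff_hz / nyquist)
        padlen = min(3 * (max(len(a), len(b)) - 1) * 3, X.shape[1] - 1)
        out = signal.filtfilt(b, a, X, axis=1, padlen=padlen)
    elif kind == "fft":
        freqs = np.fft.rfftfreq(X.shape[1], d=tr_s)
        spec = np.fft.rfft(X, axis=1)
        spec[:, freqs > cutoff_hz] = 0.0
        out = np.fft.irfft(spec, n=X.shape[1], axis=1)
    else:
        raise PreprocessError(f"unknown filter kind {kind!r}")
    return out[0] if one_d else out


def regress_nuisance(ts: np.ndarray, nuisance) -> np.ndarray:
    """Residualize each row on the nine nuisance series plus an intercept.

    Residuals are orthogonal to every regressor. A rank-deficient design
    raises, naming the offending column(s).
    """
    X = np.asarray(ts, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    if isinstance(nuisance, pd.DataFrame):
        names = list(nuisance.columns)
        N = nuisance.to_numpy(dtype=float)
    else:
        N = np.asarray(nuisance, dtype=float)
        names = [f"regressor_{i}" for i in range(N.shape[1])]
    if N.ndim != 2:
        raise PreprocessError("nuisance must be 2D (time x regressors)")
    if N.shape[0] != X.shape[1]:
        raise PreprocessError(
            f"nuisance length {N.shape[0]} != series length {X.shape[1]}"
        )
    if np.isnan(N).any():
        raise PreprocessError("nuisance table contains missing values")
    design = np.column_stack([np.ones(N.shape[0]), N])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns adding no rank over their predecessors
        bad = []
        running = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.column_stack([running, design[:, j]])
            if np.linalg.matrix_rank(cand) == running.shape[1]:
                bad.append(names[j - 1])
            else:
                running = cand
        raise PreprocessError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    resid = X - (design @ beta).T
    return resid[0] if one_d else resid


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))


def smooth_gaussian(img: nib.Nifti1Image, fwhm_mm: float = 4.0) -> nib.Nifti1Image:
    """Per-frame 3D Gaussian smoothing with the kernel specified in mm."""
    if fwhm_mm < 0:
        raise PreprocessError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return img
    data, affine = _as_array4d(img)
    sigmas_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_sizes_mm(affine)
    sigma = tuple(sigmas_vox) + ((0.0,) if data.ndim == 4 else ())
    sm = ndimage.gaussian_filter(data.astype(float), sigma=sigma)
    return nib.Nifti1Image(sm, affine, img.header)


def _trilinear_weights(src_shape, src_affine, tgt_shape, tgt_affine):
    """Precompute 8-corner gather indices and weights for trilinear resampling."""
    M = np.linalg.inv(src_affine) @ tgt_affine
    ii, jj, kk = np.indices(tgt_shape)
    tgt_vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    src = (M @ tgt_vox)[:3]
    base = np.floor(src).astype(int)
    frac = src - base
    idx_list, w_list = [], []
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        pos = base + off[:, None]
        w = np.prod(np.where(off[:, None] == 1, frac, 1.0 - frac), axis=0)
        pos = np.clip(pos, 0, np.array(src_shape)[:, None] - 1)  # replicate edges
        idx_list.append(np.ravel_multi_index(tuple(pos), src_shape))
        w_list.append(w)
    return np.array(idx_list), np.array(w_list)


def resample_to_4mm(
    img: nib.Nifti1Image,
    method: str = "trilinear",
    target_mm: float = 4.0,
) -> nib.Nifti1Image:
    """Resample onto an isotropic ``target_mm`` grid sharing the source origin.

    Trilinear interpolation by default; ``block_mean`` averages integer
    blocks and requires an integral zoom factor.
    """
    data, affine = _as_array4d(img)
    vs = voxel_sizes_mm(affine)
    if np.any(vs <= 0) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise PreprocessError("degenerate affine")
    spatial = np.array(data.shape[:3])
    if method == "block_mean":
        factors = target_mm / vs
        if not np.allclose(factors, np.round(factors)):
            raise PreprocessError(
                f"block_mean needs integral factors, got {factors}"
            )
        f = np.round(factors).astype(int)
        if np.any(spatial % f):
            raise PreprocessError(
                f"shape {tuple(spatial)} not divisible by factors {tuple(f)}"
            )
        new_shape = spatial // f
        frames = data.reshape(
            new_shape[0], f[0], new_shape[1], f[1], new_shape[2], f[2], -1
        )
        out = frames.mean(axis=(1, 3, 5))
        if data.ndim == 3:
            out = out[..., 0]
        # output voxel centres sit at source voxel f*v + (f-1)/2
        shift = np.eye(4)
        shift[:3, 3] = (f - 1) / 2.0
        new_affine = affine @ shift
        new_affine[:3, :3] = affine[:3, :3] @ np.diag(f)
        return nib.Nifti1Image(out, new_affine, img.header)
    if method != "trilinear":
        raise PreprocessError(f"unknown resampling method {method!r}")
    factors = target_mm / vs
    new_shape = np.maximum(np.ceil(spatial / factors).astype(int), 1)
    new_affine = affine @ np.diag([factors[0], factors[1], factors[2], 1.0])
    idx, w = _trilinear_weights(tuple(spatial), affine, tuple(new_shape), new_affine)
    flat = data.reshape(-1, data.shape[3]) if data.ndim == 4 else data.reshape(-1, 1)
    out = np.zeros((idx.shape[1], flat.shape[1]))
    for c in range(8):
        out += w[c][:, None] * flat[idx[c]]
    out_shape = tuple(new_shape) + ((data.shape[3],) if data.ndim == 4 else ())
    return nib.Nifti1Image(out.reshape(out_shape), new_affine, img.header)


def compute_brain_mask(data4d: np.ndarray, threshold: float = 0.10) -> np.ndarray:
    """Heuristic mask: nonzero temporal variance and mean intensity above
    ``threshold`` of the robust (98th percentile) mean-image maximum."""
    mean_img = data4d.mean(axis=3)
    robust_max = np.percentile(mean_img, 98)
    var_ok = data4d.std(axis=3) > 0
    return (mean_img > threshold * robust_max) & var_ok


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

def run_preprocess(
    scan,
    nuisance=None,
    config: Optional[PreprocessConfig] = None,
    mask: Optional[np.ndarray] = None,
) -> VoxelTimeSeriesMatrix:
    """Apply drop -> detrend -> low-pass -> nuisance regression -> smooth ->
    resample -> mask extraction, recording a provenance log.

    ``scan`` is a 4D NIfTI image or path; ``nuisance`` a 9-column table
    (DataFrame or path) sampled at the original frame rate (its first
    ``drop_k`` rows are discarded alongside the volumes, or it may already
    have the post-drop length); ``mask`` (source grid) is used when
    ``config.mask_source == "provided"``.
    """
    cfg = config or PreprocessConfig()
    if isinstance(scan, (str,)) or hasattr(scan, "__fspath__"):
        scan = nib.load(str(scan))
    if isinstance(nuisance, (str,)) or hasattr(nuisance, "__fspath__"):
        nuisance = pd.read_csv(str(nuisance), sep="\t")
    log: list = []

    img = drop_initial_volumes(scan, cfg.drop_k)
    log.append({"step": "drop_initial_volumes", "k": cfg.drop_k})
    data, affine = _as_array4d(img)
    if data.ndim != 4:
        raise PreprocessError("expected a 4D scan")
    if cfg.mask_source == "auto":
        # from the raw intensities, before detrending removes the baseline
        mask = compute_brain_mask(data, cfg.mask_threshold)
    tr_s = float(scan.header.get_zooms()[3]) if len(scan.header.get_zooms()) > 3 else 0.0
    if tr_s <= 0:
        tr_s = 3.0  # header without timing information: study default TR
    n_t = data.shape[3]

    flat = data.reshape(-1, n_t).astype(float)
    if cfg.detrend:
        flat = detrend_linear(flat)
        log.append({"step": "detrend_linear"})
    if cfg.cutoff_hz is not None:
        flat = lowpass_filter(flat, tr_s, cfg.cutoff_hz, cfg.filter_kind)
        log.append({"step": "lowpass_filter", "cutoff_hz": cfg.cutoff_hz,
                    "kind": cfg.filter_kind})
    if cfg.regress_nuisance and nuisance is not None:
        nuis = nuisance
        if len(nuis) == n_t + cfg.drop_k:
            nuis = nuis.iloc[cfg.drop_k:].reset_index(drop=True)
        flat = regress_nuisance(flat, nuis)
        log.append({"step": "regress_nuisance", "n_regressors": nuis.shape[1]})
    img = nib.Nifti1Image(flat.reshape(data.shape), affine, img.header)

    if cfg.fwhm_mm and cfg.fwhm_mm > 0:
        img = smooth_gaussian(img, cfg.fwhm_mm)
        log.append({"step": "smooth_gaussian", "fwhm_mm": cfg.fwhm_mm})
    if cfg.mask_source == "provided" and mask is None:
        raise PreprocessError("mask_source='provided' but no mask given")
    if cfg.target_mm is not None:
        src_vs = voxel_sizes_mm(img.affine)
        if not np.allclose(src_vs, cfg.target_mm):
            if mask is not None:
                mimg = resample_to_4mm(
                    nib.Nifti1Image(mask.astype(float), img.affine),
                    cfg.resample_method, cfg.target_mm)
                mask = np.asanyarray(mimg.dataobj) > 0.5
            img = resample_to_4mm(img, cfg.resample_method, cfg.target_mm)
            log.append({"step": "resample", "target_mm": cfg.target_mm,
                        "method": cfg.resample_method})

    data, affine = _as_array4d(img)
    if mask is not None:
        final_mask = np.asarray(mask, bool)
    else:
        final_mask = compute_brain_mask(data, cfg.mask_threshold)
    if final_mask.shape != data.shape[:3]:
        raise PreprocessError("mask shape does not match image grid")
    log.append({"step": "mask_extraction", "source": cfg.mask_source,
                "n_voxels": int(final_mask.sum())})
    return VoxelTimeSeriesMatrix(
        data=data[final_mask], mask=final_mask, affine=affine, tr_s=tr_s,
        provenance=log,
    )
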