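"""Voxel-wise weighted-degree ("hub") connectivity maps.

Each in-mask voxel's Pearson correlation with every other in-mask voxel is
computed; a voxel's degree is the number of partners whose correlation
exceeds a threshold (default r > 0.25, strictly; positive correlations
only; self excluded). Degree maps are z-normalized across voxels within
subject for group comparison — a monotone transform that preserves the
topography of the map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np

from .preprocess import (PreprocessConfig, VoxelTimeSeriesMatrix,
                         run_preprocess)


class ConnectivityError(ValueError):
    pass


@dataclass
class DegreeMap:
    """Per-voxel supra-threshold link counts over the in-mask voxels."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    r_threshold: float = 0.25
    subject_id: Optional[str] = None
    condition: Optional[str] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape[0] != int(self.mask.sum()):
            raise ConnectivityError("values length != mask voxel count")
        if not 0 < self.r_threshold < 1:
            raise ConnectivityError("r_threshold must lie in (0, 1)")

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.to_volume().astype(np.float32), self.affine)


@dataclass
class ZMap:
    """A degree map standardized to zero mean / unit SD across the mask."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_id: Optional[str] = None
    condition: Optional[str] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape[0] != int(self.mask.sum()):
            raise ConnectivityError("values length != mask voxel count")

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.to_volume().astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))
        sidecar = {"subject_id": self.subject_id, "condition": self.condition,
                   "provenance": self.provenance}
        with open(str(path).replace(".nii", "") + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)


def standardize_rows(ts) -> tuple[np.ndarray, np.ndarray]:
    """Centre each row and scale to unit norm; zero-variance rows are
    flagged degenerate and zeroed (so they correlate 0 with everything)."""
    X = ts.data if isinstance(ts, VoxelTimeSeriesMatrix) else np.asarray(ts)
    if X.shape[1] < 3:
        raise ConnectivityError("need at least 3 timepoints")
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    degenerate = norms <= X.shape[1] * 1e-12 * (1.0 + np.abs(X).max())
    safe = np.where(degenerate, 1.0, norms)
    S = X / safe[:, None]
    S[degenerate] = 0.0
    return S, degenerate


def degree_map(
    ts: VoxelTimeSeriesMatrix,
    r_threshold: float = 0.25,
    block_size: int = 2048,
    weighted: bool = False,
) -> DegreeMap:
    """Count, per voxel, the partners with Pearson r strictly above the
    threshold (positive side only, self excluded).

    Correlations are evaluated in column blocks so peak memory is
    O(n_voxels * block_size); the result is independent of ``block_size``.
    With ``weighted=True`` the supra-threshold correlations are summed
    instead of counted (non-default variant).
    """
    if not 0 < r_threshold < 1:
        raise ConnectivityError(f"r_threshold {r_threshold} outside (0, 1)")
    S, degenerate = standardize_rows(ts)
    n = S.shape[0]
    deg = np.zeros(n, dtype=float if weighted else np.int64)
    for j0 in range(0, n, block_size):
        B = S[j0:j0 + block_size]
        C = S @ B.T  # (n, block)
        hits = C > r_threshold
        if weighted:
            deg += np.where(hits, C, 0.0).sum(axis=1)
        else:
            deg += hits.sum(axis=1)
    # remove the self link (r_ii = 1 > threshold) for non-degenerate voxels
    deg = deg.astype(float)
    deg[~degenerate] -= 1.0 if weighted else 1
    deg[degenerate] = 0.0
    return DegreeMap(values=deg, mask=ts.mask, affine=ts.affine,
                     r_threshold=r_threshold,
                     provenance=list(ts.provenance) + [
                         {"step": "degree_map", "r_threshold": r_threshold,
                          "weighted": weighted}])


def z_normalize(d: DegreeMap) -> ZMap:
    """Standardize a degree map across in-mask voxels (sample SD).

    Rank order is preserved; a constant map yields all zeros with a warning.
    """
    if d.values.size == 0:
        raise ConnectivityError("empty mask")
    vals = np.asarray(d.values, dtype=float)
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    if sd == 0:
        warnings.warn("degree map has zero variance; z-map set to zeros")
        z = np.zeros_like(vals)
    else:
        z = (vals - vals.mean()) / sd
    return ZMap(values=z, mask=d.mask, affine=d.affine,
                subject_id=d.subject_id, condition=d.condition,
                provenance=list(d.provenance) + [{"step": "z_normalize"}])


def subject_fc_map(
    scan,
    nuisance=None,
    config: Optional[PreprocessConfig] = None,
    r_threshold: float = 0.25,
    mask: Optional[np.ndarray] = None,
    subject_id: Optional[str] = None,
    condition: Optional[str] = None,
) -> ZMap:
    """Full per-subject chain: preprocess -> degree -> z-normalize."""
    ts = run_preprocess(scan, nuisance, config, mask=mask)
    d = degree_map(ts, r_threshold=r_threshold)
    z = z_normalize(d)
    z.subject_id = subject_id
    z.condition = condition
    return z
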