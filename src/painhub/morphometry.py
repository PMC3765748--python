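"""Long-axis subdivision of labeled structures and section volumetry.

The structure's long axis is the first principal component of its voxels'
world coordinates; the label is cut perpendicular to that axis into three
equal-length sections, "top" being the section whose mean world z
(superior) coordinate is highest — the convention matching the
somatotopic lower-back representation near the vertex of the postcentral
gyrus. Section volumes are compared between groups with a pooled
two-sample t-test, optionally adjusting for age and gender in a linear
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class MorphometryError(ValueError):
    pass


@dataclass
class LabelVolume:
    labels: np.ndarray
    affine: np.ndarray
    left_id: int = 1
    right_id: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise MorphometryError("labels must be 3D")
        if not (self.labels > 0).any():
            raise MorphometryError("label volume is empty")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MorphometryError("affine is singular")


@dataclass
class SectionSet:
    """Disjoint top/middle/bottom sub-masks of one label, with the axis
    and cut positions (projection units, mm along the axis)."""

    sections: dict  # name -> 3D bool mask
    axis: np.ndarray
    centroid: np.ndarray
    cuts: tuple


def _world_coords(label_mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    idx = np.argwhere(label_mask)
    hom = np.column_stack([idx, np.ones(len(idx))])
    return (hom @ affine.T)[:, :3]


def principal_axis(label: LabelVolume, label_id: int,
                   degeneracy_tol: float = 0.05):
    """First principal component of the labeled voxels' world coordinates.

    Returns ``(unit_vector, centroid)``; the sign is fixed so the superior
    (+z world) component is non-negative (falling back to the first
    non-zero component for axes lying in the axial plane). Raises when the
    two leading eigenvalues are within ``degeneracy_tol`` relative gap —
    no unique long axis (e.g. a sphere).
    """
    mask = label.labels == label_id
    if mask.sum() < 3:
        raise MorphometryError("need at least 3 voxels")
    W = _world_coords(mask, label.affine)
    centroid = W.mean(axis=0)
    cov = np.cov((W - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or (evals[0] - evals[1]) <= degeneracy_tol * evals[0]:
        raise MorphometryError(
            f"no unique long axis: leading eigenvalues {evals[0]:.3g}, {evals[1]:.3g}"
        )
    axis = evecs[:, 0]
    if abs(axis[2]) > 1e-8:
        if axis[2] < 0:
            axis = -axis
    else:
        nz = np.flatnonzero(np.abs(axis) > 1e-8)[0]
        if axis[nz] < 0:
            axis = -axis
    return axis, centroid


def split_thirds(label: LabelVolume, label_id: int,
                 axis: Optional[np.ndarray] = None,
                 centroid: Optional[np.ndarray] = None,
                 mode: str = "equal_length") -> SectionSet:
    """Partition a label into three sections along its long axis.

    ``equal_length`` (default) cuts the [min, max] projection range into
    three equal-length intervals; ``equal_count`` uses projection terciles.
    The union of sections is exactly the parent label.
    """
    if axis is None or centroid is None:
        axis, centroid = principal_axis(label, label_id)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    mask = label.labels == label_id
    if not mask.any():
        raise MorphometryError(f"label id {label_id} not present")
    W = _world_coords(mask, label.affine)
    proj = (W - centroid) @ axis
    lo, hi = proj.min(), proj.max()
    if mode == "equal_length":
        width = (hi - lo) / 3.0
        cuts = (lo + width, lo + 2 * width)
    elif mode == "equal_count":
        cuts = tuple(np.quantile(proj, [1 / 3, 2 / 3]))
    else:
        raise MorphometryError(f"unknown mode {mode!r}")
    section_of = np.clip(np.searchsorted(np.asarray(cuts), proj, side="right"), 0, 2)
    idx = np.argwhere(mask)
    masks = []
    for s in range(3):
        m = np.zeros(label.labels.shape, dtype=bool)
        sel = idx[section_of == s]
        m[tuple(sel.T)] = True
        masks.append(m)
    # name sections by superior position: highest mean world z is "top"
    mean_z = [W[section_of == s, 2].mean() if (section_of == s).any() else -np.inf
              for s in range(3)]
    order = np.argsort(mean_z)[::-1]  # top, middle, bottom
    sections = {"top": masks[order[0]], "middle": masks[order[1]],
                "bottom": masks[order[2]]}
    return SectionSet(sections=sections, axis=axis, centroid=centroid, cuts=cuts)


def section_volume(section: np.ndarray, affine: np.ndarray) -> float:
    """Voxel count times voxel volume (|det| of the affine's 3x3 block)."""
    section = np.asarray(section, bool)
    n = int(section.sum())
    if n == 0:
        raise MorphometryError("empty section")
    return n * abs(np.linalg.det(np.asarray(affine, float)[:3, :3]))


def bilateral_volume(left_mm3: float, right_mm3: float) -> float:
    if left_mm3 <= 0 or right_mm3 <= 0:
        raise MorphometryError("both sides must have positive volume")
    return left_mm3 + right_mm3


def compare_group_volumes(volumesA: Sequence[float], volumesB: Sequence[float],
                          covariates: Optional[pd.DataFrame] = None):
    """Compare per-subject volumes between groups.

    Without covariates: pooled two-sample t. With covariates (rows matched
    to A then B; e.g. columns age, gender): OLS of
    volume ~ group + covariates, reporting the group coefficient.
    Returns ``(t, df, p_two_sided)``.
    """
    a = np.asarray(volumesA, float)
    b = np.asarray(volumesB, float)
    if a.size < 2 or b.size < 2:
        raise MorphometryError("need at least 2 subjects per group")
    if covariates is None:
        res = sps.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), a.size + b.size - 2, float(res.pvalue)
    cov = covariates.copy()
    if len(cov) != a.size + b.size:
        raise MorphometryError("covariate rows must match subjects (A then B)")
    y = np.concatenate([a, b])
    group = np.concatenate([np.ones(a.size), np.zeros(b.size)])
    Xcols = {"group": group}
    for col in cov.columns:
        vals = cov[col]
        if vals.dtype == object or str(vals.dtype) == "category":
            codes, _ = pd.factorize(vals)
            Xcols[col] = codes.astype(float)
        else:
            Xcols[col] = vals.to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame(Xcols))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise MorphometryError("collinear covariates in the volume model")
    fit = sm.OLS(y, X).fit()
    return (float(fit.tvalues["group"]), int(fit.df_resid),
            float(fit.pvalues["group"]))
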