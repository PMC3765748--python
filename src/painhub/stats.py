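"""Group-level inference on subject z-maps.

Two-sample, paired and covariate-regression t-maps are converted to z and
thresholded at Z > 2.3 with a 10-contiguous-voxel candidate floor; cluster-
level multiple-comparison correction uses the permutation max-cluster-size
null (group-label shuffling for two-sample designs, subject sign flipping
for paired and regression designs). Reports follow the cluster-table
convention: size in mm^3, Z_max and the peak's world coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats as sps

from .connectivity import ZMap

CLUSTER_COLUMNS = ["region", "cluster_mm3", "n_voxels", "z_max",
                   "x", "y", "z", "cluster_p"]


class StatsError(ValueError):
    pass


@dataclass
class StatMap:
    """Voxel-wise group statistic (t and its z-equivalent) over a mask."""

    t_values: np.ndarray
    z_values: np.ndarray
    df: int
    contrast: str
    mask: np.ndarray
    affine: np.ndarray
    n_degenerate: int = 0

    def to_volume(self, which: str = "z", fill: float = 0.0) -> np.ndarray:
        vals = self.z_values if which == "z" else self.t_values
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = vals
        return vol


def t_to_z(t, df: int):
    """Map t-statistics to standard-normal quantiles of equal tail mass.

    Monotone and antisymmetric; evaluated through the survival function on
    the matching side so extreme values stay finite and accurate.
    """
    if df < 1:
        raise StatsError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    pos = t >= 0
    z = np.empty_like(t)
    # sf keeps precision in the tail ndtri needs
    z[pos] = -special.ndtri(np.clip(sps.t.sf(t[pos], df), 1e-320, 1.0))
    z[~pos] = special.ndtri(np.clip(sps.t.sf(-t[~pos], df), 1e-320, 1.0))
    return z if z.ndim else float(z)


def z_to_t_threshold(z_threshold: float, df: int) -> float:
    """The t value whose upper tail mass equals that of ``z_threshold``."""
    return float(sps.t.isf(sps.norm.sf(z_threshold), df))


def _stack(maps: Sequence[ZMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(maps) == 0:
        raise StatsError("no maps given")
    mask = maps[0].mask
    affine = maps[0].affine
    for m in maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise StatsError("maps have mismatching masks")
        if not np.allclose(m.affine, affine):
            raise StatsError("maps have mismatching affines")
    return np.array([m.values for m in maps]), mask, affine


def _guard(numer, denom):
    bad = denom <= 0
    t = np.where(bad, 0.0, numer / np.where(bad, 1.0, denom))
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"{n_bad} zero-variance voxels set to t=0")
    return t, n_bad


def _two_sample_t(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, int, int]:
    na, nb = A.shape[0], B.shape[0]
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    t, n_bad = _guard(A.mean(axis=0) - B.mean(axis=0), sp * np.sqrt(1 / na + 1 / nb))
    return t, na + nb - 2, n_bad


def two_sample_t_map(mapsA: Sequence[ZMap], mapsB: Sequence[ZMap],
                     contrast: str = "A>B") -> StatMap:
    """Pooled-variance two-sample t (A - B) per voxel, df = nA + nB - 2."""
    A, maskA, affA = _stack(mapsA)
    B, maskB, affB = _stack(mapsB)
    if maskA.shape != maskB.shape or not np.array_equal(maskA, maskB):
        raise StatsError("group masks differ")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise StatsError("need at least 2 maps per group")
    t, df, n_bad = _two_sample_t(A, B)
    return StatMap(t, t_to_z(t, df), df, contrast, maskA, affA, n_bad)


def paired_t_map(maps_cond1: Sequence[ZMap], maps_cond2: Sequence[ZMap],
                 contrast: str = "cond1>cond2") -> StatMap:
    """Paired t on per-subject differences (cond1 - cond2), df = n - 1."""
    if len(maps_cond1) != len(maps_cond2):
        raise StatsError("paired lists must have equal length")
    ids1 = [m.subject_id for m in maps_cond1]
    ids2 = [m.subject_id for m in maps_cond2]
    if any(i is not None for i in ids1 + ids2) and ids1 != ids2:
        raise StatsError(f"subject mismatch between conditions: {ids1} vs {ids2}")
    X1, mask, affine = _stack(maps_cond1)
    X2, mask2, _ = _stack(maps_cond2)
    if not np.array_equal(mask, mask2):
        raise StatsError("group masks differ")
    n = X1.shape[0]
    if n < 2:
        raise StatsError("need at least 2 pairs")
    D = X1 - X2
    t, n_bad = _guard(D.mean(axis=0), D.std(axis=0, ddof=1) / np.sqrt(n))
    return StatMap(t, t_to_z(t, n - 1), n - 1, contrast, mask, affine, n_bad)


def covariate_regression_map(delta_maps: Sequence[ZMap], covariate,
                             contrast: str = "slope>0") -> StatMap:
    """Simple per-voxel regression of map differences on a covariate;
    t of the slope, df = n - 2."""
    Y, mask, affine = _stack(delta_maps)
    c = np.asarray(covariate, dtype=float)
    if c.ndim != 1 or c.size != Y.shape[0]:
        raise StatsError("covariate must match the number of maps")
    if c.size < 3:
        raise StatsError("need at least 3 subjects for regression")
    c_c = c - c.mean()
    scc = float(c_c @ c_c)
    if scc <= 0:
        raise StatsError("covariate has zero variance")
    Yc = Y - Y.mean(axis=0)
    scy = c_c @ Yc
    syy = (Yc * Yc).sum(axis=0)
    n = c.size
    sse = np.maximum(syy - scy ** 2 / scc, 0.0)
    t, n_bad = _guard(scy / scc, np.sqrt(sse / (n - 2) / scc))
    return StatMap(t, t_to_z(t, n - 2), n - 2, contrast, mask, affine, n_bad)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in (6, 18, 26):
        raise StatsError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def label_clusters(z_map, z_threshold: float = 2.3, min_voxels: int = 10,
                   connectivity: int = 26):
    """Connected components of {z > threshold}; components smaller than
    ``min_voxels`` are discarded and labels are renumbered by size
    (descending). Returns ``(labels_3d, sizes)``."""
    if z_threshold <= 0 or min_voxels <= 0:
        raise StatsError("thresholds must be positive")
    vol = z_map.to_volume(fill=-np.inf) if isinstance(z_map, StatMap) else np.asarray(z_map)
    lab, n = ndimage.label(vol > z_threshold, structure=_structure(connectivity))
    out = np.zeros(vol.shape, dtype=np.int32)
    if n == 0:
        return out, np.array([], dtype=int)
    counts = np.bincount(lab.ravel())[1:]
    keep = np.flatnonzero(counts >= min_voxels) + 1
    order = keep[np.argsort(counts[keep - 1], kind="stable")[::-1]]
    for new, old in enumerate(order, start=1):
        out[lab == old] = new
    return out, counts[order - 1]


def cluster_report(z_map: StatMap, clusters: np.ndarray, affine=None,
                   cluster_p=None, region: str = "") -> pd.DataFrame:
    """Per-cluster size (mm^3), Z_max and the peak voxel's world coordinate.

    Z_max ties are broken by the lowest linear voxel index (np.argmax order).
    """
    affine = z_map.affine if affine is None else np.asarray(affine)
    voxel_mm3 = abs(np.linalg.det(affine[:3, :3]))
    zvol = z_map.to_volume(fill=-np.inf)
    rows = []
    n_clusters = int(clusters.max())
    for lab in range(1, n_clusters + 1):
        inside = clusters == lab
        n_vox = int(inside.sum())
        masked = np.where(inside, zvol, -np.inf)
        peak_flat = int(np.argmax(masked))
        peak_idx = np.unravel_index(peak_flat, zvol.shape)
        world = affine @ np.array([*peak_idx, 1.0])
        p = None if cluster_p is None else float(cluster_p[lab - 1])
        rows.append({"region": region, "cluster_mm3": n_vox * voxel_mm3,
                     "n_voxels": n_vox, "z_max": float(zvol[peak_idx]),
                     "x": world[0], "y": world[1], "z": world[2],
                     "cluster_p": p})
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


@dataclass
class PermutationResult:
    stat_map: StatMap
    clusters: np.ndarray
    table: pd.DataFrame              # significant clusters only
    candidates: pd.DataFrame         # all clusters >= min_voxels, with p
    perm_max_sizes: np.ndarray
    alpha: float


def _max_cluster_sizes(T: np.ndarray, mask: np.ndarray, t_threshold: float,
                       structure: np.ndarray) -> np.ndarray:
    out = np.empty(T.shape[0], dtype=int)
    vol = np.zeros(mask.shape)
    for i in range(T.shape[0]):
        vol[mask] = T[i]
        lab, n = ndimage.label(vol > t_threshold, structure=structure)
        out[i] = 0 if n == 0 else int(np.bincount(lab.ravel())[1:].max())
    return out


def permutation_cluster_correct(
    maps,
    test_kind: str,
    maps_b=None,
    covariate=None,
    z_threshold: float = 2.3,
    min_voxels: int = 10,
    connectivity: int = 26,
    n_perm: int = 499,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Cluster-extent correction against the permutation max-cluster null.

    ``test_kind``: ``two_sample`` (maps vs maps_b, group labels shuffled),
    ``paired`` (maps and maps_b subject-matched, difference signs flipped)
    or ``regression`` (maps are per-subject differences regressed on
    ``covariate``; subjects sign-flipped about the mean map). Cluster-level
    p = (1 + #{perm max size >= observed size}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise StatsError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    structure = _structure(connectivity)

    if test_kind == "two_sample":
        if maps_b is None:
            raise StatsError("two_sample needs a second group")
        A, mask, affine = _stack(maps)
        B, mask2, _ = _stack(maps_b)
        if not np.array_equal(mask, mask2):
            raise StatsError("group masks differ")
        na, nb = A.shape[0], B.shape[0]
        if na < 2 or nb < 2:
            raise StatsError("need at least 2 subjects per group to shuffle labels")
        Y = np.vstack([A, B])
        obs = two_sample_t_map(maps, maps_b)
        df = obs.df
        n = na + nb
        sum_all = Y.sum(axis=0)
        ss_all = (Y * Y).sum(axis=0)
        T = np.empty((n_perm, Y.shape[1]))
        for p in range(n_perm):
            sel = rng.permutation(n)[:na]
            Ysel = Y[sel]
            sa = Ysel.sum(axis=0)
            qa = (Ysel * Ysel).sum(axis=0)
            sb = sum_all - sa
            qb = ss_all - qa
            va = (qa - sa * sa / na) / (na - 1)
            vb = (qb - sb * sb / nb) / (nb - 1)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            denom = np.sqrt(np.maximum(sp2, 0.0) * (1 / na + 1 / nb))
            T[p] = np.where(denom > 0, (sa / na - sb / nb) / np.where(denom > 0, denom, 1.0), 0.0)
    elif test_kind == "paired":
        if maps_b is None:
            raise StatsError("paired needs both conditions")
        X1, mask, affine = _stack(maps)
        X2, mask2, _ = _stack(maps_b)
        if not np.array_equal(mask, mask2):
            raise StatsError("group masks differ")
        D = X1 - X2
        n = D.shape[0]
        if n < 2:
            raise StatsError("need at least 2 pairs to flip signs")
        obs = paired_t_map(maps, maps_b)
        df = obs.df
        F = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
        M = (F @ D) / n
        e2 = (D * D).mean(axis=0)
        var = np.maximum((e2 - M * M) * n / (n - 1), 0.0)
        denom = np.sqrt(var / n)
        T = np.where(denom > 0, M / np.where(denom > 0, denom, 1.0), 0.0)
    elif test_kind == "regression":
        if covariate is None:
            raise StatsError("regression needs a covariate")
        Y, mask, affine = _stack(maps)
        c = np.asarray(covariate, dtype=float)
        n = Y.shape[0]
        if n < 3:
            raise StatsError("need at least 3 subjects to permute a regression")
        obs = covariate_regression_map(maps, c)
        df = obs.df
        c_c = c - c.mean()
        scc = float(c_c @ c_c)
        Yc = Y - Y.mean(axis=0)
        sqq = (Yc * Yc).sum(axis=0)
        F = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
        A = F @ Yc                       # per-perm sum of signed residual maps
        B = (F * c_c) @ Yc               # per-perm Sxy
        syy = sqq - A * A / n
        sse = np.maximum(syy - B * B / scc, 0.0)
        denom = np.sqrt(sse / (n - 2) / scc)
        T = np.where(denom > 0, (B / scc) / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        raise StatsError(f"unknown test_kind {test_kind!r}")

    t_thr = z_to_t_threshold(z_threshold, df)
    clusters, sizes = label_clusters(obs, z_threshold, min_voxels, connectivity)
    perm_max = _max_cluster_sizes(T, mask, t_thr, structure)
    pvals = np.array([(1 + (perm_max >= s).sum()) / (n_perm + 1) for s in sizes])
    candidates = cluster_report(obs, clusters, affine, cluster_p=pvals)
    sig = pvals < alpha if len(sizes) else np.array([], dtype=bool)
    table = candidates[sig].reset_index(drop=True) if len(sizes) else candidates
    # keep only significant clusters in the label volume reported as "clusters"
    sig_labels = np.flatnonzero(sig) + 1
    sig_vol = np.where(np.isin(clusters, sig_labels), clusters, 0)
    return PermutationResult(obs, sig_vol, table, candidates, perm_max, alpha)


def extract_mean_z(maps: Sequence[ZMap], cluster_mask: np.ndarray) -> pd.DataFrame:
    """Per-subject mean z over a cluster (for scatter-style summaries)."""
    cluster_mask = np.asarray(cluster_mask, bool)
    if cluster_mask.sum() == 0:
        raise StatsError("empty cluster mask")
    rows = []
    for m in maps:
        if cluster_mask.shape != m.mask.shape:
            raise StatsError("cluster mask grid differs from map grid")
        if np.any(cluster_mask & ~m.mask):
            raise StatsError("cluster mask extends outside the image mask")
        vol = m.to_volume(fill=np.nan)
        rows.append({"subject_id": m.subject_id, "condition": m.condition,
                     "mean_z": float(np.nanmean(vol[cluster_mask]))})
    return pd.DataFrame(rows)


def t_test_from_summary(m1: float, s1: float, n1: int, m2: float, s2: float,
                        n2: int, pooled: bool = True):
    """Two-sample t-test from summary statistics (means, SDs, sizes).

    Returns ``(t, df, p_two_sided)``. ``pooled=False`` gives the Welch
    variant with Satterthwaite df.
    """
    if s1 < 0 or s2 < 0:
        raise StatsError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise StatsError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, (n1 + n2 - 2 if pooled else n1 + n2 - 2), 1.0
        raise StatsError("zero variance with unequal means: t undefined")
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)
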