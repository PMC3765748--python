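"""Self-validation experiments: oracle checks and calibration simulations.

These routines re-measure the pipeline's statistical guarantees from
scratch — degree maps against a brute-force O(n^2) oracle, the family-wise
false-positive rate of the permutation cluster correction on pure-noise
cohorts, and recovery of the planted hub effect and pain-slope sign.
They run at the 4 mm analysis grid (18x18x14, the grid the 24x24x18 @ 3 mm
acquisition box downsamples to), with the temporal preprocessing chain
applied; problem sizes are documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .connectivity import ZMap, degree_map, z_normalize
from .preprocess import VoxelTimeSeriesMatrix, detrend_linear, lowpass_filter
from .stats import covariate_regression_map, permutation_cluster_correct
from .synthetic import CohortSpec, generate_scan

ANALYSIS_GRID = (18, 18, 14)
ANALYSIS_MM = 4.0


def naive_degree(X: np.ndarray, r_threshold: float = 0.25) -> np.ndarray:
    """Brute-force per-pair degree count: an independent O(n^2) oracle.

    Correlates every voxel pair with np.corrcoef, one pair at a time, and
    counts strict exceedances on the positive side, excluding self links.
    """
    n = X.shape[0]
    deg = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if X[i].std() == 0 or X[j].std() == 0:
                continue
            r = np.corrcoef(X[i], X[j])[0, 1]
            if r > r_threshold:
                deg[i] += 1
                deg[j] += 1
    return deg


def degree_oracle_check(n_instances: int = 50, seed: int = 0,
                        max_voxels: int = 200, n_timepoints: int = 116):
    """Blocked degree vs the brute-force oracle on random instances.

    Returns (instances_checked, max_absolute_difference).
    """
    rng = np.random.default_rng(seed)
    worst = 0
    for _ in range(n_instances):
        n = int(rng.integers(10, max_voxels + 1))
        X = rng.standard_normal((n, n_timepoints))
        # occasionally inject degenerate and duplicated rows
        if n > 20:
            X[0] = 5.0
            X[1] = X[2] * 2.0 + 1.0
        mask = np.zeros((n, 1, 1), bool)
        mask[:, 0, 0] = True
        ts = VoxelTimeSeriesMatrix(X, mask, np.eye(4), tr_s=3.0)
        blocked = degree_map(ts, block_size=int(rng.integers(7, 64))).values
        worst = max(worst, int(np.abs(blocked - naive_degree(X)).max()))
    return n_instances, worst


def _analysis_spec(spec: Optional[CohortSpec], **overrides) -> CohortSpec:
    base = spec or CohortSpec()
    return dataclasses.replace(base, **overrides)


def null_zmap(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """One pure-noise subject's degree z-map values at the analysis grid."""
    data, _, mask = generate_scan(spec, rho=0.0, rng=rng,
                                  grid_shape=ANALYSIS_GRID,
                                  voxel_size_mm=ANALYSIS_MM,
                                  with_confounds=False)
    return _zmap_from_scan(data, mask, spec)


def _zmap_from_scan(data: np.ndarray, mask: np.ndarray, spec: CohortSpec) -> np.ndarray:
    S = data[mask].astype(np.float64)
    S = detrend_linear(S)
    S = lowpass_filter(S, spec.tr_s, 0.08)
    affine = np.diag([ANALYSIS_MM] * 3 + [1.0])
    ts = VoxelTimeSeriesMatrix(S.astype(np.float32), mask, affine, tr_s=spec.tr_s)
    return z_normalize(degree_map(ts)).values


def _wrap_maps(values_list, mask, subject_ids=None, condition=None):
    affine = np.diag([ANALYSIS_MM] * 3 + [1.0])
    return [ZMap(v, mask, affine,
                 subject_id=None if subject_ids is None else subject_ids[i],
                 condition=condition)
            for i, v in enumerate(values_list)]


def null_fwe_rate(n_reps: int = 200, n_per_group: int = 18, n_perm: int = 99,
                  seed: int = 0, spec: Optional[CohortSpec] = None,
                  alpha: float = 0.05):
    """Family-wise false-positive rate of the cluster correction under the
    null: pure-noise cohorts, two-sample contrast, one direction.

    Returns (rate, n_reps).
    """
    spec = _analysis_spec(spec)
    root = np.random.SeedSequence(seed)
    mask = None
    n_false = 0
    for rep, child in enumerate(root.spawn(n_reps)):
        rng = np.random.default_rng(child)
        values = []
        for _ in range(2 * n_per_group):
            v = null_zmap(spec, rng)
            values.append(v)
        from .synthetic import ellipsoid_mask
        mask = ellipsoid_mask(ANALYSIS_GRID)
        maps = _wrap_maps(values, mask)
        res = permutation_cluster_correct(
            maps[:n_per_group], "two_sample", maps_b=maps[n_per_group:],
            n_perm=n_perm, seed=int(rng.integers(2 ** 31)), alpha=alpha)
        if len(res.table):
            n_false += 1
    return n_false / n_reps, n_reps


def planted_recovery(n_reps: int = 50, n_patients: int = 18, n_perm: int = 499,
                     seed: int = 0, spec: Optional[CohortSpec] = None):
    """Paired HP>LP detection of the planted hub, and sign recovery of the
    pain-rating regression slope, over seeded cohort replicates.

    A rep "detects" when a corrected-significant cluster (p < 0.05,
    >= 10 voxels) overlaps the planted hub core. The slope sign is
    "recovered" when the rating-change regression's mean slope-t over the
    hub core is positive. Returns a dict of rates.
    """
    spec = _analysis_spec(spec)
    from .synthetic import ellipsoid_mask
    mask = ellipsoid_mask(ANALYSIS_GRID)
    hub = np.zeros(ANALYSIS_GRID, bool)
    hub[spec.hub_slices(ANALYSIS_GRID)] = True
    root = np.random.SeedSequence(seed)
    n_detect = 0
    n_sign = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        rho_lp = np.clip(rng.normal(spec.coupling_lp, spec.coupling_subject_sd,
                                    n_patients), 0, 0.95)
        rho_hp = np.clip(rng.normal(spec.coupling_hp, spec.coupling_subject_sd,
                                    n_patients), 0, 0.95)
        lp_vals, hp_vals = [], []
        for rl, rh in zip(rho_lp, rho_hp):
            data, _, _ = generate_scan(spec, rl, rng, ANALYSIS_GRID,
                                       ANALYSIS_MM, with_confounds=False)
            lp_vals.append(_zmap_from_scan(data, mask, spec))
            data, _, _ = generate_scan(spec, rh, rng, ANALYSIS_GRID,
                                       ANALYSIS_MM, with_confounds=False)
            hp_vals.append(_zmap_from_scan(data, mask, spec))
        ids = [f"s{i}" for i in range(n_patients)]
        lp_maps = _wrap_maps(lp_vals, mask, ids, "LP")
        hp_maps = _wrap_maps(hp_vals, mask, ids, "HP")
        res = permutation_cluster_correct(
            hp_maps, "paired", maps_b=lp_maps, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)))
        hub_in = hub & mask
        detected = any((res.clusters == lab + 1)[hub_in].any()
                       for lab in range(len(res.table)))
        n_detect += detected
        # pain-change regression against the planted linear rule
        d_rho = rho_hp - rho_lp
        d_pain = (spec.pain_intercept + spec.pain_slope * d_rho
                  + rng.normal(0, spec.pain_noise_sd, n_patients))
        delta = _wrap_maps([h - l for h, l in zip(hp_vals, lp_vals)], mask)
        reg = covariate_regression_map(delta, d_pain)
        hub_idx = hub[mask]
        n_sign += reg.t_values[hub_idx].mean() > 0
    return {"detection_rate": n_detect / n_reps,
            "slope_sign_rate": n_sign / n_reps,
            "n_reps": n_reps}


def geometry_checks(seed: int = 0, n_labels: int = 20):
    """Thirds-partition exactness and principal-axis recovery on randomly
    rotated synthetic labels; returns summary numbers."""
    from .morphometry import principal_axis, split_thirds
    from .synthetic import generate_label_volume
    rng = np.random.default_rng(seed)
    max_angle = 0.0
    violations = 0
    for _ in range(n_labels):
        theta = rng.uniform(0, np.pi / 2)
        phi = rng.uniform(0, np.pi / 4)
        axis_true = np.array([np.cos(theta) * np.cos(phi),
                              np.sin(theta) * np.cos(phi), np.sin(phi)])
        lv = generate_label_volume(axis_direction=tuple(axis_true),
                                   radius_scale=rng.uniform(0.85, 1.1))
        for lid in (lv.left_id, lv.right_id):
            truth = axis_true.copy()
            if lid == lv.right_id:
                truth = truth * np.array([-1.0, 1.0, 1.0])
            if truth[2] < 0:
                truth = -truth
            axis_est, centroid = principal_axis(lv, lid)
            ang = np.degrees(np.arccos(np.clip(abs(axis_est @ truth), -1, 1)))
            max_angle = max(max_angle, float(ang))
            ss = split_thirds(lv, lid, axis_est, centroid)
            parent = lv.labels == lid
            union = np.zeros_like(parent)
            count = 0
            for m in ss.sections.values():
                if (union & m).any():
                    violations += 1
                union |= m
                count += m.sum()
            if count != parent.sum() or not (union == parent).all():
                violations += 1
    return {"max_axis_error_deg": max_angle, "partition_violations": violations,
            "n_labels": n_labels * 2}
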