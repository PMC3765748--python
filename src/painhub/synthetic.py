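"""Seeded synthetic cohorts emulating the study design.

Two groups of 18 subjects: patients scanned twice (low-pain and high-pain
conditions), controls once. Each scan is a 4D BOLD-like volume (default
24x24x18 grid at 3 mm, 120 frames at TR 3 s) containing a planted "hub":
a contiguous region whose voxels share a latent time series, giving them a
target pairwise correlation rho that differs by group and condition.
Pain-rating changes are generated linearly from each patient's coupling
change, so the rating-difference regression has a known ground truth.

Noise is AR(1) in time and spatially smooth (Gaussian, ~10 mm FWHM —
typical intrinsic smoothness of 3T EPI); per-voxel linear drift and mixed
nuisance series (written to the 9-column nuisance table) make detrending
and nuisance regression consequential. The hub latent enters with a
weight field that is 1 on the hub core and decays smoothly outside it
(real hubs are smooth network nodes, and a hard edge would sever the
core's local-smoothness links, cancelling the planted degree effect).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .morphometry import LabelVolume
from .preprocess import FWHM_TO_SIGMA, NUISANCE_COLUMNS


class SpecError(ValueError):
    pass


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort (defaults = the emulated study)."""

    n_per_group: int = 18
    grid_shape: tuple = (24, 24, 18)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 120          # 6-minute scan at TR 3 s
    tr_s: float = 3.0
    hub_region: Optional[tuple] = None   # (slice, slice, slice); None = default box
    coupling_control: float = 0.45
    coupling_lp: float = 0.30
    coupling_hp: float = 0.50
    coupling_subject_sd: float = 0.10
    ar1_coef: float = 0.3
    drift_amplitude: float = 5.0
    nuisance_amplitude: float = 0.5
    spatial_noise_fwhm_mm: float = 10.0
    hub_skirt_fwhm_mm: float = 11.0
    baseline: float = 1000.0
    noise_sd: float = 10.0
    pain_slope: float = 12.0
    pain_intercept: float = 0.5
    pain_noise_sd: float = 0.4
    rating_lp_mean: float = 3.8
    rating_lp_sd: float = 2.5
    rating_jitter_sd: float = 0.3
    rest_subject_index: Optional[int] = None  # patient whose coupling change is forced to 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        for name in ("coupling_control", "coupling_lp", "coupling_hp"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SpecError(f"{name} must lie in [0, 1), got {v}")
        if not 0 <= self.ar1_coef < 1:
            raise SpecError(f"ar1_coef must lie in [0, 1), got {self.ar1_coef}")
        if self.n_timepoints < 8:
            raise SpecError(f"n_timepoints must be >= 8, got {self.n_timepoints}")
        if self.n_per_group < 1:
            raise SpecError(f"n_per_group must be positive, got {self.n_per_group}")
        if len(self.grid_shape) != 3 or any(v <= 0 for v in self.grid_shape):
            raise SpecError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0:
            raise SpecError("voxel_size_mm and tr_s must be positive")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")

    def affine(self) -> np.ndarray:
        """RAS affine with the grid centred on the world origin."""
        vs = self.voxel_size_mm
        A = np.diag([vs, vs, vs, 1.0])
        A[:3, 3] = -vs * (np.array(self.grid_shape) - 1) / 2.0
        return A

    def hub_slices(self, grid_shape: Optional[tuple] = None,
                   voxel_size_mm: Optional[float] = None) -> tuple:
        """The hub box for a given grid: a fixed physical extent of
        20 x 20 x 8 mm slightly superior of the grid centre (50 voxels on
        the 4 mm analysis grid), so the planted region is grid-independent."""
        if self.hub_region is not None and grid_shape in (None, self.grid_shape):
            return self.hub_region
        shape = np.array(grid_shape or self.grid_shape)
        vs = voxel_size_mm or (self.voxel_size_mm if grid_shape in (None, self.grid_shape)
                               else 4.0)
        nxy = max(1, round(20.0 / vs))
        nz = max(1, round(8.0 / vs))
        cx, cy, cz = np.round((shape - 1) / 2).astype(int)
        return (slice(cx - nxy // 2, cx - nxy // 2 + nxy),
                slice(cy - nxy // 2, cy - nxy // 2 + nxy),
                slice(cz + 1, cz + 1 + nz))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if self.hub_region is not None:
            d["hub_region"] = [[s.start, s.stop] for s in self.hub_region]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SpecError(f"unknown cohort spec keys: {sorted(unknown)}")
        if d.get("hub_region") is not None:
            d["hub_region"] = tuple(slice(a, b) for a, b in d["hub_region"])
        return cls(**d)


def ellipsoid_mask(shape: Sequence[int]) -> np.ndarray:
    """Brain stand-in: the ellipsoid inscribed in the grid box."""
    shape = np.asarray(shape)
    centre = (shape - 1) / 2.0
    idx = np.indices(tuple(shape))
    r2 = sum(((idx[i] - centre[i]) / (shape[i] / 2.0)) ** 2 for i in range(3))
    return r2 <= 1.0


def plant_hub_signal(grid_shape, hub_mask, rho: float, n_timepoints: int,
                     rng: np.random.Generator) -> np.ndarray:
    """The idealized planted-hub model on white noise.

    Hub voxels are ``w*s(t) + e_i(t)`` with a shared unit-variance latent
    ``s``, i.i.d. unit noise ``e_i`` and ``w = sqrt(rho/(1-rho))``, so two
    hub voxels correlate at ``w^2/(w^2+1) = rho`` in expectation; non-hub
    voxels are pure noise. (Cohort generation uses the spatially smooth
    variant; this literal form is the testable closed-form contract.)
    """
    if not 0 <= rho < 1:
        raise SpecError(f"rho must lie in [0, 1), got {rho}")
    hub_mask = np.asarray(hub_mask, bool)
    data = rng.standard_normal(tuple(grid_shape) + (n_timepoints,))
    if rho > 0:
        w = np.sqrt(rho / (1 - rho))
        s = rng.standard_normal(n_timepoints)
        data[hub_mask] += w * s
    return data


def _ar1_series(shape, coef, rng):
    """Unit-marginal-variance AR(1) noise along the last axis."""
    innov = rng.standard_normal(shape, dtype=np.float32)
    if coef == 0:
        return innov
    out = signal.lfilter([1.0], [1.0, -coef], innov, axis=-1)
    return (out * np.sqrt(1.0 - coef ** 2)).astype(np.float32)


def _smooth_noise(shape, n_t, sigma_vox, ar1, rng):
    noise = _ar1_series(tuple(shape) + (n_t,), ar1, rng)
    if sigma_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0,))
        noise /= noise.std()
    return noise


def hub_weight_field(shape, hub_slices, skirt_sigma_vox: float) -> np.ndarray:
    core = np.zeros(tuple(shape), dtype=float)
    core[hub_slices] = 1.0
    if skirt_sigma_vox <= 0:
        return core
    w = ndimage.gaussian_filter(core, skirt_sigma_vox)
    peak = w[hub_slices].min()
    if peak <= 0:
        return core
    return np.clip(w / peak, 0.0, 1.0)


def _nuisance_tables(n_t, rng) -> pd.DataFrame:
    """Six motion random walks plus three AR(1) tissue-mean series."""
    mot = np.cumsum(rng.normal(0.0, 0.02, size=(6, n_t)), axis=1)
    tissue = _ar1_series((3, n_t), 0.4, rng)
    table = np.vstack([mot, tissue]).T
    return pd.DataFrame(table, columns=NUISANCE_COLUMNS)


def generate_scan(
    spec: CohortSpec,
    rho: float,
    rng: np.random.Generator,
    grid_shape: Optional[tuple] = None,
    voxel_size_mm: Optional[float] = None,
    with_confounds: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """One synthetic scan: returns (4D float32 array, nuisance table, mask).

    ``grid_shape``/``voxel_size_mm`` override the spec grid (used to
    generate directly at the analysis resolution); ``with_confounds=False``
    omits AR(1)/drift/nuisance structure (pure spatially-smooth noise).
    """
    shape = tuple(grid_shape or spec.grid_shape)
    vs = voxel_size_mm or spec.voxel_size_mm
    n_t = spec.n_timepoints
    sigma_vox = spec.spatial_noise_fwhm_mm * FWHM_TO_SIGMA / vs
    ar1 = spec.ar1_coef if with_confounds else 0.0
    noise = _smooth_noise(shape, n_t, sigma_vox, ar1, rng)

    if rho > 0:
        wfield = hub_weight_field(shape, spec.hub_slices(shape, vs),
                                  spec.hub_skirt_fwhm_mm * FWHM_TO_SIGMA / vs)
        a = np.sqrt(rho / (1.0 - rho))
        s = _ar1_series((n_t,), ar1, rng)
        aw = (a * wfield)[..., None]
        noise = (noise + aw * s) / np.sqrt(1.0 + aw * aw)

    nuis = _nuisance_tables(n_t, rng)
    data = spec.noise_sd * noise
    if with_confounds:
        t_c = (np.arange(n_t) - (n_t - 1) / 2.0) / n_t
        drift = spec.drift_amplitude * rng.uniform(-1, 1, size=shape)
        data = data + drift[..., None] * t_c
        if spec.nuisance_amplitude > 0:
            N = nuis.to_numpy()
            Nz = (N - N.mean(0)) / np.where(N.std(0) > 0, N.std(0), 1.0)
            beta = rng.normal(0.0, 1.0 / 3.0, size=shape + (9,))
            data = data + spec.noise_sd * spec.nuisance_amplitude * (beta @ Nz.T)
    mask = ellipsoid_mask(shape)
    data = np.where(mask[..., None], data + spec.baseline, 0.0)
    return data.astype(np.float32), nuis, mask


def generate_label_volume(
    grid_shape: tuple = (64, 64, 48),
    voxel_size_mm: float = 1.2,
    axis_direction: tuple = (0.5, 0.1, 0.86),
    length_vox: float = 30.0,
    radii_vox: tuple = (8.25, 8.25),
    top_third_scale: float = 1.0,
    radius_scale: float = 1.0,
    shape: str = "ellipsoid",
    center_vox: Optional[tuple] = None,
) -> LabelVolume:
    """Mirror-symmetric left/right structure labels with a known long axis.

    An ellipsoid (or box) of half-length ``length_vox/2`` and cross-section
    radii ``radii_vox`` is voxelized around ``center_vox`` (defaults to a
    left-hemisphere position); the right label is the exact array mirror.
    ``top_third_scale`` inflates the cross-section area of the third of the
    long axis nearest +z world by that volume factor (the patient-group
    effect); ``radius_scale`` scales both radii (per-subject size jitter).
    """
    grid_shape = tuple(int(v) for v in grid_shape)
    axis = np.asarray(axis_direction, float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise SpecError("axis_direction must be non-zero")
    axis = axis / nrm
    if axis[2] < 0:
        axis = -axis
    half_len = length_vox / 2.0
    radii = np.asarray(radii_vox, float) * radius_scale
    if center_vox is None:
        center_vox = (0.25 * grid_shape[0], 0.5 * (grid_shape[1] - 1),
                      0.5 * (grid_shape[2] - 1))
    centre = np.asarray(center_vox, float)

    # orthonormal frame with e1 = axis
    tmp = np.array([0.0, 0.0, 1.0])
    if abs(axis @ tmp) > 0.95:
        tmp = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(axis, tmp)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axis, e2)

    idx = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    rel = idx - centre
    u1 = rel @ axis
    u2 = rel @ e2
    u3 = rel @ e3
    r_scale = np.where(u1 > half_len / 3.0, np.sqrt(top_third_scale), 1.0)
    if shape == "ellipsoid":
        inside = ((u1 / half_len) ** 2
                  + (u2 / (radii[0] * r_scale)) ** 2
                  + (u3 / (radii[1] * r_scale)) ** 2) <= 1.0
    elif shape == "box":
        eps = 1e-6
        inside = ((np.abs(u1) <= (length_vox - 1) / 2.0 + eps)
                  & (np.abs(u2) <= (radii[0] * r_scale - 1) / 2.0 + eps)
                  & (np.abs(u3) <= (radii[1] * r_scale - 1) / 2.0 + eps))
    else:
        raise SpecError(f"unknown label shape {shape!r}")
    left = inside.reshape(grid_shape)
    if not left.any():
        raise SpecError("label is empty on this grid")
    bb = np.argwhere(left)
    if (bb.min(axis=0) == 0).any() or (bb.max(axis=0) == np.array(grid_shape) - 1).any():
        raise SpecError("label exceeds the grid")
    right = left[::-1, :, :]
    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[left] = 1
    labels[right & ~left] = 2
    vs = voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * (np.array(grid_shape) - 1) / 2.0
    return LabelVolume(labels=labels, affine=affine, left_id=1, right_id=2)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged cohort-descriptives table (18 patients, 18 controls):
    gender, age, race, and for patients BDI, pain duration and BPI."""
    from importlib import resources
    with resources.files("painhub.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _save_scan(path: Path, data: np.ndarray, affine: np.ndarray, tr_s: float) -> None:
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(np.abs(np.diag(affine)[:3])) + (tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def _subject_demographics(i: int, group: str, rng: np.random.Generator):
    age = int(np.clip(np.round(rng.normal(36.5, 9.5)), 21, 60))
    gender = "F" if (i % 3) != 2 else "M"   # ~2/3 female, as in the cohort
    return age, gender


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a full synthetic cohort to ``out_dir`` and return its table.

    Per scan: a 4D NIfTI and a 9-column nuisance TSV. Per subject: a
    structural label image (patients carry the 13%-style top-third
    inflation via ``top_third_scale``). Plus ``cohort.tsv`` indexing
    everything. Deterministic for a given (spec, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = spec.affine()
    rows = []

    def make_subject(i, group):
        sid = f"sub-{group[0]}{i + 1:02d}"
        ss = np.random.SeedSequence(entropy=spec.seed,
                                    spawn_key=(0 if group == "control" else 1, i))
        rng = np.random.default_rng(ss)
        age, gender = _subject_demographics(i, group, rng)
        # per-subject structural label
        scale = 1.13 if group == "patient" else 1.0
        lv = generate_label_volume(top_third_scale=scale,
                                   radius_scale=rng.normal(1.0, 0.08))
        label_path = out / f"{sid}_labels.nii"
        nib.save(nib.Nifti1Image(lv.labels, lv.affine), str(label_path))

        def write_scan(condition, rho, rating):
            data, nuis, _ = generate_scan(spec, rho, rng)
            img_path = out / f"{sid}_{condition}.nii"
            nui_path = out / f"{sid}_{condition}_nuisance.tsv"
            _save_scan(img_path, data, affine, spec.tr_s)
            nuis.to_csv(nui_path, sep="\t", index=False, float_format="%.6f")
            pre = float(np.clip(rating + rng.normal(0, spec.rating_jitter_sd), 0, 10))
            post = float(np.clip(rating + rng.normal(0, spec.rating_jitter_sd), 0, 10))
            rows.append({"subject_id": sid, "group": group, "condition": condition,
                         "image": img_path.name, "nuisance": nui_path.name,
                         "labels": label_path.name,
                         "rating_pre": round(pre, 2), "rating_post": round(post, 2),
                         "age": age, "gender": gender})

        if group == "control":
            rho = float(np.clip(rng.normal(spec.coupling_control,
                                           spec.coupling_subject_sd), 0, 0.95))
            write_scan("single", rho, 0.0)
        else:
            rho_lp = float(np.clip(rng.normal(spec.coupling_lp,
                                              spec.coupling_subject_sd), 0, 0.95))
            if spec.rest_subject_index is not None and i == spec.rest_subject_index:
                rho_hp = rho_lp      # the patient who rested instead of exercising
                d_rho = 0.0
            else:
                rho_hp = float(np.clip(rng.normal(spec.coupling_hp,
                                                  spec.coupling_subject_sd), 0, 0.95))
                d_rho = rho_hp - rho_lp
            lp_rating = float(np.clip(rng.normal(spec.rating_lp_mean,
                                                 spec.rating_lp_sd), 0, 10))
            d_pain = (spec.pain_intercept + spec.pain_slope * d_rho
                      + rng.normal(0, spec.pain_noise_sd))
            hp_rating = float(np.clip(lp_rating + d_pain, 0, 10))
            write_scan("LP", rho_lp, lp_rating)
            write_scan("HP", rho_hp, hp_rating)

    for i in range(spec.n_per_group):
        make_subject(i, "control")
    for i in range(spec.n_per_group):
        make_subject(i, "patient")

    table = pd.DataFrame(rows)
    table.to_csv(out / "cohort.tsv", sep="\t", index=False)
    with open(out / "cohort_spec.json", "w") as fh:
        import json
        json.dump(spec.to_dict(), fh, indent=1)
    return table
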