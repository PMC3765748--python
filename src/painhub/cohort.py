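"""Cohort bookkeeping, descriptive statistics, run configuration and
standard-format I/O (NIfTI volumes, TSV tables)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .stats import CLUSTER_COLUMNS


class CohortError(ValueError):
    pass


REQUIRED_COHORT_COLUMNS = ["subject_id", "group", "condition", "image",
                           "nuisance", "rating_pre", "rating_post"]


def read_cohort(path) -> pd.DataFrame:
    """Load and validate a cohort TSV.

    Checks group/condition consistency (controls: one ``single`` scan;
    patients: one ``LP`` and one ``HP`` scan), rating ranges, and adds a
    ``rating`` column = mean of the pre- and post-scan ratings (the value
    the analysis uses for each scan's pain level).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise CohortError(f"{path} is empty")
    if df.empty:
        raise CohortError(f"{path} has no rows")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort table missing columns: {missing}")
    bad_groups = set(df["group"]) - {"patient", "control"}
    if bad_groups:
        raise CohortError(f"unknown group labels: {sorted(bad_groups)}")
    for col in ("rating_pre", "rating_post"):
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 10).any():
            raise CohortError(f"{col} must lie within [0, 10]")
    for sid, sub in df.groupby("subject_id"):
        conds = sorted(sub["condition"])
        group = sub["group"].iloc[0]
        if sub["group"].nunique() > 1:
            raise CohortError(f"{sid}: inconsistent group labels")
        if group == "control" and conds != ["single"]:
            raise CohortError(f"{sid}: controls need exactly one 'single' scan, got {conds}")
        if group == "patient" and conds != ["HP", "LP"]:
            raise CohortError(f"{sid}: patients need one LP and one HP scan, got {conds}")
    df = df.copy()
    df["rating"] = (df["rating_pre"] + df["rating_post"]) / 2.0
    # resolve relative paths against the table's directory
    for col in ("image", "nuisance", "labels"):
        if col in df.columns:
            df[col] = [str(path.parent / p) if not Path(p).is_absolute() else p
                       for p in df[col]]
    return df


def pain_covariate(cohort: pd.DataFrame) -> pd.Series:
    """Per-patient rating difference HP - LP (each scan's rating being the
    mean of its pre/post values), indexed by subject_id."""
    pats = cohort[cohort["group"] == "patient"]
    wide = pats.pivot(index="subject_id", columns="condition", values="rating")
    return (wide["HP"] - wide["LP"]).rename("delta_rating")


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group descriptives: mean +/- sample SD of age (1 decimal) and of
    BDI / duration / BPI (2 decimals) where present, plus gender counts."""
    if table.empty:
        raise CohortError("empty table")
    rows = []
    numeric = [("age", 1), ("bdi", 2), ("duration_yrs", 2), ("bpi_avg", 2)]
    for group, sub in table.groupby("group"):
        row = {"group": group, "n": len(sub),
               "n_female": int((sub["gender"] == "F").sum()) if "gender" in sub else None,
               "n_male": int((sub["gender"] == "M").sum()) if "gender" in sub else None}
        for col, dec in numeric:
            if col in sub.columns and sub[col].notna().any():
                vals = sub[col].dropna().astype(float)
                row[f"{col}_mean"] = round(vals.mean(), dec)
                row[f"{col}_sd"] = round(vals.std(ddof=1), dec) if len(vals) > 1 else None
        rows.append(row)
    return pd.DataFrame(rows)


def write_cluster_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=[c for c in CLUSTER_COLUMNS
                                                       if c in table.columns])


def read_cluster_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_nifti(path) -> nib.Nifti1Image:
    return nib.load(str(path))


def save_nifti(img: nib.Nifti1Image, path) -> None:
    nib.save(img, str(path))


@dataclass
class RunConfig:
    """Every stage parameter, defaulting to the published pipeline."""

    drop_k: int = 4
    cutoff_hz: float = 0.08
    filter_kind: str = "butterworth"
    fwhm_mm: float = 4.0
    target_mm: float = 4.0
    r_threshold: float = 0.25
    z_threshold: float = 2.3
    min_voxels: int = 10
    connectivity: int = 26
    n_perm: int = 499
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise CohortError("r_threshold must lie in (0, 1)")
        if self.z_threshold <= 0 or self.min_voxels <= 0:
            raise CohortError("z_threshold and min_voxels must be positive")
        if self.connectivity not in (6, 18, 26):
            raise CohortError("connectivity must be 6, 18 or 26")
        if self.n_perm < 99:
            raise CohortError("n_perm must be >= 99")
        if self.drop_k < 0 or self.cutoff_hz <= 0 or self.fwhm_mm < 0:
            raise CohortError("invalid preprocessing parameter")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CohortError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def preprocess_config(self):
        from .preprocess import PreprocessConfig
        return PreprocessConfig(drop_k=self.drop_k, cutoff_hz=self.cutoff_hz,
                                filter_kind=self.filter_kind,
                                fwhm_mm=self.fwhm_mm, target_mm=self.target_mm)
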