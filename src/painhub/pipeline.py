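"""End-to-end driver: per-subject hub maps, the study's group contrasts,
the pain-rating-change regression, and ROI-thirds volumetry."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from . import connectivity as conn
from . import morphometry as morpho
from . import stats as gstats
from .cohort import RunConfig, pain_covariate, read_cohort

log = logging.getLogger("painhub")


def common_mask(zmaps) -> np.ndarray:
    mask = zmaps[0].mask.copy()
    for m in zmaps[1:]:
        mask &= m.mask
    return mask


def restrict_to_mask(zmap: conn.ZMap, mask: np.ndarray) -> conn.ZMap:
    vol = zmap.to_volume(fill=np.nan)
    return conn.ZMap(values=vol[mask], mask=mask, affine=zmap.affine,
                     subject_id=zmap.subject_id, condition=zmap.condition,
                     provenance=zmap.provenance)


def subject_maps(cohort: pd.DataFrame, config: RunConfig,
                 out_dir: Optional[Path] = None) -> dict:
    """Compute (and optionally save) every scan's z-map; returns
    {(subject_id, condition): ZMap} on the common analysis mask."""
    cfg = config.preprocess_config()
    maps = {}
    for _, row in cohort.iterrows():
        z = conn.subject_fc_map(row["image"], row["nuisance"], cfg,
                                r_threshold=config.r_threshold,
                                subject_id=row["subject_id"],
                                condition=row["condition"])
        maps[(row["subject_id"], row["condition"])] = z
    mask = common_mask(list(maps.values()))
    maps = {k: restrict_to_mask(z, mask) for k, z in maps.items()}
    if out_dir is not None:
        zdir = Path(out_dir) / "zmaps"
        zdir.mkdir(parents=True, exist_ok=True)
        for (sid, cond), z in maps.items():
            z.save(zdir / f"{sid}_{cond}_zmap.nii")
    return maps


def _contrast_tables(name, maps_a, maps_b, kind, config, seed_offset, out_dir,
                     covariate=None):
    results = {}
    if kind == "regression":
        directions = [(f"{name[0]}>{name[1]}", maps_a, None, np.asarray(covariate)),
                      (f"{name[1]}>{name[0]}", maps_a, None, -np.asarray(covariate))]
    else:
        directions = [(f"{name[0]}>{name[1]}", maps_a, maps_b, None),
                      (f"{name[1]}>{name[0]}", maps_b, maps_a, None)]
    frames = []
    for i, (label, ma, mb, cov) in enumerate(directions):
        if kind == "regression":
            res = gstats.permutation_cluster_correct(
                ma, "regression", covariate=cov,
                z_threshold=config.z_threshold, min_voxels=config.min_voxels,
                connectivity=config.connectivity, n_perm=config.n_perm,
                seed=config.seed + seed_offset + i)
        else:
            res = gstats.permutation_cluster_correct(
                ma, kind, maps_b=mb,
                z_threshold=config.z_threshold, min_voxels=config.min_voxels,
                connectivity=config.connectivity, n_perm=config.n_perm,
                seed=config.seed + seed_offset + i)
        tab = res.table.copy()
        tab.insert(0, "contrast", label)
        frames.append(tab)
        results[label] = res
    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        write_path = Path(out_dir) / f"clusters_{name[0]}_vs_{name[1]}.tsv"
        table.to_csv(write_path, sep="\t", index=False)
    return table, results


def roi_thirds_volumes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject bilateral top/middle/bottom/total volumes from each
    subject's label image."""
    rows = []
    for sid, sub in cohort.groupby("subject_id"):
        if "labels" not in sub.columns or pd.isna(sub["labels"].iloc[0]):
            continue
        img = nib.load(str(sub["labels"].iloc[0]))
        lv = morpho.LabelVolume(np.asanyarray(img.dataobj), img.affine)
        vols = {"subject_id": sid, "group": sub["group"].iloc[0]}
        if "age" in sub.columns:
            vols["age"] = sub["age"].iloc[0]
            vols["gender"] = sub["gender"].iloc[0]
        for section in ("top", "middle", "bottom"):
            total = 0.0
            for lid, side in ((lv.left_id, "left"), (lv.right_id, "right")):
                ss = morpho.split_thirds(lv, lid)
                v = morpho.section_volume(ss.sections[section], lv.affine)
                vols[f"{side}_{section}_mm3"] = v
                total += v
            vols[f"bilateral_{section}_mm3"] = total
        vols["total_mm3"] = sum(vols[f"bilateral_{s}_mm3"]
                                for s in ("top", "middle", "bottom"))
        rows.append(vols)
    return pd.DataFrame(rows)


def roi_thirds_comparison(volumes: pd.DataFrame) -> pd.DataFrame:
    """Patient-vs-control comparisons of bilateral section volumes, with
    and without age/gender adjustment."""
    out = []
    pats = volumes[volumes["group"] == "patient"]
    ctls = volumes[volumes["group"] == "control"]
    for measure in ("bilateral_top_mm3", "bilateral_middle_mm3",
                    "bilateral_bottom_mm3", "total_mm3"):
        a = pats[measure].to_numpy(float)
        b = ctls[measure].to_numpy(float)
        t, df, p = morpho.compare_group_volumes(a, b)
        row = {"measure": measure,
               "patient_mean": a.mean(), "patient_sd": a.std(ddof=1),
               "control_mean": b.mean(), "control_sd": b.std(ddof=1),
               "t": t, "df": df, "p": p}
        if {"age", "gender"} <= set(volumes.columns):
            cov = pd.concat([pats[["age", "gender"]], ctls[["age", "gender"]]],
                            ignore_index=True)
            t_adj, df_adj, p_adj = morpho.compare_group_volumes(a, b, cov)
            row.update({"t_adjusted": t_adj, "p_adjusted": p_adj})
        out.append(row)
    return pd.DataFrame(out)


def run_end_to_end(config: RunConfig, cohort_path, out_dir) -> dict:
    """Run the full analysis on a cohort directory; writes per-subject
    z-maps, contrast cluster tables, the rating-change regression table,
    ROI-thirds volumes/comparisons and scatter data; returns everything
    in memory as well."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(cohort_path)
    config.to_yaml(out / "resolved_config.yaml")

    maps = subject_maps(cohort, config, out_dir=out)
    controls = [maps[k] for k in sorted(maps) if k[1] == "single"]
    patient_ids = sorted({sid for sid, cond in maps if cond in ("LP", "HP")})
    lp = [maps[(sid, "LP")] for sid in patient_ids]
    hp = [maps[(sid, "HP")] for sid in patient_ids]
    report: dict = {"n_controls": len(controls), "n_patients": len(patient_ids)}

    tables = {}
    results = {}
    if controls and lp and len(controls) >= 2 and len(lp) >= 2:
        tables["HC_vs_LP"], r1 = _contrast_tables(("HC", "LP"), controls, lp,
                                                  "two_sample", config, 10, out)
        tables["HC_vs_HP"], r2 = _contrast_tables(("HC", "HP"), controls, hp,
                                                  "two_sample", config, 20, out)
        results.update(r1); results.update(r2)
    if len(lp) >= 2:
        tables["HP_vs_LP"], r3 = _contrast_tables(("HP", "LP"), hp, lp,
                                                  "paired", config, 30, out)
        results.update(r3)
        delta = [conn.ZMap(h.values - l.values, h.mask, h.affine,
                           subject_id=h.subject_id, condition="HP-LP")
                 for h, l in zip(hp, lp)]
        cov = pain_covariate(cohort).loc[patient_ids].to_numpy()
        if np.ptp(cov) > 0:
            tables["regression"], r4 = _contrast_tables(
                ("pos", "neg"), delta, None, "regression", config, 40, out,
                covariate=cov)
            results.update(r4)
        else:
            warnings.warn("pain covariate has no variance; regression skipped")
    else:
        warnings.warn("no patient pairs; paired and regression stages skipped")

    # scatter data: mean z in the top paired cluster (or the whole-map peak)
    scatter = None
    key = "HP>LP"
    if key in results and len(results[key].table):
        cluster_mask = results[key].clusters == 1
        scatter = gstats.extract_mean_z(controls + lp + hp, cluster_mask)
        scatter.to_csv(out / "mean_z_scatter.tsv", sep="\t", index=False)

    volumes = roi_thirds_volumes(cohort)
    if not volumes.empty:
        volumes.to_csv(out / "roi_volumes.tsv", sep="\t", index=False)
        group_n = volumes["group"].value_counts()
        if group_n.get("patient", 0) >= 2 and group_n.get("control", 0) >= 2:
            comparison = roi_thirds_comparison(volumes)
            comparison.to_csv(out / "roi_comparison.tsv", sep="\t", index=False)
            report["roi_comparison"] = comparison
        else:
            warnings.warn("one group has fewer than 2 subjects; "
                          "volume comparison skipped")

    report.update({"tables": tables, "results": results, "volumes": volumes,
                   "scatter": scatter, "maps": maps})
    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": config.__dict__,
                   "n_scans": len(maps),
                   "contrasts": sorted(tables)}, fh, indent=1, default=str)
    return report
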