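"""Orchestration: simulate -> quantify -> respond as reproducible runs.

``run_simulate`` renders a synthetic cohort to NIfTI volumes, label masks
and truth/cohort CSVs. ``run_quantify`` takes such a directory (or any
directory laid out the same way) through enhancement, AIF extraction,
perfused-tumour segmentation and kinetic fitting, appending one row per
lesion to a tidy results CSV — a failed lesion gets an explicit failure
row, and the run continues. ``run_respond`` turns per-lesion results into
the response analysis: index-lesion change tables, paired tests across
visits, progression-group comparisons, ROC for discriminating parameters
and, when a second reader's results are supplied, inter-reader ICC.

Everything is derived from a config + seed; identical inputs give
byte-identical output CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .acquisition import AcquisitionSpec
from .aif import extract_aif, refine_aif_roi, relative_enhancement
from .io import TIMEPOINTS, read_cohort_table, read_dynamic, read_mask, write_dynamic, write_mask
from .kinetics import fit_one_compartment, roi_mean_curve
from .longitudinal import INTERVALS, PARAMETERS, change_table, lesion_census
from .phantom import ProgressionEffect, generate_cohort, render_phantom
from .segmentation import max_enhancement_map, threshold_perfused_roi
from .stats import ALPHA, compare_groups, icc_agreement, paired_t, roc_auc

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_respond"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "patient_id", "timepoint", "lesion_id", "organ", "n_voxels", "volume_cm3",
    "ktrans_min^-1", "ecv_ml_per_100ml", "mtt_s", "fit_rss", "converged",
    "status", "reason",
]


@dataclass
class RunConfig:
    """Configuration shared by the pipeline stages."""

    n_patients: int = 4
    n_progressors: int = 2
    noise_sd: float = 0.02
    ktrans_rise_factor: float = 2.0
    volume_rise_factor: float = 1.5
    threshold_fraction: float = 0.5
    percentile_band: tuple = (95.0, 100.0)
    alpha: float = ALPHA
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    qc_figures: bool = False

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["acquisition"] = dataclasses.asdict(self.acquisition)
        d["percentile_band"] = list(self.percentile_band)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionSpec(**d["acquisition"])
        if "percentile_band" in d:
            d["percentile_band"] = tuple(d["percentile_band"])
        return cls(**d)


def _vol_name(pid: str, tp: str) -> str:
    return f"{pid}_{tp}_dyn.nii"


def run_simulate(config: RunConfig, seed: int, out_dir) -> Path:
    """Render a synthetic cohort to ``out_dir`` and return that path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    effect = ProgressionEffect(
        ktrans_rise_factor=config.ktrans_rise_factor,
        volume_rise_factor=config.volume_rise_factor,
    )
    scenes, truth = generate_cohort(
        n_patients=config.n_patients,
        n_progressors=config.n_progressors,
        effect=effect,
        seed=seed,
        noise_sd=config.noise_sd,
        acquisition=config.acquisition,
    )
    for pid, by_tp in scenes.items():
        for tp, scene in by_tp.items():
            t0 = time.perf_counter()
            series, masks, _ = render_phantom(scene)
            write_dynamic(series, out / _vol_name(pid, tp))
            write_mask(masks["aorta"], out / f"{pid}_{tp}_aorta.nii")
            for name, m in masks.items():
                if name.startswith("lesion_"):
                    write_mask(m, out / f"{pid}_{tp}_{name}.nii")
            logger.info("simulate %s %s: %d lesions, %.2fs",
                        pid, tp, len(scene.lesions), time.perf_counter() - t0)
    truth.to_csv(out / "truth.csv", index=False)
    cohort = truth[["patient_id", "lesion_id", "organ", "timepoint", "progression"]]
    cohort.to_csv(out / "cohort.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "run.json").write_text(json.dumps({"seed": seed, "stage": "simulate"}))
    return out


def _quantify_lesion(enh, aif, candidate, config, voxel_volume):
    emap = max_enhancement_map(enh)
    roi = threshold_perfused_roi(
        candidate, emap, fraction=config.threshold_fraction, voxel_volume=voxel_volume
    )
    curve = roi_mean_curve(enh, roi.mask)
    params = fit_one_compartment(curve, aif)
    return roi, curve, params


def _perturb_mask(mask: dio.RoiMask, rng) -> dio.RoiMask:
    """Emulate a second reader: randomly dilate or erode the candidate by one voxel."""
    from scipy import ndimage

    if rng.random() < 0.5:
        new = ndimage.binary_dilation(mask.mask)
    else:
        eroded = ndimage.binary_erosion(mask.mask)
        new = eroded if eroded.any() else mask.mask
    return dio.RoiMask(mask=new, role=mask.role, reader_id="reader2")


def run_quantify(
    data_dir, config: RunConfig, out_csv, reader_id: str = "reader1", seed: int = 0
) -> pd.DataFrame:
    """Quantify every lesion of every patient/timepoint in ``data_dir``.

    Expects the layout written by :func:`run_simulate`. ``reader_id``
    other than ``"reader1"`` perturbs the candidate masks with a seeded
    one-voxel dilation/erosion, emulating an independent second reader for
    agreement analysis.
    """
    data_dir = Path(data_dir)
    cohort = read_cohort_table(data_dir / "cohort.csv")
    rng = np.random.default_rng(seed + 1_000_003)
    rows = []
    for (pid, tp), grp in cohort.groupby(["patient_id", "timepoint"], sort=True):
        vol_path = data_dir / _vol_name(pid, tp)
        try:
            series = read_dynamic(vol_path)
            enh = relative_enhancement(series)
            aorta = read_mask(data_dir / f"{pid}_{tp}_aorta.nii", series.grid_shape)
            refined = refine_aif_roi(aorta, enh, config.percentile_band)
            aif = extract_aif(refined, enh)
        except (OSError, ValueError) as exc:
            for _, rec in grp.iterrows():
                rows.append(_failure_row(rec, pid, tp, f"series/AIF stage: {exc}"))
            continue
        for _, rec in grp.iterrows():
            lid = int(rec["lesion_id"])
            t0 = time.perf_counter()
            try:
                cand = read_mask(
                    data_dir / f"{pid}_{tp}_lesion_{lid}.nii", series.grid_shape
                )
                if reader_id != "reader1":
                    cand = _perturb_mask(cand, rng)
                roi, curve, params = _quantify_lesion(
                    enh, aif, cand, config, series.voxel_volume
                )
                if config.qc_figures:
                    _qc_figure(curve, aif, params,
                               Path(out_csv).parent / f"qc_{pid}_{tp}_lesion_{lid}.png")
                rows.append(
                    {
                        "patient_id": pid, "timepoint": tp, "lesion_id": lid,
                        "organ": rec["organ"], "n_voxels": roi.n_voxels,
                        "volume_cm3": roi.perfused_volume_cm3,
                        "ktrans_min^-1": params.ktrans,
                        "ecv_ml_per_100ml": params.ecv,
                        "mtt_s": params.mtt, "fit_rss": params.fit_rss,
                        "converged": params.converged, "status": "ok", "reason": "",
                    }
                )
                logger.info("quantify %s %s lesion %d: ok (%.2fs)",
                            pid, tp, lid, time.perf_counter() - t0)
            except (OSError, ValueError) as exc:
                rows.append(_failure_row(rec, pid, tp, str(exc)))
                logger.warning("quantify %s %s lesion %d: failed (%s)", pid, tp, lid, exc)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_csv, index=False)
    return df


def _qc_figure(curve, aif, params, path) -> None:
    """Measured enhancement curve with the model fit overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinetics import one_compartment_curve

    fit = one_compartment_curve(aif.values, curve.frame_times, params.ktrans, params.ecv)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(curve.frame_times, curve.values, color="tab:blue", label="tumour ROI mean")
    ax.plot(curve.frame_times, fit, color="tab:red",
            label=f"fit: Ktrans={params.ktrans:.2f}/min, ECV={params.ecv:.0f}")
    ax.set_xlabel("time since injection (s)")
    ax.set_ylabel("relative enhancement (a.u.)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _failure_row(rec, pid, tp, reason):
    return {
        "patient_id": pid, "timepoint": tp, "lesion_id": int(rec["lesion_id"]),
        "organ": rec.get("organ", ""), "n_voxels": 0, "volume_cm3": np.nan,
        "ktrans_min^-1": np.nan, "ecv_ml_per_100ml": np.nan, "mtt_s": np.nan,
        "fit_rss": np.nan, "converged": False, "status": "failed", "reason": reason,
    }


def run_respond(
    results_csv,
    cohort_csv,
    config: RunConfig,
    out_dir,
    reader2_results_csv=None,
) -> dict:
    """Response analysis from per-lesion results.

    Writes ``changes.csv``, ``group_tests.csv``, ``paired_tests.csv``,
    ``roc.csv`` (parameters whose group test passes alpha), ``census.csv``
    and a human-readable ``report.md`` to ``out_dir``; returns the
    assembled tables in a dict. Group comparisons with fewer than two
    patients per progression group are skipped with a named reason.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = pd.read_csv(results_csv)
    cohort = read_cohort_table(cohort_csv)
    ok = results[results["status"] == "ok"]

    changes = change_table(ok)
    changes.to_csv(out / "changes.csv", index=False)

    prog_by_patient = (
        cohort.drop_duplicates("patient_id")
        .set_index("patient_id")["progression"]
        .astype(str).str.lower().isin(["yes", "true", "1"])
    )

    paired_rows, group_rows, roc_rows = [], [], []
    # paired tests: index-lesion parameter values across visit pairs
    values = _index_lesion_values(ok)
    for param in PARAMETERS:
        for earlier, later in INTERVALS:
            sub = values.pivot(index="patient_id", columns="timepoint", values=param)
            sub = sub.dropna(subset=[earlier, later]) if {earlier, later} <= set(sub.columns) else sub.iloc[:0]
            if len(sub) < 2:
                paired_rows.append({"parameter": param, "interval": f"{earlier}->{later}",
                                    "skipped": "fewer than 2 complete pairs",
                                    "statistic": np.nan, "p_value": np.nan, "n": len(sub)})
                continue
            try:
                res = paired_t(sub[earlier].values, sub[later].values)
                paired_rows.append({"parameter": param, "interval": f"{earlier}->{later}",
                                    "skipped": "", "statistic": res.statistic,
                                    "p_value": res.p_value, "n": len(sub)})
            except ValueError as exc:
                paired_rows.append({"parameter": param, "interval": f"{earlier}->{later}",
                                    "skipped": str(exc), "statistic": np.nan,
                                    "p_value": np.nan, "n": len(sub)})

    # group comparisons + ROC on per-patient changes
    n_prog = int(prog_by_patient.sum())
    n_non = int((~prog_by_patient).sum())
    for param in PARAMETERS:
        for earlier, later in INTERVALS:
            interval = f"{earlier}->{later}"
            for kind in ("absolute_change", "percent_change"):
                sub = changes[
                    (changes["parameter"] == param)
                    & (changes["interval"] == interval)
                    & ~changes["missing"]
                ].dropna(subset=[kind])
                labels = sub["patient_id"].map(prog_by_patient)
                a = sub.loc[labels == True, kind].values  # noqa: E712 — pandas mask
                b = sub.loc[labels == False, kind].values  # noqa: E712
                row = {"parameter": param, "interval": interval, "change_kind": kind,
                       "n_progressor": len(a), "n_stable": len(b)}
                if len(a) < 2 or len(b) < 2:
                    row.update({"skipped": f"needs >= 2 patients per group "
                                           f"(progressors={len(a)}, stable={len(b)})",
                                "test": "", "statistic": np.nan, "p_value": np.nan,
                                "route": ""})
                    group_rows.append(row)
                    continue
                res = compare_groups(a, b)
                row.update({"skipped": "", "test": res.test_name,
                            "statistic": res.statistic, "p_value": res.p_value,
                            "route": res.route})
                group_rows.append(row)
                if res.p_value < config.alpha:
                    scores = np.concatenate([a, b])
                    lab = np.concatenate([np.ones(len(a), bool), np.zeros(len(b), bool)])
                    roc = roc_auc(scores, lab)
                    roc_rows.append({"parameter": param, "interval": interval,
                                     "change_kind": kind, "auc": roc.auc,
                                     "orientation": roc.orientation,
                                     "n_positive": roc.n_positive,
                                     "n_negative": roc.n_negative})

    paired_df = pd.DataFrame(paired_rows)
    group_df = pd.DataFrame(group_rows)
    roc_df = pd.DataFrame(roc_rows, columns=["parameter", "interval", "change_kind",
                                             "auc", "orientation", "n_positive",
                                             "n_negative"])
    paired_df.to_csv(out / "paired_tests.csv", index=False)
    group_df.to_csv(out / "group_tests.csv", index=False)
    roc_df.to_csv(out / "roc.csv", index=False)

    census = lesion_census(cohort)
    census_df = pd.DataFrame(
        [{"organ": k, "n": v} for k, v in sorted(census["by_organ"].items())]
        + [{"organ": "total", "n": census["total_lesions"]}]
    )
    census_df.to_csv(out / "census.csv", index=False)

    icc_rows = []
    if reader2_results_csv is not None:
        r2 = pd.read_csv(reader2_results_csv)
        icc_rows = _reader_agreement(ok, r2[r2["status"] == "ok"])
        pd.DataFrame(icc_rows).to_csv(out / "icc.csv", index=False)

    _write_report(out / "report.md", census, paired_df, group_df, roc_df, icc_rows,
                  n_prog, n_non, config)
    return {"changes": changes, "paired": paired_df, "groups": group_df,
            "roc": roc_df, "census": census, "icc": icc_rows}


def _index_lesion_values(ok: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, grp in ok.groupby("patient_id", sort=True):
        base = grp[grp["timepoint"] == "baseline"]
        if len(base) == 0:
            continue
        from .longitudinal import select_index_lesion

        idx = select_index_lesion(base)
        for _, rec in grp[grp["lesion_id"] == idx].iterrows():
            rows.append({"patient_id": pid, "timepoint": rec["timepoint"],
                         "volume": rec["volume_cm3"], "ktrans": rec["ktrans_min^-1"],
                         "ecv": rec["ecv_ml_per_100ml"], "mtt": rec["mtt_s"]})
    return pd.DataFrame(rows)


def _reader_agreement(r1: pd.DataFrame, r2: pd.DataFrame) -> list[dict]:
    keys = ["patient_id", "timepoint", "lesion_id"]
    merged = r1.merge(r2, on=keys, suffixes=("_r1", "_r2"))
    out = []
    for param, col in (("volume", "volume_cm3"), ("ktrans", "ktrans_min^-1"),
                       ("ecv", "ecv_ml_per_100ml")):
        mat = merged[[f"{col}_r1", f"{col}_r2"]].dropna().values
        if len(mat) < 3:
            out.append({"parameter": param, "icc": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "category": "insufficient data"})
            continue
        res = icc_agreement(mat)
        out.append({"parameter": param, "icc": res.icc, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "category": res.category})
    return out


def _write_report(path, census, paired_df, group_df, roc_df, icc_rows, n_prog, n_non,
                  config) -> None:
    lines = ["# Treatment-response report", ""]
    lines.append(f"Cohort: {census['n_patients']} patients "
                 f"({n_prog} progressors, {n_non} stable), "
                 f"{census['total_lesions']} lesions.")
    lines.append("")
    lines.append("## Lesion census")
    for organ, n in sorted(census["by_organ"].items()):
        lines.append(f"- {organ}: {n}")
    lines.append("")
    lines.append("## Paired tests across visits (index lesion)")
    for _, r in paired_df.iterrows():
        if r["skipped"]:
            lines.append(f"- {r['parameter']} {r['interval']}: skipped ({r['skipped']})")
        else:
            lines.append(f"- {r['parameter']} {r['interval']}: "
                         f"t = {r['statistic']:.3f}, p = {r['p_value']:.4f} (n = {r['n']})")
    lines.append("")
    lines.append("## Progression-group comparisons")
    for _, r in group_df.iterrows():
        if r["skipped"]:
            lines.append(f"- {r['parameter']} {r['interval']} [{r['change_kind']}]: "
                         f"skipped ({r['skipped']})")
        else:
            lines.append(f"- {r['parameter']} {r['interval']} [{r['change_kind']}]: "
                         f"{r['test']} ({r['route']}), statistic = {r['statistic']:.3f}, "
                         f"p = {r['p_value']:.4f}")
    lines.append("")
    lines.append(f"## ROC (group test p < {config.alpha})")
    if len(roc_df) == 0:
        lines.append("- no parameter passed the significance gate")
    for _, r in roc_df.iterrows():
        lines.append(f"- {r['parameter']} {r['interval']} [{r['change_kind']}]: "
                     f"AUC = {r['auc']:.3f} ({r['orientation']} predicts progression)")
    if icc_rows:
        lines.append("")
        lines.append("## Inter-reader agreement (ICC(2,1))")
        for r in icc_rows:
            if np.isnan(r.get("icc", np.nan)):
                lines.append(f"- {r['parameter']}: {r['category']}")
            else:
                lines.append(f"- {r['parameter']}: ICC = {r['icc']:.3f} "
                             f"(95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f}), "
                             f"{r['category']}")
    Path(path).write_text("\n".join(lines) + "\n")
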