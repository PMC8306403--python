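"""Per-patient longitudinal change tables and the lesion census.

For patients with several lesions, only the largest lesion (by baseline
perfused volume) enters the response analysis — the largest is least
affected by partial-volume effects. For each of the four parameters
(perfused volume, Ktrans, ECV, MTT) and each of the three intervals
(baseline->week4, week4->week10, baseline->week10) both the absolute and
the percentage change are tabulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import TIMEPOINTS

__all__ = [
    "PARAMETERS",
    "INTERVALS",
    "select_index_lesion",
    "change_table",
    "lesion_census",
]

PARAMETERS = ("volume", "ktrans", "ecv", "mtt")
INTERVALS = (("baseline", "week4"), ("week4", "week10"), ("baseline", "week10"))

_COLUMN_FOR = {
    "volume": "volume_cm3",
    "ktrans": "ktrans_min^-1",
    "ecv": "ecv_ml_per_100ml",
    "mtt": "mtt_s",
}


def select_index_lesion(baseline_records: pd.DataFrame) -> int:
    """Largest-baseline-volume lesion for one patient; ties break to lowest id."""
    if len(baseline_records) == 0:
        raise ValueError("patient has no baseline lesion record")
    df = baseline_records.sort_values(["volume_cm3", "lesion_id"], ascending=[False, True])
    # stable sort puts the lowest lesion_id first among equal volumes
    return int(df.iloc[0]["lesion_id"])


def change_table(
    records: pd.DataFrame,
    value_columns: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-patient index-lesion change records.

    ``records`` is the tidy per-lesion results table with columns
    patient_id, timepoint, lesion_id and the four parameter columns
    (``volume_cm3``, ``ktrans_min^-1``, ``ecv_ml_per_100ml``, ``mtt_s`` by
    default; override via ``value_columns`` mapping parameter name ->
    column). Returns 12 rows per patient (4 parameters x 3 intervals) with
    absolute and percentage change; a missing timepoint yields explicit
    rows with NaN changes and ``missing = True``, never a silent drop.
    Percentage change from a zero earlier value is NaN with
    ``percent_undefined = True``.
    """
    cols = dict(_COLUMN_FOR)
    if value_columns:
        cols.update(value_columns)
    rows = []
    for pid, grp in records.groupby("patient_id", sort=True):
        base = grp[grp["timepoint"] == "baseline"]
        idx = select_index_lesion(base)
        lesion = grp[grp["lesion_id"] == idx]
        by_tp = {tp: sub.iloc[0] for tp, sub in lesion.groupby("timepoint")}
        for param in PARAMETERS:
            col = cols[param]
            for earlier, later in INTERVALS:
                row = {
                    "patient_id": pid,
                    "lesion_id": idx,
                    "parameter": param,
                    "interval": f"{earlier}->{later}",
                    "absolute_change": np.nan,
                    "percent_change": np.nan,
                    "missing": False,
                    "percent_undefined": False,
                }
                if earlier in by_tp and later in by_tp:
                    v0 = float(by_tp[earlier][col])
                    v1 = float(by_tp[later][col])
                    row["absolute_change"] = v1 - v0
                    if v0 != 0:
                        row["percent_change"] = 100.0 * (v1 - v0) / v0
                    else:
                        row["percent_undefined"] = True
                else:
                    row["missing"] = True
                rows.append(row)
    return pd.DataFrame(rows)


def lesion_census(cohort: pd.DataFrame) -> dict:
    """Lesion counts by organ plus totals, de-duplicated over timepoints.

    A lesion is one distinct (patient_id, lesion_id) pair; organs with no
    lesions are absent from the output rather than reported as zero.
    """
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    lesions = cohort.drop_duplicates(subset=["patient_id", "lesion_id"])
    by_organ = lesions.groupby("organ").size().to_dict()
    patients = cohort.drop_duplicates(subset=["patient_id"])
    is_prog = patients["progression"].astype(str).str.lower().isin(["yes", "true", "1"])
    return {
        "total_lesions": int(len(lesions)),
        "by_organ": by_organ,
        "n_patients": int(len(patients)),
        "n_progressors": int(is_prog.sum()),
    }
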