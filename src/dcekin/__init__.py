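"""dcekin: single-compartment DCE-MRI quantification and response analysis.

From a 4D dynamic contrast-enhanced series and coarse operator ROIs to an
arterial input function, a perfused-tumour segmentation, Kety/Tofts-type
kinetic parameters (Ktrans, ECV, ECV-MTT), longitudinal per-patient change
tables and the response statistics (normality-routed group tests, ROC,
inter-reader ICC) — plus a synthetic phantom and cohort generator with
known ground truth so every stage is testable end to end.
"""

from importlib import resources

import pandas as pd

from .acquisition import AcquisitionSpec
from .aif import AifCurve, EnhancementSeries, extract_aif, refine_aif_roi, relative_enhancement
from .io import (
    DynamicSeries,
    RoiMask,
    TIMEPOINTS,
    read_cohort_table,
    read_dynamic,
    read_mask,
    write_dynamic,
    write_mask,
)
from .kinetics import (
    OneCompartmentParams,
    TissueCurve,
    fit_one_compartment,
    mtt_from_params,
    one_compartment_curve,
    predict_curve,
    roi_mean_curve,
)
from .longitudinal import change_table, lesion_census, select_index_lesion
from .phantom import (
    AifModelParams,
    LesionSpec,
    PhantomScene,
    ProgressionEffect,
    generate_cohort,
    population_aif,
    render_phantom,
    tissue_curve,
)
from .pipeline import RunConfig, run_quantify, run_respond, run_simulate
from .segmentation import (
    MaxEnhancementMap,
    PerfusedRoi,
    max_enhancement_map,
    perfused_volume,
    threshold_perfused_roi,
)
from .stats import (
    IccResult,
    RocResult,
    TestResult,
    compare_groups,
    grade_icc,
    icc_agreement,
    ks_normality,
    paired_t,
    roc_auc,
)

__version__ = "0.1.0"


def load_example_cohort() -> pd.DataFrame:
    """Lesion-level cohort table of the motivating 14-patient metastatic
    renal-cell-cancer TKI study (23 lesions, 3 six-month progressors)."""
    with resources.files("dcekin.data").joinpath("cohort_lesions.csv").open() as fh:
        return read_cohort_table(fh)
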