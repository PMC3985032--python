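"""End-to-end study orchestration.

``run_study`` executes the full chain on synthetic data: cohort generation
-> per-subject ASL simulation -> rWLS GLM fit -> CBF quantification ->
regional aggregation -> outlier exclusion -> fitness indices -> the
statistical suite (tissue contrasts, partial correlations, mediation with
bootstrap and reverse check, eCRF-component and volume analyses).  A single
study seed fans out to per-stage child seeds through a SeedSequence, so
every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from . import __version__ as _version
from .config import StudyConfig, GRAY_REGIONS, WHITE_REGIONS
from .fitness import add_fitness_columns
from .glm import fit_rwls
from .io import REQUIRED_COHORT_COLUMNS, read_cohort, read_series
from .mediation import (bootstrap_mediation, exclude_outliers, mediate,
                        normalize_volume_icv, partial_correlation, residualize,
                        stratified_residual_sensitivity)
from .quant import quantify_cbf, regional_mean_cbf, tissue_contrast
from .synthetic import build_masks, generate_cohort, simulate_asl_series

__all__ = ["StudyReport", "run_study", "ingest_real", "measure_regional_cbf"]

#: outcome regions analyzed for mediation (the measures that showed both
#: age and fitness relationships in the motivating design: global gray,
#: parietal gray, parietal white)
MEDIATION_REGIONS = ("gray", "parietal_gray", "parietal_white")


@dataclass
class StudyReport:
    cohort: pd.DataFrame
    regional_cbf: pd.DataFrame            # long table: subject, region, tissue, mean_cbf, voxel_count
    exclusions: pd.DataFrame
    tissue_contrasts: pd.DataFrame
    partial_correlations: pd.DataFrame
    component_correlations: pd.DataFrame
    sensitivity: pd.DataFrame
    volume_correlations: pd.DataFrame
    mediation: dict = field(default_factory=dict)       # region -> MediationResult
    reverse_mediation: dict = field(default_factory=dict)  # region -> BootstrapCI
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def df(d: pd.DataFrame):
            return d.to_dict(orient="records")

        med = {k: asdict(v) for k, v in self.mediation.items()}
        rev = {}
        for k, v in self.reverse_mediation.items():
            d = asdict(v)
            d.pop("samples", None)
            rev[k] = d
        return {
            "cohort": df(self.cohort),
            "regional_cbf": df(self.regional_cbf),
            "exclusions": df(self.exclusions),
            "tissue_contrasts": df(self.tissue_contrasts),
            "partial_correlations": df(self.partial_correlations),
            "component_correlations": df(self.component_correlations),
            "sensitivity": df(self.sensitivity),
            "volume_correlations": df(self.volume_correlations),
            "mediation": med,
            "reverse_mediation": rev,
            "provenance": self.provenance,
        }


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one study seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def measure_regional_cbf(series, quant_params, n_iter: int = 2) -> dict[str, "RegionalCBF"]:
    """Fit the baseline GLM (rWLS), quantify, and average over each mask."""
    fit = fit_rwls(series, n_iter=n_iter)
    cbf_map = quantify_cbf(fit.delta_m_map, fit.m0_map, quant_params)
    return {name: regional_mean_cbf(cbf_map, mask, region=name)
            for name, mask in series.masks.items()}


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full synthetic study defined by ``config``."""
    config = config or StudyConfig()
    config.validate()
    cohort_seed, imaging_seed, stats_seed = _child_seeds(config.seed, 3)

    cohort = generate_cohort(config.cohort, seed=cohort_seed)
    cohort = add_fitness_columns(cohort)

    regions = ("gray", "white") + GRAY_REGIONS + WHITE_REGIONS
    regional_rows = []
    if config.simulate_imaging:
        masks = build_masks(config.acquisition.shape)
        subject_seeds = _child_seeds(imaging_seed, len(cohort))
        for (_, subject), sseed in zip(cohort.iterrows(), subject_seeds):
            measured = measure_regional_cbf(
                simulate_asl_series(subject, config.acquisition, masks, seed=sseed),
                config.quant)
            for name, reg in measured.items():
                regional_rows.append({
                    "subject": subject["id"], "region": name, "tissue": reg.tissue,
                    "mean_cbf": reg.mean_cbf, "voxel_count": reg.voxel_count})
        regional_cbf = pd.DataFrame(regional_rows)
        wide = regional_cbf.pivot(index="subject", columns="region",
                                  values="mean_cbf")
        for region in regions:
            if region in wide.columns:
                cohort[f"meas_cbf_{region}"] = wide.loc[cohort["id"], region].to_numpy()
    else:
        # covariate-table-only mode: ground-truth regional CBF stands in for
        # the imaging-derived measurement
        regional_cbf = pd.DataFrame(
            columns=["subject", "region", "tissue", "mean_cbf", "voxel_count"])
        for region in regions:
            cohort[f"meas_cbf_{region}"] = cohort[f"cbf_{region}"]

    # outlier exclusion on the MRI-derived measures (single pass, 3-SD rule)
    mri_measures = [f"meas_cbf_{r}" for r in regions] + \
                   ["vol_superior_frontal", "vol_inferior_parietal", "icv"]
    cohort, exclusions = exclude_outliers(
        cohort, measures=mri_measures,
        threshold_sd=config.stats.outlier_threshold_sd)

    gender = cohort["gender_code"].to_numpy(dtype=float)

    # gray vs white paired contrasts
    contrast_rows = []
    for label, g_col, w_col in (
            ("global", "meas_cbf_gray", "meas_cbf_white"),
            ("frontal", "meas_cbf_frontal_gray", "meas_cbf_frontal_white"),
            ("parietal", "meas_cbf_parietal_gray", "meas_cbf_parietal_white")):
        t, df_, p = tissue_contrast(cohort[g_col], cohort[w_col])
        contrast_rows.append({"contrast": label, "t": t, "df": df_, "p": p})
    tissue_contrasts = pd.DataFrame(contrast_rows)

    # partial correlations controlling gender (one-tailed reported alongside)
    def pcorr_table(predictors: list[str]) -> pd.DataFrame:
        rows = []
        for pred in predictors:
            for region in regions:
                try:
                    pc = partial_correlation(cohort[pred],
                                             cohort[f"meas_cbf_{region}"], gender)
                    row = {"r": pc.r, "df": pc.df,
                           "p_one_tailed": pc.p_one_tailed,
                           "p_two_tailed": pc.p_two_tailed}
                except ValueError as exc:  # e.g. zero-variance region
                    logger.warning("partial correlation %s vs %s undefined: %s",
                                   pred, region, exc)
                    row = {"r": np.nan, "df": len(cohort) - 3,
                           "p_one_tailed": np.nan, "p_two_tailed": np.nan}
                rows.append({"predictor": pred, "region": region, **row})
        return pd.DataFrame(rows)

    partial_correlations = pcorr_table(
        ["age", "ecrf", "systolic_bp", "diastolic_bp", "pulse_pressure"])
    component_correlations = pcorr_table(
        ["bmi", "resting_heart_rate", "activity_score"])

    # mediation: age -> eCRF -> regional CBF on gender-residualized variables
    # (gender is regressed out of every variable of interest first)
    boot_seeds = _child_seeds(stats_seed, 2 * len(MEDIATION_REGIONS) + 1)
    age = residualize(cohort["age"], gender)
    ecrf = residualize(cohort["ecrf"], gender)
    mediation, reverse = {}, {}
    for i, region in enumerate(MEDIATION_REGIONS):
        outcome = residualize(cohort[f"meas_cbf_{region}"], gender)
        mediation[region] = mediate(
            age, ecrf, outcome, alpha=config.stats.alpha,
            n_resamples=config.stats.n_resamples,
            confidence=config.stats.confidence, random_state=boot_seeds[2 * i])
        reverse[region] = bootstrap_mediation(
            ecrf, age, outcome, n_resamples=config.stats.n_resamples,
            confidence=config.stats.confidence, seed=boot_seeds[2 * i + 1])

    # eCRF-component sensitivity analysis (gender x age strata residuals);
    # skipped (empty table) when a stratum is too small to center
    try:
        sensitivity = stratified_residual_sensitivity(
            cohort, ["ecrf", "bmi", "resting_heart_rate", "activity_score"],
            outcome="meas_cbf_gray")
    except ValueError as exc:
        logger.warning("sensitivity analysis skipped: %s", exc)
        sensitivity = pd.DataFrame(
            columns=["measure", "r", "p_two_tailed", "p_one_tailed", "n"])

    # regional volumes, ICV-normalized, vs regional CBF
    vol_rows = []
    norm = {col: normalize_volume_icv(cohort[col], cohort["icv"])
            for col in ("vol_superior_frontal", "vol_inferior_parietal")}
    for vol_col, adj in norm.items():
        for region in ("frontal_gray", "parietal_gray"):
            pc = partial_correlation(cohort[f"meas_cbf_{region}"], adj, gender)
            vol_rows.append({"volume": vol_col, "region": region, "r": pc.r,
                             "df": pc.df, "p_one_tailed": pc.p_one_tailed,
                             "p_two_tailed": pc.p_two_tailed})
    volume_correlations = pd.DataFrame(vol_rows)

    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    provenance = {
        "version": _version,
        "seed": config.seed,
        "n_subjects_retained": int(len(cohort)),
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    return StudyReport(
        cohort=cohort, regional_cbf=regional_cbf, exclusions=exclusions,
        tissue_contrasts=tissue_contrasts,
        partial_correlations=partial_correlations,
        component_correlations=component_correlations,
        sensitivity=sensitivity, volume_correlations=volume_correlations,
        mediation=mediation, reverse_mediation=reverse, provenance=provenance,
    )


def ingest_real(cohort_csv, series_dir=None, prefix_column: str = "id"):
    """Load and validate real study inputs.

    ``cohort_csv`` must carry the required covariate columns
    (:data:`~cbfmed.io.REQUIRED_COHORT_COLUMNS`).  When ``series_dir`` is
    given, one NIfTI series per subject is loaded, expecting files written
    by :func:`cbfmed.io.write_series` with the subject id as prefix; all
    per-file validation errors are collected and reported together.

    Returns ``(cohort, series_by_subject)``.
    """
    cohort = read_cohort(cohort_csv)
    series = {}
    if series_dir is not None:
        errors = []
        for subject in cohort[prefix_column]:
            try:
                series[subject] = read_series(series_dir, prefix=str(subject))
            except (OSError, ValueError) as exc:
                errors.append(f"{subject}: {exc}")
        if errors:
            raise ValueError("ingestion failed for:\n" + "\n".join(errors))
    return cohort, series
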