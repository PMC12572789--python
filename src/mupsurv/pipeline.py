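"""End-to-end analysis: catalogue → exposures → cohort → spline Cox → curves.

`run_analysis` is the single entry point the sensitivity harness re-runs
under different hooks.  Given the four study inputs (products, recalls,
participants, lexicon) it scores exposures, applies the exclusion
criteria, builds follow-up, fits one penalized spline Cox model per
requested exposure key (with total energy intake as a second spline term),
optionally stratifies proportional-hazards violators, and summarises each
exposure as linear/non-linear p-values, the HR-nadir and HRs at offsets
above the nadir.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Callable

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .coxfit import SplineTermSpec, decompose, fit_cox_pspline, ph_diagnose_and_stratify
from .curves import curve, hr_at
from .exposure import UPF_KEY, build_mli_table, build_profiles
from .lexicon import MupLexicon, load_lexicon

__all__ = ["BaseInputs", "AnalysisOptions", "run_analysis", "DEFAULT_COVARIATES"]

#: Full adjustment set (categorical covariates as produced by derive_covariates).
DEFAULT_COVARIATES = (
    "age_years_q",
    "alcohol_band",
    "bmi_band",
    "ethnicity",
    "general_health",
    "qualification",
    "psychiatric_history",
    "income_band",
    "met_per_week_q",
    "sbp_mmHg_q",
    "sex",
    "smoking_status",
    "townsend_q",
)


@dataclass
class BaseInputs:
    """The four study inputs plus the default adjustment set."""

    products: pd.DataFrame
    recalls: pd.DataFrame
    participants: pd.DataFrame
    lexicon: MupLexicon | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.lexicon is None:
            self.lexicon = load_lexicon()


@dataclass
class AnalysisOptions:
    """Hooks the sensitivity variants turn.  Defaults = the main analysis."""

    exposure_keys: tuple[str, ...] = (UPF_KEY,)
    max_products: int = 10
    recall_mode: str = "mean_over_recalls"
    landmark_years: float | None = None
    cohort_filter: Callable[[pd.DataFrame], pd.Series] | None = None
    skip_exclusions: bool = False
    minimal_exclusions: bool = False  # criterion 2 only (imputation variants)
    imputer: Callable[[pd.DataFrame], pd.DataFrame] | None = None
    covariates: tuple[str, ...] | None = None  # None = base default
    add_quintile_covariates: tuple[str, ...] = ()  # raw cols added as quintiles
    add_flag_covariates: tuple[str, ...] = ()  # raw bool cols added as-is
    drop_covariates: tuple[str, ...] = ()
    spline_covariates: tuple[str, ...] = ()  # raw continuous cols as P-splines
    include_energy_spline: bool = True
    use_cumulative_exposure: bool = False
    ph_adjust: bool = True
    n_basis: int = 8
    target_df: float = 4.0
    ties: str = "breslow"
    grid_n: int = 128
    hr_offsets: tuple[float, ...] = (10.0, 20.0)
    cutoff: date = cohort_mod.DEFAULT_CUTOFF
    alpha: float = 0.05


def _quintile(x: pd.Series, name: str) -> pd.Series:
    return pd.qcut(x.astype(float), 5, labels=[f"Q{i}" for i in range(1, 6)],
                   duplicates="drop").rename(name)


def run_analysis(base: BaseInputs, opts: AnalysisOptions | None = None) -> pd.DataFrame:
    """Run the full pipeline; one result row per exposure key.

    Row fields: n, n_events, p_linear, p_nonlinear, significant (either
    p < alpha, pre-adjustment), slope (linear log-HR component), edf,
    nadir_x, p99, hr at the configured offsets above the nadir, the
    stratified covariate set, and a status ("ok", or the error message for
    variant cells whose preconditions failed).
    """
    opts = opts or AnalysisOptions()

    mli = build_mli_table(base.products, base.lexicon, max_products=opts.max_products)
    profiles = build_profiles(base.recalls, mli, mode=opts.recall_mode)

    participants = base.participants
    if opts.imputer is not None:
        participants = opts.imputer(participants)

    merged = participants.join(profiles, how="inner")

    if opts.skip_exclusions or opts.minimal_exclusions:
        entry = pd.to_datetime(merged["last_assessment_date"])
        death = pd.to_datetime(merged.get("death_date"))
        bad = death.notna() & (death < entry)
        cohort = merged[~bad].copy()
        report = None
    else:
        cohort, report = cohort_mod.apply_exclusions(merged, cutoff=opts.cutoff)

    if opts.cohort_filter is not None:
        cohort = cohort[opts.cohort_filter(cohort)].copy()

    surv = cohort_mod.build_survival_frame(cohort, cutoff=opts.cutoff)
    if opts.landmark_years is not None:
        keep = surv["time_years"] >= opts.landmark_years
        cohort, surv = cohort[keep].copy(), surv[keep].copy()

    covs = cohort_mod.derive_covariates(cohort)
    cov_names = list(opts.covariates if opts.covariates is not None else base.covariates)
    for col in opts.add_quintile_covariates:
        qname = f"{col}_q"
        covs[qname] = _quintile(cohort[col], qname)
        cov_names.append(qname)
    for col in opts.add_flag_covariates:
        covs[col] = cohort[col].astype("category")
        cov_names.append(col)
    cov_names = [c for c in cov_names if c not in opts.drop_covariates]
    # spline-modelled continuous covariates replace their categorical form
    spline_cov_replaces = {"bmi_kg_m2": "bmi_band", "sbp_mmHg": "sbp_mmHg_q"}
    for col in opts.spline_covariates:
        repl = spline_cov_replaces.get(col)
        if repl in cov_names:
            cov_names.remove(repl)

    data = pd.concat([surv, covs], axis=1)
    data["energy_kj"] = cohort["total_energy_kj"].astype(float)
    for col in opts.spline_covariates:
        data[col] = cohort[col].astype(float)

    rows = []
    for key in opts.exposure_keys:
        row: dict[str, object] = {"exposure": key, "status": "ok"}
        try:
            if opts.use_cumulative_exposure or key == "cumulative_specific_mup":
                xvals = cohort["cumulative_specific_mup"].astype(float)
            else:
                xvals = cohort[key].astype(float)
            d = data.copy()
            d["exposure"] = xvals
            spline_terms = [
                SplineTermSpec("exposure", n_basis=opts.n_basis, target_df=opts.target_df)
            ]
            if opts.include_energy_spline:
                spline_terms.append(
                    SplineTermSpec("energy_kj", n_basis=opts.n_basis, target_df=opts.target_df)
                )
            for col in opts.spline_covariates:
                spline_terms.append(
                    SplineTermSpec(col, n_basis=opts.n_basis, target_df=opts.target_df)
                )
            fit = fit_cox_pspline(
                d,
                spline_terms=spline_terms,
                covariates=cov_names,
                ties=opts.ties,
            )
            strata_set: tuple[str, ...] = ()
            if opts.ph_adjust:
                strata_set, fit, _ = ph_diagnose_and_stratify(fit, d, alpha=opts.alpha)
            tests = decompose(fit)
            crv = curve(fit, "exposure", grid_n=opts.grid_n)
            row.update(
                n=fit.n,
                n_events=fit.n_events,
                p_linear=tests.p_linear["exposure"],
                p_nonlinear=tests.p_nonlinear["exposure"],
                slope=tests.slope["exposure"],
                edf=fit.edf["exposure"],
                nadir_x=crv.nadir_x,
                p99=crv.p99,
                strata=",".join(strata_set),
            )
            row["significant"] = bool(
                row["p_linear"] < opts.alpha or row["p_nonlinear"] < opts.alpha
            )
            for off in opts.hr_offsets:
                x = crv.nadir_x + off
                col = f"hr_nadir_plus_{off:g}"
                if x <= crv.p99:
                    row[col] = hr_at(crv, x)[0][0]
                else:
                    row[col] = np.nan
        except Exception as exc:  # variant precondition failures become cells
            row["status"] = f"failed: {exc}"
            row["significant"] = False
        rows.append(row)
    out = pd.DataFrame(rows).set_index("exposure")
    out.attrs["exclusion_report"] = None if report is None else report.to_dict()
    return out
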