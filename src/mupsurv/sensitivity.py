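"""Sensitivity-analysis harness: the 17 robustness variants.

Each variant re-runs the full pipeline with exactly one aspect changed —
a cohort filter (landmark, weight loss, atypical diet, single recall,
prior disease), an exposure mode (first recall only, MLI truncated to the
first 8/6/4 products, cumulative specific-MUP intake), a covariate change
(diet quality, waist-to-hip ratio + height for BMI, energy removed,
medications, BMI/SBP as splines, assessment centre), relaxed exclusions
with pluggable imputation, or Benjamini–Hochberg adjustment across
exposures (categories and specific markers as separate families).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import pandas as pd

from .coxfit import bh_adjust
from .pipeline import AnalysisOptions, BaseInputs, run_analysis

__all__ = [
    "SensitivitySpec",
    "IMPUTERS",
    "register_imputer",
    "default_variants",
    "run_variant",
    "run_all",
    "summarize",
]

#: Registry of pluggable imputers for variants 10–11 (knn, random_forest).
#: An imputer maps the raw participants frame to one with missing
#: covariates filled in.  None registered → the variant reports
#: status "delegated" rather than running.
IMPUTERS: dict[str, Callable[[pd.DataFrame], pd.DataFrame]] = {}


def register_imputer(name: str, fn: Callable[[pd.DataFrame], pd.DataFrame]) -> None:
    IMPUTERS[name] = fn


@dataclass(frozen=True)
class SensitivitySpec:
    """One variant: id, description and the option overrides it applies."""

    variant_id: int
    description: str
    overrides: Mapping[str, object]
    imputer_name: str | None = None

    def options(self, base_opts: AnalysisOptions) -> AnalysisOptions:
        return replace(base_opts, **dict(self.overrides))


def default_variants(mli_k: int = 8) -> list[SensitivitySpec]:
    """The 17 shipped variants; variant 15 uses ``mli_k`` products."""
    return [
        SensitivitySpec(1, "landmark: exclude follow-up < 2 years",
                        {"landmark_years": 2.0}),
        SensitivitySpec(2, "exclude unintentional weight loss",
                        {"cohort_filter": lambda df: ~df["unintentional_weight_loss"].astype(bool)}),
        SensitivitySpec(3, "exclude atypical-diet reporters",
                        {"cohort_filter": lambda df: ~df["diet_not_typical"].astype(bool)}),
        SensitivitySpec(4, "exclude single-recall participants",
                        {"cohort_filter": lambda df: df["n_recalls"] > 1}),
        SensitivitySpec(5, "exclude prior CVD/cancer",
                        {"cohort_filter": lambda df: ~df["prior_cvd_cancer"].astype(bool)}),
        SensitivitySpec(6, "first recall only", {"recall_mode": "first_recall"}),
        SensitivitySpec(7, "adjust for diet quality",
                        {"add_quintile_covariates": ("diet_quality",)}),
        SensitivitySpec(8, "waist-to-hip ratio + height instead of BMI",
                        {"add_quintile_covariates": ("waist_hip_ratio", "height_m"),
                         "drop_covariates": ("bmi_band",)}),
        SensitivitySpec(9, "energy intake removed as covariate",
                        {"include_energy_spline": False}),
        SensitivitySpec(10, "minimal exclusions + kNN imputation",
                        {"minimal_exclusions": True}, imputer_name="knn"),
        SensitivitySpec(11, "minimal exclusions + random-forest imputation",
                        {"minimal_exclusions": True}, imputer_name="random_forest"),
        SensitivitySpec(12, "adjust for cardiometabolic medication",
                        {"add_flag_covariates": ("chol_medication", "bp_medication",
                                                 "insulin_therapy")}),
        SensitivitySpec(13, "BMI and SBP as penalized splines",
                        {"spline_covariates": ("bmi_kg_m2", "sbp_mmHg")}),
        SensitivitySpec(14, "adjust for assessment centre",
                        {"add_flag_covariates": ("assessment_centre",)}),
        SensitivitySpec(15, f"MLI from first {mli_k} products", {"max_products": mli_k}),
        SensitivitySpec(16, "cumulative specific-MUP exposure",
                        {"use_cumulative_exposure": True,
                         "exposure_keys": ("cumulative_specific_mup",)}),
        SensitivitySpec(17, "Benjamini-Hochberg FDR across exposures", {}),
    ]


def run_variant(
    spec: SensitivitySpec,
    base: BaseInputs,
    base_opts: AnalysisOptions | None = None,
) -> pd.DataFrame:
    """One column of the results matrix: the variant's per-exposure results.

    Variant 17 re-reports the main analysis with BH-adjusted p-values;
    variants 10–11 run only when their imputer is registered, otherwise
    every cell carries status "delegated".
    """
    base_opts = base_opts or AnalysisOptions()
    if spec.imputer_name is not None:
        imputer = IMPUTERS.get(spec.imputer_name)
        if imputer is None:
            keys = base_opts.exposure_keys
            return pd.DataFrame(
                {"status": ["delegated"] * len(keys), "significant": False},
                index=pd.Index(keys, name="exposure"),
            )
        return run_analysis(base, replace(spec.options(base_opts), imputer=imputer))
    if spec.variant_id == 17:
        res = run_analysis(base, base_opts)
        return apply_bh(res, base)
    return run_analysis(base, spec.options(base_opts))


def apply_bh(results: pd.DataFrame, base: BaseInputs, alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust p-values within exposure families (categories | markers).

    The two families — the 9 MUP categories and the specific markers —
    are adjusted separately; the UPF aggregate and the cumulative index
    are left unadjusted.  The significance flag uses min(p_linear_bh,
    p_nonlinear_bh) < alpha.
    """
    assert base.lexicon is not None
    out = results.copy()
    cats = [k for k in out.index if k in base.lexicon.categories]
    marks = [k for k in out.index if k in base.lexicon.marker_names]
    for family in (cats, marks):
        if not family:
            continue
        for col in ("p_linear", "p_nonlinear"):
            if col in out.columns:
                vals = out.loc[family, col].astype(float)
                ok = vals.notna()
                out.loc[vals.index[ok], f"{col}_bh"] = bh_adjust(vals[ok].to_numpy())
    if "p_linear_bh" in out.columns:
        out["significant"] = (
            out.get("p_linear_bh", pd.Series(1.0, index=out.index)).fillna(1) < alpha
        ) | (
            out.get("p_nonlinear_bh", pd.Series(1.0, index=out.index)).fillna(1) < alpha
        )
    return out


def run_all(
    base: BaseInputs,
    base_opts: AnalysisOptions | None = None,
    variants: list[SensitivitySpec] | None = None,
) -> dict[str, pd.DataFrame]:
    """Main analysis plus every requested variant, keyed by column name."""
    base_opts = base_opts or AnalysisOptions()
    out = {"main": run_analysis(base, base_opts)}
    for spec in variants if variants is not None else default_variants():
        out[f"variant_{spec.variant_id}"] = run_variant(spec, base, base_opts)
    return out


def summarize(matrix: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-exposure robustness summary across analysis columns.

    Counts in how many columns each exposure ran and was significant
    (linear or non-linear p < 0.05 pre-adjustment; BH columns use their
    adjusted flags).
    """
    if not matrix:
        raise ValueError("empty results matrix")
    exposures = sorted({e for df in matrix.values() for e in df.index})
    rows = []
    for e in exposures:
        n_run = n_sig = 0
        for df in matrix.values():
            if e not in df.index:
                continue
            cell = df.loc[e]
            if str(cell.get("status", "ok")) != "ok":
                continue
            n_run += 1
            n_sig += int(bool(cell.get("significant", False)))
        rows.append({"exposure": e, "n_analyses": n_run, "n_significant": n_sig})
    return pd.DataFrame(rows).set_index("exposure")
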