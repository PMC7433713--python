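"""End-to-end orchestration: from a cohort to the report tables.

``run_full_analysis`` chains the modules in analysis order — composite
phenotyping, HWE/LD/haplotype estimation, non-compartmental PK, trend and
pairwise statistics, haplotype-phenotype association, and the combined
composite x 3435-carrier two-factor analysis — and returns an
:class:`AnalysisReport` whose tables mirror the study's reporting shapes:

* table1 — demographics by composite group (mean/SD/N plus trend p);
* table2 — the 13 PK parameters by composite group with Jonckheere-Terpstra
  trend p and Holm-adjusted pairwise Wilcoxon p-values;
* table3 — haplotype association (phenotypic mean with 95% CI and p);
* table4 — PK by composite x 3435 carrier with the two main-effect p-values;
* figure-ready series: clearance and AUC* by group, troughs against the
  4-9 ng/ml window, AUC0-12 against the >120 and <=200 ng.h/ml band.

The report is deterministic given (inputs, config, seed); the effective
configuration is echoed into the JSON summary for provenance.  Warnings
never alter the exit path; errors always propagate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .composite import COMPOSITE_ORDER, classify_cohort, composite_frequency_table
from .loci import ABCB1_LOCI, ABCB1_RSIDS, DEFAULT_LOCUS_MAP, GenotypeRecord
from .nca import PK_PARAMETER_COLUMNS, derive_pk_table, egfr_mdrd
from .popgen import (
    EmConfig,
    em_haplotype_frequencies,
    genotype_counts,
    haplotype_phenotype_association,
    hwe_exact_test,
    pairwise_ld,
)
from .stats import combined_two_factor, jonckheere_terpstra, pairwise_wilcoxon_holm

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
    "flag_subtherapeutic_exposure",
    "write_report",
]

logger = logging.getLogger(__name__)

NOT_APPLICABLE = "NA"

#: PK parameters analysed in tables 2-4, in reporting order.
PK_ANALYSIS_PARAMS = [
    "dose",
    "dose_per_tbw",
    "c12",
    "c12_per_dose",
    "cmax",
    "cmax_per_dose",
    "tmax",
    "auc_0_12",
    "auc_star",
    "cl_f",
    "cl_per_lbw",
    "auc_0_4",
    "auc_0_4_norm",
]


class AnalysisConfig(BaseModel):
    """Per-module analysis settings (one JSON document drives the run)."""

    em: dict = Field(default_factory=lambda: dict(tol=1e-8, max_iter=5000, n_restarts=10, seed=0, rare_floor=0.03))
    reference_haplotype: str = "C-G-C"
    association_phenotypes: list[str] = ["dose", "cl_f", "cl_per_lbw", "auc_star", "auc_0_4_norm", "cmax_per_dose"]
    association_covariates: list[str] = ["sex"]
    combined_phenotypes: list[str] = PK_ANALYSIS_PARAMS
    auc_band: tuple[float, float] = (120.0, 200.0)
    trough_window: tuple[float, float] = (4.0, 9.0)
    seed: int = 0

    def em_config(self) -> EmConfig:
        return EmConfig(**self.em)


@dataclass
class AnalysisReport:
    subjects: pd.DataFrame  # merged per-subject table (composite + PK + flags)
    table1: pd.DataFrame
    composite_by_race: pd.DataFrame
    table2: pd.DataFrame
    hwe: pd.DataFrame
    ld: pd.DataFrame
    haplotype_frequencies: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    exposure_flags: pd.DataFrame
    exposure_proportions: pd.DataFrame
    figure_data: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)


def flag_subtherapeutic_exposure(
    pk_table: pd.DataFrame, band: tuple[float, float] = (120.0, 200.0)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag subjects with AUC0-12 strictly below the therapeutic band floor.

    Returns (per-subject flags, proportions by race and overall).  The band
    is (low, high] — an AUC exactly at the floor is in range.
    """
    low, _ = band
    flags = pk_table[["subject_id", "auc_0_12"]].copy()
    flags["below_band"] = flags["auc_0_12"] < low
    overall = pd.DataFrame(
        {"mean": [flags["below_band"].mean()],
         "sum": [int(flags["below_band"].sum())],
         "count": [len(flags)]},
        index=["overall"],
    )
    if "race" in pk_table.columns:
        flags["race"] = pk_table["race"]
        by_race = flags.groupby("race", dropna=False)["below_band"].agg(["mean", "sum", "count"])
        props = pd.concat([by_race, overall])
    else:
        props = overall
    props.index.name = "stratum"
    return flags, props


def _group_summary_table(
    df: pd.DataFrame, params: list[str], group_col: str = "composite_class"
) -> pd.DataFrame:
    """Mean/SD/N per ordered group with JT trend p and Holm pairwise p."""
    present = [c for c in COMPOSITE_ORDER if (df[group_col] == c).any()]
    rows = []
    for param in params:
        sub = df[[group_col, param]].dropna()
        row: dict = {"parameter": param}
        groups = {}
        for cls in COMPOSITE_ORDER:
            vals = sub.loc[sub[group_col] == cls, param].to_numpy(float)
            row[f"{cls}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{cls}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"{cls}_n"] = vals.size
            if vals.size:
                groups[cls] = vals
        if len(groups) >= 2:
            ordered = [groups[c] for c in COMPOSITE_ORDER if c in groups]
            row["jt_trend_p"] = jonckheere_terpstra(ordered, method="asymptotic").p_two_sided
            for pr in pairwise_wilcoxon_holm(groups):
                a, b = pr.group_pair
                row[f"holm_p_{a}_vs_{b}"] = pr.holm_adjusted_p
        else:
            row["jt_trend_p"] = NOT_APPLICABLE
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(
    records: list[GenotypeRecord],
    profiles,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Execute the whole analysis chain on a cohort."""
    config = config or AnalysisConfig()
    exclusions: list[str] = []

    # --- composite phenotyping -------------------------------------------
    classified = classify_cohort(records)
    if classified.empty:
        raise ValueError("empty cohort: no classifiable subjects")
    n_excluded = len(records) - len(classified)
    if n_excluded:
        ids = {r.subject_id for r in records} - set(classified["subject_id"])
        exclusions += [f"incomplete CYP3A5 genotype: {sid}" for sid in sorted(ids)]
    comp_by_race = composite_frequency_table(classified)

    # --- demographics ----------------------------------------------------
    demo_rows = []
    rec_by_id = {r.subject_id: r for r in records}
    for sid in classified["subject_id"]:
        r = rec_by_id[sid]
        egfr = (
            egfr_mdrd(r.serum_creatinine, r.age, r.sex, r.race)
            if all(v is not None for v in (r.serum_creatinine, r.age, r.sex, r.race))
            else np.nan
        )
        bmi = r.tbw / r.height**2 if (r.tbw and r.height) else np.nan
        demo_rows.append(
            {"subject_id": sid, "age": r.age, "bmi": bmi,
             "scr": r.serum_creatinine, "egfr_mdrd": egfr}
        )
    demo = classified.merge(pd.DataFrame(demo_rows), on="subject_id")
    table1 = _group_summary_table(demo, ["age", "bmi", "scr", "egfr_mdrd"])

    # --- population genetics ---------------------------------------------
    em_cfg = config.em_config()
    hwe_rows, freq_frames = [], []
    strata = sorted({r.race for r in records if r.race}) or ["pooled"]
    for locus_id in ABCB1_RSIDS:
        locus = DEFAULT_LOCUS_MAP[locus_id]
        for stratum in strata:
            recs = [r for r in records if (r.race or "pooled") == stratum]
            counts = genotype_counts(recs, locus)
            if sum(counts) == 0:
                continue
            res = hwe_exact_test(counts, locus_id, stratum)
            hwe_rows.append(
                {"locus": locus_id, "stratum": stratum,
                 "hom_wt": counts[0], "het": counts[1], "hom_var": counts[2],
                 "p_value": res.p_value}
            )
    hwe = pd.DataFrame(hwe_rows)

    hap_table = em_haplotype_frequencies(records, ABCB1_LOCI, em_cfg)
    ld_rows = []
    for pair in (("rs1128503", "rs2032582"), ("rs2032582", "rs1045642"), ("rs1128503", "rs1045642")):
        ld = pairwise_ld(hap_table, pair)
        ld_rows.append({"locus_a": pair[0], "locus_b": pair[1],
                        "D": ld.D, "D_prime": ld.D_prime, "r_squared": ld.r_squared})
    ld_df = pd.DataFrame(ld_rows)

    freq_frames.append(hap_table.to_frame().assign(stratum="pooled"))
    for stratum in strata:
        recs = [r for r in records if (r.race or "pooled") == stratum]
        if recs:
            try:
                ht = em_haplotype_frequencies(recs, ABCB1_LOCI, em_cfg)
                freq_frames.append(ht.to_frame().assign(stratum=stratum))
            except ValueError as exc:
                logger.warning("haplotype EM skipped for %s: %s", stratum, exc)
    hap_freqs = pd.concat(freq_frames, ignore_index=True)

    # --- non-compartmental PK --------------------------------------------
    pk = derive_pk_table(profiles)
    subjects = classified.merge(pk, on="subject_id", how="inner")
    dropped = set(classified["subject_id"]) - set(subjects["subject_id"])
    exclusions += [f"no concentration profile: {sid}" for sid in sorted(dropped)]

    # 3435 carrier status from the genotype call
    locus3435 = DEFAULT_LOCUS_MAP["rs1045642"]
    carrier = {}
    for r in records:
        call = r.call("rs1045642")
        if not call.missing:
            carrier[r.subject_id] = "CC" if call.n_variant(locus3435) == 0 else "T-carrier"
    subjects["abcb1_3435_carrier"] = subjects["subject_id"].map(carrier)

    table2 = _group_summary_table(subjects, [p for p in PK_ANALYSIS_PARAMS if p in subjects])

    # --- haplotype-phenotype association ----------------------------------
    assoc_frames = []
    ordered_recs = [rec_by_id[sid] for sid in subjects["subject_id"]]
    covariates = None
    if config.association_covariates:
        cov_cols = {}
        if "sex" in config.association_covariates:
            cov_cols["sex"] = (subjects["sex"] == "Female").astype(float)
        if "race" in config.association_covariates:
            cov_cols["race"] = (subjects["race"] == "Black").astype(float)
        covariates = pd.DataFrame(cov_cols).reset_index(drop=True)
    for pheno in config.association_phenotypes:
        if pheno not in subjects:
            continue
        try:
            res = haplotype_phenotype_association(
                ordered_recs,
                subjects[pheno].to_numpy(float),
                ABCB1_LOCI,
                covariates=covariates,
                reference_haplotype=config.reference_haplotype,
                config=em_cfg,
                phenotype_name=pheno,
            )
        except ValueError as exc:
            logger.warning("association skipped for %s: %s", pheno, exc)
            continue
        assoc_frames.append(res.table.assign(phenotype=pheno))
    table3 = (
        pd.concat(assoc_frames, ignore_index=True)
        if assoc_frames
        else pd.DataFrame()
    )

    # --- combined two-factor ----------------------------------------------
    tf_input = subjects.dropna(subset=["abcb1_3435_carrier"])
    table4_rows = []
    if tf_input["abcb1_3435_carrier"].nunique() >= 1 and not tf_input.empty:
        results = combined_two_factor(
            tf_input, [p for p in config.combined_phenotypes if p in tf_input]
        )
        for res in results:
            row: dict = {"parameter": res.phenotype_name,
                         "p_abcb1_3435": res.p_abcb1, "p_composite": res.p_composite}
            for comp in res.cell_means.index:
                for carr in res.cell_means.columns:
                    key = f"{comp}_{carr}"
                    row[f"mean_{key}"] = res.cell_means.loc[comp, carr]
                    row[f"se_model_{key}"] = res.cell_se_model.loc[comp, carr]
                    row[f"se_sample_{key}"] = res.cell_se_sample.loc[comp, carr]
                    row[f"n_{key}"] = res.cell_n.loc[comp, carr]
            table4_rows.append(row)
    table4 = pd.DataFrame(table4_rows)

    # --- exposure flags and figure data ------------------------------------
    flags, props = flag_subtherapeutic_exposure(
        subjects, band=config.auc_band
    )
    figure_data = {
        "clearance_by_group": subjects[["subject_id", "composite_class", "race", "cl_f"]],
        "auc_star_by_group": subjects[["subject_id", "composite_class", "race", "auc_star"]],
        "troughs": subjects[["subject_id", "composite_class", "race", "c12"]].assign(
            window_low=config.trough_window[0], window_high=config.trough_window[1]
        ),
        "auc_0_12": subjects[["subject_id", "composite_class", "race", "auc_0_12"]].assign(
            band_low=config.auc_band[0], band_high=config.auc_band[1]
        ),
    }

    for msg in exclusions:
        logger.info("exclusion: %s", msg)

    return AnalysisReport(
        subjects=subjects,
        table1=table1,
        composite_by_race=comp_by_race,
        table2=table2,
        hwe=hwe,
        ld=ld_df,
        haplotype_frequencies=hap_freqs,
        table3=table3,
        table4=table4,
        exposure_flags=flags,
        exposure_proportions=props,
        figure_data=figure_data,
        config=json.loads(config.model_dump_json()),
        exclusions=exclusions,
    )


def write_report(report: AnalysisReport, out_dir) -> None:
    """Write every report table as CSV plus a JSON summary (UTF-8, comma
    separated, '.' decimal, header row)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "subjects": report.subjects,
        "table1_demographics": report.table1,
        "composite_by_race": report.composite_by_race,
        "table2_pk_by_composite": report.table2,
        "hwe": report.hwe,
        "ld": report.ld,
        "haplotype_frequencies": report.haplotype_frequencies,
        "table3_haplotype_association": report.table3,
        "table4_combined": report.table4,
        "exposure_flags": report.exposure_flags,
        "exposure_proportions": report.exposure_proportions,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=name in ("composite_by_race", "exposure_proportions"))
    for name, df in report.figure_data.items():
        df.to_csv(out / f"figure_{name}.csv", index=False)
    summary = {
        "n_subjects": int(len(report.subjects)),
        "exclusions": report.exclusions,
        "effective_config": report.config,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
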