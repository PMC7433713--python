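"""Readers and writers for cohort genotype and concentration data.

Genotypes travel either as a subject x locus CSV (columns ``subject_id``,
the six rsIDs with two-character genotype strings such as ``CT`` — the *7
insertion uses ``-``/``T`` symbols — plus ``race, sex, age, tbw_kg,
height_m, scr_mg_dl``) or as a VCF with one sample column per subject, loci
matched by rsID in the ID field, unphased GT.  Concentration profiles are a
long-format CSV (``subject_id, time_h, conc_ng_ml``) joined to a covariate
CSV carrying the dose and body measures.

VCF genotype indices map positionally onto the locus allele order
(0 = wild-type, k = k-th variant); the built-in locus map can be overridden
when a source VCF uses the opposite REF/ALT orientation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .loci import ALL_LOCI, DEFAULT_LOCUS_MAP, GenotypeRecord, Locus, LocusCall
from .nca import ConcentrationProfile, lean_body_weight

__all__ = [
    "read_genotype_csv",
    "write_genotype_csv",
    "read_genotype_vcf",
    "write_genotype_vcf",
    "read_concentration_csv",
    "write_concentration_csv",
    "profiles_from_frames",
]

logger = logging.getLogger(__name__)

GENOTYPE_COLUMNS = [
    "subject_id",
    *(l.rsid for l in ALL_LOCI),
    "race",
    "sex",
    "age",
    "tbw_kg",
    "height_m",
    "scr_mg_dl",
]

# Nominal GRCh38 coordinates on chromosome 7, used only to emit valid VCF
# records; loci are matched by rsID, never by position.
_VCF_SITES: dict[str, tuple[int, str, tuple[str, ...]]] = {
    "rs776746": (99672916, "T", ("C",)),
    "rs10264272": (99665237, "C", ("T",)),
    "rs41303343": (99652770, "A", ("AT",)),  # *7 insertion
    "rs1128503": (87550285, "C", ("T",)),
    "rs2032582": (87531302, "G", ("T", "A")),
    "rs1045642": (87509329, "C", ("T",)),
}


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_genotype_csv(path, locus_map: Mapping[str, Locus] | None = None) -> list[GenotypeRecord]:
    locus_map = dict(locus_map or DEFAULT_LOCUS_MAP)
    df = pd.read_csv(path, dtype={"subject_id": str})
    records = []
    for _, row in df.iterrows():
        calls = {
            rsid: LocusCall.from_string(rsid, row.get(rsid))
            for rsid in locus_map
        }
        records.append(
            GenotypeRecord(
                subject_id=row["subject_id"],
                calls=calls,
                race=row.get("race"),
                sex=row.get("sex"),
                age=_opt_float(row.get("age")),
                tbw=_opt_float(row.get("tbw_kg")),
                height=_opt_float(row.get("height_m")),
                serum_creatinine=_opt_float(row.get("scr_mg_dl")),
            )
        )
    return records


def write_genotype_csv(records: Iterable[GenotypeRecord], path) -> None:
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id}
        for rsid in DEFAULT_LOCUS_MAP:
            call = rec.call(rsid)
            row[rsid] = "" if call.missing else "".join(call.allele_pair)
        row.update(
            race=rec.race, sex=rec.sex, age=rec.age, tbw_kg=rec.tbw,
            height_m=rec.height, scr_mg_dl=rec.serum_creatinine,
        )
        rows.append(row)
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, index=False)


def write_genotype_vcf(records: Iterable[GenotypeRecord], path) -> None:
    """Emit the six loci as an uncompressed VCF, one sample per subject."""
    records = list(records)
    header = pysam.VariantHeader()
    header.add_line("##source=tacpgx")
    header.contigs.add("7", length=159_345_973)
    header.formats.add("GT", 1, "String", "Genotype")
    for rec in records:
        header.add_sample(rec.subject_id)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus in ALL_LOCI:
            pos, ref, alts = _VCF_SITES[locus.rsid]
            site = vcf.new_record(
                contig="7", start=pos - 1, stop=pos - 1 + len(ref),
                id=locus.rsid, alleles=(ref, *alts),
            )
            symbol_to_index = {locus.wild_type: 0}
            for k, v in enumerate(locus.variants, start=1):
                symbol_to_index[v] = k
            for rec in records:
                call = rec.call(locus.rsid)
                if call.missing:
                    site.samples[rec.subject_id]["GT"] = (None, None)
                else:
                    site.samples[rec.subject_id]["GT"] = tuple(
                        symbol_to_index[a] for a in call.allele_pair
                    )
                site.samples[rec.subject_id].phased = False
            vcf.write(site)


def read_genotype_vcf(
    path,
    covariates: pd.DataFrame | None = None,
    locus_map: Mapping[str, Locus] | None = None,
) -> list[GenotypeRecord]:
    """Read unphased genotypes from a VCF, matching loci by rsID.

    ``covariates`` (indexed or keyed by ``subject_id``) supplies
    demographics; genotype-only records are returned otherwise.
    """
    locus_map = dict(locus_map or DEFAULT_LOCUS_MAP)
    calls_by_subject: dict[str, dict[str, LocusCall]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            calls_by_subject[s] = {}
        for site in vcf:
            if site.id not in locus_map:
                logger.info("skipping unrecognized site %s", site.id)
                continue
            locus = locus_map[site.id]
            index_to_symbol = {0: locus.wild_type}
            for k, v in enumerate(locus.variants, start=1):
                index_to_symbol[k] = v
            for s in samples:
                gt = site.samples[s].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    calls_by_subject[s][site.id] = LocusCall(site.id, None, missing=True)
                else:
                    calls_by_subject[s][site.id] = LocusCall(
                        site.id, tuple(index_to_symbol[a] for a in gt)
                    )

    cov = None
    if covariates is not None:
        cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates

    records = []
    for s in samples:
        kw = {}
        if cov is not None and s in cov.index:
            row = cov.loc[s]
            kw = dict(
                race=row.get("race"), sex=row.get("sex"),
                age=_opt_float(row.get("age")), tbw=_opt_float(row.get("tbw_kg")),
                height=_opt_float(row.get("height_m")),
                serum_creatinine=_opt_float(row.get("scr_mg_dl")),
            )
        records.append(GenotypeRecord(subject_id=s, calls=calls_by_subject[s], **kw))
    return records


def write_concentration_csv(profiles: Iterable[ConcentrationProfile], path, dose_path=None) -> None:
    """Long-format concentration CSV; per-subject dose/covariate CSV optionally."""
    long_rows, dose_rows = [], []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            long_rows.append({"subject_id": p.subject_id, "time_h": t, "conc_ng_ml": c})
        dose_rows.append(
            {"subject_id": p.subject_id, "dose_mg": p.dose, "tbw_kg": p.tbw,
             "lbw_kg": p.lbw, "tau_h": p.tau}
        )
    pd.DataFrame(long_rows).to_csv(path, index=False)
    if dose_path is not None:
        pd.DataFrame(dose_rows).to_csv(dose_path, index=False)


def read_concentration_csv(conc_path, covariates: pd.DataFrame) -> list[ConcentrationProfile]:
    """Assemble profiles from a long-format CSV plus a covariate table.

    ``covariates`` must provide ``subject_id`` and ``dose_mg``; ``tbw_kg``
    and either ``lbw_kg`` or (``sex``, ``height_m``) enable the body-size
    normalizations.
    """
    long_df = pd.read_csv(conc_path, dtype={"subject_id": str})
    cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
    return profiles_from_frames(long_df, cov)


def profiles_from_frames(long_df: pd.DataFrame, cov: pd.DataFrame) -> list[ConcentrationProfile]:
    profiles = []
    for sid, grp in long_df.groupby("subject_id", sort=True):
        if sid not in cov.index:
            raise KeyError(f"no covariate row for subject {sid}")
        row = cov.loc[sid]
        grp = grp.sort_values("time_h")
        tbw = _opt_float(row.get("tbw_kg"))
        lbw = _opt_float(row.get("lbw_kg"))
        if lbw is None and row.get("sex") and _opt_float(row.get("height_m")) and tbw:
            lbw = lean_body_weight(row["sex"], tbw, float(row["height_m"]))
        profiles.append(
            ConcentrationProfile(
                subject_id=str(sid),
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["conc_ng_ml"].to_numpy(float),
                dose=float(row["dose_mg"]),
                tbw=tbw,
                lbw=lbw,
                tau=float(row.get("tau_h", 12.0) or 12.0),
            )
        )
    return profiles
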