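"""CYP3A5*3*6*7 metabolic-composite phenotyping.

Each of the three variants (*3, *6, *7) independently abolishes CYP3A5
protein expression, so enzyme status depends on the joint allelic state of
all three loci, not any single SNP:

* **Poor** metabolizer — homozygous variant at >=1 locus: both chromosomes
  certainly carry a loss-of-function allele, whatever the other loci show.
* **Extensive** metabolizer — homozygous wild-type at all three loci: two
  fully functional genes.
* **Intermediate** — heterozygous at exactly one locus.  Subjects
  heterozygous at two or more loci (and homozygous-variant at none) are
  phase-ambiguous: the variants may sit on one chromosome (one functional
  gene, intermediate) or on both (poor).  They are conservatively labelled
  Intermediate and flagged ``phase_ambiguous``.

The three classes are ordered Poor < Intermediate < Extensive and this
ordering drives the trend tests downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .loci import CYP3A5_LOCI, CYP3A5_RSIDS, GenotypeRecord, Locus, LocusCall

__all__ = [
    "COMPOSITE_ORDER",
    "MetabolicComposite",
    "classify_metabolic_composite",
    "classify_cohort",
    "composite_frequency_table",
]

logger = logging.getLogger(__name__)

#: Ordered phenotype classes, worst metabolic capacity first.
COMPOSITE_ORDER: tuple[str, ...] = ("Poor", "Intermediate", "Extensive")

_ZYGOSITY = {0: "hom_wt", 1: "het", 2: "hom_var"}


@dataclass(frozen=True)
class MetabolicComposite:
    """A composite class with the per-locus zygosities that justify it."""

    class_label: str
    basis: tuple[tuple[str, str], ...]  # (rsid, zygosity)
    phase_ambiguous: bool = False

    @property
    def rank(self) -> int:
        return COMPOSITE_ORDER.index(self.class_label)


def classify_metabolic_composite(
    calls: Mapping[str, LocusCall],
    loci: Iterable[Locus] = CYP3A5_LOCI,
) -> MetabolicComposite:
    """Classify one subject from the three CYP3A5 locus calls.

    Raises ``ValueError`` naming the locus when a call is missing or an
    allele falls outside the declared set.
    """
    dosages: dict[str, int] = {}
    for locus in loci:
        call = calls.get(locus.rsid)
        if call is None or call.missing:
            raise ValueError(f"incomplete genotype: no call at {locus.rsid}")
        call.validate_alleles(locus)
        dosages[locus.rsid] = call.n_variant(locus)

    basis = tuple((rsid, _ZYGOSITY[d]) for rsid, d in dosages.items())
    n_hom_var = sum(d == 2 for d in dosages.values())
    n_het = sum(d == 1 for d in dosages.values())

    if n_hom_var >= 1:
        # Loss on both chromosomes is certain irrespective of other loci.
        return MetabolicComposite("Poor", basis)
    if n_het == 0:
        return MetabolicComposite("Extensive", basis)
    # Heterozygous at >=1 locus, homozygous-variant at none.  With hets at
    # two or more loci the chromosomal arrangement is unobserved, so the
    # subject could be Poor or Intermediate; assign Intermediate and flag.
    return MetabolicComposite("Intermediate", basis, phase_ambiguous=n_het >= 2)


def classify_cohort(
    records: Iterable[GenotypeRecord],
    loci: Iterable[Locus] = CYP3A5_LOCI,
) -> pd.DataFrame:
    """Classify every record; subjects with incomplete CYP3A5 calls are
    excluded (never imputed) and logged.

    Returns a DataFrame with columns subject_id, composite_class (ordered
    categorical), phase_ambiguous, plus race/sex carried through.
    """
    loci = tuple(loci)
    rows = []
    for rec in records:
        try:
            comp = classify_metabolic_composite(rec.calls, loci)
        except ValueError as exc:
            logger.warning("excluding subject %s: %s", rec.subject_id, exc)
            continue
        rows.append(
            {
                "subject_id": rec.subject_id,
                "composite_class": comp.class_label,
                "phase_ambiguous": comp.phase_ambiguous,
                "race": rec.race,
                "sex": rec.sex,
            }
        )
    out = pd.DataFrame(rows, columns=["subject_id", "composite_class", "phase_ambiguous", "race", "sex"])
    out["composite_class"] = pd.Categorical(
        out["composite_class"], categories=list(COMPOSITE_ORDER), ordered=True
    )
    return out


def composite_frequency_table(
    records: Iterable[GenotypeRecord] | pd.DataFrame,
    by: str = "race",
) -> pd.DataFrame:
    """Contingency table of composite class x stratum with counts and
    column percentages (percent of each stratum in each class).

    Accepts either raw records (classified on the fly) or the output of
    :func:`classify_cohort`.
    """
    if isinstance(records, pd.DataFrame):
        classified = records
    else:
        classified = classify_cohort(records)
    if classified.empty:
        raise ValueError("empty cohort: no classifiable subjects")

    counts = pd.crosstab(classified["composite_class"], classified[by], dropna=False)
    counts = counts.reindex(list(COMPOSITE_ORDER), fill_value=0)
    col_pct = counts.div(counts.sum(axis=0).replace(0, pd.NA), axis=1) * 100.0
    row_pct = counts.div(counts.sum(axis=1).replace(0, pd.NA), axis=0) * 100.0

    out = counts.copy().astype(float)
    pieces = []
    for name, frame in (("count", counts), ("col_pct", col_pct), ("row_pct", row_pct)):
        f = frame.copy()
        f.columns = pd.MultiIndex.from_product([[name], f.columns])
        pieces.append(f)
    out = pd.concat(pieces, axis=1)
    out.index.name = "composite_class"
    return out
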