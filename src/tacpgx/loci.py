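"""Locus definitions and genotype containers.

Six single-nucleotide loci drive the analysis: three CYP3A5 loss-of-function
sites (*3 rs776746, *6 rs10264272, *7 rs41303343) and the three ABCB1
transporter sites (1236C>T rs1128503, 2677G>T/A rs2032582, 3435C>T
rs1045642).  Genotypes are unphased: a call is an unordered allele pair.

Wild-type/variant orientation is fixed by a built-in allele map and can be
overridden, since REF/ALT orientation in VCFs varies by genome build and
assay strand.  The *7 allele is an insertion; it is represented by the
single-character symbols '-' (no insertion, functional) and 'T' (inserted,
loss of function).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "Locus",
    "LocusCall",
    "GenotypeRecord",
    "CYP3A5_LOCI",
    "ABCB1_LOCI",
    "ALL_LOCI",
    "DEFAULT_LOCUS_MAP",
    "make_locus_map",
]


@dataclass(frozen=True)
class Locus:
    """A genotyped site with a declared allele set and wild-type orientation."""

    rsid: str
    gene: str
    label: str  # human-readable, e.g. "CYP3A5*3" or "ABCB1 3435C>T"
    wild_type: str
    variants: tuple[str, ...]  # one entry for bi-allelic, two for 2677

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.wild_type,) + self.variants


# Default orientation: the variant allele is the loss-of-function (CYP3A5)
# or the non-wild-type transporter allele (ABCB1).
CYP3A5_LOCI: tuple[Locus, ...] = (
    Locus("rs776746", "CYP3A5", "CYP3A5*3", wild_type="T", variants=("C",)),
    Locus("rs10264272", "CYP3A5", "CYP3A5*6", wild_type="C", variants=("T",)),
    Locus("rs41303343", "CYP3A5", "CYP3A5*7", wild_type="-", variants=("T",)),
)

ABCB1_LOCI: tuple[Locus, ...] = (
    Locus("rs1128503", "ABCB1", "ABCB1 1236C>T", wild_type="C", variants=("T",)),
    Locus("rs2032582", "ABCB1", "ABCB1 2677G>T/A", wild_type="G", variants=("T", "A")),
    Locus("rs1045642", "ABCB1", "ABCB1 3435C>T", wild_type="C", variants=("T",)),
)

ALL_LOCI: tuple[Locus, ...] = CYP3A5_LOCI + ABCB1_LOCI

DEFAULT_LOCUS_MAP: dict[str, Locus] = {loc.rsid: loc for loc in ALL_LOCI}

CYP3A5_RSIDS: tuple[str, ...] = tuple(loc.rsid for loc in CYP3A5_LOCI)
ABCB1_RSIDS: tuple[str, ...] = tuple(loc.rsid for loc in ABCB1_LOCI)


def make_locus_map(overrides: Mapping[str, Mapping[str, object]] | None = None) -> dict[str, Locus]:
    """Return the locus registry, optionally re-orienting alleles.

    ``overrides`` maps rsID to a dict with any of ``wild_type`` /
    ``variants``; everything else is inherited from the defaults.
    """
    loci = dict(DEFAULT_LOCUS_MAP)
    for rsid, fields in (overrides or {}).items():
        if rsid not in loci:
            raise KeyError(f"unknown locus {rsid!r}")
        kwargs = dict(fields)
        if "variants" in kwargs:
            kwargs["variants"] = tuple(kwargs["variants"])
        loci[rsid] = replace(loci[rsid], **kwargs)
    return loci


@dataclass(frozen=True)
class LocusCall:
    """An unphased genotype call at one locus.

    ``allele_pair`` is stored sorted so that equal genotypes compare equal
    regardless of input order; phase is never implied.
    """

    locus_id: str
    allele_pair: tuple[str, str] | None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing != (self.allele_pair is None):
            raise ValueError(
                f"{self.locus_id}: missing flag must match absence of alleles"
            )
        if self.allele_pair is not None:
            object.__setattr__(
                self, "allele_pair", tuple(sorted(self.allele_pair))
            )

    @classmethod
    def from_string(cls, locus_id: str, genotype: str | None) -> "LocusCall":
        """Parse a two-character genotype string such as ``"CT"`` or ``"-T"``.

        Empty strings, ``"NA"``, ``"."``, ``"./."`` and None denote missing.
        A separator ('/' or '|') between single-character alleles is allowed.
        """
        if genotype is None:
            return cls(locus_id, None, missing=True)
        g = str(genotype).strip()
        if g in ("", "NA", "nan", ".", "./.", ".|."):
            return cls(locus_id, None, missing=True)
        for sep in ("/", "|"):
            if sep in g:
                a, b = g.split(sep)
                return cls(locus_id, (a, b))
        if len(g) != 2:
            raise ValueError(f"{locus_id}: cannot parse genotype {genotype!r}")
        return cls(locus_id, (g[0], g[1]))

    def validate_alleles(self, locus: Locus) -> None:
        if self.missing:
            return
        for a in self.allele_pair:  # type: ignore[union-attr]
            if a not in locus.alleles:
                raise ValueError(
                    f"unknown allele {a!r} at {locus.rsid} "
                    f"(declared: {'/'.join(locus.alleles)})"
                )

    def n_variant(self, locus: Locus) -> int:
        """Variant-allele dosage (0, 1 or 2) under the locus orientation."""
        if self.missing:
            raise ValueError(f"incomplete genotype: {self.locus_id} is missing")
        return sum(a != locus.wild_type for a in self.allele_pair)  # type: ignore[union-attr]


@dataclass
class GenotypeRecord:
    """Per-subject unphased calls at the six loci plus demographics."""

    subject_id: str
    calls: dict[str, LocusCall]
    race: str | None = None  # "Black" | "White"
    sex: str | None = None  # "Male" | "Female"
    age: float | None = None  # years
    tbw: float | None = None  # kg
    height: float | None = None  # m
    serum_creatinine: float | None = None  # mg/dl
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rsid in DEFAULT_LOCUS_MAP:
            if rsid not in self.calls:
                self.calls[rsid] = LocusCall(rsid, None, missing=True)
        for name in ("age", "tbw", "height", "serum_creatinine"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{self.subject_id}: {name} must be positive, got {v}")

    def call(self, rsid: str) -> LocusCall:
        return self.calls[rsid]

    def has_complete(self, rsids) -> bool:
        return all(not self.calls[r].missing for r in rsids)
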