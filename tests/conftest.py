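import numpy as np
import pytest

from tacpgx.loci import ALL_LOCI, DEFAULT_LOCUS_MAP, GenotypeRecord, LocusCall


def make_record(subject_id="S1", genotypes=None, **demo):
    """Build a GenotypeRecord from {rsid: 'CT'}-style genotype strings;
    loci not mentioned are missing."""
    calls = {}
    for rsid in DEFAULT_LOCUS_MAP:
        g = (genotypes or {}).get(rsid)
        calls[rsid] = LocusCall.from_string(rsid, g)
    return GenotypeRecord(subject_id=subject_id, calls=calls, **demo)


def cyp_genotypes(d3, d6, d7):
    """CYP3A5 genotype strings from variant dosages (0/1/2) at *3,*6,*7."""
    out = {}
    for rsid, dose in (("rs776746", d3), ("rs10264272", d6), ("rs41303343", d7)):
        locus = DEFAULT_LOCUS_MAP[rsid]
        wt, var = locus.wild_type, locus.variants[0]
        out[rsid] = {0: wt + wt, 1: wt + var, 2: var + var}[dose]
    return out


def abcb1_record(subject_id, hap1, hap2, **demo):
    """Record with ABCB1 calls from two phased haplotypes like 'C-G-C'."""
    a1, a2 = hap1.split("-"), hap2.split("-")
    gts = {
        rsid: x + y
        for rsid, x, y in zip(("rs1128503", "rs2032582", "rs1045642"), a1, a2)
    }
    return make_record(subject_id, gts, **demo)


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)
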