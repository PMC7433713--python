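"""Population-genetic engine for the three ABCB1 loci.

Genotypes are unphased, so the haplotype pair a subject carries (the
diplotype) is latent whenever they are heterozygous at more than one locus.
This module provides:

* an exact conditional Hardy-Weinberg test per locus (stratified by race);
* pairwise linkage disequilibrium (D, D', r^2) computed from an estimated
  haplotype table on major-allele coding;
* enumeration of the diplotypes compatible with an unphased genotype;
* EM maximum-likelihood estimation of haplotype frequencies under
  Hardy-Weinberg random pairing (the Excoffier-Slatkin scheme);
* a joint maximum-likelihood haplotype-phenotype association model in the
  THESIAS style: a normal phenotype whose mean is additive in haplotype
  copy number plus covariates, with phase marginalized over compatible
  diplotypes and haplotype frequencies estimated simultaneously.

The 2677 site is tri-allelic (G>T/A).  Diplotype enumeration and the EM
operate on the full three-allele set; LD and HWE collapse T and A into a
single non-G class, since the A allele is rare and haplotype labels
(TTT/CGC) are bi-allelic per locus.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .loci import ABCB1_LOCI, ABCB1_RSIDS, GenotypeRecord, Locus

__all__ = [
    "HweResult",
    "LdResult",
    "HaplotypeTable",
    "DiplotypeExpansion",
    "AssociationResult",
    "EmConfig",
    "hwe_exact_test",
    "genotype_counts",
    "pairwise_ld",
    "enumerate_diplotypes",
    "em_haplotype_frequencies",
    "haplotype_phenotype_association",
]

logger = logging.getLogger(__name__)

Haplotype = tuple[str, ...]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HweResult:
    locus_id: str
    stratum: str
    genotype_counts: tuple[int, int, int]  # (hom_major, het, hom_minor)
    p_value: float


def _hwe_log_prob(n_het: int, n_rare: int, n_dip: int) -> float:
    """log P(n_het heterozygotes | n_rare rare alleles, n_dip diploids)
    under the conditional (allele-count-fixed) Hardy-Weinberg null."""
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n_dip - n_het - n_hom_rare
    n_common = 2 * n_dip - n_rare
    return (
        gammaln(n_dip + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_common + 1)
        + n_het * np.log(2.0)
        - (gammaln(2 * n_dip + 1) - gammaln(n_rare + 1) - gammaln(n_common + 1))
    )


def hwe_exact_test(
    counts, locus_id: str = "", stratum: str = "pooled"
) -> HweResult:
    """Exact conditional Hardy-Weinberg test for a bi-allelic locus.

    ``counts`` is ``(hom_A, het, hom_a)``.  The p-value is the total
    probability of heterozygote counts as or less probable than the one
    observed, conditional on the allele counts (Levene/Haldane
    conditional distribution; two-sided by construction).
    """
    hom_a, het, hom_b = (int(c) for c in counts)
    if min(hom_a, het, hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_dip = hom_a + het + hom_b
    if n_dip == 0:
        raise ValueError(f"empty locus: no genotypes at {locus_id or '?'}")

    n_a = 2 * hom_a + het
    n_b = 2 * hom_b + het
    n_rare = min(n_a, n_b)
    if n_rare == 0:  # monomorphic: cannot deviate
        return HweResult(locus_id, stratum, (hom_a, het, hom_b), 1.0)

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n_dip - n_rare) + 1, 2)
    logp = np.array([_hwe_log_prob(h, n_rare, n_dip) for h in hets])
    probs = np.exp(logp - logsumexp(logp))  # normalize away rounding
    p_obs = probs[hets == het][0]
    p_value = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return HweResult(locus_id, stratum, (hom_a, het, hom_b), min(p_value, 1.0))


def genotype_counts(
    records, locus: Locus, collapse_non_wt: bool = True
) -> tuple[int, int, int]:
    """(hom_wt, het, hom_var) at a locus, skipping missing calls.

    With ``collapse_non_wt`` every non-wild-type allele counts as one
    variant class (the bi-allelic collapse used for HWE/LD at 2677).
    """
    hom_wt = het = hom_var = 0
    for rec in records:
        call = rec.call(locus.rsid)
        if call.missing:
            continue
        call.validate_alleles(locus)
        d = call.n_variant(locus)
        if not collapse_non_wt and len(set(call.allele_pair)) == 2 and d == 2:
            d = 1  # two different variant alleles: het on the full allele set
        if d == 0:
            hom_wt += 1
        elif d == 1:
            het += 1
        else:
            hom_var += 1
    return hom_wt, het, hom_var


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LdResult:
    locus_pair: tuple[str, str]
    D: float
    D_prime: float  # NaN when undefined (monomorphic locus)
    r_squared: float  # NaN when undefined


def _collapse_allele(locus: Locus, allele: str) -> str:
    """Bi-allelic collapse: any non-wild-type allele becomes 'non-WT'."""
    return locus.wild_type if allele == locus.wild_type else "non-WT"


def pairwise_ld(hap_table: "HaplotypeTable", locus_pair: tuple[str, str]) -> LdResult:
    """D, D' and r^2 for a pair of loci from the estimated haplotype table.

    Two-locus gamete frequencies are obtained by summing the three-locus
    table; alleles are collapsed to bi-allelic (wild-type vs non-wild-type)
    and the statistic is computed on major-allele coding (the more frequent
    class at each locus plays 'A').  A monomorphic locus gives D = 0 with
    D' and r^2 reported as NaN, not 0/0.
    """
    idx = [hap_table.loci.index(r) for r in locus_pair]
    loci = [hap_table.locus_map[r] for r in locus_pair]

    gamete: dict[tuple[str, str], float] = {}
    for hap, f in zip(hap_table.haplotypes, hap_table.frequencies):
        key = tuple(_collapse_allele(loc, hap[i]) for i, loc in zip(idx, loci))
        gamete[key] = gamete.get(key, 0.0) + f

    # Major allele at each locus
    def marginal(pos: int) -> dict[str, float]:
        m: dict[str, float] = {}
        for key, f in gamete.items():
            m[key[pos]] = m.get(key[pos], 0.0) + f
        return m

    m0, m1 = marginal(0), marginal(1)
    A = max(m0, key=m0.get)
    B = max(m1, key=m1.get)
    pA, pB = m0[A], m1[B]
    pAB = sum(f for k, f in gamete.items() if k == (A, B))

    D = pAB - pA * pB
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA) <= 0 or min(pB, qB) <= 0:
        return LdResult(tuple(locus_pair), 0.0, float("nan"), float("nan"))

    d_max = min(pA * qB, qA * pB) if D >= 0 else min(pA * pB, qA * qB)
    d_prime = abs(D) / d_max if d_max > 0 else float("nan")
    r2 = D**2 / (pA * qA * pB * qB)
    return LdResult(tuple(locus_pair), float(D), float(d_prime), float(r2))


# ---------------------------------------------------------------------------
# Diplotype enumeration
# ---------------------------------------------------------------------------


@dataclass
class DiplotypeExpansion:
    subject_id: str
    pairs: list[tuple[Haplotype, Haplotype]]  # unordered, canonically sorted
    posterior_weights: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _genotype_pattern(record: GenotypeRecord, loci: tuple[Locus, ...]) -> tuple:
    pattern = []
    for locus in loci:
        call = record.call(locus.rsid)
        if call.missing:
            raise ValueError(
                f"incomplete genotype: {record.subject_id} missing {locus.rsid}"
            )
        call.validate_alleles(locus)
        pattern.append(call.allele_pair)
    return tuple(pattern)


def _pairs_for_pattern(pattern: tuple) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with an unphased genotype."""
    per_locus = []
    for a, b in pattern:
        per_locus.append([(a, b)] if a == b else [(a, b), (b, a)])
    seen = set()
    out: list[tuple[Haplotype, Haplotype]] = []
    for combo in itertools.product(*per_locus):
        h1 = tuple(x[0] for x in combo)
        h2 = tuple(x[1] for x in combo)
        key = (h1, h2) if h1 <= h2 else (h2, h1)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def enumerate_diplotypes(
    record: GenotypeRecord, loci: tuple[Locus, ...] = ABCB1_LOCI
) -> DiplotypeExpansion:
    """Haplotype pairs compatible with the subject's unphased calls.

    A subject heterozygous at k loci yields 2^(k-1) unordered pairs (1 when
    k = 0); a tri-allelic heterozygote expands like any other het.
    """
    pattern = _genotype_pattern(record, tuple(loci))
    return DiplotypeExpansion(record.subject_id, _pairs_for_pattern(pattern))


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------


@dataclass
class EmConfig:
    tol: float = 1e-8  # on the log-likelihood
    max_iter: int = 5000
    n_restarts: int = 10
    seed: int = 0
    rare_floor: float = 0.03  # pooling threshold for association effects


@dataclass
class HaplotypeTable:
    loci: tuple[str, ...]  # rsIDs in order
    locus_map: dict[str, Locus]
    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    log_likelihood: float
    n_chromosomes: int
    converged: bool
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": ["-".join(h) for h in self.haplotypes],
                "frequency": self.frequencies,
            }
        ).sort_values("frequency", ascending=False, ignore_index=True)

    def frequency_of(self, hap: Haplotype | str) -> float:
        if isinstance(hap, str):
            hap = tuple(hap.split("-")) if "-" in hap else tuple(hap)
        for h, f in zip(self.haplotypes, self.frequencies):
            if h == tuple(hap):
                return float(f)
        return 0.0


class _EmProblem:
    """Pre-expanded latent structure shared by the EM and the association
    model: unique genotype patterns, their compatible pairs, and index
    arrays for vectorized E-steps."""

    def __init__(self, patterns: list[tuple], counts: np.ndarray):
        self.patterns = patterns
        self.counts = counts  # subjects per pattern
        pair_lists = [_pairs_for_pattern(p) for p in patterns]
        hap_set = sorted({h for pl in pair_lists for pair in pl for h in pair})
        self.haplotypes: list[Haplotype] = hap_set
        hidx = {h: i for i, h in enumerate(hap_set)}
        self.K = len(hap_set)

        rows_h1, rows_h2, rows_pat, rows_mult = [], [], [], []
        for pi, pl in enumerate(pair_lists):
            for h1, h2 in pl:
                rows_h1.append(hidx[h1])
                rows_h2.append(hidx[h2])
                rows_pat.append(pi)
                rows_mult.append(1.0 if h1 == h2 else 2.0)
        self.h1 = np.array(rows_h1, dtype=int)
        self.h2 = np.array(rows_h2, dtype=int)
        self.pat = np.array(rows_pat, dtype=int)
        self.mult = np.array(rows_mult)
        self.n_patterns = len(patterns)

    def pair_priors(self, freqs: np.ndarray) -> np.ndarray:
        return self.mult * freqs[self.h1] * freqs[self.h2]

    def loglik(self, freqs: np.ndarray) -> float:
        pri = self.pair_priors(freqs)
        per_pat = np.zeros(self.n_patterns)
        np.add.at(per_pat, self.pat, pri)
        if np.any(per_pat <= 0):
            return -np.inf
        return float(np.dot(self.counts, np.log(per_pat)))

    def em(self, freqs: np.ndarray, tol: float, max_iter: int):
        """Run EM from a start; returns (freqs, loglik, n_iter, converged)."""
        n_chrom = 2.0 * self.counts.sum()
        ll = self.loglik(freqs)
        for it in range(1, max_iter + 1):
            pri = self.pair_priors(freqs)
            denom = np.zeros(self.n_patterns)
            np.add.at(denom, self.pat, pri)
            w = pri * self.counts[self.pat] / denom[self.pat]
            new = np.zeros(self.K)
            np.add.at(new, self.h1, w)
            np.add.at(new, self.h2, w)
            freqs = new / n_chrom
            new_ll = self.loglik(freqs)
            if abs(new_ll - ll) < tol:
                return freqs, new_ll, it, True
            ll = new_ll
        return freqs, ll, max_iter, False


def _build_problem(records, loci: tuple[Locus, ...]) -> tuple[_EmProblem, int]:
    pattern_counts: dict[tuple, int] = {}
    n_used = 0
    for rec in records:
        try:
            pat = _genotype_pattern(rec, loci)
        except ValueError as exc:
            logger.warning("EM: excluding %s (%s)", rec.subject_id, exc)
            continue
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1
        n_used += 1
    if n_used == 0:
        raise ValueError("empty cohort: no records with complete calls")
    patterns = list(pattern_counts)
    counts = np.array([pattern_counts[p] for p in patterns], dtype=float)
    return _EmProblem(patterns, counts), n_used


def em_haplotype_frequencies(
    records,
    loci: tuple[Locus, ...] = ABCB1_LOCI,
    config: EmConfig | None = None,
) -> HaplotypeTable:
    """ML haplotype frequencies from unphased genotypes by EM.

    E-step: posterior weights over each subject's compatible diplotypes
    under Hardy-Weinberg random pairing at the current frequencies.
    M-step: weighted haplotype counting.  The log-likelihood is
    non-decreasing across iterations; the best of ``n_restarts`` starts is
    returned (one near-uniform start with a small seeded perturbation, the
    rest Dirichlet-random).  Non-convergence returns ``converged=False``
    with a warning, never silently.
    """
    config = config or EmConfig()
    loci = tuple(loci)
    prob, n_used = _build_problem(records, loci)
    rng = np.random.default_rng(config.seed)

    best = None
    for r in range(max(config.n_restarts, 1)):
        if r == 0:
            start = np.ones(prob.K) + 0.01 * rng.random(prob.K)
        else:
            start = rng.dirichlet(np.ones(prob.K)) + 1e-6
        start = start / start.sum()
        freqs, ll, n_iter, conv = prob.em(start, config.tol, config.max_iter)
        if best is None or ll > best[1]:
            best = (freqs, ll, n_iter, conv)

    freqs, ll, n_iter, conv = best
    if not conv:
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations "
            f"(final log-likelihood {ll:.6f})"
        )
    return HaplotypeTable(
        loci=tuple(l.rsid for l in loci),
        locus_map={l.rsid: l for l in loci},
        haplotypes=prob.haplotypes,
        frequencies=freqs,
        log_likelihood=ll,
        n_chromosomes=2 * n_used,
        converged=conv,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Joint haplotype-phenotype association (THESIAS-style)
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    phenotype_name: str
    reference_haplotype: Haplotype
    table: pd.DataFrame  # haplotype, frequency, phenotypic_mean, ci_low, ci_high, p_value
    covariates_adjusted: list[str]
    model_log_likelihood: float
    sigma: float
    converged: bool


class _AssocModel:
    """Observed-data likelihood machinery for the joint model.

    Per subject i with phenotype y_i and covariates x_i,
        L_i = sum over compatible diplotypes j of
              P(j | f) * Normal(y_i; b0 + beta . d_j + gamma . x_i, sigma^2)
    where d_j is the per-effect-group haplotype copy count of diplotype j.
    Expansion rows (subject, diplotype) are precomputed for vectorization.
    """

    def __init__(self, expansions, y, X, hap_index, effect_group):
        # effect_group: array over haplotypes; -1 = reference (no effect)
        self.y = y
        self.X = X  # (n, n_cov), may have 0 columns
        self.n = len(y)
        self.n_eff = int(effect_group.max()) + 1 if effect_group.size else 0

        subj, h1, h2, mult = [], [], [], []
        for i, exp in enumerate(expansions):
            for a, b in exp.pairs:
                subj.append(i)
                h1.append(hap_index[a])
                h2.append(hap_index[b])
                mult.append(1.0 if a == b else 2.0)
        self.subj = np.array(subj, dtype=int)
        self.h1 = np.array(h1, dtype=int)
        self.h2 = np.array(h2, dtype=int)
        self.mult = np.array(mult)
        self.K = len(hap_index)

        # Dosage matrix per expansion row: copies of each effect group
        n_rows = len(self.subj)
        D = np.zeros((n_rows, self.n_eff))
        for hcol, arr in ((self.h1, effect_group), (self.h2, effect_group)):
            g = arr[hcol]
            valid = g >= 0
            D[np.arange(n_rows)[valid], g[valid]] += 1.0
        self.D = D
        self.Xrow = self.X[self.subj] if self.X.shape[1] else np.zeros((n_rows, 0))
        self.y_row = self.y[self.subj]

    def row_means(self, b0: float, beta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        mu = b0 + self.D @ beta
        if gamma.size:
            mu = mu + self.Xrow @ gamma
        return mu

    def loglik(self, freqs, b0, beta, gamma, sigma) -> float:
        pri = self.mult * freqs[self.h1] * freqs[self.h2]
        if np.any(pri < 0) or sigma <= 0:
            return -np.inf
        mu = self.row_means(b0, beta, gamma)
        log_phi = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((self.y_row - mu) / sigma) ** 2
        with np.errstate(divide="ignore"):
            log_terms = np.where(pri > 0, np.log(np.maximum(pri, 1e-300)) + log_phi, -np.inf)
        # grouped logsumexp over subjects, vectorized
        m = np.full(self.n, -np.inf)
        np.maximum.at(m, self.subj, log_terms)
        if np.any(np.isneginf(m)):
            return -np.inf
        s = np.zeros(self.n)
        np.add.at(s, self.subj, np.exp(log_terms - m[self.subj]))
        return float(np.sum(m + np.log(s)))

    def em(self, freqs, b0, beta, gamma, sigma, tol, max_iter, fixed_beta_mask=None):
        """EM for the joint model.  ``fixed_beta_mask`` pins selected effects
        at zero (used by the likelihood-ratio null refits)."""
        ll = self.loglik(freqs, b0, beta, gamma, sigma)
        n_rows = len(self.subj)
        design = np.column_stack([np.ones(n_rows), self.D, self.Xrow])
        free = np.ones(design.shape[1], dtype=bool)
        if fixed_beta_mask is not None:
            free[1 : 1 + self.n_eff] = ~fixed_beta_mask
        converged = False
        for it in range(1, max_iter + 1):
            # E-step
            pri = self.mult * freqs[self.h1] * freqs[self.h2]
            mu = self.row_means(b0, beta, gamma)
            dens = np.exp(-0.5 * ((self.y_row - mu) / sigma) ** 2) / sigma
            w = pri * dens
            denom = np.zeros(self.n)
            np.add.at(denom, self.subj, w)
            w = w / np.maximum(denom[self.subj], 1e-300)

            # M-step: frequencies by weighted counting
            new_f = np.zeros(self.K)
            np.add.at(new_f, self.h1, w)
            np.add.at(new_f, self.h2, w)
            freqs = new_f / (2.0 * self.n)

            # M-step: weighted least squares for the mean model
            sw = np.sqrt(w)
            A = design[:, free] * sw[:, None]
            coef_free, *_ = np.linalg.lstsq(A, self.y_row * sw, rcond=None)
            coef = np.zeros(design.shape[1])
            coef[free] = coef_free
            b0 = coef[0]
            beta = coef[1 : 1 + self.n_eff]
            gamma = coef[1 + self.n_eff :]
            resid = self.y_row - self.row_means(b0, beta, gamma)
            sigma = float(np.sqrt(np.sum(w * resid**2) / self.n))
            if sigma <= 0:
                raise ValueError("degenerate phenotype variance")

            new_ll = self.loglik(freqs, b0, beta, gamma, sigma)
            if abs(new_ll - ll) < tol:
                converged = True
                ll = new_ll
                break
            ll = new_ll
        return freqs, b0, beta, gamma, sigma, ll, converged


def _pack_params(freqs, b0, beta, gamma, sigma):
    # multinomial-logit for frequencies with the last haplotype as baseline
    eta = np.log(np.maximum(freqs[:-1], 1e-12)) - np.log(max(freqs[-1], 1e-12))
    return np.concatenate([eta, [b0], beta, gamma, [np.log(sigma)]])


def _unpack_params(theta, K, n_eff, n_cov):
    eta = theta[: K - 1]
    expo = np.exp(np.concatenate([eta, [0.0]]))
    freqs = expo / expo.sum()
    i = K - 1
    b0 = theta[i]
    beta = theta[i + 1 : i + 1 + n_eff]
    gamma = theta[i + 1 + n_eff : i + 1 + n_eff + n_cov]
    sigma = float(np.exp(theta[-1]))
    return freqs, b0, beta, gamma, sigma


def haplotype_phenotype_association(
    records,
    phenotype: np.ndarray | pd.Series,
    loci: tuple[Locus, ...] = ABCB1_LOCI,
    covariates: pd.DataFrame | None = None,
    reference_haplotype: Haplotype | str | None = None,
    config: EmConfig | None = None,
    phenotype_name: str = "phenotype",
) -> AssociationResult:
    """Joint ML association of haplotypes with a quantitative phenotype.

    The phenotype is modelled as normal with mean additive in haplotype copy
    number plus covariate terms; phase is marginalized over compatible
    diplotypes weighted by the haplotype frequencies, and frequencies and
    effects are maximized jointly.  Haplotypes below ``config.rare_floor``
    share one pooled "rare" effect.  Reported per haplotype: the phenotypic
    mean (expected phenotype of an h-homozygote at reference covariate
    levels, i.e. intercept + 2 x per-copy effect), its Wald 95% CI from the
    observed information, and a likelihood-ratio p-value against the
    reference haplotype.
    """
    config = config or EmConfig()
    loci = tuple(loci)
    y_all = np.asarray(phenotype, dtype=float)
    records = list(records)
    if len(records) != len(y_all):
        raise ValueError("records and phenotype must align")

    # Keep subjects with complete genotypes and a phenotype value
    expansions, y_list, keep_idx = [], [], []
    for i, rec in enumerate(records):
        if not np.isfinite(y_all[i]):
            continue
        try:
            expansions.append(enumerate_diplotypes(rec, loci))
        except ValueError as exc:
            logger.warning("association: excluding %s (%s)", rec.subject_id, exc)
            continue
        y_list.append(y_all[i])
        keep_idx.append(i)
    if not expansions:
        raise ValueError("empty cohort: no usable subjects")
    y = np.array(y_list)
    if np.ptp(y) == 0:
        raise ValueError("degenerate phenotype variance: phenotype is constant")

    cov_names: list[str] = []
    if covariates is not None and len(covariates.columns):
        cov = covariates.iloc[keep_idx]
        X = np.asarray(cov, dtype=float)
        cov_names = list(covariates.columns)
    else:
        X = np.zeros((len(y), 0))

    # Stage 1: genotype-only EM for initial frequencies
    hap_table = em_haplotype_frequencies(
        [records[i] for i in keep_idx], loci, config
    )
    haps = hap_table.haplotypes
    hap_index = {h: i for i, h in enumerate(haps)}
    freqs0 = hap_table.frequencies.copy()

    # Reference haplotype: default = most frequent
    if reference_haplotype is None:
        ref = haps[int(np.argmax(freqs0))]
    else:
        ref = (
            tuple(reference_haplotype.split("-"))
            if isinstance(reference_haplotype, str)
            else tuple(reference_haplotype)
        )
        if ref not in hap_index:
            raise ValueError(f"reference haplotype {ref} absent from the table")

    # Effect groups: reference -> -1; rare (< floor, non-ref) pooled
    effect_group = np.full(len(haps), -1, dtype=int)
    named: list[tuple[str, list[Haplotype]]] = []
    rare_members: list[Haplotype] = []
    g = 0
    for i, h in enumerate(haps):
        if h == ref:
            continue
        if freqs0[i] < config.rare_floor:
            rare_members.append(h)
        else:
            effect_group[i] = g
            named.append(("-".join(h), [h]))
            g += 1
    if rare_members:
        for h in rare_members:
            effect_group[hap_index[h]] = g
        named.append(("rare", rare_members))
        g += 1
    n_eff = g

    model = _AssocModel(expansions, y, X, hap_index, effect_group)

    # Initial mean model: grand mean, zero effects
    b0 = float(np.mean(y))
    beta = np.zeros(n_eff)
    gamma = np.zeros(X.shape[1])
    sigma = float(np.std(y)) or 1.0

    freqs, b0, beta, gamma, sigma, ll, conv = model.em(
        freqs0, b0, beta, gamma, sigma, config.tol, config.max_iter
    )
    if not conv:
        warnings.warn("joint association EM did not converge; results approximate")

    # Observed information for Wald CIs (full parameter vector, frequencies
    # on the multinomial-logit scale)
    K, n_cov = len(haps), X.shape[1]
    theta_hat = _pack_params(freqs, b0, beta, gamma, sigma)

    def negll(theta):
        f, b, be, ga, sg = _unpack_params(theta, K, n_eff, n_cov)
        return -model.loglik(f, b, be, ga, sg)

    cov_theta = None
    try:
        H = approx_hess(theta_hat, negll)
        cov_theta = np.linalg.pinv(H)
    except Exception as exc:  # pragma: no cover - numerical safety net
        warnings.warn(f"Hessian evaluation failed ({exc}); CIs unavailable")

    i_b0 = K - 1
    z = sps.norm.ppf(0.975)

    def mean_ci(eff_idx: int | None):
        """Phenotypic mean (h-homozygote) and Wald CI."""
        if eff_idx is None:
            m = b0
            var = cov_theta[i_b0, i_b0] if cov_theta is not None else np.nan
        else:
            j = i_b0 + 1 + eff_idx
            m = b0 + 2.0 * beta[eff_idx]
            var = (
                cov_theta[i_b0, i_b0]
                + 4.0 * cov_theta[j, j]
                + 4.0 * cov_theta[i_b0, j]
                if cov_theta is not None
                else np.nan
            )
        se = np.sqrt(var) if var >= 0 else np.nan
        return m, m - z * se, m + z * se

    # Likelihood-ratio p per effect group (vs reference)
    p_by_group: dict[int, float] = {}
    for gi in range(n_eff):
        mask = np.zeros(n_eff, dtype=bool)
        mask[gi] = True
        beta0 = beta.copy()
        beta0[gi] = 0.0
        *_, ll0, _ = model.em(
            freqs.copy(), b0, beta0, gamma.copy(), sigma,
            config.tol, config.max_iter, fixed_beta_mask=mask,
        )
        lr = max(0.0, 2.0 * (ll - ll0))
        p_by_group[gi] = float(sps.chi2.sf(lr, df=1))

    rows = []
    m, lo, hi = mean_ci(None)
    rows.append(
        {
            "haplotype": "-".join(ref),
            "frequency": float(freqs[hap_index[ref]]),
            "per_copy_effect": 0.0,
            "phenotypic_mean": m,
            "ci_low": lo,
            "ci_high": hi,
            "p_value": np.nan,
            "is_reference": True,
        }
    )
    for gi, (name, members) in enumerate(named):
        m, lo, hi = mean_ci(gi)
        rows.append(
            {
                "haplotype": name,
                "frequency": float(sum(freqs[hap_index[h]] for h in members)),
                "per_copy_effect": float(beta[gi]),
                "phenotypic_mean": m,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": p_by_group[gi],
                "is_reference": False,
            }
        )

    return AssociationResult(
        phenotype_name=phenotype_name,
        reference_haplotype=ref,
        table=pd.DataFrame(rows),
        covariates_adjusted=cov_names,
        model_log_likelihood=ll,
        sigma=sigma,
        converged=conv,
    )
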