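"""Diplotype enumeration and EM haplotype-frequency estimation, checked
against direct gamete counting, a simplex grid-search oracle, and
simulation recovery."""

import itertools

import numpy as np
import pytest

from tacpgx.loci import ABCB1_LOCI
from tacpgx.popgen import EmConfig, em_haplotype_frequencies, enumerate_diplotypes

from conftest import abcb1_record


class TestEnumerateDiplotypes:
    def test_het_at_one_locus_single_pair(self):
        rec = abcb1_record("s", "C-G-C", "T-G-C")
        exp = enumerate_diplotypes(rec)
        assert exp.n_pairs == 1
        assert exp.pairs[0] == (("C", "G", "C"), ("T", "G", "C"))

    def test_double_het_two_pairs(self):
        rec = abcb1_record("s", "C-G-C", "T-G-T")  # het at 1236 and 3435
        exp = enumerate_diplotypes(rec)
        assert exp.n_pairs == 2
        assert (("C", "G", "C"), ("T", "G", "T")) in exp.pairs  # coupling
        assert (("C", "G", "T"), ("T", "G", "C")) in exp.pairs  # repulsion

    def test_triple_het_matches_brute_force(self):
        rec = abcb1_record("s", "C-G-C", "T-T-T")
        exp = enumerate_diplotypes(rec)
        # brute force: all 2^3 ordered assignments collapsed to unordered
        pairs = set()
        for bits in itertools.product((0, 1), repeat=3):
            h1 = tuple(("C", "G", "C")[i] if b == 0 else ("T", "T", "T")[i] for i, b in enumerate(bits))
            h2 = tuple(("T", "T", "T")[i] if b == 0 else ("C", "G", "C")[i] for i, b in enumerate(bits))
            pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
        assert set(exp.pairs) == pairs
        assert exp.n_pairs == 4

    def test_triallelic_het_expands(self):
        rec = abcb1_record("s", "C-T-C", "T-A-C")  # het at 1236 and 2677 (T/A)
        assert enumerate_diplotypes(rec).n_pairs == 2

    def test_missing_call_raises(self):
        rec = abcb1_record("s", "C-G-C", "C-G-C")
        rec.calls["rs2032582"] = type(rec.calls["rs2032582"])("rs2032582", None, missing=True)
        with pytest.raises(ValueError, match="incomplete genotype"):
            enumerate_diplotypes(rec)


def grid_search_loglik(pair_sets, resolution=0.01):
    """Oracle: maximize the diplotype likelihood over the frequency simplex
    by brute-force grid search (haplotypes fixed to the observed support)."""
    support = sorted({h for pairs in pair_sets for p in pairs for h in p})
    k = len(support)
    idx = {h: i for i, h in enumerate(support)}
    steps = int(round(1.0 / resolution))
    best = -np.inf
    for combo in itertools.product(range(steps + 1), repeat=k - 1):
        if sum(combo) > steps:
            continue
        f = np.array(list(combo) + [steps - sum(combo)], dtype=float) / steps
        ll = 0.0
        for pairs in pair_sets:
            lik = sum(
                (1.0 if a == b else 2.0) * f[idx[a]] * f[idx[b]] for a, b in pairs
            )
            if lik <= 0:
                ll = -np.inf
                break
            ll += np.log(lik)
        best = max(best, ll)
    return best


class TestEmFrequencies:
    def test_phase_unambiguous_equals_gamete_counting(self):
        # every subject het at <=1 locus: frequencies are direct counts
        recs = [
            abcb1_record("a", "C-G-C", "C-G-C"),
            abcb1_record("b", "C-G-C", "T-G-C"),
            abcb1_record("c", "T-G-C", "T-G-C"),
            abcb1_record("d", "C-G-C", "C-G-T"),
        ]
        table = em_haplotype_frequencies(recs, config=EmConfig(n_restarts=3))
        assert table.frequency_of("C-G-C") == pytest.approx(4 / 8, abs=1e-9)
        assert table.frequency_of("T-G-C") == pytest.approx(3 / 8, abs=1e-9)
        assert table.frequency_of("C-G-T") == pytest.approx(1 / 8, abs=1e-9)

    def test_single_double_het_attains_grid_search_maximum(self):
        rec = abcb1_record("s", "C-G-C", "T-G-T")
        table = em_haplotype_frequencies([rec], config=EmConfig(n_restarts=5))
        # two global optima, each with likelihood 1/2
        assert table.log_likelihood == pytest.approx(np.log(0.5), abs=1e-6)
        oracle = grid_search_loglik([enumerate_diplotypes(rec).pairs])
        assert table.log_likelihood >= oracle - 1e-6

    def test_em_matches_grid_search_on_two_locus_toys(self, rng):
        # small cohorts over two effective loci (2677 fixed)
        haps = ["C-G-C", "C-G-T", "T-G-C", "T-G-T"]
        for trial in range(3):
            f = rng.dirichlet(np.ones(4) * 2)
            draws = rng.choice(4, size=(6, 2), p=f)
            recs = [
                abcb1_record(f"s{i}", haps[a], haps[b])
                for i, (a, b) in enumerate(draws)
            ]
            table = em_haplotype_frequencies(recs, config=EmConfig(n_restarts=8, seed=trial))
            oracle = grid_search_loglik(
                [enumerate_diplotypes(r).pairs for r in recs], resolution=0.02
            )
            # EM must do at least as well as the grid (up to grid resolution)
            assert table.log_likelihood >= oracle - 1e-9

    def test_loglikelihood_monotone_and_frequencies_normalized(self):
        recs = [
            abcb1_record("a", "C-G-C", "T-T-T"),
            abcb1_record("b", "C-G-T", "T-T-C"),
            abcb1_record("c", "C-G-C", "C-G-C"),
        ]
        from tacpgx.popgen import _build_problem

        prob, _ = _build_problem(recs, ABCB1_LOCI)
        freqs = np.ones(prob.K) / prob.K
        lls = [prob.loglik(freqs)]
        for _ in range(50):
            freqs, ll, _, _ = prob.em(freqs, tol=0.0, max_iter=1)
            lls.append(ll)
        assert all(b >= a - 1e-12 for a, b in zip(lls, lls[1:]))
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_simulation_recovery_within_3se(self, rng):
        truth = {"C-G-C": 0.45, "T-T-T": 0.35, "C-G-T": 0.15, "T-G-C": 0.05}
        haps = list(truth)
        p = np.array(list(truth.values()))
        n = 1000
        draws = rng.choice(len(haps), size=(n, 2), p=p)
        recs = [abcb1_record(f"s{i}", haps[a], haps[b]) for i, (a, b) in enumerate(draws)]
        table = em_haplotype_frequencies(recs, config=EmConfig(n_restarts=5, seed=0))
        for hap, f_true in truth.items():
            se = np.sqrt(f_true * (1 - f_true) / (2 * n))
            assert abs(table.frequency_of(hap) - f_true) < 3 * se

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty cohort"):
            em_haplotype_frequencies([])
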