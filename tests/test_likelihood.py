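"""Genotype-marginalized likelihoods against independent oracles.

The key oracle is the literal joint-genotype enumeration: summing, over all
G^N assignments of the K(K+1)/2 diploid genotypes to N individuals, the
product of HWE priors and per-individual multinomial pmfs (evaluated with
scipy.stats.multinomial, not the package's own pmf code).  The factorized
engine must reproduce it exactly.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import pileuplr as pl
from pileuplr.error_model import genotype_pairs, genotype_read_probs
from pileuplr.likelihood import (
    LikelihoodUnderflowError,
    cohort_loglikelihood,
    genotype_likelihood,
    genotype_likelihood_collapsed,
    hwe_genotype_prior,
    hwe_prior_matrix,
    locus_likelihood,
    ml_error_rate,
)

PAIRS4 = genotype_pairs(4)


def joint_permutation_likelihood(reads, freqs, alpha):
    """Brute-force locus likelihood: explicit sum over joint genotype assignments.

    Per-individual per-genotype pmfs come from scipy.stats.multinomial; the
    assignment sum itself is a literal loop over the G^N permutations.
    """
    n = len(reads)
    pmf = np.empty((n, len(PAIRS4)))
    prior = np.empty(len(PAIRS4))
    for g, pair in enumerate(PAIRS4):
        probs = genotype_read_probs(pair, alpha)
        prior[g] = hwe_genotype_prior(freqs, pair)
        for ind in range(n):
            depth = int(np.sum(reads[ind]))
            pmf[ind, g] = (1.0 if depth == 0
                           else sps.multinomial.pmf(reads[ind], depth, probs))
    total = 0.0
    for assignment in itertools.product(range(len(PAIRS4)), repeat=n):
        term = 1.0
        for ind, g in enumerate(assignment):
            term *= prior[g] * pmf[ind, g]
        total += term
    return total


def _random_instance(rng, n_ind, max_depth=8):
    reads = rng.integers(0, max_depth, size=(n_ind, 4))
    # some zero-depth individuals, as in real sparse data
    for i in range(n_ind):
        if rng.random() < 0.3:
            reads[i] = 0
    f = rng.dirichlet(np.ones(4) * rng.uniform(0.3, 3))
    alpha = rng.uniform(1e-4, 0.015)
    return reads, f, alpha


def test_genotype_likelihood_matches_scipy_multinomial():
    """Spot values: heterozygote vs homozygote explanations of a 3/6 pileup."""
    reads = (0, 3, 6, 0)
    lik_cg = genotype_likelihood(reads, "CG", 0.01)
    assert lik_cg == pytest.approx(84 * (0.5 - 0.01 / 3) ** 9, rel=1e-12)
    lik_aa = genotype_likelihood(reads, "AA", 0.01)
    assert lik_aa == pytest.approx(
        float(sps.multinomial.pmf(reads, 9, genotype_read_probs("AA", 0.01))),
        rel=1e-10)
    assert lik_aa < 1e-18 < lik_cg  # error-only explanation is negligible


def test_genotype_likelihood_empty_pileup_is_one():
    for g in ["AA", "CG", "TT"]:
        assert genotype_likelihood((0, 0, 0, 0), g, 0.01) == 1.0


def test_collapsed_equals_full_everywhere_applicable(rng):
    """M2/M3-style zero-category pooling must not change any genotype value."""
    for _ in range(60):
        reads = rng.integers(0, 6, size=4)
        reads[rng.choice(4, size=rng.integers(1, 4), replace=False)] = 0
        alpha = rng.uniform(0, 0.015)
        for pair in PAIRS4:
            full = genotype_likelihood(reads, pair, alpha)
            collapsed = genotype_likelihood_collapsed(reads, pair, alpha)
            assert collapsed == pytest.approx(full, abs=1e-12)


def test_collapsed_single_read_and_empty():
    # a single T read (two/three-category collapse regime)
    assert genotype_likelihood_collapsed((0, 0, 0, 1), "TT", 0.009) == \
        pytest.approx(genotype_likelihood((0, 0, 0, 1), "TT", 0.009), abs=1e-15)
    assert genotype_likelihood_collapsed((0, 0, 0, 0), "AC", 0.009) == 1.0


def test_collapsed_falls_through_when_no_zero_category():
    reads = (1, 2, 3, 4)
    assert genotype_likelihood_collapsed(reads, "AG", 0.01) == \
        pytest.approx(genotype_likelihood(reads, "AG", 0.01), abs=1e-15)


@pytest.mark.parametrize("freqs, genotype, expected", [
    ((1, 0, 0, 0), "AA", 1.0),
    ((1, 0, 0, 0), "AC", 0.0),
    ((0.5, 0.5, 0, 0), "AA", 0.25),
    ((0.5, 0.5, 0, 0), "AC", 0.5),
    ((0.5, 0.5, 0, 0), "CC", 0.25),
])
def test_hwe_prior_textbook_cases(freqs, genotype, expected):
    assert hwe_genotype_prior(np.array(freqs, float), genotype) == \
        pytest.approx(expected, abs=1e-15)


def test_hwe_priors_sum_to_one(rng):
    for _ in range(20):
        f = rng.dirichlet(np.ones(4))
        assert hwe_prior_matrix(f).sum() == pytest.approx(1.0, abs=1e-12)


def test_factorized_equals_joint_enumeration(rng):
    """Factorized engine == literal G^N joint sum, 1-3 individuals."""
    for _ in range(30):
        n_ind = int(rng.integers(1, 4))
        reads, f, alpha = _random_instance(rng, n_ind)
        expected = joint_permutation_likelihood(reads, f, alpha)
        got = locus_likelihood(reads, f, alpha)
        assert got == pytest.approx(expected, rel=1e-12)


def test_zero_depth_individuals_are_unit_factors(rng):
    reads, f, alpha = _random_instance(rng, 1, max_depth=5)
    single = locus_likelihood(reads, f, alpha)
    padded = np.vstack([reads, np.zeros((5, 4), dtype=int)])
    assert locus_likelihood(padded, f, alpha) == pytest.approx(single, rel=1e-12)


def test_all_zero_locus_likelihood_is_exactly_one():
    assert locus_likelihood(np.zeros((6, 4), int), np.full(4, 0.25), 0.009) == 1.0


def test_cohort_loglik_additivity_and_identical_models(toy_panel, rng):
    panel, counts_a, counts_b = toy_panel
    reads = rng.integers(0, 4, size=(2, 2, 4))
    cohort = pl.PileupCohort(["i1", "i2"], panel, reads)
    total, per_locus = cohort_loglikelihood(cohort, panel, counts_a, 0.01,
                                            return_per_locus=True)
    assert total == pytest.approx(per_locus.sum(), rel=1e-12)
    # per-locus values equal independent single-locus computations
    freqs = counts_a.posterior_mean_frequencies(panel)
    for j in range(2):
        assert np.exp(per_locus[j]) == pytest.approx(
            locus_likelihood(reads[:, j], freqs[j], 0.01), rel=1e-10)
    # identical models in point mode give identical logliks
    same = pl.PopulationAlleleCounts("B", panel.locus_ids, counts_a.counts)
    assert cohort_loglikelihood(cohort, panel, same, 0.01) == total


def test_empty_cohort_loglik_is_zero(toy_panel):
    panel, counts_a, _ = toy_panel
    cohort = pl.PileupCohort(["i1"], panel, np.zeros((1, 2, 4), int))
    assert cohort_loglikelihood(cohort, panel, counts_a, 0.005) == 0.0


def test_loglik_finite_and_continuous_in_alpha(bundled, bundled_cohort):
    """No NaN/-inf anywhere on (0, 0.015]; small alpha steps move it smoothly."""
    panel, counts_a, _ = bundled
    cohort, _ = bundled_cohort
    alphas = np.concatenate([[1e-9, 1e-6], np.linspace(1e-4, 0.015, 40)])
    lls = np.array([cohort_loglikelihood(cohort, panel, counts_a, a)
                    for a in alphas])
    assert np.isfinite(lls).all()
    # continuity proxy: halving the grid step roughly halves the max jump
    def max_jump(n):
        grid = np.linspace(0.001, 0.015, n)
        vals = [cohort_loglikelihood(cohort, panel, counts_a, a) for a in grid]
        return np.abs(np.diff(vals)).max()

    coarse, fine = max_jump(20), max_jump(39)
    assert fine < 0.7 * coarse


def test_impossible_reads_at_alpha_zero_raise_with_locus(toy_panel):
    panel, counts_a, _ = toy_panel
    reads = np.zeros((1, 2, 4), int)
    reads[0, 1] = [1, 1, 1, 0]  # three categories: impossible without error
    cohort = pl.PileupCohort(["i1"], panel, reads)
    with pytest.raises(LikelihoodUnderflowError, match="2:200C>T"):
        cohort_loglikelihood(cohort, panel, counts_a, 0.0)


def test_per_locus_lr_monotone_in_frequency_ratio(toy_panel):
    """At a pathogenic-reads-only locus, LR(A/B) grows with f_A/f_B."""
    panel, _, _ = toy_panel
    reads = np.zeros((1, 2, 4), int)
    reads[0, 0] = [0, 0, 3, 0]  # only pathogenic (G) reads at locus 0
    cohort = pl.PileupCohort(["i1"], panel, reads)
    n = 10_000
    lrs = []
    for fa in [0.005, 0.01, 0.02, 0.05, 0.1]:
        ca = pl.PopulationAlleleCounts("A", panel.locus_ids, np.array(
            [[int(n * (1 - fa)), 0, int(n * fa), 0], [0, n, 0, 0]]))
        cb = pl.PopulationAlleleCounts("B", panel.locus_ids, np.array(
            [[int(n * 0.999), 0, int(n * 0.001), 0], [0, n, 0, 0]]))
        la = cohort_loglikelihood(cohort, panel, ca, 0.005)
        lb = cohort_loglikelihood(cohort, panel, cb, 0.005)
        lrs.append(la - lb)
    assert np.all(np.diff(lrs) > 0)


def test_non_pathogenic_reads_slightly_favor_low_frequency_model(toy_panel):
    """Reference-only pileups are marginally more probable where the
    pathogenic allele is rarer."""
    panel, counts_a, counts_b = toy_panel
    reads = np.zeros((1, 2, 4), int)
    reads[0, 0] = [6, 0, 0, 0]  # reference reads only
    cohort = pl.PileupCohort(["i1"], panel, reads)
    la = cohort_loglikelihood(cohort, panel, counts_a, 0.005)
    lb = cohort_loglikelihood(cohort, panel, counts_b, 0.005)
    assert la < lb
    assert np.exp(la - lb) > 0.8  # only marginally


def test_ml_error_rate_deterministic_and_boundary_flag(bundled, bundled_cohort):
    panel, counts_a, _ = bundled
    cohort, truth = bundled_cohort
    e1 = ml_error_rate(cohort, panel, counts_a)
    e2 = ml_error_rate(cohort, panel, counts_a)
    assert e1.alpha_hat == e2.alpha_hat
    assert not e1.at_boundary
    # informationless cohort: flat profile, boundary warning
    empty = pl.PileupCohort(cohort.individuals, panel,
                            np.zeros_like(cohort.reads))
    flat = ml_error_rate(empty, panel, counts_a)
    assert flat.at_boundary
    assert np.allclose(flat.profile.loglik, 0.0)


def test_likelihood_ratio_profile_contract(bundled, bundled_cohort):
    panel, counts_a, counts_b = bundled
    cohort, _ = bundled_cohort
    rep = pl.likelihood_ratio_profile(cohort, panel, counts_a, counts_b,
                                      n_samples=60, rng=5)
    assert len(rep.profile) == 2 * 60
    assert set(rep.profile["model"]) == set(rep.labels)
    assert rep.overall_lr == pytest.approx(
        np.exp(rep.total_loglik[rep.labels[0]] - rep.total_loglik[rep.labels[1]]))
    # zero-depth loci have per-locus LR exactly 1
    zero_depth = cohort.depths.sum(axis=0) == 0
    assert np.allclose(rep.per_locus["lr"][zero_depth], 1.0)


def test_private_allele_audit_flags(toy_panel):
    panel, counts_a, counts_b = toy_panel
    reads = np.zeros((2, 2, 4), int)
    reads[0, 0] = [0, 0, 2, 0]   # locus 0: pathogenic reads in one individual
    reads[0, 1] = [0, 1, 0, 1]   # locus 1: pathogenic reads in both
    reads[1, 1] = [0, 0, 0, 2]
    cohort = pl.PileupCohort(["i1", "i2"], panel, reads)
    rep = pl.likelihood_ratio_profile(cohort, panel, counts_a, counts_b,
                                      n_samples=20, rng=1)
    audit = pl.private_allele_audit(rep, cohort, panel)
    status = dict(zip(audit["locus_id"], audit["status"]))
    assert status["1:100A>G"] == "private"
    assert status["2:200C>T"] == "shared"
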