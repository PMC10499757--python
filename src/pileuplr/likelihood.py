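"""Exact genotype-marginalized likelihoods and population likelihood ratios.

The probability of the observed read pileups under a candidate population
is computed by marginalizing over diploid genotypes at every locus:

    P(reads at locus) = sum over joint genotype assignments of
        prod over individuals [ HWE prior(g | freqs) * Multinomial(reads | probs(g, alpha)) ]

Because individuals are independent given the population allele
frequencies, the joint sum over all G^N genotype assignments factorizes
exactly into a product of per-individual sums over the G = K(K+1)/2
genotypes; the literal joint enumeration (10^6 terms for six individuals at
K = 4) is retained in the test suite as a brute-force oracle.  Loci are
assumed independent, so the cohort log-likelihood is the sum of per-locus
log-likelihoods.  A zero-depth locus carries no information and contributes
likelihood exactly 1.

Frequency uncertainty is handled by drawing per-locus frequencies from
Dirichlet(counts + 1) — the posterior under a uniform prior on the observed
chromosome tallies — or by fixing them at the posterior mean.  Each
candidate population model carries its own read-error rate ``alpha``,
profiled or sampled over [0, 0.015].

All accumulation is in log space; per-genotype multinomial terms use
log-gamma factorials, so no underflow occurs for ``alpha > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlogy

from .error_model import (
    genotype_pairs,
    genotype_read_probs,
    read_prob_matrix,
    validate_alpha,
)
from .panel_io import PileupCohort, PopulationAlleleCounts, VariantPanel

__all__ = [
    "LikelihoodUnderflowError",
    "genotype_likelihood",
    "genotype_likelihood_collapsed",
    "hwe_genotype_prior",
    "hwe_prior_matrix",
    "locus_likelihood",
    "locus_loglikelihoods",
    "cohort_loglikelihood",
    "ErrorRateEstimate",
    "ml_error_rate",
    "LikelihoodReport",
    "likelihood_ratio_profile",
    "private_allele_audit",
]


class LikelihoodUnderflowError(ValueError):
    """The observed reads have probability zero under the proposed model."""


# ---------------------------------------------------------------------------
# per-genotype multinomial likelihoods


def _cats_for(k: int):
    """Category labels admitting both symbol and index genotype spellings."""
    from .error_model import DEFAULT_CATEGORIES

    return DEFAULT_CATEGORIES if k == 4 else tuple(range(k))


def _log_multinomial(reads: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """log multinomial pmf, broadcasting reads (..., K) against probs (..., K).

    ``xlogy`` handles zero-probability categories: a zero count contributes
    0, a positive count contributes -inf (an impossible outcome).
    """
    reads = np.asarray(reads, dtype=float)
    n = reads.sum(axis=-1)
    coeff = gammaln(n + 1.0) - gammaln(reads + 1.0).sum(axis=-1)
    return coeff + xlogy(reads, probs).sum(axis=-1)


def genotype_likelihood(reads, genotype, alpha: float) -> float:
    """Multinomial probability of a pileup given one diploid genotype.

    ``reads`` are per-category counts; category probabilities come from the
    symmetric error model (``1 - alpha`` for a homozygote's own allele,
    ``0.5 - alpha/3`` for each heterozygote allele at K = 4, ``alpha/3``
    otherwise).  Includes the multinomial coefficient; it cancels in every
    likelihood ratio.  An all-zero pileup has probability 1.
    """
    reads = np.asarray(reads, dtype=np.int64)
    if (reads < 0).any():
        raise ValueError("negative read count")
    k = reads.shape[-1]
    probs = genotype_read_probs(genotype, alpha, categories=_cats_for(k))
    return float(np.exp(_log_multinomial(reads, probs)))


def genotype_likelihood_collapsed(reads, genotype, alpha: float) -> float:
    """Genotype likelihood via the zero-count category collapse.

    Categories with zero observed reads can be pooled into a single
    "other" category whose probability is the sum of its members'; because
    zero counts contribute a unit factor to the multinomial pmf, the
    collapsed value is identical to :func:`genotype_likelihood`.  With two
    zero categories this reduces the genotype bookkeeping from 10 to 6
    genotypes, with three to 3; with no zero category it falls through to
    the full computation, and an all-zero pileup short-circuits to 1.
    """
    reads = np.asarray(reads, dtype=np.int64)
    k = reads.shape[-1]
    if reads.sum() == 0:
        return 1.0  # no information
    zero = np.flatnonzero(reads == 0)
    if zero.size == 0:
        return genotype_likelihood(reads, genotype, alpha)
    keep = np.flatnonzero(reads > 0)
    probs = genotype_read_probs(genotype, alpha, categories=_cats_for(k))
    collapsed_probs = np.append(probs[keep], probs[zero].sum())
    collapsed_reads = np.append(reads[keep], 0)
    return float(np.exp(_log_multinomial(collapsed_reads, collapsed_probs)))


# ---------------------------------------------------------------------------
# Hardy-Weinberg genotype priors


def hwe_genotype_prior(freqs, genotype) -> float:
    """HWE prior of one genotype: ``f_a**2`` or ``2 f_a f_b``."""
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.shape[-1]
    from .error_model import _allele_indices  # shared genotype parsing

    i, j = _allele_indices(genotype, _cats_for(k))
    if i == j:
        return float(freqs[i] ** 2)
    return float(2.0 * freqs[i] * freqs[j])


def hwe_prior_matrix(freqs: np.ndarray) -> np.ndarray:
    """HWE priors for all genotypes, shape ``(..., G)`` in genotype-pair order.

    Rows sum to 1 whenever the input frequencies do.
    """
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.shape[-1]
    pairs = genotype_pairs(k)
    out = np.empty(freqs.shape[:-1] + (len(pairs),))
    for g, (i, j) in enumerate(pairs):
        if i == j:
            out[..., g] = freqs[..., i] ** 2
        else:
            out[..., g] = 2.0 * freqs[..., i] * freqs[..., j]
    return out


# ---------------------------------------------------------------------------
# locus and cohort likelihoods


def locus_loglikelihoods(reads: np.ndarray, freqs: np.ndarray,
                         alpha: float, allow_impossible: bool = False) -> np.ndarray:
    """Genotype-marginalized log-likelihood at each locus.

    Parameters
    ----------
    reads
        ``(N, L, K)`` per-individual per-locus category counts.
    freqs
        ``(L, K)`` population allele frequencies per locus.
    alpha
        Shared read-error rate.
    allow_impossible
        A pileup no genotype can produce (only possible at ``alpha = 0`` or
        degenerate frequencies) has likelihood exactly 0; by default that
        raises :class:`LikelihoodUnderflowError` naming the locus, with
        ``allow_impossible=True`` it yields ``-inf`` so profiling code can
        score ``alpha = 0`` as a (losing) candidate.

    Returns
    -------
    ``(L,)`` log-likelihoods; each is ``sum_individuals log sum_genotypes
    prior(g) * multinomial(reads | probs(g))``, the exact factorization of
    the joint genotype-assignment sum.  Exactly 0 (likelihood 1) wherever
    every individual has zero depth.
    """
    alpha = validate_alpha(alpha)
    reads = np.asarray(reads, dtype=np.int64)
    n, l, k = reads.shape
    probs = read_prob_matrix(alpha, k)            # (G, K)
    if alpha > 0:
        # all genotype read probs are positive: plain matmul in log space
        r = reads.astype(float)
        coeff = gammaln(r.sum(-1) + 1.0) - gammaln(r + 1.0).sum(-1)  # (N, L)
        log_pmf = coeff[..., None] + r @ np.log(probs).T             # (N, L, G)
    else:
        log_pmf = _log_multinomial(reads[:, :, None, :], probs[None, None, :, :])
    with np.errstate(divide="ignore"):
        log_prior = np.log(hwe_prior_matrix(freqs))  # (L, G)
    with np.errstate(invalid="ignore"):
        per_ind = logsumexp(log_pmf + log_prior[None], axis=-1)  # (N, L)
    per_ind[reads.sum(axis=-1) == 0] = 0.0   # zero depth: likelihood exactly 1
    out = per_ind.sum(axis=0)
    if not allow_impossible and np.isneginf(out).any():
        j = int(np.flatnonzero(np.isneginf(out))[0])
        raise LikelihoodUnderflowError(
            f"locus index {j}: observed reads impossible under the proposed "
            f"model (alpha={alpha}, some category frequency is exactly zero)"
        )
    return out


def locus_likelihood(pileups, freqs, alpha: float) -> float:
    """Marginal probability of all individuals' reads at one locus.

    ``pileups`` is ``(N, K)`` — one row per individual.  Equivalent to the
    joint sum over all ``G**N`` genotype assignments weighted by HWE priors
    (the enumeration the factorized engine replaces).
    """
    reads = np.asarray(pileups, dtype=np.int64)[:, None, :]
    freqs = np.asarray(freqs, dtype=float)[None, :]
    return float(np.exp(locus_loglikelihoods(reads, freqs, alpha)[0]))


def cohort_loglikelihood(cohort: PileupCohort, panel: VariantPanel,
                         pop_counts: PopulationAlleleCounts, alpha: float,
                         freq_mode: str = "point",
                         rng: np.random.Generator | None = None,
                         return_per_locus: bool = False,
                         allow_impossible: bool = False):
    """Total log-likelihood of a cohort under one population model.

    ``freq_mode="point"`` evaluates at the Dirichlet posterior-mean
    frequencies ``(c_i + 1)/(sum c + K)``; ``"dirichlet_sample"`` draws one
    fresh Dirichlet(counts + 1) frequency vector per locus (requires
    ``rng``), propagating population-frequency uncertainty.  Loci are
    independent, so the total is the sum of per-locus log-likelihoods.
    """
    if freq_mode == "point":
        freqs = pop_counts.posterior_mean_frequencies(panel)
    elif freq_mode == "dirichlet_sample":
        if rng is None:
            raise ValueError("dirichlet_sample mode requires an rng")
        shape = pop_counts.array_for(panel) + 1.0
        g = rng.standard_gamma(shape)
        freqs = g / g.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    try:
        per_locus = locus_loglikelihoods(cohort.reads, freqs, alpha,
                                         allow_impossible=allow_impossible)
    except LikelihoodUnderflowError as exc:
        j = int(str(exc).split("locus index ")[1].split(":")[0])
        raise LikelihoodUnderflowError(
            f"locus {panel.locus_ids[j]}: {exc}") from None
    if return_per_locus:
        return float(per_locus.sum()), per_locus
    return float(per_locus.sum())


# ---------------------------------------------------------------------------
# error-rate estimation


@dataclass
class ErrorRateEstimate:
    """ML read-error rate with its likelihood profile."""

    alpha_hat: float
    profile: pd.DataFrame  # columns: alpha, loglik
    at_boundary: bool
    mode: str

    def __float__(self):
        return self.alpha_hat


def ml_error_rate(cohort: PileupCohort, panel: VariantPanel,
                  pop_counts: PopulationAlleleCounts,
                  alpha_range: tuple[float, float] = (0.0, 0.015),
                  mode: str = "grid", n: int = 31,
                  freq_mode: str = "point",
                  rng: np.random.Generator | None = None) -> ErrorRateEstimate:
    """Maximum-likelihood read-error rate for one population model.

    ``mode="grid"`` evaluates a deterministic evenly spaced grid of ``n``
    alpha values; ``"sampled"`` draws ``n`` uniform alphas (seeded via
    ``rng``).  Ties are broken toward the smallest alpha.  An estimate at
    either end of ``alpha_range`` — including the flat profile of an
    informationless cohort — sets ``at_boundary``.
    """
    lo, hi = alpha_range
    if not (0.0 <= lo < hi < 1.0):
        raise ValueError(f"invalid alpha_range {alpha_range}")
    if n < 2:
        raise ValueError("need at least 2 evaluation points")
    if mode == "grid":
        alphas = np.linspace(lo, hi, n)
    elif mode == "sampled":
        if rng is None:
            raise ValueError("sampled mode requires an rng")
        alphas = np.sort(rng.uniform(lo, hi, size=n))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    logliks = np.array([
        cohort_loglikelihood(cohort, panel, pop_counts, a, freq_mode=freq_mode,
                             rng=rng, allow_impossible=True)
        for a in alphas
    ])
    best = logliks.max()
    alpha_hat = float(alphas[np.flatnonzero(logliks == best)].min())
    at_boundary = bool(np.isclose(alpha_hat, lo) or np.isclose(alpha_hat, hi)
                       or np.allclose(logliks, logliks[0]))
    return ErrorRateEstimate(
        alpha_hat=alpha_hat,
        profile=pd.DataFrame({"alpha": alphas, "loglik": logliks}),
        at_boundary=at_boundary,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio comparison of two population models


@dataclass
class LikelihoodReport:
    """Two-model likelihood comparison over a sampled (alpha, frequency) profile."""

    labels: tuple[str, str]
    per_locus: pd.DataFrame      # locus_id, loglik_a, loglik_b, log_lr, lr
    profile: pd.DataFrame        # model, alpha, loglik (n_samples rows per model)
    alpha_hat: dict[str, float]
    total_loglik: dict[str, float]
    overall_lr: float
    n_samples: int
    rng_seed: int | None = None

    @property
    def overall_log_lr(self) -> float:
        a, b = self.labels
        return self.total_loglik[a] - self.total_loglik[b]


def likelihood_ratio_profile(cohort: PileupCohort, panel: VariantPanel,
                             counts_a: PopulationAlleleCounts,
                             counts_b: PopulationAlleleCounts,
                             n_samples: int = 5000,
                             alpha_range: tuple[float, float] = (0.0, 0.015),
                             rng: np.random.Generator | int | None = None,
                             paired: bool = False,
                             rng_seed: int | None = None) -> LikelihoodReport:
    """Compare two population models by sampled maximum likelihood.

    For each model, ``n_samples`` draws of (alpha ~ Uniform(alpha_range),
    per-locus frequencies ~ Dirichlet(counts + 1)) are scored by the cohort
    log-likelihood; each model's ``alpha_hat`` is the alpha of its best
    draw and the overall likelihood ratio is the ratio of the two maxima
    (A over B; > 1 favors A).  With ``paired=True`` both models share each
    draw's alpha.  Per-locus likelihood ratios are then evaluated at each
    model's own ``alpha_hat`` with posterior-mean point frequencies, a
    convention that keeps single-locus ratios deterministic given the
    profile; zero-depth loci have per-locus LR exactly 1.
    """
    if isinstance(rng, (int, np.integer)):
        rng_seed = int(rng)
        rng = np.random.default_rng(rng_seed)
    elif rng is None:
        rng = np.random.default_rng()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = alpha_range
    label_a, label_b = counts_a.population_label, counts_b.population_label
    if label_a == label_b:
        label_a, label_b = f"{label_a}_A", f"{label_b}_B"

    rows = []
    best: dict[str, tuple[float, float]] = {}
    alphas_a = rng.uniform(lo, hi, size=n_samples)
    alphas_b = alphas_a if paired else rng.uniform(lo, hi, size=n_samples)
    for label, counts, alphas in ((label_a, counts_a, alphas_a),
                                  (label_b, counts_b, alphas_b)):
        logliks = np.array([
            cohort_loglikelihood(cohort, panel, counts, a,
                                 freq_mode="dirichlet_sample", rng=rng,
                                 allow_impossible=True)
            for a in alphas
        ])
        m = logliks.max()
        hits = np.flatnonzero(logliks == m)
        best[label] = (float(alphas[hits].min()), float(m))
        rows.append(pd.DataFrame({"model": label, "alpha": alphas,
                                  "loglik": logliks}))
    profile = pd.concat(rows, ignore_index=True)

    alpha_hat = {lab: best[lab][0] for lab in (label_a, label_b)}
    total = {lab: best[lab][1] for lab in (label_a, label_b)}
    _, ll_a = cohort_loglikelihood(cohort, panel, counts_a, alpha_hat[label_a],
                                   freq_mode="point", return_per_locus=True)
    _, ll_b = cohort_loglikelihood(cohort, panel, counts_b, alpha_hat[label_b],
                                   freq_mode="point", return_per_locus=True)
    log_lr = ll_a - ll_b
    per_locus = pd.DataFrame({
        "locus_id": panel.locus_ids,
        "loglik_a": ll_a, "loglik_b": ll_b,
        "log_lr": log_lr, "lr": np.exp(log_lr),
    })
    return LikelihoodReport(
        labels=(label_a, label_b), per_locus=per_locus, profile=profile,
        alpha_hat=alpha_hat, total_loglik=total,
        overall_lr=float(np.exp(total[label_a] - total[label_b])),
        n_samples=n_samples, rng_seed=rng_seed,
    )


def private_allele_audit(report: LikelihoodReport, cohort: PileupCohort,
                         panel: VariantPanel, top: int | None = None) -> pd.DataFrame:
    """Decompose the likelihood ratio by locus and carrier privacy.

    A locus is *private* when exactly one individual carries pathogenic
    reads there; the population-assignment model treats individuals as
    unrelated random samples, and private loci are immune to relatedness
    among the cohort (a read in one person says nothing about its kin under
    the model), so an LR driven by private loci is robust to — in fact
    conservative under — cryptic relatedness.  Returns one row per locus
    with any reads, sorted by |log LR| descending; ``top`` truncates.
    """
    path = panel.pathogenic_indices
    path_reads = cohort.reads[:, np.arange(len(panel)), path]  # (N, L)
    carriers = (path_reads > 0).sum(axis=0)
    total_path = path_reads.sum(axis=0)
    any_reads = cohort.depths.sum(axis=0) > 0
    df = report.per_locus.copy()
    df["pathogenic_reads"] = total_path
    df["n_carriers"] = carriers
    df["status"] = np.select(
        [carriers == 1, carriers > 1], ["private", "shared"], default="no_pathogenic_reads"
    )
    df = df[any_reads].copy()
    df["abs_log_lr"] = df["log_lr"].abs()
    df = df.sort_values("abs_log_lr", ascending=False).drop(columns="abs_log_lr")
    if top is not None:
        df = df.head(top)
    return df.reset_index(drop=True)
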