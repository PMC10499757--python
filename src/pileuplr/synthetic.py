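"""Synthetic panels, population counts, and cohorts with known ground truth.

The generator emulates the statistical structure of a founder-population
disease-allele study: a panel of biallelic loci whose pathogenic alleles
are systematically more frequent in a bottlenecked population A
("ASJ-like") than in a large outbred population B ("NFE-like"); chromosome
tallies at gnomAD-like sample sizes; and low-coverage cohorts whose reads
are drawn genotype-first — HWE genotype per (individual, locus), then a
multinomial read draw through the symmetric error model — under a
zero-inflated negative-binomial depth model spanning the sparse-coverage
regime (per-individual means from ~0.2 to ~20 reads/locus and roughly 40%
zero-depth cells, matching the kind of ancient-DNA data the likelihood
machinery must handle).

Every generated object carries the truth needed to score recovery:
generating population, true error rate, true frequencies, genotypes, and
the seed that reproduces the cohort byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import DEFAULT_CATEGORIES, read_prob_matrix, validate_alpha
from .likelihood import likelihood_ratio_profile, ml_error_rate
from .panel_io import (
    PileupCohort,
    PopulationAlleleCounts,
    VariantLocus,
    VariantPanel,
)
from .simulate import (
    disease_read_statistic,
    empirical_tail_p,
    simulate_statistics,
)

__all__ = [
    "DepthModel",
    "SyntheticTruth",
    "generate_panel",
    "generate_cohort",
    "RecoveryConfig",
    "recovery_experiment",
    "load_bundled_panel",
]

#: Default gnomAD-like chromosome tallies (population B a 12x multiple of A
#: so exact frequency ties are constructible for the enrichment=1 boundary).
DEFAULT_N_CHROM_A = 10_000
DEFAULT_N_CHROM_B = 120_000


@dataclass(frozen=True)
class DepthModel:
    """Zero-inflated negative-binomial read-depth model.

    Each individual ``i`` has NB mean ``mean_depths[i]`` reads per locus
    with shared ``dispersion`` (NB size parameter; variance
    ``mu + mu^2/dispersion``), and every cell is independently zeroed with
    probability ``zero_inflation``.  The defaults give an expected ~4.8k
    total reads over 159 loci x 6 individuals with ~39% zero-depth cells,
    the sparsity regime of the motivating study.
    """

    mean_depths: tuple[float, ...] = (20.0, 8.0, 4.0, 2.0, 1.0, 0.2)
    dispersion: float = 2.0
    zero_inflation: float = 0.15

    def sample(self, n_loci: int, rng: np.random.Generator) -> np.ndarray:
        """Depths of shape ``(n_individuals, n_loci)``."""
        mu = np.asarray(self.mean_depths, dtype=float)[:, None]
        if (mu < 0).any():
            raise ValueError("mean depths must be >= 0")
        n_ind = mu.shape[0]
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        r = self.dispersion
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(mu > 0, r / (r + mu), 1.0)
        depths = rng.negative_binomial(r, p, size=(n_ind, n_loci))
        depths[mu[:, 0] == 0, :] = 0
        if self.zero_inflation > 0:
            mask = rng.random((n_ind, n_loci)) < self.zero_inflation
            depths[mask] = 0
        return depths.astype(np.int64)

    @property
    def expected_total_per_locus(self) -> float:
        return float(sum(self.mean_depths) * (1.0 - self.zero_inflation))


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    generating_population: str
    alpha_true: float
    freqs_true: np.ndarray           # (L, K)
    genotypes: np.ndarray            # (N, L, 2) allele indices, sorted pairs
    depths: np.ndarray               # (N, L)
    depth_model: DepthModel
    rng_seed: int | None


def _spawn(rng: np.random.Generator | int | None) -> tuple[np.random.Generator, int | None]:
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng)), int(rng)
    if rng is None:
        return np.random.default_rng(), None
    return rng, None


def generate_panel(n_loci: int = 159,
                   rng: np.random.Generator | int | None = None,
                   *,
                   freq_high: tuple[float, float] = (0.002, 0.02),
                   freq_low: tuple[float, float] = (0.0, 0.002),
                   enrichment: float | None = None,
                   n_chrom_a: int = DEFAULT_N_CHROM_A,
                   n_chrom_b: int = DEFAULT_N_CHROM_B,
                   labels: tuple[str, str] = ("ASJ_like", "NFE_like"),
                   ) -> tuple[VariantPanel, PopulationAlleleCounts, PopulationAlleleCounts]:
    """Panel of biallelic loci with founder-enriched pathogenic frequencies.

    Target pathogenic frequencies are drawn uniformly from ``freq_high``
    for population A and ``freq_low`` for population B (founder-effect
    scale vs background), then realized as binomial chromosome tallies; a
    cell pair is redrawn if sampling noise reverses the ordering, so the
    strict frequency filter retains every generated locus by construction.
    Passing ``enrichment`` instead derives B's frequency as A's divided by
    the ratio; ``enrichment=1`` builds exactly equal realized frequencies
    (every locus then fails a strict A > B filter).
    """
    rng, _ = _spawn(rng)
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    k = len(DEFAULT_CATEGORIES)
    loci, rows_a, rows_b = [], [], []
    for m in range(n_loci):
        ref_i, alt_i = rng.choice(k, size=2, replace=False)
        fa = rng.uniform(*freq_high)
        if enrichment is not None:
            fb = fa / enrichment
        else:
            fb = rng.uniform(*freq_low)
        if enrichment == 1:
            ca = int(round(fa * n_chrom_a))
            # realized tie: B tallies are an exact multiple of A's
            if n_chrom_b % n_chrom_a:
                raise ValueError("exact ties need n_chrom_b divisible by n_chrom_a")
            cb = ca * (n_chrom_b // n_chrom_a)
        else:
            while True:
                ca = rng.binomial(n_chrom_a, fa)
                cb = rng.binomial(n_chrom_b, min(fb, 1.0))
                if ca / n_chrom_a > cb / n_chrom_b:
                    break
        counts_a = np.zeros(k, dtype=np.int64)
        counts_b = np.zeros(k, dtype=np.int64)
        counts_a[alt_i], counts_a[ref_i] = ca, n_chrom_a - ca
        counts_b[alt_i], counts_b[ref_i] = cb, n_chrom_b - cb
        ref, alt = DEFAULT_CATEGORIES[ref_i], DEFAULT_CATEGORIES[alt_i]
        pos = 1_000_000 + m
        loci.append(VariantLocus(
            locus_id=f"1:{pos}{ref}>{alt}", pathogenic_allele=alt,
            condition=f"synthetic_condition_{m:03d}", source="synthetic",
            chrom="1", pos=pos, ref=ref, alt=alt,
        ))
        rows_a.append(counts_a)
        rows_b.append(counts_b)
    panel = VariantPanel(loci)
    ids = panel.locus_ids
    return (panel,
            PopulationAlleleCounts(labels[0], ids, np.array(rows_a)),
            PopulationAlleleCounts(labels[1], ids, np.array(rows_b)))


def generate_cohort(panel: VariantPanel, pop_counts: PopulationAlleleCounts,
                    n_individuals: int = 6,
                    depth_model: DepthModel | None = None,
                    alpha_true: float = 0.009,
                    rng: np.random.Generator | int | None = None,
                    ) -> tuple[PileupCohort, SyntheticTruth]:
    """Cohort drawn genotype-first from one population's frequencies.

    Per (individual, locus): two alleles sampled independently from the
    population frequencies (HWE), a depth from the depth model, and reads
    from a multinomial over the genotype's error-model category
    probabilities.  Re-running with the same seed reproduces the cohort
    byte-identically (the seed is recorded in the truth bundle).
    """
    rng, seed = _spawn(rng)
    alpha_true = validate_alpha(alpha_true)
    depth_model = depth_model or DepthModel()
    if len(depth_model.mean_depths) != n_individuals:
        if len(depth_model.mean_depths) == 1:
            depth_model = DepthModel(depth_model.mean_depths * n_individuals,
                                     depth_model.dispersion,
                                     depth_model.zero_inflation)
        else:
            raise ValueError("depth model must give one mean per individual")
    n_loci, k = len(panel), len(panel.categories)
    freqs = pop_counts.array_for(panel).astype(float)
    freqs = freqs / freqs.sum(axis=1, keepdims=True)

    cdf = freqs.cumsum(axis=1)                                   # (L, K)
    u = rng.random((n_individuals, n_loci, 2))
    alleles = (u[..., :, None] > cdf[None, :, None, :]).sum(axis=-1)  # (N, L, 2)
    alleles = np.sort(alleles, axis=-1)

    depths = depth_model.sample(n_loci, rng)                     # (N, L)
    probs = read_prob_matrix(alpha_true, k)                      # (G, K)
    pairs = {(i, j): g for g, (i, j) in enumerate(
        [(i, j) for i in range(k) for j in range(i, k)])}
    gidx = np.vectorize(lambda a, b: pairs[(a, b)])(alleles[..., 0], alleles[..., 1])
    reads = rng.multinomial(depths, probs[gidx])
    individuals = [f"syn{i:02d}" for i in range(n_individuals)]
    cohort = PileupCohort(individuals, panel, reads)
    truth = SyntheticTruth(
        generating_population=pop_counts.population_label,
        alpha_true=alpha_true, freqs_true=freqs, genotypes=alleles,
        depths=depths, depth_model=depth_model, rng_seed=seed,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# recovery / power / calibration harness


@dataclass
class RecoveryConfig:
    """Conditions for the recovery experiment."""

    n_replicates: int = 100
    n_loci: int = 159
    n_individuals: int = 6
    alpha_true: float = 0.009
    depth_model: DepthModel = field(default_factory=DepthModel)
    generating: str = "A"            # "A" (founder-enriched) or "B"
    alpha_grid_n: int = 61           # 0.00025 steps over [0, 0.015]
    alpha_max: float = 0.015
    lr_n_samples: int = 200
    n_sims_tail: int = 500
    panel_seed_offset: int = 101


@dataclass
class RecoveryReport:
    """Per-replicate recoveries plus aggregate rates."""

    per_replicate: pd.DataFrame
    config: RecoveryConfig
    power_lr: float                  # fraction with log LR favoring truth > 0
    alpha_band_coverage: float       # fraction with alpha_hat in [2/3, 4/3] x alpha_true
    calibration_ks_p: float          # KS p of tail-p when observed ~ evaluated model
    median_alpha_hat: float


def calibration_experiment(panel: VariantPanel,
                           pop_counts: PopulationAlleleCounts, alpha: float,
                           locus_depths: np.ndarray,
                           n_replicates: int = 200, n_sims: int = 500,
                           rng: np.random.Generator | int | None = None
                           ) -> tuple[np.ndarray, float]:
    """Tail-p calibration of the disease-read statistic.

    Each replicate draws one "observed" statistic from the evaluated model
    itself and scores it against ``n_sims`` fresh null simulations; the
    resulting empirical tail probabilities should be approximately uniform
    (up to the discreteness of the statistic).  Returns the tail-p array
    and the Kolmogorov-Smirnov p-value against Uniform(0, 1).

    Note the observed draw must come from the same Dirichlet-multinomial
    model as the null: cohorts generated genotype-first concentrate
    pathogenic reads in carrier individuals, reach fewer distinct loci, and
    give strongly conservative (near-1) tail probabilities instead.
    """
    rng, _ = _spawn(rng)
    ps = np.empty(n_replicates)
    for i in range(n_replicates):
        obs = int(simulate_statistics(panel, pop_counts, alpha, locus_depths,
                                      1, rng)[0])
        sims = simulate_statistics(panel, pop_counts, alpha, locus_depths,
                                   n_sims, rng)
        ps[i] = empirical_tail_p(obs, sims)
    return ps, float(stats.kstest(ps, "uniform").pvalue)


def recovery_experiment(config: RecoveryConfig,
                        rng: np.random.Generator | int | None = None
                        ) -> RecoveryReport:
    """Score parameter recovery, model-selection power, and calibration.

    One panel is generated per experiment; each replicate simulates a fresh
    cohort from the generating population at ``alpha_true``, then records
    the grid-ML error rate under the generating model, the overall
    likelihood ratio from a sampled profile, the disease-read statistic,
    and its empirical tail probability under both population models.
    """
    rng, _ = _spawn(rng)
    panel, counts_a, counts_b = generate_panel(config.n_loci, rng)
    gen_counts, alt_counts = ((counts_a, counts_b) if config.generating == "A"
                              else (counts_b, counts_a))
    rows = []
    for rep in range(config.n_replicates):
        cohort, truth = generate_cohort(
            panel, gen_counts, config.n_individuals, config.depth_model,
            config.alpha_true, rng)
        est = ml_error_rate(cohort, panel, gen_counts,
                            alpha_range=(0.0, config.alpha_max),
                            mode="grid", n=config.alpha_grid_n)
        report = likelihood_ratio_profile(
            cohort, panel, gen_counts, alt_counts,
            n_samples=config.lr_n_samples,
            alpha_range=(0.0, config.alpha_max), rng=rng)
        stat = disease_read_statistic(cohort, panel)
        locus_depths = cohort.depths.sum(axis=0)
        tails = {}
        for label, counts in (("generating", gen_counts), ("other", alt_counts)):
            sims = simulate_statistics(panel, counts, config.alpha_true,
                                       locus_depths, config.n_sims_tail, rng)
            tails[label] = empirical_tail_p(stat, sims)
        rows.append({
            "replicate": rep, "alpha_hat": est.alpha_hat,
            "log_lr_generating_vs_other": report.overall_log_lr,
            "statistic": stat,
            "tail_p_generating": tails["generating"],
            "tail_p_other": tails["other"],
        })
    df = pd.DataFrame(rows)
    lo, hi = config.alpha_true * 2 / 3, config.alpha_true * 4 / 3
    cal_depths = config.depth_model.sample(config.n_loci, rng).sum(axis=0)
    _, ks_p = calibration_experiment(panel, gen_counts, config.alpha_true,
                                     cal_depths, rng=rng,
                                     n_sims=config.n_sims_tail)
    return RecoveryReport(
        per_replicate=df, config=config,
        power_lr=float((df["log_lr_generating_vs_other"] > 0).mean()),
        alpha_band_coverage=float(df["alpha_hat"].between(lo, hi).mean()),
        calibration_ks_p=ks_p,
        median_alpha_hat=float(df["alpha_hat"].median()),
    )


def load_bundled_panel() -> tuple[VariantPanel, PopulationAlleleCounts,
                                  PopulationAlleleCounts]:
    """Load the bundled synthetic stand-in panel and counts fixtures.

    These are generator output frozen at a fixed seed — a 159-locus panel
    with ASJ-like and NFE-like chromosome tallies.  They stand in for the
    real per-locus gnomAD counts, which are not redistributable here; see
    the methods note for the recipe to populate real counts.
    """
    from importlib import resources

    from .panel_io import read_panel, read_population_counts

    data = resources.files("pileuplr") / "data"
    with resources.as_file(data / "synthetic_panel.tsv") as p:
        panel = read_panel(p)
    with resources.as_file(data / "synthetic_counts_asj_like.tsv") as p:
        counts_a = read_population_counts(p, "ASJ_like", panel=panel)
    with resources.as_file(data / "synthetic_counts_nfe_like.tsv") as p:
        counts_b = read_population_counts(p, "NFE_like", panel=panel)
    return panel, counts_a, counts_b
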