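"""Symmetric read-error model for allele categories.

A single global miscall probability ``alpha`` governs every read: a true
allele is reported correctly with probability ``1 - alpha`` and as any one
of the other ``K - 1`` categories with probability ``alpha / (K - 1)`` each
(``alpha / 3`` for the default four nucleotides).  Two quantities derive
from this:

* error-adjusted population allele frequencies — the category distribution
  of a read drawn from a random chromosome of the population;
* per-genotype read-category probabilities — the category distribution of a
  read drawn from a known diploid genotype, the building block of the
  genotype-marginalized likelihood.

Both are pure functions of ``alpha`` and are exact for any number of
categories ``K >= 2``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CATEGORIES",
    "ALPHA_ANALYSIS_MAX",
    "validate_alpha",
    "adjust_frequencies",
    "genotype_read_probs",
    "read_prob_matrix",
    "genotype_pairs",
]

#: Canonical nucleotide category order.
DEFAULT_CATEGORIES: tuple[str, ...] = ("A", "C", "G", "T")

#: Upper end of the error-rate range of analytical interest (1.5%).
ALPHA_ANALYSIS_MAX: float = 0.015

_FREQ_TOL = 1e-8


def validate_alpha(alpha: float) -> float:
    """Check ``0 <= alpha < 1`` and return it as a float."""
    alpha = float(alpha)
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"read error rate must be in [0, 1), got {alpha}")
    return alpha


def adjust_frequencies(freqs: np.ndarray, alpha: float) -> np.ndarray:
    """Error-adjusted allele frequencies.

    With miscall rate ``alpha``, a read sampled from a random chromosome
    shows category ``i`` with probability

        ``f_i * (1 - alpha) + (1 - f_i) * alpha / (K - 1)``

    i.e. either the true allele read correctly or any other allele misread
    as ``i``.

    Parameters
    ----------
    freqs
        Allele frequencies, shape ``(..., K)``; each row must sum to 1.
    alpha
        Per-read miscall probability.

    Returns
    -------
    ndarray of the same shape, rows summing to 1.
    """
    alpha = validate_alpha(alpha)
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.shape[-1]
    if k < 2:
        raise ValueError("need at least two allele categories")
    totals = freqs.sum(axis=-1)
    if not np.allclose(totals, 1.0, atol=_FREQ_TOL):
        raise ValueError("allele frequencies must sum to 1")
    return freqs * (1.0 - alpha) + (1.0 - freqs) * (alpha / (k - 1))


def genotype_pairs(k: int) -> list[tuple[int, int]]:
    """Ordered unordered allele pairs ``(i, j)`` with ``i <= j``.

    For ``k = 4`` this yields the ten diploid genotypes in the order
    AA, AC, AG, AT, CC, CG, CT, GG, GT, TT.
    """
    return [(i, j) for i in range(k) for j in range(i, k)]


def _allele_indices(genotype, categories: Sequence[str]) -> tuple[int, int]:
    """Resolve a genotype given as 'CG', ('C','G') or (1, 2)."""
    if isinstance(genotype, str):
        alleles = tuple(genotype)
    else:
        alleles = tuple(genotype)
    if len(alleles) != 2:
        raise ValueError(f"a diploid genotype has two alleles, got {genotype!r}")
    idx = []
    for a in alleles:
        if isinstance(a, (int, np.integer)):
            if not 0 <= int(a) < len(categories):
                raise ValueError(f"allele index {a} out of range")
            idx.append(int(a))
        else:
            try:
                idx.append(categories.index(a) if isinstance(categories, list)
                           else list(categories).index(a))
            except ValueError:
                raise ValueError(
                    f"allele {a!r} not among categories {tuple(categories)}"
                ) from None
    return idx[0], idx[1]


def genotype_read_probs(
    genotype,
    alpha: float,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> np.ndarray:
    """Read-category probabilities for a diploid genotype.

    A homozygote ``a/a`` emits its own allele with probability ``1 - alpha``
    and each other category with ``alpha / (K - 1)``.  A heterozygote
    ``a/b`` emits each carried allele with probability
    ``0.5 * (1 - alpha) + 0.5 * alpha / (K - 1)`` (which reduces to the
    familiar ``0.5 - alpha / 3`` at ``K = 4``) and each non-carried
    category with ``alpha / (K - 1)``.

    Parameters
    ----------
    genotype
        Unordered allele pair: string like ``"CG"``, pair of symbols, or
        pair of category indices.
    alpha
        Per-read miscall probability.
    categories
        Allele category labels; defaults to A, C, G, T.

    Returns
    -------
    ndarray of length ``K`` summing to 1.
    """
    alpha = validate_alpha(alpha)
    k = len(categories)
    i, j = _allele_indices(genotype, categories)
    err = alpha / (k - 1)
    probs = np.full(k, err)
    if i == j:
        probs[i] = 1.0 - alpha
    else:
        het = 0.5 * (1.0 - alpha) + 0.5 * err
        probs[i] = het
        probs[j] = het
    return probs


def read_prob_matrix(alpha: float, k: int = 4) -> np.ndarray:
    """Read-category probabilities for all ``K(K+1)/2`` genotypes at once.

    Returns an array of shape ``(G, K)`` whose rows follow
    :func:`genotype_pairs` order; row ``g`` equals
    :func:`genotype_read_probs` for genotype ``g``.
    """
    alpha = validate_alpha(alpha)
    err = alpha / (k - 1)
    het = 0.5 * (1.0 - alpha) + 0.5 * err
    pairs = genotype_pairs(k)
    mat = np.full((len(pairs), k), err)
    for g, (i, j) in enumerate(pairs):
        if i == j:
            mat[g, i] = 1.0 - alpha
        else:
            mat[g, i] = het
            mat[g, j] = het
    return mat
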