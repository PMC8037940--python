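"""Exact test of Hardy-Weinberg equilibrium.

Rare pharmacogenetic alleles (often a single carrier in ~900 patients) make
asymptotic chi-square HWE tests invalid, so genotype QC here uses the exact
conditional test: conditional on the observed allele counts, the number of
heterozygotes H in a sample of N diploids with n_a minor alleles has

    P(H = h) = N! * n_a! * n_A! * 2**h
               / ( n_AA! * h! * n_aa! * (2N)! )

over heterozygote counts h with the same parity as n_a. The two-sided
p-value is the probability-ordering sum: the total probability of all
heterozygote counts no more probable than the observed one.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["hwe_exact_test", "het_count_distribution"]

# relative slack when comparing term probabilities to the observed term, so
# that exactly-tied configurations computed in floating point are included
_TIE_REL_TOL = 1e-9


def het_count_distribution(n_total: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the heterozygote count given allele counts.

    Parameters
    ----------
    n_total
        Number of diploid individuals N.
    n_minor
        Total count of the minor allele (0 <= n_minor <= N; the conditional
        distribution is symmetric in minor/major so callers fold counts).

    Returns
    -------
    (het_counts, probabilities), each a 1-D array over the support
    {h : h <= n_minor, h ≡ n_minor (mod 2), (n_minor - h)/2 + h <= N}.
    """
    n_major = 2 * n_total - n_minor
    h = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - h) // 2
    hom_major = (n_major - h) // 2
    ok = hom_major >= 0
    h, hom_minor, hom_major = h[ok], hom_minor[ok], hom_major[ok]
    logp = (
        gammaln(n_total + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        + h * np.log(2.0)
        - gammaln(hom_minor + 1)
        - gammaln(h + 1)
        - gammaln(hom_major + 1)
        - gammaln(2 * n_total + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return h, p


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value for one biallelic variant.

    Parameters are the three genotype counts. Monomorphic variants (minor
    allele count zero) return 1.0; use a genotype-count check upstream when
    a monomorphic flag is needed. The result is in (0, 1] and symmetric in
    the two homozygote counts.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n_total = sum(counts)
    if n_total < 1:
        raise ValueError("at least one genotyped individual required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n_total - n_alt)
    if n_minor == 0:
        return 1.0
    support, probs = het_count_distribution(n_total, n_minor)
    p_obs = probs[support == n_het]
    if p_obs.size == 0:  # impossible configuration given the counts
        raise ValueError(
            f"heterozygote count {n_het} incompatible with allele counts"
        )
    p_value = probs[probs <= p_obs[0] * (1.0 + _TIE_REL_TOL)].sum()
    return float(min(p_value, 1.0))
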