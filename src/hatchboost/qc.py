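"""Genotype quality control ahead of parentage.

Filters follow the usual GT-seq parentage workflow: drop loci with <90%
call rate, then drop individuals with >=10% missing genotypes on the
retained loci, and flag duplicate samples by pairwise shared-call identity.
Boundary semantics: a locus at exactly 90% coverage is retained; an
individual at exactly 10% missing is removed.
"""

from __future__ import annotations

import itertools

import numpy as np

from .genotypes import GenotypeMatrix


def filter_loci(m: GenotypeMatrix, min_coverage: float = 0.90) -> GenotypeMatrix:
    """Retain loci whose non-missing call fraction is >= ``min_coverage``.

    The individual set and the relative order of retained loci are
    unchanged. Raises ``ValueError`` if no locus survives.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must lie in (0, 1]")
    coverage = 1.0 - m.locus_missing_fraction()
    keep = coverage >= min_coverage - 1e-12
    if not keep.any():
        raise ValueError("no loci survive the coverage filter")
    return GenotypeMatrix(m.individual_ids, m.locus_ids[keep], m.calls[:, keep])


def filter_individuals(m: GenotypeMatrix, max_missing: float = 0.10) -> GenotypeMatrix:
    """Remove individuals whose missing fraction is >= ``max_missing``.

    The boundary is exclusive of retention (a fish missing exactly 10% of
    loci is dropped). The locus set is unchanged. Raises ``ValueError`` if
    no individual survives.
    """
    if not 0.0 <= max_missing < 1.0:
        raise ValueError("max_missing must lie in [0, 1)")
    frac = m.individual_missing_fraction()
    keep = frac < max_missing - 1e-12
    if not keep.any():
        raise ValueError("no individuals survive the missingness filter")
    return GenotypeMatrix(m.individual_ids[keep], m.locus_ids, m.calls[keep])


def apply_qc(m: GenotypeMatrix, min_coverage: float = 0.90,
             max_missing: float = 0.10) -> GenotypeMatrix:
    """Locus filter first, then individual filter on the retained loci."""
    return filter_individuals(filter_loci(m, min_coverage), max_missing)


def find_duplicates(m: GenotypeMatrix, min_identity: float = 0.95):
    """Pairs of individuals whose shared-call identity >= ``min_identity``.

    Identity is the fraction of jointly non-missing loci with equal calls.
    Returns a set of unordered id pairs (tuples sorted lexicographically).
    Pairs with zero jointly non-missing loci are indeterminate and are
    returned separately.

    Returns
    -------
    duplicates : set of (id, id)
    indeterminate : set of (id, id)
    """
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0.5, 1]")
    calls = m.calls
    present = ~np.isnan(calls)
    n = m.n_individuals
    duplicates, indeterminate = set(), set()
    # pairwise match counts via matrix products over the one-hot encoding;
    # fine for the cohort sizes a yearly parentage run sees
    onehot = np.stack([((calls == g) & present).astype(np.int64)
                       for g in (0.0, 1.0, 2.0)])
    match = np.einsum("gij,gkj->ik", onehot, onehot)
    joint = (present.astype(np.int64) @ present.T.astype(np.int64))
    for i, k in itertools.combinations(range(n), 2):
        pair = tuple(sorted((m.individual_ids[i], m.individual_ids[k])))
        if joint[i, k] == 0:
            indeterminate.add(pair)
        elif match[i, k] / joint[i, k] >= min_identity:
            duplicates.add(pair)
    return duplicates, indeterminate


def allele_frequencies(m: GenotypeMatrix) -> np.ndarray:
    """Per-locus reference-allele frequency from non-missing calls.

    Raises ``ValueError`` if any locus has no non-missing call.
    """
    present = ~np.isnan(m.calls)
    counts = present.sum(axis=0)
    if (counts == 0).any():
        bad = m.locus_ids[counts == 0]
        raise ValueError(f"loci with all calls missing: {list(bad[:5])}")
    return np.nansum(m.calls, axis=0) / (2.0 * counts)
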