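"""Biallelic SNP genotype container.

Genotypes are stored as counts of the reference allele (0, 1, 2) with
``NaN`` marking missing calls, in an individuals x loci float array. This
is the common encoding for GT-seq style parentage panels, where a few
hundred unlinked, high-MAF SNPs are scored per fish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_CODE = 3  # integer sentinel used by the fast-path code views


@dataclass
class GenotypeMatrix:
    """Individuals x loci biallelic genotype matrix.

    Parameters
    ----------
    individual_ids : array-like of str
        Row identifiers, unique.
    locus_ids : array-like of str
        Column identifiers, unique.
    calls : ndarray of float, shape (n_individuals, n_loci)
        Reference-allele counts in {0, 1, 2}; ``NaN`` is missing.
    """

    individual_ids: np.ndarray
    locus_ids: np.ndarray
    calls: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual identifiers")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus identifiers")
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing (NaN)")
        self._index = {iid: i for i, iid in enumerate(self.individual_ids)}

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row(self, individual_id) -> np.ndarray:
        return self.calls[self._index[individual_id]]

    def codes(self) -> np.ndarray:
        """Integer view with missing calls mapped to ``MISSING_CODE``."""
        c = self.calls.copy()
        c[np.isnan(c)] = MISSING_CODE
        return c.astype(np.int8)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def locus_missing_fraction(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def individual_missing_fraction(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=1)

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given ids (order preserved
        as in this matrix, not the argument order)."""
        ri = np.arange(self.n_individuals)
        ci = np.arange(self.n_loci)
        if individuals is not None:
            keep = set(individuals)
            ri = ri[[iid in keep for iid in self.individual_ids]]
        if loci is not None:
            keep = set(loci)
            ci = ci[[lid in keep for lid in self.locus_ids]]
        return GenotypeMatrix(
            self.individual_ids[ri], self.locus_ids[ci], self.calls[np.ix_(ri, ci)]
        )

    # -- I/O -----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=pd.Index(self.individual_ids, name="id"),
            columns=list(self.locus_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(df.index.to_numpy(dtype=object),
                   np.asarray(df.columns, dtype=object),
                   df.to_numpy(dtype=float))

    def write_csv(self, path) -> None:
        """Wide CSV: one row per individual, one column per locus, empty
        cell = missing."""
        df = self.to_frame()
        # write integer codes, blanks for missing
        df.to_csv(path, float_format="%.0f")

    @classmethod
    def read_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls.from_frame(df.astype(float))

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Import biallelic records from a VCF; the GT field is mapped to a
        reference-allele count. Multiallelic records are skipped with a
        warning."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = np.asarray(vcf.samples, dtype=object)
        locus_ids, columns = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                warnings.warn(
                    f"skipping multiallelic record {var.CHROM}:{var.POS}",
                    stacklevel=2,
                )
                continue
            name = var.ID or f"{var.CHROM}_{var.POS}"
            # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            gt = var.gt_types
            col = np.full(len(samples), np.nan)
            col[gt == 0] = 2.0  # two reference alleles
            col[gt == 1] = 1.0
            col[gt == 3] = 0.0
            locus_ids.append(name)
            columns.append(col)
        if not columns:
            raise ValueError("no biallelic records found in VCF")
        return cls(samples, np.asarray(locus_ids, dtype=object),
                   np.column_stack(columns))
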