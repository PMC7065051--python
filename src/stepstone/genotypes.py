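"""Diploid multilocus genotype container.

Genotypes are stored as an integer array of shape ``(n_individuals,
n_loci, 2)``; allele labels are positive integers (fragment sizes or
repeat numbers) and 0 is the missing code at both allele positions.
Haploid records (exactly one of the two positions missing) are invalid:
a genotype is either fully called or fully missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite genotypes grouped by sample.

    Attributes
    ----------
    alleles
        int array ``(n_individuals, n_loci, 2)``; 0 encodes missing.
    samples
        sample (population) label per individual, length ``n_individuals``.
    individuals
        unique individual identifiers, length ``n_individuals``.
    loci
        ordered locus names, length ``n_loci``.
    """

    alleles: np.ndarray
    samples: np.ndarray
    individuals: np.ndarray
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=object)
        self.individuals = np.asarray(self.individuals, dtype=object)
        self.loci = list(self.loci)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        n, L, _ = self.alleles.shape
        if len(self.samples) != n or len(self.individuals) != n:
            raise ValueError("samples/individuals length mismatch with alleles")
        if len(self.loci) != L:
            raise ValueError("loci length mismatch with alleles")
        if (self.alleles < 0).any():
            raise ValueError("allele labels must be non-negative integers")
        n_missing = (self.alleles == MISSING).sum(axis=2)
        half = np.argwhere(n_missing == 1)
        if len(half):
            i, l = half[0]
            raise ValueError(
                "haploid record (one allele missing): individual "
                f"{self.individuals[i]!r} locus {self.loci[l]!r}"
                + (f" and {len(half) - 1} more" if len(half) > 1 else "")
            )

    # -- shape -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def sample_names(self) -> list[str]:
        """Sample labels in order of first appearance."""
        return list(pd.unique(pd.Series(self.samples)))

    def sample_sizes(self) -> pd.Series:
        return pd.Series(self.samples).value_counts().reindex(self.sample_names)

    # -- masks -----------------------------------------------------------
    def called(self) -> np.ndarray:
        """Boolean ``(n_individuals, n_loci)``: genotype fully called."""
        return (self.alleles != MISSING).all(axis=2)

    def sample_mask(self, sample: str) -> np.ndarray:
        if sample not in set(self.samples):
            raise KeyError(f"unknown sample label {sample!r}")
        return self.samples == sample

    # -- subsetting ------------------------------------------------------
    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.alleles[mask], self.samples[mask], self.individuals[mask], self.loci
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        unknown = set(keep) - set(self.samples)
        if unknown:
            raise KeyError(f"unknown sample label(s): {sorted(unknown)}")
        mask = np.isin(self.samples, list(keep))
        return self.subset_individuals(mask)

    def drop_loci(self, loci: list[str]) -> "GenotypeMatrix":
        keep = [i for i, l in enumerate(self.loci) if l not in set(loci)]
        return GenotypeMatrix(
            self.alleles[:, keep, :],
            self.samples,
            self.individuals,
            [self.loci[i] for i in keep],
        )

    # -- conversion ------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long format: sample, individual, locus, allele1, allele2 (0 = missing)."""
        n, L, _ = self.alleles.shape
        return pd.DataFrame(
            {
                "sample": np.repeat(self.samples, L),
                "individual": np.repeat(self.individuals, L),
                "locus": np.tile(np.asarray(self.loci, dtype=object), n),
                "allele1": self.alleles[:, :, 0].ravel(),
                "allele2": self.alleles[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, loci: list[str] | None = None) -> "GenotypeMatrix":
        required = {"sample", "individual", "locus", "allele1", "allele2"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"long genotype table missing columns {sorted(missing_cols)}")
        if loci is None:
            loci = list(pd.unique(df["locus"]))
        ind_order = list(dict.fromkeys(zip(df["sample"], df["individual"])))
        ind_index = {key: i for i, key in enumerate(ind_order)}
        loc_index = {l: j for j, l in enumerate(loci)}
        alleles = np.zeros((len(ind_order), len(loci), 2), dtype=np.int64)
        rows = [ind_index[(s, i)] for s, i in zip(df["sample"], df["individual"])]
        cols = [loc_index[l] for l in df["locus"]]
        alleles[rows, cols, 0] = df["allele1"].to_numpy(np.int64)
        alleles[rows, cols, 1] = df["allele2"].to_numpy(np.int64)
        samples = np.array([s for s, _ in ind_order], dtype=object)
        individuals = np.array([i for _, i in ind_order], dtype=object)
        return cls(alleles, samples, individuals, loci)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
            and list(self.samples) == list(other.samples)
            and list(self.individuals) == list(other.individuals)
        )
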