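"""Microsatellite population-genetic statistics.

The central statistic is a three-level hierarchical AMOVA on allele
identity (among samples / among individuals within samples / within
individuals), from which the fixation indices are formed as variance
component ratios::

    FST = Va / (Va + Vb + Vc)
    FIS = Vb / (Vb + Vc)
    FIT = (Va + Vb) / (Va + Vb + Vc)

which satisfy (1 - FIS)(1 - FST) = 1 - FIT identically.  Pairwise FST is
the same estimator applied to each pair of samples; significance comes
from permutation (individuals among samples for FST, allele copies among
individuals within samples for FIS), with the sequential +1 correction
p = (count + 1) / (n_permutations + 1).

Missing genotypes are handled by per-locus pairwise deletion throughout;
nothing is ever imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "sample_summary_stats",
    "allelic_richness",
    "null_allele_frequency",
    "amova",
    "AmovaResult",
    "pairwise_fst_matrix",
    "PairwiseFstMatrix",
    "bonferroni_threshold",
]


# ---------------------------------------------------------------------------
# allele frequencies and descriptive statistics
# ---------------------------------------------------------------------------

def allele_frequencies(
    genotypes: GenotypeMatrix, sample: str
) -> dict[str, pd.DataFrame]:
    """Per-locus allele counts and frequencies for one sample.

    Missing genotypes are excluded from denominators.  A locus with zero
    called genotypes maps to an empty frame (frequencies undefined).
    """
    mask = genotypes.sample_mask(sample)
    out: dict[str, pd.DataFrame] = {}
    for j, locus in enumerate(genotypes.loci):
        copies = genotypes.alleles[mask, j, :].ravel()
        copies = copies[copies != MISSING]
        counts = pd.Series(copies).value_counts().sort_index()
        df = pd.DataFrame({"count": counts})
        df["freq"] = df["count"] / df["count"].sum() if len(df) else np.nan
        df.index.name = "allele"
        out[locus] = df
    return out


def allelic_richness(counts: Sequence[int] | pd.Series, g: int) -> float:
    """Rarefied allele count: expected number of distinct alleles in a
    random subsample of ``g`` allele copies.

    ``Ar = sum_a [1 - C(N - N_a, g) / C(N, g)]`` over observed alleles,
    where ``N`` is the total number of copies and ``N_a`` each allele's
    count.
    """
    c = np.asarray(pd.Series(counts).to_numpy(), dtype=np.int64)
    c = c[c > 0]
    N = int(c.sum())
    if not 1 <= g <= N:
        raise ValueError(f"rarefaction size g={g} must be in [1, N={N}]")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - int(ci), g) / denom for ci in c))


def _default_rarefaction_g(genotypes: GenotypeMatrix) -> int:
    """Smallest doubled per-sample count of complete genotypes over all
    (sample, locus) cells with any data."""
    called = genotypes.called()
    best = None
    for sample in genotypes.sample_names:
        mask = genotypes.samples == sample
        per_locus = called[mask].sum(axis=0)
        for n in per_locus:
            if n > 0:
                best = int(n) if best is None else min(best, int(n))
    if best is None:
        raise ValueError("no called genotypes anywhere")
    return 2 * best


def sample_summary_stats(
    genotypes: GenotypeMatrix, rarefaction_g: int | None = None
) -> pd.DataFrame:
    """Descriptive statistics per sample, averaged over loci.

    Columns: Na (mean alleles/locus), Ne (effective alleles, 1/sum p^2),
    Np (private alleles, observed in exactly one sample), Ho (observed
    heterozygosity among called genotypes), He (Nei's 1 - sum p^2) and Ar
    (rarefied allelic richness at ``rarefaction_g`` copies).
    """
    samples = genotypes.sample_names
    freqs = {s: allele_frequencies(genotypes, s) for s in samples}
    if rarefaction_g is None:
        rarefaction_g = _default_rarefaction_g(genotypes)

    # which samples carry each allele, for private-allele counts
    carriers: dict[tuple[str, int], set[str]] = {}
    for s in samples:
        for locus, df in freqs[s].items():
            for allele in df.index:
                carriers.setdefault((locus, int(allele)), set()).add(s)

    rows = []
    for s in samples:
        mask = genotypes.samples == s
        na, ne, he, ar = [], [], [], []
        ho_num = ho_den = 0
        np_count = 0
        for j, locus in enumerate(genotypes.loci):
            df = freqs[s][locus]
            if len(df) == 0:
                continue
            p = df["freq"].to_numpy()
            na.append(len(df))
            ne.append(1.0 / np.sum(p**2))
            he.append(1.0 - np.sum(p**2))
            g = min(rarefaction_g, int(df["count"].sum()))
            ar.append(allelic_richness(df["count"], g))
            np_count += sum(
                1 for allele in df.index if carriers[(locus, int(allele))] == {s}
            )
            geno = genotypes.alleles[mask, j, :]
            called = (geno != MISSING).all(axis=1)
            ho_num += int((geno[called, 0] != geno[called, 1]).sum())
            ho_den += int(called.sum())
        rows.append(
            {
                "sample": s,
                "Na": float(np.mean(na)) if na else np.nan,
                "Ne": float(np.mean(ne)) if ne else np.nan,
                "Np": np_count,
                "Ho": ho_num / ho_den if ho_den else np.nan,
                "He": float(np.mean(he)) if he else np.nan,
                "Ar": float(np.mean(ar)) if ar else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# null alleles
# ---------------------------------------------------------------------------

def null_allele_frequency(
    genotypes: GenotypeMatrix,
    locus: str,
    estimator: Literal["brookfield1", "chakraborty"] = "chakraborty",
    samples: Iterable[str] | None = None,
) -> float:
    """Null-allele frequency at a locus from the heterozygosity deficit.

    ``brookfield1``: r = (He - Ho) / (1 + He);
    ``chakraborty``: r = (He - Ho) / (He + Ho).
    Computed on the pooled called genotypes of the given samples (all
    samples by default).  Negative estimates are clamped to 0; He = Ho = 0
    is undefined and returns NaN.
    """
    if locus not in genotypes.loci:
        raise KeyError(f"unknown locus {locus!r}")
    j = genotypes.loci.index(locus)
    if samples is not None:
        genotypes = genotypes.subset_samples(list(samples))
    geno = genotypes.alleles[:, j, :]
    called = (geno != MISSING).all(axis=1)
    if not called.any():
        raise ValueError(f"locus {locus!r} has no called genotypes")
    geno = geno[called]
    ho = float((geno[:, 0] != geno[:, 1]).mean())
    p = pd.Series(geno.ravel()).value_counts(normalize=True).to_numpy()
    he = float(1.0 - np.sum(p**2))
    if he == 0.0 and ho == 0.0:
        return float("nan")
    if estimator == "brookfield1":
        r = (he - ho) / (1.0 + he)
    elif estimator == "chakraborty":
        r = (he - ho) / (he + ho)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return max(r, 0.0)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _encode_locus(genotypes: GenotypeMatrix, j: int) -> np.ndarray:
    """Allele codes at locus j: int array (n_individuals, 2), -1 = missing."""
    geno = genotypes.alleles[:, j, :]
    alleles = np.unique(geno[geno != MISSING])
    codes = np.searchsorted(alleles, geno)
    codes[geno == MISSING] = -1
    return codes


def _ss_from_counts(counts: np.ndarray, n_copies: int) -> float:
    """Sum of squared deviations within a group of allele copies under the
    allele-identity metric: (n - sum c_a^2 / n) / 2."""
    if n_copies == 0:
        return 0.0
    return float(n_copies - np.sum(counts.astype(float) ** 2) / n_copies) / 2.0


def _locus_ss(codes: np.ndarray, sample_idx: np.ndarray, k: int) -> tuple[float, float, float]:
    """(SS among samples, SS among individuals within samples, SS within
    individuals) at one locus; individuals with missing genotypes at this
    locus are dropped (pairwise deletion)."""
    called = (codes >= 0).all(axis=1)
    codes = codes[called]
    grp = sample_idx[called]
    if len(codes) == 0:
        return 0.0, 0.0, 0.0
    n_alleles = int(codes.max()) + 1
    flat = codes.ravel()
    tot_counts = np.bincount(flat, minlength=n_alleles)
    ss_total = _ss_from_counts(tot_counts, len(flat))
    ss_wi = float((codes[:, 0] != codes[:, 1]).sum()) / 2.0
    ss_within_samples = 0.0
    for s in range(k):
        sel = codes[grp == s].ravel()
        if len(sel):
            c = np.bincount(sel, minlength=n_alleles)
            ss_within_samples += _ss_from_counts(c, len(sel))
    ss_ai = ss_within_samples - ss_wi
    ss_ap = ss_total - ss_within_samples
    return ss_ap, ss_ai, ss_wi


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition over diploid allele copies."""

    table: pd.DataFrame  # strata x (df, SS, MS, variance, percent)
    fst: float
    fis: float
    fit: float
    p_fst: float | None = None
    p_fis: float | None = None
    n_permutations: int = 0

    @property
    def variance_components(self) -> tuple[float, float, float]:
        v = self.table["variance"]
        return float(v.iloc[0]), float(v.iloc[1]), float(v.iloc[2])


def f_statistics_from_components(va: float, vb: float, vc: float) -> dict[str, float]:
    """Fixation indices and stratum percentages from variance components.

    Accepts externally estimated components (e.g. a published AMOVA
    table); percentages are of the summed components.
    """
    total = va + vb + vc
    return {
        "fst": va / total,
        "fis": vb / (vb + vc),
        "fit": (va + vb) / total,
        "pct_among_samples": 100.0 * va / total,
        "pct_among_individuals": 100.0 * vb / total,
        "pct_within_individuals": 100.0 * vc / total,
    }


def _amova_core(
    per_locus_codes: list[np.ndarray],
    sample_idx: np.ndarray,
    sizes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Summed SS, df and variance components for a given grouping."""
    k = len(sizes)
    n_ind = int(sizes.sum())
    ss = np.zeros(3)
    for codes in per_locus_codes:
        ss += _locus_ss(codes, sample_idx, k)
    df = np.array([k - 1, n_ind - k, n_ind], dtype=float)
    ms = np.divide(ss, df, out=np.zeros(3), where=df > 0)
    # unequal-n coefficient for the among-sample component
    n0 = (n_ind - np.sum(sizes.astype(float) ** 2) / n_ind) / (k - 1) if k > 1 else np.nan
    vc = ms[2]
    vb = (ms[1] - vc) / 2.0
    va = (ms[0] - ms[1]) / (2.0 * n0) if k > 1 else 0.0
    return ss, df, (va, vb, vc)


def amova(
    genotypes: GenotypeMatrix,
    n_permutations: int = 0,
    seed: int | None = None,
    locus_exclude: Iterable[str] = (),
) -> AmovaResult:
    """Three-level AMOVA (among samples / among individuals / within
    individuals) on allele identity, locus SS summed over loci.

    Permutation p-values: FST by permuting individuals among samples,
    FIS by permuting allele copies among individuals within samples.
    Samples with fewer than 2 individuals are excluded with a warning.
    """
    excl = set(locus_exclude)
    if excl:
        genotypes = genotypes.drop_loci(list(excl))
    sizes_all = genotypes.sample_sizes()
    small = [s for s, n in sizes_all.items() if n < 2]
    if small:
        import warnings

        warnings.warn(f"excluding sample(s) with < 2 individuals: {small}")
        genotypes = genotypes.subset_samples(
            [s for s in genotypes.sample_names if s not in set(small)]
        )
    samples = genotypes.sample_names
    if len(samples) < 2:
        raise ValueError("AMOVA needs at least 2 samples with >= 2 individuals")
    order = {s: i for i, s in enumerate(samples)}
    sample_idx = np.array([order[s] for s in genotypes.samples])
    sizes = np.bincount(sample_idx, minlength=len(samples))

    per_locus = [_encode_locus(genotypes, j) for j in range(genotypes.n_loci)]
    ss, df, (va, vb, vc) = _amova_core(per_locus, sample_idx, sizes)
    total = va + vb + vc
    fst = va / total
    fis = vb / (vb + vc) if (vb + vc) != 0 else float("nan")
    fit = (va + vb) / total
    strata = ["among_samples", "among_individuals", "within_individuals"]
    comp = np.array([va, vb, vc])
    table = pd.DataFrame(
        {
            "df": df.astype(int),
            "SS": ss,
            "MS": np.divide(ss, df, out=np.full(3, np.nan), where=df > 0),
            "variance": comp,
            "percent": 100.0 * comp / total,
        },
        index=pd.Index(strata, name="stratum"),
    )
    table.loc["total"] = [
        int(df.sum()), ss.sum(), np.nan, total, 100.0 * comp.sum() / total,
    ]
    table["df"] = table["df"].astype(int)

    p_fst = p_fis = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits_fst = 0
        for _ in range(n_permutations):
            perm = rng.permutation(sample_idx)
            _, _, (pva, pvb, pvc) = _amova_core(per_locus, perm, sizes)
            if pva / (pva + pvb + pvc) >= fst:
                hits_fst += 1
        p_fst = (hits_fst + 1) / (n_permutations + 1)

        hits_fis = 0
        for _ in range(n_permutations):
            permed = []
            for codes in per_locus:
                c = codes.copy()
                for s in range(len(sizes)):
                    rowsel = np.flatnonzero((sample_idx == s) & (c >= 0).all(axis=1))
                    if len(rowsel) > 1:
                        copies = c[rowsel].ravel()
                        rng.shuffle(copies)
                        c[rowsel] = copies.reshape(-1, 2)
                permed.append(c)
            _, _, (pva, pvb, pvc) = _amova_core(permed, sample_idx, sizes)
            pfis = pvb / (pvb + pvc) if (pvb + pvc) != 0 else -np.inf
            if pfis >= fis:
                hits_fis += 1
        p_fis = (hits_fis + 1) / (n_permutations + 1)

    return AmovaResult(table, float(fst), float(fis), float(fit), p_fst, p_fis, n_permutations)


# ---------------------------------------------------------------------------
# pairwise FST
# ---------------------------------------------------------------------------

@dataclass
class PairwiseFstMatrix:
    """Pairwise AMOVA-FST with permutation p-values.

    ``fst`` holds values clamped to [0, 1] for reporting; ``fst_raw``
    keeps the unclamped estimates.  ``significant`` applies the
    Bonferroni-corrected threshold over all pairs.
    """

    fst: pd.DataFrame
    fst_raw: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    n_permutations: int
    alpha: float
    per_test_alpha: float


def bonferroni_threshold(alpha: float, n_samples: int) -> tuple[int, float]:
    """Number of unordered pairs and the per-test significance level."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    n_pairs = n_samples * (n_samples - 1) // 2
    return n_pairs, alpha / n_pairs


def pairwise_fst_matrix(
    genotypes: GenotypeMatrix,
    n_permutations: int = 0,
    seed: int | None = None,
    alpha: float = 0.05,
    locus_exclude: Iterable[str] = (),
) -> PairwiseFstMatrix:
    """Pairwise FST for every pair of samples by two-sample AMOVA.

    Pairs where either side has < 2 individuals are left missing (NaN).
    Permutations (individuals between the two samples) give one-sided
    p-values with the +1 correction; the significance flag uses
    ``alpha / n_pairs``.
    """
    excl = set(locus_exclude)
    if excl:
        genotypes = genotypes.drop_loci(list(excl))
    samples = genotypes.sample_names
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 samples")
    n_pairs, per_test = bonferroni_threshold(alpha, k)
    rng = np.random.default_rng(seed)

    fst = pd.DataFrame(0.0, index=samples, columns=samples)
    raw = pd.DataFrame(0.0, index=samples, columns=samples)
    pv = pd.DataFrame(np.nan, index=samples, columns=samples)
    sizes_all = genotypes.sample_sizes()

    per_locus_all = [_encode_locus(genotypes, j) for j in range(genotypes.n_loci)]
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            a, b = samples[a_i], samples[b_i]
            if sizes_all[a] < 2 or sizes_all[b] < 2:
                fst.loc[a, b] = fst.loc[b, a] = np.nan
                raw.loc[a, b] = raw.loc[b, a] = np.nan
                continue
            mask = np.isin(genotypes.samples, [a, b])
            sub_idx = (genotypes.samples[mask] == b).astype(int)
            sizes = np.bincount(sub_idx, minlength=2)
            codes = [c[mask] for c in per_locus_all]
            _, _, (va, vb, vc) = _amova_core(codes, sub_idx, sizes)
            value = va / (va + vb + vc)
            raw.loc[a, b] = raw.loc[b, a] = value
            clamped = float(min(max(value, 0.0), 1.0))
            fst.loc[a, b] = fst.loc[b, a] = clamped
            if n_permutations > 0:
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(sub_idx)
                    _, _, (qa, qb, qc) = _amova_core(codes, perm, sizes)
                    if qa / (qa + qb + qc) >= value:
                        hits += 1
                pval = (hits + 1) / (n_permutations + 1)
                pv.loc[a, b] = pv.loc[b, a] = pval
    np.fill_diagonal(fst.values, 0.0)
    np.fill_diagonal(raw.values, 0.0)
    sig = pv <= per_test
    return PairwiseFstMatrix(fst, raw, pv, sig, n_permutations, alpha, per_test)
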