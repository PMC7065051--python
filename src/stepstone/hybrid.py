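"""Maximum-likelihood hybrid index and the purity filter.

For an individual with called genotypes, the hybrid index ``h`` is the
proportion of its alleles inherited from species A (the *edulis*-like
panel; ``h = 1`` pure A, ``h = 0`` pure B).  Each allele copy ``a``
contributes ``log[h p_A(a) + (1 - h) p_B(a)]`` to the log-likelihood,
where ``p_A``/``p_B`` are the parental panel frequencies; the terms are
log-concave in ``h``, so the likelihood is unimodal and the maximizer is
found exactly on a 1e-6 lattice over [0, 1].

Alleles absent from a finite reference panel receive a floor frequency
``1 / (2 n_panel + 1)`` before renormalization, so no observed allele
makes the likelihood degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .synthetic import ParentalPanel

_LATTICE = 1_000_000  # h resolved to 1e-6


def _floored(freqs: pd.Series, alleles: Iterable[int], panel_size: int) -> pd.Series:
    eps = 1.0 / (2 * panel_size + 1)
    union = pd.Index(sorted(set(freqs.index) | set(alleles)))
    f = freqs.reindex(union, fill_value=0.0).astype(float)
    f[f <= 0] = eps
    return f / f.sum()


def _panel_probs(
    genotypes: GenotypeMatrix,
    panel: ParentalPanel,
    locus_exclude: Iterable[str],
    floor: bool = True,
) -> tuple[list[int], dict[int, tuple[pd.Series, pd.Series]]]:
    """Locus column indices used, and (p_A, p_B) per column.

    With ``floor=False`` the raw panel frequencies are used and alleles
    absent from a panel carry probability 0 (likelihood may hit -inf at
    the support boundary).
    """
    excl = set(locus_exclude)
    cols = [
        j for j, l in enumerate(genotypes.loci) if l in set(panel.loci) and l not in excl
    ]
    probs = {}
    for j in cols:
        locus = genotypes.loci[j]
        observed = genotypes.alleles[:, j, :]
        observed = set(observed[observed != MISSING].tolist())
        if floor:
            pa = _floored(panel.freqs_a[locus], observed, panel.n_a)
            pb = _floored(panel.freqs_b[locus], observed, panel.n_b)
        else:
            union = pd.Index(sorted(set(panel.freqs_a[locus].index) | set(
                panel.freqs_b[locus].index) | observed))
            pa = panel.freqs_a[locus].reindex(union, fill_value=0.0).astype(float)
            pb = panel.freqs_b[locus].reindex(union, fill_value=0.0).astype(float)
        probs[j] = (pa, pb)
    return cols, probs


def hybrid_loglik(
    genotypes: GenotypeMatrix,
    individual,
    panel: ParentalPanel,
    h: float,
    locus_exclude: Iterable[str] = (),
    floor: bool = True,
) -> float:
    """Log-likelihood of hybrid index ``h`` for one individual.

    Sums ``log[h p_A(a) + (1 - h) p_B(a)]`` over both allele copies of
    every called panel locus.  NaN if the individual has no called panel
    loci.  With ``floor=False`` alleles absent from a panel have
    probability 0 and the likelihood can reach -inf at the boundary.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must be in [0, 1]")
    matches = np.flatnonzero(genotypes.individuals == individual)
    if len(matches) == 0:
        raise KeyError(f"unknown individual {individual!r}")
    alleles = genotypes.alleles[int(matches[0])]
    cols, probs = _panel_probs(genotypes, panel, locus_exclude, floor=floor)
    total = 0.0
    used = 0
    with np.errstate(divide="ignore"):
        for j in cols:
            a1, a2 = alleles[j]
            if a1 == MISSING:
                continue
            pa, pb = probs[j]
            for a in (a1, a2):
                total += np.log(h * pa[a] + (1.0 - h) * pb[a])
            used += 1
    if used == 0:
        return float("nan")
    return float(total)


def _loglik_on_lattice(pa: np.ndarray, pb: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Summed log-likelihood at lattice points ``ks`` (h = k * 1e-6).

    The A and B weights are computed as ``k / 1e6`` and
    ``(1e6 - k) / 1e6`` (1e6 is exactly representable, so the boundary
    weights are exactly 0 and 1) so that swapping the panels maps the
    evaluation at ``k`` bitwise onto the evaluation at ``1e6 - k``.
    """
    wa = ks.astype(float) / 1e6
    wb = (_LATTICE - ks).astype(float) / 1e6
    # pa, pb: (n_copies,) arrays of panel frequencies for the observed copies
    vals = wa[:, None] * pa[None, :] + wb[:, None] * pb[None, :]
    return np.log(vals).sum(axis=1)


@dataclass
class HybridIndexResult:
    """Per-individual hybrid index estimates."""

    frame: pd.DataFrame  # individual, sample, h, loglik, loci_used, pure
    threshold: float = 1.0
    tolerance: float = 1e-6

    def __len__(self) -> int:
        return len(self.frame)


def estimate_hybrid_index(
    genotypes: GenotypeMatrix,
    panel: ParentalPanel,
    grid_step: float = 1e-3,
    locus_exclude: Iterable[str] = (),
    pure_threshold: float = 1.0,
    pure_tolerance: float = 1e-6,
) -> HybridIndexResult:
    """Maximum-likelihood ``h`` per individual on a 1e-6 lattice.

    A coarse grid at ``grid_step`` brackets the optimum; the bracket is
    refined tenfold per level down to 1e-6.  Because the log-likelihood
    is concave in ``h``, this returns the global lattice argmax.
    Individuals with zero called loci, and unidentifiable panels
    (identical frequency tables), yield ``h = NaN`` with a flag.
    """
    if not 0.0 < grid_step <= 0.1:
        raise ValueError("grid_step must be in (0, 0.1]")
    identifiable = panel.is_identifiable()
    cols, probs = _panel_probs(genotypes, panel, locus_exclude)
    coarse_step_k = max(int(round(grid_step * _LATTICE)), 1)

    rows = []
    for i in range(genotypes.n_individuals):
        alleles = genotypes.alleles[i]
        pa_list, pb_list = [], []
        used = 0
        for j in cols:
            a1, a2 = alleles[j]
            if a1 == MISSING:
                continue
            pa, pb = probs[j]
            pa_list += [pa[a1], pa[a2]]
            pb_list += [pb[a1], pb[a2]]
            used += 1
        if used == 0 or not identifiable:
            rows.append((genotypes.individuals[i], genotypes.samples[i],
                         np.nan, np.nan, used, False))
            continue
        pa_arr = np.asarray(pa_list, float)
        pb_arr = np.asarray(pb_list, float)

        ks = np.arange(0, _LATTICE + 1, coarse_step_k)
        if ks[-1] != _LATTICE:
            ks = np.append(ks, _LATTICE)
        step = coarse_step_k
        best = int(ks[np.argmax(_loglik_on_lattice(pa_arr, pb_arr, ks))])
        while step > 1:
            step = max(step // 10, 1)
            lo = max(best - 2 * step * 10, 0)
            hi = min(best + 2 * step * 10, _LATTICE)
            ks = np.arange(lo, hi + 1, step)
            best = int(ks[np.argmax(_loglik_on_lattice(pa_arr, pb_arr, ks))])
        h_hat = best / 1e6
        ll = float(_loglik_on_lattice(pa_arr, pb_arr, np.array([best]))[0])
        pure = h_hat >= pure_threshold - pure_tolerance
        rows.append((genotypes.individuals[i], genotypes.samples[i], h_hat, ll, used, pure))

    frame = pd.DataFrame(
        rows, columns=["individual", "sample", "h", "loglik", "loci_used", "pure"]
    )
    return HybridIndexResult(frame, pure_threshold, pure_tolerance)


def filter_pure(
    genotypes: GenotypeMatrix,
    results: HybridIndexResult,
    threshold: float = 1.0,
    tolerance: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain individuals with ``h >= threshold - tolerance``.

    Returns the filtered genotypes and a per-sample retention report
    (n, retained, fraction) with an ``overall`` row.  Raises if nothing
    survives.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    h = results.frame.set_index("individual")["h"]
    aligned = h.reindex(genotypes.individuals)
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()])[:5]
        raise ValueError(f"no hybrid index for individual(s): {missing}")
    keep = (aligned >= threshold - tolerance).to_numpy()
    report_rows = []
    for sample in genotypes.sample_names:
        mask = genotypes.samples == sample
        n = int(mask.sum())
        r = int((keep & mask).sum())
        report_rows.append({"sample": sample, "n": n, "retained": r, "fraction": r / n})
    report = pd.DataFrame(report_rows).set_index("sample")
    report.loc["overall"] = {
        "n": genotypes.n_individuals,
        "retained": int(keep.sum()),
        "fraction": keep.mean(),
    }
    if not keep.any():
        raise ValueError("all individuals removed by the purity filter")
    return genotypes.subset_individuals(keep), report


def panel_from_samples(
    genotypes: GenotypeMatrix,
    sample_a: str,
    sample_b: str,
    loci: Iterable[str] | None = None,
) -> ParentalPanel:
    """Build a parental panel from two reference samples in the data.

    Sample A is the *edulis*-like orientation (h = 1); panel sizes are
    the numbers of genotyped individuals.
    """
    from .popgen import allele_frequencies

    loci = list(loci) if loci is not None else list(genotypes.loci)
    fa = allele_frequencies(genotypes, sample_a)
    fb = allele_frequencies(genotypes, sample_b)
    freqs_a = {l: fa[l]["freq"].rename(None) for l in loci if len(fa[l])}
    freqs_b = {l: fb[l]["freq"].rename(None) for l in loci if len(fb[l])}
    common = sorted(set(freqs_a) & set(freqs_b))
    if not common:
        raise ValueError("reference samples share no genotyped loci")
    na = int((genotypes.samples == sample_a).sum())
    nb = int((genotypes.samples == sample_b).sum())
    return ParentalPanel(
        {l: freqs_a[l] for l in common}, {l: freqs_b[l] for l in common}, na, nb
    )
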