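"""Synthetic study systems: gridded flow fields and stepping-stone
metapopulation genotypes.

The generators produce data with the statistical structure the analysis
assumes — an asymmetric exchange field, microsatellites evolving under a
strict one-step stepwise mutation model, null alleles, missing data, and
introgression from a second parental gene pool — so that every
downstream stage can be exercised and its estimators checked against
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .genotypes import MISSING, GenotypeMatrix

#: M2 principal lunar semidiurnal tidal period, hours.
M2_PERIOD_H = 12.42

#: default per-gamete per-generation microsatellite mutation rate
DEFAULT_MUTATION_RATE = 0.001564


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

@dataclass
class FlowFieldSpec:
    """Parameters for a synthetic 2-D velocity field.

    The field is a steady residual circulation plus a spatially uniform
    tidal oscillation: ``u(x,y,t) = residual_u(x,y) + A·cos(2πt/T + φ_u)``
    (and likewise ``v`` with its own phase).  ``residual`` is either a
    constant ``(u, v)`` in m/s or the string ``"gyre"`` for an
    anticlockwise rotation around the domain centre.
    """

    extent_km: tuple[float, float] = (400.0, 300.0)
    resolution_km: float = 10.0
    duration_days: float = 84.0
    snapshot_interval_h: float = 1.0
    residual: Any = (0.05, 0.0)
    gyre_speed: float = 0.1
    tide_amplitude: float = 0.5
    tide_period_h: float = M2_PERIOD_H
    tide_phase: tuple[float, float] = (0.0, np.pi / 2)
    origin_lat: float | None = None
    origin_lon: float | None = None

    def __post_init__(self) -> None:
        if self.resolution_km <= 0 or self.snapshot_interval_h <= 0:
            raise ValueError("resolution and snapshot interval must be positive")
        if self.tide_period_h <= 0:
            raise ValueError("tidal period must be positive")
        if min(self.extent_km) <= 0 or self.duration_days <= 0:
            raise ValueError("extent and duration must be positive")


def make_flow_field(spec: FlowFieldSpec | None = None, seed: int | None = None, **kw) -> xr.Dataset:
    """Build a synthetic flow field on an x/y/t grid (km, km, hours).

    Velocities are in m/s.  The dataset carries ``origin_lat``/``origin_lon``
    attributes when set, anchoring the km plane to geographic coordinates
    at 111.19 km per degree.
    """
    if spec is None:
        spec = FlowFieldSpec(**kw)
    elif kw:
        raise TypeError("pass either a FlowFieldSpec or keyword arguments, not both")
    Lx, Ly = spec.extent_km
    x = np.arange(0.0, Lx + spec.resolution_km / 2, spec.resolution_km)
    y = np.arange(0.0, Ly + spec.resolution_km / 2, spec.resolution_km)
    t = np.arange(0.0, spec.duration_days * 24.0 + spec.snapshot_interval_h / 2,
                  spec.snapshot_interval_h)
    X, Y = np.meshgrid(x, y, indexing="xy")  # (ny, nx)

    if isinstance(spec.residual, str):
        if spec.residual != "gyre":
            raise ValueError(f"unknown residual spec {spec.residual!r}")
        # solid-body anticlockwise rotation, speed = gyre_speed at domain edge
        xc, yc = Lx / 2, Ly / 2
        rmax = max(xc, yc)
        ru = -spec.gyre_speed * (Y - yc) / rmax
        rv = spec.gyre_speed * (X - xc) / rmax
    elif callable(spec.residual):
        ru, rv = spec.residual(X, Y)
        ru, rv = np.broadcast_to(ru, X.shape), np.broadcast_to(rv, X.shape)
    else:
        u0, v0 = spec.residual
        ru = np.full_like(X, float(u0))
        rv = np.full_like(X, float(v0))

    omega = 2 * np.pi / spec.tide_period_h
    pu, pv = spec.tide_phase
    tide_u = spec.tide_amplitude * np.cos(omega * t + pu)
    tide_v = spec.tide_amplitude * np.cos(omega * t + pv)
    u = ru[None, :, :] + tide_u[:, None, None]
    v = rv[None, :, :] + tide_v[:, None, None]

    attrs = {"units_velocity": "m s-1", "units_xy": "km", "units_t": "h"}
    if spec.origin_lat is not None:
        attrs["origin_lat"] = float(spec.origin_lat)
    if spec.origin_lon is not None:
        attrs["origin_lon"] = float(spec.origin_lon)
    return xr.Dataset(
        {
            "u": (("t", "y", "x"), u),
            "v": (("t", "y", "x"), v),
        },
        coords={"t": t, "y": y, "x": x},
        attrs=attrs,
    )


# ---------------------------------------------------------------------------
# Wright–Fisher stepping-stone metapopulation
# ---------------------------------------------------------------------------

@dataclass
class PopSimSpec:
    """Forward Wright–Fisher simulation parameters.

    ``migration[i, j]`` is the probability that an offspring born in deme
    ``j`` draws its parents from deme ``i`` (backward migration; rows are
    source demes, columns destination demes).  Columns are renormalized to
    sum to 1.  Mutation follows the strict one-step stepwise model with a
    reflecting floor at repeat count 1.
    """

    n_demes: int
    deme_sizes: int | Sequence[int] = 50
    migration: np.ndarray | None = None
    n_loci: int = 7
    mutation_rate: float = DEFAULT_MUTATION_RATE
    n_generations: int = 200
    founder_n_alleles: int = 20
    founder_repeat_min: int = 11
    founder_pool: Mapping[str, pd.Series] | None = None
    deme_names: Sequence[str] | None = None
    locus_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        sizes = self.deme_sizes
        if np.isscalar(sizes):
            sizes = [int(sizes)] * self.n_demes
        sizes = [int(s) for s in sizes]
        if len(sizes) != self.n_demes:
            raise ValueError("deme_sizes length must equal n_demes")
        if min(sizes) < 2:
            raise ValueError("deme sizes must be >= 2")
        self.deme_sizes = sizes
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.migration is None:
            self.migration = np.eye(self.n_demes)
        M = np.asarray(self.migration, dtype=float)
        if M.shape != (self.n_demes, self.n_demes):
            raise ValueError(
                f"migration matrix shape {M.shape} != ({self.n_demes}, {self.n_demes})"
            )
        if (M < 0).any():
            raise ValueError("migration probabilities must be non-negative")
        colsum = M.sum(axis=0)
        if (colsum <= 0).any():
            raise ValueError("every migration column needs positive mass")
        self.migration = M / colsum
        if self.deme_names is None:
            width = len(str(self.n_demes))
            self.deme_names = [f"d{i + 1:0{width}d}" for i in range(self.n_demes)]
        if self.locus_names is None:
            self.locus_names = [f"L{j + 1}" for j in range(self.n_loci)]

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "PopSimSpec":
        d = dict(m)
        if "migration" in d and d["migration"] is not None:
            d["migration"] = np.asarray(d["migration"], dtype=float)
        return cls(**d)


def island_migration_matrix(n_demes: int, m: float) -> np.ndarray:
    """Finite island model: migrate with probability ``m``, uniformly over
    the other ``n_demes - 1`` demes; stay put with probability ``1 - m``."""
    if not 0 <= m <= 1:
        raise ValueError("migration rate m must be in [0, 1]")
    M = np.full((n_demes, n_demes), m / (n_demes - 1))
    np.fill_diagonal(M, 1 - m)
    return M


def stepping_stone_migration_matrix(n_demes: int, m: float) -> np.ndarray:
    """Linear stepping-stone: exchange ``m/2`` with each nearest neighbour."""
    M = np.eye(n_demes) * (1 - m)
    for j in range(n_demes):
        nbrs = [k for k in (j - 1, j + 1) if 0 <= k < n_demes]
        for k in nbrs:
            M[k, j] = m / len(nbrs)
    return M


@dataclass
class MetapopulationSim:
    """Result of a forward simulation: final genotypes + ground truth."""

    genotypes: GenotypeMatrix
    true_migration: pd.DataFrame  # rows = source deme, columns = destination
    spec: PopSimSpec


def simulate_metapopulation(spec: PopSimSpec, seed: int | None = None) -> MetapopulationSim:
    """Run a forward Wright–Fisher simulation and return final genotypes.

    Each generation every deme ``j`` produces ``deme_sizes[j]`` offspring
    (census conservation); each offspring draws a source deme from column
    ``j`` of the migration matrix, then two parents uniformly (with
    replacement) from that deme and one random allele per locus from each
    parent.  Transmitted alleles mutate ±1 repeat with probability
    ``mutation_rate``, reflecting at repeat 1.
    """
    rng = np.random.default_rng(seed)
    D, L = spec.n_demes, spec.n_loci
    sizes = list(spec.deme_sizes)
    M = spec.migration
    cum = M.cumsum(axis=0)

    # founder pool: equifrequent repeat ladder unless a table is supplied
    if spec.founder_pool is not None:
        pools = []
        for name in spec.locus_names:
            s = spec.founder_pool[name]
            pools.append((s.index.to_numpy(np.int64), s.to_numpy(float) / s.sum()))
    else:
        ladder = np.arange(
            spec.founder_repeat_min, spec.founder_repeat_min + spec.founder_n_alleles
        )
        pools = [(ladder, np.full(len(ladder), 1 / len(ladder)))] * L

    demes = []
    for n in sizes:
        geno = np.empty((n, L, 2), dtype=np.int64)
        for l, (alleles, freqs) in enumerate(pools):
            geno[:, l, :] = rng.choice(alleles, size=(n, 2), p=freqs)
        demes.append(geno)

    mu = spec.mutation_rate
    equal_sizes = len(set(sizes)) == 1
    size_arr = np.asarray(sizes)
    loc_idx = np.arange(L)[None, :]
    for _ in range(spec.n_generations):
        pool = np.stack(demes) if equal_sizes else None  # (D, n, L, 2)
        new_demes = []
        for j, n in enumerate(sizes):
            src = np.searchsorted(cum[:, j], rng.random(n))
            kid = np.empty((n, L, 2), dtype=np.int64)
            for copy in range(2):
                parent = (rng.random(n) * size_arr[src]).astype(np.int64)
                which = rng.integers(0, 2, size=(n, L))
                if pool is not None:
                    kid[:, :, copy] = pool[src[:, None], parent[:, None], loc_idx, which]
                else:
                    rows = np.stack([demes[s][p] for s, p in zip(src, parent)])
                    kid[:, :, copy] = rows[np.arange(n)[:, None], loc_idx, which]
            new_demes.append(kid)
        if mu > 0:
            for kid in new_demes:
                mask = rng.random(kid.shape) < mu
                if mask.any():
                    steps = rng.integers(0, 2, size=int(mask.sum())) * 2 - 1
                    vals = kid[mask] + steps
                    vals[vals < 1] = 2 - vals[vals < 1]  # reflect at repeat floor 1
                    kid[mask] = vals
        demes = new_demes

    alleles = np.concatenate(demes, axis=0)
    samples = np.repeat(np.asarray(spec.deme_names, dtype=object), sizes)
    individuals = np.array(
        [f"{d}_{i + 1:03d}" for d, n in zip(spec.deme_names, sizes) for i in range(n)],
        dtype=object,
    )
    gm = GenotypeMatrix(alleles, samples, individuals, list(spec.locus_names))
    mig = pd.DataFrame(M, index=list(spec.deme_names), columns=list(spec.deme_names))
    return MetapopulationSim(gm, mig, spec)


def subsample_individuals(
    gm: GenotypeMatrix, n_per_sample: int, seed: int | None = None
) -> GenotypeMatrix:
    """Random subsample of ``n_per_sample`` individuals from every sample."""
    rng = np.random.default_rng(seed)
    keep = np.zeros(gm.n_individuals, dtype=bool)
    for sample in gm.sample_names:
        idx = np.flatnonzero(gm.samples == sample)
        if len(idx) < n_per_sample:
            raise ValueError(f"sample {sample!r} has fewer than {n_per_sample} individuals")
        keep[rng.choice(idx, size=n_per_sample, replace=False)] = True
    return gm.subset_individuals(keep)


def migration_from_arrivals(
    proportions: pd.DataFrame, self_recruitment: float = 0.5
) -> pd.DataFrame:
    """Convert arrival proportions (rows = origin) into a backward migration
    matrix for :func:`simulate_metapopulation`.

    Column ``j`` is proportional to the particle flux into site ``j`` from
    every origin plus a local self-recruitment mass on the diagonal, then
    normalized to sum to 1.  The self-recruitment term represents larvae
    produced and retained locally; it keeps columns well defined for sites
    that receive no particles at all.
    """
    if self_recruitment <= 0:
        raise ValueError("self_recruitment must be positive")
    P = proportions.to_numpy(float).copy()
    M = P + self_recruitment * np.eye(len(P))
    M /= M.sum(axis=0)
    return pd.DataFrame(M, index=proportions.index, columns=proportions.columns)


# ---------------------------------------------------------------------------
# parental panels and hybrid introgression
# ---------------------------------------------------------------------------

@dataclass
class ParentalPanel:
    """Per-locus allele frequencies of two parental species.

    Species A is the *edulis*-like pool (hybrid index 1), species B the
    *galloprovincialis*-like pool (hybrid index 0).
    """

    freqs_a: dict[str, pd.Series]
    freqs_b: dict[str, pd.Series]
    n_a: int = 48
    n_b: int = 48

    def __post_init__(self) -> None:
        if set(self.freqs_a) != set(self.freqs_b):
            raise ValueError("panels must cover the same loci")
        for side in (self.freqs_a, self.freqs_b):
            for locus, s in side.items():
                total = float(s.sum())
                if not np.isclose(total, 1.0, atol=1e-8) or (s < 0).any():
                    raise ValueError(
                        f"panel frequencies at locus {locus!r} do not sum to 1 (got {total})"
                    )

    @property
    def loci(self) -> list[str]:
        return list(self.freqs_a)

    def is_identifiable(self) -> bool:
        """False when the two frequency tables are identical at every locus
        (the hybrid index is then undefined)."""
        for locus in self.loci:
            a, b = self.freqs_a[locus], self.freqs_b[locus]
            union = a.index.union(b.index)
            if not np.allclose(
                a.reindex(union, fill_value=0.0), b.reindex(union, fill_value=0.0)
            ):
                return True
        return False

    def private_alleles(self, locus: str) -> tuple[set[int], set[int]]:
        a = set(self.freqs_a[locus][self.freqs_a[locus] > 0].index)
        b = set(self.freqs_b[locus][self.freqs_b[locus] > 0].index)
        return a - b, b - a


def make_parental_panels(
    n_loci: int,
    n_private_per_locus: int = 4,
    shared_fraction: float = 0.0,
    seed: int | None = None,
    n_shared_per_locus: int = 4,
    panel_size: int = 48,
    locus_names: Sequence[str] | None = None,
) -> ParentalPanel:
    """Two parental reference panels with controllable overlap.

    ``shared_fraction`` is the frequency mass each species places on a
    common allele set (with identical frequencies, drawn once): 0 makes
    every locus fully diagnostic; 1 makes the two tables identical and the
    hybrid index unidentifiable.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    freqs_a: dict[str, pd.Series] = {}
    freqs_b: dict[str, pd.Series] = {}
    for locus in locus_names:
        shared = np.arange(101, 101 + n_shared_per_locus)
        priv_a = np.arange(201, 201 + n_private_per_locus)
        priv_b = np.arange(301, 301 + n_private_per_locus)
        shared_f = rng.dirichlet(np.full(len(shared), 2.0)) * shared_fraction
        fa = rng.dirichlet(np.full(len(priv_a), 2.0)) * (1 - shared_fraction)
        fb = rng.dirichlet(np.full(len(priv_b), 2.0)) * (1 - shared_fraction)
        a = pd.Series(
            np.concatenate([shared_f, fa]),
            index=np.concatenate([shared, priv_a]).astype(np.int64),
        )
        b = pd.Series(
            np.concatenate([shared_f, fb]),
            index=np.concatenate([shared, priv_b]).astype(np.int64),
        )
        freqs_a[locus] = a[a > 0] / a.sum() if a.sum() > 0 else a
        freqs_b[locus] = b[b > 0] / b.sum() if b.sum() > 0 else b
    return ParentalPanel(freqs_a, freqs_b, n_a=panel_size, n_b=panel_size)


def _draw_h(h_true, rng: np.random.Generator, n: int) -> np.ndarray:
    if callable(h_true):
        return np.asarray(h_true(rng, n), dtype=float)
    h = np.asarray(h_true, dtype=float)
    if h.ndim == 0:
        h = np.full(n, float(h))
    if len(h) != n:
        raise ValueError("h_true length must match the number of selected individuals")
    if ((h < 0) | (h > 1)).any():
        raise ValueError("h_true values must lie in [0, 1]")
    return h


def inject_hybrids(
    genotypes: GenotypeMatrix,
    panel: ParentalPanel,
    fraction: float,
    h_true=lambda rng, n: rng.beta(2.0, 2.0, size=n),
    seed: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replace a fraction of individuals with hybrid genotypes.

    Each allele copy of a selected individual is drawn from species A's
    frequencies with probability ``h`` and from species B's with
    probability ``1 - h`` (no linkage), at every panel locus that was
    called in the original genotype.  Returns the modified genotypes and a
    per-individual record of the true ``h`` (NaN for untouched
    individuals).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    missing_loci = set(panel.loci) - set(genotypes.loci)
    if missing_loci:
        raise ValueError(f"panel loci not present in genotypes: {sorted(missing_loci)}")
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    n_sel = int(round(fraction * n))
    selected = rng.choice(n, size=n_sel, replace=False) if n_sel else np.array([], int)
    h = _draw_h(h_true, rng, n_sel)

    alleles = genotypes.alleles.copy()
    loc_index = {l: j for j, l in enumerate(genotypes.loci)}
    for ind, h_i in zip(selected, h):
        for locus in panel.loci:
            j = loc_index[locus]
            if alleles[ind, j, 0] == MISSING:
                continue  # preserve missingness pattern
            for copy in range(2):
                side = panel.freqs_a if rng.random() < h_i else panel.freqs_b
                f = side[locus]
                alleles[ind, j, copy] = rng.choice(f.index.to_numpy(), p=f.to_numpy())
    out = GenotypeMatrix(alleles, genotypes.samples, genotypes.individuals, genotypes.loci)
    truth = pd.DataFrame(
        {
            "individual": genotypes.individuals,
            "sample": genotypes.samples,
            "true_h": np.nan,
        }
    )
    truth.loc[selected, "true_h"] = h
    return out, truth


# ---------------------------------------------------------------------------
# null alleles
# ---------------------------------------------------------------------------

def apply_null_alleles(
    genotypes: GenotypeMatrix,
    null_freq: float | Mapping[str, float],
    seed: int | None = None,
) -> GenotypeMatrix:
    """Silence allele copies independently with per-locus probability.

    A genotype with one silenced copy is recorded as homozygous for the
    visible allele (the classic null-allele artefact); both copies
    silenced yields a missing genotype.
    """
    if np.isscalar(null_freq):
        rates = {l: float(null_freq) for l in genotypes.loci}
    else:
        rates = {l: float(null_freq.get(l, 0.0)) for l in genotypes.loci}
    for l, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"null allele frequency for {l!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alleles = genotypes.alleles.copy()
    for j, locus in enumerate(genotypes.loci):
        r = rates[locus]
        if r == 0:
            continue
        called = (alleles[:, j, :] != MISSING).all(axis=1)
        silenced = rng.random((genotypes.n_individuals, 2)) < r
        silenced &= called[:, None]
        one = silenced.sum(axis=1) == 1
        both = silenced.all(axis=1)
        # single silenced copy -> apparent homozygote for the visible allele
        visible = np.where(silenced[one, 0], alleles[one, j, 1], alleles[one, j, 0])
        alleles[one, j, 0] = visible
        alleles[one, j, 1] = visible
        alleles[both, j, :] = MISSING
    return GenotypeMatrix(alleles, genotypes.samples, genotypes.individuals, genotypes.loci)
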