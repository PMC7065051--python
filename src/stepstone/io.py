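"""File formats: GenePop and long-CSV genotypes, labelled square matrices,
gridded flow fields.

Matrix convention, fixed package-wide: **rows are origins (sources),
columns are destinations**.  The convention is stated in the header of
every matrix file written, because the exchange matrices are asymmetric
and orientation mistakes are silent.

All writers accept provenance header lines (config hash + seed) which are
emitted as ``#``-prefixed comments and skipped on read.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import xarray as xr

from .genotypes import MISSING, GenotypeMatrix

_ORIENTATION_NOTE = "orientation: rows = origin/source, columns = destination"


def _write_header(fh, header_lines: Iterable[str] | None, orientation: bool = False):
    for line in header_lines or ():
        fh.write(f"# {line}\n")
    if orientation:
        fh.write(f"# {_ORIENTATION_NOTE}\n")


# ---------------------------------------------------------------------------
# labelled square matrices (arrival counts, FST, distances, migration)
# ---------------------------------------------------------------------------

def write_matrix_csv(
    path: str | Path,
    matrix: pd.DataFrame,
    header_lines: Iterable[str] | None = None,
) -> None:
    """Write a labelled square matrix (rows = origin, columns = destination)."""
    _check_square(matrix)
    with open(path, "w") as fh:
        _write_header(fh, header_lines, orientation=True)
        matrix.to_csv(fh)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a labelled square matrix written by :func:`write_matrix_csv`."""
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_square(df)
    return df


def _check_square(df: pd.DataFrame) -> None:
    rows, cols = list(map(str, df.index)), list(map(str, df.columns))
    if set(rows) != set(cols) or len(rows) != len(cols):
        only_r = sorted(set(rows) - set(cols))
        only_c = sorted(set(cols) - set(rows))
        raise ValueError(
            "row/column label mismatch in square matrix: "
            f"rows-only={only_r}, columns-only={only_c}"
        )


# ---------------------------------------------------------------------------
# genotypes: long CSV
# ---------------------------------------------------------------------------

def read_genotypes_long_csv(path: str | Path) -> GenotypeMatrix:
    """Long CSV with columns sample,individual,locus,allele1,allele2; 0 = missing."""
    df = pd.read_csv(path, comment="#")
    return GenotypeMatrix.from_long_frame(df)


def write_genotypes_long_csv(
    path: str | Path,
    genotypes: GenotypeMatrix,
    header_lines: Iterable[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, header_lines)
        genotypes.to_long_frame().to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# genotypes: GenePop (3-digit allele coding, 0 = missing)
# ---------------------------------------------------------------------------

def write_genepop(
    path: str | Path,
    genotypes: GenotypeMatrix,
    title: str = "stepstone export",
    header_lines: Iterable[str] | None = None,
) -> None:
    """Write genotypes in GenePop format with 3-digit allele coding.

    Allele labels must be < 1000 to fit the coding; sample membership is
    encoded by ``Pop`` blocks in first-appearance order.
    """
    if genotypes.alleles.max(initial=0) > 999:
        raise ValueError("GenePop 3-digit coding requires allele labels <= 999")
    with open(path, "w") as fh:
        for line in header_lines or ():
            title += f" | {line}"
        fh.write(title + "\n")
        for locus in genotypes.loci:
            fh.write(locus + "\n")
        for sample in genotypes.sample_names:
            fh.write("Pop\n")
            mask = genotypes.samples == sample
            for ind, row in zip(genotypes.individuals[mask], genotypes.alleles[mask]):
                codes = " ".join(f"{a1:03d}{a2:03d}" for a1, a2 in row)
                fh.write(f"{sample}:{ind} ,  {codes}\n")


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a GenePop file (3-digit coding; ``Pop`` separators, 0 = missing)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"GenePop file {path} too short")
    body = lines[1:]
    # locus names: either one per line or a single comma-separated line
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = [s.strip() for s in body[i].split(",") if s.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(body):
        raise ValueError(f"GenePop file {path} has no Pop blocks")
    records: list[tuple[str, str, list[int]]] = []
    pop_counter = 0
    sample_label = None
    for line in body[i:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_counter += 1
            sample_label = None
            continue
        if "," not in s:
            raise ValueError(f"malformed GenePop record (no comma): {s!r}")
        name, geno = s.split(",", 1)
        name = name.strip()
        if ":" in name:
            sample_label, ind = name.split(":", 1)
        else:
            sample_label = sample_label or f"pop{pop_counter}"
            ind = name
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"record {name!r} has {len(codes)} genotypes, expected {len(loci)}"
            )
        alleles = []
        for locus, code in zip(loci, codes):
            if not re.fullmatch(r"\d{4}|\d{6}", code):
                raise ValueError(f"bad GenePop genotype code {code!r} for {name!r}")
            w = len(code) // 2
            a1, a2 = int(code[:w]), int(code[w:])
            if (a1 == MISSING) != (a2 == MISSING):
                raise ValueError(
                    f"haploid record: individual {name!r} locus {locus!r} code {code!r}"
                )
            alleles.extend([a1, a2])
        records.append((sample_label, ind.strip(), alleles))
    arr = np.array([r[2] for r in records], dtype=np.int64).reshape(len(records), len(loci), 2)
    return GenotypeMatrix(
        arr,
        np.array([r[0] for r in records], dtype=object),
        np.array([r[1] for r in records], dtype=object),
        loci,
    )


def read_genotype_table(
    path: str | Path, dialect: Literal["genepop", "long_csv"] = "long_csv"
) -> GenotypeMatrix:
    """Read diploid genotypes from GenePop or long CSV."""
    if dialect == "genepop":
        return read_genepop(path)
    if dialect == "long_csv":
        return read_genotypes_long_csv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

def write_flow_field(path: str | Path, flow: xr.Dataset) -> None:
    """Persist a flow field (u, v on x/y/t) as netCDF."""
    flow.to_netcdf(path)


def read_flow_field(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path) as ds:
        return ds.load()
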