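import numpy as np
import pandas as pd
import pytest

from stepstone.genotypes import GenotypeMatrix
from stepstone.sites import SiteTable


def make_genotypes(records, loci):
    """Build a GenotypeMatrix from [(sample, individual, [(a1, a2), ...]), ...]."""
    alleles = np.array([[list(g) for g in r[2]] for r in records], dtype=np.int64)
    return GenotypeMatrix(
        alleles,
        np.array([r[0] for r in records], dtype=object),
        np.array([r[1] for r in records], dtype=object),
        list(loci),
    )


@pytest.fixture
def two_sample_genotypes():
    """Two samples x two individuals x one locus."""
    return make_genotypes(
        [
            ("A", "a1", [(100, 100)]),
            ("A", "a2", [(100, 120)]),
            ("B", "b1", [(120, 120)]),
            ("B", "b2", [(100, 120)]),
        ],
        ["L1"],
    )


@pytest.fixture
def fixed_difference_genotypes():
    """Two samples fixed for different alleles, all homozygous."""
    recs = [("A", f"a{i}", [(100, 100)]) for i in range(4)]
    recs += [("B", f"b{i}", [(120, 120)]) for i in range(4)]
    return make_genotypes(recs, ["L1"])


@pytest.fixture
def line_sites():
    """Four sites on a line, 20 km apart, in the km plane and as lat/lon."""
    ids = ["A", "B", "C", "D"]
    x = np.array([20.0, 40.0, 60.0, 80.0])
    y = np.full(4, 25.0)
    table = SiteTable(
        pd.DataFrame({"site_id": ids, "lat": y / 111.19, "lon": x / 111.19})
    )
    positions = pd.DataFrame(
        {"x_km": x, "y_km": y}, index=pd.Index(ids, name="site_id")
    )
    return table, positions
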