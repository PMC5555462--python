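import numpy as np
import pandas as pd
import pytest

import rcscan as rc


@pytest.fixture(scope="session")
def default_map():
    return rc.default_marker_map()


@pytest.fixture(scope="session")
def small_map():
    """Three-chromosome toy map: cheap to breed, still multi-chromosome."""
    rows = []
    for chrom, n, length in (("1", 30, 90.0), ("2", 20, 60.0), ("4", 25, 100.0)):
        for j in range(n):
            pos = (j + 0.5) * length / n
            rows.append(
                {
                    "marker": f"c{chrom}_{j + 1}",
                    "chrom": chrom,
                    "pos_bp": int(pos * 1e6),
                    "pos_cm": pos * 0.5,
                }
            )
    return rc.MarkerMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def bred_panel(small_map):
    """31-strain RCS panel on the toy map (10 AcB + 21 BcA), fixed seed."""
    return rc.breed_rcs_panel(rc.BreedingConfig(seed=11), small_map)


def make_phenotypes(groups: dict, condition: str = "baseline") -> pd.DataFrame:
    """Phenotype frame from {strain: iterable of IgE values} (linear scale)."""
    rows = []
    i = 0
    for strain, values in groups.items():
        for v in values:
            i += 1
            rows.append(
                {
                    "animal_id": f"a{i:04d}",
                    "strain": strain,
                    "condition": condition,
                    "ige_ng_ml": float(v),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def pheno_factory():
    return make_phenotypes
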