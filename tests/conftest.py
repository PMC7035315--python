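import numpy as np
import pandas as pd
import pytest

from ibexload import CohortSpec, GenotypeTable, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two focal populations + three outgroup species, a little missingness."""
    spec = CohortSpec(
        n_populations=2,
        n_individuals_per_population=10,
        n_sites_per_category={c: 150 for c in
                              ("modifier", "low", "moderate", "high", "intergenic")},
        missing_rate=0.02,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def tiny_table():
    """Ten hand-planted sites x four samples for brute-force tallies."""
    rng = np.random.default_rng(5)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5 + ["chr2"] * 5,
            "pos": list(range(100, 600, 100)) * 2,
            "ref": ["A"] * 10,
            "alt": ["T"] * 10,
        }
    )
    dosage = rng.integers(0, 3, size=(10, 4)).astype(np.int8)
    dosage[3, 1] = -1  # one missing call
    return GenotypeTable(sites, dosage, ["w", "x", "y", "z"])


def site_info_for(table, impact="modifier", derived="ALT"):
    """Minimal polarized site-info frame aligned with a genotype table."""
    return pd.DataFrame(
        {
            "chrom": table.sites["chrom"],
            "pos": table.sites["pos"],
            "impact": impact,
            "derived_allele": derived,
        }
    )
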