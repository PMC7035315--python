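"""Shared in-memory containers for the empirical pipeline.

The common currency is a :class:`GenotypeTable`: a sites × samples matrix of
diploid alternative-allele dosages (0, 1, 2; ``-1`` for missing) together
with per-site metadata (chromosome, 1-based position, REF, ALT).  A *sample
manifest* (a plain :class:`pandas.DataFrame`) maps each sample column to a
population and species and marks outgroup samples used for derived-allele
polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")
MANIFEST_COLUMNS = ("sample", "population", "species", "role")


@dataclass
class GenotypeTable:
    """Diploid biallelic genotypes for a set of sites and samples.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (1-based positions).
        An ``alt`` value containing a comma marks a multiallelic record kept
        only so downstream polarization can flag it UNKNOWN.
    dosage
        ``(n_sites, n_samples)`` int8 array of ALT-allele dosages;
        ``MISSING`` (−1) encodes an uncalled genotype.
    samples
        Sample names, one per dosage column.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (sites x samples)")
        if len(self.sites) != self.dosage.shape[0]:
            raise ValueError(
                f"sites ({len(self.sites)}) and dosage rows "
                f"({self.dosage.shape[0]}) disagree"
            )
        if len(self.samples) != self.dosage.shape[1]:
            raise ValueError(
                f"samples ({len(self.samples)}) and dosage columns "
                f"({self.dosage.shape[1]}) disagree"
            )
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites table lacks columns {missing_cols}")
        self.sites = self.sites.reset_index(drop=True)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    # -- views -------------------------------------------------------------
    def subset_samples(self, names) -> "GenotypeTable":
        idx = self.sample_indices(names)
        return GenotypeTable(self.sites.copy(), self.dosage[:, idx], list(names))

    def subset_sites(self, selector) -> "GenotypeTable":
        selector = np.asarray(selector)
        if selector.dtype == bool:
            selector = np.flatnonzero(selector)
        return GenotypeTable(
            self.sites.iloc[selector], self.dosage[selector], self.samples
        )

    # -- derived quantities -------------------------------------------------
    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes (sites x samples)."""
        return self.dosage != MISSING

    def genotype_rate(self) -> np.ndarray:
        """Fraction of called genotypes per site."""
        return self.called().mean(axis=1)

    def alt_frequency(self, sample_names=None) -> np.ndarray:
        """Per-site ALT allele frequency over called genotypes.

        Sites with no called genotype in the chosen sample set get NaN.
        """
        if sample_names is None:
            dos = self.dosage
        else:
            dos = self.dosage[:, self.sample_indices(sample_names)]
        called = dos != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, dos, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.dosage, other.dosage)
            and self.sites[list(SITE_COLUMNS)]
            .reset_index(drop=True)
            .equals(other.sites[list(SITE_COLUMNS)].reset_index(drop=True))
        )


# -- sample manifest helpers ---------------------------------------------


def make_manifest(records) -> pd.DataFrame:
    """Build a manifest DataFrame from (sample, population, species, role)."""
    df = pd.DataFrame(records, columns=list(MANIFEST_COLUMNS))
    bad = set(df["role"]) - {"focal", "outgroup"}
    if bad:
        raise ValueError(f"manifest roles must be focal/outgroup, got {bad}")
    return df


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    return manifest


def focal_populations(manifest: pd.DataFrame) -> list:
    m = validate_manifest(manifest)
    return sorted(m.loc[m["role"] == "focal", "population"].unique())


def population_samples(manifest: pd.DataFrame, population: str) -> list:
    m = validate_manifest(manifest)
    out = m.loc[
        (m["population"] == population) & (m["role"] == "focal"), "sample"
    ].tolist()
    if not out:
        raise KeyError(f"no focal samples for population {population!r}")
    return out


def outgroup_samples(manifest: pd.DataFrame) -> list:
    m = validate_manifest(manifest)
    return m.loc[m["role"] == "outgroup", "sample"].tolist()


def outgroup_species(manifest: pd.DataFrame) -> dict:
    """Map species name -> list of outgroup sample names."""
    m = validate_manifest(manifest)
    og = m[m["role"] == "outgroup"]
    return {sp: grp["sample"].tolist() for sp, grp in og.groupby("species")}
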