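"""Self-contained synthetic cohorts with known, planted structure.

Fixtures emulate the layout of a multi-species resequencing study: several
focal populations plus outgroup species genotyped jointly, per-site impact
annotations (functional impact category, conservation scores, expression
support), an intergenic control SNP set, and GATK-style INFO fields for hard
filtering.  Every downstream stage can therefore be tested against a truth
table without any external download.

Model: each site's derived-allele frequency is drawn per population from a
category-specific Beta distribution; individual genotypes are Binomial(2, f)
(Hardy–Weinberg within population).  Sites are unlinked — the empirical
statistics treat sites marginally, so linkage is deliberately not modelled.
Outgroup species are written as extra sample columns fixed for the ancestral
(REF) allele, so ALT is the true derived allele at every generated site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeTable, make_manifest
from .vcfio import read_tsv, read_vcf, write_tsv, write_vcf

CATEGORIES = ("modifier", "low", "moderate", "high", "intergenic")

# Plausible annotation-score ranges per category.  Coding categories are
# generated to pass the expression/conservation retention filter; intergenic
# control sites are flagged and carry no expression support.
_SCORE_RANGES = {
    #               gerp         phylop       fpkm
    "modifier": ((-1.5, 2.0), (-1.0, 1.0), (0.5, 20.0)),
    "low": ((-1.0, 2.0), (-0.5, 1.5), (0.5, 30.0)),
    "moderate": ((2.0, 4.0), (1.0, 3.0), (0.5, 30.0)),
    "high": ((4.0, 8.0), (2.0, 6.0), (0.5, 30.0)),
    "intergenic": ((-1.5, 1.5), (-1.0, 1.0), (0.0, 0.0)),
}

_BASES = ("A", "C", "G", "T")


@dataclass
class CohortSpec:
    """Specification of a synthetic multi-population cohort.

    ``beta_params`` maps category -> (alpha, beta) of the per-site derived
    frequency distribution, either one pair shared by all populations or a
    list with one pair per population.
    """

    n_populations: int = 2
    n_individuals_per_population: object = 10
    n_outgroup_species: int = 3
    n_individuals_per_outgroup: int = 2
    n_sites_per_category: dict = field(
        default_factory=lambda: {c: 200 for c in CATEGORIES}
    )
    beta_params: dict = field(
        default_factory=lambda: {
            "modifier": (0.5, 2.0),
            "low": (0.5, 2.5),
            "moderate": (0.4, 3.0),
            "high": (0.2, 4.0),
            "intergenic": (0.5, 2.0),
        }
    )
    missing_rate: float = 0.0
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self):
        if int(self.n_populations) < 1:
            raise ValueError("n_populations: must be >= 1")
        self.n_populations = int(self.n_populations)
        if np.isscalar(self.n_individuals_per_population):
            self.n_individuals_per_population = [
                int(self.n_individuals_per_population)
            ] * self.n_populations
        else:
            self.n_individuals_per_population = [
                int(x) for x in self.n_individuals_per_population
            ]
        if len(self.n_individuals_per_population) != self.n_populations:
            raise ValueError(
                "n_individuals_per_population: need one count per population"
            )
        if any(n < 1 for n in self.n_individuals_per_population):
            raise ValueError("n_individuals_per_population: counts must be >= 1")
        if self.n_outgroup_species < 1:
            raise ValueError("n_outgroup_species: must be >= 1")
        if self.n_individuals_per_outgroup < 1:
            raise ValueError("n_individuals_per_outgroup: must be >= 1")
        for cat, n in self.n_sites_per_category.items():
            if cat not in CATEGORIES:
                raise ValueError(f"n_sites_per_category: unknown category {cat!r}")
            if int(n) < 1:
                raise ValueError(f"n_sites_per_category[{cat}]: must be >= 1")
        for cat, params in self.beta_params.items():
            if cat not in CATEGORIES:
                raise ValueError(f"beta_params: unknown category {cat!r}")
            for pair in self._beta_pairs(cat):
                a, b = pair
                if not (a > 0 and b > 0):
                    raise ValueError(
                        f"beta_params[{cat}]: alpha/beta must be positive"
                    )
        if not 0.0 <= float(self.missing_rate) < 1.0:
            raise ValueError("missing_rate: must be in [0, 1)")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes: must be >= 1")

    def _beta_pairs(self, category) -> list:
        params = self.beta_params[category]
        if np.isscalar(params[0]):
            return [tuple(params)] * self.n_populations
        if len(params) != self.n_populations:
            raise ValueError(
                f"beta_params[{category}]: need one (alpha, beta) per population"
            )
        return [tuple(p) for p in params]


@dataclass
class Cohort:
    """A generated cohort: genotypes + manifest + annotations + truth."""

    genotypes: GenotypeTable
    manifest: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec | None = None

    @property
    def populations(self) -> list:
        m = self.manifest
        return sorted(m.loc[m["role"] == "focal", "population"].unique())


def _site_metadata(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Lay sites out over chromosomes, 100 bp apart, category-blocked."""
    rows = []
    per_chrom_pos = {f"chr{c + 1}": 1000 for c in range(spec.n_chromosomes)}
    chrom_names = list(per_chrom_pos)
    i = 0
    for cat in CATEGORIES:
        n = spec.n_sites_per_category.get(cat, 0)
        for _ in range(n):
            chrom = chrom_names[i % spec.n_chromosomes]
            pos = per_chrom_pos[chrom]
            per_chrom_pos[chrom] += 100
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "id": f"site{i}",
                    "ref": _BASES[ref],
                    "alt": _BASES[alt],
                    "category": cat,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort from the Beta-Binomial model of ``spec``.

    Returns genotypes for focal populations and outgroup species (outgroups
    fixed homozygous-reference: ALT is derived by construction), a sample
    manifest, the per-site annotation table, and a truth table recording each
    site's category, true derived allele, and true per-population frequency.
    """
    rng = np.random.default_rng(spec.seed)
    meta = _site_metadata(spec, rng)
    n_sites = len(meta)

    pops = [f"pop{p + 1}" for p in range(spec.n_populations)]
    samples, manifest_rows = [], []
    for p, pop in enumerate(pops):
        for k in range(spec.n_individuals_per_population[p]):
            name = f"{pop}_ind{k + 1}"
            samples.append(name)
            manifest_rows.append((name, pop, "focal_species", "focal"))
    for s in range(spec.n_outgroup_species):
        sp = f"outgroup{s + 1}"
        for k in range(spec.n_individuals_per_outgroup):
            name = f"{sp}_ind{k + 1}"
            samples.append(name)
            manifest_rows.append((name, sp, sp, "outgroup"))
    manifest = make_manifest(manifest_rows)
    n_focal = sum(spec.n_individuals_per_population)
    n_out = spec.n_outgroup_species * spec.n_individuals_per_outgroup

    dosage = np.zeros((n_sites, n_focal + n_out), dtype=np.int8)
    truth_freq = np.zeros((n_sites, spec.n_populations))
    for cat in CATEGORIES:
        mask = (meta["category"] == cat).to_numpy()
        n_cat = int(mask.sum())
        if n_cat == 0:
            continue
        col0 = 0
        for p in range(spec.n_populations):
            a, b = spec._beta_pairs(cat)[p]
            n_ind = spec.n_individuals_per_population[p]
            freqs = rng.beta(a, b, size=n_cat)
            truth_freq[mask, p] = freqs
            geno = rng.binomial(2, freqs[:, None], size=(n_cat, n_ind))
            dosage[np.ix_(mask, np.arange(col0, col0 + n_ind))] = geno
            col0 += n_ind
    # outgroup columns stay 0 (fixed ancestral)

    if spec.missing_rate > 0:
        drop = rng.random(dosage.shape) < spec.missing_rate
        dosage[drop] = MISSING

    # annotation scores drawn inside category-typical ranges
    ann_rows = {
        "chrom": meta["chrom"],
        "pos": meta["pos"],
        "ref": meta["ref"],
        "alt": meta["alt"],
        "snpeff_category": meta["category"].where(
            meta["category"] != "intergenic", "modifier"
        ),
        "intergenic": (meta["category"] == "intergenic").astype(int),
    }
    gerp = np.empty(n_sites)
    phylop = np.empty(n_sites)
    fpkm = np.empty(n_sites)
    phastcons = np.empty(n_sites)
    for cat in CATEGORIES:
        mask = (meta["category"] == cat).to_numpy()
        n_cat = int(mask.sum())
        if n_cat == 0:
            continue
        (g_lo, g_hi), (p_lo, p_hi), (f_lo, f_hi) = _SCORE_RANGES[cat]
        gerp[mask] = rng.uniform(g_lo, g_hi, n_cat)
        phylop[mask] = rng.uniform(p_lo, p_hi, n_cat)
        fpkm[mask] = rng.uniform(f_lo, f_hi, n_cat) if f_hi > f_lo else f_lo
        phastcons[mask] = (
            1.0 if cat == "high" else np.round(rng.uniform(0, 0.99, n_cat), 3)
        )
    annotation = pd.DataFrame(
        {
            **ann_rows,
            "gerp": np.round(gerp, 3),
            "phylop": np.round(phylop, 3),
            "phastcons": phastcons,
            "max_fpkm": np.round(fpkm, 3),
        }
    )[
        [
            "chrom",
            "pos",
            "ref",
            "alt",
            "snpeff_category",
            "gerp",
            "phylop",
            "phastcons",
            "max_fpkm",
            "intergenic",
        ]
    ]

    truth = meta[["chrom", "pos", "id", "category"]].copy()
    truth["derived_allele"] = "ALT"
    for p, pop in enumerate(pops):
        truth[f"true_freq_{pop}"] = np.round(truth_freq[:, p], 6)

    table = GenotypeTable(meta[["chrom", "pos", "id", "ref", "alt"]], dosage, samples)
    return Cohort(table, manifest, annotation, truth, spec)


# -- hard-filter fixture --------------------------------------------------

# values safely inside / outside each GATK threshold
_PASS_RANGES = {
    "QD": (10.0, 30.0),
    "FS": (0.0, 10.0),
    "SOR": (0.5, 2.0),
    "MQ": (40.0, 60.0),
    "MQRankSum": (-2.0, 2.0),
    "ReadPosRankSum": (-2.0, 2.0),
}
_FAIL_VALUES = {
    "QD": 1.0,
    "FS": 60.0,
    "SOR": 6.0,
    "MQ": 10.0,
    "MQRankSum": 4.0,
    "ReadPosRankSum": -4.0,
    "AN": 40,
}


def generate_filter_fixture(
    n_sites: int, fraction_failing: float, seed: int, n_samples: int = 4
):
    """VCF fixture for the hard-filter stage.

    Exactly ``round(n_sites * fraction_failing)`` sites violate at least one
    GATK threshold; the rest sit safely inside every pass range.  Returns
    ``(genotype_table, info_df, failing_ids)`` where ``failing_ids`` is the
    truth list of site IDs that must fail.
    """
    if not 0.0 <= fraction_failing <= 1.0:
        raise ValueError("fraction_failing: must be in [0, 1]")
    if n_sites < 1:
        raise ValueError("n_sites: must be >= 1")
    rng = np.random.default_rng(seed)
    n_fail = int(round(n_sites * fraction_failing))
    fail_idx = set(rng.choice(n_sites, size=n_fail, replace=False).tolist())

    rows, info_rows = [], []
    for i in range(n_sites):
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            {
                "chrom": "chr1",
                "pos": 1000 + 10 * i,
                "id": f"fs{i}",
                "ref": _BASES[ref],
                "alt": _BASES[alt],
            }
        )
        rec = {
            key: round(rng.uniform(lo, hi), 3) for key, (lo, hi) in _PASS_RANGES.items()
        }
        rec["AN"] = int(2 * n_samples * 16)  # comfortably above AN threshold
        if i in fail_idx:
            # violate one to three thresholds
            keys = rng.choice(
                list(_FAIL_VALUES), size=rng.integers(1, 4), replace=False
            )
            for key in keys:
                rec[key] = _FAIL_VALUES[key]
        info_rows.append(rec)
    sites = pd.DataFrame(rows)
    dosage = rng.integers(0, 3, size=(n_sites, n_samples), dtype=np.int8)
    table = GenotypeTable(sites, dosage, [f"s{j + 1}" for j in range(n_samples)])
    info = pd.DataFrame(info_rows)
    failing_ids = [f"fs{i}" for i in sorted(fail_idx)]
    return table, info, failing_ids


# -- bundle I/O -----------------------------------------------------------

_BUNDLE_FILES = {
    "vcf": "cohort.vcf",
    "annotation": "annotation.tsv",
    "manifest": "manifest.tsv",
    "controls": "control_sites.tsv",
    "truth": "truth_sites.tsv",
    "scenario": "scenario.yaml",
}


def write_fixture_bundle(cohort: Cohort, directory, scenario: dict | None = None):
    """Write the cohort as a fixture bundle (VCF + TSVs + scenario file).

    Re-reading with :func:`read_fixture_bundle` reproduces the in-memory
    objects exactly.  Returns the mapping of logical name -> path.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = {k: directory / v for k, v in _BUNDLE_FILES.items()}
        write_vcf(paths["vcf"], cohort.genotypes)
        write_tsv(paths["annotation"], cohort.annotation)
        write_tsv(paths["manifest"], cohort.manifest)
        controls = cohort.truth.loc[
            cohort.truth["category"] == "intergenic", ["chrom", "pos", "id"]
        ]
        write_tsv(paths["controls"], controls)
        write_tsv(paths["truth"], cohort.truth)
        if scenario is None:
            scenario = {"patches": [{"name": "p1", "k": 100}], "events": []}
        with open(paths["scenario"], "w") as fh:
            yaml.safe_dump(scenario, fh, sort_keys=False)
    except OSError as exc:
        raise OSError(f"cannot write fixture bundle under {directory}: {exc}") from exc
    return paths


def read_fixture_bundle(directory) -> Cohort:
    directory = Path(directory)
    paths = {k: directory / v for k, v in _BUNDLE_FILES.items()}
    table, _info = read_vcf(paths["vcf"])
    table = GenotypeTable(
        table.sites[["chrom", "pos", "id", "ref", "alt"]], table.dosage, table.samples
    )
    manifest = read_tsv(paths["manifest"])
    annotation = read_tsv(paths["annotation"])
    truth = read_tsv(paths["truth"])
    return Cohort(table, manifest, annotation, truth)
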