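"""Population-genetic summaries of deleterious mutation load.

Implemented statistics: category-stratified site frequency spectra (SFS),
per-individual derived-allele and derived-homozygote counts, the Rxy
relative derived-allele statistic with intergenic-control standardization
and delete-one-chromosome jackknifing, nucleotide diversity, per-individual
heterozygosity, a sliding-window run-of-homozygosity (ROH) scanner with
PLINK-style parameters, F_ROH, and downsampling replicates.

Rxy compares derived-allele abundance of a mutation class between two
populations X and Y.  With ``f_i^X`` the derived-allele frequency at site i
among called genotypes of X,

    L_XnotY = Σ_i f_i^X (1 − f_i^Y),    L_YnotX = Σ_i f_i^Y (1 − f_i^X)

and Rxy = (L_XnotY / L_YnotX) ÷ (L′_XnotY / L′_YnotX), where the primed
sums run over a putatively neutral (intergenic) control SNP set.  The
standardization makes the ratio robust to sample-size differences and
population substructure (Do et al. 2015).  Rxy < 1 indicates a relative
deficit of the class in X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


# -- site alignment helper -------------------------------------------------


def align_to_sites(table: GenotypeTable, site_df: pd.DataFrame) -> GenotypeTable:
    """Subset ``table`` to the (chrom, pos) rows of ``site_df``, in order."""
    key = table.sites.assign(_row=np.arange(table.n_sites))
    merged = site_df[["chrom", "pos"]].merge(
        key[["chrom", "pos", "_row"]], on=["chrom", "pos"], how="left"
    )
    if merged["_row"].isna().any():
        missing = merged[merged["_row"].isna()]
        raise KeyError(
            f"{len(missing)} sites not found in genotype table "
            f"(first: {missing.iloc[0]['chrom']}:{missing.iloc[0]['pos']})"
        )
    return table.subset_sites(merged["_row"].to_numpy(int))


# -- site frequency spectrum ----------------------------------------------


@dataclass
class SFS:
    """Histogram of derived-allele counts across segregating sites.

    ``counts[i]`` is the number of sites with derived-allele count ``i + 1``
    in a sample of ``n`` diploids; indices run over 1..2n−1 (monomorphic
    classes excluded).
    """

    category: str
    counts: np.ndarray
    n: int

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    def binned(self, bin_edges=None, max_unbinned: int = 10) -> pd.DataFrame:
        """Display form: exact counts up to ``max_unbinned``, then the mean
        number of sites per allele-count value within each interval.

        ``bin_edges`` are inclusive (lo, hi) pairs over the derived-count
        axis; default: intervals of width 5 from ``max_unbinned + 1``.
        """
        rows = [
            {"bin": str(i + 1), "sites_per_count": float(self.counts[i])}
            for i in range(min(max_unbinned, len(self.counts)))
        ]
        top = len(self.counts)
        if bin_edges is None:
            bin_edges = [
                (lo, min(lo + 4, top)) for lo in range(max_unbinned + 1, top + 1, 5)
            ]
        for lo, hi in bin_edges:
            width = hi - lo + 1
            total = self.counts[lo - 1 : hi].sum()
            rows.append(
                {"bin": f"{lo}-{hi}", "sites_per_count": float(total) / width}
            )
        return pd.DataFrame(rows)


def sfs_by_category(
    table: GenotypeTable,
    site_info: pd.DataFrame,
    samples,
    category: str,
    category_column: str = "impact",
) -> SFS:
    """SFS of derived-allele counts for one mutation category.

    ``site_info`` is aligned row-for-row with ``table.sites`` and carries
    ``derived_allele`` plus the category column.  Sites with any missing
    call among ``samples`` and sites monomorphic in the subset are excluded.
    """
    if len(site_info) != table.n_sites:
        raise ValueError("site_info must align with the genotype table")
    keep = (
        (site_info[category_column].to_numpy() == category)
        & (site_info["derived_allele"].to_numpy() == "ALT")
    )
    idx = table.sample_indices(samples)
    dos = table.dosage[:, idx]
    complete = (dos != MISSING).all(axis=1)
    keep &= complete
    n = len(idx)
    counts = np.zeros(max(2 * n - 1, 0), dtype=np.int64)
    if not keep.any():
        logger.warning("empty SFS for category %r", category)
        return SFS(category, counts, n)
    derived = dos[keep].sum(axis=1)
    seg = (derived > 0) & (derived < 2 * n)
    vals, freq = np.unique(derived[seg], return_counts=True)
    counts[vals - 1] = freq
    return SFS(category, counts, n)


# -- individual counts -----------------------------------------------------


def individual_counts(
    table: GenotypeTable,
    site_info: pd.DataFrame,
    samples,
    category_column: str = "impact",
    max_missing_rate: float = 0.1,
) -> pd.DataFrame:
    """Per-individual derived-allele and derived-homozygote counts.

    Sites with a missing rate above ``max_missing_rate`` (computed over
    ``samples``) or with unknown derived state are dropped; an individual's
    own missing genotypes simply do not count.  Returns one row per
    (individual, category).
    """
    if len(site_info) != table.n_sites:
        raise ValueError("site_info must align with the genotype table")
    idx = table.sample_indices(samples)
    dos = table.dosage[:, idx]
    called = dos != MISSING
    site_ok = (
        ((~called).mean(axis=1) <= max_missing_rate)
        & (site_info["derived_allele"].to_numpy() == "ALT")
    )
    rows = []
    for cat in pd.unique(site_info[category_column].dropna()):
        mask = site_ok & (site_info[category_column].to_numpy() == cat)
        sub = dos[mask]
        sub_called = sub != MISSING
        alleles = np.where(sub_called, sub, 0).sum(axis=0)
        homs = ((sub == 2) & sub_called).sum(axis=0)
        for j, name in enumerate(samples):
            rows.append(
                {
                    "individual": name,
                    "category": cat,
                    "derived_alleles": int(alleles[j]),
                    "derived_homozygotes": int(homs[j]),
                    "n_sites_used": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


# -- Rxy -------------------------------------------------------------------


@dataclass
class RxyResult:
    """Point estimate of Rxy plus its jackknife distribution."""

    category: str
    rxy: float
    pseudovalues: np.ndarray = field(default_factory=lambda: np.array([]))
    blocks: list = field(default_factory=list)
    n_category_sites: int = 0
    n_control_sites: int = 0

    @property
    def jackknife_se(self) -> float:
        pv = self.pseudovalues[~np.isnan(self.pseudovalues)]
        b = len(pv)
        if b < 2:
            return np.nan
        return float(np.sqrt((b - 1) / b * np.sum((pv - pv.mean()) ** 2)))


def _site_frequencies(sites: pd.DataFrame, pop: str) -> np.ndarray:
    dc = sites[f"derived_count_{pop}"].to_numpy(float)
    nc = sites[f"n_called_{pop}"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nc > 0, dc / (2 * nc), np.nan)


def _usable(sites: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    keep = (
        (sites["derived_allele"] == "ALT")
        & (sites[f"n_called_{x}"] > 0)
        & (sites[f"n_called_{y}"] > 0)
    )
    return sites.loc[keep]


def _l_ratio(sites: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    fx, fy = _site_frequencies(sites, x), _site_frequencies(sites, y)
    return float(np.sum(fx * (1 - fy))), float(np.sum(fy * (1 - fx)))


def rxy(
    category_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    pop_x: str,
    pop_y: str,
    category: str = "",
) -> RxyResult:
    """Rxy of ``pop_x`` vs ``pop_y`` standardized by control sites.

    Site tables carry ``derived_count_<pop>`` / ``n_called_<pop>`` columns
    as produced by polarization; sites with unknown derived state or no
    called genotype in either population are dropped.
    """
    cat = _usable(category_sites, pop_x, pop_y)
    ctrl = _usable(control_sites, pop_x, pop_y)
    if len(cat) == 0 or len(ctrl) == 0:
        raise ValueError("need >= 1 usable category site and control site")
    lxy, lyx = _l_ratio(cat, pop_x, pop_y)
    clxy, clyx = _l_ratio(ctrl, pop_x, pop_y)
    if lyx == 0 or clyx == 0 or clxy == 0:
        raise ValueError(
            "zero derived-allele sum in a denominator; use a larger control "
            "set or more category sites"
        )
    value = (lxy / lyx) / (clxy / clyx)
    return RxyResult(
        category, value, n_category_sites=len(cat), n_control_sites=len(ctrl)
    )


def jackknife_rxy(
    category_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    pop_x: str,
    pop_y: str,
    block_column: str = "chrom",
    category: str = "",
) -> RxyResult:
    """Delete-one-block Rxy: one leave-one-out estimate per chromosome block.

    Category and control sites of the deleted block are both removed.  A
    block whose deletion empties the control set yields a NaN pseudovalue
    (reported, not raised).
    """
    full = rxy(category_sites, control_sites, pop_x, pop_y, category)
    blocks = sorted(
        set(category_sites[block_column]) | set(control_sites[block_column])
    )
    if len(blocks) < 2:
        raise ValueError("jackknife needs >= 2 blocks")
    pvs = []
    for b in blocks:
        cat_b = category_sites.loc[category_sites[block_column] != b]
        ctrl_b = control_sites.loc[control_sites[block_column] != b]
        try:
            pvs.append(rxy(cat_b, ctrl_b, pop_x, pop_y).rxy)
        except ValueError:
            logger.warning("jackknife block %r leaves no usable sites", b)
            pvs.append(np.nan)
    full.pseudovalues = np.array(pvs)
    full.blocks = blocks
    return full


# -- diversity -------------------------------------------------------------


def nucleotide_diversity(
    table: GenotypeTable, samples, sequence_length_bp: float
) -> float:
    """π: mean pairwise difference per base pair.

    Per site, π_i = 2 p̂ (1 − p̂) · n_i/(n_i − 1) with n_i called alleles;
    sites with fewer than two called alleles contribute nothing.
    """
    if sequence_length_bp <= 0:
        raise ValueError("sequence_length_bp must be positive")
    idx = table.sample_indices(samples)
    dos = table.dosage[:, idx]
    called = dos != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, dos, 0).sum(axis=1)
    ok = n_alleles >= 2
    p = alt[ok] / n_alleles[ok]
    corr = n_alleles[ok] / (n_alleles[ok] - 1)
    return float(np.sum(2 * p * (1 - p) * corr) / sequence_length_bp)


def heterozygosity_per_kb(
    table: GenotypeTable, sample: str, callable_length_bp: float
) -> float:
    """Individual heterozygous-site count per kilobase of callable genome."""
    if callable_length_bp <= 0:
        raise ValueError("callable_length_bp must be positive")
    j = table.sample_indices([sample])[0]
    n_het = int((table.dosage[:, j] == 1).sum())
    return n_het * 1000.0 / callable_length_bp


# -- runs of homozygosity --------------------------------------------------


@dataclass
class ROHParams:
    """Sliding-window ROH scan parameters (PLINK-style semantics)."""

    window_snp: int = 100
    window_het: int = 2
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 500.0
    density_kb_per_snp: float = 10.0
    gap_kb: float = 100.0


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def roh_scan(
    table: GenotypeTable, sample: str, params: ROHParams | None = None
) -> pd.DataFrame:
    """Detect runs of homozygosity for one individual.

    Windows of ``window_snp`` consecutive SNPs are *homozygous* when they
    contain at most ``window_het`` heterozygous and ``window_missing``
    missing calls.  A SNP qualifies when the homozygous fraction of windows
    spanning it exceeds ``window_threshold``.  Maximal runs of qualifying
    SNPs — broken where consecutive SNPs are more than ``gap_kb`` apart —
    are reported as ROH when they have at least ``min_snp`` SNPs, span at
    least ``min_kb``, and average at most ``density_kb_per_snp`` per SNP.
    """
    p = params or ROHParams()
    j = table.sample_indices([sample])[0]
    out = []
    for chrom, grp in table.sites.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        rows, pos = rows[order], pos[order]
        dos = table.dosage[rows, j]
        m = len(pos)
        if m < p.window_snp:
            logger.info("chromosome %s has %d < %d SNPs; skipped", chrom, m, p.window_snp)
            continue
        het = (dos == 1).astype(np.int64)
        mis = (dos == MISSING).astype(np.int64)
        w = p.window_snp
        hom_win = (
            (_sliding_sum(het, w) <= p.window_het)
            & (_sliding_sum(mis, w) <= p.window_missing)
        ).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(hom_win)])
        n_win = m - w + 1
        starts = np.maximum(0, np.arange(m) - w + 1)
        stops = np.minimum(np.arange(m), n_win - 1) + 1  # exclusive
        span = stops - starts
        hom_frac = (cum[stops] - cum[starts]) / span
        qual = hom_frac > p.window_threshold
        # break runs at non-qualifying SNPs and at large gaps
        gap_break = np.zeros(m, dtype=bool)
        gap_break[1:] = np.diff(pos) > p.gap_kb * 1000
        run_id = np.cumsum(~qual | gap_break)
        for _, snps in pd.Series(np.arange(m)[qual]).groupby(run_id[qual]):
            s = snps.to_numpy()
            n_snps = len(s)
            start, end = int(pos[s[0]]), int(pos[s[-1]])
            length = end - start + 1
            if (
                n_snps >= p.min_snp
                and length >= p.min_kb * 1000
                and length / n_snps <= p.density_kb_per_snp * 1000
            ):
                out.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "n_snps": n_snps,
                        "length_bp": length,
                    }
                )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_snps", "length_bp"])


def f_roh(
    roh: pd.DataFrame, genome_length_bp: float, min_length_bp: float = 2_500_000
) -> float:
    """Fraction of the genome in ROH at least ``min_length_bp`` long.

    Intervals are merged per chromosome before length filtering.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if len(roh) == 0:
        return 0.0
    total = 0
    for _, grp in roh.groupby("chrom"):
        ivs = grp.sort_values("start")[["start", "end"]].to_numpy()
        cur_s, cur_e = ivs[0]
        merged = []
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        for s, e in merged:
            length = e - s + 1
            if length >= min_length_bp:
                total += length
    return total / genome_length_bp


# -- resampling and composition --------------------------------------------


def downsample_replicates(
    statistic, samples, k: int = 4, replicates: int = 100, seed: int = 0
) -> np.ndarray:
    """Distribution of ``statistic`` over downsampled individual sets.

    Each replicate draws ``k`` individuals without replacement from
    ``samples`` and evaluates ``statistic(subset)``.
    """
    samples = list(samples)
    if k > len(samples):
        raise ValueError(f"k={k} exceeds population size {len(samples)}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        pick = rng.choice(len(samples), size=k, replace=False)
        out.append(statistic([samples[i] for i in pick]))
    return np.asarray(out)


def category_proportions(
    site_info: pd.DataFrame, pop: str, category_column: str = "impact"
) -> pd.Series:
    """Fraction of sites polymorphic in ``pop`` belonging to each category."""
    dc = site_info[f"derived_count_{pop}"].to_numpy(float)
    nc = site_info[f"n_called_{pop}"].to_numpy(float)
    known = site_info["derived_allele"].to_numpy() == "ALT"
    poly = known & (dc > 0) & (dc < 2 * nc)
    if not poly.any():
        raise ValueError(f"no polymorphic sites in population {pop!r}")
    cats = site_info.loc[poly, category_column]
    return cats.value_counts(normalize=True).sort_index()
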