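"""Site filtering, impact classification and derived-allele polarization.

This stage turns raw genotypes plus per-site annotations into the
analysis-ready site set used by all load statistics:

1. GATK-style hard filters on INFO statistics (QD, FS, SOR, MQ, rank sums,
   AN), all printed comparisons strict — a site *fails* when e.g. QD < 2.0
   and passes at exact equality.
2. A minimum per-site genotyping rate (default 90%).
3. A multi-nucleotide-polymorphism guard: SNPs closer than 3 bp to their
   nearest neighbour on the same chromosome are dropped (both members of a
   too-close pair).
4. Functional impact categories (high / moderate / low / modifier, as
   assigned by an snpEff-style annotator) and phylogenetic conservation
   classes (GERP bins at −2, 2, 4, 6; phyloP > 1 conserved; phastCons = 1
   conserved).
5. Retention for load analysis: expressed (max FPKM > 0.3 in ≥1 organ),
   GERP > −2, and the proximity rule.
6. Polarization against outgroup species: ALT is the derived allele iff its
   frequency is exactly zero across all called outgroup genotypes;
   multiallelic sites and sites where ALT segregates in any outgroup are
   UNKNOWN and excluded from derived-allele statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields
from enum import Enum

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeTable,
    focal_populations,
    outgroup_species,
    population_samples,
)

logger = logging.getLogger(__name__)


class ImpactCategory(str, Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    MODIFIER = "modifier"


class ConservationClass(str, Enum):
    EXCLUDED = "excluded"
    NEUTRAL = "neutral"
    MODERATE = "moderate"
    LARGE = "large"
    EXTREME = "extreme"
    # binary classes used by phyloP / phastCons
    CONSERVED = "conserved"
    NOT_CONSERVED = "not_conserved"


@dataclass
class FilterThresholds:
    """Hard-filter and retention thresholds (all configurable).

    Defaults follow common GATK hard-filtering practice for non-model
    genomes: a site fails when QD < 2.0, FS > 40.0, SOR > 5.0, MQ < 20.0,
    |MQRankSum| > 3.0, |ReadPosRankSum| > 3.0 or AN < 62.
    """

    qd_min: float = 2.0
    fs_max: float = 40.0
    sor_max: float = 5.0
    mq_min: float = 20.0
    mqranksum_abs_max: float = 3.0
    readposranksum_abs_max: float = 3.0
    an_min: float = 62
    genotype_rate_min: float = 0.9
    min_snp_distance_bp: int = 3
    fpkm_min: float = 0.3
    gerp_retention_min: float = -2.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name}: must be finite")
        if not 0.0 < self.genotype_rate_min <= 1.0:
            raise ValueError("genotype_rate_min: must be in (0, 1]")


def apply_hard_filters(info: pd.DataFrame, thresholds: FilterThresholds | None = None):
    """Evaluate GATK-style hard filters on a per-site INFO table.

    Missing rank-sum annotations pass (sites without heterozygous calls
    genuinely lack these fields); a site flagged ``parse_error`` is excluded
    and logged.  Returns ``(pass_mask, fail_counts)`` where ``fail_counts``
    tallies sites failing each individual filter.
    """
    th = thresholds or FilterThresholds()
    n = len(info)

    def col(name):
        return (
            pd.to_numeric(info[name], errors="coerce").to_numpy(float)
            if name in info
            else np.full(n, np.nan)
        )

    qd, fs, sor, mq, an = col("QD"), col("FS"), col("SOR"), col("MQ"), col("AN")
    mqrs, rprs = col("MQRankSum"), col("ReadPosRankSum")
    with np.errstate(invalid="ignore"):
        fails = {
            "QD": qd < th.qd_min,
            "FS": fs > th.fs_max,
            "SOR": sor > th.sor_max,
            "MQ": mq < th.mq_min,
            "MQRankSum": np.abs(mqrs) > th.mqranksum_abs_max,
            "ReadPosRankSum": np.abs(rprs) > th.readposranksum_abs_max,
            "AN": an < th.an_min,
        }
    # NaN comparisons are False: absent annotations pass, as intended
    any_fail = np.zeros(n, dtype=bool)
    fail_counts = {}
    for name, mask in fails.items():
        mask = np.asarray(mask) & ~np.isnan(col(name) if name != "parse" else qd)
        fail_counts[name] = int(mask.sum())
        any_fail |= mask
    if "parse_error" in info:
        parse_bad = info["parse_error"].to_numpy(bool)
        if parse_bad.any():
            logger.warning(
                "%d sites excluded due to malformed INFO values", parse_bad.sum()
            )
        fail_counts["parse_error"] = int(parse_bad.sum())
        any_fail |= parse_bad
    return ~any_fail, fail_counts


def genotype_rate_filter(table: GenotypeTable, rate_min: float = 0.9) -> np.ndarray:
    """Per-site pass mask: called fraction >= ``rate_min``."""
    return table.genotype_rate() >= rate_min


def mnp_proximity_filter(
    sites: pd.DataFrame, min_distance_bp: int = 3
) -> np.ndarray:
    """Drop SNPs with a neighbour closer than ``min_distance_bp``.

    Distance is |pos_i − pos_j| on the same chromosome; both members of a
    too-close pair fail; a distance equal to the minimum passes.
    """
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    ok = np.ones(len(sites), dtype=bool)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            warnings.warn(f"positions on {c} unsorted; sorting internally")
            order = np.argsort(p, kind="stable")
            idx, p = idx[order], p[order]
        if len(p) < 2:
            continue
        gaps = np.diff(p)
        close = gaps < min_distance_bp
        bad = np.zeros(len(p), dtype=bool)
        bad[:-1] |= close
        bad[1:] |= close
        ok[idx[bad]] = False
    return ok


_IMPACT_ALIASES = {c.value: c for c in ImpactCategory}


def classify_impact(label: str) -> ImpactCategory:
    """Map an annotator impact label to an :class:`ImpactCategory`.

    Case and surrounding whitespace are normalized; anything outside the
    four canonical labels is rejected.
    """
    key = str(label).strip().lower()
    try:
        return _IMPACT_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized impact category {label!r}") from None


def classify_impact_column(labels) -> tuple[pd.Series, list]:
    """Vectorized :func:`classify_impact`; returns (categories, rejected)."""
    out, rejected = [], []
    for lab in labels:
        try:
            out.append(classify_impact(lab).value)
        except ValueError:
            out.append(None)
            rejected.append(lab)
    return pd.Series(out, index=getattr(labels, "index", None)), rejected


def classify_conservation(score, source: str = "gerp") -> ConservationClass:
    """Bin a conservation score.

    GERP: ≤ −2 excluded, (−2, 2] neutral, (2, 4] moderate, (4, 6] large,
    > 6 extreme.  phyloP: conserved iff score > 1.  phastCons: conserved iff
    score equals 1 (the maximum observed value).  A missing score is
    EXCLUDED.
    """
    src = source.lower()
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return ConservationClass.EXCLUDED
    s = float(score)
    if src == "gerp":
        if s <= -2:
            return ConservationClass.EXCLUDED
        if s <= 2:
            return ConservationClass.NEUTRAL
        if s <= 4:
            return ConservationClass.MODERATE
        if s <= 6:
            return ConservationClass.LARGE
        return ConservationClass.EXTREME
    if src == "phylop":
        return (
            ConservationClass.CONSERVED
            if s > 1
            else ConservationClass.NOT_CONSERVED
        )
    if src == "phastcons":
        return (
            ConservationClass.CONSERVED
            if s == 1
            else ConservationClass.NOT_CONSERVED
        )
    raise ValueError(f"unknown conservation source {source!r}")


def retain_for_load_analysis(
    annotation: pd.DataFrame, thresholds: FilterThresholds | None = None
):
    """Expression + conservation + proximity retention.

    A site is retained iff max FPKM > ``fpkm_min`` (strict), GERP >
    ``gerp_retention_min`` (strict), and it passes the SNP-proximity rule.
    Returns ``(mask, tally)`` with per-criterion exclusion counts (a site can
    count against several criteria).
    """
    th = thresholds or FilterThresholds()
    fpkm_ok = annotation["max_fpkm"].to_numpy(float) > th.fpkm_min
    gerp_ok = annotation["gerp"].to_numpy(float) > th.gerp_retention_min
    prox_ok = mnp_proximity_filter(annotation, th.min_snp_distance_bp)
    mask = fpkm_ok & gerp_ok & prox_ok
    tally = {
        "fpkm": int((~fpkm_ok).sum()),
        "gerp": int((~gerp_ok).sum()),
        "proximity": int((~prox_ok).sum()),
    }
    return mask, tally


def polarize_derived(
    table: GenotypeTable, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Polarize each site against the outgroup species.

    ALT is defined as derived iff its frequency is exactly zero among all
    called outgroup genotypes; if ALT segregates in any outgroup the site is
    UNKNOWN, as are multiallelic sites and sites with no called outgroup
    genotype.  Returns a per-site DataFrame with ``derived_allele`` in
    {ALT, UNKNOWN} plus per-population derived counts and called sample
    sizes (columns ``derived_count_<pop>`` / ``n_called_<pop>``) computed
    over called genotypes only.
    """
    og = outgroup_species(manifest)
    if not og:
        raise ValueError("outgroup manifest is empty; cannot polarize")
    og_names = [s for names in og.values() for s in names]
    og_dos = table.dosage[:, table.sample_indices(og_names)]
    og_called = og_dos != MISSING
    og_alt = np.where(og_called, og_dos, 0).sum(axis=1)
    og_n = og_called.sum(axis=1)

    multi = table.sites["alt"].astype(str).str.contains(",").to_numpy()
    no_outgroup = og_n == 0
    if no_outgroup.any():
        warnings.warn(
            f"{int(no_outgroup.sum())} sites have no called outgroup genotype; "
            "derived state set to unknown"
        )
    derived = np.where(
        multi | no_outgroup | (og_alt > 0), "UNKNOWN", "ALT"
    )

    out = table.sites[["chrom", "pos"]].copy()
    if "id" in table.sites:
        out["id"] = table.sites["id"]
    out["derived_allele"] = derived
    for pop in focal_populations(manifest):
        cols = table.sample_indices(population_samples(manifest, pop))
        dos = table.dosage[:, cols]
        called = dos != MISSING
        out[f"derived_count_{pop}"] = np.where(called, dos, 0).sum(axis=1)
        out[f"n_called_{pop}"] = called.sum(axis=1)
    return out


def classify_sites(
    table: GenotypeTable,
    info: pd.DataFrame,
    annotation: pd.DataFrame,
    manifest: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
):
    """Run the full filtering + classification + polarization pipeline.

    Returns ``(retained_sites, report)``: the analysis-ready site table
    (impact category, conservation class, derived counts per population) and
    a dict of exclusion tallies per stage.  Intergenic control sites bypass
    the expression/conservation retention step (they standardize Rxy) but
    share all quality filters.
    """
    th = thresholds or FilterThresholds()
    ann = annotation.reset_index(drop=True)
    hard_ok, hard_tally = apply_hard_filters(info, th)
    rate_ok = genotype_rate_filter(table, th.genotype_rate_min)

    impact, rejected = classify_impact_column(ann["snpeff_category"])
    if rejected:
        logger.warning("%d sites with unrecognized impact labels", len(rejected))
    impact_ok = impact.notna().to_numpy()

    retain_ok, retain_tally = retain_for_load_analysis(ann, th)
    intergenic = ann["intergenic"].to_numpy(bool)
    prox_ok = mnp_proximity_filter(ann, th.min_snp_distance_bp)
    keep = hard_ok & rate_ok & impact_ok & np.where(
        intergenic, prox_ok, retain_ok
    )

    pol = polarize_derived(table, manifest)
    retained = pol.loc[keep].copy()
    retained.insert(2, "impact", impact[keep].to_numpy())
    retained.insert(
        3,
        "gerp_class",
        [classify_conservation(g, "gerp").value for g in ann.loc[keep, "gerp"]],
    )
    retained.insert(4, "intergenic", intergenic[keep].astype(int))
    report = {
        "hard_filter": hard_tally,
        "genotype_rate_excluded": int((~rate_ok).sum()),
        "retention": retain_tally,
        "unrecognized_impact": len(rejected),
        "n_input": len(ann),
        "n_retained": int(keep.sum()),
    }
    return retained.reset_index(drop=True), report
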