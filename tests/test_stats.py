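"""Load statistics against brute-force oracles and worked arithmetic."""

import numpy as np
import pandas as pd
import pytest

import ibexload as ib
from ibexload.containers import GenotypeTable
from ibexload.stats import ROHParams, align_to_sites

from conftest import site_info_for


def _table(dosages, chrom="chr1", start=100, step=100, samples=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": start + step * np.arange(n_sites),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeTable(sites, dosages, samples)


class TestSFS:
    def test_two_site_example(self):
        # 3 diploids; site A dosages (1,0,0), site B (2,1,0):
        # derived counts 1 and 3 -> SFS over 1..5 = [1,0,1,0,0]
        table = _table([[1, 0, 0], [2, 1, 0]])
        info = site_info_for(table)
        spec = ib.sfs_by_category(table, info, table.samples, "modifier")
        assert list(spec.counts) == [1, 0, 1, 0, 0]
        assert spec.n_segregating == 2

    def test_fixed_derived_sites_excluded(self):
        table = _table([[2, 2, 2], [2, 2, 2]])
        spec = ib.sfs_by_category(table, site_info_for(table), table.samples, "modifier")
        assert spec.n_segregating == 0

    def test_sites_with_missing_calls_excluded(self):
        table = _table([[1, -1, 0], [1, 0, 0]])
        spec = ib.sfs_by_category(table, site_info_for(table), table.samples, "modifier")
        assert list(spec.counts) == [1, 0, 0, 0, 0]

    def test_total_equals_segregating_count(self, small_cohort):
        pol = ib.polarize_derived(small_cohort.genotypes, small_cohort.manifest)
        pol["impact"] = small_cohort.truth["category"].to_numpy()
        samples = [s for s in small_cohort.genotypes.samples if s.startswith("pop1")]
        spec = ib.sfs_by_category(small_cohort.genotypes, pol, samples, "modifier")
        # independent tally
        dos = small_cohort.genotypes.dosage[
            :, small_cohort.genotypes.sample_indices(samples)
        ]
        complete = (dos != -1).all(axis=1)
        usable = (
            complete
            & (pol["impact"] == "modifier").to_numpy()
            & (pol["derived_allele"] == "ALT").to_numpy()
        )
        counts = dos[usable].sum(axis=1)
        assert spec.n_segregating == int(((counts > 0) & (counts < 2 * len(samples))).sum())

    def test_binned_display_rule(self):
        # two sites at derived counts 11 and 13; interval 11-14 spans four
        # count values -> mean 0.5 sites per count value
        counts = np.zeros(19, dtype=np.int64)
        counts[10] = 1  # count 11
        counts[12] = 1  # count 13
        spec = ib.SFS("modifier", counts, 10)
        binned = spec.binned(bin_edges=[(11, 14)])
        assert binned.iloc[-1]["bin"] == "11-14"
        assert binned.iloc[-1]["sites_per_count"] == pytest.approx(0.5)
        # counts <= 10 stay exact
        assert len(binned) == 11


class TestIndividualCounts:
    def test_reference_individual_zero(self):
        table = _table(np.zeros((5, 2), dtype=int))
        out = ib.individual_counts(table, site_info_for(table), table.samples)
        assert (out[["derived_alleles", "derived_homozygotes"]] == 0).all().all()

    def test_heterozygous_individual(self):
        k = 4
        dos = np.zeros((6, 2), dtype=int)
        dos[:k, 0] = 1
        table = _table(dos)
        out = ib.individual_counts(table, site_info_for(table), table.samples)
        me = out[out["individual"] == "s0"].iloc[0]
        assert me["derived_alleles"] == k and me["derived_homozygotes"] == 0

    def test_matches_brute_force_tally(self, tiny_table):
        info = site_info_for(tiny_table)
        out = ib.individual_counts(
            tiny_table, info, tiny_table.samples, max_missing_rate=0.5
        )
        for j, name in enumerate(tiny_table.samples):
            alleles = homs = 0
            for i in range(tiny_table.n_sites):
                d = tiny_table.dosage[i, j]
                if d < 0:
                    continue
                alleles += d
                homs += d == 2
            row = out[out["individual"] == name].iloc[0]
            assert row["derived_alleles"] == alleles
            assert row["derived_homozygotes"] == homs

    def test_high_missing_sites_dropped(self):
        dos = np.array([[1, -1], [1, 1]], dtype=np.int8)  # site 0: 50% missing
        table = _table(dos)
        out = ib.individual_counts(
            table, site_info_for(table), table.samples, max_missing_rate=0.1
        )
        assert (out["n_sites_used"] == 1).all()


def _freq_frame(rows, pop_cols=("x", "y"), chrom="c1"):
    recs = []
    for i, freqs in enumerate(rows):
        rec = {"chrom": chrom, "pos": (i + 1) * 10, "derived_allele": "ALT"}
        for pop, f in zip(pop_cols, freqs):
            rec[f"derived_count_{pop}"] = int(round(f * 20))
            rec[f"n_called_{pop}"] = 10
        recs.append(rec)
    return pd.DataFrame(recs)


class TestRxy:
    def test_identical_frequencies_give_unity(self):
        cat = _freq_frame([(0.3, 0.3), (0.5, 0.5)])
        ctrl = _freq_frame([(0.2, 0.2), (0.4, 0.4)])
        assert ib.rxy(cat, ctrl, "x", "y").rxy == pytest.approx(1.0)

    def test_worked_example(self):
        cat = _freq_frame([(0.1, 0.5)])
        ctrl = _freq_frame([(0.5, 0.5)])
        assert ib.rxy(cat, ctrl, "x", "y").rxy == pytest.approx(1 / 9)

    def test_reciprocity(self):
        cat = _freq_frame([(0.1, 0.5)])
        ctrl = _freq_frame([(0.5, 0.5)])
        assert ib.rxy(cat, ctrl, "y", "x").rxy == pytest.approx(9.0)

    def test_reciprocity_on_random_sites(self):
        rng = np.random.default_rng(4)
        cat = _freq_frame(rng.random((30, 2)) * 0.9 + 0.05)
        ctrl = _freq_frame(rng.random((50, 2)) * 0.9 + 0.05)
        fwd = ib.rxy(cat, ctrl, "x", "y").rxy
        rev = ib.rxy(cat, ctrl, "y", "x").rxy
        assert fwd * rev == pytest.approx(1.0, abs=1e-12)

    def test_zero_control_denominator_raises(self):
        cat = _freq_frame([(0.1, 0.5)])
        ctrl = _freq_frame([(0.0, 0.0)])
        with pytest.raises(ValueError, match="control"):
            ib.rxy(cat, ctrl, "x", "y")


class TestJackknife:
    def test_homogeneous_blocks_reproduce_estimate(self):
        cat = pd.concat(
            [_freq_frame([(0.1, 0.4)], chrom=c) for c in ("c1", "c2", "c3")],
            ignore_index=True,
        )
        ctrl = pd.concat(
            [_freq_frame([(0.3, 0.3)], chrom=c) for c in ("c1", "c2", "c3")],
            ignore_index=True,
        )
        res = ib.jackknife_rxy(cat, ctrl, "x", "y")
        assert np.allclose(res.pseudovalues, res.rxy)

    def test_two_blocks_match_brute_force(self):
        cat = pd.concat(
            [_freq_frame([(0.1, 0.5)], chrom="c1"), _freq_frame([(0.3, 0.2)], chrom="c2")],
            ignore_index=True,
        )
        ctrl = pd.concat(
            [_freq_frame([(0.5, 0.5)], chrom="c1"), _freq_frame([(0.4, 0.4)], chrom="c2")],
            ignore_index=True,
        )
        res = ib.jackknife_rxy(cat, ctrl, "x", "y")
        for i, block in enumerate(res.blocks):
            expect = ib.rxy(
                cat[cat["chrom"] != block], ctrl[ctrl["chrom"] != block], "x", "y"
            ).rxy
            assert res.pseudovalues[i] == pytest.approx(expect)

    def test_planted_deficit_detected(self):
        # HIGH-impact sites generated rarer in pop X (Beta mean 0.02 vs 0.10)
        spec = ib.CohortSpec(
            n_populations=2,
            n_individuals_per_population=15,
            n_sites_per_category={"high": 1500, "intergenic": 1500},
            beta_params={
                "high": [(0.2, 9.8), (1.0, 9.0)],  # X mean 0.02, Y mean 0.10
                "intergenic": (1.0, 9.0),
            },
            n_chromosomes=6,
            seed=21,
        )
        cohort = ib.generate_cohort(spec)
        pol = ib.polarize_derived(cohort.genotypes, cohort.manifest)
        pol["category"] = cohort.truth["category"].to_numpy()
        res = ib.jackknife_rxy(
            pol[pol["category"] == "high"],
            pol[pol["category"] == "intergenic"],
            "pop1", "pop2",
        )
        assert res.rxy < 1
        assert (res.pseudovalues < 1).all()


class TestDiversity:
    def test_monomorphic_pi_zero(self):
        table = _table(np.zeros((4, 3), dtype=int))
        assert ib.nucleotide_diversity(table, table.samples, 100) == 0.0

    def test_two_diploid_example(self):
        table = _table([[0, 2]])
        assert ib.nucleotide_diversity(table, table.samples, 1) == pytest.approx(2 / 3)

    def test_length_scaling(self):
        table = _table([[0, 1], [1, 2]])
        assert ib.nucleotide_diversity(table, table.samples, 200) == pytest.approx(
            ib.nucleotide_diversity(table, table.samples, 100) / 2
        )

    def test_zero_length_raises(self):
        table = _table([[0, 1]])
        with pytest.raises(ValueError):
            ib.nucleotide_diversity(table, table.samples, 0)

    def test_converges_to_beta_expectation(self):
        # E[per-site pi] = 2 E[p(1-p)] for Binomial sampling of alleles
        a, b, n_sites = 1.0, 4.0, 10_000
        spec = ib.CohortSpec(
            n_populations=1,
            n_individuals_per_population=10,
            n_sites_per_category={"modifier": n_sites},
            beta_params={"modifier": (a, b)},
            seed=13,
        )
        cohort = ib.generate_cohort(spec)
        samples = [s for s in cohort.genotypes.samples if s.startswith("pop1")]
        pi = ib.nucleotide_diversity(cohort.genotypes, samples, n_sites)
        expect = 2 * a * b / ((a + b) * (a + b + 1))
        # SE of the mean per-site pi, via the empirical site-level spread
        p = cohort.truth["true_freq_pop1"].to_numpy()
        se = np.std(2 * p * (1 - p)) / np.sqrt(n_sites)
        assert abs(pi - expect) < 3 * max(se, 1e-3)

    def test_heterozygosity_examples(self):
        dos = np.zeros((5, 1), dtype=int)
        table = _table(dos)
        assert ib.heterozygosity_per_kb(table, "s0", 10_000) == 0.0
        dos[:, 0] = 1
        table = _table(dos)
        assert ib.heterozygosity_per_kb(table, "s0", 10_000) == pytest.approx(0.5)
        assert ib.heterozygosity_per_kb(table, "s0", 20_000) == pytest.approx(0.25)


def _roh_oracle(pos, dosage, p: ROHParams):
    """Direct O(n*w) re-implementation of the window scan."""
    m = len(pos)
    if m < p.window_snp:
        return []
    w = p.window_snp
    hom_win = []
    for start in range(m - w + 1):
        window = dosage[start : start + w]
        hom_win.append(
            (window == 1).sum() <= p.window_het
            and (window == -1).sum() <= p.window_missing
        )
    qual = []
    for j in range(m):
        starts = range(max(0, j - w + 1), min(j, m - w) + 1)
        frac = sum(hom_win[s] for s in starts) / len(list(starts))
        qual.append(frac > p.window_threshold)
    out, run = [], []
    for j in range(m):
        if qual[j] and (not run or pos[j] - pos[run[-1]] <= p.gap_kb * 1000):
            run.append(j)
        else:
            out.append(run)
            run = [j] if qual[j] else []
    out.append(run)
    intervals = []
    for run in out:
        if not run:
            continue
        length = pos[run[-1]] - pos[run[0]] + 1
        if (
            len(run) >= p.min_snp
            and length >= p.min_kb * 1000
            and length / len(run) <= p.density_kb_per_snp * 1000
        ):
            intervals.append((int(pos[run[0]]), int(pos[run[-1]]), len(run)))
    return intervals


def _roh_fixture(rng, n_snps, span_bp, planted=None, het_rate=0.3, miss_rate=0.02):
    pos = np.sort(rng.choice(np.arange(1, span_bp), size=n_snps, replace=False))
    dosage = np.where(rng.random(n_snps) < het_rate, 1, rng.integers(0, 2, n_snps) * 2)
    dosage = np.where(rng.random(n_snps) < miss_rate, -1, dosage).astype(np.int8)
    if planted:
        lo, hi = planted
        inside = (pos >= lo) & (pos <= hi)
        dosage[inside] = np.where(rng.random(inside.sum()) < 0.005, 1, 2)
    return pos, dosage


class TestROH:
    def _scan(self, pos, dosage, params):
        table = GenotypeTable(
            pd.DataFrame({"chrom": "c", "pos": pos, "ref": "A", "alt": "T"}),
            dosage.reshape(-1, 1), ["me"],
        )
        return ib.roh_scan(table, "me", params)

    def test_fully_homozygous_chromosome_single_roh(self):
        pos = np.linspace(1, 6_000_000, 2000).astype(int)
        dosage = np.zeros(2000, dtype=np.int8)
        got = self._scan(pos, dosage, ROHParams())
        assert len(got) == 1
        assert got.iloc[0]["start"] == pos[0] and got.iloc[0]["end"] == pos[-1]

    def test_short_run_rejected(self):
        # homozygous tract spanning only 400 kb: below the 500 kb minimum
        pos = np.linspace(1, 400_000, 1500).astype(int)
        dosage = np.zeros(1500, dtype=np.int8)
        assert len(self._scan(pos, dosage, ROHParams())) == 0

    def test_planted_tract_matches_oracle(self):
        rng = np.random.default_rng(9)
        params = ROHParams()
        pos, dosage = _roh_fixture(
            rng, 1500, 3_000_000, planted=(1_000_000, 2_000_000)
        )
        got = self._scan(pos, dosage, params)
        expect = _roh_oracle(pos, dosage, params)
        assert [tuple(r) for r in got[["start", "end", "n_snps"]].to_numpy()] == expect
        assert len(expect) >= 1  # the planted 1-Mb tract is found

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(1000 + seed)
        if seed % 2:
            params = ROHParams()
            lo = int(rng.integers(100_000, 1_500_000))
            planted = (lo, lo + int(rng.integers(400_000, 1_500_000)))
            pos, dosage = _roh_fixture(
                rng, int(rng.integers(1000, 2000)), 4_000_000, planted=planted
            )
        else:
            params = ROHParams(window_snp=20, min_snp=20, min_kb=50, gap_kb=30)
            pos, dosage = _roh_fixture(
                rng, int(rng.integers(1000, 2000)), 2_000_000,
                het_rate=float(rng.uniform(0.0, 0.2)),
            )
        got = self._scan(pos, dosage, params)
        expect = _roh_oracle(pos, dosage, params)
        assert [tuple(r) for r in got[["start", "end", "n_snps"]].to_numpy()] == expect

    def test_froh_examples(self):
        assert ib.f_roh(pd.DataFrame(columns=["chrom", "start", "end"]), 50e6) == 0.0
        one = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [5_000_000]})
        assert ib.f_roh(one, 50e6) == pytest.approx(0.1)
        short = pd.DataFrame({"chrom": ["c"], "start": [1], "end": [2_400_000]})
        assert ib.f_roh(short, 50e6) == 0.0
        with pytest.raises(ValueError):
            ib.f_roh(one, 0)

    def test_froh_merges_overlaps(self):
        roh = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [1, 2_000_000], "end": [3_000_000, 6_000_000]}
        )
        assert ib.f_roh(roh, 60e6) == pytest.approx(6_000_000 / 60e6)


class TestDownsampling:
    def test_population_of_exactly_k_constant(self):
        table = _table([[0, 1, 2, 1]])
        stat = lambda names: ib.nucleotide_diversity(table, names, 10)
        vals = ib.downsample_replicates(stat, table.samples, k=4, replicates=10, seed=0)
        assert np.allclose(vals, vals[0])

    def test_seed_reproducibility(self):
        table = _table(np.random.default_rng(0).integers(0, 3, (20, 8)))
        stat = lambda names: ib.nucleotide_diversity(table, names, 20)
        a = ib.downsample_replicates(stat, table.samples, k=4, replicates=20, seed=5)
        b = ib.downsample_replicates(stat, table.samples, k=4, replicates=20, seed=5)
        assert np.array_equal(a, b)

    def test_k_larger_than_population_raises(self):
        with pytest.raises(ValueError):
            ib.downsample_replicates(lambda s: 0, ["a", "b"], k=3)

    def test_replicate_mean_tracks_full_sample_pi(self, small_cohort):
        samples = [s for s in small_cohort.genotypes.samples if s.startswith("pop1")]
        n_sites = small_cohort.genotypes.n_sites
        stat = lambda names: ib.nucleotide_diversity(
            small_cohort.genotypes, names, n_sites
        )
        full = stat(samples)
        vals = ib.downsample_replicates(stat, samples, k=4, replicates=100, seed=3)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # downsampled pi is unbiased for the sample-level pi
        assert abs(vals.mean() - full) < max(3 * se, 0.05 * full)


class TestCategoryProportions:
    def test_single_high_site_among_hundred(self):
        rows = [("high", 3)] + [("modifier", 5)] * 99
        df = pd.DataFrame(
            {
                "impact": [r[0] for r in rows],
                "derived_allele": "ALT",
                "derived_count_p": [r[1] for r in rows],
                "n_called_p": 10,
            }
        )
        props = ib.category_proportions(df, "p")
        assert props["high"] == pytest.approx(0.01)
        assert props.sum() == pytest.approx(1.0)

    def test_no_high_sites(self):
        df = pd.DataFrame(
            {"impact": ["modifier"] * 5, "derived_allele": "ALT",
             "derived_count_p": [1] * 5, "n_called_p": 10}
        )
        assert "high" not in ib.category_proportions(df, "p")

    def test_no_polymorphic_sites_raises(self):
        df = pd.DataFrame(
            {"impact": ["modifier"], "derived_allele": "ALT",
             "derived_count_p": [0], "n_called_p": 10}
        )
        with pytest.raises(ValueError):
            ib.category_proportions(df, "p")


def test_align_to_sites_subsets_in_order(tiny_table):
    sub = tiny_table.sites.iloc[[7, 2, 5]][["chrom", "pos"]]
    aligned = align_to_sites(tiny_table, sub)
    assert np.array_equal(aligned.dosage, tiny_table.dosage[[7, 2, 5]])
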