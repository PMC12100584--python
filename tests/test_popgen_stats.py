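import numpy as np
import pytest

from hybridpaint import formats_io as fio
from hybridpaint import popgen_stats as ps
from hybridpaint import synthetic_data as sd

from conftest import random_genotype_matrix


def _toy_gm(dosages, depths=None, positions=None, chroms=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_ind = dosages.shape
    positions = np.arange(1, n_sites + 1) * 100 if positions is None else np.asarray(positions)
    chroms = np.array(["chr1"] * n_sites, dtype=object) if chroms is None else np.asarray(chroms, dtype=object)
    ref = np.array(["A"] * n_sites, dtype=object)
    alt = np.array(["G"] * n_sites, dtype=object)
    depths = np.full((n_sites, n_ind), 10, dtype=np.int32) if depths is None else np.asarray(depths, dtype=np.int32)
    sites = fio.SiteTable(chroms, positions, ref, alt)
    return fio.GenotypeMatrix(sites, [f"i{k}" for k in range(n_ind)], dosages, depths)


class TestFilters:
    def test_maf_below_threshold_dropped(self):
        # 10 individuals, one het: p = 0.05 -> kept; one site with p = 0.02 impossible
        # with integer dosages, so use 25 individuals: 1 het -> MAF 0.02
        dosage = np.zeros((2, 25), dtype=np.int8)
        dosage[0, 0] = 1  # MAF 0.02 < 0.03 -> dropped
        dosage[1, :3] = 1  # MAF 0.06 -> kept
        gm = _toy_gm(dosage)
        fc = ps.FilterConfig(min_site_depth=0, max_site_depth=10_000)
        out, report = ps.apply_filters(gm, fc)
        assert out.n_sites == 1 and out.sites.pos[0] == 200
        assert report.failed_maf == 1

    def test_all_pass_matrix_is_identity(self):
        dosage = np.array([[0, 1, 2, 1], [1, 1, 0, 2]], dtype=np.int8)
        gm = _toy_gm(dosage)
        fc = ps.FilterConfig(min_site_depth=0, max_site_depth=10_000)
        out, report = ps.apply_filters(gm, fc)
        assert np.array_equal(out.dosage, gm.dosage)
        assert report.n_sites_out == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rule_by_rule_oracle(self, seed):
        """Surviving sites equal an independent per-rule evaluation in loops."""
        gm = random_genotype_matrix(seed, n_sites=60, n_ind=8, missing_rate=0.15)
        fc = ps.FilterConfig(min_maf=0.1, min_call_rate=0.75, min_ind_depth=5,
                             min_site_depth=40, max_site_depth=130)
        out, _ = ps.apply_filters(gm, fc)

        expected_keep = []
        for j in range(gm.n_sites):
            doses = []
            for i in range(gm.n_individuals):
                d = int(gm.dosage[j, i])
                if d != fio.MISSING and gm.depth[j, i] >= fc.min_ind_depth:
                    doses.append(d)
            if len(doses) / gm.n_individuals < fc.min_call_rate or not doses:
                continue
            p = sum(doses) / (2 * len(doses))
            if min(p, 1 - p) < fc.min_maf:
                continue
            total_depth = int(gm.depth[j].sum())
            if not (fc.min_site_depth <= total_depth <= fc.max_site_depth):
                continue
            expected_keep.append((str(gm.sites.chrom[j]), int(gm.sites.pos[j])))
        got = list(zip(out.sites.chrom, (int(p) for p in out.sites.pos)))
        assert got == expected_keep

    @pytest.mark.parametrize("seed", range(3))
    def test_idempotent(self, seed):
        gm = random_genotype_matrix(seed, n_sites=50, n_ind=6)
        fc = ps.FilterConfig(min_site_depth=0, max_site_depth=10_000, min_maf=0.05)
        once, _ = ps.apply_filters(gm, fc)
        twice, _ = ps.apply_filters(once, fc)
        assert np.array_equal(once.dosage, twice.dosage)
        assert list(once.sites.pos) == list(twice.sites.pos)

    def test_empty_output_warns_not_raises(self):
        gm = _toy_gm(np.zeros((3, 4), dtype=np.int8))  # monomorphic: MAF 0
        with pytest.warns(UserWarning, match="all sites removed"):
            out, _ = ps.apply_filters(gm, ps.FilterConfig())
        assert out.n_sites == 0


def _wc_theta_oracle(dosage_a, dosage_b):
    """Literal loop transcription of the two-population Weir-Cockerham (1984)
    variance components with the observed-heterozygosity term; independent of
    the vectorised implementation under test."""
    thetas = []
    for row_a, row_b in zip(dosage_a, dosage_b):
        comps = []
        for row in (row_a, row_b):
            called = [d for d in row if d != fio.MISSING]
            n = len(called)
            p = sum(called) / (2 * n)
            h = sum(1 for d in called if d == 1) / n
            comps.append((n, p, h))
        (n1, p1, h1), (n2, p2, h2) = comps
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        thetas.append((a, b, c))
    num = sum(t[0] for t in thetas)
    den = sum(t[0] + t[1] + t[2] for t in thetas)
    return num / den


class TestWeirCockerham:
    def test_fixed_difference_gives_theta_one(self):
        dosage = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        gm = _toy_gm(dosage)
        a, b, c = ps.wc_site_components(gm, ["i0", "i1", "i2"], ["i3", "i4", "i5"])
        assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)

    def test_identical_panels_give_theta_near_zero(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=(80, 8)).astype(np.int8)
        gm = _toy_gm(np.concatenate([col, col], axis=1))
        ids = gm.individuals
        df = ps.weir_cockerham_fst(gm, ids[:8], ids[8:], window_bp=10_000_000)
        assert abs(df["theta"].iloc[0]) < 0.1

    @pytest.mark.parametrize("seed", range(4))
    def test_window_theta_matches_loop_oracle(self, seed):
        gm = random_genotype_matrix(seed, n_sites=20, n_ind=10, missing_rate=0.1)
        ids_a, ids_b = gm.individuals[:5], gm.individuals[5:]
        df = ps.weir_cockerham_fst(gm, ids_a, ids_b, window_bp=10**9, min_called=2)
        sub_a = gm.subset_individuals(ids_a)
        sub_b = gm.subset_individuals(ids_b)
        usable = [
            j for j in range(gm.n_sites)
            if (sub_a.dosage[j] != fio.MISSING).sum() >= 2
            and (sub_b.dosage[j] != fio.MISSING).sum() >= 2
        ]
        for chrom in np.unique(gm.sites.chrom):
            rows = [j for j in usable if gm.sites.chrom[j] == chrom]
            expect = _wc_theta_oracle(sub_a.dosage[rows], sub_b.dosage[rows])
            got = df.loc[df["chrom"] == chrom, "theta"].iloc[0]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_invariant_under_allele_label_swap(self):
        gm = random_genotype_matrix(7, n_sites=30, n_ind=8)
        swapped_dosage = np.where(gm.dosage == fio.MISSING, fio.MISSING, 2 - gm.dosage)
        gm_sw = fio.GenotypeMatrix(gm.sites, gm.individuals, swapped_dosage, gm.depth)
        ids_a, ids_b = gm.individuals[:4], gm.individuals[4:]
        t1 = ps.weir_cockerham_fst(gm, ids_a, ids_b)["theta"]
        t2 = ps.weir_cockerham_fst(gm_sw, ids_a, ids_b)["theta"]
        np.testing.assert_allclose(t1, t2, atol=1e-12)

    def test_empty_window_reported_missing(self):
        dosage = np.array([[0, 0, 2, 2]], dtype=np.int8)
        gm = _toy_gm(dosage, depths=np.full((1, 4), 10))
        gm.dosage[0, :2] = fio.MISSING  # panel A has < 2 calls
        df = ps.weir_cockerham_fst(gm, ["i0", "i1"], ["i2", "i3"])
        assert np.isnan(df["theta"].iloc[0]) and df["n_sites"].iloc[0] == 0


class TestLdPruning:
    def test_every_50th_of_500_keeps_10(self):
        gm = random_genotype_matrix(0, n_sites=500, n_ind=2, missing_rate=0)
        pruned = ps.ld_prune_every_nth(gm.sites, 50)
        assert pruned.n_sites == 10
        assert pruned.pos[0] == gm.sites.pos[0]

    def test_n_equals_one_is_identity(self):
        gm = random_genotype_matrix(1, n_sites=30, n_ind=2)
        pruned = ps.ld_prune_every_nth(gm.sites, 1)
        assert list(pruned.pos) == list(gm.sites.pos)

    def test_fewer_variants_than_n_keeps_first(self):
        gm = random_genotype_matrix(2, n_sites=49, n_ind=2)
        pruned = ps.ld_prune_every_nth(gm.sites, 50)
        assert pruned.n_sites == 1 and pruned.pos[0] == gm.sites.pos[0]


class TestPattersonD:
    def test_equal_patterns_give_zero(self):
        n = 20
        p1 = np.full(n, 0.5)
        p2 = np.full(n, 0.5)
        p3 = np.full(n, 0.8)
        p4 = np.zeros(n)
        res = ps.patterson_d(p1, p2, p3, p4, np.array(["c"] * n, dtype=object),
                             np.arange(1, n + 1) * 1000)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_fixed_pattern_counts_30_10_give_half(self):
        """30 pure ABBA sites and 10 pure BABA sites force D = 0.5."""
        p1 = np.array([0.0] * 30 + [1.0] * 10)
        p2 = np.array([1.0] * 30 + [0.0] * 10)
        p3 = np.ones(40)
        p4 = np.zeros(40)
        res = ps.patterson_d(p1, p2, p3, p4, np.array(["c"] * 40, dtype=object),
                             np.arange(1, 41) * 100)
        assert res.n_abba == pytest.approx(30) and res.n_baba == pytest.approx(10)
        assert res.d == pytest.approx(0.5)

    def test_sign_flips_when_p1_p2_swap(self, small_panels):
        gm = small_panels.gm
        pn = small_panels.panels
        pops = (pn.parent_a[:2], pn.parent_a[2:], pn.parent_b, pn.outgroup)
        swapped = (pn.parent_a[2:], pn.parent_a[:2], pn.parent_b, pn.outgroup)
        d1 = ps.patterson_d_from_genotypes(gm, pops, block_size_bp=5_000_000)
        d2 = ps.patterson_d_from_genotypes(gm, swapped, block_size_bp=5_000_000)
        assert d1.d == pytest.approx(-d2.d, abs=1e-12)

    def test_se_undefined_with_single_block(self):
        p = np.full(5, 0.5)
        res = ps.patterson_d(p, p, p, np.zeros(5), np.array(["c"] * 5, dtype=object),
                             np.arange(1, 6) * 10)
        assert res.n_blocks == 1 and np.isnan(res.se)

    def test_introgression_shifts_d_positive(self):
        """Replacing a fraction of P2 genotypes by P3 alleles makes D > 0."""
        cfg = sd.SimConfig(n_macro=0, n_intermediate=0, n_micro=2, include_z=False,
                           micro_length=10_000_000, n_sites_per_chrom=400,
                           fraction_fixed_diff=0.2, fraction_shared_poly=0.5, seed=13)
        panels = sd.simulate_parental_panels(cfg, 6, 4, n_outgroup=2)
        gm = panels.gm
        a = panels.panels.parent_a
        rng = np.random.default_rng(0)
        p2_cols = [gm.column(i) for i in a[3:]]
        donor = gm.column(panels.panels.parent_b[0])
        introgressed = rng.random(gm.n_sites) < 0.10
        dosage = gm.dosage.copy()
        for c in p2_cols:
            dosage[introgressed, c] = gm.dosage[introgressed, donor]
        gm_intro = fio.GenotypeMatrix(gm.sites, gm.individuals, dosage, gm.depth)
        res = ps.patterson_d_from_genotypes(
            gm_intro, (a[:3], a[3:], panels.panels.parent_b, panels.panels.outgroup)
        )
        assert res.d > 0.05

    def test_jackknife_se_tracks_replicate_scatter(self):
        """Block-jackknife SE within 20% of the empirical SD of D across
        independent simulation replicates."""
        rng = np.random.SeedSequence(99)
        ds, ses = [], []
        for child in rng.spawn(150):
            seed = int(child.generate_state(1)[0] % 2**31)
            cfg = sd.SimConfig(n_macro=0, n_intermediate=0, n_micro=1, include_z=False,
                               micro_length=12_000_000, n_sites_per_chrom=300,
                               fraction_fixed_diff=0.2, fraction_shared_poly=0.5,
                               seed=seed)
            panels = sd.simulate_parental_panels(cfg, 6, 4, n_outgroup=2)
            a = panels.panels.parent_a
            res = ps.patterson_d_from_genotypes(
                panels.gm, (a[:3], a[3:], panels.panels.parent_b, panels.panels.outgroup)
            )
            ds.append(res.d)
            ses.append(res.se)
        ratio = np.mean(ses) / np.std(ds)
        assert 0.8 < ratio < 1.2
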