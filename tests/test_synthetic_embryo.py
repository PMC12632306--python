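import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, poisson

import twinlin as tl
from twinlin.synthetic_embryo import sample_tissue, sequence_counts


class TestSimulateLineage:
    def test_zero_mutation_rate_gives_only_denovo(self):
        p = tl.SimulationParams(mutation_rate=0.0, n_generations=5, seed=1)
        tree, catalog = tl.simulate_lineage(p)
        assert (catalog["origin_class"] == "denovo").all()
        assert set(catalog["origin_node"]) == {1}

    def test_mean_eem_count_matches_poisson_expectation(self):
        """Monte Carlo: total EEM count ~ Poisson over the 2^(g+1)-2 non-root nodes."""
        mu, g, reps = 1.2, 10, 500
        n_nonroot = 2 ** (g + 1) - 2
        expect = mu * n_nonroot
        se = np.sqrt(expect / reps)  # SE of the mean of Poisson totals
        totals = []
        for seed in range(reps):
            p = tl.SimulationParams(mutation_rate=mu, n_generations=g, seed=seed,
                                    denovo_count=0)
            _, catalog = tl.simulate_lineage(p)
            totals.append(len(catalog))
        assert abs(np.mean(totals) - expect) < 3 * se

    def test_denovo_in_all_leaves_eems_in_strict_subset(self, default_tree):
        params, tree, catalog = default_tree
        leaves = tree.cells_at(tree.n_generations)
        genotypes = [tree.genotype(leaf) for leaf in leaves[:64]]
        dn = catalog.index[catalog["origin_class"] == "denovo"]
        for v in dn[:5]:
            assert all(v in g for g in genotypes)
        eems = catalog[catalog["origin_class"] == "eem"]
        # every EEM below generation 0 is absent from at least one leaf
        all_leaf_genos = [tree.genotype(leaf) for leaf in leaves]
        for v, row in eems.head(10).iterrows():
            carried = sum(v in g for g in all_leaf_genos)
            assert 0 < carried < len(leaves)

    def test_same_seed_bit_identical(self):
        p = tl.SimulationParams(seed=42, n_generations=6)
        t1, c1 = tl.simulate_lineage(p)
        t2, c2 = tl.simulate_lineage(p)
        assert t1.node_mutations == t2.node_mutations
        pd.testing.assert_frame_equal(c1, c2)

    def test_invalid_generations_rejected(self):
        with pytest.raises(ValueError):
            tl.SimulationParams(n_generations=0)

    def test_per_node_counts_fit_poisson(self):
        """Chi-square goodness of fit of per-node EEM counts at 10k+ nodes."""
        p = tl.SimulationParams(mutation_rate=1.2, n_generations=13, seed=7,
                                denovo_count=0)
        tree, catalog = tl.simulate_lineage(p)
        n_nodes = 2**14 - 2
        counts = np.zeros(n_nodes, dtype=int)
        per_node = catalog.groupby("origin_node").size()
        counts[per_node.index.to_numpy() - 2] = per_node.to_numpy()
        kmax = 6
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = poisson.pmf(np.arange(kmax), 1.2)
        probs = np.append(probs, 1 - probs.sum())
        res = chisquare(observed, probs * n_nodes)
        assert res.pvalue > 0.01


class TestTwinning:
    def test_para_private_mutation_sets_disjoint(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "para", 3, seed=5)
        assert (part.true_a, part.true_b) == (1.0, 0.0)
        l1 = set(tree.leaves_of(int(part.twins["twin1"][0])))
        l2 = set(tree.leaves_of(int(part.twins["twin2"][0])))
        muts1 = set().union(*(tree.genotype(c) for c in l1))
        muts2 = set().union(*(tree.genotype(c) for c in l2))
        dn = set(catalog.index[catalog["origin_class"] == "denovo"])
        private1 = muts1 - muts2 - dn
        private2 = muts2 - muts1 - dn
        assert private1 and private2
        assert not (private1 & private2)

    def test_sub_twin1_nested_and_late_eems_absent_from_twin2(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "sub", 5, seed=2)
        assert part.true_a == 1.0
        assert 0 < part.true_b < 1
        c = int(part.twins["twin1"][0])
        own = set(tree.node_mutations.get(c, []))
        leaves2 = part.leaves("twin2", tree)
        muts2 = set().union(*(tree.genotype(x) for x in leaves2))
        assert not (own & muts2)  # founder's own EEMs never reach Twin 2

    def test_full_balanced_allocation_matches_hypergeometric_oracle(self):
        """Random 32/32 partition of 64 cells: with X of Twin 1's founders
        on the L1 side, a - b = (X - 16) / 16, X ~ Hypergeometric(64, 32, 32);
        E|a - b| = 0.09857 by enumeration (and the bound E|a - b| < 0.1 holds)."""
        p = tl.SimulationParams(seed=0, n_generations=7, mutation_rate=0.5)
        tree, _ = tl.simulate_lineage(p)
        diffs = []
        for seed in range(200):
            part = tl.apply_twinning(tree, "full", 6, allocation=0.5, seed=seed)
            diffs.append(abs(part.true_a - part.true_b))
        from scipy.stats import hypergeom

        x = np.arange(0, 33)
        pmf = hypergeom.pmf(x, 64, 32, 32)
        oracle_mean = float((pmf * np.abs(x - 16) / 16).sum())  # 0.09857
        oracle_sd = float(np.sqrt((pmf * (np.abs(x - 16) / 16) ** 2).sum() - oracle_mean**2))
        se = oracle_sd / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - oracle_mean) < 3 * se
        assert oracle_mean < 0.1  # the enumerated expectation meets the bound

    def test_full_targeted_contributions_exact(self, default_tree):
        _, tree, _ = default_tree
        part = tl.apply_twinning(
            tree, "full", 6, contributions=(0.75, 0.5), founders_per_twin=16, seed=1
        )
        assert part.true_a == pytest.approx(0.75)
        assert part.true_b == pytest.approx(0.5)

    def test_conservation_at_twinning(self, default_tree):
        _, tree, _ = default_tree
        for mode, kwargs in [("sub", {}), ("full", {"allocation": 0.4})]:
            part = tl.apply_twinning(tree, mode, 5, seed=3, **kwargs)
            total = sum(len(v) for v in part.twins.values())
            assert total == 2**5

    def test_full_requires_valid_allocation(self, default_tree):
        _, tree, _ = default_tree
        with pytest.raises(ValueError):
            tl.apply_twinning(tree, "full", 5, allocation=1.5)

    def test_twin_order_a_ge_b(self, default_tree):
        _, tree, _ = default_tree
        for seed in range(5):
            part = tl.apply_twinning(tree, "full", 6, allocation=0.3, seed=seed)
            assert part.true_a >= part.true_b


class TestSampling:
    def test_denovo_true_vaf_half_everywhere(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "sub", 4, seed=1)
        rng = np.random.default_rng(0)
        for twin in ("twin1", "twin2"):
            s = sample_tissue(tree, catalog, part, twin, "buccal", 16, rng)
            dn = catalog.index[catalog["origin_class"] == "denovo"]
            assert (s.cell_fraction.loc[dn] == 1.0).all()

    def test_every_eem_fraction_in_unit_interval(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "full", 5, allocation=0.5, seed=2)
        rng = np.random.default_rng(1)
        s = sample_tissue(tree, catalog, part, "twin1", "buccal", 32, rng)
        eems = s.cell_fraction.drop(
            catalog.index[catalog["origin_class"] == "denovo"], errors="ignore"
        )
        assert ((eems > 0) & (eems <= 1)).all()

    def test_absent_variant_yields_error_rate_reads(self):
        params = tl.SimulationParams(seed=0)
        rng = np.random.default_rng(0)
        frac = pd.Series(0.0, index=[f"v{i}" for i in range(2000)])
        reads = sequence_counts(frac, 700, params, rng)
        # expected alt fraction = seq_error / 3
        assert reads["alt"].sum() / reads["depth"].sum() == pytest.approx(
            params.seq_error / 3, rel=0.5
        )

    def test_unknown_twin_or_tissue_rejected(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "sub", 4, seed=1)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_tissue(tree, catalog, part, "twin9", "buccal", 8, rng)
        with pytest.raises(ValueError):
            sample_tissue(tree, catalog, part, "twin1", "liver", 8, rng)

    def test_depth_regime_validated(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "sub", 4, seed=1)
        with pytest.raises(ValueError):
            tl.sample_and_sequence(tree, catalog, part, "twin1", "buccal", 8, "nanopore", params)


class TestMixing:
    def _bloods(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "para", 3, seed=4)
        rng = np.random.default_rng(9)
        b1 = sample_tissue(tree, catalog, part, "twin1", "cord_blood", 16, rng)
        b2 = sample_tissue(tree, catalog, part, "twin2", "cord_blood", 16, rng)
        return b1, b2

    def test_f_one_matches_twin1_composition(self, default_tree):
        b1, b2 = self._bloods(default_tree)
        m1, m2 = tl.mix_cord_blood(b1, b2, 1.0, "monochorionic")
        union = b1.cell_fraction.index.union(b2.cell_fraction.index)
        pd.testing.assert_series_equal(
            m1.cell_fraction, b1.cell_fraction.reindex(union, fill_value=0.0),
            check_names=False,
        )
        pd.testing.assert_series_equal(m1.cell_fraction, m2.cell_fraction)

    def test_dichorionic_identity(self, default_tree):
        b1, b2 = self._bloods(default_tree)
        o1, o2 = tl.mix_cord_blood(b1, b2, 0.7, "dichorionic")
        assert o1 is b1 and o2 is b2
        # no EEM of one twin appears in the co-twin's unmixed blood
        e1 = set(b1.cell_fraction.index[b1.cell_fraction > 0])
        e2 = set(b2.cell_fraction.index[b2.cell_fraction > 0])
        dn = e1 & e2  # shared entries are the de novo set (fraction 1 in both)
        assert all(b1.cell_fraction[v] == 1.0 for v in dn)

    def test_linear_mixture_value(self, default_tree):
        b1, b2 = self._bloods(default_tree)
        clonal = b1.cell_fraction.index[
            (b1.cell_fraction == 1.0)
            & (b2.cell_fraction.reindex(b1.cell_fraction.index, fill_value=0) == 0)
        ]
        m1, _ = tl.mix_cord_blood(b1, b2, 0.7, "monochorionic")
        for v in clonal[:3]:
            assert m1.cell_fraction[v] == pytest.approx(0.7)  # VAF 0.35

    def test_f_out_of_range(self, default_tree):
        b1, b2 = self._bloods(default_tree)
        with pytest.raises(ValueError):
            tl.mix_cord_blood(b1, b2, 1.2, "monochorionic")


class TestSingleCells:
    def test_no_noise_matrix_equals_truth(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "sub", 4, seed=1)
        rng = np.random.default_rng(2)
        s = sample_tissue(tree, catalog, part, "twin1", "pbmc", 16, rng)
        sc = tl.ScParams(ado_rate=0.0, locus_dropout=0.0, fp_rate=0.0, n_cells=16)
        mat = tl.simulate_single_cells(tree, catalog, s, sc, seed=3)
        assert (mat.data.to_numpy() != -1).all()
        dn = [v for v in mat.variants if catalog.loc[v, "origin_class"] == "denovo"]
        assert (mat.data[dn] == 1).all().all()

    def test_missing_fraction_near_locus_dropout(self, default_tree):
        params, tree, catalog = default_tree
        part = tl.apply_twinning(tree, "sub", 4, seed=1)
        rng = np.random.default_rng(2)
        s = sample_tissue(tree, catalog, part, "twin1", "pbmc", 16, rng)
        sc = tl.ScParams(n_cells=60)  # defaults: lambda = 0.46
        mat = tl.simulate_single_cells(tree, catalog, s, sc, seed=3)
        missing = (mat.data.to_numpy() == -1).mean()
        assert missing == pytest.approx(0.46, abs=0.03)


class TestCohort:
    def test_default_composition(self):
        fams = tl.synthetic_embryo._family_categories(tl.CohortConfig())
        membranes = [m for _, m, _ in fams]
        assert membranes.count("MCMA") == 8
        assert membranes.count("MCDA") == 7
        assert membranes.count("DCDA") == 7
        assert membranes.count("DCTA") == 1
        assert membranes.count("DZ") == 6
        cats = [c for _, _, c in fams if c in ("para", "sub", "full")]
        assert sorted([cats.count("para"), cats.count("sub"), cats.count("full")]) == [3, 9, 10]

    def test_dz_twins_share_no_eem_positions(self, small_cohort):
        fam = [f for f, t in small_cohort.truth["families"].items()
               if t.get("zygosity") == "DZ"][0]
        table = small_cohort.tables[fam]
        truth = small_cohort.truth["families"][fam]
        vaf = table.pivot("vaf")
        buccal = [s for s in table.samples if s.endswith("_buccal")]
        eems = [v for v, c in truth["variant_class"].items() if c == "eem"]
        # an EEM with true presence in one twin has zero cell fraction in
        # the other; detection there is impossible beyond sequencing error
        det = (table.pivot("alt").loc[eems, buccal].fillna(0) >= 3) & (
            vaf.loc[eems, buccal].fillna(0) >= 0.03
        )
        assert (det.sum(axis=1) <= 1).all()

    def test_monochorionic_mixing_fraction_in_range(self):
        cfg = tl.CohortConfig(n_mcma=2, n_mcda=1, n_dcda=0, n_triplets=0, n_dz=0)
        bundle = tl.simulate_cohort(cfg, seed=5)
        for fam, truth in bundle.truth["families"].items():
            f = truth["blood_twin1_fraction"]["twin1_cord_blood"]
            assert 0.56 <= max(f, 1 - f) <= 0.83

    def test_golden_same_seed_byte_identical(self, tmp_path, small_config):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        tl.write_cohort(tl.simulate_cohort(small_config, seed=21), out1)
        tl.write_cohort(tl.simulate_cohort(small_config, seed=21), out2)
        files1 = sorted(p.name for p in out1.iterdir())
        assert files1 == sorted(p.name for p in out2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(out1, out2, files1, shallow=False)
        assert not mismatch and not errors

    def test_different_seed_differs(self, tmp_path, small_config):
        b1 = tl.simulate_cohort(small_config, seed=1)
        b2 = tl.simulate_cohort(small_config, seed=2)
        f = list(b1.tables)[0]
        assert not b1.tables[f].counts.equals(b2.tables[f].counts)


class TestPairVafGenerator:
    def test_cluster_positions_follow_model(self):
        df = tl.simulate_pair_vafs(0.8, 0.6, seed=1)
        anchor = df[df["cluster"] == "anchor"]
        counter = df[df["cluster"] == "counter"]
        assert anchor["vaf1_true"].to_numpy() == pytest.approx(0.4)
        assert anchor["vaf2_true"].to_numpy() == pytest.approx(0.3)
        assert counter["vaf1_true"].to_numpy() == pytest.approx(0.1)
        assert counter["vaf2_true"].to_numpy() == pytest.approx(0.2)

    def test_requires_dominant_l1(self):
        with pytest.raises(ValueError):
            tl.simulate_pair_vafs(0.4, 0.3)
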