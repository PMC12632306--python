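import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinlin as tl
from twinlin.anchor_model import (
    AnchorFitError,
    ModelConfig,
    classify_category,
    detect_anchor_clusters,
    divisions_between_founders,
    estimate_ab,
    fit_pair,
    genetic_distance,
    multisample_refine,
    triplet_topology,
)


class TestDetectClusters:
    def test_constructed_symmetric_input(self):
        pts = [(0.48, 0.29)] * 3 + [(0.02, 0.21)] * 2
        anchor, counter = detect_anchor_clusters(pts)
        assert anchor.centroid == pytest.approx((0.48, 0.29))
        assert counter.centroid == pytest.approx((0.02, 0.21))
        # the reflection of the anchor through (0.25, 0.25) is (0.02, 0.21)
        assert (0.5 - anchor.centroid[0], 0.5 - anchor.centroid[1]) == pytest.approx(
            counter.centroid
        )

    def test_all_sums_below_half_returns_counter_only(self):
        pts = [(0.05, 0.2)] * 3 + [(0.01, 0.02)] * 2
        anchor, counter = detect_anchor_clusters(pts)
        assert anchor is None
        assert counter is not None
        assert counter.centroid == pytest.approx((0.05, 0.2))

    def test_empty_input_fails(self):
        with pytest.raises(AnchorFitError):
            detect_anchor_clusters(np.empty((0, 2)))


class TestEstimateAB:
    @pytest.mark.parametrize(
        "anchor_c,counter_c,expected",
        [
            ((0.5, 0.0), (0.0, 0.5), (1.0, 0.0)),  # para geometry
            ((0.35, 0.30), (0.15, 0.20), (0.7, 0.6)),  # consistent pair
        ],
    )
    def test_both_clusters(self, anchor_c, counter_c, expected):
        from twinlin.anchor_model import Cluster

        a, b, order = estimate_ab(
            Cluster([1], anchor_c), Cluster([2], counter_c)
        )
        assert (a, b) == pytest.approx(expected)
        assert order == ("twin1", "twin2")

    def test_anchor_only(self):
        from twinlin.anchor_model import Cluster

        a, b, _ = estimate_ab(Cluster([1], (0.5, 0.3)), None)
        assert (a, b) == pytest.approx((1.0, 0.6))

    def test_both_absent_fails(self):
        with pytest.raises(AnchorFitError):
            estimate_ab(None, None)

    def test_twin_order_swap(self):
        from twinlin.anchor_model import Cluster

        a, b, order = estimate_ab(Cluster([1], (0.2, 0.45)), None, twin_names=("x", "y"))
        assert a >= b
        assert order == ("y", "x")


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(1.0, 0.0, "para"), (1.0, 0.6, "sub"), (0.7, 0.6, "full"),
         (0.95, 0.05, "para"), (0.85, 0.4, "discordant")],
    )
    def test_examples(self, a, b, expected):
        assert classify_category(a, b) == expected

    @given(
        b=st.floats(0, 1, allow_nan=False),
        frac=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_every_point_gets_exactly_one_label(self, b, frac):
        a = b + (1 - b) * frac  # guarantees 0 <= b <= a <= 1
        assert classify_category(a, b) in {"para", "sub", "full", "discordant"}

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            classify_category(0.3, 0.8)


class TestModelIdentities:
    def test_midpoint_of_anchor_and_counter_is_quarter_quarter(self):
        """Exact under the model: (anchor + counter) / 2 = (0.25, 0.25)."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            b = rng.uniform(0, 1)
            a = rng.uniform(max(b, 1 - b), 1)  # a >= b and a + b >= 1
            anchor = np.array([a / 2, b / 2])
            counter = np.array([(1 - a) / 2, (1 - b) / 2])
            assert np.allclose((anchor + counter) / 2, [0.25, 0.25])

    def test_l1_plus_l2_account_for_all_soma(self):
        """2*anchor VAF + 2*counter VAF = 1 in each twin (100% identity)."""
        df = tl.simulate_pair_vafs(0.8, 0.55, seed=0)
        v_a = df[df["cluster"] == "anchor"][["vaf1_true", "vaf2_true"]].iloc[0]
        v_c = df[df["cluster"] == "counter"][["vaf1_true", "vaf2_true"]].iloc[0]
        total = 2 * v_a.to_numpy() + 2 * v_c.to_numpy()
        assert total == pytest.approx([1.0, 1.0])


class TestFitPair:
    def test_twin_order_invariance(self):
        df = tl.simulate_pair_vafs(1.0, 0.5, seed=4)
        v = df[["vaf1", "vaf2"]].to_numpy()
        fit1 = fit_pair(v, twin_names=("t1", "t2"))
        fit2 = fit_pair(v[:, ::-1], twin_names=("t2", "t1"))
        assert fit1.a == pytest.approx(fit2.a, abs=1e-9)
        assert fit1.b == pytest.approx(fit2.b, abs=1e-9)
        assert fit1.twin_order[0] == fit2.twin_order[0] == "t1"
        assert fit1.category == fit2.category

    @pytest.mark.parametrize(
        "a,b,cat", [(1.0, 0.0, "para"), (1.0, 0.5, "sub"), (0.7, 0.7, "full")]
    )
    def test_recovers_known_geometry(self, a, b, cat):
        df = tl.simulate_pair_vafs(a, b, seed=11)
        fit = fit_pair(df[["vaf1", "vaf2"]].to_numpy())
        assert abs(fit.a - a) <= 0.05
        assert abs(fit.b - b) <= 0.05
        assert fit.category == cat


class TestDistanceAndDivisions:
    def test_genetic_distance_counts_singletons(self):
        det = pd.DataFrame({"t1": [1, 1, 1, 0, 0], "t2": [1, 0, 0, 1, 0]}).astype(bool)
        assert genetic_distance(det) == 3

    def test_all_shared_zero(self):
        det = pd.DataFrame({"t1": [1, 1], "t2": [1, 1]}).astype(bool)
        assert genetic_distance(det) == 0

    @pytest.mark.parametrize(
        "n,mode,expected", [(6, "round", 5), (5, "floor", 4), (0, "round", 0)]
    )
    def test_division_examples(self, n, mode, expected):
        assert divisions_between_founders(n, 1.2, mode=mode) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            divisions_between_founders(-1, 1.2)


class TestMultisampleRefine:
    def _matrix(self):
        # three nested lineages over 8 samples, noise-free
        samples = [f"s{i}" for i in range(8)]
        rows = {
            "root1": [0.5] * 8,
            "root2": [0.5] * 8,
            "cladeA1": [0.4, 0.45, 0.5, 0.42, 0.0, 0.0, 0.0, 0.0],
            "cladeA2": [0.38, 0.44, 0.48, 0.40, 0.0, 0.0, 0.0, 0.0],
            "cladeB1": [0.0, 0.0, 0.0, 0.0, 0.35, 0.3, 0.4, 0.33],
            "subA1": [0.2, 0.22, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        }
        return pd.DataFrame(rows, index=samples).T

    def test_noise_free_clades_recovered(self):
        ref = multisample_refine(self._matrix())
        lab = ref.labels
        assert lab["root1"] == lab["root2"]
        assert lab["cladeA1"] == lab["cladeA2"]
        assert lab["cladeA1"] != lab["cladeB1"]
        assert lab["subA1"] not in (lab["cladeA1"], lab["cladeB1"], lab["root1"])
        assert ref.newick.endswith(";")

    def test_nesting_follows_detection_containment(self):
        ref = multisample_refine(self._matrix())
        # the root cluster (detected everywhere) must be ancestral: it is
        # the outermost label in the Newick string
        root_label = ref.labels["root1"]
        assert ref.newick.rstrip(";").endswith(root_label)

    def test_fewer_than_three_samples_refused(self):
        m = self._matrix().iloc[:, :2]
        with pytest.raises(ValueError, match="anchor"):
            multisample_refine(m)

    def test_cluster_recovery_at_low_placental_depth(self):
        """EEM clusters recovered from noisy multi-tissue VAF profiles.

        Eight samples (2 buccal-like, 2 cord-like, 4 shallow placental
        patches at 24x) with five true origin clusters; adjusted Rand index
        vs the generating clusters must reach 0.8 on average.
        """
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        depths = [60, 60, 60, 60, 24, 24, 24, 24]
        # five lineages with distinct sample-fraction profiles
        profiles = {
            "anchor": [1.0, 1.0, 0.9, 0.8, 0.6, 1.0, 0.9, 0.7],
            "counter": [0.0, 0.0, 0.1, 0.2, 0.4, 0.0, 0.1, 0.3],
            "cladeA": [0.6, 0.5, 0.0, 0.0, 0.3, 0.8, 0.0, 0.0],
            "cladeB": [0.4, 0.5, 0.0, 0.0, 0.0, 0.0, 0.9, 0.1],
            "cladeC": [0.0, 0.0, 0.6, 0.5, 0.0, 0.0, 0.0, 0.6],
        }
        aris = []
        for _ in range(20):
            rows, labels = [], []
            for name, frac in profiles.items():
                for _k in range(4):  # four EEMs per cluster
                    d = rng.poisson(depths)
                    v = np.array(frac) / 2
                    alt = rng.binomial(d, v)
                    rows.append(np.where(d > 0, alt / np.maximum(d, 1), 0.0))
                    labels.append(name)
            m = pd.DataFrame(rows, index=[f"e{i}" for i in range(len(rows))],
                             columns=[f"s{j}" for j in range(8)])
            ref = multisample_refine(m)
            aris.append(adjusted_rand_score(labels, ref.labels.to_numpy()))
        assert np.mean(aris) >= 0.8

    def test_refinement_splits_profile_outlier(self):
        """An EEM co-located with the counter-anchor in two samples but with
        a distinct multi-tissue profile lands in its own cluster."""
        m = self._matrix()
        m.loc["impostor"] = [0.0, 0.0, 0.0, 0.0, 0.35, 0.3, 0.0, 0.0]
        m.loc["impostor", "s0"] = 0.3  # distinct placental-style profile
        ref = multisample_refine(m)
        assert ref.labels["impostor"] != ref.labels["cladeB1"]


class TestTripletTopology:
    def _fit(self, cat, pure):
        from twinlin.anchor_model import AnchorFit

        return AnchorFit(None, None, 1.0, 0.5 if cat == "sub" else 0.0,
                         (pure, "other"), cat, 0.1)

    def test_two_consecutive_buds_resolved(self):
        fits = {
            ("T1", "T2"): self._fit("sub", "T1"),
            ("T1", "T3"): self._fit("sub", "T1"),
            ("T2", "T3"): self._fit("sub", "T2"),
        }
        shared = {("T1", "T2"): 9, ("T1", "T3"): 4, ("T2", "T3"): 4}
        topo = triplet_topology(fits, shared)
        assert topo.status == "resolved"
        assert topo.newick == "((T1,T2),T3);"

    def test_three_para_pairs_star(self):
        fits = {p: self._fit("para", p[0]) for p in
                [("T1", "T2"), ("T1", "T3"), ("T2", "T3")]}
        shared = {p: 0 for p in fits}
        topo = triplet_topology(fits, shared)
        assert topo.status == "star"

    def test_inconsistent_nesting_flagged(self):
        fits = {
            ("T1", "T2"): self._fit("sub", "T1"),
            ("T1", "T3"): self._fit("sub", "T3"),  # T3 pure: contradicts T3 outer
            ("T2", "T3"): self._fit("sub", "T2"),
        }
        shared = {("T1", "T2"): 9, ("T1", "T3"): 2, ("T2", "T3"): 2}
        topo = triplet_topology(fits, shared)
        assert topo.status == "unresolvable"

    def test_simulated_triplets_recovered(self):
        ok = 0
        for seed in range(10):
            cfg = tl.CohortConfig(n_mcma=0, n_mcda=0, n_dcda=0, n_dz=0, n_triplets=1)
            b = tl.simulate_cohort(cfg, seed=100 + seed)
            fam = list(b.tables)[0]
            from twinlin.pipeline import _analyze_triplet

            r = _analyze_triplet(b.tables[fam], fam, b.targeted[fam])
            ok += r.get("topology") == "((triplet1,triplet2),triplet3);"
        assert ok >= 9
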