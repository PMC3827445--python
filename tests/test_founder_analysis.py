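"""Founder identification under f-criteria, founder dating and the
migration-time scan."""

import numpy as np
import pandas as pd
import pytest

from conftest import unique_mutations
from phylofounder.clade_dating import HVS1_CLOCK, ClockModel, piecewise_correction
from phylofounder.errors import ConfigurationError
from phylofounder.founder_analysis import (
    FounderCluster,
    define_sink,
    founder_age,
    identify_founders,
    migration_scan,
)
from phylofounder.synthetic_data import DemeConfig, FounderEvent, Scenario, simulate_dataset
from phylofounder.tree import RootedMutationTree

SOURCE = {"S1", "S2"}
SINK = {"K1", "K2"}


class TestIdentifyFounders:
    def test_f1_recovers_toy_cluster(self, toy_founder_tree):
        clusters = identify_founders(toy_founder_tree, SOURCE, SINK, "f1")
        assert len(clusters) == 1
        c = clusters[0]
        assert c.founder_node == "h"
        assert (c.n_f, c.m_f, c.rho_f) == (2, 3, 1.5)
        assert not c.at_root

    def test_f2_rejects_single_derived_branch_node(self, toy_founder_tree):
        """With only one derived source branch at h, f2 pushes the founder
        rootward (here: to the root, with a warning)."""
        with pytest.warns(UserWarning, match="root"):
            clusters = identify_founders(toy_founder_tree, SOURCE, SINK, "f2")
        assert len(clusters) == 1
        assert clusters[0].founder_node == "root"
        assert clusters[0].at_root

    def test_f0_accepts_plain_match(self, toy_founder_tree):
        clusters = identify_founders(toy_founder_tree, SOURCE, SINK, "f0")
        assert clusters[0].founder_node == "h"

    def test_empty_sink_gives_empty_list(self, toy_founder_tree):
        assert identify_founders(toy_founder_tree, SOURCE, set(), "f1") == []

    def test_direct_match_without_derived_source_branch_suppressed(self):
        """A sink tip matching a source tip directly (recent back migration)
        must not found a cluster at that node under f1."""
        muts = unique_mutations()
        t = RootedMutationTree("root")
        t.add_child("root", "n1", [next(muts)], multiplicity=2, sample_ids=("S1", "K1"))
        with pytest.warns(UserWarning):
            clusters = identify_founders(t, {"S1"}, {"K1"}, "f1")
        assert clusters[0].founder_node != "n1"

    def test_f0_would_accept_the_direct_match(self):
        muts = unique_mutations()
        t = RootedMutationTree("root")
        t.add_child("root", "n1", [next(muts)], multiplicity=2, sample_ids=("S1", "K1"))
        clusters = identify_founders(t, {"S1"}, {"K1"}, "f0")
        assert clusters[0].founder_node == "n1"
        assert clusters[0].rho_f == 0.0

    def test_overlapping_ids_rejected(self, toy_founder_tree):
        with pytest.raises(ValueError):
            identify_founders(toy_founder_tree, {"S1", "K1"}, {"K1"}, "f1")

    def test_missing_samples_rejected(self, toy_founder_tree):
        with pytest.raises(ValueError, match="absent"):
            identify_founders(toy_founder_tree, {"S1", "ghost"}, SINK, "f1")

    def test_sigma_and_neff_on_toy_cluster(self, toy_founder_tree):
        c = identify_founders(toy_founder_tree, SOURCE, SINK, "f1")[0]
        # branches below h used by sink members: k1 (1 mut, w=1/2), k2 (2, w=1/2)
        assert c.sigma_f == pytest.approx(np.sqrt(0.25 * 1 + 0.25 * 2))
        assert c.n_eff == pytest.approx(1.5 / 0.75)

    def test_conservation_and_criterion_monotonicity(self):
        """Cluster sizes always sum to the sink count, and stricter criteria
        push each sink lineage to an equal-or-closer-to-root founder."""
        for seed in range(10):
            sc = Scenario(
                source=DemeConfig(12, "star"),
                sink=DemeConfig(12, "constant", ne_years=20_000),
                founder_events=(FounderEvent(30_000.0, 2),),
                seed=seed,
            )
            ds = simulate_dataset(sc)
            tree = ds.to_mutation_tree()
            depth = {n: len(tree.path_to_root(n)) for n in tree.nodes}
            assignments = {}
            for crit in ("f0", "f1", "f2"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # root fallthroughs expected
                    clusters = identify_founders(
                        tree, ds.source_ids(), ds.sink_ids(), crit
                    )
                assert sum(c.n_f for c in clusters) == len(ds.sink_ids())
                assignments[crit] = {
                    s: depth[c.founder_node] for c in clusters for s in c.sink_members
                }
            for s in assignments["f0"]:
                assert assignments["f1"][s] <= assignments["f0"][s]
                assert assignments["f2"][s] <= assignments["f1"][s]


class TestFounderAge:
    def make(self, rho, n_f=2):
        m = int(rho * n_f)
        from phylofounder.clade_dating import age_from_rho

        return FounderCluster(
            founder_node="x", founder_label="F1",
            sink_members=["a"] * n_f, m_f=m, sigma_f=0.5,
            n_eff=float(n_f), age=age_from_rho(rho, 0.5, HVS1_CLOCK, n_f),
        )

    def test_hvs1_conversion(self):
        assert founder_age(self.make(1.5), HVS1_CLOCK).age_years == pytest.approx(25_015.5)
        assert founder_age(self.make(1.0), HVS1_CLOCK).age_years == pytest.approx(16_677.0)

    def test_zero_rho(self):
        c = self.make(0.0)
        assert founder_age(c, HVS1_CLOCK).age_years == 0.0


class TestMigrationScan:
    def cluster(self, rho_f, n_f, n_eff=None):
        from phylofounder.clade_dating import age_from_rho

        m_f = int(round(rho_f * n_f))
        return FounderCluster(
            founder_node="x", founder_label=f"F{n_f}_{rho_f}",
            sink_members=[f"k{i}" for i in range(n_f)], m_f=m_f,
            sigma_f=0.1, n_eff=float(n_eff if n_eff is not None else n_f),
            age=age_from_rho(rho_f, 0.1, HVS1_CLOCK, n_f),
        )

    def test_zero_mutations_peak_at_time_zero(self):
        scan = migration_scan([self.cluster(0.0, 5)])
        assert scan.mode_years == 0.0
        assert scan.aggregate[0] == scan.aggregate.max()

    def test_mode_matches_analytic_gamma_mode(self):
        clock = ClockModel("toy", 1000.0)
        c = self.cluster(1.0, 1, n_eff=1)
        scan = migration_scan([c], clock, grid_step=200.0, t_max=10_000.0)
        assert scan.mode_years == pytest.approx(1000.0)  # m_eff * mu / n_eff

    def test_identical_clusters_aggregate_equals_each(self):
        a, b = self.cluster(2.0, 10), self.cluster(2.0, 10)
        b.founder_label = "other"
        scan = migration_scan([a, b])
        np.testing.assert_allclose(scan.aggregate, scan.per_founder[a.founder_label])

    def test_masses_normalized_and_nonnegative(self):
        rng = np.random.default_rng(2)
        clusters = [
            self.cluster(float(rng.uniform(0, 4)), int(rng.integers(1, 30)))
            for _ in range(6)
        ]
        for i, c in enumerate(clusters):
            c.founder_label = f"F{i}"
        scan = migration_scan(clusters)
        for mass in scan.per_founder.values():
            assert mass.min() >= 0
            assert abs(mass.sum() - 1) < 1e-9
        assert abs(scan.aggregate.sum() - 1) < 1e-9

    def test_aggregate_weights_are_sink_frequencies(self):
        a, b = self.cluster(1.0, 30), self.cluster(3.0, 10)
        b.founder_label = "B"
        scan = migration_scan([a, b])
        assert scan.weights[a.founder_label] == pytest.approx(0.75)
        expected = 0.75 * scan.per_founder[a.founder_label] + 0.25 * scan.per_founder["B"]
        np.testing.assert_allclose(scan.aggregate, expected / expected.sum())

    def test_mode_beyond_grid_warns(self):
        with pytest.warns(UserWarning, match="beyond"):
            migration_scan([self.cluster(10.0, 5)], t_max=20_000.0)

    def test_corrected_clock_rejected(self):
        bent = ClockModel("bent", 1000.0, piecewise_correction([(1000.0, 3000.0)]))
        with pytest.raises(ValueError):
            migration_scan([self.cluster(1.0, 5)], bent)

    def test_empty_clusters_rejected(self):
        with pytest.raises(ValueError):
            migration_scan([])


class TestDefineSink:
    META = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c", "d"],
            "population": ["Xhosa", "Sotho", "Somali", "Daza"],
            "region": ["southern", "southern", "eastern", "central"],
        }
    )

    def test_region_filter(self):
        sink, source = define_sink(self.META, "region == 'southern'")
        assert sink == {"a", "b"} and source == {"c", "d"}

    def test_compound_filter(self):
        sink, _ = define_sink(
            self.META, "region == 'southern' and population == 'Sotho'"
        )
        assert sink == {"b"}

    def test_missing_column_rejected(self):
        with pytest.raises(ConfigurationError):
            define_sink(self.META, "language == 'bantu'")

    def test_empty_result_rejected(self):
        with pytest.raises(ConfigurationError):
            define_sink(self.META, "region == 'northern'")
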