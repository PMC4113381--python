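"""Synthetic-data generator: bookkeeping, determinism, and null behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import zonemap as zm
from zonemap.simulate import _platform_universes, _substream


class TestSimulateDataset:
    def test_matrix_shape_matches_design(self):
        design = zm.SimulationDesign(tissues=[("T", ("A", "B"))], n_genes=1000,
                                     n_replicates=4, seed=1)
        matrix, _ = zm.simulate_dataset(design, "T")
        assert matrix.values.shape == (1000, 8)
        assert matrix.zones == ["A", "B"]

    def test_seeded_determinism(self, two_zone_design):
        m1, t1 = zm.simulate_dataset(two_zone_design, "T")
        m2, t2 = zm.simulate_dataset(two_zone_design, "T")
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.planted == t2.planted

    def test_empty_program_list_gives_empty_truth(self):
        design = zm.SimulationDesign(tissues=[("T", ("A", "B"))], n_genes=50,
                                     n_replicates=2, seed=3)
        _, truth = zm.simulate_dataset(design, "T")
        assert all(len(v) == 0 for v in truth.planted.values())

    def test_values_are_finite(self, two_zone_design):
        matrix, _ = zm.simulate_dataset(two_zone_design, "T")
        assert np.isfinite(matrix.values.to_numpy()).all()

    def test_planted_truth_thresholded_on_effect_difference(self, two_zone_design):
        _, truth = zm.simulate_dataset(two_zone_design, "T")
        up_a = truth.planted_for("T", "A", "B", "A")
        # program amplitudes start at log2(2.5) >= log2(2): all 30 planted
        assert len(up_a) == 30
        assert truth.planted_for("T", "A", "B", "B") == frozenset()

    def test_unknown_tissue_raises(self, two_zone_design):
        with pytest.raises(KeyError, match="unknown tissue"):
            zm.simulate_dataset(two_zone_design, "nope")

    def test_null_anova_pvalues_are_uniform(self):
        """With no planted effects, per-gene ANOVA p is U(0,1) (KS check)."""
        design = zm.SimulationDesign(tissues=[("T", ("A", "B"))], n_genes=1000,
                                     n_replicates=4, seed=11)
        matrix, _ = zm.simulate_dataset(design, "T")
        a = matrix.zone_values("A").to_numpy()
        b = matrix.zone_values("B").to_numpy()
        _, p = stats.f_oneway(a, b, axis=1)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestDesignValidation:
    @pytest.mark.parametrize("kwargs", [
        {"rho": 1.5}, {"rho": -0.1}, {"platform_overlap": 2.0},
        {"sigma": 0.0}, {"n_replicates": 1}, {"n_genes": 0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            zm.SimulationDesign(tissues=[("T", ("A", "B"))], **kwargs)

    def test_tissue_pair_requires_two_tissues(self, two_zone_design):
        with pytest.raises(ValueError, match="2 tissues"):
            zm.simulate_tissue_pair(two_zone_design)


class TestTissuePair:
    def make_design(self, rho, overlap=0.8, seed=5, size=30, n_genes=400):
        programs = [
            zm.ZoneProgram("pa", "X", {"A": 1.0}, size=size),
            zm.ZoneProgram("pb", "Y", {"C": 1.0}, size=size),
        ]
        return zm.SimulationDesign(
            tissues=[("X", ("A", "B")), ("Y", ("C", "D"))], n_genes=n_genes,
            programs=programs, correspondences=[("pa", "pb")], rho=rho,
            platform_overlap=overlap, seed=seed)

    def test_platform_overlap_fraction(self):
        design = self.make_design(rho=0.5, overlap=0.8)
        a, b, _ = zm.simulate_tissue_pair(design)
        inter = len(a.gene_universe & b.gene_universe)
        assert abs(inter - 0.8 * design.n_genes) <= 1

    def test_full_overlap_gives_identical_universes(self):
        design = self.make_design(rho=0.5, overlap=1.0)
        a, b, _ = zm.simulate_tissue_pair(design)
        assert a.gene_universe == b.gene_universe

    def test_rho_zero_means_no_deliberate_sharing(self):
        _, _, truth = zm.simulate_tissue_pair(self.make_design(rho=0.0))
        assert truth.shared_pairs == {}

    def test_rho_one_shares_entire_program(self):
        _, _, truth = zm.simulate_tissue_pair(self.make_design(rho=1.0))
        share = truth.shared_pairs[(("X", ("A", "B"), "A"), ("Y", ("C", "D"), "C"))]
        assert len(share) == 30
        assert share == truth.planted_for("X", "A", "B", "A")

    def test_shared_fraction_matches_rho(self):
        _, _, truth = zm.simulate_tissue_pair(self.make_design(rho=0.6))
        (share,) = set(truth.shared_pairs.values())
        assert abs(len(share) - 0.6 * 30) <= 0.5

    def test_shared_genes_planted_on_both_sides(self):
        _, _, truth = zm.simulate_tissue_pair(self.make_design(rho=0.8))
        for (ka, kb), genes in truth.shared_pairs.items():
            assert genes <= truth.planted[ka]
            assert genes <= truth.planted[kb]

    def test_overcommitted_rho_raises(self):
        programs = [
            zm.ZoneProgram("pa", "X", {"A": 1.0}, size=30),
            zm.ZoneProgram("pb", "Y", {"C": 1.0}, size=30),
            zm.ZoneProgram("pc", "Y", {"D": 1.0}, size=30),
        ]
        design = zm.SimulationDesign(
            tissues=[("X", ("A", "B")), ("Y", ("C", "D"))], n_genes=400,
            programs=programs, rho=0.8,
            correspondences=[("pa", "pb"), ("pa", "pc")], seed=1)
        with pytest.raises(ValueError, match="cannot honor rho"):
            zm.simulate_tissue_pair(design)

    def test_pair_determinism(self):
        design = self.make_design(rho=0.8)
        a1, b1, _ = zm.simulate_tissue_pair(design)
        a2, b2, _ = zm.simulate_tissue_pair(design)
        pd.testing.assert_frame_equal(a1.values, a2.values)
        pd.testing.assert_frame_equal(b1.values, b2.values)


class TestSimulateQpcr:
    ZONES = ("SZ", "IDZ")

    def profile(self, effect=0.0):
        return {"18S": {z: 0.0 for z in self.ZONES},
                "gene1": {"SZ": effect, "IDZ": 0.0}}

    def test_zero_effect_zero_noise_equal_expression(self):
        table = zm.simulate_qpcr(self.profile(0.0), noise_sd=0.0, seed=2)
        rel = zm.relative_expression_table(table)
        by_zone = rel.groupby("zone")["relative_expression"].mean()
        assert np.allclose(by_zone["SZ"], by_zone["IDZ"])

    def test_one_log2_effect_doubles_expression(self):
        table = zm.simulate_qpcr(self.profile(1.0), noise_sd=0.0, seed=2)
        rel = zm.relative_expression_table(table).groupby("zone")[
            "relative_expression"].mean()
        assert np.isclose(rel["SZ"], 2.0 * rel["IDZ"])

    def test_triplicates_and_reference_everywhere(self):
        table = zm.simulate_qpcr(self.profile(1.0), n_animals=4, seed=2)
        counts = table.data.groupby(["animal", "zone", "gene"]).size()
        assert (counts == 3).all()
        assert set(table.data["gene"]) == {"18S", "gene1"}

    def test_determinism(self):
        t1 = zm.simulate_qpcr(self.profile(1.0), seed=9)
        t2 = zm.simulate_qpcr(self.profile(1.0), seed=9)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_missing_reference_gene_raises(self):
        with pytest.raises(KeyError, match="reference gene"):
            zm.simulate_qpcr({"gene1": {"SZ": 0.0, "IDZ": 0.0}}, seed=1)

    def test_too_few_animals_raises(self):
        with pytest.raises(ValueError, match="2 animals"):
            zm.simulate_qpcr(self.profile(), n_animals=1)


class TestSimulateProbeMatrix:
    def gene_values(self):
        return pd.DataFrame([[8.0, 9.0, 10.0], [6.0, 6.5, 7.0]],
                            index=["g1", "g2"], columns=["s1", "s2", "s3"])

    def test_zero_noise_zero_offsets_reproduce_gene_values(self):
        pm = zm.simulate_probe_matrix(self.gene_values(), 3, np.zeros(3),
                                      noise_sd=0.0, seed=1)
        logged = np.log2(pm.values.to_numpy())
        expected = np.repeat(self.gene_values().to_numpy(), 3, axis=0)
        assert np.allclose(logged, expected)

    def test_median_polish_recovers_gene_profile_up_to_constant(self):
        offsets = np.array([-0.5, 0.0, 0.8])
        pm = zm.simulate_probe_matrix(self.gene_values(), 3, offsets,
                                      noise_sd=0.0, seed=1)
        summary = zm.summarize_probes(pm, quantile=False)
        for g in ("g1", "g2"):
            diff = summary.loc[g].to_numpy() - self.gene_values().loc[g].to_numpy()
            assert np.allclose(diff - diff[0], 0.0, atol=1e-9)

    def test_determinism_and_mapping(self):
        pm1 = zm.simulate_probe_matrix(self.gene_values(), 2, [0.1, -0.1],
                                       noise_sd=0.2, seed=4)
        pm2 = zm.simulate_probe_matrix(self.gene_values(), 2, [0.1, -0.1],
                                       noise_sd=0.2, seed=4)
        pd.testing.assert_frame_equal(pm1.values, pm2.values)
        assert pm1.genes == ["g1", "g2"]

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="probe_offsets"):
            zm.simulate_probe_matrix(self.gene_values(), 3, [0.0, 0.0])


def test_substreams_differ_by_label():
    s1 = _substream(1, "matrix", "A").normal(size=4)
    s2 = _substream(1, "matrix", "B").normal(size=4)
    assert not np.allclose(s1, s2)


def test_platform_universes_sizes():
    design = zm.SimulationDesign(tissues=[("X", ("A", "B")), ("Y", ("C", "D"))],
                                 n_genes=100, platform_overlap=0.37, seed=0)
    a, b, shared = _platform_universes(design, np.random.default_rng(0))
    assert len(a) == len(b) == 100
    assert len(set(a) & set(b)) == len(shared) == 37
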