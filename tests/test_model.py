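import numpy as np
import pytest

from traitgroups import (ConsensusClustering, ErrorModel, adjusted_rand_index)
from traitgroups.consensus import ConsensusAccumulator


def _small_model(four_group_mixture, **kwargs):
    table, _, error_model = four_group_mixture
    defaults = dict(n_resamples=4, g_range=(2, 6), k_range=(2, 8),
                    em_restarts=1)
    defaults.update(kwargs)
    return ConsensusClustering(table, error_model, **defaults)


class TestConfigValidation:
    def test_invalid_k_range_fails_before_compute(self, four_group_mixture):
        table, _, error_model = four_group_mixture
        with pytest.raises(ValueError, match="K range"):
            ConsensusClustering(table, error_model,
                                k_range=(2, table.n_species + 1))

    def test_invalid_g_range_fails_before_compute(self, four_group_mixture):
        table, _, error_model = four_group_mixture
        with pytest.raises(ValueError, match="G range"):
            ConsensusClustering(table, error_model,
                                g_range=(10, table.n_species))

    def test_missing_taxon_in_error_model(self, small_table):
        incomplete = ErrorModel.from_pools({
            ("angiosperm", j): [0.0] for j in small_table.trait_names
        })
        with pytest.raises(ValueError, match="gymnosperm"):
            ConsensusClustering(small_table, incomplete, g_range=(1, 2),
                                k_range=(2, 4))

    def test_unknown_modes_rejected(self, four_group_mixture):
        table, _, error_model = four_group_mixture
        for bad in (dict(assignment="mode"), dict(scale="zscore"),
                    dict(scale_refit="sometimes")):
            with pytest.raises(ValueError):
                ConsensusClustering(table, error_model, **bad)


class TestFit:
    def test_same_seed_bit_reproducible(self, four_group_mixture):
        model = _small_model(four_group_mixture)
        a = model.fit(seed=9)
        b = model.fit(seed=9)
        np.testing.assert_array_equal(a.consensus.values, b.consensus.values)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.selected_K == b.selected_K

    def test_recovers_known_groups(self, four_group_mixture):
        table, truth, _ = four_group_mixture
        model = _small_model(four_group_mixture)
        results = model.fit(seed=0)
        assert results.selected_K == 4
        assert adjusted_rand_index(results.labels, truth) >= 0.95

    def test_accumulation_is_order_independent(self, four_group_mixture):
        """Resamples are embarrassingly parallel: accumulating the members
        in any order yields the identical consensus matrix."""
        model = _small_model(four_group_mixture)
        members = [model._fit_member(50 + s, s) for s in range(1, 5)]
        n = model.trait_table.n_species
        forward, backward = ConsensusAccumulator(n), ConsensusAccumulator(n)
        for m in members:
            forward.add_member(m)
        for m in reversed(members):
            backward.add_member(m)
        np.testing.assert_array_equal(forward.finalize().values,
                                      backward.finalize().values)

    def test_sampling_mode_accumulates_s_times_a_vectors(self,
                                                         four_group_mixture):
        model = _small_model(four_group_mixture, assignment="sample",
                            n_assignments=3, n_resamples=2)
        results = model.fit(seed=1)
        assert results.consensus.n_samples_total == 6

    def test_scaling_variants_run(self, four_group_mixture):
        for kwargs in (dict(scale="none"),
                       dict(scale="robust", scale_refit="from_x")):
            model = _small_model(four_group_mixture, n_resamples=2, **kwargs)
            results = model.fit(seed=3)
            assert results.selected_K >= 2


@pytest.fixture(scope="module")
def results(four_group_mixture):
    return _small_model(four_group_mixture).fit(seed=0)


class TestResults:

    def test_summary_reports_key_quantities(self, results):
        text = results.summary()
        assert f"Selected K*                 {results.selected_K}" in text
        assert "Consensus SE bound" in text
        assert "Within-group consensus" in text

    def test_diagnostic_tables_are_consistent(self, results):
        curves = results.bic_curves()
        assert set(curves.columns) == {"resample", "G", "bic"}
        assert curves["resample"].nunique() == 4
        sil = results.silhouette_curve()
        np.testing.assert_allclose(sil["mean"],
                                   sil["total"] / results.partition.n_species)
        stab = results.species_stability()
        assert np.nanmin(stab) >= 0 and np.nanmax(stab) <= 1

    def test_artifact_round_trips(self, results, tmp_path):
        from traitgroups import load_consensus, read_labels

        results.save_labels(tmp_path / "labels.csv")
        ids, labels = read_labels(tmp_path / "labels.csv")
        np.testing.assert_array_equal(labels, results.labels)
        results.save_consensus(tmp_path / "c.h5")
        back = load_consensus(tmp_path / "c.h5")
        np.testing.assert_allclose(back.values, results.consensus.values,
                                   atol=1e-7)
        newick = results.to_newick(tmp_path / "tree.nwk")
        assert newick.count(",") == results.partition.n_species - 1

    def test_group_map_covers_all_species(self, results):
        gmap = results.group_map()
        assert len(gmap) == results.partition.n_species
        assert set(gmap.values()) == set(range(1, results.selected_K + 1))


class TestCli:
    def test_simulate_cluster_diversity_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from traitgroups.cli import main

        runner = CliRunner()
        prefix = str(tmp_path / "sim")
        out = runner.invoke(main, [
            "simulate", "--n-species", "120", "--n-traits", "3",
            "--n-groups", "3", "--seed", "1", "--out", prefix,
        ])
        assert out.exit_code == 0, out.output
        out = runner.invoke(main, [
            "cluster", "--traits", f"{prefix}_traits.csv",
            "--errors", f"{prefix}_errors.csv",
            "--n-resamples", "3", "--g-min", "2", "--g-max", "5",
            "--k-min", "2", "--k-max", "6", "--seed", "1",
            "--out", str(tmp_path / "run"),
        ])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "run" / "labels.csv").exists()
        assert (tmp_path / "run" / "consensus.h5").exists()
        assert (tmp_path / "run" / "dendrogram.nwk").exists()
        assert "Selected K*" in out.output

        comm = tmp_path / "community.csv"
        from traitgroups import read_labels

        ids, _ = read_labels(tmp_path / "run" / "labels.csv")
        header = ",".join(["site"] + [str(s) for s in ids[:6]])
        comm.write_text(f"{header}\nsiteA,1,1,1,0,1,1\nsiteB,1,0,0,1,1,0\n")
        out = runner.invoke(main, [
            "diversity", "--community", str(comm),
            "--groups", str(tmp_path / "run" / "labels.csv"),
            "--min-groups", "2", "--out", str(tmp_path / "metrics.csv"),
        ])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "metrics.csv").exists()

        out = runner.invoke(main, [
            "inspect", "--consensus", str(tmp_path / "run" / "consensus.h5"),
        ])
        assert out.exit_code == 0, out.output
        assert "SE bound" in out.output

    def test_cluster_reports_input_errors_cleanly(self, tmp_path):
        from click.testing import CliRunner

        from traitgroups.cli import main

        traits = tmp_path / "t.csv"
        traits.write_text("species,a\nx,1\nx,2\n")
        errors = tmp_path / "e.csv"
        errors.write_text("taxon,trait,error_value\nall,a,0.0\n")
        runner = CliRunner()
        out = runner.invoke(main, [
            "cluster", "--traits", str(traits), "--errors", str(errors),
            "--out", str(tmp_path / "o"),
        ])
        assert out.exit_code == 2
        assert "input error" in out.output
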