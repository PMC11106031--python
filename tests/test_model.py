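"""End-to-end model fitting: probability bookkeeping, modes, persistence."""

import numpy as np
import pandas as pd
import pytest

from rdpeaks import BinningParams, RnaDnaPeakModel
from rdpeaks.io import FineTrack, GeneRecord, load_dataset, read_narrowpeak
from rdpeaks import model as model_mod


class TestProbabilityBookkeeping:
    def test_probabilities_sum_to_one(self, small_results):
        for fit in small_results.fits.values():
            assert fit.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cis_compartment_carries_cis_fraction(self, small_results):
        for fit in small_results.fits.values():
            cis = fit.grid.table.is_cis.to_numpy() & ~fit.grid.table.is_gene_body.to_numpy()
            assert fit.probs[cis].sum() == pytest.approx(fit.n_cis / fit.n_total, abs=1e-9)

    def test_counts_conserved(self, small_results, small_sim):
        contacts, _, _ = small_sim
        fit = small_results.fits["simRNA"]
        assert fit.counts.sum() + fit.n_rejected == len(contacts)


class TestModes:
    def test_no_scaling_changes_only_cis(self, small_model, small_results):
        flat = small_model.fit(no_scaling=True)
        default_fit = small_results.fits["simRNA"]
        flat_fit = flat.fits["simRNA"]
        trans = ~default_fit.grid.table.is_cis.to_numpy()
        np.testing.assert_allclose(
            default_fit.pvalue[trans], flat_fit.pvalue[trans], rtol=1e-10
        )
        cis_tested = ~trans & default_fit.tested & (default_fit.counts > 0)
        assert not np.allclose(
            default_fit.pvalue[cis_tested], flat_fit.pvalue[cis_tested]
        )
        assert (flat_fit.scaling_factor == 1.0).all()

    def test_uniform_background_differs_on_heterogeneous_input(self, small_model):
        default = small_model.fit()
        uniform = small_model.fit(no_background=True)
        d = default.fits["simRNA"]
        u = uniform.fits["simRNA"]
        assert not np.allclose(d.bg_prob, u.bg_prob)
        assert not np.allclose(
            d.pvalue[d.tested], u.pvalue[u.tested], rtol=1e-3
        )

    def test_parallel_equals_serial(self, small_model, small_results, tmp_path):
        par = small_model.fit(n_jobs=2)
        f1 = tmp_path / "serial.narrowPeak"
        f2 = tmp_path / "parallel.narrowPeak"
        small_results.to_narrowpeak(f1)
        par.to_narrowpeak(f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestStagedExecution:
    def test_stage_chain_equals_fit(self, small_config, small_sim, small_binning):
        contacts, _, track = small_sim
        state = {"rna_name": "simRNA"}
        model_mod.stage_bins(
            state, contacts, small_config.gene, small_config.chromsizes, small_binning
        )
        model_mod.stage_background(state, track)
        model_mod.stage_scaling(state)
        model_mod.stage_pvalues(state)
        whole = RnaDnaPeakModel(
            contacts, small_config.chromsizes, {"simRNA": small_config.gene},
            background=track, bg_binsize=small_config.fine_window,
            binning_params=small_binning,
        ).fit()
        fit = whole.fits["simRNA"]
        np.testing.assert_array_equal(state["counts"], fit.counts)
        np.testing.assert_allclose(state["pvalue"], fit.pvalue, equal_nan=True)

    def test_stage_order_enforced(self):
        with pytest.raises(ValueError, match="bins"):
            model_mod.require_stage({"stage": ""}, "bins", "background")

    def test_state_payload_roundtrip(self, small_config, small_sim, small_binning):
        contacts, _, track = small_sim
        state = {"rna_name": "simRNA"}
        model_mod.stage_bins(
            state, contacts, small_config.gene, small_config.chromsizes, small_binning
        )
        model_mod.stage_background(state, track)
        payload = model_mod.payload_from_state(state)
        back = model_mod.state_from_payload("simRNA", payload, small_config.chromsizes)
        np.testing.assert_array_equal(back["counts"], state["counts"])
        np.testing.assert_allclose(back["bg_prob"], state["bg_prob"])
        pd.testing.assert_frame_equal(
            back["grid"].table, state["grid"].table, check_dtype=False
        )


class TestPersistence:
    def test_save_and_reload_container(self, small_results, tmp_path):
        path = tmp_path / "run.h5"
        small_results.save(path)
        data = load_dataset(path)
        fit = small_results.fits["simRNA"]
        arrays = data["rnas"]["simRNA"]["arrays"]
        np.testing.assert_array_equal(arrays["count"], fit.counts)
        np.testing.assert_allclose(arrays["pvalue"], fit.pvalue, equal_nan=True)
        np.testing.assert_allclose(
            arrays["qvalue_global"], fit.qvalue_global, equal_nan=True
        )
        assert data["rnas"]["simRNA"]["attrs"]["N"] == fit.n_total

    def test_narrowpeak_export_parses_strictly(self, small_results, tmp_path):
        path = tmp_path / "peaks.narrowPeak"
        small_results.to_narrowpeak(path, 0.05)
        peaks = read_narrowpeak(path)
        assert len(peaks) > 0
        assert (peaks.name == "simRNA").all()
        starts = peaks.groupby("chrom")["start"].apply(lambda s: s.is_monotonic_increasing)
        assert starts.all()


class TestModelSurface:
    def test_summary_mentions_rna_and_peaks(self, small_results):
        text = small_results.summary()
        assert "simRNA" in text and "peaks" in text

    def test_scaling_diagnostic_table(self, small_results):
        diag = small_results.scaling_table("simRNA")
        assert set(diag.columns) == {"distance", "f_raw", "f_fit_step1", "f_fit_step2"}
        assert (diag.f_fit_step2 > 0).all()

    def test_min_contacts_excludes_sparse_rnas(self, small_config, small_sim):
        contacts, _, track = small_sim
        sparse = pd.DataFrame(
            {"chrom": "chrCis", "start": [5], "end": [10], "rna_name": "sparseRNA"}
        )
        both = pd.concat([contacts, sparse], ignore_index=True)
        genes = {
            "simRNA": small_config.gene,
            "sparseRNA": GeneRecord("chrCis", 0, 100, "sparseRNA"),
        }
        model = RnaDnaPeakModel(
            both, small_config.chromsizes, genes, background=track,
            bg_binsize=small_config.fine_window,
        )
        assert model.rnas == ["simRNA"]

    def test_ota_parameterization_runs(self, small_config, rng):
        """High-resolution one-to-all setup: fine bins, custom input track."""
        chromsizes = {"chrA": 200_000, "chrB": 200_000}
        gene = GeneRecord("chrA", 100_000, 102_000, "otaRNA")
        n = 3000
        pos_a = rng.integers(0, 199_900, n // 2)
        pos_b = rng.integers(0, 199_900, n // 2)
        contacts = pd.DataFrame(
            {
                "chrom": ["chrA"] * (n // 2) + ["chrB"] * (n // 2),
                "start": np.concatenate([pos_a, pos_b]),
                "end": np.concatenate([pos_a, pos_b]) + 100,
                "rna_name": "otaRNA",
            }
        )
        track = FineTrack(1000, chromsizes)
        for c in chromsizes:
            track.values[c][:] = rng.poisson(5, len(track.values[c])) + 1.0
        model = RnaDnaPeakModel(
            contacts, chromsizes, {"otaRNA": gene}, background=track,
            binning_params=BinningParams.ota(trans_max=20_000),
        )
        res = model.fit()
        fit = res.fits["otaRNA"]
        assert 400 <= fit.trans_binsize <= 20_000
        assert fit.startsize == 100
        assert fit.probs.sum() == pytest.approx(1.0, abs=1e-9)
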