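import numpy as np
import pandas as pd
import pytest

from pausekit.gene_model import filter_genes, load_annotation, make_pausing_windows
from pausekit.pausing import paired_wilcoxon
from pausekit.pipeline import run_chip_pipeline
from pausekit.signal_io import count_fragments
from pausekit.synthetic_data import (
    SyntheticConfig,
    assign_truth,
    chrom_length,
    simulate_annotation,
    simulate_dose_response,
    simulate_fragments,
    simulate_peaks,
    write_gtf,
)
from pausekit.gene_model import body_regions, promoter_regions


class TestAnnotation:
    def test_requested_violations_emitted(self):
        cfg = SyntheticConfig(seed=0, n_genes=30, n_short_genes=2, n_close_pairs=1)
        genes = simulate_annotation(cfg)
        assert sum(g.length < 1000 for g in genes) == 2
        kept, report = filter_genes(genes)
        assert report.reasons()["short_gene"] == 2
        assert report.reasons()["proximal_pair"] == 2

    def test_same_seed_byte_identical_gtf(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_genes=25)
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(simulate_annotation(cfg), str(p1))
        write_gtf(simulate_annotation(cfg), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_gtf_roundtrip(self, tmp_path):
        cfg = SyntheticConfig(seed=3, n_genes=25)
        genes = simulate_annotation(cfg)
        path = tmp_path / "a.gtf"
        write_gtf(genes, str(path))
        assert load_annotation(str(path)) == sorted(
            genes, key=lambda g: (g.chrom, g.start, g.gene_id)
        )

    def test_zero_genes(self):
        assert simulate_annotation(SyntheticConfig(n_genes=0)) == []

    def test_strands_alternate(self):
        genes = simulate_annotation(SyntheticConfig(seed=1, n_genes=10))
        assert {g.strand for g in genes} == {"+", "-"}


class TestTruth:
    def test_pi_gain_is_log2_delta_for_affected(self):
        cfg = SyntheticConfig(seed=2, n_genes=50)
        truth = assign_truth(simulate_annotation(cfg), cfg)
        aff = truth[truth["affected"]]
        assert np.allclose(
            aff["true_pi_treated"] - aff["true_pi_vehicle"], np.log2(cfg.treated_effect)
        )
        un = truth[~truth["affected"]]
        assert np.allclose(un["phi_treated"], un["phi_vehicle"])

    def test_delta_one_means_no_treatment_effect(self):
        cfg = SyntheticConfig(seed=2, n_genes=50, treated_effect=1.0)
        truth = assign_truth(simulate_annotation(cfg), cfg)
        assert np.allclose(truth["phi_treated"], truth["phi_vehicle"])


class TestFragments:
    def test_same_seed_identical_output(self):
        cfg = SyntheticConfig(seed=4, n_genes=20, depth_per_gene=100)
        genes = simulate_annotation(cfg)
        truth = assign_truth(genes, cfg)
        f1 = simulate_fragments(genes, truth, cfg, "treated", 1)
        f2 = simulate_fragments(genes, truth, cfg, "treated", 1)
        pd.testing.assert_frame_equal(f1.fragments, f2.fragments)

    def test_replicates_differ(self):
        cfg = SyntheticConfig(seed=4, n_genes=20, depth_per_gene=100)
        genes = simulate_annotation(cfg)
        truth = assign_truth(genes, cfg)
        f1 = simulate_fragments(genes, truth, cfg, "treated", 1)
        f2 = simulate_fragments(genes, truth, cfg, "treated", 2)
        assert not f1.fragments.equals(f2.fragments)

    def test_promoter_fraction_converges_to_phi(self):
        """Empirical per-gene promoter fraction approaches configured φ′ at depth."""
        cfg = SyntheticConfig(seed=5, n_genes=8, depth_per_gene=10_000,
                              background_rate=0.0)
        genes = simulate_annotation(cfg)
        truth = assign_truth(genes, cfg)
        frags = simulate_fragments(genes, truth, cfg, "vehicle", 1)
        sizes = {cfg.chrom: chrom_length(cfg, genes)}
        windows = make_pausing_windows(genes, chrom_sizes=sizes)
        prom = count_fragments(frags, promoter_regions(windows)).counts
        body = count_fragments(frags, body_regions(windows)).counts
        frac = prom / (prom + body)
        for gid in truth.index:
            assert frac[gid] == pytest.approx(truth.loc[gid, "phi_vehicle"], abs=0.01)

    def test_no_promoter_signal_when_phi_tiny(self):
        cfg = SyntheticConfig(seed=6, n_genes=10, depth_per_gene=500,
                              baseline_pi_mean=-15.0, baseline_pi_sd=0.0,
                              background_rate=0.0)
        genes = simulate_annotation(cfg)
        truth = assign_truth(genes, cfg)
        frags = simulate_fragments(genes, truth, cfg, "vehicle", 1)
        sizes = {cfg.chrom: chrom_length(cfg, genes)}
        windows = make_pausing_windows(genes, chrom_sizes=sizes)
        prom = count_fragments(frags, promoter_regions(windows)).counts
        assert prom.sum() <= 2  # at most stochastic spill


class TestPeaks:
    def _setup(self, **kw):
        cfg = SyntheticConfig(seed=7, n_genes=15, **kw)
        genes = simulate_annotation(cfg)
        return cfg, genes, assign_truth(genes, cfg)

    def test_threshold_above_all_occupancies_gives_empty(self):
        cfg, genes, truth = self._setup(peak_occupancy_threshold=10**9)
        reps = simulate_peaks(truth, genes, cfg)
        assert all(p.peaks.empty for p in reps)

    def test_zero_jitter_replicates_identical(self):
        cfg, genes, truth = self._setup(peak_jitter_bp=0)
        r1, r2 = simulate_peaks(truth, genes, cfg)
        pd.testing.assert_frame_equal(r1.peaks, r2.peaks)

    def test_all_promoters_peaked_when_threshold_low(self):
        cfg, genes, truth = self._setup(peak_occupancy_threshold=0.0)
        r1, _ = simulate_peaks(truth, genes, cfg)
        assert len(r1.peaks) == len(genes)


class TestDoseResponse:
    def test_zero_noise_lies_on_curve(self):
        from pausekit.dose_response import four_pl

        cfg = SyntheticConfig(seed=8, noise_sd_percent=0.0)
        table, truth = simulate_dose_response(cfg)
        nz = table[table["dose_nM"] > 0]
        expected = four_pl(nz["dose_nM"].to_numpy(), **truth)
        assert np.allclose(nz["response_pct"].to_numpy(), expected)

    def test_same_seed_identical_table(self):
        t1, _ = simulate_dose_response(SyntheticConfig(seed=9))
        t2, _ = simulate_dose_response(SyntheticConfig(seed=9))
        pd.testing.assert_frame_equal(t1, t2)

    def test_mean_response_at_ic50_is_midpoint(self):
        cfg = SyntheticConfig(seed=10, doses_nM=(500.0, 1000.0, 2000.0),
                              n_dose_replicates=400)
        table, truth = simulate_dose_response(cfg)
        at_ic50 = table[table["dose_nM"] == truth["ic50"]]["response_pct"]
        assert at_ic50.mean() == pytest.approx(
            (truth["top"] + truth["bottom"]) / 2, abs=1.0
        )


class TestNullCalibration:
    def test_wilcoxon_p_roughly_uniform_without_effect(self):
        """δ = 1: vehicle and treated are exchangeable, p should be null."""
        ps = []
        for seed in range(15):
            cfg = SyntheticConfig(seed=seed, n_genes=60, depth_per_gene=200,
                                  treated_effect=1.0, peak_occupancy_threshold=1.0)
            res = run_chip_pipeline(cfg)
            ps.append(res.wilcoxon.p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert min(ps) > 1e-4  # no runaway significance under the null


class TestEndToEndRecovery:
    def test_pipeline_recovers_affected_genes(self):
        """Sensitivity ≥ 0.9 for increased/paused calls at λ ≥ 200, δ ≥ 4."""
        cfg = SyntheticConfig(seed=7, n_genes=120, depth_per_gene=200,
                              treated_effect=4.0, peak_occupancy_threshold=1.0)
        res = run_chip_pipeline(cfg)
        truth = res.truth
        aff = truth.index[truth["affected"]]
        called_inc = set(res.diff_table.index[res.diff_table["class"] == "increased"])
        sens_diff = np.mean([g in called_inc for g in aff if g in res.diff_table.index])
        assert sens_diff >= 0.9
        # paused classification: treated PI above threshold for affected genes
        pi_t = res.pi["treated"]
        sens_pause = np.mean([pi_t[g] > 1.0 for g in aff if g in pi_t.index])
        assert sens_pause >= 0.9
        # affected fraction recovered
        frac = res.fraction_increased
        assert frac == pytest.approx(truth["affected"].mean(), abs=0.07)
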