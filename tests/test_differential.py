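import numpy as np
import pandas as pd
import pytest

from pausekit.differential import (
    PromoterCountMatrix,
    bh_fdr,
    consensus_peaks,
    differential_test,
    promoter_universe,
    size_factors,
)
from pausekit.signal_io import PeakSet
from pausekit.synthetic_data import simulate_count_matrix


def _peaks(rows, sample="s"):
    return PeakSet(sample, pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestConsensusPeaks:
    def test_single_replicate_peak_excluded(self):
        cs = consensus_peaks(_peaks([("chr1", 100, 200)]), _peaks([("chr1", 500, 600)]))
        assert cs.peaks.empty

    def test_overlapping_pair_emits_union(self):
        cs = consensus_peaks(_peaks([("chr1", 100, 200)]), _peaks([("chr1", 150, 250)]))
        assert list(cs.peaks.iloc[0]) == ["chr1", 100, 250]

    def test_idempotent_on_identical_inputs(self):
        p = _peaks([("chr1", 100, 200), ("chr2", 0, 50)])
        cs = consensus_peaks(p, p)
        pd.testing.assert_frame_equal(
            cs.peaks.reset_index(drop=True), p.peaks[["chrom", "start", "end"]]
        )

    def test_symmetric_in_replicates(self):
        a = _peaks([("chr1", 100, 200), ("chr1", 400, 500)])
        b = _peaks([("chr1", 150, 300)])
        pd.testing.assert_frame_equal(consensus_peaks(a, b).peaks,
                                      consensus_peaks(b, a).peaks)

    def test_book_ended_peaks_do_not_merge(self):
        # [100,200) and [200,300) share no bp
        cs = consensus_peaks(_peaks([("chr1", 100, 200)]), _peaks([("chr1", 200, 300)]))
        assert cs.peaks.empty

    def test_empty_replicate_gives_empty_consensus(self):
        cs = consensus_peaks(_peaks([]), _peaks([("chr1", 0, 10)]))
        assert cs.peaks.empty


class TestPromoterUniverse:
    PROMOTERS = pd.DataFrame(
        {
            "region_id": ["p1", "p2", "p3"],
            "chrom": ["chr1"] * 3,
            "start": [1000, 5000, 9000],
            "end": [1600, 5600, 9600],
        }
    )

    def test_single_condition_peak_retains_promoter(self):
        veh = consensus_peaks(_peaks([("chr1", 1500, 1700)]),
                              _peaks([("chr1", 1400, 1800)]), "vehicle")
        assert promoter_universe([veh], self.PROMOTERS) == ["p1"]

    def test_promoter_without_peak_excluded(self):
        veh = consensus_peaks(_peaks([("chr1", 1500, 1700)]),
                              _peaks([("chr1", 1400, 1800)]), "vehicle")
        trt = consensus_peaks(_peaks([("chr1", 5100, 5200)]),
                              _peaks([("chr1", 5100, 5300)]), "treated")
        assert promoter_universe([veh, trt], self.PROMOTERS) == ["p1", "p2"]


class TestSizeFactors:
    def test_doubled_sample_has_double_factor(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, size=200)
        m = PromoterCountMatrix(
            pd.DataFrame({"A": a, "B": 2 * a}),
            {"A": "vehicle", "B": "treated"},
        )
        f = size_factors(m)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        a = np.arange(1, 101)
        m = PromoterCountMatrix(
            pd.DataFrame({"A": a, "B": a}), {"A": "vehicle", "B": "treated"}
        )
        f = size_factors(m)
        assert f["A"] == pytest.approx(f["B"])

    def test_matches_direct_median_of_ratios_formula(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(300, 4)) + 1,
                              columns=list("ABCD"))
        m = PromoterCountMatrix(counts, dict.fromkeys("ABCD", "c"))
        f = size_factors(m)
        # independent re-implementation: literal median over count/geomean ratios
        geo = np.prod(counts.to_numpy(), axis=1) ** (1 / 4)
        for j, s in enumerate("ABCD"):
            expected = np.median(counts[s].to_numpy() / geo)
            assert f[s] == pytest.approx(expected)


class TestBHFDR:
    def test_hand_worked_example(self):
        # q_i = min over j>=i of p_(j) * m / j
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDifferentialTest:
    def test_identical_counts_no_change(self):
        counts = pd.DataFrame(
            {s: np.arange(10, 110, 10) for s in
             ["vehicle_rep1", "vehicle_rep2", "treated_rep1", "treated_rep2"]}
        )
        m = PromoterCountMatrix(
            counts,
            {s: s.split("_")[0] for s in counts.columns},
        )
        tab = differential_test(m)
        assert np.allclose(tab["log2fc"], 0.0)
        assert (tab["class"] == "no_change").all()

    def test_null_simulation_calibrated(self):
        m, _ = simulate_count_matrix(n_promoters=2000, dispersion=0.05, seed=3)
        tab = differential_test(m)
        assert (tab["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_strong_increase_detected(self):
        # 4-fold treated increase at mean 100, dispersion 0.05
        m, truth = simulate_count_matrix(
            n_promoters=500, mean_log=np.log(100), mean_sd=0.0,
            dispersion=0.05, log2fc=2.0, affected_fraction=0.2, seed=4,
        )
        tab = differential_test(m)
        aff = truth["affected"]
        assert ((tab["class"][aff] == "increased") & (tab["q"][aff] < 0.05)).mean() > 0.95

    def test_invariant_to_column_order_within_condition(self):
        m, _ = simulate_count_matrix(n_promoters=200, seed=5)
        cols = list(m.counts.columns)
        swapped = [cols[1], cols[0], cols[3], cols[2]]
        m2 = PromoterCountMatrix(
            m.counts[swapped], m.conditions,
            size_factors=m.size_factors[swapped],
        )
        t1, t2 = differential_test(m), differential_test(m2)
        assert np.allclose(t1["p"], t2["p"])
        assert np.allclose(t1["log2fc"], t2["log2fc"])

    def test_all_zero_promoters_dropped(self):
        m, _ = simulate_count_matrix(n_promoters=50, seed=6)
        counts = m.counts.copy()
        counts.iloc[0] = 0
        tab = differential_test(PromoterCountMatrix(counts, m.conditions,
                                                    size_factors=m.size_factors))
        assert len(tab) == 49

    def test_fewer_than_two_replicates_rejected(self):
        counts = pd.DataFrame({"v": [1, 2], "t": [3, 4]})
        m = PromoterCountMatrix(counts, {"v": "vehicle", "t": "treated"})
        with pytest.raises(ValueError):
            differential_test(m)


class TestAgainstDESeq2:
    def test_significant_sets_overlap_with_pydeseq2(self):
        """Independent NB machinery should call essentially the same promoters."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        m, _ = simulate_count_matrix(
            n_promoters=300, log2fc=2.0, affected_fraction=0.3,
            dispersion=0.02, seed=11,
        )
        tab = differential_test(m)
        meta = pd.DataFrame(
            {"condition": [m.conditions[s] for s in m.counts.columns]},
            index=m.counts.columns,
        )
        dds = DeseqDataSet(counts=m.counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "treated", "vehicle"], quiet=True)
        st.summary()
        res = st.results_df
        mine = set(tab.index[(tab["q"] < 0.05) & (tab["log2fc"] > 0)])
        theirs = set(res.index[(res["padj"] < 0.05) & (res["log2FoldChange"] > 0)])
        jaccard = len(mine & theirs) / len(mine | theirs)
        assert jaccard > 0.8
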