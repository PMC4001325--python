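import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from polwave import pause_dynamics as pdyn
from polwave.genomic_io import GenomicInterval, SignalTrack
from polwave.synthetic_data import gen_promoter_decay_series
from tests.conftest import make_gene, uniform_track


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exhaustive_peak_scan(track, gene, lo, hi):
    """Scan every 10-bp window with center on a multiple of 10."""
    best_c, best = None, 0.0
    for c in range((lo // 10) * 10, hi + 10, 10):
        reg = gene.tx_region(c - 5, c + 5)
        cnt = track.region_sum(reg.start, reg.end)
        if cnt > best:
            best, best_c = cnt, c
    return best_c


def hypergeom_fisher_p(a, b, c, d):
    """Two-sided Fisher p by direct enumeration of the hypergeometric tail."""
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)

    def logp(x):
        return (math.lgamma(n1 + 1) - math.lgamma(x + 1) - math.lgamma(n1 - x + 1)
                + math.lgamma(n2 + 1) - math.lgamma(k - x + 1)
                - math.lgamma(n2 - k + x + 1)
                - (math.lgamma(n1 + n2 + 1) - math.lgamma(k + 1)
                   - math.lgamma(n1 + n2 - k + 1)))

    p_obs = logp(a)
    return sum(math.exp(lp) for x in range(lo, hi + 1)
               if (lp := logp(x)) <= p_obs + 1e-9)


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

class TestSelectActiveGenes:
    def _cohort(self, rng, n=40):
        genes, tracks = [], {}
        for i in range(n):
            g = make_gene(f"g{i}", chrom=f"c{i}", end=20_000)
            genes.append(g)
            dens = 0.002 * (i + 1)
            tracks[(f"c{i}", "+")] = uniform_track(chrom=f"c{i}", end=20_000,
                                                   density=dens)
        return genes, tracks

    def test_background_threshold_excludes(self, rng):
        genes, tracks = self._cohort(rng)
        weak = make_gene("weak", chrom="cw", end=20_000)
        tracks[("cw", "+")] = uniform_track(chrom="cw", end=20_000,
                                            density=4e-4)
        kept = pdyn.select_active_genes(genes + [weak], tracks)
        assert "weak" not in {g.gene_id for g in kept}

    def test_top_75_percent_counting(self, rng):
        genes, tracks = self._cohort(rng, n=40)
        kept = pdyn.select_active_genes(genes, tracks)
        assert len(kept) == int(np.ceil(0.75 * 40))
        # kept are exactly the top-density genes
        assert {g.gene_id for g in kept} == {f"g{i}" for i in range(10, 40)}

    def test_bidirectional_pair_excluded(self):
        a = make_gene("a", start=10_000, end=30_000, strand="+")
        b = make_gene("b", start=200, end=10_800, strand="-")  # TSS 800 bp away
        tracks = {("chr1", "+"): uniform_track(end=30_000, density=0.01),
                  ("chr1", "-"): uniform_track(strand="-", end=30_000,
                                               density=0.01)}
        with pytest.raises(ValueError):
            pdyn.select_active_genes([a, b], tracks)  # both excluded -> empty

    def test_short_genes_excluded(self):
        g = make_gene("short", end=3000)
        tracks = {("chr1", "+"): uniform_track(end=3000, density=0.01)}
        with pytest.raises(ValueError):
            pdyn.select_active_genes([g], tracks)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

class TestCallPeak:
    def test_single_spike(self):
        g = make_gene(start=10_000, end=30_000)
        tr = SignalTrack.from_positions("chr1", "+", [10_050], [10])
        pk = pdyn.call_peak(tr, g)
        assert pk.tx_center == 50
        assert (pk.region.start, pk.region.end) == (10_000 - 75, 10_000 + 175)

    def test_uniform_ties_break_most_5prime(self):
        g = make_gene(start=10_000, end=30_000)
        tr = uniform_track(start=8_000, end=12_000, density=1.0)
        pk = pdyn.call_peak(tr, g)
        assert pk.tx_center == -500  # abuts the search-region start

    def test_zero_signal_no_peak(self):
        g = make_gene(start=10_000, end=30_000)
        assert pdyn.call_peak(SignalTrack("chr1", "+"), g) is None

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        g = make_gene(start=10_000, end=30_000)
        pos = rng.integers(9_000, 11_000, size=40)
        tr = SignalTrack.from_positions("chr1", "+", np.unique(pos),
                                        rng.integers(1, 9, len(np.unique(pos))))
        pk = pdyn.call_peak(tr, g)
        oracle = exhaustive_peak_scan(tr, g, -500, 500)
        if oracle is None:
            assert pk is None
        else:
            reg = g.tx_region(oracle - 5, oracle + 5)
            assert pk.count >= tr.region_sum(reg.start, reg.end) - 1e-9

    def test_minus_strand_peak(self):
        g = make_gene(start=10_000, end=30_000, strand="-")
        tr = SignalTrack.from_positions("chr1", "-", [29_950], [10])  # tx +50
        pk = pdyn.call_peak(tr, g)
        assert pk.tx_center == 50


class TestPausingIndex:
    def test_equal_densities_give_unity(self):
        g = make_gene(end=60_000)
        tr = uniform_track(density=0.1)
        pk = pdyn.call_peak(tr, g)
        pi = pdyn.pausing_index(tr, g, pk)
        assert pi == pytest.approx(1.0, rel=0.05)

    def test_tenfold_peak(self):
        g = make_gene(end=21_000)
        body = uniform_track(end=21_000, density=0.05)
        spike = SignalTrack.from_positions(
            "chr1", "+", np.arange(0, 250, 50), np.full(5, 0.45 * 250 / 5),
            width=50)
        tr = SignalTrack("chr1", "+",
                         np.concatenate([spike.starts, body.starts[5:]]),
                         np.concatenate([spike.ends, body.ends[5:]]),
                         np.concatenate([spike.values + 0.05,
                                         body.values[5:]]))
        pk = pdyn.call_peak(tr, g)
        pi = pdyn.pausing_index(tr, g, pk)
        assert pi == pytest.approx(10.0, rel=0.15)

    def test_zero_body_reads_finite(self):
        g = make_gene(end=21_000)
        tr = SignalTrack.from_positions("chr1", "+", [50], [100])
        pk = pdyn.call_peak(tr, g)
        pi = pdyn.pausing_index(tr, g, pk)
        # pseudo-count 1: ((100+1)/250) / (1/20000)
        assert pi == pytest.approx((101 / 250) / (1 / 20_000))


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

class TestFoldChange:
    def test_identical_libraries(self):
        tr = uniform_track(end=10_000, density=0.1)
        fc = pdyn.region_fold_change(tr, tr, GenomicInterval("chr1", 0, 1000))
        assert fc.fold == 1.0 and fc.p == 1.0 and fc.call == "unchanged"

    def test_p_matches_hypergeometric_enumeration(self):
        a, b, c, d = 100, 10_000, 50, 10_000
        treated = SignalTrack("chr1", "+", [0, 1000], [1000, 2000],
                              [a / 1000, b / 1000])
        control = SignalTrack("chr1", "+", [0, 1000], [1000, 2000],
                              [c / 1000, d / 1000])
        fc = pdyn.region_fold_change(treated, control,
                                     GenomicInterval("chr1", 0, 1000))
        assert fc.p == pytest.approx(hypergeom_fisher_p(a, b, c, d), rel=1e-6)

    def test_extreme_depletion_called_decrease(self):
        treated = SignalTrack("chr1", "+", [1000], [2000], [1.0])
        control = SignalTrack("chr1", "+", [0, 1000], [1000, 2000],
                              [0.2, 1.0])
        fc = pdyn.region_fold_change(treated, control,
                                     GenomicInterval("chr1", 0, 1000))
        assert fc.call == "decrease"

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(500, 2000), st.integers(500, 2000))
    def test_swap_symmetry(self, a, c, b, d):
        treated = SignalTrack("chr1", "+", [0, 1000], [1000, 2000],
                              [a / 1000, b / 1000])
        control = SignalTrack("chr1", "+", [0, 1000], [1000, 2000],
                              [c / 1000, d / 1000])
        reg = GenomicInterval("chr1", 0, 1000)
        f1 = pdyn.region_fold_change(treated, control, reg)
        f2 = pdyn.region_fold_change(control, treated, reg)
        assert f1.p == pytest.approx(f2.p, rel=1e-9)
        assert f1.fold == pytest.approx(1 / f2.fold, rel=1e-9)


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

class TestFitDecay:
    def _noiseless(self, lam, r0=500.0,
                   times=(0.0, 0.0, 12.5, 12.5, 25.0, 50.0, 50.0)):
        return [(t, r0 * np.exp(-lam * t)) for t in times]

    def test_noiseless_recovery_exact(self):
        fit = pdyn.fit_decay(self._noiseless(0.1), n_boot=200, seed=0)
        assert fit.lam == pytest.approx(0.1, abs=1e-4)
        assert fit.sd_lam < 1e-4
        assert fit.high_confidence

    def test_half_life_identity(self):
        fit = pdyn.fit_decay(self._noiseless(0.05), n_boot=100, seed=1)
        assert fit.half_life * fit.lam == pytest.approx(np.log(2))

    def test_constant_counts_give_no_decay(self):
        fit = pdyn.fit_decay(self._noiseless(0.0), n_boot=200, seed=2)
        assert abs(fit.lam) < 1e-3
        assert fit.half_life > 500 or fit.half_life == float("inf")
        assert not fit.high_confidence

    def test_requires_three_timepoints_with_control(self):
        with pytest.raises(ValueError):
            pdyn.fit_decay([(0.0, 100), (12.5, 50)])
        with pytest.raises(ValueError):
            pdyn.fit_decay([(5.0, 100), (12.5, 50), (25.0, 25)])

    def test_gauss_newton_matches_scipy(self):
        rng = np.random.default_rng(3)
        t = np.array([0.0, 0.0, 12.5, 12.5, 25.0, 50.0, 50.0])
        y = rng.poisson(400 * np.exp(-0.08 * t)).astype(float)
        r0, lam, conv = pdyn.fit_exponential_decay(t[None, :], y[None, :])
        assert conv[0]
        popt, _ = curve_fit(lambda tt, R, L: R * np.exp(-L * tt), t, y,
                            p0=(y[0], 0.05))
        assert lam[0] == pytest.approx(popt[1], abs=1e-5)
        assert r0[0] == pytest.approx(popt[0], rel=1e-4)

    @pytest.mark.parametrize("lam", [0.02, 0.05, 0.1, 0.2])
    def test_unbiased_on_poisson_grid(self, lam):
        df, _ = gen_promoter_decay_series(60, lam, 500, seed=int(lam * 1000))
        ests = []
        for gid, sub in df.groupby("gene_id"):
            fit = pdyn.fit_decay(sub[["time_min", "count"]].to_numpy(),
                                 n_boot=300, seed=11)
            if fit is not None:
                ests.append(fit.lam)
        mean = np.mean(ests)
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(mean - lam) < max(4 * se, 0.05 * lam)
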