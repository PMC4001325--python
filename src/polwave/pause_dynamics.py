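"""Promoter-proximal Pol II analysis.

Active-gene selection, pause/divergent peak calling around the TSS, pausing
index, drug-response fold changes with Fisher exact significance, and the
bootstrap first-order exponential-decay fit of promoter-peak time courses
(R_t = R_WT * exp(-lambda * t)).

Promoter offsets are transcription-direction coordinates with the TSS at 0:
the sense pause search window is [-500, +500), the divergent (antisense)
window [-1000, +500); a peak is the 250-bp region centered on the maximal
10-bp window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .genomic_io import GeneModel, GenomicInterval, MappabilityMask, SignalTrack

__all__ = [
    "PausePeak",
    "DecayFit",
    "FoldChangeResult",
    "select_active_genes",
    "call_peak",
    "pausing_index",
    "region_fold_change",
    "fit_exponential_decay",
    "fit_decay",
]

PEAK_WIDTH = 250
WINDOW = 10
SENSE_SEARCH = (-500, 500)
DIVERGENT_SEARCH = (-1000, 500)
BACKGROUND_DENSITY = 5e-4          # reads/bp, 10x gene-poor-region average


@dataclass
class PausePeak:
    region: GenomicInterval        # 250 bp, genomic coordinates
    density: float                 # reads/bp over the peak (scaled)
    count: float                   # raw reads in the peak
    kind: str                      # sense_pause | divergent
    tx_center: int                 # window center, bp relative to TSS


@dataclass
class DecayFit:
    lam: float                     # decay rate, 1/min
    sd_lam: float
    r_wt: float                    # fitted t=0 level
    n_boot: int                    # converged bootstrap fits
    high_confidence: bool          # sd_lam < 0.5 * lam

    @property
    def half_life(self) -> float:
        return np.log(2) / self.lam if self.lam > 0 else float("inf")


@dataclass
class FoldChangeResult:
    region_kind: str
    fold: float
    p: float
    call: str                      # increase | decrease | unchanged


# ---------------------------------------------------------------------------
# gene selection
# ---------------------------------------------------------------------------

def select_active_genes(genes: list[GeneModel], tracks: dict,
                        background_density: float = BACKGROUND_DENSITY,
                        top_frac: float = 0.75, min_length: int = 3500,
                        bidirectional_window: int = 1000,
                        tandem_window: int = 10_000) -> list[GeneModel]:
    """Active, long, well-resolved genes.

    ``tracks`` maps (chrom, strand) -> control SignalTrack.  Keeps genes with
    gene-body density (+1 kb to polyA) above background, in the top
    ``top_frac`` of the above-background set by density, longer than
    ``min_length``, excluding bidirectional genes (opposite-strand TSS within
    1 kb) and tandem genes (same-strand upstream polyA within 10 kb).
    """
    dens = {}
    for g in genes:
        tr = tracks.get((g.chrom, g.strand))
        if tr is None or g.length <= 1000:
            continue
        body = g.tx_region(1000, g.length)
        dens[g.gene_id] = tr.region_density(body.start, body.end, scaled=True)
    active = [g for g in genes
              if dens.get(g.gene_id, 0) > background_density]
    if active:
        ranked = sorted(active, key=lambda g: dens[g.gene_id], reverse=True)
        keep_n = int(np.ceil(top_frac * len(ranked)))
        active = ranked[:keep_n]
    out = []
    for g in active:
        if g.length <= min_length:
            continue
        bidir = any(o.chrom == g.chrom and o.strand != g.strand and
                    abs(o.tss - g.tss) <= bidirectional_window
                    for o in genes if o.gene_id != g.gene_id)
        if bidir:
            continue
        tandem = any(o.chrom == g.chrom and o.strand == g.strand and
                     o.gene_id != g.gene_id and
                     0 < g.genomic_to_tx(o.polya_end) * -1 <= tandem_window
                     for o in genes)
        if tandem:
            continue
        out.append(g)
    if not out:
        raise ValueError("no genes pass the active-gene selection")
    return out


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def call_peak(track: SignalTrack, gene: GeneModel,
              kind: str = "sense_pause") -> PausePeak | None:
    """Maximal 10-bp window in the TSS search region -> 250-bp peak.

    Window centers sit on multiples of 10 bp (transcription-direction
    coordinates); ties go to the most 5' window in scan order.  Returns None
    when the search region carries no signal (no-peak marker).
    """
    lo, hi = SENSE_SEARCH if kind == "sense_pause" else DIVERGENT_SEARCH
    centers = np.arange((lo // WINDOW) * WINDOW, hi + WINDOW, WINDOW)
    best_c, best_count = None, 0.0
    for c in centers:
        a = gene.tx_to_genomic(int(c) - WINDOW // 2)
        b = gene.tx_to_genomic(int(c) + WINDOW // 2)
        if min(a, b) < 0:
            continue   # window falls off the chromosome start
        reg = gene.tx_region(int(c) - WINDOW // 2, int(c) + WINDOW // 2)
        cnt = track.region_sum(reg.start, reg.end)
        if cnt > best_count:
            best_count, best_c = cnt, int(c)
    if best_c is None:
        return None
    lo_pk = best_c - PEAK_WIDTH // 2
    # shift the 250-bp peak inward if it would fall off the chromosome start
    if gene.strand == "+":
        lo_pk = max(lo_pk, -gene.tss)
    else:
        lo_pk = min(lo_pk, gene.tss - PEAK_WIDTH)
    peak_reg = gene.tx_region(lo_pk, lo_pk + PEAK_WIDTH)
    count = track.region_sum(peak_reg.start, peak_reg.end)
    return PausePeak(peak_reg, count * track.scale / PEAK_WIDTH, count,
                     kind, best_c)


def pausing_index(track: SignalTrack, gene: GeneModel, peak: PausePeak,
                  pseudo: float = 1.0,
                  mask: MappabilityMask | None = None) -> float:
    """Pause-peak density over gene-body density (+1 kb from TSS to polyA).

    A pseudo-count is added to both region counts, so the index is always
    finite.
    """
    body = gene.tx_region(1000, g_len := gene.length)
    mappable = (g_len - 1000) - (mask.overlap_bp(body.start, body.end)
                                 if mask else 0)
    body_count = track.region_sum(body.start, body.end, mask)
    peak_density = (peak.count + pseudo) / PEAK_WIDTH
    body_density = (body_count + pseudo) / max(mappable, 1)
    return peak_density / body_density


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def region_fold_change(treated: SignalTrack, control: SignalTrack,
                       region: GenomicInterval, pseudo: float = 1.0,
                       region_kind: str = "gene_body_proximal",
                       alpha: float = 0.05) -> FoldChangeResult:
    """Spike-scaled density ratio with Fisher exact significance.

    The 2x2 table is [region reads vs rest-of-library reads] x [treated vs
    control], on raw counts; the fold uses pseudo-counted, spike-scaled
    densities.
    """
    t_cnt = treated.region_sum(region.start, region.end)
    c_cnt = control.region_sum(region.start, region.end)
    fold = ((t_cnt + pseudo) * treated.scale) / ((c_cnt + pseudo) * control.scale)
    a = int(round(t_cnt))
    b = max(int(round(treated.total())) - a, 0)
    c = int(round(c_cnt))
    d = max(int(round(control.total())) - c, 0)
    _, p = fisher_exact([[a, b], [c, d]])
    if p < alpha and fold > 1:
        call = "increase"
    elif p < alpha and fold < 1:
        call = "decrease"
    else:
        call = "unchanged"
    return FoldChangeResult(region_kind, float(fold), float(p), call)


# ---------------------------------------------------------------------------
# exponential decay fitting
# ---------------------------------------------------------------------------

def fit_exponential_decay(t: np.ndarray, y: np.ndarray, max_iter: int = 100,
                          tol: float = 1e-8):
    """Vectorized Gauss-Newton least squares for y ~ R0 * exp(-lam * t).

    ``t`` and ``y`` are (B, m) batches; returns (r0, lam, converged) arrays.
    Initialization: lam from a log-linear regression of the positive counts,
    R0 from its intercept.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    B = y.shape[0]
    # log-linear init on y + 0.5 (guards zeros)
    ly = np.log(np.maximum(y, 0) + 0.5)
    tm = t.mean(axis=1, keepdims=True)
    lym = ly.mean(axis=1, keepdims=True)
    var_t = np.sum((t - tm) ** 2, axis=1)
    slope = np.where(var_t > 0,
                     np.sum((t - tm) * (ly - lym), axis=1) / np.maximum(var_t, 1e-12),
                     0.0)
    lam = np.clip(-slope, 1e-4, 5.0)
    r0 = np.exp(lym[:, 0] - slope * tm[:, 0])
    converged = np.zeros(B, dtype=bool)
    ok = np.ones(B, dtype=bool)
    for _ in range(max_iter):
        e = np.exp(-lam[:, None] * t)
        f = r0[:, None] * e
        resid = y - f
        j1 = e                                  # d f / d r0
        j2 = -f * t                             # d f / d lam
        a11 = np.sum(j1 * j1, axis=1)
        a12 = np.sum(j1 * j2, axis=1)
        a22 = np.sum(j2 * j2, axis=1) + 1e-12   # mild damping
        g1 = np.sum(j1 * resid, axis=1)
        g2 = np.sum(j2 * resid, axis=1)
        det = a11 * a22 - a12 * a12
        good = np.abs(det) > 1e-300
        d_r0 = np.where(good, (a22 * g1 - a12 * g2) / np.where(good, det, 1), 0)
        d_lam = np.where(good, (a11 * g2 - a12 * g1) / np.where(good, det, 1), 0)
        ok &= good & np.isfinite(d_r0) & np.isfinite(d_lam)
        step_r0 = np.clip(d_r0, -np.abs(r0) - 1, np.abs(r0) + 1)
        step_lam = np.clip(d_lam, -0.5, 0.5)
        r0 = np.clip(r0 + np.where(ok, step_r0, 0), 1e-9, 1e12)
        new_lam = np.clip(lam + np.where(ok, step_lam, 0), -0.5, 5.0)
        rel = np.maximum(np.abs(step_r0) / np.maximum(np.abs(r0), 1e-9),
                         np.abs(step_lam) / np.maximum(np.abs(new_lam), 1e-9))
        newly = ok & ~converged & (rel < tol)
        converged |= newly
        lam = new_lam
        if converged.all():
            break
    return r0, lam, converged & ok


def fit_decay(datasets, n_boot: int = 1000, seed: int = 0,
              min_converged_frac: float = 0.5) -> DecayFit | None:
    """Bootstrap decay-rate fit over (time_min, count) datasets.

    Each bootstrap draw resamples n-of-n datasets with replacement (n = 7 for
    the seven-dataset drug course) and fits R_t = R_WT * exp(-lambda t) by
    nonlinear least squares.  lambda is the mean over converged fits, sd the
    standard deviation; the gene is rejected (None) when fewer than half the
    fits converge.  Needs >= 3 distinct timepoints including a t=0 control.
    """
    pts = np.asarray(datasets, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("datasets must be (time_min, count) pairs")
    times, counts = pts[:, 0], pts[:, 1]
    if len(np.unique(times)) < 3 or 0.0 not in times:
        raise ValueError("need >= 3 distinct timepoints including t = 0")
    m = len(times)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    tb, yb = times[idx], counts[idx]
    # degenerate draws (a single distinct time) cannot constrain lambda
    informative = (tb.max(axis=1) - tb.min(axis=1)) > 0
    r0, lam, conv = fit_exponential_decay(tb, yb)
    conv &= informative
    if conv.mean() < min_converged_frac:
        return None
    lam_mean = float(np.mean(lam[conv]))
    return DecayFit(lam=lam_mean, sd_lam=float(np.std(lam[conv])),
                    r_wt=float(np.mean(r0[conv])), n_boot=int(conv.sum()),
                    high_confidence=bool(np.std(lam[conv]) < 0.5 * lam_mean
                                         and lam_mean > 0))
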