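"""Two-state binomial-emission HMMs for inhibition-wave and TU calling.

Three uses of the same machinery:

1. *Regional transition-point calling*: treated/control read-count ratios per
   bin are digitized to 41 levels (0..40 at step 0.05, clipped at 2.0) and
   modeled as binomial emissions from hidden states ``affected`` (the 5'
   region cleared by the drug) and ``unaffected``.  The topology is
   unidirectional (affected -> unaffected, never back) with the chain started
   in the affected state; the transition point is the wave front.
2. *Genome-wide transcription-unit calling*: binary 200-bp occupancy bins,
   B(2, e) emissions, full two-way transitions, Viterbi decoding into active
   runs.
3. *Regional TU-end calling*: like (1) but started in the *active* state,
   detecting the changepoint into inactivity downstream of a gene.

Baum-Welch estimates (e1, e2, p11) under the constrained topology; genes
whose fit does not converge within the iteration cap are dropped by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .genomic_io import GeneModel, GenomicInterval, SignalTrack

__all__ = [
    "BIN_SIZE_BY_TIMEPOINT",
    "LENGTH_CUTOFF_BY_TIMEPOINT",
    "RatioObservations",
    "HmmModel",
    "TransitionPoint",
    "TranscriptionUnit",
    "digitize_ratio",
    "build_ratio_observations",
    "baum_welch_fit",
    "call_transition_point",
    "call_transcription_units",
    "pair_divergent_tus",
    "call_tu_end",
    "select_wave_genes",
]

#: bin sizes chosen so a gene spans roughly 30-40 bins at each timepoint
BIN_SIZE_BY_TIMEPOINT = {5.0: 500, 12.5: 1000, 25.0: 2000, 50.0: 5000}
#: minimum gene length analyzed at each timepoint (bp)
LENGTH_CUTOFF_BY_TIMEPOINT = {5.0: 30_000, 12.5: 30_000, 25.0: 60_000, 50.0: 150_000}

RATIO_CLIP = 2.0
RATIO_STEP = 0.05
N_STATES_DIGITIZED = int(round(RATIO_CLIP / RATIO_STEP))  # 40


def digitize_ratio(ratio) -> np.ndarray:
    """Clip ratios to [0, 2] and digitize at step 0.05 -> integer states 0..40."""
    r = np.clip(np.asarray(ratio, dtype=float), 0.0, RATIO_CLIP)
    return np.rint(r / RATIO_STEP).astype(int)


@dataclass
class RatioObservations:
    """Digitized treated/control ratio bins for one gene at one timepoint."""

    gene_id: str
    timepoint: float
    bin_size: int
    states: np.ndarray                 # integer states, dropped bins removed
    edges_tx: np.ndarray               # 3' edge (bp downstream of TSS) per kept bin
    normalization_factor: float        # mean raw ratio of the last five 3' bins

    def __len__(self):
        return len(self.states)


@dataclass
class HmmModel:
    """Two-state binomial HMM.

    State 0 starts the chain with near-unit probability (pi1 = 0.999 rather
    than exactly 1, so an unaffected start remains representable and an
    all-unaffected gene yields no transition call).
    """

    e1: float = 0.1                    # emission success prob, state 0
    e2: float = 0.5                    # emission success prob, state 1
    p11: float = 0.95                  # P(stay in state 0)
    p22: float = 1.0                   # P(stay in state 1); 1.0 = unidirectional
    n_trials: int = N_STATES_DIGITIZED
    unidirectional: bool = True
    pi1: float = 0.999                 # initial mass in state 0
    converged: bool = False
    n_iter: int = 0
    loglik_history: list = field(default_factory=list)

    @property
    def p12(self) -> float:
        return 1.0 - self.p11

    def transition_matrix(self) -> np.ndarray:
        return np.array([[self.p11, 1.0 - self.p11],
                         [1.0 - self.p22, self.p22]])

    def emission_probs(self, obs: np.ndarray) -> np.ndarray:
        """(T, 2) matrix of P(obs_t | state)."""
        obs = np.asarray(obs)
        return np.column_stack([binom.pmf(obs, self.n_trials, self.e1),
                                binom.pmf(obs, self.n_trials, self.e2)])


@dataclass
class TransitionPoint:
    gene_id: str
    timepoint: float
    position: int                      # bp downstream of TSS
    replicate_id: str = ""
    confidence: float = float("nan")   # posterior P(affected) at the call


@dataclass
class TranscriptionUnit:
    interval: GenomicInterval
    strand: str
    paired_partner: int | None = None  # index of divergent partner


# ---------------------------------------------------------------------------
# forward-backward / Baum-Welch / Viterbi
# ---------------------------------------------------------------------------

def _forward_backward(b: np.ndarray, a: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward.  Returns (gamma, xi_sum, loglik)."""
    T = b.shape[0]
    alpha = np.empty((T, 2))
    c = np.empty(T)
    alpha[0] = pi * b[0]
    c[0] = alpha[0].sum()
    if c[0] == 0:
        return None, None, -np.inf
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ a) * b[t]
        c[t] = alpha[t].sum()
        if c[t] == 0:
            return None, None, -np.inf
        alpha[t] /= c[t]
    beta = np.empty((T, 2))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (a @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # expected transition counts summed over t
    xi_sum = np.zeros((2, 2))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * a) * (b[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    return gamma, xi_sum, float(np.sum(np.log(c)))


def posterior_affected(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    """Posterior probability of state 0 per bin (forward-backward)."""
    b = model.emission_probs(obs)
    gamma, _, ll = _forward_backward(b, model.transition_matrix(),
                                     np.array([model.pi1, 1.0 - model.pi1]))
    if gamma is None:
        raise ValueError("observation sequence has zero likelihood")
    return gamma[:, 0]


def viterbi_path(obs: np.ndarray, model: HmmModel,
                 pi=None) -> np.ndarray:
    """Most likely state path (0/1) under the model."""
    if pi is None:
        pi = (model.pi1, 1.0 - model.pi1)
    b = np.log(np.maximum(model.emission_probs(obs), 1e-300))
    a = np.log(np.maximum(model.transition_matrix(), 1e-300))
    T = b.shape[0]
    lp = np.log(np.maximum(np.asarray(pi, dtype=float), 1e-300)) + b[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        cand = lp[:, None] + a
        back[t] = np.argmax(cand, axis=0)
        lp = cand[back[t], [0, 1]] + b[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(lp))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def baum_welch_fit(obs, template: HmmModel | None = None, max_iter: int = 200,
                   tol: float = 1e-6) -> HmmModel | None:
    """EM fit of the two-state binomial HMM; None on failure.

    Failure = degenerate input (all observations identical) or no convergence
    within ``max_iter`` iterations (max absolute parameter change >= tol).
    The log-likelihood is non-decreasing across iterations (EM guarantee) and
    is recorded in ``loglik_history``.
    """
    obs = np.asarray(obs, dtype=int)
    if len(obs) < 2 or np.all(obs == obs[0]):
        return None
    m = HmmModel() if template is None else HmmModel(
        e1=template.e1, e2=template.e2, p11=template.p11, p22=template.p22,
        n_trials=template.n_trials, unidirectional=template.unidirectional,
        pi1=template.pi1)
    if template is None:
        m.p11 = 1.0 - 1.0 / len(obs)   # p12 init = 1/n_bins
    pi = np.array([m.pi1, 1.0 - m.pi1])
    eps = 1e-6
    for it in range(1, max_iter + 1):
        b = m.emission_probs(obs)
        gamma, xi_sum, ll = _forward_backward(b, m.transition_matrix(), pi)
        if gamma is None:
            return None
        m.loglik_history.append(ll)
        w = gamma.sum(axis=0)
        e1_new = float(np.clip(np.dot(gamma[:, 0], obs) /
                               max(w[0] * m.n_trials, 1e-12), eps, 1 - eps))
        e2_new = float(np.clip(np.dot(gamma[:, 1], obs) /
                               max(w[1] * m.n_trials, 1e-12), eps, 1 - eps))
        denom0 = gamma[:-1, 0].sum()
        p11_new = float(np.clip(xi_sum[0, 0] / denom0, eps, 1 - eps)) \
            if denom0 > 1e-12 else m.p11
        if m.unidirectional:
            p22_new = 1.0
        else:
            denom1 = gamma[:-1, 1].sum()
            p22_new = float(np.clip(xi_sum[1, 1] / denom1, eps, 1 - eps)) \
                if denom1 > 1e-12 else m.p22
        delta = max(abs(e1_new - m.e1), abs(e2_new - m.e2),
                    abs(p11_new - m.p11), abs(p22_new - m.p22))
        m.e1, m.e2, m.p11, m.p22 = e1_new, e2_new, p11_new, p22_new
        m.n_iter = it
        if delta < tol:
            m.converged = True
            return m
    return None   # iteration cap reached without convergence


# ---------------------------------------------------------------------------
# regional transition-point calling
# ---------------------------------------------------------------------------

def build_ratio_observations(treated: SignalTrack, control: SignalTrack,
                             gene: GeneModel, timepoint: float,
                             span: int | None = None,
                             bin_size: int | None = None,
                             max_zero_control_frac: float = 0.2,
                             ) -> RatioObservations | None:
    """Digitized per-bin treated/control ratios over the analysis span.

    The span runs from the TSS to 60 kb (150 kb at the 50-min point), capped
    at the gene length.  Ratios are internally normalized by the mean of the
    last five 3' bins, clipped to [0, 2] and digitized at step 0.05.
    Zero-control bins are dropped; genes with more than 20% such bins return
    None (dropped).
    """
    if bin_size is None:
        bin_size = BIN_SIZE_BY_TIMEPOINT[float(timepoint)]
    if span is None:
        span = 150_000 if float(timepoint) >= 50 else 60_000
    span = min(span, gene.length)
    n_bins = span // bin_size
    if n_bins < 6:
        return None
    tre = np.empty(n_bins)
    ctl = np.empty(n_bins)
    for i in range(n_bins):
        reg = gene.tx_region(i * bin_size, (i + 1) * bin_size)
        tre[i] = treated.region_sum(reg.start, reg.end, scaled=True)
        ctl[i] = control.region_sum(reg.start, reg.end, scaled=True)
    zero = ctl <= 0
    if zero.mean() > max_zero_control_frac:
        return None
    keep = ~zero
    ratio = tre[keep] / ctl[keep]
    edges = (np.arange(1, n_bins + 1) * bin_size)[keep]
    tail = ratio[-5:]
    norm = float(tail.mean())
    if norm <= 0:
        return None
    states = digitize_ratio(ratio / norm)
    return RatioObservations(gene.gene_id, float(timepoint), bin_size,
                             states, edges, norm)


def call_transition_point(obs: RatioObservations, model: HmmModel,
                          mode: str = "posterior",
                          replicate_id: str = "") -> TransitionPoint | None:
    """Wave-front position: 3' edge of the last bin called affected.

    ``mode='posterior'``: last bin with P(affected) >= 0.5 (default).
    ``mode='viterbi'``: last bin decoded as affected.  None when the chain
    never leaves/never enters the affected state at the 5' end.
    """
    if mode == "posterior":
        post = posterior_affected(obs.states, model)
        idx = np.nonzero(post >= 0.5)[0]
        if len(idx) == 0:
            return None
        last = int(idx[-1])
        conf = float(post[last])
    elif mode == "viterbi":
        path = viterbi_path(obs.states, model)
        idx = np.nonzero(path == 0)[0]
        if len(idx) == 0:
            return None
        last = int(idx[-1])
        conf = float(posterior_affected(obs.states, model)[last])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TransitionPoint(obs.gene_id, obs.timepoint,
                           int(obs.edges_tx[last]), replicate_id, conf)


# ---------------------------------------------------------------------------
# transcription-unit calling
# ---------------------------------------------------------------------------

def _binary_bins(track: SignalTrack, start: int, end: int,
                 bin_size: int = 200) -> np.ndarray:
    """1 if any read overlaps the bin, else 0."""
    n = max((end - start) // bin_size, 1)
    occ = np.zeros(n, dtype=int)
    keep = (track.values > 0) & (track.ends > start) & (track.starts < end)
    for s, e in zip(track.starts[keep], track.ends[keep]):
        i0 = max((s - start) // bin_size, 0)
        i1 = min((e - 1 - start) // bin_size, n - 1)
        occ[i0:i1 + 1] = 1
    return occ


def call_transcription_units(track: SignalTrack, chrom_end: int | None = None,
                             bin_size: int = 200,
                             max_iter: int = 1000) -> list[TranscriptionUnit]:
    """De novo TU calling on binary 200-bp bins with B(2, e) emissions.

    Full two-way transitions; Viterbi runs of the active (higher-emission)
    state are emitted as TUs.  Empty tracks give an empty list.
    """
    if track.total() == 0:
        return []
    if chrom_end is None:
        chrom_end = int(track.ends.max())
    obs = _binary_bins(track, 0, chrom_end, bin_size)
    template = HmmModel(e1=0.05, e2=0.6, p11=0.99, p22=0.99,
                        n_trials=2, unidirectional=False)
    model = baum_welch_fit(obs, template, max_iter=max_iter)
    if model is None:
        return []
    path = viterbi_path(obs, model, pi=(0.5, 0.5))
    active_state = 0 if model.e1 > model.e2 else 1
    active = path == active_state
    tus: list[TranscriptionUnit] = []
    i = 0
    n = len(active)
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            tus.append(TranscriptionUnit(
                GenomicInterval(track.chrom, i * bin_size,
                                (j + 1) * bin_size, track.strand),
                track.strand))
            i = j + 1
        else:
            i += 1
    return tus


def pair_divergent_tus(sense_tus: list[TranscriptionUnit],
                       antisense_tus: list[TranscriptionUnit],
                       max_gap: int = 2000) -> list[tuple[int, int]]:
    """Pair sense/antisense TUs whose starts lie within ``max_gap`` bp.

    A sense TU starts at its genomic start; an antisense (minus-strand) TU
    starts at its genomic end.  Pairs are flagged on both TUs.
    """
    pairs = []
    for i, s in enumerate(sense_tus):
        for j, a in enumerate(antisense_tus):
            a_start = a.interval.end if a.strand == "-" else a.interval.start
            s_start = s.interval.start if s.strand == "+" else s.interval.end
            if abs(s_start - a_start) <= max_gap:
                s.paired_partner = j
                a.paired_partner = i
                pairs.append((i, j))
                break
    return pairs


def call_tu_end(track: SignalTrack, gene: GeneModel, bin_size: int = 200,
                extension: int = 50_000, max_iter: int = 200) -> int:
    """Position (bp downstream of TSS) where activity transitions to inactive.

    Binary bins run from the TSS to 50 kb past the annotated 3' end; the
    unidirectional HMM starts in the *active* state.  If no inactive region
    is found the span limit is returned.
    """
    span = gene.length + extension
    n_bins = span // bin_size
    occ = np.empty(n_bins, dtype=int)
    for i in range(n_bins):
        reg = gene.tx_region(i * bin_size, (i + 1) * bin_size)
        occ[i] = 1 if track.region_sum(reg.start, reg.end) > 0 else 0
    template = HmmModel(e1=0.6, e2=0.05, p11=0.99, p22=1.0,
                        n_trials=2, unidirectional=True)
    model = baum_welch_fit(occ, template, max_iter=max_iter)
    if model is None or model.e1 <= model.e2:
        return span   # uniformly active (or degenerate): end at span limit
    post = posterior_affected(occ, model)   # state 0 = active here
    idx = np.nonzero(post >= 0.5)[0]
    if len(idx) == 0:
        return 0
    return int((idx[-1] + 1) * bin_size)


# ---------------------------------------------------------------------------
# wave-gene selection
# ---------------------------------------------------------------------------

def replicates_agree(x1: float, x2: float, bin_size: int,
                     rel_tol: float = 0.2) -> bool:
    """Reproducibility rule: agree within max(1 bin, 20% of the mean)."""
    tol = max(bin_size, rel_tol * 0.5 * (x1 + x2))
    return abs(x1 - x2) <= tol


def select_wave_genes(genes: list[GeneModel], timepoint: float, *,
                      tss_paired: set[str],
                      internal_divergent: set[str] = frozenset(),
                      premature: set[str] = frozenset(),
                      transitions: dict[str, tuple[float, float]] | None = None,
                      bin_size: int | None = None) -> list[str]:
    """Genes eligible for wave calling at a timepoint.

    Filters: per-timepoint length cutoff; paired (divergent) TU at the TSS;
    no internal divergent TU pair; no premature termination; and, when two
    replicate transition points are supplied, replicate reproducibility.
    """
    if bin_size is None:
        bin_size = BIN_SIZE_BY_TIMEPOINT[float(timepoint)]
    cutoff = LENGTH_CUTOFF_BY_TIMEPOINT[float(timepoint)]
    out = []
    for g in genes:
        if g.length < cutoff:
            continue
        if g.gene_id not in tss_paired:
            continue
        if g.gene_id in internal_divergent or g.gene_id in premature:
            continue
        if transitions is not None:
            if g.gene_id not in transitions:
                continue
            x1, x2 = transitions[g.gene_id]
            if not replicates_agree(x1, x2, bin_size):
                continue
        out.append(g.gene_id)
    return out
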