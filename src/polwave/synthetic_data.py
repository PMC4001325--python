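"""Synthetic GRO-seq / RNA-seq / feature inputs with recorded ground truth.

Every generator draws Poisson read noise (coverage is count data), is
deterministic under a fixed seed, and returns a :class:`SyntheticTruth`
sidecar recording the planted quantities so downstream stages can be tested
for recovery.  Defaults mirror the study design: FP/Trp timepoints on the
{0, 2, 5, 12.5, 25, 50} min grid, two replicates per timepoint (with an
option to drop one), and sequencing depth giving on the order of 30-40
occupied ratio bins per gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, SignalTrack
from .pol2_simulator import SimConfig

__all__ = [
    "SyntheticTruth",
    "wave_front_position",
    "gen_wave_tracks",
    "gen_promoter_decay_series",
    "gen_sawtooth_rnaseq",
    "gen_feature_table",
]

TIMEPOINT_GRID = (0.0, 2.0, 5.0, 12.5, 25.0, 50.0)
_CELL = 50  # bp resolution of generated coverage


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    seed: int
    payload: dict = field(default_factory=dict)

    def write_json(self, path) -> None:
        def _clean(o):
            if isinstance(o, dict):
                return {str(k): _clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [_clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return o
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "payload": _clean(self.payload)}, fh,
                      indent=1)


def wave_front_position(sim: SimConfig, t_minutes: float,
                        grid_bp: int = 10) -> float:
    """Deterministic wave front x(t) from dx/dt = v(x) (kinetic prediction)."""
    xs = np.arange(0, sim.gene_length + grid_bp, grid_bp, dtype=float)
    v = np.maximum(np.asarray(sim.v_fn(xs, np.full_like(xs, 100.0))), 1e-9)
    # cumulative traversal time to each grid point (s)
    t_of_x = np.concatenate([[0.0], np.cumsum(grid_bp / v[:-1])])
    t_s = t_minutes * 60.0
    if t_s >= t_of_x[-1]:
        return float(sim.gene_length)
    return float(np.interp(t_s, t_of_x, xs))


def gen_wave_tracks(genes: list[GeneModel], sim: SimConfig, timepoints,
                    depth: float, seed: int, replicates: int = 2,
                    drop: tuple | None = None):
    """Control plus treated tracks with the 5' region cleared up to the front.

    ``depth`` is reads/kb of control gene-body coverage.  Treated tracks at
    time t are cleared upstream of the kinetic front x(t) of ``sim`` and
    Poisson-sampled per 50-bp cell.  The control profile follows flux
    conservation (density proportional to 1/v(x)); for a constant-rate model
    it is uniform.  Returns ``(tracks, truth)`` with
    ``tracks[(t, rep)][(chrom, strand)] -> SignalTrack``; ``drop=(t, rep)``
    omits one replicate (the discarded-replicate scenario).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    bad = [t for t in timepoints if float(t) not in TIMEPOINT_GRID]
    if bad:
        raise ValueError(f"timepoints outside supported grid: {bad}")
    rng = np.random.default_rng(seed)
    fronts = {float(t): wave_front_position(sim, float(t)) for t in timepoints
              if float(t) > 0}
    tracks: dict = {}
    truth = SyntheticTruth(seed, {
        "fronts_bp": fronts,
        "depth_reads_per_kb": depth,
        "gene_ids": [g.gene_id for g in genes],
    })
    all_t = sorted({0.0} | {float(t) for t in timepoints})
    for t in all_t:
        for rep in range(1, replicates + 1):
            if drop is not None and (t, rep) == tuple(drop):
                continue
            per_chrom: dict = {}
            for g in genes:
                L = g.length
                n_cells = L // _CELL
                xs = (np.arange(n_cells) + 0.5) * _CELL
                v = np.maximum(np.asarray(
                    sim.v_fn(np.minimum(xs, sim.gene_length - 1),
                             np.full(n_cells, 100.0))), 1e-9)
                base = (depth / 1000.0) / np.mean(1.0 / v) / v  # mean = depth/kb
                mu = base * _CELL
                if t > 0:
                    mu = np.where(xs < fronts[t], 0.0, mu)
                counts = rng.poisson(mu)
                # cell offsets -> genomic runs in transcription direction
                if g.strand == "+":
                    starts = g.tss + np.arange(n_cells) * _CELL
                else:
                    starts = g.tss - (np.arange(n_cells) + 1) * _CELL
                key = (g.chrom, g.strand)
                per_chrom.setdefault(key, ([], []))
                per_chrom[key][0].append(starts)
                per_chrom[key][1].append(counts)
            built = {}
            for (chrom, strand), (sl, cl) in per_chrom.items():
                built[(chrom, strand)] = SignalTrack.from_positions(
                    chrom, strand, np.concatenate(sl), np.concatenate(cl),
                    width=_CELL)
            tracks[(t, rep)] = built
    return tracks, truth


def gen_promoter_decay_series(n_genes: int, lam: float, r0: float,
                              timepoints=(0.0, 12.5, 25.0, 50.0),
                              replicates: int = 2, seed: int = 0,
                              drop: tuple | None = None):
    """Promoter-peak counts ~ Poisson(R0 * exp(-lambda * t)) per gene/replicate.

    Returns ``(counts, truth)`` where counts is a tidy DataFrame with columns
    gene_id, time_min, replicate, count.  ``drop=(t, rep)`` omits one dataset.
    """
    if lam < 0:
        raise ValueError("decay rate must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for t in timepoints:
        mu = r0 * np.exp(-lam * float(t))
        for rep in range(1, replicates + 1):
            if drop is not None and (float(t), rep) == tuple(drop):
                continue
            counts = rng.poisson(mu, size=n_genes)
            for i in range(n_genes):
                rows.append((f"g{i}", float(t), rep, int(counts[i])))
    df = pd.DataFrame(rows, columns=["gene_id", "time_min", "replicate",
                                     "count"])
    truth = SyntheticTruth(seed, {"lambda_per_min": lam, "r0": r0,
                                  "half_life_min": np.log(2) / lam
                                  if lam > 0 else float("inf")})
    return df, truth


def gen_sawtooth_rnaseq(genes: list[GeneModel], v, depth: float, seed: int = 0,
                        tau: float = 60.0, exon_factor: float = 20.0):
    """Unstranded intronic RNA-seq with a co-transcriptional saw-tooth.

    Expected intronic density at distance d bp upstream of the intron's 3'
    splice site is c * (1 + d / (v * tau)) with dwell constant ``tau`` (s) and
    per-gene elongation rate ``v`` (bp/s, scalar or mapping gene_id -> v);
    exonic density is a constant ``exon_factor * c``.  c = depth/1000
    reads/bp.  Poisson noise per 50-bp cell.  Returns ``(tracks, truth)``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    c = depth / 1000.0
    v_of = (lambda g: float(v[g.gene_id])) if isinstance(v, dict) \
        else (lambda g: float(v))
    per_chrom: dict = {}
    truth_v = {}
    for g in genes:
        vg = v_of(g)
        truth_v[g.gene_id] = vg
        n_cells = g.length // _CELL
        offs = (np.arange(n_cells) + 0.5) * _CELL
        mu = np.full(n_cells, exon_factor * c * _CELL)   # exonic default
        for intron in g.introns:
            # tx offsets of the intron
            a = g.genomic_to_tx(intron.start if g.strand == "+" else intron.end)
            b = a + len(intron)
            inside = (offs >= a) & (offs < b)
            d = b - offs[inside]                         # distance to 3'SS
            mu[inside] = c * (1.0 + d / (vg * tau)) * _CELL
        counts = rng.poisson(mu)
        if g.strand == "+":
            starts = g.tss + np.arange(n_cells) * _CELL
        else:
            starts = g.tss - (np.arange(n_cells) + 1) * _CELL
        per_chrom.setdefault(g.chrom, ([], []))
        per_chrom[g.chrom][0].append(starts)
        per_chrom[g.chrom][1].append(counts)
    tracks = {chrom: SignalTrack.from_positions(chrom, ".", np.concatenate(sl),
                                                np.concatenate(cl), width=_CELL)
              for chrom, (sl, cl) in per_chrom.items()}
    truth = SyntheticTruth(seed, {"v_bp_per_s": truth_v, "tau_s": tau,
                                  "c_reads_per_bp": c})
    return tracks, truth


def gen_feature_table(n_genes: int, coefficients, noise_sd: float | None = None,
                      target_r2: float | None = None, seed: int = 0,
                      proxy_noise_sd: float = 0.6):
    """Feature matrix with planted linear effects on an elongation-rate z.

    Primary features (exon_density, CpG_content, H3K79me2) are independent
    standard normals; rate_z = X beta + eps.  Either ``noise_sd`` or
    ``target_r2`` must be given.  With ``target_r2`` the noise is calibrated
    against the *realized sample* variance of X beta and projected orthogonal
    to the design, so the planted variance decomposition
    var(X beta)/var(rate) holds exactly in the generated cohort (not just in
    expectation).  Proxy features are
    deterministic-plus-noise functions of primaries (intron1_length of
    exon_density, negatively; CpG_methylation of CpG_content, positively) to
    exercise the dependency analysis.  Returns ``(DataFrame, truth)``.
    """
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (3,):
        raise ValueError("need exactly three primary coefficients")
    var_signal = float(np.sum(beta ** 2))
    if target_r2 is not None and not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    if target_r2 is not None and var_signal == 0:
        raise ValueError("target_r2 needs a nonzero coefficient")
    if target_r2 is None and noise_sd is None:
        raise ValueError("give noise_sd or target_r2")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_genes, 3))
    signal = X @ beta
    if target_r2 is not None:
        eps = rng.standard_normal(n_genes)
        # project the noise orthogonal to the design (and the mean) and scale
        # it so the sample variance ratio equals target_r2 exactly
        X1 = np.column_stack([np.ones(n_genes), X])
        eps -= X1 @ np.linalg.lstsq(X1, eps, rcond=None)[0]
        var_sig = signal.var()
        eps *= np.sqrt(var_sig * (1 - target_r2) / target_r2) / eps.std()
        noise_sd = float(eps.std())
    else:
        eps = rng.standard_normal(n_genes) * noise_sd
    rate = signal + eps
    df = pd.DataFrame(X, columns=["exon_density", "CpG_content", "H3K79me2"])
    df["intron1_length"] = -0.9 * df["exon_density"] + \
        proxy_noise_sd * rng.standard_normal(n_genes)
    df["CpG_methylation"] = 0.9 * df["CpG_content"] + \
        proxy_noise_sd * rng.standard_normal(n_genes)
    df["rate_z"] = rate
    df.index = [f"g{i}" for i in range(n_genes)]
    truth = SyntheticTruth(seed, {
        "beta": beta, "noise_sd": noise_sd,
        "planted_r2": (target_r2 if target_r2 is not None else
                       var_signal / (var_signal + noise_sd ** 2)),
        "proxies": {"intron1_length": "exon_density",
                    "CpG_methylation": "CpG_content"},
    })
    return df, truth
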