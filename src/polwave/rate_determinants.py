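"""Rank-z multivariate modeling of elongation-rate determinants.

Heterogeneous genomic features (exon density, CpG content and methylation,
ChIP densities, intron 1 length, ...) are made comparable by the rank-based
inverse normal transform z_i = Phi^-1((rank_i - 0.5) / n), ties broken by a
seeded random permutation.  Simple and multivariate least squares on the
z-scores, the iterative residual analysis (how much of a secondary feature's
correlation a primary feature explains; > 66% = dependent), per-pair PCA
directions, and 6-mer enrichment between slow and fast gene groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genomic_io import GeneModel

__all__ = [
    "FeatureMatrix",
    "ModelFit",
    "rank_z_transform",
    "extract_region_features",
    "kmer_enrichment",
    "iterative_linear_model",
    "dependency_matrix",
    "multivariate_fit",
]

#: transcription-direction offsets (bp from TSS) per named region; the mid
#: region is the average 12.5-25 min transition region (7.5-30 kb)
REGIONS = {
    "promoter": (-500, 500),
    "mid_transition": (7_500, 30_000),
    "late_transition": (30_000, 90_000),
}

DEPENDENCY_THRESHOLD = 0.66


@dataclass
class FeatureMatrix:
    values: pd.DataFrame              # genes x features, raw scale
    z: pd.DataFrame | None            # rank-z transformed (None below n = 3)


@dataclass
class ModelFit:
    beta: pd.Series
    r2: float
    nested_r2: list
    residuals: np.ndarray
    pca_directions: dict = field(default_factory=dict)


def rank_z_transform(values, seed: int = 0) -> np.ndarray:
    """Inverse-normal transform of percentile ranks, (i - 0.5)/n convention.

    Ties are randomly ordered with the given seed, so the output is always a
    permutation of the fixed quantile set Phi^-1((i - 0.5)/n).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 values for rank-z")
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(n)            # random tie order, seeded
    order = np.lexsort((jitter, v))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    return norm.ppf((ranks - 0.5) / n)


def _cpg_density(seq: str) -> float:
    s = seq.upper()
    return s.count("CG") / max(len(s), 1)


def _gc_content(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


def extract_region_features(genes: list[GeneModel], chip_tracks: dict,
                            sequences, region: str = "mid_transition",
                            seed: int = 0) -> FeatureMatrix:
    """Per-gene feature matrix over a named region.

    ``chip_tracks``: feature name -> {chrom: SignalTrack} (read densities).
    ``sequences``: chrom -> sequence string (or a pyfaidx.Fasta).  Computed
    features: each ChIP density, CpG_content, GC_content, exon_count,
    exon_density (exons/kb), intron1_length.
    """
    lo, hi = REGIONS[region]
    rows = []
    for g in genes:
        reg = g.tx_region(max(lo, -g.tss if g.strand == "+" else lo), hi)
        row = {"gene_id": g.gene_id}
        seq = sequences[g.chrom]
        sub = str(seq[reg.start:reg.end])
        row["CpG_content"] = _cpg_density(sub)
        row["GC_content"] = _gc_content(sub)
        n_ex = sum(1 for ex in g.exons if ex.overlap(reg) > 0)
        row["exon_count"] = n_ex
        row["exon_density"] = n_ex / (len(reg) / 1000.0)
        row["intron1_length"] = g.intron1_length
        for name, tracks in chip_tracks.items():
            tr = tracks[g.chrom] if isinstance(tracks, dict) else tracks
            row[name] = tr.region_density(reg.start, reg.end, scaled=True)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id")
    z = None
    if len(df) >= 3:   # rank-z needs a cohort
        z = pd.DataFrame({c: rank_z_transform(df[c].to_numpy(), seed=seed)
                          for c in df.columns}, index=df.index)
    return FeatureMatrix(df, z)


def kmer_enrichment(slow_seqs, fast_seqs, k: int = 6,
                    pseudo: float = 1.0) -> pd.DataFrame:
    """All 4^k k-mer counts per group and the slow/fast occurrence ratio.

    Sequences are the transcribed (sense) strands; the table is indexed by
    the RNA-sense k-mer (U for T) and sorted by descending ratio.
    """
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    idx = {km: i for i, km in enumerate(kmers)}

    def count(seqs):
        c = np.zeros(len(kmers))
        for s in seqs:
            s = s.upper()
            for i in range(len(s) - k + 1):
                j = idx.get(s[i:i + k])
                if j is not None:
                    c[j] += 1
        return c

    slow = count(slow_seqs)
    fast = count(fast_seqs)
    ratio = (slow + pseudo) / (fast + pseudo)
    df = pd.DataFrame({
        "kmer": [km.replace("T", "U") for km in kmers],
        "slow_count": slow.astype(int),
        "fast_count": fast.astype(int),
        "ratio": ratio,
    }).sort_values("ratio", ascending=False).reset_index(drop=True)
    return df


def _r2_simple(y: np.ndarray, x: np.ndarray) -> float:
    cx = np.corrcoef(x, y)[0, 1]
    return float(cx ** 2)


def iterative_linear_model(rate_z, feature_z: pd.DataFrame, primary: str,
                           secondary: str, seed: int = 0):
    """Fraction of the secondary feature's correlation explained by the primary.

    Residuals of rate ~ primary are rank-z re-transformed and fitted against
    the secondary; fraction = 1 - R2(resid ~ 2) / R2(rate ~ 2).  Returns
    (fraction, dependent) or (nan, None) when the secondary carries no
    correlation to start with.
    """
    y = np.asarray(rate_z, dtype=float)
    x1 = feature_z[primary].to_numpy()
    x2 = feature_z[secondary].to_numpy()
    r2_orig = _r2_simple(y, x2)
    if r2_orig < 1e-6:
        return float("nan"), None
    slope, icpt = np.polyfit(x1, y, 1)
    resid = y - (icpt + slope * x1)
    resid_z = rank_z_transform(resid, seed=seed)
    r2_resid = _r2_simple(resid_z, x2)
    frac = 1.0 - r2_resid / r2_orig
    return float(frac), bool(frac > DEPENDENCY_THRESHOLD)


def dependency_matrix(rate_z, feature_z: pd.DataFrame,
                      seed: int = 0) -> pd.DataFrame:
    """All primary x secondary explained fractions (diagonal = 1)."""
    cols = list(feature_z.columns)
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    for p in cols:
        for s in cols:
            if p == s:
                mat.loc[p, s] = 1.0
            else:
                frac, _ = iterative_linear_model(rate_z, feature_z, p, s,
                                                 seed=seed)
                mat.loc[p, s] = frac
    return mat


def multivariate_fit(rate_z, feature_z: pd.DataFrame,
                     columns: list[str] | None = None) -> ModelFit:
    """OLS of rate z-scores on feature z-scores with a nested R2 ladder.

    nested_r2[i] is the R2 using the first i+1 columns; the full-model fit
    supplies beta and residuals.  pca_directions holds, per feature, the
    leading eigenvector of the 2x2 correlation matrix with the rate.
    """
    y = np.asarray(rate_z, dtype=float)
    if columns is None:
        columns = list(feature_z.columns)
    nested = []
    beta = None
    resid = None
    for i in range(1, len(columns) + 1):
        X = feature_z[columns[:i]].to_numpy()
        X1 = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
        pred = X1 @ coef
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        nested.append(float(1 - ss_res / ss_tot))
        if i == len(columns):
            beta = pd.Series(coef[1:], index=columns)
            resid = y - pred
    pca = {}
    for c in columns:
        corr = np.corrcoef(y, feature_z[c].to_numpy())
        w, vecs = np.linalg.eigh(corr)
        pca[c] = vecs[:, np.argmax(w)]
    return ModelFit(beta, nested[-1], nested, resid, pca)
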