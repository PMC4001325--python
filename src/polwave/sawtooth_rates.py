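"""Relative elongation rates from intronic RNA-seq saw-tooth gradients.

Intronic RNA is spliced and degraded co-transcriptionally, so reads pile up
in proportion to how long Pol II dwells between a position and the next 3'
splice site: slow polymerases build steeper 5'-high gradients.  Long introns
(>= 10 kb, split at internal alternative exons) are pooled in 10-kb length
bins, aligned at their 3' splice sites, profiled in 100-bp windows and
normalized to the last kb before the 3'SS; the linear-regression slope of
the normalized profile against distance from the 3'SS is the (relative)
inverse-rate readout.  Distance increases 3'SS -> 5', so steeper *positive*
slope means slower Pol II.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, GenomicInterval, SignalTrack

__all__ = [
    "IntronGroup",
    "select_and_split_introns",
    "aggregate_3ss_profile",
    "gradient_slope",
]

MIN_INTRON = 10_000
MAX_ESTIMATE = 50_000      # slopes estimated up to 50 kb
MAX_PLOT = 80_000
GROUP_BIN = 10_000
PROFILE_WINDOW = 100
NORM_WINDOW = 1000         # last kb before the 3'SS


@dataclass
class IntronGroup:
    length_bin: tuple            # [L, L + 10 kb)
    n_introns: int
    distances: np.ndarray        # window midpoints, bp upstream of the 3'SS
    profile: np.ndarray          # pooled density normalized to the 3'SS kb


def _intron_3ss(gene: GeneModel, intron: GenomicInterval) -> int:
    """Genomic position of the intron's 3' splice site."""
    return intron.end if gene.strand == "+" else intron.start


def select_and_split_introns(genes: list[GeneModel],
                             alt_exons: dict | None = None,
                             min_length: int = MIN_INTRON,
                             max_length: int = MAX_ESTIMATE):
    """Qualifying introns, split at annotated alternative exons.

    ``alt_exons`` maps gene_id -> list of GenomicInterval exons from other
    isoforms; an intron containing one is split into a 5' and a 3' piece
    (the exon removed).  Pieces shorter than ``min_length`` or longer than
    ``max_length`` are excluded.  Returns [(gene, intron_interval), ...].
    """
    out = []
    for g in genes:
        for intron in g.introns:
            if len(intron) < min_length:
                continue
            pieces = [intron]
            for ex in (alt_exons or {}).get(g.gene_id, []):
                new_pieces = []
                for p in pieces:
                    if ex.start > p.start and ex.end < p.end:
                        new_pieces.append(GenomicInterval(p.chrom, p.start,
                                                          ex.start, p.strand))
                        new_pieces.append(GenomicInterval(p.chrom, ex.end,
                                                          p.end, p.strand))
                    else:
                        new_pieces.append(p)
                pieces = new_pieces
            for p in pieces:
                if min_length <= len(p) <= max_length:
                    out.append((g, p))
    return out


def aggregate_3ss_profile(introns, track_by_chrom,
                          window: int = PROFILE_WINDOW) -> list[IntronGroup]:
    """Pool intron coverage by length bin, aligned at the 3' splice site.

    ``track_by_chrom`` maps chrom -> unstranded SignalTrack (or a single
    track).  Counts per 100-bp window at each distance from the 3'SS are
    pooled across the group's introns and divided by the group's density over
    the last kb before the 3'SS.  Groups with zero reads in the normalization
    window are dropped.
    """
    groups: dict = {}
    for g, intron in introns:
        lb = (len(intron) // GROUP_BIN) * GROUP_BIN
        groups.setdefault(lb, []).append((g, intron))
    out = []
    for lb in sorted(groups):
        members = groups[lb]
        n_win = lb // window
        pooled = np.zeros(n_win)
        covered = np.zeros(n_win)
        norm_count = 0.0
        for g, intron in members:
            track = track_by_chrom[g.chrom] if isinstance(track_by_chrom, dict) \
                else track_by_chrom
            ss3 = _intron_3ss(g, intron)
            sign = -1 if g.strand == "+" else 1   # step upstream of the 3'SS
            for w in range(n_win):
                d0, d1 = w * window, (w + 1) * window
                if d1 > len(intron):
                    break
                a = ss3 + sign * d1
                b = ss3 + sign * d0
                lo, hi = (a, b) if a < b else (b, a)
                pooled[w] += track.region_sum(lo, hi)
                covered[w] += window
            nlo, nhi = sorted((ss3, ss3 + sign * NORM_WINDOW))
            norm_count += track.region_sum(nlo, nhi)
        if norm_count <= 0:
            continue   # dropped: no reads in the normalization window
        norm_density = norm_count / (len(members) * NORM_WINDOW)
        with np.errstate(invalid="ignore", divide="ignore"):
            profile = (pooled / covered) / norm_density
        dist = (np.arange(n_win) + 0.5) * window
        good = covered > 0
        out.append(IntronGroup((lb, lb + GROUP_BIN), len(members),
                               dist[good], profile[good]))
    return out


def gradient_slope(group: IntronGroup, max_distance: int = MAX_ESTIMATE):
    """OLS slope (per bp) of normalized density on distance from the 3'SS.

    Returns (slope, sd) with sd the standard error of the slope.  Positive
    slope in this distance convention = denser toward the 5'SS = slower
    Pol II.
    """
    use = group.distances <= max_distance
    x = group.distances[use]
    y = group.profile[use]
    if len(x) < 3:
        raise ValueError("too few windows for a slope")
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    resid = y - (ym + slope * (x - xm))
    sd = float(np.sqrt(np.sum(resid ** 2) / max(n - 2, 1) / sxx))
    return float(slope), sd


def sawtooth_slope_table(groups: list[IntronGroup]) -> pd.DataFrame:
    """Per-group slope summary (length bin, n introns, slope, sd)."""
    rows = []
    for gr in groups:
        s, sd = gradient_slope(gr)
        rows.append({"length_bin_lo": gr.length_bin[0],
                     "length_bin_hi": gr.length_bin[1],
                     "n_introns": gr.n_introns, "slope": s, "sd": sd})
    return pd.DataFrame(rows)
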