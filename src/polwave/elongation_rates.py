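"""From wave transition points to elongation rates and their kinematics.

Rates are distances traveled by the inhibition-wave front over the window
between drug timepoints: early (5-12.5 min), mid (12.5-25 min), late
(25-50 min).  The acceleration constant is the per-minute multiplicative
rate growth a with v_end = v_start * a**dt (dt between window midpoints).
Exon correction removes the linear rate-vs-exon-density trend and quantifies
the additive per-exon traversal delay.  The density-vs-inverse-rate
comparison implements the flux argument: with no termination, steady-state
density D(x) is proportional to 1/v(x), so v^-1 staying at or above D
(both normalized at the most-downstream point) is the signature of
acceleration rather than termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "WINDOWS",
    "ElongationRate",
    "AccelerationConstant",
    "RateDensityProfile",
    "rate_from_transitions",
    "acceleration_constant",
    "exon_corrected_rate",
    "density_vs_inverse_rate",
    "production_rate_slope",
]

#: (t1, t2) minutes per named measurement window
WINDOWS = {"early": (5.0, 12.5), "mid": (12.5, 25.0), "late": (25.0, 50.0)}


@dataclass
class ElongationRate:
    gene_id: str
    window: str
    x1: float       # bp
    x2: float
    t1: float       # min
    t2: float

    @property
    def v(self) -> float:
        """kb/min"""
        return (self.x2 - self.x1) / (self.t2 - self.t1) / 1000.0

    @property
    def region_length(self) -> float:
        return self.x2 - self.x1


@dataclass
class AccelerationConstant:
    gene_id: str
    a: float
    phase: str      # early->mid | mid->late


@dataclass
class RateDensityProfile:
    positions: np.ndarray
    density: np.ndarray      # normalized at the most-downstream point
    v_inv: np.ndarray        # normalized likewise
    call: str                # acceleration-consistent | termination-suspected


def rate_from_transitions(x1: float, t1: float, x2: float, t2: float,
                          gene_id: str = "", window: str | None = None
                          ) -> ElongationRate:
    """v = (x2 - x1) / (t2 - t1); wave regression (x2 < x1) is rejected."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if x2 < x1:
        raise ValueError("non-physical regression of the wave (x2 < x1)")
    if window is None:
        window = next((k for k, (a, b) in WINDOWS.items()
                       if (a, b) == (t1, t2)), f"{t1}-{t2}")
    return ElongationRate(gene_id, window, x1, x2, t1, t2)


def acceleration_constant(v_start: float, v_end: float, dt: float,
                          gene_id: str = "", phase: str = "",
                          linear: bool = False) -> AccelerationConstant:
    """a = (v_end / v_start) ** (1 / dt), the per-minute rate multiplier.

    ``dt`` is the gap between window midpoints (min).  ``linear=True``
    switches to the additive alternative a = 1 + (v_end - v_start) /
    (v_start * dt).
    """
    if v_start <= 0:
        raise ValueError("v_start must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if linear:
        a = 1.0 + (v_end - v_start) / (v_start * dt)
    else:
        a = float((v_end / v_start) ** (1.0 / dt))
    return AccelerationConstant(gene_id, a, phase)


def exon_corrected_rate(rates: list[ElongationRate], exon_counts,
                        min_genes: int = 10):
    """Remove the rate-vs-exon-density trend; estimate the per-exon delay.

    ``exon_counts[i]`` is the number of exons inside rate i's transition
    region.  Only regions with exon density > 0 enter the regressions.
    Returns (corrected_rates_kb_per_min, per_exon_delay_s, slope): the
    correction subtracts slope * (density - cohort mean density) from the
    observed rate (slope from the rate ~ exon-density regression), and the
    additive per-exon delay is the slope of traversal time per kb (60/v
    seconds) on exon density (exons/kb) - each extra exon in a kb adds that
    many seconds.
    """
    exon_counts = np.asarray(exon_counts, dtype=float)
    v = np.array([r.v for r in rates])
    length_kb = np.array([r.region_length / 1000.0 for r in rates])
    dens = exon_counts / length_kb                      # exons/kb
    use = dens > 0
    if use.sum() < min_genes:
        raise ValueError(f"need >= {min_genes} genes with exons in the region")
    if np.allclose(dens[use], dens[use][0]):
        raise ValueError("exon density is constant; regression undefined")
    slope, icpt = np.polyfit(dens[use], v[use], 1)
    corrected = v - slope * (dens - dens[use].mean())
    delay, _ = np.polyfit(dens[use], 60.0 / v[use], 1)   # s per exon
    return corrected, float(delay), float(slope)


def density_vs_inverse_rate(positions, density, rates,
                            min_x: float = 2300.0,
                            tolerance: float | None = None
                            ) -> RateDensityProfile:
    """Normalized D and v^-1 profiles and the acceleration/termination call.

    Both series are normalized at the most-downstream common position.  The
    run is acceleration-consistent iff v^-1 >= D - tolerance at every
    measured x >= ``min_x`` (the average 5-min transition point, 2.3 kb);
    default tolerance is one pooled standard error of the density profile.
    """
    x = np.asarray(positions, dtype=float)
    d = np.asarray(density, dtype=float)
    vinv = 1.0 / np.asarray(rates, dtype=float)
    if d[-1] <= 0 or not np.isfinite(vinv[-1]):
        raise ValueError("most-downstream point must have positive D and v")
    dn = d / d[-1]
    vn = vinv / vinv[-1]
    if tolerance is None:
        tolerance = float(np.std(dn, ddof=1) / np.sqrt(len(dn))) if len(dn) > 1 else 0.0
    use = x >= min_x
    ok = np.all(vn[use] >= dn[use] - tolerance)
    return RateDensityProfile(x, dn, vn,
                              "acceleration-consistent" if ok
                              else "termination-suspected")


def production_rate_slope(predictor, mrna, span: float = 0.75):
    """Log-log LOESS slopes of mRNA on a predictor, per expression half.

    ``predictor`` is GRO-seq density (or density * rate, the production
    rate); slopes come from central differences of the LOESS fit, averaged
    over the lower and upper 50 percentiles of the predictor.  Returns
    (slope_lower, slope_upper).
    """
    xp = np.log10(np.asarray(predictor, dtype=float))
    yp = np.log10(np.asarray(mrna, dtype=float))
    if np.any(~np.isfinite(xp)) or np.any(~np.isfinite(yp)):
        raise ValueError("predictor and mrna must be positive")
    fit = lowess(yp, xp, frac=span, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    grad = np.gradient(ys, xs)
    med = np.median(xs)
    lower = float(np.mean(grad[xs <= med]))
    upper = float(np.mean(grad[xs > med]))
    return lower, upper
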