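"""Microtubule depolymerization rates and Hill concentration-response fits.

End positions are traced frame-by-frame from a kymograph of a shrinking
microtubule, each end's shrinkage speed comes from a least-squares slope of
position against time, and rate-versus-concentration series are fitted
with a baseline-offset Hill curve

    v(C) = v0 + (v_max - v0) * C^h / (K^h + C^h)

where v0 is residual activity at zero motor, v_max the saturating rate, K
the half-maximal concentration (nM) and h the Hill coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kymograph import Kymograph

__all__ = ["EndTrace", "DepolyRates", "HillFit", "trace_mt_ends", "fit_depoly_rate", "fit_hill", "hill_curve"]


@dataclass
class EndTrace:
    """Per-frame end positions of one microtubule.

    ``minus_um``/``plus_um`` are NaN where ``valid`` is False (segment lost
    or vanished). Positions are µm from the left edge of the field; the
    plus end is the right-hand edge of the bright segment.
    """

    times: np.ndarray
    minus_um: np.ndarray
    plus_um: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.minus_um) == len(self.plus_um) == len(self.valid) == n):
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        ok = self.valid
        if np.any(self.plus_um[ok] < self.minus_um[ok]):
            raise ValueError("plus end left of minus end in a valid frame")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def trace_mt_ends(kymo: Kymograph, threshold: float | None = None) -> EndTrace:
    """Trace the two ends of the microtubule segment in every frame.

    Per frame the microtubule is the longest contiguous run of
    above-threshold pixels; each end position is refined to sub-pixel
    precision by linear interpolation of the intensity crossing at the
    threshold. With ``threshold=None`` the cut is placed at half-maximum
    between robust background and signal plateaus — for a Gaussian-blurred
    edge the half-maximum crossing sits at the true end position. A numeric
    ``threshold`` is interpreted as sigmas above background, estimated from
    the dimmest 20% of pixels.

    Frames with no segment are masked invalid; an empty first frame is an
    error (no microtubule to start from).
    """
    data = kymo.data
    lo = float(np.percentile(data, 5))
    hi = float(np.percentile(data, 95))
    if threshold is None:
        thr = lo + 0.5 * (hi - lo)
    else:
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        dark = data[data <= np.percentile(data, 20)]
        bg = float(np.mean(dark))
        sd = float(np.std(dark))
        thr = bg + threshold * sd

    n_frames, n_pixels = data.shape
    minus = np.full(n_frames, np.nan)
    plus = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)
    px = kymo.pixel_size
    for f in range(n_frames):
        row = data[f]
        mask = row > thr
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        segments = np.split(idx, breaks + 1)
        seg = max(segments, key=len)
        i0, i1 = int(seg[0]), int(seg[-1])
        minus[f] = _edge_cross(row, i0, -1, thr) * px
        plus[f] = _edge_cross(row, i1, +1, thr) * px
        valid[f] = True
    if not valid[0]:
        raise ValueError("no microtubule segment in the first frame")
    times = kymo.times()
    return EndTrace(times, minus, plus, valid)


def _edge_cross(row: np.ndarray, i: int, direction: int, thr: float) -> float:
    """Sub-pixel threshold crossing next to edge pixel ``i`` (pixel units).

    ``direction`` −1 looks at the outside neighbour on the left (minus
    end), +1 on the right (plus end). Pixel centre of index j is j + 0.5.
    """
    j = i + direction
    center = i + 0.5
    if j < 0 or j >= row.size or row[j] >= thr:
        return center
    frac = (row[i] - thr) / (row[i] - row[j])  # in (0, 1]
    return center + direction * frac


@dataclass
class DepolyRates:
    """Per-end and summary shrinkage rates, µm min⁻¹ (positive = shrinking)."""

    minus_rate: float
    plus_rate: float

    @property
    def mean_rate(self) -> float:
        """Per-microtubule rate: mean of the two ends."""
        return 0.5 * (self.minus_rate + self.plus_rate)

    @property
    def total_rate(self) -> float:
        """Total length-loss rate: sum of the two ends."""
        return self.minus_rate + self.plus_rate


def fit_depoly_rate(trace: EndTrace) -> DepolyRates:
    """Least-squares shrinkage rate of each end, in µm min⁻¹.

    The minus end shrinks rightwards (+x) and the plus end leftwards, so
    both signed rates are positive for depolymerization; growth comes out
    negative and is deliberately not clipped.
    """
    ok = trace.valid
    if ok.sum() < 5:
        raise ValueError(f"only {int(ok.sum())} valid frames; need >= 5")
    t = trace.times[ok]
    minus_slope = np.polyfit(t, trace.minus_um[ok], 1)[0]
    plus_slope = np.polyfit(t, trace.plus_um[ok], 1)[0]
    return DepolyRates(minus_rate=minus_slope * 60.0, plus_rate=-plus_slope * 60.0)


def hill_curve(conc, v0: float, v_max: float, K: float, h: float):
    """Baseline-offset Hill curve v(C) = v0 + (v_max − v0)·C^h/(K^h + C^h)."""
    conc = np.asarray(conc, dtype=float)
    ch = np.power(conc, h, where=conc > 0, out=np.zeros_like(conc))
    return v0 + (v_max - v0) * ch / (K**h + ch)


@dataclass
class HillFit:
    """Fitted Hill parameters; rates in µm min⁻¹, K in nM."""

    v0: float
    v_max: float
    K: float
    h: float
    rss: float

    def predict(self, conc):
        return hill_curve(conc, self.v0, self.v_max, self.K, self.h)


def fit_hill(
    concentrations,
    rates,
    sem=None,
    fix_v0: float | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> HillFit:
    """Weighted least-squares Hill fit with multi-start optimization.

    Parameters
    ----------
    concentrations, rates : array-like
        Concentration (nM) / mean rate (µm min⁻¹) pairs; at least 4
        distinct concentrations (3 suffice when ``fix_v0`` pins the
        baseline).
    sem : array-like, optional
        Standard errors; residuals are weighted 1/sem where given.
    fix_v0 : float, optional
        Pin the baseline (e.g. 0 for no spontaneous depolymerization).
    n_starts : int
        Seeded random multi-starts; the best residual sum of squares wins.

    Raises ValueError with diagnostics if no start converges.
    """
    conc = np.asarray(concentrations, dtype=float)
    rate = np.asarray(rates, dtype=float)
    if conc.shape != rate.shape:
        raise ValueError("concentrations and rates must have the same shape")
    n_params = 3 if fix_v0 is not None else 4
    if len(np.unique(conc)) < max(4, n_params):
        raise ValueError(
            f"need >= {max(4, n_params)} distinct concentrations for {n_params} parameters"
        )
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    w = np.ones_like(rate)
    if sem is not None:
        sem = np.asarray(sem, dtype=float)
        pos = sem > 0
        w[pos] = 1.0 / sem[pos]

    rmin, rmax = float(rate.min()), float(rate.max())
    span = max(rmax - rmin, 1e-9)
    cpos = conc[conc > 0]
    cmid = float(np.median(cpos)) if cpos.size else 1.0

    def residuals(p):
        if fix_v0 is not None:
            v0, (vmax, K, h) = fix_v0, p
        else:
            v0, vmax, K, h = p
        return w * (hill_curve(conc, v0, vmax, K, h) - rate)

    rng = np.random.default_rng(seed)
    starts = []
    for k in range(n_starts):
        vmax0 = rmax * (1.0 + 0.2 * rng.standard_normal()) if rmax > 0 else span
        K0 = cmid * 10 ** rng.uniform(-1, 1)
        h0 = 10 ** rng.uniform(np.log10(0.5), np.log10(4.0))
        if fix_v0 is not None:
            starts.append([vmax0, max(K0, 1e-6), h0])
        else:
            v00 = max(rmin, 0.0) * rng.uniform(0.0, 1.5)
            starts.append([v00, vmax0, max(K0, 1e-6), h0])

    if fix_v0 is not None:
        lower = [0.0, 1e-12, 1e-3]
        upper = [np.inf, np.inf, 100.0]
    else:
        lower = [0.0, 0.0, 1e-12, 1e-3]
        upper = [np.inf, np.inf, np.inf, 100.0]

    best = None
    failures = []
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper), method="trf")
        except Exception as exc:
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        rss = float(np.sum(residuals(sol.x) ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise ValueError(f"Hill fit failed from all {n_starts} starts: {failures[:3]}")
    rss, p = best
    if fix_v0 is not None:
        v0, (vmax, K, h) = fix_v0, p
    else:
        v0, vmax, K, h = p
    if vmax < v0:
        warnings.warn("fitted v_max below v0: decreasing response", stacklevel=2)
    return HillFit(v0=float(v0), v_max=float(vmax), K=float(K), h=float(h), rss=rss)
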