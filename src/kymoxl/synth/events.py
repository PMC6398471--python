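"""Single-molecule binding-event simulation and kymograph rendering.

Models the lattice binding of a depolymerase motor (e.g. MCAK) imaged by
TIRF: landings are a homogeneous Poisson process in time, uniform along the
microtubules, with i.i.d. exponential dwell times of mean 1/koff. Rendering
integrates each event's presence over camera frames, spreads it spatially by
a Gaussian point-spread function, and adds Gaussian camera noise on a
constant background.

Photobleaching is deliberately not modelled: it would shorten apparent
dwells and bias off-rate estimates, and the analyses downstream use
durations only. Bound-state 1D diffusion is available (``diffusion_coef``)
but defaults to zero for the same reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ..kymograph import Kymograph

__all__ = ["SimulationConfig", "GroundTruthEvents", "simulate_binding_events", "render_kymograph"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for a single-molecule binding simulation.

    Parameters
    ----------
    kon_density : float
        Landing rate density, events s⁻¹ µm⁻¹ pM⁻¹.
    koff : float
        Detachment rate, s⁻¹; mean dwell τ = 1/koff.
    concentration : float
        Motor concentration, pM (assay range 5-100 pM).
    mt_lengths : tuple of float
        Microtubule lengths, µm.
    duration : float
        Acquisition length, s. Zero is allowed and yields no events.
    frame_interval : float
        Camera frame interval, s (0.13 s full-chip; 0.015 s binned).
    pixel_size : float
        µm per pixel (0.16 µm full-chip; 0.86 µm binned).
    psf_sigma : float
        Gaussian PSF sigma, µm.
    noise_sd : float
        Additive Gaussian camera noise, intensity units.
    amplitude : float
        Peak-pixel intensity of a molecule present for a full frame.
    background : float
        Constant background level.
    diffusion_coef : float
        Bound-state 1D diffusion coefficient, µm² s⁻¹ (default 0).
    seed : int
        Reproducibility seed; identical configs give identical output.
    """

    kon_density: float = 1e-3
    koff: float = 1.6
    concentration: float = 50.0
    mt_lengths: tuple[float, ...] = (30.0, 30.0, 30.0, 30.0, 30.0)
    duration: float = 120.0
    frame_interval: float = 0.13
    pixel_size: float = 0.16
    psf_sigma: float = 0.17
    noise_sd: float = 1.0
    amplitude: float = 10.0
    background: float = 10.0
    diffusion_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mt_lengths", tuple(float(L) for L in self.mt_lengths))
        positive = {
            "kon_density": self.kon_density,
            "koff": self.koff,
            "concentration": self.concentration,
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "psf_sigma": self.psf_sigma,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if any(L <= 0 for L in self.mt_lengths):
            raise ValueError("all microtubule lengths must be strictly positive")
        if self.noise_sd < 0 or self.diffusion_coef < 0:
            raise ValueError("noise_sd and diffusion_coef must be non-negative")

    @property
    def tau(self) -> float:
        """Mean dwell time 1/koff, s."""
        return 1.0 / self.koff

    @property
    def total_length(self) -> float:
        return float(sum(self.mt_lengths))

    @property
    def expected_events(self) -> float:
        """Poisson mean: kon_density * C * sum(L) * T."""
        return self.kon_density * self.concentration * self.total_length * self.duration

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mt_lengths"] = list(self.mt_lengths)
        return d


@dataclass
class GroundTruthEvents:
    """Continuous-time truth behind a rendered kymograph.

    ``events`` columns: mt_id (int), position_um, t_on (s), dwell_s.
    """

    events: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.events)

    def for_mt(self, mt_id: int) -> pd.DataFrame:
        return self.events[self.events["mt_id"] == mt_id]


def simulate_binding_events(config: SimulationConfig) -> GroundTruthEvents:
    """Draw a Poisson stream of landings with exponential dwells.

    The event count is Poisson with mean ``kon_density * C * sum(L) * T``;
    landing times are uniform on [0, T), positions uniform along the pooled
    microtubule length (each microtubule weighted by its length), and dwells
    exponential with mean 1/koff.
    """
    rng = np.random.default_rng(config.seed)
    n = rng.poisson(config.expected_events) if config.duration > 0 else 0
    if n == 0:
        empty = pd.DataFrame(columns=["mt_id", "position_um", "t_on", "dwell_s"])
        return GroundTruthEvents(empty.astype({"mt_id": int}), config)
    lengths = np.array(config.mt_lengths)
    mt_id = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    position = rng.uniform(0.0, lengths[mt_id])
    t_on = rng.uniform(0.0, config.duration, size=n)
    dwell = rng.exponential(config.tau, size=n)
    events = pd.DataFrame(
        {"mt_id": mt_id, "position_um": position, "t_on": t_on, "dwell_s": dwell}
    ).sort_values("t_on", ignore_index=True)
    return GroundTruthEvents(events, config)


def render_kymograph(
    truth: GroundTruthEvents, config: SimulationConfig | None = None, mt_id: int = 0
) -> Kymograph:
    """Render one microtubule's events into a kymograph.

    Frame ``f`` covers time ``[f*dt, (f+1)*dt)``; an event contributes to a
    frame in proportion to its temporal overlap with it (camera photon
    integration), spread spatially by the PSF. ``amplitude`` is the
    peak-pixel intensity of a molecule present for the whole frame. Output
    shape is ``(ceil(T/dt), ceil(L/pixel_size))``.
    """
    if config is None:
        config = truth.config
    if config is None:
        raise ValueError("no SimulationConfig available")
    if len(config.mt_lengths) == 0:
        raise ValueError("empty microtubule set")
    if not 0 <= mt_id < len(config.mt_lengths):
        raise ValueError(f"mt_id {mt_id} out of range")

    dt = config.frame_interval
    n_frames = math.ceil(config.duration / dt)
    n_pixels = math.ceil(config.mt_lengths[mt_id] / config.pixel_size)
    image = np.full((n_frames, n_pixels), config.background, dtype=float)
    # independent, deterministic streams for diffusion and camera noise
    rng = np.random.default_rng([config.seed, mt_id, 1])

    edges = np.arange(n_pixels + 1) * config.pixel_size
    events = truth.for_mt(mt_id)
    for ev in events.itertuples(index=False):
        t0, t1 = ev.t_on, ev.t_on + ev.dwell_s
        f0 = int(t0 // dt)
        f1 = min(int(t1 // dt), n_frames - 1)
        if f0 >= n_frames or f1 < f0:
            continue
        frames = np.arange(f0, f1 + 1)
        overlap = (
            np.minimum((frames + 1) * dt, t1) - np.maximum(frames * dt, t0)
        ) / dt
        if config.diffusion_coef > 0:
            steps = rng.normal(
                0.0, math.sqrt(2.0 * config.diffusion_coef * dt), size=len(frames)
            )
            xs = ev.position_um + np.concatenate([[0.0], np.cumsum(steps[:-1])])
        else:
            xs = np.full(len(frames), ev.position_um)
        for f, frac, x in zip(frames, overlap, xs):
            w = ndtr((edges[1:] - x) / config.psf_sigma) - ndtr(
                (edges[:-1] - x) / config.psf_sigma
            )
            peak = w.max()
            if peak <= 0:
                continue
            image[f] += config.amplitude * frac * (w / peak)
    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)
    meta = {
        "mt_id": mt_id,
        "config": config.to_dict(),
        "n_truth_events": int(len(events)),
    }
    return Kymograph(image, dt, config.pixel_size, meta)
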