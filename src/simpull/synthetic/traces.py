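"""Synthetic SiMPull photobleaching traces with known ground truth.

The generator emulates what the microscope records for one immobilized
GFP-tagged complex: a staircase that starts at
``background + m * unit_intensity`` (m = active fluorophores) and drops
by one ``unit_intensity`` each time a fluorophore bleaches, plus
additive Gaussian camera noise.  Bleach times are independent geometric
draws.  A population draws each spot's true oligomer size from an
:class:`OligomerSpec`, adds one extra GFP with probability
``self_dimer_fraction`` (GFP self-dimerization), and thins by the dark
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..trace import GFPPhotophysics, Trace

__all__ = [
    "OligomerSpec",
    "simulate_trace",
    "simulate_population",
    "make_staircase",
    "spots_per_field",
]

#: Typical SiMPull surface density: ~100-300 spots in a 2,500 um^2 field.
SPOT_DENSITY_RANGE = (100, 300)
FIELD_AREA_UM2 = 2500.0


def spots_per_field(rng: np.random.Generator | None = None) -> int:
    """Draw a realistic spot count for one 2,500 um^2 imaging field."""
    rng = np.random.default_rng() if rng is None else rng
    return int(rng.integers(SPOT_DENSITY_RANGE[0], SPOT_DENSITY_RANGE[1] + 1))


@dataclass(frozen=True)
class OligomerSpec:
    """Ground-truth oligomer-size distribution for a simulated condition.

    ``probabilities`` maps oligomer size k (>= 1) to the fraction of
    spots whose complex truly contains k tagged molecules.
    """

    probabilities: dict[int, float]
    n_spots: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.probabilities:
            raise ValueError("probabilities must be non-empty")
        ks = sorted(self.probabilities)
        if any((not float(k).is_integer()) or k < 1 for k in ks):
            raise ValueError("oligomer sizes must be integers >= 1")
        ps = np.array([self.probabilities[k] for k in ks], dtype=float)
        if np.any(ps < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(ps.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {ps.sum()!r}")
        if self.n_spots <= 0:
            raise ValueError("n_spots must be positive")
        object.__setattr__(
            self, "probabilities", {int(k): float(self.probabilities[k]) for k in ks}
        )

    @property
    def sizes(self) -> np.ndarray:
        return np.array(sorted(self.probabilities), dtype=int)

    @property
    def mean_size(self) -> float:
        return float(sum(k * p for k, p in self.probabilities.items()))


def _simulate_trace(
    n_fluorophores: int,
    phys: GFPPhotophysics,
    n_frames: int,
    rng: np.random.Generator,
    spot_id: str,
    frame_interval: float,
) -> Trace:
    if n_fluorophores < 0:
        raise ValueError("n_fluorophores must be >= 0")
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")

    # dark-fraction thinning: only mature fluorophores contribute signal
    if phys.dark_fraction > 0 and n_fluorophores > 0:
        m = int(rng.binomial(n_fluorophores, 1.0 - phys.dark_fraction))
    else:
        m = int(n_fluorophores)

    # geometric bleach frames (>= 1 trial); a fluorophore active in
    # frames [0, b) contributes unit_intensity there and bleaches at b.
    bleach = rng.geometric(phys.bleach_rate, size=m) if m else np.empty(0, dtype=int)
    frames = np.arange(n_frames)
    active = (bleach[:, None] > frames[None, :]).sum(axis=0) if m else np.zeros(n_frames)
    signal = phys.background_level + phys.unit_intensity * active
    if phys.noise_sd > 0:
        signal = signal + rng.normal(0.0, phys.noise_sd, size=n_frames)
    return Trace(
        spot_id=spot_id,
        intensities=signal,
        frame_interval=frame_interval,
        truth=m,
        truth_bleach_frames=tuple(int(b) for b in np.sort(bleach)),
    )


def simulate_trace(
    n_fluorophores: int,
    phys: GFPPhotophysics | None = None,
    n_frames: int = 800,
    seed: int = 0,
    spot_id: str = "spot0000",
    frame_interval: float = 0.1,
) -> Trace:
    """Simulate one spot's photobleaching trace.

    The noiseless skeleton is a non-increasing staircase; ``truth`` on
    the returned :class:`~simpull.trace.Trace` records the active
    fluorophore count after dark-fraction thinning and
    ``truth_bleach_frames`` the frame at which each one bleached.
    """
    phys = GFPPhotophysics() if phys is None else phys
    rng = np.random.default_rng(seed)
    return _simulate_trace(n_fluorophores, phys, n_frames, rng, spot_id, frame_interval)


def simulate_population(
    spec: OligomerSpec,
    phys: GFPPhotophysics | None = None,
    n_frames: int = 800,
    seed: int | None = None,
    frame_interval: float = 0.1,
) -> list[Trace]:
    """Simulate one SiMPull field: a list of traces with truth labels.

    Each spot's true oligomer size k is drawn from ``spec``; the
    apparent tagged count is k plus one with probability
    ``phys.self_dimer_fraction`` (one extra partner recruited through a
    GFP–GFP contact; the increment is capped at +1), then thinned by the
    dark fraction inside the per-trace simulation.
    """
    phys = GFPPhotophysics() if phys is None else phys
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes = spec.sizes
    probs = np.array([spec.probabilities[int(k)] for k in sizes])
    ks = rng.choice(sizes, size=spec.n_spots, p=probs)
    apparent = ks + (rng.random(spec.n_spots) < phys.self_dimer_fraction)
    width = max(4, len(str(spec.n_spots - 1)))
    return [
        _simulate_trace(
            int(apparent[i]), phys, n_frames, rng, f"spot{i:0{width}d}", frame_interval
        )
        for i in range(spec.n_spots)
    ]


def make_staircase(
    bleach_frames: list[int] | tuple[int, ...],
    phys: GFPPhotophysics | None = None,
    n_frames: int = 200,
    spot_id: str = "stair",
    noise_sd: float | None = None,
    seed: int = 0,
) -> Trace:
    """Build a deterministic staircase trace with steps at given frames.

    Useful as an exactly-known input for the step detector: the trace
    starts at ``background + len(bleach_frames) * unit_intensity`` and
    drops one unit at each listed frame (frames need not be distinct;
    coincident frames produce a double-height drop).
    """
    phys = GFPPhotophysics() if phys is None else phys
    frames = np.asarray(bleach_frames, dtype=int)
    if frames.size and (frames.min() < 1 or frames.max() >= n_frames):
        raise ValueError("bleach frames must lie in [1, n_frames)")
    t = np.arange(n_frames)
    active = (frames[:, None] > t[None, :]).sum(axis=0) if frames.size else np.zeros(n_frames)
    y = phys.background_level + phys.unit_intensity * active
    sd = phys.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sd, size=n_frames)
    return Trace(
        spot_id=spot_id,
        intensities=y,
        truth=int(frames.size),
        truth_bleach_frames=tuple(int(b) for b in np.sort(frames)),
    )
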