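"""Core data containers for single-molecule photobleaching traces.

A SiMPull experiment images hundreds of surface-immobilized protein
complexes; each diffraction-limited spot yields one fluorescence
intensity time trace.  The number of abrupt downward photobleaching
steps in a trace estimates the number of GFP-tagged subunits in that
complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GFPPhotophysics", "Trace"]

MIN_TRACE_LENGTH = 10


@dataclass(frozen=True)
class GFPPhotophysics:
    """Photophysical parameters of the GFP tag used by the simulator.

    Parameters
    ----------
    self_dimer_fraction : float
        Probability that a spot carries one extra GFP recruited through
        GFP–GFP self-association.  The default 0.30 reproduces the
        canonical GFP-only control (~70% one-step / ~30% two-step spots).
    dark_fraction : float
        Probability that a given GFP is non-fluorescent (immature
        chromophore).  Default 0: every tag is counted.
    bleach_rate : float
        Per-frame bleaching hazard of one active fluorophore.  Bleach
        times are geometric with this parameter.
    unit_intensity : float
        Mean camera counts contributed by one active fluorophore; this
        is also the height of a single photobleaching step.
    background_level : float
        Mean counts of the fully bleached spot (surface background).
    noise_sd : float
        Per-frame additive Gaussian noise sd (EMCCD read-noise proxy).
        The signal-to-noise ratio is ``unit_intensity / noise_sd``
        (20 at the defaults).
    """

    self_dimer_fraction: float = 0.30
    dark_fraction: float = 0.0
    bleach_rate: float = 0.01
    unit_intensity: float = 100.0
    background_level: float = 50.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("self_dimer_fraction", "dark_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p!r}")
        if not 0.0 < self.bleach_rate <= 1.0:
            raise ValueError(f"bleach_rate must be in (0, 1], got {self.bleach_rate!r}")
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def snr(self) -> float:
        """Step height over read-noise sd (infinite for noiseless traces)."""
        return np.inf if self.noise_sd == 0 else self.unit_intensity / self.noise_sd


@dataclass(frozen=True)
class Trace:
    """One spot's fluorescence intensity time trace.

    ``truth`` and ``truth_bleach_frames`` carry the simulator's ground
    truth (active fluorophore count and the frame at which each one
    bleached); they are ``None`` for real data.
    """

    spot_id: str
    intensities: np.ndarray
    frame_interval: float = 0.1
    truth: int | None = None
    truth_bleach_frames: tuple[int, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intensities must be one-dimensional")
        if arr.size < MIN_TRACE_LENGTH:
            raise ValueError(
                f"trace {self.spot_id!r} has {arr.size} frames; "
                f"at least {MIN_TRACE_LENGTH} required"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"trace {self.spot_id!r} contains non-finite intensities")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.truth is not None and self.truth < 0:
            raise ValueError("truth fluorophore count must be >= 0")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return int(self.intensities.size)

    @property
    def n_frames(self) -> int:
        return len(self)
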