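"""Synthetic two-channel fixed-cell images with ground-truth masks.

Channel 1 emulates a nuclear stain (Hoechst-like) filling the nucleus;
channel 2 emulates diffuse GFP whose integrated intensity is split
between nucleus and cytosol according to a configurable nuclear signal
fraction, with optional bright circular granules.  Geometry is simple
(ellipse cell, ellipse nucleus, disk granules) — enough to test
localization and granule quantification against exactly known truth,
not a point-spread-function-accurate microscope model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GranuleSpec",
    "CellSpec",
    "SyntheticImageSpec",
    "SyntheticImage",
    "simulate_cell_image",
    "write_image",
]


@dataclass(frozen=True)
class GranuleSpec:
    """One circular granule: center (row, col) px, radius px, and the
    factor by which it amplifies the local diffuse GFP intensity."""

    center: tuple[float, float]
    radius: float
    amplification: float = 10.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("granule radius must be positive")
        if self.amplification <= 1:
            raise ValueError("granule amplification must exceed 1")

    @property
    def area_px(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class CellSpec:
    """Ellipse cell with an ellipse nucleus and optional granules.

    ``total_intensity`` is the cell's integrated GFP signal (counts);
    ``nuclear_signal_fraction`` of it falls on nuclear pixels.
    """

    center: tuple[float, float]
    cell_axes: tuple[float, float] = (30.0, 22.0)
    nucleus_axes: tuple[float, float] = (13.0, 10.0)
    nucleus_center: tuple[float, float] | None = None
    nuclear_signal_fraction: float = 0.5
    total_intensity: float = 2.0e6
    granules: tuple[GranuleSpec, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.nuclear_signal_fraction <= 1.0:
            raise ValueError("nuclear_signal_fraction must be in [0, 1]")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        nc = self.center if self.nucleus_center is None else self.nucleus_center
        object.__setattr__(self, "nucleus_center", tuple(float(v) for v in nc))
        # nucleus must fit inside the cell (ellipse containment, axis-aligned)
        dr = abs(nc[0] - self.center[0])
        dc = abs(nc[1] - self.center[1])
        if (
            dr + self.nucleus_axes[0] > self.cell_axes[0]
            or dc + self.nucleus_axes[1] > self.cell_axes[1]
        ):
            raise ValueError("nucleus not contained in cell")
        for g in self.granules:
            rr = (g.center[0] - self.center[0]) / self.cell_axes[0]
            cc = (g.center[1] - self.center[1]) / self.cell_axes[1]
            if rr * rr + cc * cc > 1.0:
                raise ValueError("granule center outside cell")
        object.__setattr__(self, "granules", tuple(self.granules))


@dataclass(frozen=True)
class SyntheticImageSpec:
    """One synthetic field: image shape, calibration, cells, noise, seed."""

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.25  # um per pixel
    cells: tuple[CellSpec, ...] = ()
    background_offset: float = 100.0
    nuclear_stain_level: float = 2000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "cells", tuple(self.cells))


@dataclass(frozen=True)
class SyntheticImage:
    """Rendered field plus every ground-truth quantity a test needs."""

    nuclear_channel: np.ndarray
    gfp_channel: np.ndarray
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    granule_labels: np.ndarray
    granule_areas_um2: dict[int, list[float]]  # cell label -> analytic areas
    nuclear_fractions: dict[int, float]  # cell label -> rendered nuclear fraction
    spec: SyntheticImageSpec

    @property
    def stack(self) -> np.ndarray:
        return np.stack([self.nuclear_channel, self.gfp_channel])


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return ((r - center[0]) / axes[0]) ** 2 + ((c - center[1]) / axes[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2


def simulate_cell_image(spec: SyntheticImageSpec) -> SyntheticImage:
    """Render a two-channel field with known masks and granule areas.

    GFP intensity is uniform within nucleus and within cytosol,
    weighted so nuclear pixels carry ``nuclear_signal_fraction`` of the
    cell's integrated signal; granules multiply the local diffuse
    intensity inside their disk.  The recorded ground-truth nuclear
    fraction is recomputed from the rendered noiseless image, so it is
    exact up to rasterization even when granules shift the balance.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    nuc_ch = np.full(shape, spec.background_offset, dtype=float)
    gfp = np.full(shape, spec.background_offset, dtype=float)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    granule_labels = np.zeros(shape, dtype=np.int32)
    granule_areas: dict[int, list[float]] = {}
    nuclear_fractions: dict[int, float] = {}
    g_label = 0

    for idx, cell in enumerate(spec.cells, start=1):
        cmask = _ellipse_mask(shape, cell.center, cell.cell_axes)
        nmask = _ellipse_mask(shape, cell.nucleus_center, cell.nucleus_axes) & cmask
        if np.any(cell_labels[cmask] != 0):
            raise ValueError("cells must not overlap")
        cyto = cmask & ~nmask
        n_nuc, n_cyt = int(nmask.sum()), int(cyto.sum())
        if n_nuc == 0 or n_cyt == 0:
            raise ValueError("degenerate cell geometry (empty nucleus or cytosol)")
        f = cell.nuclear_signal_fraction
        dens = np.zeros(shape)
        dens[nmask] = f * cell.total_intensity / n_nuc
        dens[cyto] = (1.0 - f) * cell.total_intensity / n_cyt
        for g in cell.granules:
            gmask = _disk_mask(shape, g.center, g.radius) & cmask
            dens[gmask] *= g.amplification
            g_label += 1
            granule_labels[gmask] = g_label
            granule_areas.setdefault(idx, []).append(
                g.area_px * spec.pixel_size**2
            )
        granule_areas.setdefault(idx, [])
        gfp += dens
        nuc_ch[nmask] += spec.nuclear_stain_level
        cell_labels[cmask] = idx
        nucleus_labels[nmask] = idx
        nuclear_fractions[idx] = float(dens[nmask].sum() / dens[cmask].sum())

    if spec.noise_sd > 0:
        nuc_ch = nuc_ch + rng.normal(0.0, spec.noise_sd, size=shape)
        gfp = gfp + rng.normal(0.0, spec.noise_sd, size=shape)
    return SyntheticImage(
        nuclear_channel=nuc_ch,
        gfp_channel=gfp,
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        granule_labels=granule_labels,
        granule_areas_um2=granule_areas,
        nuclear_fractions=nuclear_fractions,
        spec=spec,
    )


def write_image(img: SyntheticImage, out_dir: str | Path, stem: str = "field") -> dict[str, Path]:
    """Write the field as 16-bit multi-page TIFF plus label-mask TIFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = np.clip(np.round(img.stack), 0, 65535).astype(np.uint16)
    paths = {
        "image": out_dir / f"{stem}.tif",
        "cell_labels": out_dir / f"{stem}_cells.tif",
        "nucleus_labels": out_dir / f"{stem}_nuclei.tif",
        "granule_labels": out_dir / f"{stem}_granules.tif",
    }
    tifffile.imwrite(paths["image"], stack)
    tifffile.imwrite(paths["cell_labels"], img.cell_labels.astype(np.uint16))
    tifffile.imwrite(paths["nucleus_labels"], img.nucleus_labels.astype(np.uint16))
    tifffile.imwrite(paths["granule_labels"], img.granule_labels.astype(np.uint16))
    return paths
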