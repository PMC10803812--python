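"""Quantitative analysis of three-channel confocal biofilm z-stacks.

Stacks carry three fluorescence channels — SYTO9 (nucleic acids, i.e.
cells), Sypro Orange (protein) and Concanavalin A (polysaccharide), the
latter two marking the extracellular polymeric substance (EPS) matrix.
Each stack is a (channel, z, y, x) grid of 8-bit intensities with z = 0 at
the substrate.

The pipeline, in order:

1. per-slice in-plane median denoising,
2. per-channel global Otsu thresholding over the full 3-D histogram
   (voxels strictly above the threshold are "detected"),
3. removal of the first four z slices, where dye binding to the bare
   substrate produces >1% spurious coverage in stained controls,
4. OR-merge of channel masks: all three channels for total-biomass
   metrics, Sypro + ConA only for EPS metrics,
5. metric extraction: per-slice detected area, maximum area and area
   coverage, maximum biofilm height (MBH: number of slices with any
   detected voxel x slice thickness, slices need not be contiguous),
   biovolume (sum of slice areas x slice thickness), and the EPS
   biovolume fraction.

Otsu is global per channel rather than per slice because a per-slice
threshold on an empty slice would segment pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (
    FormatError,
    InsufficientDepthError,
    OutOfRangeError,
    ParameterError,
)

__all__ = [
    "CHANNELS",
    "ZStack",
    "BinaryStack",
    "BiofilmImageMetrics",
    "median_denoise",
    "otsu_binarize",
    "remove_base_slices",
    "merge_binary",
    "slice_areas",
    "max_area",
    "max_biofilm_height",
    "biovolume",
    "quantify_stack",
    "DEFAULT_BASE_SLICES",
    "DEFAULT_MEDIAN_KERNEL",
]

#: Fixed channel order: nucleic acid, protein, polysaccharide.
CHANNELS: Tuple[str, str, str] = ("syto9", "sypro_orange", "cona")

DEFAULT_BASE_SLICES = 4
DEFAULT_MEDIAN_KERNEL = 3


@dataclass
class ZStack:
    """Three-channel confocal stack with voxel geometry.

    ``data`` is (channel, z, y, x), 8-bit intensity scale, z index 0 at
    the substrate increasing upward.
    """

    data: np.ndarray
    pixel_um: float
    slice_um: float
    channels: Tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError("stack data must be 4-D (channel, z, y, x)")
        if self.data.shape[0] != 3 or len(self.channels) != 3:
            raise FormatError(
                f"expected exactly 3 channels, got {self.data.shape[0]}"
            )
        if self.pixel_um <= 0 or self.slice_um <= 0:
            raise ParameterError("voxel dimensions must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def frame_area_um2(self) -> float:
        _, _, ny, nx = self.data.shape
        return ny * nx * self.pixel_um**2

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise OutOfRangeError(
                f"unknown channel {channel!r}; have {self.channels}"
            ) from None


@dataclass
class BinaryStack:
    """Boolean (z, y, x) detection mask with geometry and provenance.

    ``degenerate`` marks a mask produced from a constant channel, for
    which no Otsu threshold exists (the mask is empty).
    """

    mask: np.ndarray
    pixel_um: float
    slice_um: float
    provenance: Tuple[str, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise FormatError("mask must be 3-D (z, y, x)")


@dataclass
class BiofilmImageMetrics:
    """Scalar metrics of one quantified stack.

    ``eps_fraction`` is EPS biovolume over total biovolume, or ``None``
    when the total biovolume is zero. The EPS mask uses a different
    channel subset, so ``eps_biovolume_um3 <= biovolume_um3`` is not
    enforced.
    """

    area_coverage: float
    max_area_um2: float
    mbh_um: float
    biovolume_um3: float
    eps_biovolume_um3: float
    eps_fraction: Optional[float]
    n_slices_analyzed: int


def median_denoise(stack: ZStack, kernel: int = DEFAULT_MEDIAN_KERNEL) -> ZStack:
    """In-plane median filter applied per channel, per z slice.

    ``kernel`` is the odd square footprint side; edges are handled by
    reflection; ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return replace(stack, data=stack.data.copy())
    out = np.empty_like(stack.data)
    for c in range(stack.data.shape[0]):
        for z in range(stack.data.shape[1]):
            out[c, z] = ndimage.median_filter(
                stack.data[c, z], size=kernel, mode="reflect"
            )
    return replace(stack, data=out)


def otsu_binarize(stack: ZStack, channel: str) -> BinaryStack:
    """Threshold one channel over its full 3-D histogram.

    The Otsu threshold maximizes between-class variance of the global
    intensity histogram; voxels strictly above it are detected. A constant
    channel has no threshold: the result is an empty mask flagged
    ``degenerate`` rather than an error, mirroring blank controls.
    """
    idx = stack.channel_index(channel)
    ch = stack.data[idx]
    if np.ptp(ch) == 0:
        return BinaryStack(
            mask=np.zeros(ch.shape, dtype=bool),
            pixel_um=stack.pixel_um,
            slice_um=stack.slice_um,
            provenance=(f"otsu[{channel}]:degenerate",),
            degenerate=True,
        )
    threshold = threshold_otsu(ch)
    return BinaryStack(
        mask=ch > threshold,
        pixel_um=stack.pixel_um,
        slice_um=stack.slice_um,
        provenance=(f"otsu[{channel}]:t={threshold}",),
    )


def remove_base_slices(
    mask: BinaryStack, n: int = DEFAULT_BASE_SLICES
) -> BinaryStack:
    """Drop the first ``n`` z slices (substrate staining artifact region)."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    if n == 0:
        return replace(mask, mask=mask.mask.copy())
    if mask.mask.shape[0] <= n:
        raise InsufficientDepthError(
            f"stack has {mask.mask.shape[0]} slices, cannot remove {n}"
        )
    return replace(
        mask,
        mask=mask.mask[n:].copy(),
        provenance=mask.provenance + (f"remove_base_slices[{n}]",),
    )


def merge_binary(masks: Sequence[BinaryStack]) -> BinaryStack:
    """Voxelwise OR of identically shaped masks."""
    if not masks:
        raise OutOfRangeError("need at least one mask")
    shape = masks[0].mask.shape
    for m in masks[1:]:
        if m.mask.shape != shape:
            raise FormatError(
                f"mask shape {m.mask.shape} != {shape}; cannot merge"
            )
    merged = np.zeros(shape, dtype=bool)
    provenance: Tuple[str, ...] = ()
    for m in masks:
        merged |= m.mask
        provenance += m.provenance
    return BinaryStack(
        mask=merged,
        pixel_um=masks[0].pixel_um,
        slice_um=masks[0].slice_um,
        provenance=provenance + ("merge",),
        degenerate=all(m.degenerate for m in masks),
    )


def slice_areas(mask: BinaryStack) -> np.ndarray:
    """Detected area per z slice (µm^2): pixel count x pixel area."""
    counts = mask.mask.sum(axis=(1, 2))
    return counts * mask.pixel_um**2


def max_area(mask: BinaryStack) -> Tuple[float, float]:
    """(maximum slice area in µm^2, coverage fraction of the frame)."""
    areas = slice_areas(mask)
    if areas.size == 0:
        return 0.0, 0.0
    peak = float(areas.max())
    _, ny, nx = mask.mask.shape
    frame = ny * nx * mask.pixel_um**2
    return peak, peak / frame


def max_biofilm_height(mask: BinaryStack) -> float:
    """MBH (µm): number of slices with >= 1 detected voxel x slice thickness.

    Occupied slices need not be contiguous, so a hollow-looking biofilm
    still counts every occupied plane.
    """
    occupied = int(np.count_nonzero(mask.mask.any(axis=(1, 2))))
    return occupied * mask.slice_um


def biovolume(mask: BinaryStack) -> float:
    """Biovolume (µm^3): sum of per-slice areas x slice thickness."""
    return float(slice_areas(mask).sum() * mask.slice_um)


def quantify_stack(
    stack: ZStack,
    *,
    kernel: int = DEFAULT_MEDIAN_KERNEL,
    base_slices: int = DEFAULT_BASE_SLICES,
) -> BiofilmImageMetrics:
    """Run the full pipeline on one stack and return its metrics.

    filter -> per-channel Otsu -> remove base slices -> merge -> metrics.
    Total-biomass metrics merge all three channels; EPS metrics merge only
    the Sypro Orange and ConA masks. Thresholds are computed on the full
    stack (including base slices, which are removed afterwards).
    """
    if stack.n_slices <= base_slices:
        raise InsufficientDepthError(
            f"need more than {base_slices} slices, got {stack.n_slices}"
        )
    denoised = median_denoise(stack, kernel)
    binaries = {
        ch: remove_base_slices(otsu_binarize(denoised, ch), base_slices)
        for ch in stack.channels
    }
    total = merge_binary([binaries[ch] for ch in stack.channels])
    eps = merge_binary([binaries[stack.channels[1]], binaries[stack.channels[2]]])

    peak_area, coverage = max_area(total)
    total_bv = biovolume(total)
    eps_bv = biovolume(eps)
    return BiofilmImageMetrics(
        area_coverage=coverage,
        max_area_um2=peak_area,
        mbh_um=max_biofilm_height(total),
        biovolume_um3=total_bv,
        eps_biovolume_um3=eps_bv,
        eps_fraction=(eps_bv / total_bv) if total_bv > 0 else None,
        n_slices_analyzed=total.mask.shape[0],
    )
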