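"""Physical and imaging configuration for a stirred biofilm reactor.

A :class:`ReactorConfig` carries the constants of the number balances
(bulk volume ``V``, influent flow ``Q``, colonizable biofilm area ``A``)
together with the confocal voxel geometry (in-plane pixel size, z interval,
frame dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

#: Default frame side in micrometres (confocal field of view).
DEFAULT_FRAME_UM = 212.5
#: Default frame side in pixels.
DEFAULT_FRAME_PX = 1024
#: Default z interval between slices, micrometres.
DEFAULT_SLICE_UM = 1.0

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class ReactorConfig:
    """Physical constants of one annular reactor and its imaging geometry.

    Parameters
    ----------
    volume_ml
        Bulk water volume V (mL). The default 1008 mL is back-derived as
        Q x HRT = 2.1 mL/min x 480 min for an 8 h residence time.
    flow_ml_min
        Influent flow Q (mL/min).
    biofilm_area_cm2
        Colonizable biofilm area A (cm^2) used to scale areal biofilm
        counts to whole-reactor cell numbers.
    pixel_um, slice_um
        Voxel geometry of the confocal stacks (µm per pixel in-plane and
        per z step).
    frame_um, frame_px
        Field-of-view side length in micrometres and pixels; must agree
        with ``pixel_um`` to within 0.1 %.
    """

    volume_ml: float = 1008.0
    flow_ml_min: float = 2.1
    biofilm_area_cm2: float = 190.0
    frame_um: float = DEFAULT_FRAME_UM
    frame_px: int = DEFAULT_FRAME_PX
    pixel_um: float = field(default=DEFAULT_FRAME_UM / DEFAULT_FRAME_PX)
    slice_um: float = DEFAULT_SLICE_UM

    def __post_init__(self) -> None:
        for name in ("volume_ml", "flow_ml_min", "biofilm_area_cm2",
                     "frame_um", "frame_px", "pixel_um", "slice_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        expected = self.frame_px * self.pixel_um
        if abs(expected - self.frame_um) > 1e-3 * self.frame_um:
            raise ParameterError(
                "frame_px * pixel_um = %.4f µm disagrees with frame_um = "
                "%.4f µm by more than 0.1%%" % (expected, self.frame_um)
            )

    @property
    def flow_ml_day(self) -> float:
        """Influent flow in mL/day (Q x 1440)."""
        return self.flow_ml_min * MINUTES_PER_DAY

    @property
    def hrt_hours(self) -> float:
        """Mean hydraulic residence time V/Q in hours."""
        return self.volume_ml / self.flow_ml_min / 60.0
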