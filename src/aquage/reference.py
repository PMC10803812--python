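"""Reference operating constants and phase-average water quality.

Phase-level summary concentrations and reactor operating constants for
the chloraminated annular-reactor water-age experiment that this package
models. Cell counts and ATP are geometric means over each phase
(Phase I: typical building occupancy; Phase II: reduced occupancy and
elevated influent water age); biofilm values are final concentrations per
coupon area. These serve as worked-example inputs for the derived-metric
and number-balance routines.
"""

from __future__ import annotations

#: Phase-average bulk summaries. Units: chlorine mg/L, counts cells/mL,
#: ATP nM, temperature degC.
PHASE_SUMMARY = {
    ("tap_reservoir", "I"): dict(
        chlorine=1.5, tcc=5.3e3, icc=9.9e2, atpt=1.0e-3, atpi=4.6e-4,
        temperature=22.6, ph=7.78,
    ),
    ("tap_reservoir", "II"): dict(
        chlorine=0.74, tcc=1.2e4, icc=2.5e3, atpt=4.6e-3, atpi=7.9e-4,
        temperature=23.7, ph=7.69,
    ),
    ("reactor_bulk", "I"): dict(
        chlorine=0.62, tcc=3.9e4, icc=2.2e4, atpt=1.1e-2, atpi=7.5e-3,
        temperature=22.4, ph=8.85,
    ),
    ("reactor_bulk", "II"): dict(
        chlorine=0.11, tcc=1.9e5, icc=1.3e5, atpt=4.4e-2, atpi=3.8e-2,
        temperature=23.5, ph=8.78,
    ),
}

#: Final biofilm concentrations per phase. Units: counts cells/cm^2,
#: ATP nmol/cm^2.
BIOFILM_SUMMARY = {
    "I": dict(tcc_area=3.2e5, icc_area=5.6e4, atpt_area=6.1e-5,
              atpi_area=1.6e-5),
    "II": dict(tcc_area=1.3e6, icc_area=5.6e5, atpt_area=4.9e-4,
               atpi_area=1.8e-4),
}

#: Storage reservoir between the tap and the reactors.
RESERVOIR_VOLUME_ML = 10_000.0
RESERVOIR_FLOW_ML_MIN = 150.0

#: Reactor influent flow (peristaltic pump average) and nominal HRT.
REACTOR_FLOW_ML_MIN = 2.1
REACTOR_HRT_HOURS = 8.0

#: Confocal imaging frame and replication guidance.
FRAME_UM = 212.5
FRAME_PX = 1024
Z_INTERVAL_UM = 1.0
MIN_FRAMES_PER_SLIDE = 5
#: Minimum total imaged area recommended for representative biofilm sampling.
MIN_TOTAL_IMAGED_AREA_UM2 = 2.25e5
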