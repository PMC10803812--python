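"""Intact-cell-count number balances for a stirred reactor.

The reactor is modelled as a continuously stirred tank (CSTR) with bulk
water volume V (mL), influent flow Q (mL/day) drawn from a tap reservoir
at concentration C_tap (cells/mL), bulk concentration C_AR, and a wall
biofilm pool C_BF (cells/cm^2) on colonizable area A (cm^2). Growth and
decay of cells in the bulk and net transfer of cells between biofilm and
bulk cannot be separated from count data alone, so they are lumped into a
single source term, the Net Growth/Transfer Rate (NGTR, cells/day):

    dN/dt = (dN/dt)_bulk + (dN/dt)_biofilm = tap_in - out + NGTR

Two estimators solve this balance for NGTR from intact cell counts (ICC):

* **NSS** (non-steady state): between two biofilm sampling days t1 < t2,
  accumulation is the change in total reactor cells
  Delta[C_AR*V + C_BF*A] / (t2 - t1), and the advective terms use the
  average of all bulk sampling events in the window, so
  NGTR = dN/dt - Q*(mean C_tap - mean C_AR).
* **ISS** (instantaneous steady state): at a single sampling event,
  accumulation is assumed zero, giving NGTR = (C_AR - C_tap) * Q without
  any biofilm measurement.

Negative NGTR (net decay, e.g. during high chlorine) is reported as-is;
only the tap-input/NGTR ratio is flagged undefined when NGTR <= 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

from .config import ReactorConfig
from .errors import InsufficientDataError, OutOfRangeError
from .water_metrics import BiofilmSample, WaterSample

__all__ = [
    "NgtrEstimate",
    "ngtr_instantaneous",
    "interval_average",
    "ngtr_nonsteady",
    "tap_to_ngtr_ratio",
    "balance_series",
]

logger = logging.getLogger("aquage.number_balance")

#: Default source label for the tap reservoir feeding the reactors.
TAP_SOURCE = "tapres"

#: Biofilm coupons are pulled within 72 h of the bulk sample; a bulk event
#: within this many days may stand in for the concentration at a biofilm day.
DEFAULT_MATCH_TOLERANCE_DAYS = 3.0


@dataclass
class NgtrEstimate:
    """One solved number balance.

    ``method`` is ``"ISS"`` or ``"NSS"``. Rates are cells/day.
    ``accumulation`` is the storage term dN/dt (NSS only).
    ``ratio_tap_to_ngtr`` is tap_input/ngtr, or ``None`` when NGTR <= 0
    (net decay: the ratio is not meaningful).
    """

    method: str
    t2: float
    ngtr: float
    tap_input: float
    effluent_output: float
    t1: Optional[float] = None
    accumulation: Optional[float] = None
    ratio_tap_to_ngtr: Optional[float] = None
    reactor: Optional[str] = None

    def residual(self) -> float:
        """Balance residual dN/dt - (tap_in - out + NGTR); 0 by construction."""
        acc = self.accumulation if self.accumulation is not None else 0.0
        return acc - (self.tap_input - self.effluent_output + self.ngtr)


def _ratio_or_none(tap_input: float, ngtr: float) -> Optional[float]:
    return tap_input / ngtr if ngtr > 0 else None


def ngtr_instantaneous(
    c_tap: float,
    c_ar: float,
    config: ReactorConfig,
    *,
    day: float = 0.0,
    reactor: Optional[str] = None,
) -> NgtrEstimate:
    """ISS estimate from one paired tap/reactor sampling event.

    0 = C_tap*Q - C_AR*Q + NGTR, so NGTR = (C_AR - C_tap) * Q with Q in
    mL/day. Negative results indicate net decay and are kept.
    """
    if c_tap < 0 or c_ar < 0:
        raise OutOfRangeError("concentrations must be >= 0")
    q_day = config.flow_ml_day
    tap_input = c_tap * q_day
    effluent = c_ar * q_day
    ngtr = effluent - tap_input
    return NgtrEstimate(
        method="ISS",
        t2=day,
        ngtr=ngtr,
        tap_input=tap_input,
        effluent_output=effluent,
        ratio_tap_to_ngtr=_ratio_or_none(tap_input, ngtr),
        reactor=reactor,
    )


def interval_average(
    series: Sequence[WaterSample], t1: float, t2: float, field: str = "icc"
) -> float:
    """Arithmetic mean of ``field`` over events in the half-open window (t1, t2]."""
    if not t1 < t2:
        raise OutOfRangeError("need t1 < t2")
    values = [
        getattr(s, field)
        for s in series
        if t1 < s.day <= t2 and getattr(s, field) is not None
    ]
    if not values:
        raise InsufficientDataError(
            f"no events with {field!r} in window ({t1}, {t2}]"
        )
    return sum(values) / len(values)


def _nearest_event(
    series: Sequence[WaterSample], day: float, tolerance: float, field: str
) -> WaterSample:
    candidates = [s for s in series if getattr(s, field) is not None]
    if not candidates:
        raise InsufficientDataError(f"no events carry {field!r}")
    best = min(candidates, key=lambda s: abs(s.day - day))
    if abs(best.day - day) > tolerance:
        raise InsufficientDataError(
            f"nearest bulk event to day {day} is {abs(best.day - day):.2f} d "
            f"away (> {tolerance} d tolerance)"
        )
    return best


def ngtr_nonsteady(
    bulk: Sequence[WaterSample],
    biofilm_t1: BiofilmSample,
    biofilm_t2: BiofilmSample,
    config: ReactorConfig,
    *,
    tap_source: str = TAP_SOURCE,
    match_tolerance_days: float = DEFAULT_MATCH_TOLERANCE_DAYS,
    storage_concentration: str = "nearest",
) -> NgtrEstimate:
    """NSS estimate between two consecutive biofilm sampling events.

    ``bulk`` is the combined bulk series; tap-reservoir events are those
    with ``source == tap_source`` and reactor events those with
    ``source == biofilm_t1.reactor``. The storage term uses the bulk
    concentration at t1/t2 from the nearest reactor event within
    ``match_tolerance_days`` (``storage_concentration="nearest"``), or the
    window-mean bulk concentration (``"window_mean"``).
    """
    if biofilm_t1.reactor != biofilm_t2.reactor:
        raise OutOfRangeError("biofilm samples must come from the same reactor")
    t1, t2 = biofilm_t1.day, biofilm_t2.day
    if not t1 < t2:
        raise OutOfRangeError("need biofilm_t1.day < biofilm_t2.day")
    if biofilm_t1.icc_area is None or biofilm_t2.icc_area is None:
        raise InsufficientDataError("biofilm events lack icc_area")
    if storage_concentration not in ("nearest", "window_mean"):
        raise OutOfRangeError(
            "storage_concentration must be 'nearest' or 'window_mean'"
        )

    tap_series = [s for s in bulk if s.source == tap_source]
    ar_series = [s for s in bulk if s.source == biofilm_t1.reactor]

    mean_tap = interval_average(tap_series, t1, t2, "icc")
    mean_ar = interval_average(ar_series, t1, t2, "icc")

    if storage_concentration == "nearest":
        c_ar_t1 = _nearest_event(ar_series, t1, match_tolerance_days, "icc").icc
        c_ar_t2 = _nearest_event(ar_series, t2, match_tolerance_days, "icc").icc
    else:
        c_ar_t1 = c_ar_t2 = mean_ar

    v = config.volume_ml
    a = config.biofilm_area_cm2
    q_day = config.flow_ml_day

    n_t1 = c_ar_t1 * v + biofilm_t1.icc_area * a
    n_t2 = c_ar_t2 * v + biofilm_t2.icc_area * a
    accumulation = (n_t2 - n_t1) / (t2 - t1)

    tap_input = mean_tap * q_day
    effluent = mean_ar * q_day
    ngtr = accumulation - tap_input + effluent
    return NgtrEstimate(
        method="NSS",
        t1=t1,
        t2=t2,
        ngtr=ngtr,
        tap_input=tap_input,
        effluent_output=effluent,
        accumulation=accumulation,
        ratio_tap_to_ngtr=_ratio_or_none(tap_input, ngtr),
        reactor=biofilm_t1.reactor,
    )


def tap_to_ngtr_ratio(est: NgtrEstimate) -> Optional[float]:
    """Ratio of tap cell input to NGTR; ``None`` when NGTR <= 0."""
    return _ratio_or_none(est.tap_input, est.ngtr)


def balance_series(
    bulk: Sequence[WaterSample],
    biofilm: Sequence[BiofilmSample],
    config: ReactorConfig,
    *,
    tap_source: str = TAP_SOURCE,
    iss_pair_tolerance_days: float = 1.0,
    match_tolerance_days: float = DEFAULT_MATCH_TOLERANCE_DAYS,
    storage_concentration: str = "nearest",
) -> List[NgtrEstimate]:
    """Apply both balances across full monitoring series.

    One ISS estimate per reactor bulk event that has a tap-reservoir event
    within ``iss_pair_tolerance_days`` (unpaired events are skipped with a
    warning); one NSS estimate per consecutive same-reactor biofilm pair.
    Results are ordered NSS-then-ISS by (reactor, day).
    """
    tap_series = sorted(
        (s for s in bulk if s.source == tap_source and s.icc is not None),
        key=lambda s: s.day,
    )
    estimates: List[NgtrEstimate] = []

    bf_by_reactor: dict = {}
    for b in sorted(biofilm, key=lambda b: (b.reactor, b.day)):
        bf_by_reactor.setdefault(b.reactor, []).append(b)
    for reactor, events in sorted(bf_by_reactor.items()):
        for first, second in zip(events, events[1:]):
            try:
                estimates.append(
                    ngtr_nonsteady(
                        bulk,
                        first,
                        second,
                        config,
                        tap_source=tap_source,
                        match_tolerance_days=match_tolerance_days,
                        storage_concentration=storage_concentration,
                    )
                )
            except InsufficientDataError as exc:
                logger.warning(
                    "skipping NSS window (%s, %s] for %s: %s",
                    first.day, second.day, reactor, exc,
                )

    ar_events = sorted(
        (s for s in bulk if s.source != tap_source and s.icc is not None),
        key=lambda s: (s.source, s.day),
    )
    for s in ar_events:
        if not tap_series:
            logger.warning("no tap events; skipping ISS on day %s", s.day)
            continue
        tap = min(tap_series, key=lambda t: abs(t.day - s.day))
        if abs(tap.day - s.day) > iss_pair_tolerance_days:
            logger.warning(
                "no tap event within %.1f d of %s day %s; skipping ISS",
                iss_pair_tolerance_days, s.source, s.day,
            )
            continue
        estimates.append(
            ngtr_instantaneous(
                tap.icc, s.icc, config, day=s.day, reactor=s.source
            )
        )
    return estimates
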