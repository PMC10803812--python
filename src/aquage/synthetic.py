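"""Synthetic reactor series and confocal stacks with exact ground truth.

Two generators make every pipeline stage testable without laboratory data:

* :func:`simulate_reactor_series` forward-integrates the CSTR cell number
  balance — V dC/dt = Q (C_tap - C) + NGTR(t) - B(t), with B(t) the rate
  at which cells accumulate in the wall biofilm pool — and samples the
  trajectory with multiplicative lognormal measurement noise, the noise
  model matching the geometric-mean reporting convention of cytometry
  series. The truth record keeps the exact state trajectory and the
  cumulative net influx, so estimator recovery and number conservation
  can be checked against it.
* :func:`simulate_zstack` rasterizes hemispherical (optionally hollow)
  biofilm clusters into a three-channel voxel grid. A tunable fraction of
  cluster voxels is EPS-only (protein/polysaccharide channels); the
  remainder are compact cell colonies carrying the nucleic-acid channel.
  Background is sparse shot noise (isolated bright pixels with Gaussian
  amplitude) of the kind in-plane median filtering removes; an optional
  substrate staining artifact plants contiguous patches confined to the
  first four slices. Truth stores the exact voxel masks.

Defaults echo the study scale this package targets: Q = 2.1 mL/min,
V = 1008 mL, tap ICC ~1e3 cells/mL, reactor ICC ~1e4-1e5 cells/mL,
1024 px frames of 212.5 µm at 1 µm z steps.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import DEFAULT_FRAME_PX, DEFAULT_FRAME_UM, ReactorConfig
from .errors import OutOfRangeError, SimulationError
from .water_metrics import BiofilmSample, WaterSample

__all__ = [
    "Profile",
    "piecewise_constant",
    "SeriesScenario",
    "SeriesTruth",
    "SimulatedSeries",
    "simulate_reactor_series",
    "Cluster",
    "StackScenario",
    "StackTruth",
    "SimulatedStack",
    "simulate_zstack",
    "make_fixture_suite",
]

Profile = Union[float, Callable[[float], float]]


def _as_profile(p: Profile) -> Callable[[float], float]:
    if callable(p):
        return p
    value = float(p)
    return lambda _day: value


def piecewise_constant(
    breaks: Sequence[float], values: Sequence[float]
) -> Callable[[float], float]:
    """Left-closed piecewise-constant profile.

    ``values[i]`` applies on ``[breaks[i], breaks[i+1])``; days before
    ``breaks[0]`` take ``values[0]`` and days past the last break keep the
    final value.
    """
    if len(breaks) != len(values) or not breaks:
        raise OutOfRangeError("breaks and values must have equal nonzero length")
    b = np.asarray(breaks, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.any(np.diff(b) <= 0):
        raise OutOfRangeError("breaks must be strictly increasing")

    def profile(day: float) -> float:
        idx = int(np.searchsorted(b, day, side="right")) - 1
        return float(v[max(idx, 0)])

    return profile


# --------------------------------------------------------------------------
# Reactor time series
# --------------------------------------------------------------------------

@dataclass
class SeriesScenario:
    """Forward-model scenario for one reactor and its tap reservoir.

    Profiles may be constants or callables of elapsed day. ``noise_gcv``
    is the geometric CV of the multiplicative lognormal measurement noise
    applied to every sampled quantity (0.1 is typical of triplicate
    cytometry/ATP monitoring). ``initial_car=None`` starts the bulk at the
    steady state of the day-0 forcing. The seed fully determines output.
    """

    config: ReactorConfig = field(default_factory=ReactorConfig)
    duration_days: float = 30.0
    sample_interval_days: float = 1.0
    tap_profile: Profile = 1.0e3
    ngtr_profile: Profile = 5.0e7
    biofilm_accum_profile: Profile = 2.0e6
    noise_gcv: float = 0.1
    seed: int = 0
    initial_car: Optional[float] = None
    initial_nbf: float = 0.0
    rk_substeps: int = 100
    reactor: str = "AR1"
    tap_source: str = "tapres"
    phase_change_day: Optional[float] = None
    biofilm_sample_days: Optional[Sequence[float]] = None
    # realism factors for the secondary measured quantities
    tcc_over_icc: float = 1.8
    biofilm_tcc_over_icc: float = 3.3
    atpi_per_cell_nmol: float = 3.4e-10
    atpi_over_atpt: float = 0.7


@dataclass
class SeriesTruth:
    """Exact (noise-free) state at the sampling times.

    ``net_influx`` is the cumulative integral of Q*C_tap - Q*C_AR + NGTR,
    integrated with the same RK4 scheme as the state, so number
    conservation V*(C-C0) + (Nbf-Nbf0) = net_influx holds to rounding.
    """

    times: np.ndarray
    c_ar: np.ndarray
    n_bf: np.ndarray
    net_influx: np.ndarray
    scenario: SeriesScenario

    def mean_ngtr(self, t1: float, t2: float) -> float:
        """Time-averaged true NGTR on (t1, t2) by midpoint quadrature."""
        ngtr = _as_profile(self.scenario.ngtr_profile)
        h = self.scenario.sample_interval_days / self.scenario.rk_substeps
        n = max(int(round((t2 - t1) / h)), 1)
        mids = t1 + (np.arange(n) + 0.5) * (t2 - t1) / n
        return float(np.mean([ngtr(t) for t in mids]))


@dataclass
class SimulatedSeries:
    bulk: List[WaterSample]
    biofilm: List[BiofilmSample]
    truth: SeriesTruth


def _rk4_path(scn: SeriesScenario) -> SeriesTruth:
    cfg = scn.config
    v, q = cfg.volume_ml, cfg.flow_ml_day
    tap = _as_profile(scn.tap_profile)
    ngtr = _as_profile(scn.ngtr_profile)
    bf = _as_profile(scn.biofilm_accum_profile)

    n_samples = int(round(scn.duration_days / scn.sample_interval_days))
    h = scn.sample_interval_days / scn.rk_substeps

    if scn.initial_car is None:
        c = tap(0.0) + (ngtr(0.0) - bf(0.0)) / q
        if c < 0:
            raise SimulationError(
                "steady-state initial bulk concentration is negative; "
                "supply initial_car explicitly"
            )
    else:
        c = float(scn.initial_car)
    nbf = float(scn.initial_nbf)
    j = 0.0

    def deriv(t: float, state: Tuple[float, float, float]):
        c_, _, _ = state
        flux = q * (tap(t) - c_) + ngtr(t)
        return (
            (flux - bf(t)) / v,   # dC/dt
            bf(t),                # dN_bf/dt
            flux,                 # d(net influx)/dt
        )

    times = [0.0]
    cs, nbfs, js = [c], [nbf], [j]
    t = 0.0
    for i in range(n_samples):
        for _ in range(scn.rk_substeps):
            y = (c, nbf, j)
            k1 = deriv(t, y)
            k2 = deriv(t + h / 2, tuple(y[m] + h / 2 * k1[m] for m in range(3)))
            k3 = deriv(t + h / 2, tuple(y[m] + h / 2 * k2[m] for m in range(3)))
            k4 = deriv(t + h, tuple(y[m] + h * k3[m] for m in range(3)))
            c, nbf, j = (
                y[m] + h / 6 * (k1[m] + 2 * k2[m] + 2 * k3[m] + k4[m])
                for m in range(3)
            )
            t += h
            if c < 0:
                raise SimulationError(
                    f"bulk concentration driven negative at day {t:.3f}; "
                    "scenario infeasible"
                )
        t = (i + 1) * scn.sample_interval_days  # avoid drift
        times.append(t)
        cs.append(c)
        nbfs.append(nbf)
        js.append(j)

    return SeriesTruth(
        times=np.array(times),
        c_ar=np.array(cs),
        n_bf=np.array(nbfs),
        net_influx=np.array(js),
        scenario=scn,
    )


def simulate_reactor_series(scn: SeriesScenario) -> SimulatedSeries:
    """Integrate the scenario and emit noisy sampled series plus truth.

    Bulk output contains one tap-reservoir and one reactor event per
    sampling time; biofilm output covers ``biofilm_sample_days`` (default:
    every sampling time) with areal concentrations N_bf/A.
    """
    truth = _rk4_path(scn)
    cfg = scn.config
    tap = _as_profile(scn.tap_profile)
    sigma = float(np.log1p(scn.noise_gcv))
    rng = np.random.default_rng([scn.seed % (2**31), 101])

    def jitter(value: float) -> float:
        if sigma == 0 or value == 0:
            return value
        return value * float(np.exp(rng.normal(0.0, sigma)))

    def phase(day: float) -> Optional[str]:
        if scn.phase_change_day is None:
            return None
        return "I" if day < scn.phase_change_day else "II"

    bulk: List[WaterSample] = []
    for day, c in zip(truth.times, truth.c_ar):
        for source, icc_true in ((scn.tap_source, tap(day)), (scn.reactor, c)):
            icc = jitter(icc_true)
            tcc = max(jitter(icc_true * scn.tcc_over_icc), icc)
            atpi = jitter(icc * 1000.0 * scn.atpi_per_cell_nmol)
            atpt = max(jitter(atpi / scn.atpi_over_atpt), atpi)
            bulk.append(
                WaterSample(
                    day=float(day), source=source, phase=phase(day),
                    tcc=tcc, icc=icc, atpt=atpt, atpi=atpi,
                )
            )

    if scn.biofilm_sample_days is None:
        bf_days = truth.times
    else:
        bf_days = np.asarray(sorted(scn.biofilm_sample_days), dtype=float)
    biofilm: List[BiofilmSample] = []
    for day in bf_days:
        idx = int(np.argmin(np.abs(truth.times - day)))
        icc_area = jitter(truth.n_bf[idx] / cfg.biofilm_area_cm2)
        biofilm.append(
            BiofilmSample(
                day=float(truth.times[idx]),
                reactor=scn.reactor,
                icc_area=icc_area,
                tcc_area=max(jitter(icc_area * scn.biofilm_tcc_over_icc),
                             icc_area),
            )
        )
    return SimulatedSeries(bulk=bulk, biofilm=biofilm, truth=truth)


# --------------------------------------------------------------------------
# Confocal z-stacks
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    """One biofilm cluster: a hemisphere (or hollow shell) seated on z=0.

    ``intensity`` is the (syto9, sypro, cona) 8-bit foreground triple;
    cell voxels carry the SYTO9 intensity, EPS voxels the Sypro/ConA
    intensities.
    """

    center_um: Tuple[float, float]
    radius_um: float
    shape: str = "hemisphere"
    intensity: Tuple[int, int, int] = (200, 180, 160)
    shell_thickness_um: float = 2.0

    def __post_init__(self) -> None:
        if self.shape not in ("hemisphere", "hollow_shell"):
            raise OutOfRangeError(f"unknown cluster shape {self.shape!r}")
        if self.radius_um <= 0:
            raise OutOfRangeError("radius_um must be positive")
        if any(not 0 < i <= 255 for i in self.intensity):
            raise OutOfRangeError("intensities must be in 1..255")


@dataclass
class StackScenario:
    """Scenario for one synthetic three-channel stack.

    ``eps_voxel_fraction`` is the target fraction of cluster voxels that
    are EPS-only; the complement is packed into compact spherical cell
    colonies (radius ``cell_blob_radius_um``) so the nucleic-acid signal
    survives median filtering. Background is shot noise: a fraction
    ``background_density`` of voxels per channel receive an amplitude
    drawn from N(background_mean, background_sd) clipped to 1..255.
    ``base_artifact`` plants 3x3-pixel patches totalling
    ``base_artifact_coverage`` of the frame in slices 0-3 of every
    channel, emulating dye bound to the bare substrate.
    """

    frame_px: int = DEFAULT_FRAME_PX
    n_slices: int = 30
    pixel_um: float = DEFAULT_FRAME_UM / DEFAULT_FRAME_PX
    slice_um: float = 1.0
    clusters: Tuple[Cluster, ...] = ()
    eps_voxel_fraction: float = 0.92
    cell_blob_radius_um: float = 2.5
    background_mean: float = 40.0
    background_sd: float = 10.0
    background_density: float = 0.02
    base_artifact: bool = False
    base_artifact_coverage: float = 0.02
    base_artifact_intensity: int = 170
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.eps_voxel_fraction <= 1:
            raise OutOfRangeError("eps_voxel_fraction must be in [0, 1]")
        for c in self.clusters:
            cx, cy = c.center_um
            side = self.frame_px * self.pixel_um
            if not (0 <= cx <= side and 0 <= cy <= side):
                raise OutOfRangeError("cluster center outside the frame")


@dataclass
class StackTruth:
    """Exact voxel-level ground truth of a synthetic stack.

    Masks are (z, y, x) booleans of cluster voxels only (background noise
    and the base artifact are excluded by definition). ``metrics`` reports
    the truth on the analyzed sub-stack after base-slice removal, for
    direct comparison with pipeline output.
    """

    mask_total: np.ndarray
    mask_eps: np.ndarray
    pixel_um: float
    slice_um: float
    eps_fraction_actual: Optional[float]

    def per_slice_areas(self, base_slices: int = 0) -> np.ndarray:
        counts = self.mask_total[base_slices:].sum(axis=(1, 2))
        return counts * self.pixel_um**2

    def metrics(self, base_slices: int = 4) -> dict:
        total = self.mask_total[base_slices:]
        eps = self.mask_eps[base_slices:]
        areas = total.sum(axis=(1, 2)) * self.pixel_um**2
        max_area = float(areas.max()) if areas.size else 0.0
        frame = total.shape[1] * total.shape[2] * self.pixel_um**2
        total_bv = float(areas.sum() * self.slice_um)
        eps_bv = float(eps.sum() * self.pixel_um**2 * self.slice_um)
        return {
            "area_coverage": max_area / frame,
            "max_area_um2": max_area,
            "mbh_um": float(np.count_nonzero(total.any(axis=(1, 2)))
                            * self.slice_um),
            "biovolume_um3": total_bv,
            "eps_biovolume_um3": eps_bv,
            "eps_fraction": (eps_bv / total_bv) if total_bv > 0 else None,
            "n_slices_analyzed": int(total.shape[0]),
        }


@dataclass
class SimulatedStack:
    data: np.ndarray  # (3, z, y, x) uint8
    pixel_um: float
    slice_um: float
    truth: StackTruth


def _rasterize_cluster(
    cluster: Cluster, shape: Tuple[int, int, int], pixel_um: float, slice_um: float
) -> np.ndarray:
    nz, ny, nx = shape
    cx, cy = cluster.center_um
    r = cluster.radius_um
    x = (np.arange(nx) + 0.5) * pixel_um - cx
    y = (np.arange(ny) + 0.5) * pixel_um - cy
    z = (np.arange(nz) + 0.5) * slice_um
    d2 = (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    inside = d2 <= r**2
    if cluster.shape == "hollow_shell":
        inner = max(r - cluster.shell_thickness_um, 0.0)
        inside &= d2 >= inner**2
    return inside


def _pack_cell_blobs(
    mask_total: np.ndarray,
    target_cell_voxels: int,
    blob_radius_um: float,
    pixel_um: float,
    slice_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Compact spherical cell colonies inside the cluster mask."""
    cells = np.zeros_like(mask_total)
    if target_cell_voxels <= 0:
        return cells
    occupied = np.argwhere(mask_total)
    rz = max(int(np.ceil(blob_radius_um / slice_um)), 1)
    ry = rx = max(int(np.ceil(blob_radius_um / pixel_um)), 1)
    zz, yy, xx = np.ogrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    ball = (
        (zz * slice_um) ** 2 + (yy * pixel_um) ** 2 + (xx * pixel_um) ** 2
    ) <= blob_radius_um**2
    nz, ny, nx = mask_total.shape
    for _ in range(10_000):
        if cells.sum() >= target_cell_voxels:
            break
        cz, cy, cx = occupied[rng.integers(len(occupied))]
        z0, z1 = max(cz - rz, 0), min(cz + rz + 1, nz)
        y0, y1 = max(cy - ry, 0), min(cy + ry + 1, ny)
        x0, x1 = max(cx - rx, 0), min(cx + rx + 1, nx)
        bz0, by0, bx0 = z0 - (cz - rz), y0 - (cy - ry), x0 - (cx - rx)
        sub = ball[bz0:bz0 + (z1 - z0), by0:by0 + (y1 - y0),
                   bx0:bx0 + (x1 - x0)]
        cells[z0:z1, y0:y1, x0:x1] |= sub & mask_total[z0:z1, y0:y1, x0:x1]
    return cells


def simulate_zstack(scn: StackScenario) -> SimulatedStack:
    """Rasterize the scenario into a (3, z, y, x) uint8 stack + truth."""
    shape = (scn.n_slices, scn.frame_px, scn.frame_px)
    seed = scn.seed % (2**31)
    rng_cells = np.random.default_rng([seed, 11])
    rng_bg = np.random.default_rng([seed, 13])
    rng_art = np.random.default_rng([seed, 17])

    data = np.zeros((3,) + shape, dtype=np.uint8)
    mask_total = np.zeros(shape, dtype=bool)
    mask_eps = np.zeros(shape, dtype=bool)

    for cluster in scn.clusters:
        cmask = _rasterize_cluster(cluster, shape, scn.pixel_um, scn.slice_um)
        cmask_new = cmask & ~mask_total  # union semantics for overlaps
        n_voxels = int(cmask_new.sum())
        if n_voxels == 0:
            continue
        target_cells = int(round((1.0 - scn.eps_voxel_fraction) * n_voxels))
        cells = _pack_cell_blobs(
            cmask_new, target_cells, scn.cell_blob_radius_um,
            scn.pixel_um, scn.slice_um, rng_cells,
        )
        eps = cmask_new & ~cells
        i_syto, i_sypro, i_cona = cluster.intensity
        data[0][cells] = i_syto
        data[1][eps] = i_sypro
        data[2][eps] = i_cona
        mask_total |= cmask_new
        mask_eps |= eps

    if scn.background_density > 0 and scn.background_sd >= 0:
        for c in range(3):
            hit = rng_bg.random(shape) < scn.background_density
            amp = np.clip(
                rng_bg.normal(scn.background_mean, scn.background_sd,
                              int(hit.sum())),
                1, 255,
            ).astype(np.uint8)
            channel = data[c]
            channel[hit] = np.maximum(channel[hit], amp)

    if scn.base_artifact:
        n_base = min(4, scn.n_slices)
        patches = max(
            int(np.ceil(scn.base_artifact_coverage * scn.frame_px**2 / 9)), 1
        )
        for z in range(n_base):
            ys = rng_art.integers(0, max(scn.frame_px - 3, 1), patches)
            xs = rng_art.integers(0, max(scn.frame_px - 3, 1), patches)
            for y0, x0 in zip(ys, xs):
                for c in range(3):
                    patch = data[c, z, y0:y0 + 3, x0:x0 + 3]
                    np.maximum(
                        patch, scn.base_artifact_intensity, out=patch
                    )

    n_total = int(mask_total.sum())
    truth = StackTruth(
        mask_total=mask_total,
        mask_eps=mask_eps,
        pixel_um=scn.pixel_um,
        slice_um=scn.slice_um,
        eps_fraction_actual=(mask_eps.sum() / n_total) if n_total else None,
    )
    return SimulatedStack(
        data=data, pixel_um=scn.pixel_um, slice_um=scn.slice_um, truth=truth
    )


# --------------------------------------------------------------------------
# Canonical fixture suite
# --------------------------------------------------------------------------

def canonical_series_scenarios(seed: int) -> dict:
    """The three canonical reactor scenarios: steady, step, decay."""
    return {
        "steady": SeriesScenario(
            duration_days=10.0, sample_interval_days=0.25,
            ngtr_profile=5.0e7, biofilm_accum_profile=2.0e6,
            noise_gcv=0.1, seed=seed,
        ),
        "step_ngtr": SeriesScenario(
            duration_days=10.0, sample_interval_days=0.25,
            ngtr_profile=piecewise_constant([0.0, 5.0], [5.0e7, 5.0e8]),
            biofilm_accum_profile=0.0, noise_gcv=0.1,
            phase_change_day=5.0, seed=seed + 1,
        ),
        "decay": SeriesScenario(
            duration_days=5.0, sample_interval_days=0.25,
            ngtr_profile=-2.0e6, biofilm_accum_profile=0.0,
            initial_car=5.0e3, initial_nbf=1.0e7,
            noise_gcv=0.1, seed=seed + 2,
        ),
    }


def canonical_stack_scenarios(seed: int) -> dict:
    """The four canonical stack scenarios on a small test-scale frame."""
    common = dict(frame_px=128, n_slices=26, pixel_um=1.0, slice_um=1.0)
    return {
        "blank": StackScenario(
            clusters=(), background_density=0.01, seed=seed, **common
        ),
        "single_cluster": StackScenario(
            clusters=(Cluster(center_um=(64.0, 64.0), radius_um=18.0),),
            seed=seed + 1, **common,
        ),
        "hollow_cluster": StackScenario(
            clusters=(
                Cluster(center_um=(64.0, 64.0), radius_um=20.0,
                        shape="hollow_shell", shell_thickness_um=3.0),
            ),
            seed=seed + 2, **common,
        ),
        "high_coverage": StackScenario(
            clusters=(
                Cluster(center_um=(36.0, 40.0), radius_um=22.0),
                Cluster(center_um=(90.0, 60.0), radius_um=18.0),
                Cluster(center_um=(56.0, 98.0), radius_um=16.0),
            ),
            base_artifact=True, seed=seed + 3, **common,
        ),
    }


def make_fixture_suite(seed: int, outdir: Union[str, Path]) -> Path:
    """Write the canonical fixture set (3 series + 4 stacks) with truth JSON.

    Output is fully determined by ``seed``: series CSVs, stack TIFFs and
    truth JSONs are byte-identical across runs with the same seed.
    """
    from . import io as aio  # deferred to avoid an import cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    for name, scn in canonical_series_scenarios(seed).items():
        d = out / f"series_{name}"
        d.mkdir(exist_ok=True)
        sim = simulate_reactor_series(scn)
        aio.write_bulk_series(sim.bulk, d / "bulk.csv")
        aio.write_biofilm_series(sim.biofilm, d / "biofilm.csv")
        truth = {
            "times": sim.truth.times.tolist(),
            "c_ar": sim.truth.c_ar.tolist(),
            "n_bf": sim.truth.n_bf.tolist(),
            "net_influx": sim.truth.net_influx.tolist(),
            "mean_ngtr_overall": sim.truth.mean_ngtr(
                0.0, scn.duration_days
            ),
            "seed": scn.seed,
        }
        (d / "truth.json").write_text(json.dumps(truth, sort_keys=True))

    for name, scn in canonical_stack_scenarios(seed).items():
        d = out / f"stack_{name}"
        d.mkdir(exist_ok=True)
        sim = simulate_zstack(scn)
        aio.write_zstack_array(
            sim.data, d / "stack.tif"
        )
        truth = {
            "n_cluster_voxels": int(sim.truth.mask_total.sum()),
            "n_eps_voxels": int(sim.truth.mask_eps.sum()),
            "eps_fraction_actual": sim.truth.eps_fraction_actual,
            "metrics_after_base_removal": sim.truth.metrics(4),
            "pixel_um": sim.pixel_um,
            "slice_um": sim.slice_um,
            "seed": scn.seed,
        }
        (d / "truth.json").write_text(json.dumps(truth, sort_keys=True))

    return out
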