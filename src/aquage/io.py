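"""File I/O and run configuration.

CSV interchange is comma-separated UTF-8 with a header row and ``.``
decimals; days are floats; missing measurements are empty fields. Stacks
travel as multi-page TIFF: pages are z-major within channel, channels in
the fixed order (syto9, sypro_orange, cona), or as three single-channel
files in that order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import ReactorConfig
from .errors import FormatError, ParseError, SchemaError
from .imaging import CHANNELS, ZStack
from .water_metrics import BiofilmSample, WaterSample

__all__ = [
    "BULK_COLUMNS",
    "BIOFILM_COLUMNS",
    "load_bulk_series",
    "write_bulk_series",
    "load_biofilm_series",
    "write_biofilm_series",
    "load_zstack",
    "write_zstack",
    "write_zstack_array",
    "RunConfig",
    "ImagingOptions",
    "BalanceOptions",
    "PathsConfig",
    "load_run_config",
]

BULK_COLUMNS = [
    "day", "source", "phase", "tcc_cells_ml", "icc_cells_ml",
    "atpt_nM", "atpi_nM", "cl2_total_mg_l", "temp_c", "ph",
]
BIOFILM_COLUMNS = [
    "day", "reactor", "tcc_cells_cm2", "icc_cells_cm2",
    "atpt_nmol_cm2", "atpi_nmol_cm2",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based + header row
        raise ParseError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"{col!r} at line {row}"
        )
    return out


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def load_bulk_series(path: Union[str, Path]) -> List[WaterSample]:
    """Read a bulk-water CSV into typed samples sorted by (source, day).

    An empty chlorine field means "below the limit of detection" and is
    stored as 0 with the ``chlorine_below_lod`` flag, distinct from a
    measured zero.
    """
    df = pd.read_csv(path)
    _require_columns(df, BULK_COLUMNS, path)
    for col in BULK_COLUMNS:
        if col in ("source", "phase"):
            continue
        df[col] = _numeric(df, col, path)
    samples = []
    for _, r in df.iterrows():
        chlorine = _opt(r["cl2_total_mg_l"])
        samples.append(
            WaterSample(
                day=float(r["day"]),
                source=str(r["source"]),
                phase=None if pd.isna(r["phase"]) else str(r["phase"]),
                tcc=_opt(r["tcc_cells_ml"]),
                icc=_opt(r["icc_cells_ml"]),
                atpt=_opt(r["atpt_nM"]),
                atpi=_opt(r["atpi_nM"]),
                chlorine_total=0.0 if chlorine is None else chlorine,
                chlorine_below_lod=chlorine is None,
                temperature=_opt(r["temp_c"]),
                ph=_opt(r["ph"]),
            )
        )
    return sorted(samples, key=lambda s: (s.source, s.day))


def write_bulk_series(
    samples: Sequence[WaterSample], path: Union[str, Path]
) -> None:
    rows = []
    for s in sorted(samples, key=lambda s: (s.source, s.day)):
        rows.append({
            "day": s.day,
            "source": s.source,
            "phase": s.phase,
            "tcc_cells_ml": s.tcc,
            "icc_cells_ml": s.icc,
            "atpt_nM": s.atpt,
            "atpi_nM": s.atpi,
            "cl2_total_mg_l": None if s.chlorine_below_lod else s.chlorine_total,
            "temp_c": s.temperature,
            "ph": s.ph,
        })
    pd.DataFrame(rows, columns=BULK_COLUMNS).to_csv(path, index=False)


def load_biofilm_series(path: Union[str, Path]) -> List[BiofilmSample]:
    """Read a biofilm CSV into typed samples sorted by (reactor, day)."""
    df = pd.read_csv(path)
    _require_columns(df, BIOFILM_COLUMNS, path)
    for col in BIOFILM_COLUMNS:
        if col == "reactor":
            continue
        df[col] = _numeric(df, col, path)
    samples = [
        BiofilmSample(
            day=float(r["day"]),
            reactor=str(r["reactor"]),
            tcc_area=_opt(r["tcc_cells_cm2"]),
            icc_area=_opt(r["icc_cells_cm2"]),
            atpt_area=_opt(r["atpt_nmol_cm2"]),
            atpi_area=_opt(r["atpi_nmol_cm2"]),
        )
        for _, r in df.iterrows()
    ]
    return sorted(samples, key=lambda s: (s.reactor, s.day))


def write_biofilm_series(
    samples: Sequence[BiofilmSample], path: Union[str, Path]
) -> None:
    rows = [
        {
            "day": s.day,
            "reactor": s.reactor,
            "tcc_cells_cm2": s.tcc_area,
            "icc_cells_cm2": s.icc_area,
            "atpt_nmol_cm2": s.atpt_area,
            "atpi_nmol_cm2": s.atpi_area,
        }
        for s in sorted(samples, key=lambda s: (s.reactor, s.day))
    ]
    pd.DataFrame(rows, columns=BIOFILM_COLUMNS).to_csv(path, index=False)


def _read_pages(path) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: cannot read TIFF ({exc})") from exc
    if arr.dtype == object or arr.ndim not in (2, 3, 4):
        raise FormatError(f"{path}: inconsistent page shapes or layout")
    return arr


def load_zstack(
    path: Union[str, Path, Sequence[Union[str, Path]]],
    config: Optional[ReactorConfig] = None,
    *,
    pixel_um: Optional[float] = None,
    slice_um: Optional[float] = None,
) -> ZStack:
    """Load a stack from one multi-channel TIFF or three single-channel TIFFs.

    A single file must hold 3*Z pages (z-major within channel, channel
    order syto9, sypro_orange, cona) or an explicit 4-D (3, z, y, x)
    series. Voxel geometry comes from ``config`` unless overridden.
    """
    cfg = config or ReactorConfig()
    px = pixel_um if pixel_um is not None else cfg.pixel_um
    sz = slice_um if slice_um is not None else cfg.slice_um

    if isinstance(path, (str, Path)):
        arr = _read_pages(path)
        if arr.ndim == 4:
            if arr.shape[0] != 3:
                raise FormatError(
                    f"{path}: expected 3 channels, got {arr.shape[0]}"
                )
            data = arr
        elif arr.ndim == 3:
            if arr.shape[0] % 3 != 0:
                raise FormatError(
                    f"{path}: page count {arr.shape[0]} is not a multiple "
                    "of 3 channels"
                )
            z = arr.shape[0] // 3
            data = arr.reshape(3, z, arr.shape[1], arr.shape[2])
        else:
            raise FormatError(f"{path}: single-page file is not a stack")
    else:
        paths = list(path)
        if len(paths) != 3:
            raise FormatError(
                f"expected 3 single-channel files, got {len(paths)}"
            )
        channels = [_read_pages(p) for p in paths]
        shapes = {c.shape for c in channels}
        if len(shapes) != 1 or channels[0].ndim != 3:
            raise FormatError("single-channel files disagree in shape")
        data = np.stack(channels, axis=0)
    return ZStack(data=data, pixel_um=px, slice_um=sz, channels=CHANNELS)


def write_zstack(stack: ZStack, path: Union[str, Path]) -> None:
    """Write a stack as one multi-page TIFF (pages z-major within channel)."""
    write_zstack_array(stack.data, path)


def write_zstack_array(data: np.ndarray, path: Union[str, Path]) -> None:
    c, z, y, x = data.shape
    tifffile.imwrite(path, np.asarray(data, dtype=np.uint8).reshape(c * z, y, x))


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class ImagingOptions:
    kernel: int = 3
    base_slices: int = 4


@dataclass
class BalanceOptions:
    tap_source: str = "tapres"
    match_tolerance_days: float = 3.0
    iss_pair_tolerance_days: float = 1.0
    storage_concentration: str = "nearest"


@dataclass
class PathsConfig:
    bulk_csv: Optional[str] = None
    biofilm_csv: Optional[str] = None
    stacks: List[str] = field(default_factory=list)
    out_dir: str = "aquage_out"


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown YAML keys are rejected."""

    reactor: ReactorConfig = field(default_factory=ReactorConfig)
    imaging: ImagingOptions = field(default_factory=ImagingOptions)
    balance: BalanceOptions = field(default_factory=BalanceOptions)
    paths: PathsConfig = field(default_factory=PathsConfig)
    seed: int = 0


def _build(cls, mapping, where):
    if mapping is None:
        return cls()
    if not isinstance(mapping, dict):
        raise SchemaError(f"{where}: expected a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"{where}: unknown key(s) {sorted(unknown)}")
    return cls(**mapping)


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    allowed = {"reactor", "imaging", "balance", "paths", "seed"}
    unknown = set(raw) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown key(s) {sorted(unknown)}")
    return RunConfig(
        reactor=_build(ReactorConfig, raw.get("reactor"), "reactor"),
        imaging=_build(ImagingOptions, raw.get("imaging"), "imaging"),
        balance=_build(BalanceOptions, raw.get("balance"), "balance"),
        paths=_build(PathsConfig, raw.get("paths"), "paths"),
        seed=int(raw.get("seed", 0)),
    )
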