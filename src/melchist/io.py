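"""Shared data model and on-disk layout for MELC runs.

A MELC acquisition is a sequence of stain/image/bleach cycles on a single
tissue section.  Each cycle stains up to three antibodies (one per optical
channel), acquires a 3D fluorescence z-stack per channel, photo-bleaches,
and acquires a matching post-bleach z-stack.  This module defines the
in-memory containers for such a run, the marker-panel configuration, and
TIFF/CSV/YAML readers and writers for the documented directory layout:

    reference_phase.tif
    blank_bleach.tif                     # pre-run blank (cycle-1 background)
    cycle{NN}_{channel}_fluo.tif         # multi-page, 2*z_steps+1 planes
    cycle{NN}_{channel}_bleach.tif
    cycle{NN}_{channel}_secondary.tif    # optional, uncoupled antibodies
    panel.yaml
    manifest.json

Pixel data are 16-bit unsigned on disk; floats in [0, 1] internally.
Coordinates are 0-based (row, col); physical position = index * pixel pitch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNELS = ("PE", "FITC", "DAPI")
LOCALIZATIONS = ("nuclear", "membrane", "structure")
GATING_ROLES = ("lineage_exclusion", "inclusion", "exploratory", "none")

U16_MAX = 65535.0


class ConfigError(ValueError):
    """Invalid panel / rules / parameter configuration."""


class ValidationError(ValueError):
    """A container violates its invariants."""


class LoadError(IOError):
    """A required file is missing or unreadable."""


@dataclass(frozen=True)
class MarkerSpec:
    """One antibody/stain in the panel and its analysis role."""

    name: str
    cycle_index: int
    channel: str
    localization: str
    gating_role: str = "none"
    uses_secondary_antibody: bool = False

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise ConfigError(f"{self.name}: cycle_index must be >= 1")
        if self.channel not in CHANNELS:
            raise ConfigError(f"{self.name}: unknown channel {self.channel!r}")
        if self.localization not in LOCALIZATIONS:
            raise ConfigError(f"{self.name}: unknown localization {self.localization!r}")
        if self.gating_role not in GATING_ROLES:
            raise ConfigError(f"{self.name}: unknown gating_role {self.gating_role!r}")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical geometry of the run.

    pixel_pitch_um is the sample-plane pixel size (0.325 um for the 20x/0.8 NA
    setup with a 6.5 um camera pixel and no binning); z_steps the half-range
    of the z-stack (planes = 2*z_steps + 1, spaced z_step_um apart).
    """

    pixel_pitch_um: float = 0.325
    z_steps: int = 7
    z_step_um: float = 1.0
    image_shape: tuple[int, int] = (2048, 2048)
    max_autofocus_shift_px: int = 50

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValidationError("pixel_pitch_um must be > 0")
        if self.z_steps < 0:
            raise ValidationError("z_steps must be >= 0")
        if min(self.image_shape) < 64:
            raise ValidationError("image_shape entries must be >= 64")

    @property
    def n_planes(self) -> int:
        return 2 * self.z_steps + 1


@dataclass
class CycleRecord:
    """One (cycle, channel) acquisition: one marker, its stacks."""

    cycle_index: int
    channel: str
    marker: MarkerSpec
    fluorescence_zstack: np.ndarray
    bleach_zstack: np.ndarray
    secondary_only_zstack: np.ndarray | None = None

    @property
    def markers(self) -> list[MarkerSpec]:
        return [self.marker]


@dataclass
class MelcRun:
    """A full acquisition: reference image, ordered cycle records, panel."""

    reference_phase_contrast: np.ndarray
    cycles: list[CycleRecord]
    geometry: AcquisitionGeometry
    panel: list[MarkerSpec]
    blank_bleach_zstack: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        validate_panel(self.panel)
        shape = tuple(self.geometry.image_shape)
        if self.reference_phase_contrast.shape != shape:
            raise ValidationError(
                f"reference image shape {self.reference_phase_contrast.shape} "
                f"!= geometry image_shape {shape}"
            )
        n_planes = self.geometry.n_planes
        order = [(c.cycle_index, c.channel) for c in self.cycles]
        if sorted(set(order)) != order:
            raise ValidationError("cycles must be strictly ascending by (cycle_index, channel)")
        for rec in self.cycles:
            for label, stack in (
                ("fluorescence", rec.fluorescence_zstack),
                ("bleach", rec.bleach_zstack),
                ("secondary", rec.secondary_only_zstack),
            ):
                if stack is None:
                    continue
                if stack.ndim != 3 or stack.shape[0] != n_planes:
                    raise ValidationError(
                        f"cycle {rec.cycle_index} {rec.channel} {label} stack has "
                        f"{stack.shape[0] if stack.ndim == 3 else '?'} planes, "
                        f"expected {n_planes}"
                    )
                if stack.shape[1:] != shape:
                    raise ValidationError(
                        f"cycle {rec.cycle_index} {rec.channel} {label} stack shape "
                        f"{stack.shape[1:]} != {shape}"
                    )
            if rec.marker.uses_secondary_antibody and rec.secondary_only_zstack is None:
                raise ValidationError(
                    f"marker {rec.marker.name} flagged uses_secondary_antibody but "
                    "no secondary-only stack supplied"
                )

    @property
    def cycle_indices(self) -> list[int]:
        return sorted({c.cycle_index for c in self.cycles})

    def marker_names(self) -> list[str]:
        return [m.name for m in self.panel]


def validate_panel(panel: Iterable[MarkerSpec]) -> None:
    panel = list(panel)
    names = [m.name for m in panel]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate marker name(s) in panel: {dupes}")
    slots = [(m.cycle_index, m.channel) for m in panel]
    if len(set(slots)) != len(slots):
        dupes = sorted({s for s in slots if slots.count(s) > 1})
        raise ConfigError(f"duplicate (cycle, channel) slot(s) in panel: {dupes}")


# ---------------------------------------------------------------------------
# panel config (YAML)

def parse_panel(config: dict | str | Path) -> list[MarkerSpec]:
    """Parse a marker-panel config (mapping or YAML file path)."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    try:
        entries = config["markers"]
    except (KeyError, TypeError):
        raise ConfigError("panel config must contain a 'markers' list")
    panel = [
        MarkerSpec(
            name=e["name"],
            cycle_index=int(e["cycle"]),
            channel=e["channel"],
            localization=e["localization"],
            gating_role=e.get("gating_role", "none"),
            uses_secondary_antibody=bool(e.get("uses_secondary_antibody", False)),
        )
        for e in entries
    ]
    validate_panel(panel)
    return panel


def panel_to_dict(panel: list[MarkerSpec]) -> dict:
    return {
        "markers": [
            {
                "name": m.name,
                "cycle": m.cycle_index,
                "channel": m.channel,
                "localization": m.localization,
                "gating_role": m.gating_role,
                "uses_secondary_antibody": m.uses_secondary_antibody,
            }
            for m in panel
        ]
    }


# ---------------------------------------------------------------------------
# image I/O helpers

def to_u16(img: np.ndarray) -> np.ndarray:
    """Clip a [0, 1]-scaled float image into canonical 16-bit counts."""
    return np.clip(np.asarray(img, dtype=np.float64) * U16_MAX, 0, U16_MAX).astype(np.uint16)


def from_u16(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64) / U16_MAX


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"missing image file: {path}")
    return tifffile.imread(path)


def write_image(path: str | Path, img: np.ndarray) -> None:
    tifffile.imwrite(Path(path), img, photometric="minisblack")


def _stack_name(cycle_index: int, channel: str, kind: str) -> str:
    return f"cycle{cycle_index:02d}_{channel}_{kind}.tif"


def write_run(run: MelcRun, path: str | Path) -> Path:
    """Write a MelcRun to a directory in the documented layout (16-bit TIFFs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_image(path / "reference_phase.tif", to_u16(run.reference_phase_contrast))
    if run.blank_bleach_zstack is not None:
        write_image(path / "blank_bleach.tif", to_u16(run.blank_bleach_zstack))
    for rec in run.cycles:
        write_image(path / _stack_name(rec.cycle_index, rec.channel, "fluo"),
                    to_u16(rec.fluorescence_zstack))
        write_image(path / _stack_name(rec.cycle_index, rec.channel, "bleach"),
                    to_u16(rec.bleach_zstack))
        if rec.secondary_only_zstack is not None:
            write_image(path / _stack_name(rec.cycle_index, rec.channel, "secondary"),
                        to_u16(rec.secondary_only_zstack))
    with open(path / "panel.yaml", "w") as fh:
        yaml.safe_dump(panel_to_dict(run.panel), fh, sort_keys=False)
    manifest = {
        "geometry": {
            "pixel_pitch_um": run.geometry.pixel_pitch_um,
            "z_steps": run.geometry.z_steps,
            "z_step_um": run.geometry.z_step_um,
            "image_shape": list(run.geometry.image_shape),
            "max_autofocus_shift_px": run.geometry.max_autofocus_shift_px,
        },
        "has_blank": run.blank_bleach_zstack is not None,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def read_run(path: str | Path, panel_config: str | Path | dict | None = None) -> MelcRun:
    """Read a MelcRun from a directory written by :func:`write_run`.

    A missing bleach stack is an error; cycle 1 additionally requires the
    run-level blank acquisition as its background.
    """
    path = Path(path)
    panel = parse_panel(panel_config if panel_config is not None else path / "panel.yaml")
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise LoadError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    g = manifest["geometry"]
    geometry = AcquisitionGeometry(
        pixel_pitch_um=g["pixel_pitch_um"],
        z_steps=g["z_steps"],
        z_step_um=g["z_step_um"],
        image_shape=tuple(g["image_shape"]),
        max_autofocus_shift_px=g["max_autofocus_shift_px"],
    )
    reference = from_u16(read_image(path / "reference_phase.tif"))
    blank = None
    if manifest.get("has_blank"):
        blank = from_u16(read_image(path / "blank_bleach.tif"))
    cycles = []
    for m in sorted(panel, key=lambda m: (m.cycle_index, m.channel)):
        fluo_path = path / _stack_name(m.cycle_index, m.channel, "fluo")
        bleach_path = path / _stack_name(m.cycle_index, m.channel, "bleach")
        if not fluo_path.exists():
            raise LoadError(f"cycle {m.cycle_index} ({m.name}): missing {fluo_path.name}")
        if not bleach_path.exists():
            raise LoadError(f"cycle {m.cycle_index} ({m.name}): missing {bleach_path.name}")
        secondary = None
        sec_path = path / _stack_name(m.cycle_index, m.channel, "secondary")
        if sec_path.exists():
            secondary = from_u16(read_image(sec_path))
        elif m.uses_secondary_antibody:
            raise LoadError(f"marker {m.name} needs a secondary-only stack: {sec_path.name}")
        cycles.append(CycleRecord(
            cycle_index=m.cycle_index,
            channel=m.channel,
            marker=m,
            fluorescence_zstack=from_u16(read_image(fluo_path)),
            bleach_zstack=from_u16(read_image(bleach_path)),
            secondary_only_zstack=secondary,
        ))
    if blank is None and cycles:
        # the first cycle has no earlier bleach image to subtract
        raise LoadError("run has no blank_bleach.tif: cycle 1 background is undefined")
    return MelcRun(
        reference_phase_contrast=reference,
        cycles=cycles,
        geometry=geometry,
        panel=panel,
        blank_bleach_zstack=blank,
    )


# ---------------------------------------------------------------------------
# cell table

FIXED_COLUMNS = ["cell_id", "centroid_row", "centroid_col", "centroid_y_um",
                 "centroid_x_um", "area_px"]
TRAILING_COLUMNS = ["gated_type", "compartment", "cluster_id"]


@dataclass
class CellTable:
    """One record per segmented cell: geometry, per-marker MFI, annotations.

    ``df`` holds the fixed geometry columns, one ``mfi_<marker>`` column per
    panel marker (in panel order), then gated_type / compartment / cluster_id.
    """

    df: pd.DataFrame
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in FIXED_COLUMNS:
            if col not in self.df.columns:
                raise ValidationError(f"cell table missing column {col!r}")
        ids = self.df["cell_id"]
        if len(ids) != len(set(ids)):
            raise ValidationError("cell_id values must be unique")
        for m in self.markers:
            col = f"mfi_{m}"
            if col not in self.df.columns:
                raise ValidationError(f"cell table missing MFI column for marker {m!r}")
            vals = self.df[col]
            if len(vals) and ((vals < -1e-9) | (vals > 1 + 1e-9)).any():
                raise ValidationError(f"MFI values for {m!r} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.df)

    def mfi_matrix(self) -> np.ndarray:
        """Cells x markers MFI matrix in panel order."""
        return self.df[[f"mfi_{m}" for m in self.markers]].to_numpy(dtype=float)

    def column_order(self) -> list[str]:
        """Stable on-disk column order."""
        return FIXED_COLUMNS + [f"mfi_{m}" for m in self.markers] + TRAILING_COLUMNS


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write the table as CSV with the stable documented column order."""
    df = table.df.copy()
    for col in TRAILING_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col != "cluster_id" else pd.NA
    cols = FIXED_COLUMNS + [f"mfi_{m}" for m in table.markers] + TRAILING_COLUMNS
    df[cols].to_csv(path, index=False, float_format="%.6f")


def read_cell_table(path: str | Path, markers: list[str] | None = None) -> CellTable:
    df = pd.read_csv(path)
    if markers is None:
        markers = [c[len("mfi_"):] for c in df.columns if c.startswith("mfi_")]
    if "gated_type" in df.columns:
        df["gated_type"] = df["gated_type"].fillna("others").astype(str)
    if "compartment" in df.columns:
        df["compartment"] = df["compartment"].fillna("unassigned").astype(str)
    return CellTable(df=df, markers=list(markers))


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    write_image(path, labels.astype(np.int32))


def read_label_image(path: str | Path) -> np.ndarray:
    return read_image(path).astype(np.int64)
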