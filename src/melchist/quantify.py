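"""Per-cell marker quantification and flow-cytometry-style threshold gating.

Mean fluorescence intensity (MFI) is measured per segmented cell on the
corrected, [0, 1]-scaled marker images — over the full cell mask for
membrane and structure markers, over the nucleus mask for nuclear markers.
Cells are then classified by binarizing MFIs against per-marker thresholds
and evaluating gating rules in priority order (first satisfied rule wins;
unmatched cells are "others").  The shipped default rule set encodes the
tonsil phenotypes: B cells (CD45+CD19+), T helper (CD45+CD3+CD4+),
cytotoxic T (CD45+CD3+CD8+), plasma (CD138+), myeloid (CD14+ in this
panel), endothelial (CD31+) and ILCs (Lin- CD45+ CD127+, Lin being the
panel's lineage-exclusion markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import (
    AcquisitionGeometry,
    CellTable,
    ConfigError,
    MarkerSpec,
    ValidationError,
)


@dataclass(frozen=True)
class GatingRule:
    """One cell-type definition.

    ``any_of`` holds disjunctive clauses; each clause is a conjunction of
    signed marker terms ("CD16+", "CD56-").  Unsigned names in
    requires_positive / requires_negative are implicit +/-.
    """

    type_name: str
    priority: int
    requires_positive: tuple[str, ...] = ()
    requires_negative: tuple[str, ...] = ()
    any_of: tuple[tuple[str, ...], ...] = ()

    def referenced_markers(self) -> set[str]:
        names = set(self.requires_positive) | set(self.requires_negative)
        for clause in self.any_of:
            names |= {term.rstrip("+-") for term in clause}
        return names

    def matches(self, positive: dict[str, bool]) -> bool:
        if any(not positive[m] for m in self.requires_positive):
            return False
        if any(positive[m] for m in self.requires_negative):
            return False
        if self.any_of:
            def clause_ok(clause: tuple[str, ...]) -> bool:
                for term in clause:
                    name = term.rstrip("+-")
                    want = not term.endswith("-")
                    if positive[name] != want:
                        return False
                return True
            return any(clause_ok(c) for c in self.any_of)
        return True


@dataclass
class ThresholdSet:
    """Per-marker MFI thresholds with provenance (manual vs Otsu default)."""

    thresholds: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, t in self.thresholds.items():
            if not (0 < t < 1):
                raise ValidationError(f"threshold for {m} must be in (0, 1), got {t}")

    def __getitem__(self, marker: str) -> float:
        return self.thresholds[marker]


def extract_mfi(
    cells: np.ndarray,
    corrected: dict[str, np.ndarray],
    panel: list[MarkerSpec],
    nuclei: np.ndarray | None = None,
    geometry: AcquisitionGeometry | None = None,
) -> CellTable:
    """Geometry and per-marker MFI for every segmented cell.

    ``corrected`` images must be pre-scaled to [0, 1].  Nuclear markers are
    measured over the matching nucleus mask (same label ids as the cells),
    everything else over the full cell mask.
    """
    cells = np.asarray(cells)
    pitch = geometry.pixel_pitch_um if geometry is not None else 0.325
    ids = np.array([i for i in np.unique(cells) if i > 0], dtype=np.int64)
    missing = [m.name for m in panel if m.name not in corrected]
    if missing:
        raise ValidationError(f"corrected images missing for markers: {missing}")
    need_nuclei = any(m.localization == "nuclear" for m in panel)
    if need_nuclei and nuclei is None:
        raise ValidationError("nucleus label image required for nuclear markers")
    rows: dict[str, list] = {c: [] for c in
                             ("cell_id", "centroid_row", "centroid_col",
                              "centroid_y_um", "centroid_x_um", "area_px")}
    if len(ids):
        centroids = ndimage.center_of_mass(np.ones_like(cells), cells, ids)
        areas = ndimage.sum_labels(np.ones_like(cells), cells, ids)
        for i, (cr, cc), a in zip(ids, centroids, areas):
            rows["cell_id"].append(int(i))
            rows["centroid_row"].append(cr)
            rows["centroid_col"].append(cc)
            rows["centroid_y_um"].append(cr * pitch)
            rows["centroid_x_um"].append(cc * pitch)
            rows["area_px"].append(int(a))
    df = pd.DataFrame(rows)
    if need_nuclei and len(ids):
        nuc_areas = ndimage.sum_labels(np.ones_like(cells), nuclei, ids)
        if np.any(nuc_areas == 0):
            bad = [int(i) for i, a in zip(ids, nuc_areas) if a == 0]
            raise ValidationError(f"cells without nucleus pixels: {bad}")
    for m in panel:
        img = np.asarray(corrected[m.name], dtype=np.float64)
        if img.shape != cells.shape:
            raise ValidationError(
                f"image for {m.name} has shape {img.shape}, labels {cells.shape}"
            )
        if img.max() > 1 + 1e-6:
            raise ValidationError(f"image for {m.name} not scaled to [0, 1]")
        mask = nuclei if m.localization == "nuclear" else cells
        vals = ndimage.mean(img, labels=mask, index=ids) if len(ids) else []
        df[f"mfi_{m.name}"] = np.clip(vals, 0.0, 1.0)
    return CellTable(df=df, markers=[m.name for m in panel])


def default_thresholds(
    table: CellTable,
    markers: list[str] | None = None,
    manual_overrides: dict[str, float] | None = None,
) -> ThresholdSet:
    """Otsu threshold per marker on the per-cell MFI distribution (256-bin),
    clipped to [0.05, 0.95]; degenerate (constant) markers get 0.5 with a
    warning.  Manual overrides replace the defaults verbatim.
    """
    if len(table) < 20:
        raise ValidationError("need >= 20 cells to derive thresholds")
    markers = markers if markers is not None else table.markers
    thresholds: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for m in markers:
        vals = table.df[f"mfi_{m}"].to_numpy(dtype=float)
        if np.ptp(vals) < 1e-12:
            warnings.warn(f"marker {m} has constant MFI; defaulting threshold to 0.5")
            thresholds[m] = 0.5
            provenance[m] = "otsu_default"
            continue
        t = float(threshold_otsu(vals, nbins=256))
        thresholds[m] = float(np.clip(t, 0.05, 0.95))
        provenance[m] = "otsu_default"
    for m, t in (manual_overrides or {}).items():
        thresholds[m] = float(t)
        provenance[m] = "manual"
    return ThresholdSet(thresholds=thresholds, provenance=provenance)


def gate_cells(
    table: CellTable, thresholds: ThresholdSet, rules: list[GatingRule]
) -> CellTable:
    """Assign a gated type per cell: binarize MFIs (MFI >= t is positive),
    evaluate rules by ascending priority, first satisfied rule wins, else
    "others".  Deterministic and independent of cell order.
    """
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ConfigError("gating-rule priorities must be unique")
    referenced = set().union(*(r.referenced_markers() for r in rules)) if rules else set()
    unknown = referenced - set(table.markers)
    if unknown:
        raise ConfigError(f"gating rules reference unknown markers: {sorted(unknown)}")
    missing_thresholds = referenced - set(thresholds.thresholds)
    if missing_thresholds:
        raise ConfigError(f"no thresholds for markers: {sorted(missing_thresholds)}")
    ordered = sorted(rules, key=lambda r: r.priority)
    types = []
    for _, row in table.df.iterrows():
        positive = {
            m: bool(row[f"mfi_{m}"] >= thresholds[m])
            for m in table.markers if m in thresholds.thresholds
        }
        assigned = "others"
        for rule in ordered:
            if rule.matches(positive):
                assigned = rule.type_name
                break
        types.append(assigned)
    df = table.df.copy()
    df["gated_type"] = types
    return CellTable(df=df, markers=table.markers)


def count_types(table: CellTable) -> dict[str, dict[str, float]]:
    """Counts and frequencies per gated type, including "others"."""
    if "gated_type" not in table.df.columns:
        raise ValidationError("table is not gated")
    counts = table.df["gated_type"].value_counts()
    n = int(counts.sum())
    return {
        t: {"count": int(c), "frequency": float(c / n)} for t, c in counts.items()
    }


# ---------------------------------------------------------------------------
# rule configuration

def rules_from_config(config: dict | str | Path) -> list[GatingRule]:
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    rules = []
    for e in config["rules"]:
        rules.append(GatingRule(
            type_name=e["type"],
            priority=int(e["priority"]),
            requires_positive=tuple(e.get("positive", ())),
            requires_negative=tuple(e.get("negative", ())),
            any_of=tuple(tuple(c) for c in e.get("any_of", ())),
        ))
    return rules


def default_tonsil_rules() -> list[GatingRule]:
    """The shipped tonsil rule set (see data/tonsil_rules.yaml)."""
    ref = resources.files("melchist").joinpath("data/tonsil_rules.yaml")
    with resources.as_file(ref) as path:
        return rules_from_config(path)
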