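"""Spatial neighborhood analysis: 10 um niches, structure proximity,
tissue compartments.

A niche is the region within a fixed radius (default 10 um, the average
immune-cell diameter) around a seed cell — the seed cell's mask dilated by
a Euclidean disk.  Niche composition tallies the gated types of the member
cells (by default: cells whose centroid falls inside the niche region).
Structure proximity measures, per seed-type cell, the minimum Euclidean
distance from the cell mask to a structure mask (vessels, fibers).
Compartments are smooth-score argmax regions built from compartment-defining
marker images (e.g. B-follicle from CD19, T zone from CD3, connective
septum from stromal markers), with a border band around the follicle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import AcquisitionGeometry, CellTable, ConfigError, ValidationError


@dataclass
class NicheParams:
    radius_um: float = 10.0
    membership: str = "centroid_in_region"  # or "any_overlap"
    structure_distance_um: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValidationError("radius_um must be > 0")
        if self.membership not in ("centroid_in_region", "any_overlap"):
            raise ValidationError(f"unknown membership rule {self.membership!r}")


@dataclass
class NicheRecord:
    seed_cell_id: int
    region: np.ndarray                  # boolean niche mask
    member_cell_ids: list[int]
    composition: dict[str, int]         # gated type -> count (seed excluded)
    structure_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class CompartmentMap:
    labels: np.ndarray                  # 0 = unassigned
    names: dict[int, str]               # label -> compartment name

    def name_image(self) -> np.ndarray:
        return self.labels

    def label_of(self, name: str) -> int:
        for k, v in self.names.items():
            if v == name:
                return k
        raise KeyError(name)


def radius_px(radius_um: float, geometry: AcquisitionGeometry) -> int:
    """Physical radius in pixels (= 31 px for 10 um at 0.325 um/px)."""
    return int(round(radius_um / geometry.pixel_pitch_um))


def build_niches(
    cells: np.ndarray,
    table: CellTable,
    seed_type: str,
    params: NicheParams | None = None,
    geometry: AcquisitionGeometry | None = None,
) -> list[NicheRecord]:
    """One niche per seed-type cell.

    The niche region is the set of pixels within ``radius_um`` (Euclidean)
    of the seed cell's mask.  Membership: "centroid_in_region" includes a
    cell whose (rounded) centroid pixel lies in the region (inclusive
    boundary); "any_overlap" includes a cell whose mask touches the region.
    The seed itself is never counted in the composition.
    """
    params = params or NicheParams()
    geometry = geometry or AcquisitionGeometry(image_shape=cells.shape)
    cells = np.asarray(cells)
    if "gated_type" not in table.df.columns:
        raise ValidationError("table must be gated before niche analysis")
    known_types = set(table.df["gated_type"])
    if seed_type not in known_types:
        warnings.warn(f"no cells of seed type {seed_type!r}; empty niche list")
        return []
    r_px = radius_px(params.radius_um, geometry)
    seeds = table.df.loc[table.df["gated_type"] == seed_type, "cell_id"].tolist()
    centroid_px = {
        int(row.cell_id): (int(round(row.centroid_row)), int(round(row.centroid_col)))
        for row in table.df.itertuples()
    }
    types = dict(zip(table.df["cell_id"].astype(int), table.df["gated_type"]))
    records = []
    for sid in seeds:
        seed_mask = cells == sid
        if not seed_mask.any():
            raise ValidationError(f"seed cell {sid} absent from label image")
        dist = ndimage.distance_transform_edt(~seed_mask)
        region = dist <= r_px
        members: list[int] = []
        for cid in types:
            if cid == sid:
                continue
            if params.membership == "centroid_in_region":
                rr, cc = centroid_px[cid]
                inside = (0 <= rr < region.shape[0] and 0 <= cc < region.shape[1]
                          and bool(region[rr, cc]))
            else:
                inside = bool((region & (cells == cid)).any())
            if inside:
                members.append(cid)
        comp: dict[str, int] = {}
        for cid in members:
            comp[types[cid]] = comp.get(types[cid], 0) + 1
        records.append(NicheRecord(
            seed_cell_id=int(sid), region=region,
            member_cell_ids=members, composition=comp,
        ))
    return records


def niche_enrichment(
    niches: list[NicheRecord], table: CellTable
) -> pd.DataFrame:
    """Pooled niche composition vs whole-tissue frequencies per gated type.

    Whole-tissue frequencies exclude the seed cells themselves so the two
    frequency vectors answer the same question ("what surrounds a seed?"
    vs "what is anywhere?").  Both columns sum to 1.
    """
    if not niches:
        raise ValidationError("need >= 1 niche")
    seed_ids = {n.seed_cell_id for n in niches}
    tissue = table.df[~table.df["cell_id"].isin(seed_ids)]
    tissue_counts = tissue["gated_type"].value_counts()
    pooled: dict[str, int] = {}
    for n in niches:
        for t, c in n.composition.items():
            pooled[t] = pooled.get(t, 0) + c
    all_types = sorted(set(tissue_counts.index) | set(pooled))
    n_tissue = int(tissue_counts.sum())
    n_niche = sum(pooled.values())
    rows = []
    for t in all_types:
        niche_count = pooled.get(t, 0)
        rows.append({
            "type": t,
            "whole_tissue_freq": tissue_counts.get(t, 0) / n_tissue if n_tissue else 0.0,
            "niche_freq": niche_count / n_niche if n_niche else 0.0,
            "per_niche_mean_count": niche_count / len(niches),
        })
    return pd.DataFrame(rows).set_index("type")


def structure_proximity(
    table: CellTable,
    structure_masks: dict[str, np.ndarray],
    cells: np.ndarray,
    params: NicheParams | None = None,
    geometry: AcquisitionGeometry | None = None,
    seed_type: str | None = None,
) -> dict[str, float]:
    """Fraction of (seed-type) cells within ``structure_distance_um`` of
    each structure mask, by minimum Euclidean mask-to-mask distance.
    """
    params = params or NicheParams()
    geometry = geometry or AcquisitionGeometry(image_shape=cells.shape)
    cells = np.asarray(cells)
    df = table.df
    if seed_type is not None:
        df = df[df["gated_type"] == seed_type]
    ids = df["cell_id"].astype(int).tolist()
    max_d_px = params.structure_distance_um / geometry.pixel_pitch_um
    out: dict[str, float] = {}
    for name, mask in structure_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cells.shape:
            raise ValidationError(f"structure mask {name!r} shape mismatch")
        if not mask.any():
            warnings.warn(f"structure mask {name!r} is empty; fraction 0")
            out[name] = 0.0
            continue
        dist = ndimage.distance_transform_edt(~mask)
        if not ids:
            out[name] = 0.0
            continue
        min_dist = ndimage.minimum(dist, labels=cells, index=ids)
        out[name] = float(np.mean(np.asarray(min_dist) <= max_d_px))
    return out


def segment_compartments(
    corrected: dict[str, np.ndarray],
    config: dict[str, list[str]],
    thresholds: dict[str, float] | None = None,
    geometry: AcquisitionGeometry | None = None,
    smooth_sigma_um: float = 20.0,
    score_floor: float = 0.1,
    border_of: str | None = "follicle",
    border_radius_um: float = 10.0,
) -> CompartmentMap:
    """Smooth-score compartment segmentation.

    Per compartment, the binarized defining-marker images are summed and
    Gaussian smoothed (sigma in um); each pixel goes to the argmax score if
    that score clears ``score_floor``, else stays unassigned (0).  If
    ``border_of`` names a segmented compartment, the band within
    ``border_radius_um`` outside it is relabelled as "<name>_border".
    """
    if not config:
        raise ConfigError("no compartments configured")
    for comp, markers in config.items():
        if not markers:
            raise ConfigError(f"compartment {comp!r} has no defining markers")
        for m in markers:
            if m not in corrected:
                raise ConfigError(f"compartment {comp!r}: no image for marker {m!r}")
    shape = next(iter(corrected.values())).shape
    geometry = geometry or AcquisitionGeometry(image_shape=shape)
    sigma_px = smooth_sigma_um / geometry.pixel_pitch_um
    names = sorted(config)
    scores = np.zeros((len(names),) + shape)
    for k, comp in enumerate(names):
        acc = np.zeros(shape)
        for m in config[comp]:
            img = np.asarray(corrected[m], dtype=np.float64)
            scale = img.max()
            t = (thresholds or {}).get(m, 0.5) * (scale if scale > 1 else 1.0)
            acc += (img >= t).astype(np.float64)
        scores[k] = ndimage.gaussian_filter(acc, sigma_px)
    best = np.argmax(scores, axis=0)
    best_score = np.take_along_axis(scores, best[None], axis=0)[0]
    labels = np.where(best_score >= score_floor, best + 1, 0).astype(np.int32)
    name_table = {k + 1: n for k, n in enumerate(names)}
    if border_of is not None and border_of in names:
        core = labels == (names.index(border_of) + 1)
        if core.any():
            dist = ndimage.distance_transform_edt(~core)
            band = (dist > 0) & (dist <= radius_px(border_radius_um, geometry))
            border_label = len(names) + 1
            labels[band] = border_label
            name_table[border_label] = f"{border_of}_border"
    return CompartmentMap(labels=labels, names=name_table)


def assign_compartments(
    table: CellTable, comp: CompartmentMap, seed_type: str | None = None
) -> tuple[CellTable, dict[str, float]]:
    """Each cell takes the compartment of its centroid pixel ("unassigned"
    outside every compartment).  Also returns the seed-type distribution
    over compartments (unassigned cells excluded from the denominator).
    """
    labels = comp.labels
    out = []
    for row in table.df.itertuples():
        rr, cc = int(round(row.centroid_row)), int(round(row.centroid_col))
        if 0 <= rr < labels.shape[0] and 0 <= cc < labels.shape[1]:
            out.append(comp.names.get(int(labels[rr, cc]), "unassigned"))
        else:
            out.append("unassigned")
    df = table.df.copy()
    df["compartment"] = out
    gated = CellTable(df=df, markers=table.markers)
    sel = df
    if seed_type is not None:
        if "gated_type" not in df.columns:
            raise ValidationError("table must be gated to compute a type distribution")
        sel = df[df["gated_type"] == seed_type]
    assigned = sel[sel["compartment"] != "unassigned"]
    dist: dict[str, float] = {}
    if len(assigned):
        counts = assigned["compartment"].value_counts()
        dist = {k: float(v / counts.sum()) for k, v in counts.items()}
    return gated, dist
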