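"""End-to-end orchestration: raw run -> corrected images -> probability
maps -> segmentation -> cell table -> gating -> niches/compartments ->
clustering, with provenance and deterministic seed fan-out.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    ClusterParams,
    cluster_cells,
    cluster_heatmap,
    embed_tsne,
    gate_cluster_agreement,
    transform_expression,
)
from .io import (
    CellTable,
    ConfigError,
    MelcRun,
    U16_MAX,
    read_image,
    read_run,
    write_cell_table,
    write_image,
    write_label_image,
)
from .pixelclass import (
    compute_pixel_features,
    labels_from_truth,
    predict_probability_maps,
    sum_membranes,
    train_pixel_classifier,
)
from .preprocess import PreprocessParams, preprocess_run
from .quantify import (
    count_types,
    default_thresholds,
    default_tonsil_rules,
    extract_mfi,
    gate_cells,
    rules_from_config,
)
from .segment import SegmentationParams, segment_cells, segment_nuclei
from .spatial import (
    NicheParams,
    assign_compartments,
    build_niches,
    niche_enrichment,
    segment_compartments,
    structure_proximity,
)

DEFAULT_COMPARTMENTS = {
    "follicle": ["CD19"],
    "t_zone": ["CD3"],
    "septum": ["SMA", "Fibronectin"],
}


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    seed: int = 0
    tissue_mode: str = "tonsil"           # or "colon"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    niche: NicheParams = field(default_factory=NicheParams)
    cluster: ClusterParams | None = None  # derived from tissue_mode if None
    rules_file: str | None = None         # None: shipped tonsil rules
    manual_thresholds: dict[str, float] = field(default_factory=dict)
    seed_cell_type: str = "ILC"
    compartments: dict[str, list[str]] | None = None
    pixel_label_file: str | None = None   # training labels (post-crop frame)

    def __post_init__(self) -> None:
        if self.tissue_mode not in ("tonsil", "colon"):
            raise ConfigError(f"unknown tissue_mode {self.tissue_mode!r}")
        if self.cluster is None:
            self.cluster = ClusterParams(
                n_components=52 if self.tissue_mode == "tonsil" else 48,
                expression_cutoff=None if self.tissue_mode == "tonsil" else 0.1,
                seed=stage_seed(self.seed, "cluster"),
            )


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _params_hash(config: RunConfig) -> str:
    def default(o):
        return sorted(o) if isinstance(o, set) else str(o)
    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(
    run: MelcRun | str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    truth_class_image: np.ndarray | None = None,
) -> dict:
    """Execute every stage in fixed order and write all artifacts.

    Pixel-classifier training labels come from, in order of preference:
    ``config.pixel_label_file`` (a label TIFF in the post-crop frame),
    ``truth_class_image`` (a synthetic ground-truth class image in the
    reference frame, auto-scribbled over ~6% of the area), or a
    ``truth_class_image.tif`` found next to a run directory.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = (rules_from_config(config.rules_file) if config.rules_file
             else default_tonsil_rules())

    run_path: Path | None = None
    if not isinstance(run, MelcRun):
        run_path = Path(run)
        run = read_run(run_path)
    if truth_class_image is None and run_path is not None:
        candidate = run_path / "truth_class_image.tif"
        if candidate.exists():
            truth_class_image = read_image(candidate)

    # 1. preprocessing ------------------------------------------------------
    corrected, shifts = preprocess_run(run, config.preprocess)
    margin = (config.preprocess.crop_margin_px
              if config.preprocess.crop_margin_px is not None
              else max((max(abs(a), abs(b)) for a, b in shifts.values()), default=0))
    corr_dir = out / "corrected"
    corr_dir.mkdir(exist_ok=True)
    for name, img in corrected.items():
        write_image(corr_dir / f"{name}.tif", img.astype(np.float32))
    with open(out / "shifts.json", "w") as fh:
        json.dump({str(k): list(v) for k, v in shifts.items()}, fh, indent=2)
    scaled = {name: img / U16_MAX for name, img in corrected.items()}

    # 2. pixel classification ----------------------------------------------
    nuclear = [m.name for m in run.panel if m.localization == "nuclear"]
    if not nuclear:
        raise ConfigError("panel has no nuclear (DAPI-like) marker")
    dapi = scaled[nuclear[0]]
    summem = sum_membranes(scaled, run.panel)
    features, feature_names = compute_pixel_features((dapi, summem))
    if config.pixel_label_file is not None:
        labels = read_image(config.pixel_label_file)
    elif truth_class_image is not None:
        cls = np.asarray(truth_class_image)
        if margin:
            cls = cls[margin:-margin, margin:-margin]
        labels = labels_from_truth(cls, seed=stage_seed(config.seed, "labels"))
    else:
        raise ConfigError("no pixel-classifier training labels available")
    model = train_pixel_classifier(
        features, labels, seed=stage_seed(config.seed, "classifier"),
        feature_names=feature_names,
    )
    maps = predict_probability_maps(model, features)
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for name, img in (("p_nuclei", maps.p_nuc), ("p_membrane", maps.p_mem),
                      ("p_ecm", maps.p_ecm)):
        write_image(maps_dir / f"{name}.tif", img.astype(np.float32))

    # 3. segmentation -------------------------------------------------------
    nuclei = segment_nuclei(maps.p_nuc, config.segmentation)
    cells = segment_cells(nuclei, maps.p_mem, config.segmentation)
    write_label_image(out / "nuclei_labels.tif", nuclei)
    write_label_image(out / "cell_labels.tif", cells)

    # 4. quantification and gating -----------------------------------------
    table = extract_mfi(cells, scaled, run.panel, nuclei=nuclei,
                        geometry=run.geometry)
    thresholds = default_thresholds(table, manual_overrides=config.manual_thresholds)
    table = gate_cells(table, thresholds, rules)
    counts = count_types(table)

    # 5. spatial analysis ---------------------------------------------------
    niches = build_niches(cells, table, config.seed_cell_type, config.niche,
                          run.geometry)
    enrichment = (niche_enrichment(niches, table) if niches else pd.DataFrame())
    structure_markers = [m.name for m in run.panel if m.localization == "structure"]
    masks = {m: scaled[m] >= 0.5 * scaled[m].max() for m in structure_markers}
    if "CD31" in scaled and "CD31" in thresholds.thresholds:
        masks["vessels_CD31"] = scaled["CD31"] >= thresholds["CD31"]
    proximity = structure_proximity(
        table, masks, cells, config.niche, run.geometry,
        seed_type=config.seed_cell_type,
    ) if masks else {}
    comp_config = config.compartments or {
        k: v for k, v in DEFAULT_COMPARTMENTS.items()
        if all(m in scaled for m in v)
    }
    compartment_info = {}
    if comp_config:
        comp = segment_compartments(scaled, comp_config,
                                    thresholds=thresholds.thresholds,
                                    geometry=run.geometry)
        write_label_image(out / "compartments.tif", comp.labels)
        table, comp_dist = assign_compartments(table, comp,
                                               seed_type=config.seed_cell_type)
        compartment_info = {"names": comp.names, "seed_type_distribution": comp_dist}

    # 6. clustering ---------------------------------------------------------
    cparams = config.cluster
    matrix, kept = transform_expression(table, cparams)
    cluster_info = {}
    cluster_ids = np.full(len(table), -1)
    if kept.sum() >= 12:
        n_kept = int(kept.sum())
        if cparams.perplexity >= n_kept / 3:
            # small field of view: shrink the perplexity to stay feasible
            cparams = replace(cparams, perplexity=max((n_kept - 1) / 3.5, 2.0))
        embedding = embed_tsne(matrix, cparams)
        ids = cluster_cells(embedding, "auto", seed=cparams.seed,
                            k_range=cparams.k_range)
        cluster_ids[kept] = ids
        kept_table = CellTable(df=table.df.loc[kept].reset_index(drop=True),
                               markers=table.markers)
        heatmap = cluster_heatmap(kept_table, ids)
        heatmap.to_csv(out / "heatmap.csv")
        emb_df = pd.DataFrame({
            "cell_id": kept_table.df["cell_id"],
            "tsne_x": embedding[:, 0],
            "tsne_y": embedding[:, 1],
            "cluster_id": ids,
        })
        emb_df.to_csv(out / "clusters.csv", index=False)
        agreement = None
        gated = kept_table.df["gated_type"].to_numpy()
        focus_mask = gated == config.seed_cell_type
        if focus_mask.any():
            per_cluster = pd.Series(ids[focus_mask]).value_counts()
            focus_cluster = int(per_cluster.idxmax())
            agreement, _ = gate_cluster_agreement(
                kept_table, ids, focus_cluster, config.seed_cell_type
            )
            cluster_info["focus_cluster"] = focus_cluster
        cluster_info.update({
            "n_clusters": int(len(np.unique(ids))),
            "agreement": agreement,
        })

    table.df["cluster_id"] = cluster_ids
    table = CellTable(df=table.df, markers=table.markers)
    write_cell_table(table, out / "cells.csv")
    if niches:
        with open(out / "niches.json", "w") as fh:
            json.dump([
                {"seed_cell_id": n.seed_cell_id,
                 "member_cell_ids": n.member_cell_ids,
                 "composition": n.composition} for n in niches
            ], fh, indent=2)

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("labels", "classifier", "cluster")},
        "params_hash": _params_hash(config),
        "shifts": {str(k): list(v) for k, v in shifts.items()},
        "crop_margin_px": int(margin),
        "n_cells": int(len(table)),
        "classifier_oob_accuracy": model.oob_accuracy,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {
        "corrected": corrected,
        "shifts": shifts,
        "margin": margin,
        "maps": maps,
        "nuclei": nuclei,
        "cells": cells,
        "table": table,
        "thresholds": thresholds,
        "counts": counts,
        "niches": niches,
        "enrichment": enrichment,
        "structure_proximity": proximity,
        "compartments": compartment_info,
        "clusters": cluster_info,
        "provenance": provenance,
    }
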