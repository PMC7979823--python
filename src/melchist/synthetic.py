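"""Miniature synthetic MELC runs with full ground truth.

The generator renders a flat 2D "tissue" of non-overlapping round cells
(disk nuclei, annular membranes) plus fibrous structures, and images it the
way a cyclic stain/bleach acquisition would:

* per (cycle, channel) acquisition, the noiseless scene of that marker plus
  structured autofluorescence and the residual signal left over from the
  previous stain in the same channel,
* multiplied by a smooth illumination field fixed to the camera,
* translated by the cycle's integer stage shift,
* defocused per z-plane proportionally to |z|, with additive Gaussian noise,
* and a matching post-bleach stack (autofluorescence + bleach residual).

Everything the pipeline is supposed to recover — shifts, illumination field,
cell positions/types/expression, class maps, structure masks — is returned
as :class:`GroundTruth` and serves as the test oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    AcquisitionGeometry,
    ConfigError,
    CycleRecord,
    MarkerSpec,
    MelcRun,
    validate_panel,
    write_image,
    write_run,
)


class PlacementError(RuntimeError):
    """Requested cell count cannot be placed without overlap."""


@dataclass(frozen=True)
class CellTypeSpec:
    type_name: str
    frequency: float
    expression: dict[str, float]  # marker name -> mean intensity in [0, 1]


@dataclass
class SceneSpec:
    """Parameters of one synthetic acquisition."""

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 150
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    panel: list[MarkerSpec] = field(default_factory=list)
    pixel_pitch_um: float = 0.325
    nucleus_radius_um: float = 3.0
    cell_radius_um: float = 5.0
    z_steps: int = 2
    illumination_amplitude: float = 0.0
    autofluorescence_level: float = 0.0
    bleach_residual_fraction: float = 0.0
    stage_shifts_px: dict[int, tuple[int, int]] = field(default_factory=dict)
    defocus_blur_sigma_per_z: float = 1.0
    noise_sd: float = 0.0
    structure_intensity: float = 0.6
    n_fibers_per_structure: int = 3
    seed: int = 0
    # explicit placement override: list of (row, col, type_name)
    cells: list[tuple[float, float, str]] | None = None
    # rare populations that must be represented regardless of rounding
    min_type_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_panel(self.panel)
        if self.cell_types:
            total = sum(t.frequency for t in self.cell_types)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"cell-type frequencies sum to {total}, not 1")
        if not (0 <= self.bleach_residual_fraction < 1):
            raise ConfigError("bleach_residual_fraction must be in [0, 1)")
        for cyc, (dr, dc) in self.stage_shifts_px.items():
            if max(abs(dr), abs(dc)) > min(self.image_shape) // 4:
                raise ConfigError(f"cycle {cyc} shift {(dr, dc)} unreasonably large")

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_pitch_um

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius_um / self.pixel_pitch_um

    @property
    def geometry(self) -> AcquisitionGeometry:
        max_shift = max(
            [max(abs(dr), abs(dc)) for dr, dc in self.stage_shifts_px.values()],
            default=0,
        )
        return AcquisitionGeometry(
            pixel_pitch_um=self.pixel_pitch_um,
            z_steps=self.z_steps,
            z_step_um=1.0,
            image_shape=tuple(self.image_shape),
            max_autofocus_shift_px=max(max_shift, 1),
        )

    def type_by_name(self, name: str) -> CellTypeSpec:
        for t in self.cell_types:
            if t.type_name == name:
                return t
        raise KeyError(name)


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a synthetic run."""

    cell_centers_px: np.ndarray          # (n, 2) float, reference frame
    cell_types: list[str]
    nucleus_labels: np.ndarray           # label i+1 for cell i
    cell_labels: np.ndarray
    class_image: np.ndarray              # 1 nuclei, 2 membrane, 3 ECM/background
    shifts: dict[int, tuple[int, int]]   # cycle_index -> (dr, dc)
    illumination_field: np.ndarray       # mean-1 multiplicative field
    expression: pd.DataFrame             # cells x markers, type means
    scenes: dict[str, np.ndarray]        # marker -> noiseless unshifted scene
    structure_masks: dict[str, np.ndarray]
    autofluorescence: np.ndarray

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.cell_types:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def cropped(self, margin: int) -> "GroundTruth":
        """Ground truth restricted to the post-preprocessing cropped frame."""
        if margin == 0:
            return self
        sl = (slice(margin, -margin), slice(margin, -margin))
        return GroundTruth(
            cell_centers_px=self.cell_centers_px - margin,
            cell_types=self.cell_types,
            nucleus_labels=self.nucleus_labels[sl],
            cell_labels=self.cell_labels[sl],
            class_image=self.class_image[sl],
            shifts=self.shifts,
            illumination_field=self.illumination_field[sl],
            expression=self.expression,
            scenes={k: v[sl] for k, v in self.scenes.items()},
            structure_masks={k: v[sl] for k, v in self.structure_masks.items()},
            autofluorescence=self.autofluorescence[sl],
        )


def translate(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with zero fill (no wrap-around)."""
    out = np.zeros_like(img)
    h, w = img.shape[-2:]
    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rs_src = slice(max(-dr, 0), h + min(-dr, 0))
    cs_src = slice(max(-dc, 0), w + min(-dc, 0))
    out[..., rs, cs] = img[..., rs_src, cs_src]
    return out


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid placement guaranteeing >= 2*cell_radius center spacing."""
    h, w = spec.image_shape
    r_cell = spec.cell_radius_px
    min_spacing = 2.0 * r_cell
    jitter = 3.0
    pitch = min_spacing + 2 * jitter
    border = r_cell + 2.0
    rows = np.arange(border + jitter, h - border - jitter + 1e-9, pitch)
    cols = np.arange(border + jitter, w - border - jitter + 1e-9, pitch)
    sites = np.array([(r, c) for r in rows for c in cols])
    if len(sites) < spec.n_cells:
        raise PlacementError(
            f"cannot place {spec.n_cells} cells of radius {r_cell:.1f} px "
            f"in a {h}x{w} image ({len(sites)} sites available)"
        )
    order = rng.permutation(len(sites))[: spec.n_cells]
    chosen = sites[order]
    chosen += rng.uniform(-jitter, jitter, size=chosen.shape)
    return chosen


def _assign_types(spec: SceneSpec, rng: np.random.Generator) -> list[str]:
    """Deterministic counts by largest remainder, then a shuffled assignment."""
    n = spec.n_cells
    fracs = np.array([t.frequency * n for t in spec.cell_types])
    counts = np.floor(fracs).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(fracs - counts))
    counts[order[:remainder]] += 1
    # guarantee rare populations; steal from the most abundant types
    for i, t in enumerate(spec.cell_types):
        want = spec.min_type_counts.get(t.type_name, 0)
        while counts[i] < want:
            donor = int(np.argmax(counts))
            if donor == i or counts[donor] <= 1:
                raise PlacementError(f"cannot satisfy min count for {t.type_name}")
            counts[donor] -= 1
            counts[i] += 1
    labels: list[str] = []
    for t, k in zip(spec.cell_types, counts):
        labels.extend([t.type_name] * int(k))
    labels = list(np.array(labels)[rng.permutation(n)])
    return labels


def _paint_disks(shape, centers, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    r_int = int(np.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = yy**2 + xx**2 <= radius**2
    h, w = shape
    for (r, c) in centers:
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = max(ri - r_int, 0), min(ri + r_int + 1, h)
        c0, c1 = max(ci - r_int, 0), min(ci + r_int + 1, w)
        mask[r0:r1, c0:c1] |= disk[
            r0 - (ri - r_int) : disk.shape[0] - ((ri + r_int + 1) - r1),
            c0 - (ci - r_int) : disk.shape[1] - ((ci + r_int + 1) - c1),
        ]
    return mask


def _label_disks(shape, centers, radius) -> np.ndarray:
    """Non-overlapping disks labelled 1..n in cell order."""
    labels = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(centers, start=1):
        m = _paint_disks(shape, [(r, c)], radius)
        labels[m] = i
    return labels


def _fiber_mask(shape, rng: np.random.Generator, n_fibers: int) -> np.ndarray:
    """Smooth sinusoidal curves of ~2 px width spanning the image."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    t = np.arange(h)
    for _ in range(n_fibers):
        c0 = rng.uniform(0.15 * w, 0.85 * w)
        amp = rng.uniform(0.05 * w, 0.15 * w)
        period = rng.uniform(0.8 * h, 2.0 * h)
        phase = rng.uniform(0, 2 * np.pi)
        cols = c0 + amp * np.sin(2 * np.pi * t / period + phase)
        cols = np.clip(cols, 1, w - 2).astype(int)
        for dc in (-1, 0, 1):
            mask[t, np.clip(cols + dc, 0, w - 1)] = True
    return mask


def _illumination_field(shape, amplitude, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative Gaussian-bump field (not mean-normalized)."""
    h, w = shape
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    r0 = rng.uniform(0.25, 0.75) * h
    c0 = rng.uniform(0.25, 0.75) * w
    sigma = 0.45 * min(h, w)
    rr, cc = np.mgrid[0:h, 0:w]
    return 1.0 + amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


def simulate_run(spec: SceneSpec) -> tuple[MelcRun, GroundTruth]:
    """Render a full synthetic MELC run; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    markers = sorted(spec.panel, key=lambda m: (m.cycle_index, m.channel))
    marker_names = [m.name for m in spec.panel]

    if spec.cells is not None:
        centers = np.array([(r, c) for r, c, _ in spec.cells], dtype=float)
        types = [t for _, _, t in spec.cells]
        spec.n_cells = len(types)
    else:
        centers = _place_cells(spec, rng)
        types = _assign_types(spec, rng)

    nuc_labels = _label_disks(shape, centers, spec.nucleus_radius_px)
    cell_labels = _label_disks(shape, centers, spec.cell_radius_px)
    cell_mask = cell_labels > 0
    nuc_mask = nuc_labels > 0
    inner = _paint_disks(shape, centers, spec.cell_radius_px - 3.0)
    membrane_mask = cell_mask & ~inner
    class_image = np.full(shape, 3, dtype=np.int32)
    class_image[membrane_mask] = 2
    class_image[nuc_mask] = 1

    # per-cell expression = type means (exact, so noiseless recovery is exact)
    expr = pd.DataFrame(0.0, index=range(1, len(types) + 1), columns=marker_names)
    for i, tname in enumerate(types, start=1):
        tspec = spec.type_by_name(tname)
        for m, v in tspec.expression.items():
            expr.loc[i, m] = v

    structure_masks: dict[str, np.ndarray] = {}
    scenes: dict[str, np.ndarray] = {}
    for m in markers:
        scene = np.zeros(shape, dtype=np.float64)
        if m.localization == "structure":
            fmask = _fiber_mask(shape, rng, spec.n_fibers_per_structure)
            structure_masks[m.name] = fmask
            scene[fmask] = spec.structure_intensity
        else:
            vals = expr[m.name].to_numpy()
            if m.localization == "nuclear":
                scene = vals[np.maximum(nuc_labels - 1, 0)] * (nuc_labels > 0)
            else:  # membrane
                scene = vals[np.maximum(cell_labels - 1, 0)] * membrane_mask
        scenes[m.name] = scene

    autofluo = spec.autofluorescence_level * (0.5 + 0.5 * cell_mask.astype(np.float64))
    field_img = _illumination_field(shape, spec.illumination_amplitude, rng)

    zs = np.arange(-spec.z_steps, spec.z_steps + 1)

    def render_stack(base: np.ndarray, dr: int, dc: int) -> np.ndarray:
        planes = []
        for z in zs:
            sigma = spec.defocus_blur_sigma_per_z * abs(int(z))
            plane = ndimage.gaussian_filter(base, sigma) if sigma > 0 else base
            plane = field_img * translate(plane, dr, dc)
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.noise_sd, shape)
            # detector counts cannot go negative; the 16-bit ceiling only
            # applies when a run is written to disk
            planes.append(np.clip(plane, 0.0, None))
        return np.stack(planes)

    shifts = {c: tuple(spec.stage_shifts_px.get(c, (0, 0))) for c in
              sorted({m.cycle_index for m in markers})}

    blank = render_stack(autofluo, 0, 0)

    prev_in_channel: dict[str, np.ndarray] = {}
    cycles: list[CycleRecord] = []
    for m in markers:
        dr, dc = shifts[m.cycle_index]
        leftover = spec.bleach_residual_fraction * prev_in_channel.get(
            m.channel, np.zeros(shape)
        )
        fluo = render_stack(scenes[m.name] + leftover + autofluo, dr, dc)
        bleach = render_stack(
            spec.bleach_residual_fraction * scenes[m.name] + autofluo, dr, dc
        )
        cycles.append(CycleRecord(
            cycle_index=m.cycle_index,
            channel=m.channel,
            marker=m,
            fluorescence_zstack=fluo,
            bleach_zstack=bleach,
        ))
        prev_in_channel[m.channel] = scenes[m.name]

    # phase contrast shows cell bodies, nuclei and fibrous structures alike
    any_fibers = np.zeros(shape, dtype=bool)
    for fmask in structure_masks.values():
        any_fibers |= fmask
    reference = np.clip(
        0.15 + 0.45 * cell_mask + 0.25 * nuc_mask + 0.3 * any_fibers
        + rng.normal(0.0, 0.01, shape),
        0.0, 1.0,
    )

    run = MelcRun(
        reference_phase_contrast=reference,
        cycles=cycles,
        geometry=spec.geometry,
        panel=list(spec.panel),
        blank_bleach_zstack=blank,
    )
    truth = GroundTruth(
        cell_centers_px=centers,
        cell_types=list(types),
        nucleus_labels=nuc_labels,
        cell_labels=cell_labels,
        class_image=class_image,
        shifts=shifts,
        illumination_field=field_img,
        expression=expr,
        scenes=scenes,
        structure_masks=structure_masks,
        autofluorescence=autofluo,
    )
    return run, truth


# ---------------------------------------------------------------------------
# default tonsil-like study conditions

TONSIL_PANEL: list[MarkerSpec] = [
    MarkerSpec("DAPI", 1, "DAPI", "nuclear", "none"),
    MarkerSpec("CD45", 1, "PE", "membrane", "inclusion"),
    MarkerSpec("CD3", 1, "FITC", "membrane", "lineage_exclusion"),
    MarkerSpec("CD4", 2, "PE", "membrane", "exploratory"),
    MarkerSpec("CD8", 2, "FITC", "membrane", "exploratory"),
    MarkerSpec("CD19", 3, "PE", "membrane", "lineage_exclusion"),
    MarkerSpec("CD127", 3, "FITC", "membrane", "inclusion"),
    MarkerSpec("CD138", 4, "PE", "membrane", "exploratory"),
    MarkerSpec("CD14", 4, "FITC", "membrane", "lineage_exclusion"),
    MarkerSpec("CD31", 5, "PE", "membrane", "exploratory"),
    MarkerSpec("SMA", 5, "FITC", "structure", "none"),
    MarkerSpec("Fibronectin", 6, "PE", "structure", "none"),
]

# expression means leave headroom so that signal + autofluorescence + bleach
# residual times the brightest illumination never saturates the 16-bit range
TONSIL_TYPES: list[CellTypeSpec] = [
    CellTypeSpec("B", 0.28, {"DAPI": 0.65, "CD45": 0.55, "CD19": 0.60}),
    CellTypeSpec("T_helper", 0.20, {"DAPI": 0.65, "CD45": 0.55, "CD3": 0.60, "CD4": 0.50}),
    CellTypeSpec("T_cytotoxic", 0.12, {"DAPI": 0.65, "CD45": 0.55, "CD3": 0.60, "CD8": 0.50}),
    CellTypeSpec("plasma", 0.08, {"DAPI": 0.65, "CD138": 0.60}),
    CellTypeSpec("myeloid", 0.10, {"DAPI": 0.65, "CD45": 0.50, "CD14": 0.55}),
    CellTypeSpec("endothelial", 0.08, {"DAPI": 0.65, "CD31": 0.60}),
    CellTypeSpec("ILC", 0.02, {"DAPI": 0.65, "CD45": 0.55, "CD127": 0.60}),
    CellTypeSpec("other", 0.12, {"DAPI": 0.65}),
]


def default_tonsil_like_spec(
    seed: int,
    *,
    image_shape: tuple[int, int] = (512, 512),
    n_cells: int = 150,
    noise_sd: float = 0.05,
    illumination_amplitude: float = 0.25,
    autofluorescence_level: float = 0.12,
    bleach_residual_fraction: float = 0.10,
    max_shift_px: int = 8,
    z_steps: int = 2,
) -> SceneSpec:
    """Miniature tonsil-like scene: 8 cell types incl. rare Lin- CD45+ CD127+
    ILCs, a 12-marker panel over 6 cycles, and every acquisition corruption
    (shifts, uneven illumination, autofluorescence, bleach residual, noise)
    switched on at realistic levels.  At least two ILCs are always present.
    """
    rng = np.random.default_rng(seed)
    n_cycles = max(m.cycle_index for m in TONSIL_PANEL)
    shifts = {
        c: (int(rng.integers(-max_shift_px, max_shift_px + 1)),
            int(rng.integers(-max_shift_px, max_shift_px + 1)))
        for c in range(1, n_cycles + 1)
    }
    spec = SceneSpec(
        image_shape=image_shape,
        n_cells=n_cells,
        cell_types=list(TONSIL_TYPES),
        panel=list(TONSIL_PANEL),
        z_steps=z_steps,
        illumination_amplitude=illumination_amplitude,
        autofluorescence_level=autofluorescence_level,
        bleach_residual_fraction=bleach_residual_fraction,
        stage_shifts_px=shifts,
        noise_sd=noise_sd,
        seed=seed,
        min_type_counts={"ILC": 2},
    )
    return spec


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist ground truth next to a written run (JSON + label TIFFs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "cell_centers_px": truth.cell_centers_px.tolist(),
        "cell_types": truth.cell_types,
        "shifts": {str(k): list(v) for k, v in truth.shifts.items()},
        "expression": truth.expression.to_dict(orient="list"),
    }
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(payload, fh)
    write_image(path / "truth_nucleus_labels.tif", truth.nucleus_labels.astype(np.int32))
    write_image(path / "truth_cell_labels.tif", truth.cell_labels.astype(np.int32))
    write_image(path / "truth_class_image.tif", truth.class_image.astype(np.int32))
    write_image(path / "truth_illumination.tif", truth.illumination_field.astype(np.float32))


def write_simulated_run(spec: SceneSpec, path: str | Path) -> tuple[MelcRun, GroundTruth]:
    run, truth = simulate_run(spec)
    write_run(run, path)
    write_ground_truth(truth, path)
    return run, truth
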