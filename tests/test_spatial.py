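"""Niche composition vs brute-force oracles, structure proximity,
compartment segmentation and assignment."""

import numpy as np
import pandas as pd
import pytest

from melchist.io import AcquisitionGeometry, CellTable, ConfigError
from melchist.spatial import (
    CompartmentMap,
    NicheParams,
    assign_compartments,
    build_niches,
    niche_enrichment,
    radius_px,
    segment_compartments,
    structure_proximity,
)
from melchist.synthetic import default_tonsil_like_spec, simulate_run

GEOM = AcquisitionGeometry(image_shape=(128, 128))


def table_from_truth(truth, type_override=None) -> CellTable:
    types = type_override if type_override is not None else truth.cell_types
    df = pd.DataFrame({
        "cell_id": np.arange(1, len(types) + 1),
        "centroid_row": truth.cell_centers_px[:, 0],
        "centroid_col": truth.cell_centers_px[:, 1],
        "centroid_y_um": truth.cell_centers_px[:, 0] * 0.325,
        "centroid_x_um": truth.cell_centers_px[:, 1] * 0.325,
        "area_px": 10,
        "mfi_CD45": 0.5,
        "gated_type": list(types),
    })
    return CellTable(df=df, markers=["CD45"])


def brute_force_composition(cells, table, seed_id, r_px, membership):
    """O(N^2) oracle: exact Euclidean distances from every candidate to the
    seed mask."""
    seed_px = np.argwhere(cells == seed_id)
    comp = {}
    members = []
    for row in table.df.itertuples():
        if row.cell_id == seed_id:
            continue
        if membership == "centroid_in_region":
            p = np.array([[round(row.centroid_row), round(row.centroid_col)]])
        else:
            p = np.argwhere(cells == row.cell_id)
        d = np.sqrt(((p[:, None, :] - seed_px[None, :, :]) ** 2).sum(-1)).min()
        if d <= r_px:
            members.append(row.cell_id)
            comp[row.gated_type] = comp.get(row.gated_type, 0) + 1
    return members, comp


@pytest.fixture(scope="module")
def small_scene():
    spec = default_tonsil_like_spec(55, image_shape=(128, 128), n_cells=9,
                                    noise_sd=0.0, max_shift_px=0)
    spec.stage_shifts_px = {}
    _, truth = simulate_run(spec)
    return truth


class TestBuildNiches:
    @pytest.mark.parametrize("membership", ["centroid_in_region", "any_overlap"])
    def test_matches_brute_force_oracle(self, small_scene, membership):
        truth = small_scene
        table = table_from_truth(truth)
        seed_type = truth.cell_types[0]
        params = NicheParams(membership=membership)
        niches = build_niches(truth.cell_labels, table, seed_type, params, GEOM)
        assert len(niches) == truth.cell_types.count(seed_type)
        r = radius_px(10.0, GEOM)
        for n in niches:
            members, comp = brute_force_composition(
                truth.cell_labels, table, n.seed_cell_id, r, membership)
            assert sorted(n.member_cell_ids) == sorted(members)
            assert n.composition == comp

    def test_single_pixel_seed_area_matches_disk(self):
        cells = np.zeros((128, 128), dtype=np.int32)
        cells[64, 64] = 1
        df = pd.DataFrame({
            "cell_id": [1], "centroid_row": [64.0], "centroid_col": [64.0],
            "centroid_y_um": [64 * 0.325], "centroid_x_um": [64 * 0.325],
            "area_px": [1], "mfi_CD45": [0.5], "gated_type": ["ILC"],
        })
        table = CellTable(df=df, markers=["CD45"])
        niches = build_niches(cells, table, "ILC", NicheParams(), GEOM)
        r = radius_px(10.0, GEOM)
        assert r == 31
        area = niches[0].region.sum()
        assert abs(area - np.pi * r**2) <= 0.02 * np.pi * r**2

    def test_isolated_seed_has_empty_composition(self):
        cells = np.zeros((128, 128), dtype=np.int32)
        cells[10:14, 10:14] = 1
        cells[100:104, 100:104] = 2
        df = pd.DataFrame({
            "cell_id": [1, 2], "centroid_row": [12.0, 102.0],
            "centroid_col": [12.0, 102.0], "centroid_y_um": [0.0, 0.0],
            "centroid_x_um": [0.0, 0.0], "area_px": [16, 16],
            "mfi_CD45": [0.5, 0.5], "gated_type": ["ILC", "B"],
        })
        niches = build_niches(cells, CellTable(df=df, markers=["CD45"]),
                              "ILC", NicheParams(), GEOM)
        assert niches[0].composition == {}
        assert niches[0].member_cell_ids == []

    def test_no_seeds_warns_and_returns_empty(self, small_scene):
        table = table_from_truth(small_scene,
                                 type_override=["B"] * len(small_scene.cell_types))
        with pytest.warns(UserWarning, match="no cells"):
            out = build_niches(small_scene.cell_labels, table, "ILC",
                               NicheParams(), GEOM)
        assert out == []


class TestNicheEnrichment:
    def test_uniform_placement_matches_tissue_frequencies(self):
        """Under random type assignment, pooled niche frequencies agree with
        tissue frequencies within 3 binomial SDs."""
        rng = np.random.default_rng(99)
        n = 400
        shape = (512, 512)
        centers = np.stack([rng.uniform(5, shape[0] - 5, n),
                            rng.uniform(5, shape[1] - 5, n)], axis=1)
        # rare seed population (like ILCs) among abundant bystanders
        types = rng.choice(["seed", "A", "B", "C"], size=n,
                           p=[0.05, 0.475, 0.285, 0.19])
        cells = np.zeros(shape, dtype=np.int32)
        for i, (r, c) in enumerate(centers, start=1):
            cells[int(r), int(c)] = i
        df = pd.DataFrame({
            "cell_id": np.arange(1, n + 1),
            "centroid_row": centers[:, 0], "centroid_col": centers[:, 1],
            "centroid_y_um": 0.0, "centroid_x_um": 0.0, "area_px": 1,
            "mfi_CD45": 0.5, "gated_type": types,
        })
        table = CellTable(df=df, markers=["CD45"])
        geom = AcquisitionGeometry(image_shape=shape)
        niches = build_niches(cells, table, "seed", NicheParams(radius_um=20), geom)
        enrich = niche_enrichment(niches, table)
        n_members = sum(sum(x.composition.values()) for x in niches)
        assert n_members >= 50
        for t in ("A", "B", "C"):
            p = enrich.loc[t, "whole_tissue_freq"]
            sd = np.sqrt(p * (1 - p) / n_members)
            assert abs(enrich.loc[t, "niche_freq"] - p) <= 3 * sd

    def test_single_niche_single_member(self):
        cells = np.zeros((128, 128), dtype=np.int32)
        cells[60:64, 60:64] = 1
        cells[60:64, 70:74] = 2
        df = pd.DataFrame({
            "cell_id": [1, 2], "centroid_row": [62.0, 62.0],
            "centroid_col": [62.0, 72.0], "centroid_y_um": 0.0,
            "centroid_x_um": 0.0, "area_px": 16, "mfi_CD45": 0.5,
            "gated_type": ["ILC", "plasma"],
        })
        table = CellTable(df=df, markers=["CD45"])
        niches = build_niches(cells, table, "ILC", NicheParams(), GEOM)
        enrich = niche_enrichment(niches, table)
        assert enrich.loc["plasma", "niche_freq"] == 1.0

    def test_constructed_enrichment_detected(self):
        """Plasma cells placed right next to ILC seeds are enriched."""
        spec = default_tonsil_like_spec(0, image_shape=(256, 256), n_cells=2)
        cells_list = [(60.0, 60.0, "ILC"), (60.0, 85.0, "plasma"),
                      (200.0, 200.0, "ILC"), (200.0, 225.0, "plasma")]
        # distant background of B cells
        for k, r in enumerate(range(30, 230, 40)):
            cells_list.append((float(r), 150.0, "B"))
        spec.cells = cells_list
        _, truth = simulate_run(spec)
        table = table_from_truth(truth)
        geom = AcquisitionGeometry(image_shape=(256, 256))
        niches = build_niches(truth.cell_labels, table, "ILC",
                              NicheParams(), geom)
        enrich = niche_enrichment(niches, table)
        assert enrich.loc["plasma", "niche_freq"] > enrich.loc["plasma", "whole_tissue_freq"]


class TestStructureProximity:
    def test_overlapping_cell_counted_distance_zero(self, small_scene):
        truth = small_scene
        table = table_from_truth(truth)
        mask = truth.cell_labels == 1
        out = structure_proximity(table, {"s": mask}, truth.cell_labels,
                                  NicheParams(), GEOM)
        assert out["s"] > 0

    def test_far_cell_not_counted(self):
        cells = np.zeros((128, 128), dtype=np.int32)
        cells[10:14, 10:14] = 1
        mask = np.zeros((128, 128), dtype=bool)
        mask[120:, 120:] = True  # ~150 px away >> 31 px
        df = pd.DataFrame({
            "cell_id": [1], "centroid_row": [12.0], "centroid_col": [12.0],
            "centroid_y_um": 0.0, "centroid_x_um": 0.0, "area_px": 16,
            "mfi_CD45": 0.5, "gated_type": ["ILC"],
        })
        out = structure_proximity(CellTable(df=df, markers=["CD45"]),
                                  {"s": mask}, cells, NicheParams(), GEOM)
        assert out["s"] == 0.0

    def test_matches_brute_force_distances(self, small_scene):
        truth = small_scene
        table = table_from_truth(truth)
        mask = truth.structure_masks["Fibronectin"]
        params = NicheParams(structure_distance_um=6.0)
        out = structure_proximity(table, {"f": mask}, truth.cell_labels,
                                  params, GEOM)
        mask_px = np.argwhere(mask)
        hits = 0
        ids = table.df["cell_id"].tolist()
        for cid in ids:
            cell_px = np.argwhere(truth.cell_labels == cid)
            d = np.sqrt(((cell_px[:, None, :] - mask_px[None, :, :]) ** 2)
                        .sum(-1)).min()
            hits += d <= 6.0 / 0.325
        assert out["f"] == pytest.approx(hits / len(ids))

    def test_monotone_in_distance(self, small_scene):
        truth = small_scene
        table = table_from_truth(truth)
        mask = truth.structure_masks["SMA"]
        fracs = [
            structure_proximity(table, {"s": mask}, truth.cell_labels,
                                NicheParams(structure_distance_um=d), GEOM)["s"]
            for d in (2.0, 5.0, 10.0, 20.0)
        ]
        assert fracs == sorted(fracs)

    def test_empty_mask_warns_zero(self, small_scene):
        table = table_from_truth(small_scene)
        with pytest.warns(UserWarning, match="empty"):
            out = structure_proximity(table, {"s": np.zeros((128, 128), bool)},
                                      small_scene.cell_labels, NicheParams(), GEOM)
        assert out["s"] == 0.0


class TestCompartments:
    def test_blob_becomes_follicle_with_border_ring(self):
        shape = (192, 192)
        rr, cc = np.mgrid[0:192, 0:192]
        blob = ((rr - 96) ** 2 + (cc - 96) ** 2 <= 40**2).astype(float)
        imgs = {"CD19": blob, "CD3": np.zeros(shape)}
        geom = AcquisitionGeometry(image_shape=shape)
        comp = segment_compartments(imgs, {"follicle": ["CD19"], "t_zone": ["CD3"]},
                                    geometry=geom, smooth_sigma_um=3.0,
                                    score_floor=0.3)
        follicle = comp.label_of("follicle")
        border = comp.label_of("follicle_border")
        assert comp.labels[96, 96] == follicle
        # a point just outside the follicle core lies in the border band
        edge = np.argwhere(comp.labels == follicle)
        rmax = np.abs(edge - 96).max()
        assert comp.labels[96, 96 + rmax + 5] == border

    def test_all_scores_below_floor_unassigned(self):
        imgs = {"CD19": np.zeros((96, 96))}
        comp = segment_compartments(imgs, {"follicle": ["CD19"]},
                                    geometry=AcquisitionGeometry(image_shape=(96, 96)),
                                    score_floor=0.1)
        assert (comp.labels == 0).all()

    def test_compartments_disjoint(self):
        rng = np.random.default_rng(3)
        imgs = {"CD19": rng.random((96, 96)), "CD3": rng.random((96, 96))}
        comp = segment_compartments(imgs, {"follicle": ["CD19"], "t_zone": ["CD3"]},
                                    geometry=AcquisitionGeometry(image_shape=(96, 96)),
                                    border_of=None)
        assert set(np.unique(comp.labels)) <= {0, 1, 2}

    def test_empty_marker_list_is_config_error(self):
        with pytest.raises(ConfigError, match="no defining markers"):
            segment_compartments({"CD19": np.zeros((96, 96))}, {"follicle": []})


class TestAssignCompartments:
    @staticmethod
    def comp_map(shape=(128, 128)):
        labels = np.zeros(shape, dtype=np.int32)
        labels[:, :64] = 1   # septum on the left
        labels[:, 64:] = 2   # follicle on the right
        return CompartmentMap(labels=labels, names={1: "septum", 2: "follicle"})

    def test_centroid_determines_compartment(self):
        comp = self.comp_map()
        df = pd.DataFrame({
            "cell_id": [1, 2], "centroid_row": [10.0, 10.0],
            "centroid_col": [10.0, 100.0], "centroid_y_um": 0.0,
            "centroid_x_um": 0.0, "area_px": 4, "mfi_CD45": 0.5,
            "gated_type": ["ILC", "B"],
        })
        out, _ = assign_compartments(CellTable(df=df, markers=["CD45"]), comp)
        assert out.df["compartment"].tolist() == ["septum", "follicle"]

    def test_all_ilcs_in_septum_distribution_is_one(self):
        comp = self.comp_map()
        df = pd.DataFrame({
            "cell_id": [1, 2, 3], "centroid_row": [10.0, 50.0, 100.0],
            "centroid_col": [10.0, 30.0, 100.0], "centroid_y_um": 0.0,
            "centroid_x_um": 0.0, "area_px": 4, "mfi_CD45": 0.5,
            "gated_type": ["ILC", "ILC", "B"],
        })
        _, dist = assign_compartments(CellTable(df=df, markers=["CD45"]),
                                      comp, seed_type="ILC")
        assert dist == {"septum": 1.0}

    def test_unassigned_excluded_from_distribution(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[:32] = 1
        comp = CompartmentMap(labels=labels, names={1: "septum"})
        df = pd.DataFrame({
            "cell_id": [1, 2], "centroid_row": [10.0, 50.0],
            "centroid_col": [10.0, 50.0], "centroid_y_um": 0.0,
            "centroid_x_um": 0.0, "area_px": 4, "mfi_CD45": 0.5,
            "gated_type": ["ILC", "ILC"],
        })
        out, dist = assign_compartments(CellTable(df=df, markers=["CD45"]),
                                        comp, seed_type="ILC")
        assert out.df["compartment"].tolist() == ["septum", "unassigned"]
        assert dist == {"septum": 1.0}
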