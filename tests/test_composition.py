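import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from benthomap.composition import (
    BhtClass,
    CompositionConfig,
    OHT_CATEGORIES,
    OhtCategory,
    area_summary,
    build_hub_layer,
    build_oht_layer,
    compose_bht,
    compose_bht_grid,
    detect_species_rich,
    eliminate_small_patches,
    intersect_endo_epi,
    polygon_mask,
    rasterize_majority,
    rasterize_polygon_majority,
)
from benthomap.hardbottom import GridGeometry
from benthomap.sediment import EunisSubstrate


def make_grid(n=10, cell=1000.0):
    return GridGeometry(x0=0.0, y0=n * cell, cell_size=cell, n_rows=n, n_cols=n)


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def test_majority_rule():
    fine = np.empty((2, 2), dtype=object)
    fine[:] = "sand"
    fine[0, 0] = "mud"
    out = rasterize_majority(fine, factor=2)
    assert out[0, 0] == "sand"


def test_majority_tie_harder_wins():
    fine = np.array(
        [["sand", "sand"], ["mixed_sediment_hard", "mixed_sediment_hard"]], dtype=object
    )
    out = rasterize_majority(fine, factor=2)
    assert out[0, 0] == "mixed_sediment_hard"


def test_majority_single_class_identity():
    fine = np.full((4, 4), "mud", dtype=object)
    out = rasterize_majority(fine, factor=2)
    assert (out == "mud").all()


def test_majority_gap_is_na(caplog):
    fine = np.full((2, 2), None, dtype=object)
    with caplog.at_level("WARNING"):
        out = rasterize_majority(fine, factor=2)
    assert out[0, 0] is None


def test_polygon_majority_areal_share():
    grid = make_grid(n=2, cell=100.0)
    left = box(0, 0, 120, 200)  # covers col 0 plus 20 % of col 1
    right = box(120, 0, 200, 200)
    out = rasterize_polygon_majority([(left, "sand"), (right, "mud")], grid)
    assert out[0, 0] == "sand" and out[0, 1] == "mud"


def test_polygon_majority_repairs_invalid(caplog):
    bowtie = Polygon([(0, 0), (200, 200), (200, 0), (0, 200)])
    grid = make_grid(n=2, cell=100.0)
    with caplog.at_level("WARNING"):
        out = rasterize_polygon_majority([(bowtie, "sand")], grid)
    assert "repaired" in caplog.text


# ---------------------------------------------------------------------------
# BHT composition
# ---------------------------------------------------------------------------

def test_compose_bht_examples():
    assert str(compose_bht(True, EunisSubstrate.SAND)) == "Infralittoral sand"
    assert str(compose_bht(False, EunisSubstrate.MUD)) == "Circalittoral mud"
    got = compose_bht(True, EunisSubstrate.SAND, peat_with_mussels=True)
    assert str(got) == "Infralittoral rock and biogenic reef"


def test_bht_vocabulary():
    with pytest.raises(ValueError):
        BhtClass(zone="abyssal", substrate=EunisSubstrate.MUD)


def test_compose_bht_grid_na_passthrough():
    substrate = np.array([["sand", None]], dtype=object)
    photic = np.array([[True, True]])
    out = compose_bht_grid(photic, substrate)
    assert out[0, 0] == "Infralittoral sand" and out[0, 1] is None


# ---------------------------------------------------------------------------
# Patch elimination
# ---------------------------------------------------------------------------

def patch_grid(k, n=20):
    grid = np.full((n, n), "bg", dtype=object)
    rr, cc = divmod(np.arange(k), n)
    grid[5 + rr, 5 + cc] = "patch"
    return grid


def test_three_cells_at_50m_merged():
    out = eliminate_small_patches(patch_grid(3), cell_size_m=50.0)
    assert not (out == "patch").any()


def test_four_cells_at_50m_retained():
    out = eliminate_small_patches(patch_grid(4), cell_size_m=50.0)
    assert (out == "patch").sum() == 4


def test_any_patch_at_1km_retained():
    out = eliminate_small_patches(patch_grid(1), cell_size_m=1000.0)
    assert (out == "patch").sum() == 1


def test_elimination_conserves_cells_and_labels(rng):
    labels = np.array(["a", "b", "c"], dtype=object)[
        rng.integers(0, 3, size=(15, 15))
    ]
    out = eliminate_small_patches(labels, cell_size_m=50.0)
    assert out.shape == labels.shape
    assert all(v is not None for v in out.ravel())
    assert set(out.ravel()) <= set(labels.ravel())


def test_isolated_patch_without_neighbour_kept():
    grid = np.full((3, 3), None, dtype=object)
    grid[1, 1] = "only"
    out = eliminate_small_patches(grid, cell_size_m=50.0)
    assert out[1, 1] == "only"


def test_four_connectivity():
    # two diagonal cells are two patches of 1 (0.25 ha each), not one of 2
    grid = np.full((10, 10), "bg", dtype=object)
    grid[2, 2] = grid[3, 3] = "p"
    out = eliminate_small_patches(grid, cell_size_m=50.0)
    assert not (out == "p").any()


# ---------------------------------------------------------------------------
# Endo/epi intersection and HUB layer
# ---------------------------------------------------------------------------

def test_intersection_rules():
    assert intersect_endo_epi("3L9", "1E1", hard=True) == "1E1"
    assert intersect_endo_epi("3L9", None, hard=False) == "3L9"
    assert intersect_endo_epi("3L9", None, hard=True) is None


def hub_inputs():
    substrate = np.array([["sand", "mixed_sediment_hard"]], dtype=object)
    photic = np.array([[True, False]])
    hard = np.array([[False, True]])
    endo = np.array([["3L9", "3L3"]], dtype=object)
    epi = np.array([[None, "2T"]], dtype=object)
    return substrate, photic, hard, endo, epi


def test_build_hub_layer_examples():
    codes, table = build_hub_layer(*hub_inputs(), cell_area_km2=1.0)
    assert codes[0, 0] == "AA.J3L9"
    assert codes[0, 1] == "AB.M2T"
    assert table["area_km2"].sum() == 2.0


def test_hub_layer_peat_union():
    substrate, photic, hard, endo, epi = hub_inputs()
    peat = np.array([[True, False]])
    codes, _ = build_hub_layer(substrate, photic, hard, endo, epi, peat=peat)
    assert codes[0, 0] == "AA.G+AA.J3L9"


def test_hub_layer_na_propagation():
    substrate = np.array([[None, "sand"]], dtype=object)
    photic = np.array([[True, True]])
    hard = np.array([[False, True]])
    endo = np.array([["3L9", "3L9"]], dtype=object)
    epi = np.array([[None, None]], dtype=object)
    codes, table = build_hub_layer(substrate, photic, hard, endo, epi)
    assert codes[0, 0] is None  # sediment NA
    assert codes[0, 1] is None  # hard cell without epi prediction
    assert len(table) == 0


def test_hub_zone_and_substrate_congruent_with_bht(small_seascape):
    """Congruence invariant on a synthetic fixture."""
    from benthomap.pipeline import PipelineConfig, run_pipeline

    res = run_pipeline(PipelineConfig(out_dir="scratch/congruence", seed=3,
                                      n_grab=120, n_video=60))
    bht, hub = res["bht"], res["hub"]
    letter_to_bht = {"H": "mud", "J": "sand", "I": "coarse sediment",
                     "M": "mixed sediment (hard substrate)"}
    for idx in np.ndindex(hub.shape):
        code = hub[idx]
        if code is None or bht[idx] is None or "+" in code:
            continue
        zone, rest = code.split(".")
        expected_zone = "Infralittoral" if zone == "AA" else "Circalittoral"
        assert str(bht[idx]).startswith(expected_zone)
        if rest[0] in letter_to_bht:
            assert letter_to_bht[rest[0]] in str(bht[idx])


# ---------------------------------------------------------------------------
# OHT layer
# ---------------------------------------------------------------------------

def test_oht_vocabulary_of_five():
    assert len(OHT_CATEGORIES) == 5
    with pytest.raises(ValueError):
        OhtCategory("kelp_forest")


def test_arctica_cells_from_hub_code():
    grid = make_grid(n=2)
    codes = np.array([["AB.H3L3", "AA.J3L9"], ["AB.H3L3", None]], dtype=object)
    layer, table = build_oht_layer(codes, grid)
    assert layer["arctica_aphotic_mud"].sum() == 2


def test_seagrass_inclusion_thresholds():
    grid = make_grid(n=2)
    codes = np.full((2, 2), None, dtype=object)
    prob = np.array([[0.55, 0.40], [0.10, 0.49]])
    dens = np.array([[0.0, 5.0], [12.0, 0.0]])
    layer, _ = build_oht_layer(codes, grid, seagrass_probability=prob, seagrass_density=dens)
    sg = layer["seagrass_macrophytes"]
    assert sg[0, 0]  # probability 55 % >= 50
    assert not sg[0, 1]  # 40 % and 5/m2: neither criterion
    assert sg[1, 0]  # density 12/m2 >= 10
    assert not sg[1, 1]  # 49 % just below


def test_reef_takes_precedence_over_species_rich():
    grid = make_grid(n=4, cell=1000.0)
    codes = np.full((4, 4), None, dtype=object)
    reef = box(0.0, 2000.0, 2000.0, 4000.0)  # covers rows 0-1, cols 0-1
    sr = np.zeros((4, 4), dtype=bool)
    sr[0, 0] = sr[3, 3] = True
    layer, table = build_oht_layer(codes, grid, reef_polygons=[reef], species_rich_mask=sr)
    assert not layer["species_rich_gravel"][0, 0]  # ceded to the reef
    assert layer["species_rich_gravel"][3, 3]
    overlap = layer["species_rich_gravel"] & polygon_mask(layer["reefs_1170"], grid)
    assert not overlap.any()


def test_polygon_area_exact_not_gridded():
    grid = make_grid(n=4, cell=1000.0)
    codes = np.full((4, 4), None, dtype=object)
    tri = Polygon([(0, 0), (3000, 0), (0, 3000)])

    def shoelace(coords):
        s = 0.0
        for (x1, y1), (x2, y2) in zip(coords, coords[1:]):
            s += x1 * y2 - x2 * y1
        return abs(s) / 2.0

    _, table = build_oht_layer(codes, grid, reef_polygons=[tri])
    reef_km2 = float(table.loc[table["class"] == "reefs_1170", "area_km2"].iloc[0])
    expected = shoelace(list(tri.exterior.coords)) / 1e6
    assert reef_km2 == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Species-rich detection
# ---------------------------------------------------------------------------

def sr_stations(rows):
    return pd.DataFrame(
        rows, columns=["station_id", "row", "col", "single_pct", "combined_pct"]
    )


def test_species_rich_three_stations_candidate():
    eligible = np.ones((5, 5), dtype=bool)
    st = sr_stations([("s1", 0, 0, 12.0, 0.0), ("s2", 1, 1, 15.0, 0.0), ("s3", 2, 2, 11.0, 0.0)])
    out = detect_species_rich(st, eligible)
    assert out["candidate"] and out["n_qualifying_stations"] == 3


def test_species_rich_two_stations_not_candidate():
    eligible = np.ones((5, 5), dtype=bool)
    st = sr_stations([("s1", 0, 0, 12.0, 0.0), ("s2", 1, 1, 15.0, 0.0)])
    assert not detect_species_rich(st, eligible)["candidate"]


def test_species_rich_combined_share_rule():
    eligible = np.ones((5, 5), dtype=bool)
    st = sr_stations([("s1", 0, 0, 4.0, 5.0), ("s2", 1, 1, 3.0, 6.0), ("s3", 2, 2, 2.0, 5.5)])
    assert detect_species_rich(st, eligible)["candidate"]


def test_species_rich_substrate_test_reported_separately():
    eligible = np.ones((2, 2), dtype=bool)
    st = sr_stations([("s1", 0, 0, 12.0, 0.0), ("s2", 0, 1, 15.0, 0.0), ("s3", 1, 0, 11.0, 0.0)])
    shares = pd.DataFrame({"gravel_coarse_shell_pct": [40.0, 45.0]})
    out = detect_species_rich(st, eligible, sediment_shares=shares)
    assert out["candidate"] is True
    assert out["substrate_designation_met"] is False


# ---------------------------------------------------------------------------
# Area accounting
# ---------------------------------------------------------------------------

def test_area_summary_arithmetic():
    labels = np.array([["sand"] * 6 + ["mud"] * 4] * 10, dtype=object)
    table = area_summary(labels, cell_area_km2=1.0)
    sand = table[table["class"] == "sand"].iloc[0]
    assert sand["area_km2"] == 60.0 and sand["area_pct"] == pytest.approx(60.0)


def test_area_percentages_sum_to_100(small_seascape):
    table = area_summary(small_seascape.sediment, cell_area_km2=1.0)
    assert table["area_pct"].sum() == pytest.approx(100.0, abs=0.2)


def test_area_summary_order_invariant(rng):
    labels = np.array(["a", "b", "c"], dtype=object)[rng.integers(0, 3, size=(8, 8))]
    t1 = area_summary(labels, cell_area_km2=1.0)
    t2 = area_summary(labels.T.copy(), cell_area_km2=1.0)
    pd.testing.assert_frame_equal(t1, t2)


def test_empty_layer_empty_table():
    table = area_summary(np.full((3, 3), None, dtype=object), cell_area_km2=1.0)
    assert len(table) == 0


def test_config_constants():
    cfg = CompositionConfig()
    assert cfg.min_patch_ha == 1.0
    assert cfg.seagrass_probability_pct == 50.0
    assert cfg.seagrass_density_per_m2 == 10.0
    assert cfg.confidence_pct == 67.0
    assert cfg.species_rich_min_stations == 3
    assert cfg.species_rich_single_pct == 10.0
    assert cfg.species_rich_combined_pct == 5.0
    assert cfg.species_rich_substrate_pct == 50.0
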