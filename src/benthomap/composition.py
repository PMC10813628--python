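"""Composition of the BHT, OHT and HUB map layers with area accounting.

The broad-habitat layer combines zone (photic -> infralittoral, aphotic
-> circalittoral) with the attributed substrate and is generalised by
removing patches under one hectare.  The biotope (HUB) layer intersects
the endo- and epibenthic predictions (epi wins on hard-substrate cells)
and completes codes with substrate and zone; it is never generalised.
The other-habitat layer carries polygon habitats through unchanged and
adds rule-derived categories, with reefs taking precedence over
species-rich gravel areas.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .hub import compose_hub
from .sediment import EunisSubstrate

__all__ = [
    "BhtClass",
    "OhtCategory",
    "CompositionConfig",
    "rasterize_majority",
    "rasterize_polygon_majority",
    "compose_bht",
    "compose_bht_grid",
    "eliminate_small_patches",
    "intersect_endo_epi",
    "build_hub_layer",
    "build_oht_layer",
    "detect_species_rich",
    "area_summary",
    "polygon_mask",
    "OHT_CATEGORIES",
]

log = logging.getLogger(__name__)

# harder substrate wins ties in majority rasterisation
_SUBSTRATE_HARDNESS = {
    EunisSubstrate.MUD: 0,
    EunisSubstrate.SAND: 1,
    EunisSubstrate.COARSE_SEDIMENT: 2,
    EunisSubstrate.MIXED_SEDIMENT_HARD: 3,
    EunisSubstrate.ROCK_BIOGENIC_REEF: 4,
}

OHT_CATEGORIES = (
    "reefs_1170",
    "sandbanks_1110",
    "seagrass_macrophytes",
    "species_rich_gravel",
    "arctica_aphotic_mud",
)


def _hardness(value) -> int:
    try:
        return _SUBSTRATE_HARDNESS[EunisSubstrate(value)]
    except (ValueError, KeyError):
        return -1


@dataclass(frozen=True)
class BhtClass:
    """zone x substrate broad habitat type."""

    zone: str  # "infralittoral" or "circalittoral"
    substrate: EunisSubstrate

    def __post_init__(self):
        if self.zone not in ("infralittoral", "circalittoral"):
            raise ValueError(f"unknown zone {self.zone!r}")

    def __str__(self) -> str:
        names = {
            EunisSubstrate.MUD: "mud",
            EunisSubstrate.SAND: "sand",
            EunisSubstrate.COARSE_SEDIMENT: "coarse sediment",
            EunisSubstrate.MIXED_SEDIMENT_HARD: "mixed sediment (hard substrate)",
            EunisSubstrate.ROCK_BIOGENIC_REEF: "rock and biogenic reef",
        }
        return f"{self.zone.capitalize()} {names[self.substrate]}"


@dataclass(frozen=True)
class OhtCategory:
    name: str

    def __post_init__(self):
        if self.name not in OHT_CATEGORIES:
            raise ValueError(
                f"unknown OHT category {self.name!r}; vocabulary: {OHT_CATEGORIES}"
            )


@dataclass(frozen=True)
class CompositionConfig:
    """Fixed thresholds of the layering and generalisation rules."""

    min_patch_ha: float = 1.0  # BHT layer only
    seagrass_probability_pct: float = 50.0
    seagrass_density_per_m2: float = 10.0
    confidence_pct: float = 67.0
    species_rich_min_stations: int = 3
    species_rich_single_pct: float = 10.0
    species_rich_combined_pct: float = 5.0
    species_rich_substrate_pct: float = 50.0


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def rasterize_majority(fine: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a fine categorical grid to a coarser one by areal
    majority; ties go to the harder substrate."""
    if factor <= 0:
        raise ValueError("aggregation factor must be positive")
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        raise ValueError("fine grid shape must be a multiple of the factor")
    out = np.empty((nr // factor, nc // factor), dtype=object)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = fine[i * factor:(i + 1) * factor, j * factor:(j + 1) * factor]
            values = [v for v in block.ravel() if v is not None]
            if not values:
                out[i, j] = None
                log.warning("coverage gap at coarse cell (%d, %d)", i, j)
                continue
            counts = Counter(values)
            best = max(counts.values())
            tied = [v for v, c in counts.items() if c == best]
            out[i, j] = max(tied, key=_hardness)
    return out


def polygon_mask(geometry: BaseGeometry, grid) -> np.ndarray:
    """Boolean mask of cells whose centre lies in the geometry."""
    from shapely.geometry import Point
    from shapely.prepared import prep

    xx, yy = grid.cell_centres()
    prepared = prep(geometry)
    mask = np.zeros(xx.shape, dtype=bool)
    for idx in np.ndindex(xx.shape):
        mask[idx] = prepared.contains(Point(xx[idx], yy[idx]))
    return mask


def rasterize_polygon_majority(
    polygons: list[tuple[BaseGeometry, str]], grid
) -> np.ndarray:
    """Attribute each cell the class of greatest areal overlap among the
    (geometry, class) pairs; ties go to the harder substrate."""
    from shapely.geometry import box

    out = np.full((grid.n_rows, grid.n_cols), None, dtype=object)
    repaired = []
    for geom, cls in polygons:
        if not geom.is_valid:
            geom = make_valid(geom)
            log.warning("repaired invalid polygon for class %r", cls)
        repaired.append((geom, cls))
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            x0 = grid.x0 + col * grid.cell_size
            y1 = grid.y0 - row * grid.cell_size
            cell = box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
            shares: dict[str, float] = {}
            for geom, cls in repaired:
                a = cell.intersection(geom).area
                if a > 0:
                    shares[cls] = shares.get(cls, 0.0) + a
            if not shares:
                log.warning("coverage gap at cell (%d, %d)", row, col)
                continue
            best = max(shares.values())
            tied = [c for c, a in shares.items() if abs(a - best) < 1e-9]
            out[row, col] = max(tied, key=_hardness)
    return out


# ---------------------------------------------------------------------------
# BHT
# ---------------------------------------------------------------------------

def compose_bht(
    photic: bool, substrate: EunisSubstrate, peat_with_mussels: bool = False
) -> BhtClass:
    """Zone from the photic flag; peat covered by mussels becomes
    rock/biogenic reef."""
    zone = "infralittoral" if photic else "circalittoral"
    if peat_with_mussels:
        substrate = EunisSubstrate.ROCK_BIOGENIC_REEF
    return BhtClass(zone=zone, substrate=EunisSubstrate(substrate))


def compose_bht_grid(
    photic: np.ndarray, substrate: np.ndarray, peat: np.ndarray | None = None
) -> np.ndarray:
    out = np.full(substrate.shape, None, dtype=object)
    for idx in np.ndindex(substrate.shape):
        if substrate[idx] is None:
            continue
        is_peat = bool(peat[idx]) if peat is not None else False
        out[idx] = str(
            compose_bht(bool(photic[idx]), EunisSubstrate(substrate[idx]), is_peat)
        )
    return out


def eliminate_small_patches(
    labels: np.ndarray, cell_size_m: float, config: CompositionConfig = CompositionConfig()
) -> np.ndarray:
    """Merge 4-connected same-label patches under the minimum mapping
    unit into the modal label of their boundary neighbours.

    Total cell count is conserved and no new label is created; patches
    without any labelled neighbour are left unchanged (and logged).
    Intended for the BHT layer only.
    """
    min_cells = config.min_patch_ha * 10_000.0 / cell_size_m**2
    out = labels.copy()
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for label in sorted({v for v in labels.ravel() if v is not None}, key=str):
        mask = labels == label
        components, n_comp = ndimage.label(mask, structure=structure)
        for comp in range(1, n_comp + 1):
            comp_mask = components == comp
            if comp_mask.sum() >= min_cells:
                continue
            grown = ndimage.binary_dilation(comp_mask, structure=structure)
            boundary = grown & ~comp_mask
            neighbours = [
                out[idx] for idx in zip(*np.nonzero(boundary))
                if out[idx] is not None and out[idx] != label
            ]
            if not neighbours:
                log.info("patch of %r has no labelled neighbour; kept", label)
                continue
            modal = Counter(neighbours).most_common(1)[0][0]
            out[comp_mask] = modal
    return out


# ---------------------------------------------------------------------------
# HUB
# ---------------------------------------------------------------------------

def intersect_endo_epi(
    endo_token: str | None, epi_token: str | None, hard: bool
) -> str | None:
    """Epi community on hard-substrate dominated cells, endo elsewhere;
    a hard cell without an epi prediction stays NA."""
    return epi_token if hard else endo_token


def build_hub_layer(
    substrate: np.ndarray,
    photic: np.ndarray,
    hard: np.ndarray,
    endo_tokens: np.ndarray,
    epi_tokens: np.ndarray,
    peat: np.ndarray | None = None,
    cell_area_km2: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full HUB code per cell plus the per-code area table (km^2)."""
    codes = np.full(substrate.shape, None, dtype=object)
    for idx in np.ndindex(substrate.shape):
        sub = substrate[idx]
        if sub is None:
            continue
        token = intersect_endo_epi(endo_tokens[idx], epi_tokens[idx], bool(hard[idx]))
        if token is None:
            continue
        if peat is not None and peat[idx]:
            # peat bottoms colonised by mussels enter as a union code
            base = compose_hub(bool(photic[idx]), "peat", None)
            over = compose_hub(bool(photic[idx]), EunisSubstrate.SAND, token)
            codes[idx] = f"{base}+{over}"
            continue
        codes[idx] = compose_hub(bool(photic[idx]), EunisSubstrate(sub), token)
    table = area_summary(codes, cell_area_km2=cell_area_km2)
    return codes, table


# ---------------------------------------------------------------------------
# OHT
# ---------------------------------------------------------------------------

def detect_species_rich(
    stations: pd.DataFrame,
    eligible_mask: np.ndarray,
    sediment_shares: pd.DataFrame | None = None,
    config: CompositionConfig = CompositionConfig(),
) -> dict:
    """Indicator-taxon test for species-rich gravel/coarse-sand areas.

    ``stations`` needs columns ``station_id``, ``row``, ``col`` and
    per-station indicator biomass percentages ``single_pct`` (largest
    single indicator taxon) and ``combined_pct``.  A station qualifies
    at single >= 10 % or combined >= 5 %; the area is a candidate when
    at least 3 qualifying stations fall on eligible cells.  The
    substrate designation test (gravel/coarse-sand/shell > 50 %) is
    evaluated separately from ``sediment_shares`` (column
    ``gravel_coarse_shell_pct``) and reported, never merged into the
    candidate decision.
    """
    qualifying = stations[
        (stations["single_pct"] >= config.species_rich_single_pct)
        | (stations["combined_pct"] >= config.species_rich_combined_pct)
    ]
    on_eligible = qualifying[
        [bool(eligible_mask[int(r), int(c)]) for r, c in zip(qualifying["row"], qualifying["col"])]
    ] if len(qualifying) else qualifying
    candidate = len(on_eligible) >= config.species_rich_min_stations
    designated = None
    if sediment_shares is not None and "gravel_coarse_shell_pct" in sediment_shares:
        designated = bool(
            (sediment_shares["gravel_coarse_shell_pct"] > config.species_rich_substrate_pct).all()
        )
    return {
        "candidate": candidate,
        "n_qualifying_stations": int(len(on_eligible)),
        "substrate_designation_met": designated,
        "stations": list(on_eligible["station_id"]),
    }


def build_oht_layer(
    hub_codes: np.ndarray,
    grid,
    reef_polygons: list[BaseGeometry] | None = None,
    sandbank_polygons: list[BaseGeometry] | None = None,
    seagrass_probability: np.ndarray | None = None,
    seagrass_density: np.ndarray | None = None,
    species_rich_mask: np.ndarray | None = None,
    config: CompositionConfig = CompositionConfig(),
) -> tuple[dict, pd.DataFrame]:
    """Assemble the OHT layer.

    Polygon habitats (reefs, sandbanks) are carried through as given and
    their areas measured exactly; gridded categories are cell sets.
    Where reef and species-rich gravel overlap, the reef wins and the
    species-rich area is reduced accordingly.  Returns ``(layer,
    area_table)`` where ``layer`` maps category -> mask or geometry.
    """
    cell_km2 = grid.cell_area_m2 / 1e6
    layer: dict[str, object] = {}

    def _union(polys):
        from shapely.ops import unary_union

        fixed = []
        for g in polys:
            if not g.is_valid:
                g = make_valid(g)
                log.warning("repaired invalid OHT polygon")
            fixed.append(g)
        return unary_union(fixed)

    reef_geom = _union(reef_polygons) if reef_polygons else None
    if reef_geom is not None:
        layer["reefs_1170"] = reef_geom
    if sandbank_polygons:
        layer["sandbanks_1110"] = _union(sandbank_polygons)

    # seagrass / macrophytes: modelled occurrence >= 50 % or density >= 10/m^2
    if seagrass_probability is not None or seagrass_density is not None:
        shape = (grid.n_rows, grid.n_cols)
        prob = seagrass_probability if seagrass_probability is not None else np.zeros(shape)
        dens = seagrass_density if seagrass_density is not None else np.zeros(shape)
        layer["seagrass_macrophytes"] = (
            (prob * 100.0 >= config.seagrass_probability_pct)
            | (dens >= config.seagrass_density_per_m2)
        )

    # quahog mud: cells whose HUB code is the aphotic muddy Arctica class
    arctica = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for idx in np.ndindex(hub_codes.shape):
        arctica[idx] = hub_codes[idx] == "AB.H3L3"
    layer["arctica_aphotic_mud"] = arctica

    if species_rich_mask is not None:
        sr = species_rich_mask.copy()
        if reef_geom is not None:
            overlap = polygon_mask(reef_geom, grid)
            removed = int((sr & overlap).sum())
            if removed:
                log.info(
                    "%d species-rich cell(s) ceded to overlapping reef areas", removed
                )
            sr &= ~overlap
        layer["species_rich_gravel"] = sr

    rows = []
    for name in OHT_CATEGORIES:
        if name not in layer:
            continue
        value = layer[name]
        if isinstance(value, BaseGeometry):
            km2 = value.area / 1e6
        else:
            km2 = float(value.sum()) * cell_km2
        rows.append({"class": name, "area_km2": km2})
    table = pd.DataFrame(rows, columns=["class", "area_km2"])
    total = grid.n_rows * grid.n_cols * cell_km2
    table["area_pct"] = 100.0 * table["area_km2"] / total if total else 0.0
    return layer, table


# ---------------------------------------------------------------------------
# Area accounting
# ---------------------------------------------------------------------------

def area_summary(labels: np.ndarray, cell_area_km2: float) -> pd.DataFrame:
    """Per-class area table: km^2 and percent of the mapped (non-NA)
    area; percentages sum to 100 over the realised classes."""
    flat = [v for v in labels.ravel() if v is not None]
    counts = Counter(flat)
    rows = [
        {"class": cls, "area_km2": n * cell_area_km2}
        for cls, n in sorted(counts.items(), key=lambda kv: str(kv[0]))
    ]
    table = pd.DataFrame(rows, columns=["class", "area_km2"])
    mapped = table["area_km2"].sum()
    table["area_pct"] = 100.0 * table["area_km2"] / mapped if mapped else 0.0
    return table
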