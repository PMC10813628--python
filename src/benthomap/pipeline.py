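"""End-to-end orchestration on a run directory.

Stages: simulate -> classify-sediment -> hardbottom -> assign-hub ->
fit -> predict -> compose -> summarize.  Every stage reads the previous
stage's files from the run directory and writes its own; outputs are
write-once per run and a manifest records the seed and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, hardbottom, hub, io, model, sediment, synthetic

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    extent: float = 10_000.0
    cell_size: float = 1000.0
    n_grab: int = 300
    n_video: int = 120
    biomass_concentration: float = 0.0
    cover_noise_sd: float = 0.0
    n_trees_grid: tuple[int, ...] = (250,)
    mtry_offsets: tuple[int, ...] = (0,)
    imbalance: str = "none"

    def seascape_config(self) -> synthetic.SeascapeConfig:
        return synthetic.SeascapeConfig(
            extent=self.extent,
            cell_size=self.cell_size,
            seed=self.seed,
            n_grab=self.n_grab,
            n_video=self.n_video,
            biomass_concentration=self.biomass_concentration,
            cover_noise_sd=self.cover_noise_sd,
        )


#: Representative grain-size composition per generator sediment class,
#: used to drive the granulometric classifier on the map grid.
CLASS_COMPOSITIONS = {
    "M": dict(mud=0.80, sand=0.18, gravel=0.02),
    "sM": dict(mud=0.55, sand=0.43, gravel=0.02),
    "mS": dict(mud=0.30, sand=0.68, gravel=0.02),
    "S": dict(mud=0.05, sand=0.92, gravel=0.03),
    "gS": dict(mud=0.05, sand=0.60, gravel=0.35),
    "sG": dict(mud=0.04, sand=0.36, gravel=0.60),
    "G": dict(mud=0.02, sand=0.10, gravel=0.88),
    "LagSed": dict(mud=0.05, sand=0.45, gravel=0.50, hard_cover_pct=40.0),
    "Peat": dict(mud=0.10, sand=0.85, gravel=0.05),
}


def substrate_of_class(cls: str) -> sediment.EunisSubstrate:
    comp = sediment.GrainSizeComposition(**CLASS_COMPOSITIONS[cls])
    return sediment.classify_eunis(comp)


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # -- simulate ---------------------------------------------------------
    try:
        scape = synthetic.generate_seascape(config.seascape_config())
        grid = scape.grid
        for name, layer in scape.environment.items():
            io.write_ascii_grid(out / f"predictor_{name}.asc", layer,
                                x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        io.write_class_grid(out / "sediment.asc", scape.sediment,
                            x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        pd.DataFrame(scape.boulders, columns=["x", "y"]).to_csv(
            out / "boulders.csv", index=False)
        scape.stations.to_csv(out / "stations.csv", index=False)
        counts["simulate"] = {
            "cells": int(grid.n_rows * grid.n_cols),
            "boulders": int(len(scape.boulders)),
            "stations": int(scape.stations["station_id"].nunique()),
        }
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    # -- classify-sediment ------------------------------------------------
    try:
        substrate = np.empty(scape.sediment.shape, dtype=object)
        for idx in np.ndindex(scape.sediment.shape):
            substrate[idx] = substrate_of_class(str(scape.sediment[idx])).value
        io.write_class_grid(out / "substrate.asc", substrate,
                            x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        counts["classify_sediment"] = {
            "classes": sorted({str(v) for v in substrate.ravel()})
        }
    except Exception as exc:
        raise StageError(f"stage 'classify-sediment' failed: {exc}") from exc

    # -- hardbottom -------------------------------------------------------
    try:
        boulder_counts = hardbottom.grid_boulder_counts(scape.boulders, grid)
        boulder_classes = hardbottom.classify_boulder_density_grid(boulder_counts)
        hard, _prov = hardbottom.hard_substrate_mask(boulder_classes, scape.sediment)
        io.write_ascii_grid(out / "boulder_counts.asc", boulder_counts.astype(float),
                            x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        io.write_ascii_grid(out / "hard_mask.asc", hard.astype(float),
                            x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        counts["hardbottom"] = {"hard_cells": int(hard.sum())}
    except Exception as exc:
        raise StageError(f"stage 'hardbottom' failed: {exc}") from exc

    # -- assign-hub -------------------------------------------------------
    try:
        labelled = hub.label_stations(scape.stations)
        kept, excluded = hub.apply_conventions(labelled)
        kept.to_csv(out / "stations_labelled.csv", index=False)
        excluded.to_csv(out / "stations_excluded.csv", index=False)
        counts["assign_hub"] = {"kept": int(len(kept)), "excluded": int(len(excluded))}
    except Exception as exc:
        raise StageError(f"stage 'assign-hub' failed: {exc}") from exc

    # -- fit + predict ----------------------------------------------------
    results = {}
    grids = {}
    for realm in ("endo", "epi"):
        part = kept[kept["realm"] == realm].rename(
            columns={"harmonized_label": "final"}
        )
        part = part.assign(label=part["final"])
        # singleton classes cannot be split 70/30 with both sides non-empty
        label_counts = part["label"].value_counts()
        singletons = label_counts[label_counts < 2].index
        if len(singletons):
            log.warning(
                "realm %s: dropping singleton class(es) %s before fitting",
                realm, sorted(singletons),
            )
            part = part[~part["label"].isin(singletons)]
        if part["label"].nunique() < 2:
            log.warning("realm %s has <2 classes; prediction skipped", realm)
            grids[realm] = model.PredictionGrid(
                tokens=np.full(scape.sediment.shape, None, dtype=object),
                probability=np.full(scape.sediment.shape, np.nan),
            )
            continue
        try:
            X, y = model.build_feature_matrix(
                part, scape.environment, scape.sediment, realm,
                photic=scape.photic, hard=hard if realm == "epi" else None,
            )
            cfg = model.ModelConfig(
                realm=realm, seed=config.seed,
                n_trees_grid=config.n_trees_grid,
                mtry_offsets=config.mtry_offsets,
                imbalance=config.imbalance,
            )
            fitres = model.fit(cfg, X, y)
            fitres.to_json(out / f"fit_{realm}.json")
            fitres.confusion.to_csv(out / f"confusion_{realm}.csv")
            results[realm] = fitres
        except Exception as exc:
            raise StageError(f"stage 'fit' ({realm}) failed: {exc}") from exc
        try:
            grids[realm] = model.predict_grid(
                fitres, scape.environment, scape.sediment, realm,
                photic=scape.photic,
                mask=hard if realm == "epi" else None,
            )
        except Exception as exc:
            raise StageError(f"stage 'predict' ({realm}) failed: {exc}") from exc
    counts["fit"] = {
        realm: {"accuracy": res.accuracy, "kappa": res.kappa}
        for realm, res in results.items()
    }

    # -- compose ----------------------------------------------------------
    try:
        cell_km2 = grid.cell_area_m2 / 1e6
        substrate_hard = substrate.copy()
        substrate_hard[hard] = sediment.EunisSubstrate.MIXED_SEDIMENT_HARD.value
        bht = composition.compose_bht_grid(scape.photic, substrate_hard)
        bht = composition.eliminate_small_patches(bht, grid.cell_size)
        hub_codes, hub_table = composition.build_hub_layer(
            substrate_hard, scape.photic, hard,
            grids["endo"].tokens, grids["epi"].tokens,
            cell_area_km2=cell_km2,
        )
        oht_layer, oht_table = composition.build_oht_layer(hub_codes, grid)
        io.write_class_grid(out / "bht.asc", bht,
                            x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        io.write_class_grid(out / "hub.asc", hub_codes,
                            x0=grid.x0, y0=0.0, cell_size=grid.cell_size)
        counts["compose"] = {
            "bht_na": int(sum(v is None for v in bht.ravel())),
            "hub_na": int(sum(v is None for v in hub_codes.ravel())),
        }
    except Exception as exc:
        raise StageError(f"stage 'compose' failed: {exc}") from exc

    # -- summarize --------------------------------------------------------
    try:
        bht_table = composition.area_summary(bht, cell_area_km2=cell_km2)
        bht_table.to_csv(out / "area_bht.csv", index=False)
        hub_table.to_csv(out / "area_hub.csv", index=False)
        oht_table.to_csv(out / "area_oht.csv", index=False)
    except Exception as exc:
        raise StageError(f"stage 'summarize' failed: {exc}") from exc

    io.write_manifest(out / "manifest.json", seed=config.seed,
                      config=dataclasses.asdict(config), counts=counts)
    return {
        "bht": bht, "hub": hub_codes, "oht": oht_layer,
        "tables": {"bht": bht_table, "hub": hub_table, "oht": oht_table},
        "fit": results, "counts": counts, "seascape": scape,
    }
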