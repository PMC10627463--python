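"""Staged pipeline runner.

Each stage reads the artifacts written by its predecessors from the output
directory and writes its own, so runs can be resumed and inspected stage by
stage. A manifest records the config hash, the master seed and per-stage
timing, making any run reconstructible from its output directory alone.

Stages: ``simulate`` (synthetic landscape, truth and records), ``delineate``
(patches from rasters), ``network`` (least-cost table + per-distance edge
lists), ``metrics`` (per-distance predictor tables), ``occurrence``
(sampling-intensity labels), ``fit`` (replicate BRTs at one distance),
``sweep`` (the full sensitivity analysis) and ``report`` (figures and
summary tables).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .brt import BRTConfig, run_replicates
from .config import RunConfig, config_hash
from .metrics import PREDICTOR_COLUMNS, component_census, predictor_table
from .network import (
    DispersalParams,
    build_network,
    cost_threshold,
    d0_for_max_distance,
    interpatch_costs,
    write_network_csv,
)
from .occurrence import (
    assign_occurrence_state,
    detection_curve,
    sampling_intensity,
    select_intensity_threshold,
)
from .patches import binarize, delineate_patches, patchset_from_labels
from .rasters import Raster, read_raster, write_raster
from .sensitivity import (
    SweepDesign,
    collate_importance_curves,
    regress_auc_on_distance,
    run_sweep,
)

log = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "delineate",
    "network",
    "metrics",
    "occurrence",
    "fit",
    "sweep",
    "report",
]


class StageError(RuntimeError):
    pass


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(f"missing artifact {path.name}; run the '{producer}' stage first")
    return path


class Pipeline:
    def __init__(self, cfg: RunConfig, out_dir: str | Path | None = None):
        self.cfg = cfg
        self.out = Path(out_dir or cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- artifact access -------------------------------------------------
    def _patches(self):
        suit = read_raster(_require(self.out / "suitability.tif", "simulate"))
        labels = read_raster(_require(self.out / "labels.tif", "delineate"))
        return patchset_from_labels(labels, suit)

    def _observations(self) -> pd.DataFrame:
        return pd.read_csv(_require(self.out / "observations.csv", "simulate"))

    def _all_distances(self) -> list[float]:
        sw = self.cfg.sweep
        distances = set(sw.fixed_distances) | set(sw.species_specific_distance.values())
        return sorted(distances)

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg
        land = synthetic.LandscapeConfig(
            seed=cfg.seed, **cfg.landscape.model_dump()
        )
        suit = synthetic.generate_suitability(land)
        mask = synthetic.generate_mask(land)
        write_raster(suit, self.out / "suitability.tif")
        write_raster(mask, self.out / "mask.tif")

        binary = binarize(suit, cfg.delineation.binarization_threshold)
        patches = delineate_patches(binary, mask, suit, cfg.delineation.connectivity)
        truth_cfg = synthetic.OccupancyTruthConfig(
            seed=cfg.seed, **cfg.occupancy_truth.model_dump()
        )
        params = DispersalParams(
            d0=truth_cfg.true_d0, p=cfg.kernel.p, prob_min=cfg.kernel.prob_min
        )
        costs = interpatch_costs(patches, cost_cap=cost_threshold(params))
        net = build_network(patches, costs, params)
        occupancy = synthetic.generate_true_occupancy(patches, net, truth_cfg)
        samp = synthetic.SamplingConfig(seed=cfg.seed, **cfg.sampling.model_dump())
        obs = synthetic.generate_observations(patches, occupancy, samp)
        synthetic.write_truth_bundle(
            self.out / "synthetic",
            suit,
            mask,
            patches,
            occupancy,
            obs,
            configs={"landscape": land, "occupancy": truth_cfg, "sampling": samp},
        )
        obs.to_csv(self.out / "observations.csv", index=False)

    def stage_delineate(self) -> None:
        cfg = self.cfg
        suit = read_raster(
            Path(cfg.suitability_path)
            if cfg.suitability_path
            else _require(self.out / "suitability.tif", "simulate")
        )
        mask = read_raster(
            Path(cfg.mask_path)
            if cfg.mask_path
            else _require(self.out / "mask.tif", "simulate")
        )
        binary = binarize(suit, cfg.delineation.binarization_threshold)
        patches = delineate_patches(binary, mask, suit, cfg.delineation.connectivity)
        write_raster(
            Raster(patches.labels.astype(np.int32), suit.cell_size, suit.origin),
            self.out / "labels.tif",
        )
        patches.to_dataframe().to_csv(self.out / "patches.csv", index=False)
        patches.to_geojson(self.out / "patches.geojson")

    def stage_network(self) -> None:
        cfg = self.cfg
        patches = self._patches()
        distances = self._all_distances()
        cap = max(distances)
        costs = interpatch_costs(patches, cost_cap=cap)
        pd.DataFrame(
            [(i, j, c) for (i, j), c in sorted(costs.items())],
            columns=["patch_i", "patch_j", "cost_m"],
        ).to_csv(self.out / "costs.csv", index=False)
        netdir = self.out / "networks"
        netdir.mkdir(exist_ok=True)
        for dist in distances:
            d0 = d0_for_max_distance(dist, cfg.kernel.p, cfg.kernel.prob_min)
            params = DispersalParams(d0=d0, p=cfg.kernel.p, prob_min=cfg.kernel.prob_min)
            net = build_network(patches, costs, params, max_dispersal_distance=dist)
            tag = f"{int(dist)}m"
            write_network_csv(net, netdir / f"nodes_{tag}.csv", netdir / f"edges_{tag}.csv")
            import networkx as nx

            nx.write_graphml(net, netdir / f"network_{tag}.graphml")

    def stage_metrics(self) -> None:
        cfg = self.cfg
        patches = self._patches()
        _require(self.out / "costs.csv", "network")
        costs_df = pd.read_csv(self.out / "costs.csv")
        costs = {
            (int(r.patch_i), int(r.patch_j)): float(r.cost_m)
            for r in costs_df.itertuples()
        }
        mdir = self.out / "metrics"
        mdir.mkdir(exist_ok=True)
        census_rows = []
        for dist in self._all_distances():
            d0 = d0_for_max_distance(dist, cfg.kernel.p, cfg.kernel.prob_min)
            params = DispersalParams(d0=d0, p=cfg.kernel.p, prob_min=cfg.kernel.prob_min)
            net = build_network(patches, costs, params, max_dispersal_distance=dist)
            preds = predictor_table(net)
            preds.to_csv(mdir / f"predictors_{int(dist)}m.csv")
            census = component_census(net)
            census_rows.append(
                {
                    "distance": dist,
                    "n_patches": len(net.nodes),
                    "n_edges": len(net.edges),
                    "n_components": census.n_components,
                    "giant_component_size": census.giant_component_size,
                }
            )
        pd.DataFrame(census_rows).to_csv(mdir / "component_census.csv", index=False)
        with open(mdir / "component_census.json", "w") as fh:
            json.dump(census_rows, fh, indent=1)

    def stage_occurrence(self) -> None:
        cfg = self.cfg
        patches = self._patches()
        obs = (
            pd.read_csv(cfg.observations_path)
            if cfg.observations_path
            else self._observations()
        )
        for sp in cfg.sweep.species:
            counts = sampling_intensity(
                obs, patches, sp, snap_distance=cfg.sweep.snap_distance
            )
            curve = detection_curve(counts)
            curve.rename("mean_focal_detections").to_csv(
                self.out / f"detection_curve_{sp}.csv"
            )
            thr = (
                cfg.sweep.intensity_threshold
                if cfg.sweep.intensity_threshold is not None
                else select_intensity_threshold(curve)
            )
            table = assign_occurrence_state(counts, thr)
            table.to_csv(self.out / f"occurrence_{sp}.csv")

    def stage_fit(self) -> None:
        """Replicate BRTs for each species at its species-specific distance
        (or the largest fixed distance when none is configured)."""
        cfg = self.cfg
        patches = self._patches()
        costs_df = pd.read_csv(_require(self.out / "costs.csv", "network"))
        costs = {
            (int(r.patch_i), int(r.patch_j)): float(r.cost_m)
            for r in costs_df.itertuples()
        }
        for sp in cfg.sweep.species:
            occ_path = _require(self.out / f"occurrence_{sp}.csv", "occurrence")
            occ = pd.read_csv(occ_path, index_col="patch_id")
            dist = cfg.sweep.species_specific_distance.get(
                sp, max(cfg.sweep.fixed_distances)
            )
            d0 = d0_for_max_distance(dist, cfg.kernel.p, cfg.kernel.prob_min)
            params = DispersalParams(d0=d0, p=cfg.kernel.p, prob_min=cfg.kernel.prob_min)
            net = build_network(patches, costs, params, max_dispersal_distance=dist)
            preds = predictor_table(net)
            labelled = occ["state"].dropna()
            X = preds.loc[labelled.index, PREDICTOR_COLUMNS]
            brt_cfg = BRTConfig(
                seed=cfg.seed,
                **{
                    k: v
                    for k, v in cfg.brt.model_dump().items()
                    if k != "n_replicates"
                },
            )
            reps, _ = run_replicates(
                X, labelled.to_numpy(), brt_cfg, n_replicates=cfg.brt.n_replicates
            )
            reps.to_csv(self.out / f"brt_replicates_{sp}_{int(dist)}m.csv", index=False)

    def stage_sweep(self) -> None:
        cfg = self.cfg
        patches = self._patches()
        obs = (
            pd.read_csv(cfg.observations_path)
            if cfg.observations_path
            else self._observations()
        )
        design = SweepDesign(
            species=tuple(cfg.sweep.species),
            fixed_distances=tuple(cfg.sweep.fixed_distances),
            species_specific_distance=dict(cfg.sweep.species_specific_distance),
        )
        brt_cfg = BRTConfig(
            seed=cfg.seed,
            **{k: v for k, v in cfg.brt.model_dump().items() if k != "n_replicates"},
        )
        result = run_sweep(
            design,
            patches,
            obs,
            brt_cfg,
            n_replicates=cfg.brt.n_replicates,
            p=cfg.kernel.p,
            prob_min=cfg.kernel.prob_min,
            intensity_threshold=cfg.sweep.intensity_threshold,
            snap_distance=cfg.sweep.snap_distance,
            master_seed=cfg.seed,
        )
        result.summary.to_csv(self.out / "sweep_summary.csv", index=False)
        result.replicates.to_csv(self.out / "sweep_replicates.csv", index=False)
        collate_importance_curves(result).to_csv(
            self.out / "importance_curves.csv", index=False
        )
        regs = []
        for sp in design.species:
            if result.replicates.empty:
                continue
            sub = result.replicates[result.replicates["species"] == sp]
            if sub["distance"].nunique() >= 3:
                regs.append(regress_auc_on_distance(result, sp))
        pd.DataFrame(regs).to_csv(self.out / "regressions.csv", index=False)
        if result.failures:
            with open(self.out / "sweep_failures.json", "w") as fh:
                json.dump(result.failures, fh, indent=1)

    def stage_report(self) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        summary = pd.read_csv(_require(self.out / "sweep_summary.csv", "sweep"))
        figdir = self.out / "figures"
        figdir.mkdir(exist_ok=True)

        def per_species(ax, ycol, ylabel):
            for sp, grp in summary.groupby("species"):
                ax.plot(grp["distance"] / 1000, grp[ycol], "o-", label=sp)
            ax.set_xlabel("maximum dispersal distance (km)")
            ax.set_ylabel(ylabel)
            ax.legend()

        fig, ax = plt.subplots(figsize=(5, 4))
        per_species(ax, "n_components", "number of components")
        ax.set_yscale("log")
        fig.savefig(figdir / "components_vs_distance.png", dpi=150)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        per_species(ax, "mean_auc_cv", "mean AUC-cv")
        fig.savefig(figdir / "auc_vs_distance.png", dpi=150)
        plt.close(fig)

        curves = pd.read_csv(_require(self.out / "importance_curves.csv", "sweep"))
        fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
        for ax, pred in zip(axes, ["HSI", "neigh3", "habAv"]):
            sub = curves[curves["predictor"] == pred]
            for sp, grp in sub.groupby("species"):
                ax.plot(grp["distance"] / 1000, grp["mean_influence"], "o-", label=sp)
            ax.set_title(pred)
            ax.set_xlabel("distance (km)")
        axes[0].set_ylabel("mean relative influence (%)")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(figdir / "importance_vs_distance.png", dpi=150)
        plt.close(fig)

    # -- driver ----------------------------------------------------------
    def run(self, stages: list[str]) -> dict:
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}; valid: {STAGES}")
        manifest_path = self.out / "manifest.json"
        manifest = {
            "config_hash": config_hash(self.cfg),
            "seed": self.cfg.seed,
            "config": self.cfg.model_dump(),
            "stages": {},
        }
        if manifest_path.exists():
            with open(manifest_path) as fh:
                prev = json.load(fh)
            if prev.get("config_hash") == manifest["config_hash"]:
                manifest["stages"] = prev.get("stages", {})
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            log.info("stage %s starting", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                manifest["stages"][stage] = {
                    "status": "failed",
                    "error": repr(exc),
                    "seconds": round(time.time() - t0, 2),
                }
                with open(manifest_path, "w") as fh:
                    json.dump(manifest, fh, indent=1)
                raise
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 2),
            }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest
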