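"""End-to-end orchestration: simulate → select-vars → fit → evaluate →
predict → project → report.

A single :class:`PipelineConfig` (YAML-serializable) carries every knob;
all stage outputs land in one run directory, written once and never
mutated by later stages, with a manifest recording the config hash, the
seeds actually used and each stage's artifacts.  Re-running with the same
config reproduces the run bit-for-bit.

Stage seeds derive from one root seed with fixed offsets (split +1,
cross-validation uses the ensemble's random_state, importance +2) so
component-level reruns stay reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .algorithms import load_sdm, save_sdm
from .ensemble import (
    DEFAULT_ALGORITHMS,
    EnsembleSDM,
    ensemble_predict,
    split_indices,
    variable_importance,
)
from .errors import ValidationError
from .geodata import (
    ClimateStack,
    GridSpec,
    OccurrenceSet,
    extract_values,
    read_map,
    read_occurrences,
    read_stack,
    regions_from_raster,
    thin_occurrences,
    write_map,
    write_occurrences,
    write_regions,
    write_stack,
)
from .projection import (
    BinaryMap,
    SuitabilityMap,
    binarize,
    change_map,
    classify_five,
    consensus,
    consensus_votes_needed,
    find_threshold,
)
from .reporting import area_by_region, cell_areas, change_summary, render_report
from .synthetic import SyntheticWorld, TruthConfig, make_world
from .vif import VIFPruner

STAGES = ("simulate", "select_vars", "fit", "evaluate", "predict", "project", "report")


@dataclass
class PipelineConfig:
    """Every parameter of a pipeline run, with the standard defaults."""

    # input paths (all optional; a synthetic world is generated when absent)
    stack_paths: list[str] = field(default_factory=list)
    stack_names: list[str] = field(default_factory=list)
    occurrences_path: str | None = None
    regions_path: str | None = None
    future_paths: dict[str, list[list[str]]] = field(default_factory=dict)
    # scenario -> list of per-GCM path lists (same names as stack_names)

    # synthetic-world settings (used when stack_paths is empty)
    grid_rows: int = 100
    grid_cols: int = 100
    grid_origin: tuple[float, float] = (33.0, -9.0)
    grid_cell_size: float = 0.05
    n_layers: int = 8
    smoothness: float = 5.0
    cross_corr: float = 0.95
    n_presence: int = 200
    n_gcms: int = 17

    # modelling parameters
    vif_threshold: float = 10.0
    train_fraction: float = 0.7
    k_folds: int = 5
    auc_gate: float = 0.77
    min_contribution: float = 0.05
    threshold_mode: str = "derive"  # "derive" | "fixed"
    fixed_threshold: float = 0.34
    agreement: float = 0.66
    n_background: int = 500
    land_area_km2: float | None = None
    cell_area_mode: str = "constant"
    cell_area_km2: float = 25.0
    algorithms: list[str] = field(default_factory=lambda: list(DEFAULT_ALGORITHMS))
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.threshold_mode not in ("derive", "fixed"):
            raise ValidationError("threshold_mode must be 'derive' or 'fixed'")
        if not 0 < self.agreement <= 1:
            raise ValidationError("agreement must be in (0, 1]")
        if not 0 <= self.fixed_threshold <= 1:
            raise ValidationError("fixed_threshold must be in [0, 1]")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "grid_origin" in doc:
            doc["grid_origin"] = tuple(doc["grid_origin"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self) -> str:
        doc = dataclasses.asdict(self)
        doc["grid_origin"] = list(doc["grid_origin"])
        return yaml.safe_dump(doc, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


class PipelineRun:
    """Stage executor bound to one run directory (write-once)."""

    def __init__(self, config: PipelineConfig, run_dir):
        config.validate()
        self.config = config
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.run_dir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "version": __version__,
                "stages": {},
            }
            (self.run_dir / "config.yaml").write_text(config.to_yaml())

    # -- manifest helpers ---------------------------------------------------
    def _record(self, stage: str, outputs: dict) -> None:
        self.manifest["stages"][stage] = outputs
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _rel(self, path) -> str:
        return str(Path(path).relative_to(self.run_dir))

    def _abs(self, path) -> Path:
        return self.run_dir / path

    # -- data access --------------------------------------------------------
    def load_stack(self) -> ClimateStack:
        cfg = self.config
        if cfg.stack_paths:
            return read_stack(cfg.stack_paths, cfg.stack_names)
        meta = json.loads((self.run_dir / "simulate" / "layers.json").read_text())
        return read_stack([self._abs(p) for p in meta["paths"]], meta["names"])

    def load_occurrences(self) -> OccurrenceSet:
        cfg = self.config
        if cfg.occurrences_path:
            return read_occurrences(cfg.occurrences_path)
        return read_occurrences(self.run_dir / "simulate" / "occurrences.csv")

    def load_regions(self):
        cfg = self.config
        path = cfg.regions_path or self.run_dir / "simulate" / "regions.tif"
        names_path = self.run_dir / "simulate" / "region_names.json"
        names = None
        if names_path.exists():
            names = {int(k): v for k, v in json.loads(names_path.read_text()).items()}
        return regions_from_raster(path, names)

    def load_futures(self) -> dict[str, list[ClimateStack]]:
        cfg = self.config
        if cfg.future_paths:
            return {
                scen: [read_stack(paths, cfg.stack_names) for paths in gcms]
                for scen, gcms in cfg.future_paths.items()
            }
        meta = json.loads((self.run_dir / "simulate" / "futures.json").read_text())
        return {
            scen: [
                read_stack([self._abs(p) for p in g["paths"]], g["names"])
                for g in gcms
            ]
            for scen, gcms in meta.items()
        }

    # -- stages -------------------------------------------------------------
    def simulate(self) -> SyntheticWorld:
        cfg = self.config
        grid = GridSpec(cfg.grid_rows, cfg.grid_cols, cfg.grid_origin, cfg.grid_cell_size)
        truth_cfg = TruthConfig(
            grid=grid,
            n_layers=cfg.n_layers,
            smoothness=cfg.smoothness,
            cross_corr=cfg.cross_corr,
            n_presence=cfg.n_presence,
            n_background=cfg.n_background,
            seed=cfg.seed,
        )
        world = make_world(truth_cfg, n_gcms=cfg.n_gcms)
        out = self.run_dir / "simulate"
        out.mkdir(exist_ok=True)
        paths = write_stack(world.stack, out / "layers")
        (out / "layers.json").write_text(
            json.dumps(
                {
                    "names": world.stack.names,
                    "paths": [self._rel(p) for p in paths.values()],
                }
            )
        )
        # thinning is idempotent here (points sit at distinct cell centres)
        occ = thin_occurrences(world.occurrences, grid, seed=cfg.seed)
        write_occurrences(occ, out / "occurrences.csv")
        write_regions(world.regions, out / "regions.tif")
        (out / "region_names.json").write_text(
            json.dumps(world.regions.region_names)
        )
        futures_meta = {}
        for g, stack in enumerate(world.future_stacks):
            gdir = out / f"gcm_{g:02d}"
            gpaths = write_stack(stack, gdir)
            futures_meta.setdefault("future", []).append(
                {
                    "names": stack.names,
                    "paths": [self._rel(p) for p in gpaths.values()],
                }
            )
        (out / "futures.json").write_text(json.dumps(futures_meta))
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "beta": truth_cfg.beta.tolist(),
                    "true_suitable_fraction": world.true_suitable_fraction,
                    "truth_threshold": world.truth_threshold,
                    "seed": cfg.seed,
                }
            )
        )
        write_map(
            world.true_suitability, grid, out / "true_suitability.tif", "float32",
            world.stack.nodata_mask,
        )
        self._record(
            "simulate",
            {
                "layers": self._rel(out / "layers"),
                "occurrences": self._rel(out / "occurrences.csv"),
                "regions": self._rel(out / "regions.tif"),
                "futures": self._rel(out / "futures.json"),
                "truth": self._rel(out / "truth.json"),
            },
        )
        return world

    def select_vars(self) -> list[str]:
        stack = self.load_stack()
        occ = self.load_occurrences()
        X, _, _ = extract_values(stack, occ)
        pruner = VIFPruner(threshold=self.config.vif_threshold).fit(X)
        out = self.run_dir / "select_vars"
        out.mkdir(exist_ok=True)
        pruner.table_.to_frame().to_csv(out / "vif_report.csv", index=False)
        (out / "retained.json").write_text(json.dumps(pruner.retained_))
        self._record(
            "select_vars",
            {
                "vif_report": self._rel(out / "vif_report.csv"),
                "retained": pruner.retained_,
            },
        )
        return pruner.retained_

    def _design(self):
        stack = self.load_stack()
        occ = self.load_occurrences()
        retained = json.loads(
            (self.run_dir / "select_vars" / "retained.json").read_text()
        )
        X, y, _ = extract_values(stack, occ)
        return stack, X[retained], y

    def fit(self) -> EnsembleSDM:
        cfg = self.config
        stack, X, y = self._design()
        train_idx, test_idx = split_indices(y, cfg.train_fraction, seed=cfg.seed + 1)
        model = EnsembleSDM(
            algorithms=cfg.algorithms,
            auc_gate=cfg.auc_gate,
            min_contribution=cfg.min_contribution,
            k=cfg.k_folds,
            random_state=cfg.seed,
        ).fit(X.iloc[train_idx], y[train_idx])
        out = self.run_dir / "fit"
        out.mkdir(exist_ok=True)
        np.save(out / "train_idx.npy", train_idx)
        np.save(out / "test_idx.npy", test_idx)
        for aid, member in model.members_.items():
            save_sdm(member, out / f"member_{aid}.json")
        (out / "ensemble.json").write_text(
            json.dumps(
                {
                    "weights": model.weights_,
                    "members": sorted(model.members_),
                    "mean_cv_aucs": {
                        a: r.mean_auc for a, r in model.cv_results_.items()
                    },
                    "variable_names": model.variable_names_,
                }
            )
        )
        self._record(
            "fit",
            {
                "ensemble": self._rel(out / "ensemble.json"),
                "weights": model.weights_,
            },
        )
        return model

    def load_ensemble(self) -> EnsembleSDM:
        out = self.run_dir / "fit"
        doc = json.loads((out / "ensemble.json").read_text())
        model = EnsembleSDM(algorithms=self.config.algorithms)
        model.weights_ = doc["weights"]
        model.members_ = {
            aid: load_sdm(out / f"member_{aid}.json") for aid in doc["members"]
        }
        model.variable_names_ = doc["variable_names"]
        model.cv_results_ = {}
        return model

    def evaluate(self) -> pd.DataFrame:
        cfg = self.config
        stack, X, y = self._design()
        model = self.fit() if not (self.run_dir / "fit").exists() else self.load_ensemble()
        test_idx = np.load(self.run_dir / "fit" / "test_idx.npy")
        holdout_auc = None
        if len(test_idx):
            from .ensemble import auc_from_labels

            holdout_auc = auc_from_labels(
                y[test_idx], model.score_samples(X.iloc[test_idx])
            )
        doc = json.loads((self.run_dir / "fit" / "ensemble.json").read_text())
        rows = [
            {
                "algorithm": aid,
                "mean_cv_auc": auc,
                "weight": doc["weights"].get(aid, 0.0),
                "in_ensemble": aid in doc["weights"],
            }
            for aid, auc in doc["mean_cv_aucs"].items()
        ]
        table = pd.DataFrame(rows)
        out = self.run_dir / "evaluate"
        out.mkdir(exist_ok=True)
        table.to_csv(out / "evaluation.csv", index=False)
        importance = variable_importance(
            model, X, y, n_permutations=5, seed=cfg.seed + 2
        )
        importance.rename("importance_percent").to_csv(out / "importance.csv")
        summary = {"holdout_auc": holdout_auc}
        (out / "summary.json").write_text(json.dumps(summary))
        self._record(
            "evaluate",
            {
                "evaluation": self._rel(out / "evaluation.csv"),
                "importance": self._rel(out / "importance.csv"),
                "holdout_auc": holdout_auc,
            },
        )
        return table

    def predict(self) -> BinaryMap:
        cfg = self.config
        stack, X, y = self._design()
        model = self.load_ensemble()
        smap = ensemble_predict(model, stack)
        if cfg.threshold_mode == "fixed":
            threshold = cfg.fixed_threshold
        else:
            train_idx = np.load(self.run_dir / "fit" / "train_idx.npy")
            threshold = find_threshold(
                y[train_idx], model.score_samples(X.iloc[train_idx])
            )
        binary = binarize(smap, threshold)
        classes = classify_five(smap, threshold)
        out = self.run_dir / "predict"
        out.mkdir(exist_ok=True)
        write_map(smap.values, smap.grid, out / "suitability.tif", "float32", smap.mask)
        write_map(binary.suitable, smap.grid, out / "binary.tif", "uint8", smap.mask)
        write_map(classes.classes, smap.grid, out / "classes.tif", "uint8", smap.mask)
        (out / "threshold.json").write_text(
            json.dumps(
                {
                    "threshold": threshold,
                    "mode": cfg.threshold_mode,
                    "class_bin_edges": classes.bin_edges,
                }
            )
        )
        self._record(
            "predict",
            {
                "suitability": self._rel(out / "suitability.tif"),
                "binary": self._rel(out / "binary.tif"),
                "classes": self._rel(out / "classes.tif"),
                "threshold": threshold,
            },
        )
        return binary

    def project(self) -> dict[str, BinaryMap]:
        cfg = self.config
        model = self.load_ensemble()
        threshold = json.loads(
            (self.run_dir / "predict" / "threshold.json").read_text()
        )["threshold"]
        cur_values, grid, cur_mask = read_map(self.run_dir / "predict" / "binary.tif")
        current = BinaryMap(grid, cur_values, cur_mask)
        futures = self.load_futures()
        out = self.run_dir / "project"
        out.mkdir(exist_ok=True)
        results = {}
        meta = {}
        for scen, stacks in futures.items():
            per_gcm = []
            for g, stack in enumerate(stacks):
                smap = ensemble_predict(model, stack)
                per_gcm.append(binarize(smap, threshold))
                write_map(
                    smap.values, grid, out / f"{scen}_gcm{g:02d}.tif", "float32",
                    smap.mask,
                )
            cons = consensus(per_gcm, cfg.agreement)
            chg = change_map(current, cons)
            write_map(cons.suitable, grid, out / f"{scen}_consensus.tif", "uint8", cons.mask)
            write_map(chg.codes, grid, out / f"{scen}_change.tif", "uint8", chg.mask)
            meta[scen] = {
                "n_gcms": len(per_gcm),
                "votes_needed": consensus_votes_needed(len(per_gcm), cfg.agreement),
                "consensus": self._rel(out / f"{scen}_consensus.tif"),
                "change": self._rel(out / f"{scen}_change.tif"),
            }
            results[scen] = cons
        (out / "projection.json").write_text(json.dumps(meta))
        self._record("project", meta)
        return results

    def report(self) -> dict[str, str]:
        cfg = self.config
        regions = self.load_regions()
        areas = cell_areas(regions.grid, cfg.cell_area_mode, cfg.cell_area_km2)
        cur_values, grid, cur_mask = read_map(self.run_dir / "predict" / "binary.tif")
        current = BinaryMap(grid, cur_values, cur_mask)
        current_report = area_by_region(
            current, regions, areas, cfg.land_area_km2, cfg.cell_area_mode
        )
        out = self.run_dir / "report"
        out.mkdir(exist_ok=True)
        outputs = {"current": self._rel(out / "current_area.csv")}
        (out / "current_area.csv").write_text(render_report(current_report))
        proj_meta_path = self.run_dir / "project" / "projection.json"
        if proj_meta_path.exists():
            meta = json.loads(proj_meta_path.read_text())
            for scen, info in meta.items():
                values, _, mask = read_map(self._abs(info["change"]))
                loss = {}
                gain = {}
                for rid in regions.ids:
                    name = regions.region_names[rid]
                    sel = regions.region_id == rid
                    loss[name] = float(areas[sel & (values == 1)].sum())
                    gain[name] = float(areas[sel & (values == 3)].sum())
                rep = change_summary(
                    current_report, loss, gain, scenario=scen
                )
                path = out / f"change_{scen}.csv"
                path.write_text(render_report(rep))
                outputs[scen] = self._rel(path)
        self._record("report", outputs)
        return outputs


def run_pipeline(config: PipelineConfig, run_dir) -> Path:
    """Execute all stages in order; returns the run directory."""
    run = PipelineRun(config, run_dir)
    if not config.stack_paths:
        run.simulate()
    run.select_vars()
    run.fit()
    run.evaluate()
    run.predict()
    run.project()
    run.report()
    return run.run_dir
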