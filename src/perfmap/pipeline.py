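"""One-command end-to-end run: simulate -> score maps -> GLM -> nulls ->
enrichment -> PLS -> trajectories -> territories -> manifest.

The pipeline is deliberately file-oriented: each stage writes its outputs
(TSV for maps and tables, JSON for fitted models and summaries), and the
run manifest records every written file with a content hash so re-running
an identical configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import enrichment as _enrichment
from . import nulls as _nulls
from . import pls as _pls
from . import scoremaps as _scoremaps
from . import territories as _territories
from . import trajectories as _trajectories

__all__ = ["RunConfig", "RunManifest", "load_parcel_map", "write_parcel_map",
           "run_pipeline"]

log = logging.getLogger("perfmap")

ALL_STAGES = ("simulate", "scoremaps", "glm", "nulls", "enrichment",
              "pls", "trajectories", "territories")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    outdir: str = "perfmap_run"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    n_null: int = 1000
    n_perm: int = 1000
    n_boot: int = 1000
    cv_splits: int = 200
    cv_perms: int = 100
    cohort: _cohort.CohortConfig = field(default_factory=_cohort.CohortConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a TOML config; keys mirror the dataclass fields."""
        import tomllib
        raw = tomllib.loads(Path(path).read_text())
        cohort_kwargs = raw.pop("cohort", {})
        if "age_ranges" in cohort_kwargs:
            cohort_kwargs["age_ranges"] = tuple(tuple(r) for r in cohort_kwargs["age_ranges"])
        return cls(cohort=_cohort.CohortConfig(**cohort_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


@dataclass
class RunManifest:
    config: dict
    stages: Dict[str, dict]
    seed: int
    version: str

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "seed": self.seed, "version": self.version}, indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_parcel_map(path, parcel_ids: Optional[Sequence[int]] = None) -> pd.Series:
    """Read a parcel-keyed map (TSV: parcel_id, value), order-normalized.

    Duplicate ids, missing parcels relative to the supplied geometry order,
    and NaN values are all rejected — no silent imputation.
    """
    tab = pd.read_csv(path, sep="\t")
    if not {"parcel_id", "value"} <= set(tab.columns):
        raise ValueError("parcel map needs columns parcel_id, value")
    ids = tab["parcel_id"].to_numpy()
    dupes = tab["parcel_id"][tab["parcel_id"].duplicated()].unique()
    if dupes.size:
        raise ValueError(f"duplicate parcel_id(s): {dupes[:5].tolist()}")
    if tab["value"].isna().any() or not np.all(np.isfinite(tab["value"].to_numpy(dtype=float))):
        raise ValueError("parcel map contains missing or non-finite values")
    series = pd.Series(tab["value"].to_numpy(dtype=float), index=ids, name="value")
    if parcel_ids is not None:
        missing = [int(p) for p in parcel_ids if p not in series.index]
        if missing:
            raise ValueError(f"parcel map missing geometry parcels: {missing}")
        series = series.loc[list(parcel_ids)]
    return series


def write_parcel_map(path, values: np.ndarray,
                     parcel_ids: Optional[Sequence[int]] = None) -> None:
    values = np.asarray(values, dtype=float)
    ids = list(parcel_ids) if parcel_ids is not None else list(range(1, len(values) + 1))
    pd.DataFrame({"parcel_id": ids, "value": values}).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: Dict[str, dict] = {}
    ctx: Dict[str, object] = {}

    def record(stage: str, params: dict, files: List[Path]) -> None:
        stages[stage] = {
            "parameters": params,
            "outputs": {str(f.relative_to(outdir)): _sha256(f) for f in files},
            "status": "ok",
        }

    enabled = [s for s in ALL_STAGES if s in set(config.stages)]
    deps = {"scoremaps": {"simulate"}, "glm": {"simulate"}, "nulls": {"simulate"},
            "enrichment": {"simulate", "scoremaps", "nulls"},
            "pls": {"simulate"}, "trajectories": {"simulate"},
            "territories": {"simulate"}}
    for s in enabled:
        missing = deps.get(s, set()) - set(enabled)
        if missing:
            raise ValueError(f"stage {s!r} requires {sorted(missing)}")

    for stage in enabled:
        log.info("[%s] starting", stage)
        try:
            if stage == "simulate":
                coh = _cohort.simulate_cohort(config.cohort)
                ctx["cohort"] = coh
                coh.write(outdir / "cohort")
                files = sorted((outdir / "cohort").glob("*"))
                record(stage, {"seed": config.cohort.seed,
                               "n_subjects": config.cohort.n_subjects,
                               "n_parcels": config.cohort.n_parcels}, files)

            elif stage == "scoremaps":
                coh = ctx["cohort"]
                z = _scoremaps.standardize_subjects(coh.values)
                ctx["standardized"] = z
                res = _scoremaps.pca_score_map(z, n_components=5)
                ctx["score_map"] = res.score_map
                f1 = outdir / "score_map.tsv"
                write_parcel_map(f1, res.score_map)
                f2 = outdir / "pca_summary.json"
                f2.write_text(json.dumps({
                    "variance_explained": res.variance_explained.tolist(),
                    "truth_shared_corr": float(np.corrcoef(
                        res.score_map, coh.truth["shared_map"])[0, 1]),
                }))
                record(stage, {"n_components": 5, "center_columns": False}, [f1, f2])

            elif stage == "glm":
                coh = ctx["cohort"]
                # the generator's mean model is log-linear, so slopes live on
                # the log scale; fit the linear model to log-perfusion
                fit = _scoremaps.glm_effect_maps(np.log(coh.values), coh.covariates,
                                                 terms=("age", "sex"))
                ctx["age_map"] = fit.coef("age")
                f1 = outdir / "age_effect_map.tsv"
                write_parcel_map(f1, fit.coef("age"))
                f2 = outdir / "glm_summary.json"
                f2.write_text(json.dumps({
                    "truth_slope_corr": float(np.corrcoef(
                        fit.coef("age"), coh.truth["slope_map"])[0, 1]),
                    "n_bonferroni_age": int(fit.bonferroni_mask[1].sum()),
                }))
                record(stage, {"terms": ["age", "sex"]}, [f1, f2])

            elif stage == "nulls":
                coh = ctx["cohort"]
                spin = _nulls.spin_assignments(coh.centroids, config.n_null, config.seed)
                vasa = _nulls.vasa_assignments(coh.centroids, config.n_null, config.seed)
                ctx["spin"], ctx["vasa"] = spin, vasa
                f1 = outdir / "spin_ensemble.npy"
                f2 = outdir / "vasa_ensemble.npy"
                spin.save(f1)
                vasa.save(f2)
                files = [f1, f1.with_suffix(".json"), f2, f2.with_suffix(".json")]
                record(stage, {"n_null": config.n_null, "seed": config.seed}, files)

            elif stage == "enrichment":
                coh = ctx["cohort"]
                ann = _cohort.simulate_annotations(
                    coh.distances, ctx["score_map"], seed=config.seed + 1)
                table = _enrichment.run_gcea(ctx["score_map"], ann, ctx["vasa"],
                                             ds_threshold=None)
                f1 = outdir / "enrichment.tsv"
                _enrichment.write_enrichment_table(table, f1)
                record(stage, {"n_null": config.n_null,
                               "n_categories": len(ann.categories)}, [f1])

            elif stage == "pls":
                coh = ctx["cohort"]
                model = _pls.pls_fit(coh.values, coh.biomarkers.to_numpy())
                perm_p = _pls.pls_permutation(model, config.n_perm, config.seed)
                boot = _pls.pls_bootstrap(model, config.n_boot, config.seed)
                cv = _pls.pls_crossval(coh.values, coh.biomarkers.to_numpy(),
                                       n_splits=config.cv_splits,
                                       n_perm=config.cv_perms, seed=config.seed)
                f1 = outdir / "pls_summary.json"
                f1.write_text(json.dumps({
                    "covariance_explained": model.covariance_explained.tolist(),
                    "lv_p": perm_p.tolist(),
                    "cv_mean_r": cv.mean_r, "cv_p": cv.p,
                }))
                f2 = outdir / "pls_biomarkers.tsv"
                pd.DataFrame({
                    "biomarker": list(coh.biomarkers.columns),
                    "weight": model.V[:, 0],
                    "loading": model.y_loadings[:, 0],
                    "bootstrap_ratio": boot["y_bootstrap_ratios"][:, 0],
                }).to_csv(f2, sep="\t", index=False)
                record(stage, {"n_perm": config.n_perm, "n_boot": config.n_boot,
                               "cv_splits": config.cv_splits}, [f1, f2])

            elif stage == "trajectories":
                coh = ctx["cohort"]
                files = []
                summary = {}
                for sex_code, name in ((1, "male"), (0, "female")):
                    rows = coh.covariates["sex"].to_numpy() == sex_code
                    ages = coh.covariates["age"].to_numpy()[rows]
                    wb = coh.values[rows].mean(axis=1)  # whole-brain mean perfusion
                    fit = _trajectories.fit_gg_fp(ages, wb, seed=config.seed)
                    grid = np.linspace(ages.min(), ages.max(), 50)
                    curves = _trajectories.centile_curves(fit, grid, (5, 50, 95))
                    f = outdir / f"trajectory_{name}.tsv"
                    pd.DataFrame({"age": grid, "c05": curves[0], "c50": curves[1],
                                  "c95": curves[2]}).to_csv(f, sep="\t", index=False)
                    files.append(f)
                    summary[name] = fit.to_dict()
                fj = outdir / "trajectory_fits.json"
                fj.write_text(json.dumps(summary))
                record(stage, {"centiles": [5, 50, 95]}, files + [fj])

            elif stage == "territories":
                coh = ctx["cohort"]
                cov = _territories.perfusion_covariance(coh.values)
                # signed covariance graphs lose between-block connectivity
                # under top-k sparsification + clipping; embed the full graph
                grad = _territories.diffusion_gradients(cov, sparsity=0.0)
                labels = (grad.gradients[:, 0] > 0).astype(int)
                truth = np.asarray(coh.truth["territory_labels"])
                acc = max(np.mean(labels == truth), np.mean(labels != truth))
                f1 = outdir / "gradients.tsv"
                pd.DataFrame(grad.gradients,
                             columns=[f"g{k + 1}" for k in range(grad.gradients.shape[1])]
                             ).to_csv(f1, sep="\t", index=False)
                f2 = outdir / "territory_summary.json"
                f2.write_text(json.dumps({
                    "lambdas": grad.lambdas.tolist(),
                    "territory_accuracy": float(acc),
                }))
                record(stage, {"n_components": 5}, [f1, f2])
        except Exception:
            log.exception("[%s] failed; completed outputs preserved in %s", stage, outdir)
            raise RuntimeError(f"pipeline stage {stage!r} failed") from None
        log.info("[%s] done", stage)

    from importlib.metadata import version as _pkg_version
    try:
        version = _pkg_version("perfmap")
    except Exception:
        version = "unknown"
    manifest = RunManifest(config=config.to_dict(), stages=stages,
                           seed=config.seed, version=version)
    manifest.write(outdir / "manifest.json")
    return manifest
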