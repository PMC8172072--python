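"""End-to-end orchestration: simulate -> prepare -> select -> project -> validate.

Each stage reads/writes plain CSV/JSON artifacts in an output directory and
is individually re-runnable from those artifacts; a manifest records the
config hash, derived per-stage seeds and per-stage row counts. Outputs are
written to ``<name>.partial`` and renamed on stage success, so an aborted
stage leaves its partial artifact behind for inspection.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, models, projection, synthetic, validation
from .mccv import CVConfig, MCCVSelector
from .models import enumerate_candidates

STAGES = ("simulate", "prepare", "select", "project", "validate")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "survey_csv": None,  # external input when simulate is disabled
    "population_csv": None,
    "fit_years": [1991, 2014],
    "validation_years": [2015, 2017],
    "horizon": 2035,
    "simulate": {"years": [1991, 2017], "n_per_year": 8000, "age_range": [18, 95]},
    "prepare": {"min_cell_n": 50},
    "select": {
        "n_runs": 1000,
        "train_fraction": 0.8,
        "families": ["linear", "nonlinear"],
        "outcomes": ["mu", "sigma"],
        "optional_terms": None,
    },
    "project": {"ages": [18, 100], "n_draws": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, **overrides) -> dict:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, raw)
    cfg = _merge(cfg, overrides)
    if cfg["horizon"] < cfg["fit_years"][1]:
        raise ValueError("horizon must not precede the last fitted year")
    return cfg


def stage_seeds(seed: int) -> dict:
    """One deterministic child seed per stage (all < 2**31), so a stage
    re-run in isolation matches the same stage inside a full run."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)
    }


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Artifact:
    """Write-to-partial-then-rename helper."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.partial = self.path.with_name(self.path.name + ".partial")

    def commit(self):
        os.replace(self.partial, self.path)


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    art = _Artifact(path)
    df.to_csv(art.partial, index=False)
    art.commit()
    return art.path


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _merge(DEFAULT_CONFIG, config)
    enabled = list(cfg["stages"])
    seeds = stage_seeds(cfg["seed"])
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "stages": {},
    }

    # fail fast on missing external inputs before any fitting work
    if "simulate" not in enabled:
        for key in ("survey_csv", "population_csv"):
            p = cfg.get(key)
            if p is None or not Path(p).exists():
                raise StageError(
                    "prepare" if key == "survey_csv" else "project",
                    f"{key} is required when simulate is disabled: {p!r} not found",
                )

    survey_path = outdir / "survey.csv"
    population_path = outdir / "population.csv"
    cohorts_path = outdir / "cohorts.csv"
    models_path = outdir / "models.json"

    if "simulate" in enabled:
        sim = dict(cfg["simulate"])
        y0, y1 = sim.pop("years")
        sim["years"] = tuple(range(y0, y1 + 1))
        sim["age_range"] = tuple(sim.get("age_range", (18, 95)))
        gcfg = synthetic.GeneratorConfig(seed=seeds["simulate"], **sim)
        records = synthetic.generate_survey(gcfg)
        art = _Artifact(survey_path)
        synthetic.write_survey_csv(records, art.partial)
        art.commit()
        pop = synthetic.generate_population_weights(
            range(cfg["fit_years"][0], cfg["horizon"] + 1),
            (18, 100),
            growth_rate=0.003,
            seed=seeds["simulate"],
        )
        _write_csv(pop, population_path)
        manifest["stages"]["simulate"] = {
            "survey_rows": len(records),
            "population_rows": len(pop),
            "outputs": [str(survey_path), str(population_path)],
        }
    else:
        survey_path = Path(cfg["survey_csv"])
        population_path = Path(cfg["population_csv"])

    if "prepare" in enabled:
        try:
            records = synthetic.read_survey_csv(survey_path)
            fit_lo, fit_hi = cfg["fit_years"]
            fitset = records[(records["year"] >= fit_lo) & (records["year"] <= fit_hi)]
            kept, removed = cohort.filter_records(fitset)
            cohorts = cohort.build_cohort_dataset(
                cohort.assign_cohorts(kept), min_cell_n=cfg["prepare"]["min_cell_n"]
            )
        except Exception as exc:
            raise StageError("prepare", str(exc)) from exc
        art = _Artifact(cohorts_path)
        cohort.write_cohort_csv(cohorts, art.partial)
        art.commit()
        manifest["stages"]["prepare"] = {
            "removed_fraction": removed,
            "cohort_rows": len(cohorts),
            "outputs": [str(cohorts_path)],
        }

    fitted: dict = {}
    if "select" in enabled:
        try:
            cohorts = cohort.read_cohort_csv(cohorts_path)
            frame = cohort.cohort_model_frame(cohorts)
            sel_cfg = cfg["select"]
            ranking_paths = []
            for outcome in sel_cfg["outcomes"]:
                for family in sel_cfg["families"]:
                    cands = enumerate_candidates(
                        outcome, family, sel_cfg.get("optional_terms")
                    )
                    sel = MCCVSelector(
                        cands,
                        train_fraction=sel_cfg["train_fraction"],
                        n_runs=sel_cfg["n_runs"],
                        random_state=seeds["select"],
                    ).fit(frame)
                    rp = outdir / f"ranking_{outcome}_{family}.csv"
                    art = _Artifact(rp)
                    sel.ranking_.to_csv(art.partial)
                    art.commit()
                    ranking_paths.append(str(rp))
                    wl = outdir / f"winners_{outcome}_{family}.csv"
                    _write_csv(sel.ranking_.winner_log, wl)
                    fitted[f"{outcome}_{family}"] = sel.best_model_
        except StageError:
            raise
        except Exception as exc:
            raise StageError("select", str(exc)) from exc
        art = _Artifact(models_path)
        models.save_models_json(fitted, art.partial)
        art.commit()
        manifest["stages"]["select"] = {
            "selected": {k: m.candidate.id for k, m in fitted.items()},
            "outputs": ranking_paths + [str(models_path)],
        }

    if "project" in enabled:
        try:
            if not fitted:
                fitted = models.load_models_json(models_path)
            pop = synthetic.read_population_csv(population_path)
            a0, a1 = cfg["project"]["ages"]
            years = range(cfg["fit_years"][1] + 1, cfg["horizon"] + 1)
            outputs = []
            for family in cfg["select"]["families"]:
                mu_m = fitted[f"mu_{family}"]
                sig_m = fitted[f"sigma_{family}"]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fc = projection.project(
                        mu_m, sig_m, years, range(a0, a1 + 1), pop,
                        horizon=cfg["horizon"],
                    )
                p = outdir / f"forecast_{family}.csv"
                _write_csv(fc, p)
                outputs.append(str(p))
                n_draws = cfg["project"].get("n_draws", 0)
                if n_draws:
                    ucfg = projection.UncertaintyConfig(
                        n_draws=n_draws, seed=seeds["project"]
                    )
                    ufc = projection.uncertainty(
                        mu_m, sig_m, years, range(a0, a1 + 1), pop, ucfg=ucfg
                    )
                    up = outdir / f"forecast_{family}_intervals.csv"
                    _write_csv(ufc, up)
                    outputs.append(str(up))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("project", str(exc)) from exc
        manifest["stages"]["project"] = {"outputs": outputs}

    if "validate" in enabled:
        try:
            if not fitted:
                fitted = models.load_models_json(models_path)
            records = synthetic.read_survey_csv(survey_path)
            v0, v1 = cfg["validation_years"]
            held = records[(records["year"] >= v0) & (records["year"] <= v1)]
            held, _ = cohort.filter_records(held)
            summary = {}
            cells = []
            for family in cfg["select"]["families"]:
                rep = validation.validate_models(
                    fitted[f"mu_{family}"], fitted[f"sigma_{family}"], held
                )
                summary[f"mae_{family}"] = rep.mae
                summary[f"mae_pct_{family}"] = rep.mae_pct
                summary[f"rmse_{family}"] = rep.rmse
                c = rep.cells.copy()
                c["family"] = family
                cells.append(c)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("validate", str(exc)) from exc
        vp = outdir / "validation.json"
        art = _Artifact(vp)
        with open(art.partial, "w") as fh:
            json.dump(summary, fh, indent=1)
        art.commit()
        _write_csv(pd.concat(cells, ignore_index=True), outdir / "validation_cells.csv")
        manifest["stages"]["validate"] = {
            "summary": summary,
            "outputs": [str(vp), str(outdir / "validation_cells.csv")],
        }

    mpath = outdir / "manifest.json"
    art = _Artifact(mpath)
    with open(art.partial, "w") as fh:
        json.dump(manifest, fh, indent=1)
    art.commit()
    return manifest
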