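"""End-to-end orchestration of the signature-discovery pipeline.

``run_pipeline`` drives the full flow on a YAML config: simulate (or load)
two single-cell cohorts -> QC + normalization -> tumor-vs-blood Treg DE per
cohort -> shared DEGs and their overlap coefficient -> lineage-specificity
filter -> per-variant ensemble best-subset scoring and signature selection
(shared-DEG list plus any supplied gene-list files, e.g. trajectory-branch
lists) -> train/test split and linear-SVM training on the primary survival
cohort -> pan-cohort evaluation.  Every stage writes its table under the run
directory, a JSON manifest records every threshold and seed, and a JSON-lines
log tracks stage execution.
"""

from __future__ import annotations

import json
import time as _time
from pathlib import Path

import pandas as pd
import yaml

from . import deg as deg_mod
from . import io as io_mod
from . import prognosis as prog_mod
from . import specificity as spec_mod
from . import synthetic as syn_mod
from .feature_selection import EnsembleConfig, ensemble_score, select_signature

__all__ = ["validate_config", "run_pipeline"]

REQUIRED_FIELDS = (
    "seed",
    "outdir",
    "sc_cohorts",
    "survival_cohorts",
    "primary_cohort",
    "deg_filter",
    "specificity",
    "ensemble",
    "split",
)


def validate_config(config: dict) -> dict:
    """Check required fields before any stage executes."""
    missing = [f for f in REQUIRED_FIELDS if f not in config]
    if missing:
        raise ValueError(f"pipeline config missing required fields: {missing}")
    if len(config["sc_cohorts"]) < 2:
        raise ValueError("need at least two single-cell cohorts for shared DEGs")
    if config["primary_cohort"] not in config["survival_cohorts"]:
        raise ValueError(
            f"primary_cohort {config['primary_cohort']!r} not among survival_cohorts"
        )
    return config


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def event(self, stage: str, status: str, **extra) -> None:
        rec = {"t": _time.time(), "stage": stage, "status": status, **extra}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _stage(log: _RunLog, name: str):
    class _Ctx:
        def __enter__(self):
            log.event(name, "start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                log.event(name, "done")
            else:
                log.event(name, "error", error=f"{exc_type.__name__}: {exc}")
            return False

    return _Ctx()


def _sc_config(spec: dict, seed: int, offset: int) -> syn_mod.ScSimConfig:
    spec = dict(spec)
    planted = [syn_mod.PlantedGene(*p) for p in spec.pop("planted_de", [])]
    spec.setdefault("seed", seed + offset)
    if "lineages" in spec:
        spec["lineages"] = {
            lin: dict(counts) for lin, counts in spec["lineages"].items()
        }
    return syn_mod.ScSimConfig(planted_de=planted, **spec)


def _surv_config(name: str, spec: dict, seed: int, offset: int) -> syn_mod.SurvSimConfig:
    spec = dict(spec)
    planted = [tuple(p) for p in spec.pop("planted_prognostic", [])]
    spec.setdefault("seed", seed + offset)
    spec.setdefault("cohort", name)
    return syn_mod.SurvSimConfig(planted_prognostic=planted, **spec)


def run_pipeline(config_path: str | Path) -> Path:
    """Execute the pipeline described by the YAML config; returns the run dir."""
    config_path = Path(config_path)
    config = validate_config(yaml.safe_load(config_path.read_text()))
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run_log.jsonl")
    manifest: dict = {
        "config": config,
        "seed": seed,
        "stages": {},
        "versions": {"tregsig": _version()},
    }

    # --- single-cell side -------------------------------------------------
    sc_sets = {}
    with _stage(log, "simulate_sc"):
        for i, (name, spec) in enumerate(sorted(config["sc_cohorts"].items())):
            sc_sets[name] = syn_mod.simulate_sc_cohort(_sc_config(spec, seed, 100 + i))
    with _stage(log, "qc_normalize"):
        for name in sc_sets:
            cset = io_mod.qc_filter_cells(
                sc_sets[name], **config.get("qc", {"min_genes": 1, "max_genes": 10**9})
            )
            sc_sets[name] = io_mod.zscore_genes(io_mod.normalize_lognorm(cset))

    deg_filter = deg_mod.DegFilter(**config["deg_filter"])
    tables = {}
    with _stage(log, "deg"):
        for name, cset in sc_sets.items():
            table = deg_mod.rank_sum_de(
                cset,
                cset.cell_mask(tissue="TI", lineage="Treg"),
                cset.cell_mask(tissue="PB", lineage="Treg"),
            )
            table.to_csv(outdir / f"deg_{name}.tsv", sep="\t")
            tables[name] = table

    with _stage(log, "shared_degs"):
        ordered = [tables[n] for n in sorted(tables)]
        shared = deg_mod.shared_degs(ordered, deg_filter, direction="up")
        per_cohort = {
            n: deg_mod.apply_deg_filter(tables[n], deg_filter, "up") for n in sorted(tables)
        }
        names = sorted(tables)
        overlap = (
            deg_mod.overlap_coefficient(per_cohort[names[0]], per_cohort[names[1]])
            if all(len(per_cohort[n]) for n in names[:2])
            else float("nan")
        )
        (outdir / "shared_degs.txt").write_text("\n".join(shared) + "\n")
        manifest["stages"]["shared_degs"] = {
            "n_per_cohort": {n: int(len(per_cohort[n])) for n in names},
            "n_shared": int(len(shared)),
            "overlap_coefficient": overlap,
        }

    with _stage(log, "specificity"):
        first = sc_sets[sorted(sc_sets)[0]]
        spec_cfg = dict(config["specificity"])
        if "other_lineages" in spec_cfg:
            spec_cfg["other_lineages"] = tuple(spec_cfg["other_lineages"])
        treg_specific = spec_mod.lineage_specificity_filter(first, **spec_cfg)
        (outdir / "treg_specific_genes.txt").write_text("\n".join(treg_specific) + "\n")
        manifest["stages"]["specificity"] = {"n_pass": int(len(treg_specific))}

    # --- candidate gene-set variants ---------------------------------------
    variants: dict[str, list[str]] = {
        "shared": [g for g in shared if g in set(treg_specific)]
    }
    for vname, path in config.get("gene_lists", {}).items():
        genes = [
            g.strip() for g in Path(path).read_text().splitlines() if g.strip()
        ]
        variants[vname] = [g for g in genes if g in set(treg_specific)]

    # --- survival side ------------------------------------------------------
    cohorts = {}
    with _stage(log, "simulate_survival"):
        for i, (name, spec) in enumerate(sorted(config["survival_cohorts"].items())):
            cohorts[name] = syn_mod.simulate_survival_cohort(
                _surv_config(name, spec, seed, 200 + i)
            )
            io_mod.write_survival_tsv(cohorts[name], outdir / f"survival_{name}.tsv")

    primary = cohorts[config["primary_cohort"]]
    split = prog_mod.SplitSpec(seed=seed, **config["split"])
    train, test = prog_mod.split_cohort(primary, split)
    manifest["stages"]["split"] = {"n_train": train.n_samples, "n_test": test.n_samples}

    results: dict[str, dict] = {}
    for vname, candidates in variants.items():
        with _stage(log, f"select_{vname}"):
            if len(candidates) < config["ensemble"].get("subset_size", 5):
                manifest["stages"][f"select_{vname}"] = {
                    "skipped": f"only {len(candidates)} candidates pass the filters"
                }
                log.event(f"select_{vname}", "skipped", n_candidates=len(candidates))
                continue
            ens_cfg = EnsembleConfig(
                candidate_genes=candidates, seed=seed, **config["ensemble"]
            )
            score = ensemble_score(train, ens_cfg)
            signature = select_signature(score, ens_cfg)
            pd.DataFrame(
                {"points": score.points, "inclusions": score.inclusions}
            ).to_csv(outdir / f"ensemble_points_{vname}.tsv", sep="\t")
            (outdir / f"signature_{vname}.txt").write_text("\n".join(signature) + "\n")
            manifest["stages"][f"select_{vname}"] = {
                "n_candidates": len(candidates),
                "rounds": ens_cfg.rounds,
                "min_inclusions": int(score.inclusions.min()),
                "max_inclusions": int(score.inclusions.max()),
                "n_models": score.n_models,
                "signature": signature,
            }

        with _stage(log, f"prognose_{vname}"):
            model = prog_mod.train_survival_classifier(train, signature)
            model.to_json(outdir / f"model_{vname}.json")
            eval_cohorts = [test] + [
                cohorts[n] for n in sorted(cohorts) if n != config["primary_cohort"]
            ]
            _, table = prog_mod.pan_cohort_evaluation(eval_cohorts, model)
            table.to_csv(outdir / f"evaluation_{vname}.tsv", sep="\t")
            results[vname] = {
                "signature": signature,
                "cost": model.cost,
                "evaluation": json.loads(table.to_json(orient="index")),
            }
            if "grade_stratify" in config:
                gval = config["grade_stratify"]
                try:
                    gev = prog_mod.grade_stratified_evaluation(
                        test, prog_mod.predict_outcome_groups(model, test), gval
                    )
                    results[vname]["grade_stratified"] = gev.row()
                except ValueError as exc:
                    results[vname]["grade_stratified"] = {"error": str(exc)}

    manifest["results"] = results
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.event("pipeline", "done")
    return outdir


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("tregsig")
    except PackageNotFoundError:
        return "dev"
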