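"""End-to-end pipeline: outcome -> binarize -> mine -> bayes -> reports.

Everything is a pure function of (input files, configs, seed): the manifest
records sha256 digests of inputs and outputs plus run parameters and
contains no timestamps, so repeated runs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np

from . import __version__
from .bayes import DEFAULT_DRAWS, path_posterior
from .coding import binarize, load_codings
from .errors import GuhaPathsError, PipelineError, ValidationError
from .lifetable import (
    BufferSpec,
    LifeTable,
    buffer_sensitivity,
    compute_outcomes,
    write_sensitivity_report,
)
from .mining import (
    ScheduleResult,
    load_schedule,
    paths_to_frame,
    predicate_frequency,
    run_schedule,
    stratified_run,
)

import pandas as pd

log = logging.getLogger("guhapaths")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    cohort_csv: str
    life_table_csv: str
    coding_path: str
    schedule_path: str
    out_dir: str
    seed: int
    buffer_months: tuple[int, ...] = (3, 6, 9)
    primary_buffer: int = 9
    stratify_by: str | None = None
    posterior_draws: int = DEFAULT_DRAWS
    log_level: str = "INFO"

    def validate(self) -> None:
        for label in ("cohort_csv", "life_table_csv", "coding_path", "schedule_path"):
            path = getattr(self, label)
            if not FsPath(path).is_file():
                raise ValidationError(f"{label} does not exist: {path}")
        if self.primary_buffer not in self.buffer_months:
            raise ValidationError(
                f"primary buffer {self.primary_buffer} not among {self.buffer_months}"
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GuhaPathsError as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return decorate


@_stage("load")
def _load(cfg: PipelineConfig):
    cohort = pd.read_csv(cfg.cohort_csv)
    life_table = LifeTable.from_csv(cfg.life_table_csv)
    codings = load_codings(cfg.coding_path)
    schedule = load_schedule(cfg.schedule_path)
    return cohort, life_table, codings, schedule


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write the artifact bundle; returns the manifest."""
    logging.basicConfig(level=cfg.log_level)
    cfg.validate()
    out = FsPath(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort, life_table, codings, schedule = _load(cfg)

    # Outcome stage: primary-buffer classification plus buffer sensitivity.
    @_stage("outcome")
    def _outcome():
        outcomes = compute_outcomes(cohort, life_table, BufferSpec(cfg.primary_buffer))
        report = buffer_sensitivity(outcomes, cfg.buffer_months)
        return outcomes, report

    outcomes, sensitivity = _outcome()
    outcomes.to_csv(out / "outcomes.csv", index=False)
    write_sensitivity_report(sensitivity, out / "sensitivity.json")

    @_stage("binarize")
    def _binarize():
        return binarize(cohort, codings, outcomes)

    matrix = _binarize()
    matrix.to_csv(out / "matrix.csv", out / "matrix_meta.json")

    @_stage("mine")
    def _mine():
        if cfg.stratify_by:
            strata = stratified_run(matrix, schedule, cfg.stratify_by)
            return None, strata
        return run_schedule(matrix, schedule), None

    schedule_result, strata = _mine()

    mined: dict[str, ScheduleResult] = (
        {"all": schedule_result} if schedule_result is not None else strata
    )
    path_counts = {}
    for name, result in mined.items():
        suffix = "" if name == "all" else f"_{name}"
        paths_to_frame(result.unique_paths).to_csv(
            out / f"paths{suffix}.tsv", sep="\t", index=False
        )
        with open(out / f"paths{suffix}.json", "w") as fh:
            json.dump(
                [
                    {
                        "predicates": list(p.antecedent),
                        "table": p.table.to_json(),
                        "freq_coefficient": p.freq_coefficient,
                        "fisher_p": p.fisher_p,
                        "tasks": sorted(p.tasks),
                    }
                    for p in result.unique_paths
                ],
                fh,
                indent=2,
            )
            fh.write("\n")
        predicate_frequency(result).to_csv(
            out / f"predicate_frequency{suffix}.tsv", sep="\t"
        )
        path_counts[name] = {
            "per_task": result.per_task_counts,
            "unique": len(result.unique_paths),
            "verifications": {
                label: res.verifications for label, res in result.task_results.items()
            },
        }
        for label, res in result.task_results.items():
            log.info(
                "stratum=%s task=%s paths=%d verifications=%d pruned=%d",
                name, label, len(res.paths), res.verifications, res.pruned,
            )

    # Bayesian stage: posterior per unique path at the strictest p among the
    # tasks that found it; per-path seeds spawned from the pipeline seed.
    @_stage("bayes")
    def _bayes():
        rows = []
        for name, result in mined.items():
            p_by_label = {t.label: t.p for t in schedule}
            seeds = np.random.SeedSequence(cfg.seed).generate_state(
                max(1, len(result.unique_paths))
            )
            for i, path in enumerate(result.unique_paths):
                p_task = max(p_by_label[label] for label in path.tasks)
                summary = path_posterior(
                    path.table,
                    p_task=p_task,
                    draws=cfg.posterior_draws,
                    seed=int(seeds[i] % (2**31)),
                    path=path.antecedent,
                )
                rows.append(
                    {
                        "stratum": name,
                        "predicates": ";".join(path.antecedent),
                        "ratio_mean": summary.ratio_mean,
                        "ci_low": summary.ci_low,
                        "ci_high": summary.ci_high,
                        "level": summary.level,
                        "p_task": summary.p_task,
                        "prob_exceeds": summary.prob_exceeds,
                        "draws": summary.draws,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "stratum", "predicates", "ratio_mean", "ci_low", "ci_high",
                "level", "p_task", "prob_exceeds", "draws",
            ],
        )

    posteriors = _bayes()
    posteriors.to_csv(out / "posteriors.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "inputs": {
            "cohort_csv": _sha256(cfg.cohort_csv),
            "life_table_csv": _sha256(cfg.life_table_csv),
            "coding_path": _sha256(cfg.coding_path),
            "schedule_path": _sha256(cfg.schedule_path),
        },
        "config": {
            "buffer_months": list(cfg.buffer_months),
            "primary_buffer": cfg.primary_buffer,
            "stratify_by": cfg.stratify_by,
            "posterior_draws": cfg.posterior_draws,
        },
        "counts": {
            "rows": int(len(cohort)),
            "predicates": int(matrix.n_columns - 1),
            "deaths": int((outcomes["vital_status"] == "died").sum()),
            "premature": int(outcomes["premature"].sum()),
            "paths": path_counts,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
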