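"""End-to-end orchestration: generate → randomize → landmark → report.

``run_full_study`` executes the whole simulation study and writes every
artifact (registry, allocation, endpoint and results tables, a statistics
JSON, and a run log with content hashes); ``replay_from_registry`` runs only
the analysis stages on existing registry/allocation files — the path a user
with real registry data takes.  ``replicate_significance`` repeats the
pipeline in memory across seeds to study the sampling distribution of the
arm-versus-control tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import landmark as lm
from .generator import GeneratorConfig, GeneratorError, generate_cohort, realized_marginals
from .inference import (
    InferenceError,
    build_results_table,
    n1_chi_squared,
    nnr,
    rate_z_test,
)
from .landmark import DEFAULT_LANDMARKS, LandmarkError, apply_landmark, endpoint_table
from .randomization import (
    AllocationTable,
    CONTROL_ARM,
    RandomizationError,
    allocate,
    allocation_summary,
)
from .registry import Cohort, RegistryError, read_registry, write_registry

__all__ = ["RunConfig", "StudyResult", "PipelineError", "run_full_study",
           "replay_from_registry", "analyze", "replicate_significance"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulation-study run.

    Seeds are explicit — there are no wall-clock defaults, so a config fully
    determines its outputs.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    block_size: int = 4
    landmarks: Mapping[str, Optional[int]] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARKS))
    randomization_seed: int = 1
    truncate_to_balance: bool = False
    output_dir: Optional[str] = None

    def validate(self) -> None:
        self.generator.validate()
        days = [d for d in self.landmarks.values() if d is not None]
        if any(d < 1 for d in days) or len(set(days)) != len(days):
            raise PipelineError("config", "landmark days must be positive and distinct")
        if CONTROL_ARM not in self.landmarks or self.landmarks[CONTROL_ARM] is not None:
            raise PipelineError("config", "Control arm must be present and unbounded")

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "block_size": self.block_size,
            "landmarks": dict(self.landmarks),
            "randomization_seed": self.randomization_seed,
            "truncate_to_balance": self.truncate_to_balance,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"generator", "block_size", "landmarks", "randomization_seed",
                 "truncate_to_balance", "output_dir"}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown run config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig.from_dict(kwargs["generator"])
        return cls(**kwargs)


@dataclass
class StudyResult:
    """In-memory bundle of one study run."""

    cohort: Cohort
    table: AllocationTable
    truncated: list
    endpoints: pd.DataFrame
    results: pd.DataFrame
    stats: dict
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> path


def _comparisons(endpoints: pd.DataFrame) -> tuple[list, dict, dict]:
    """All arm-vs-control tests and NNRs from a tidy endpoint table."""
    comps, nnrs, ep_objs = [], {}, {}
    for _, row in endpoints.iterrows():
        ep_objs[(row["crbsi_definition"], row["arm"])] = lm.EndpointResult(
            arm=row["arm"], crbsi_definition=row["crbsi_definition"],
            n_cvc=int(row["n_cvc"]), events=int(row["events"]),
            cvc_days=int(row["cvc_days"]))
    for definition in lm.CRBSI_DEFINITIONS:
        control = ep_objs.get((definition, CONTROL_ARM))
        if control is None:
            raise InferenceError(f"missing {CONTROL_ARM} arm for definition {definition!r}")
        for (defn, arm), ep in ep_objs.items():
            if defn != definition or arm == CONTROL_ARM:
                continue
            try:
                comps.append(n1_chi_squared(ep.events, ep.n_cvc,
                                            control.events, control.n_cvc,
                                            arm_summary=ep, control_summary=control))
            except InferenceError:
                pass  # zero-margin table: no test, cell stays empty
            try:
                comps.append(rate_z_test(ep.events, ep.cvc_days,
                                         control.events, control.cvc_days,
                                         arm_summary=ep, control_summary=control))
            except InferenceError:
                pass
            try:
                if ep.n_cvc == control.n_cvc:
                    nnrs[(definition, arm)] = nnr(control.events, ep.events, ep.n_cvc)
            except InferenceError:
                pass  # no preventable events: NNR undefined
    return comps, nnrs, ep_objs


def analyze(cohort: Cohort, table: AllocationTable,
            landmarks: Mapping[str, Optional[int]] = DEFAULT_LANDMARKS,
            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Landmark truncation plus the full inference layer.

    Returns (endpoint table, results table, statistics dict).
    """
    truncated = apply_landmark(cohort, table, landmarks)
    endpoints = endpoint_table(truncated)
    comps, nnrs, _ = _comparisons(endpoints)
    results = build_results_table(_endpoint_objects(endpoints), comps, nnrs)
    stats = {
        "comparisons": [
            {
                "crbsi_definition": c.arm_summary.crbsi_definition,
                "arm": c.arm_summary.arm,
                "statistic_name": c.statistic_name,
                "statistic_value": c.statistic_value,
                "p_value": c.p_value,
            }
            for c in comps
        ],
        "nnr": {f"{d}:{a}": v for (d, a), v in sorted(nnrs.items())},
    }
    return endpoints, results, stats


def _endpoint_objects(endpoints: pd.DataFrame) -> list:
    return [
        lm.EndpointResult(arm=row["arm"], crbsi_definition=row["crbsi_definition"],
                          n_cvc=int(row["n_cvc"]), events=int(row["events"]),
                          cvc_days=int(row["cvc_days"]))
        for _, row in endpoints.iterrows()
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_artifacts(out: Path, cohort, table, endpoints, results, stats,
                     config_dict: dict, audit: dict) -> dict[str, str]:
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": out / "registry.csv",
        "allocation": out / "allocation.csv",
        "endpoints": out / "endpoints.csv",
        "results": out / "results.csv",
        "results_json": out / "results.json",
    }
    write_registry(cohort, paths["registry"])
    table.to_frame().to_csv(paths["allocation"], index=False)
    endpoints.to_csv(paths["endpoints"], index=False)
    results.to_csv(paths["results"], index=False)
    payload = {"stats": stats, "audit": audit}
    paths["results_json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                                     encoding="utf-8")
    log = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "artifact_sha256": {k: _sha256(p) for k, p in paths.items()},
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["run_log"] = log_path
    return {k: str(p) for k, p in paths.items()}


def run_full_study(config: RunConfig) -> StudyResult:
    """Run generate → randomize → landmark → report; write all artifacts.

    Re-running with an identical config reproduces byte-identical outputs.
    """
    config.validate()
    try:
        cohort = generate_cohort(config.generator)
    except GeneratorError as exc:
        raise PipelineError("generate", str(exc)) from exc
    try:
        table = allocate(cohort, block_size=config.block_size,
                         seed=config.randomization_seed,
                         truncate_to_balance=config.truncate_to_balance)
    except RandomizationError as exc:
        raise PipelineError("randomize", str(exc)) from exc
    try:
        endpoints, results, stats = analyze(cohort, table, config.landmarks)
        truncated = apply_landmark(cohort, table, config.landmarks)
    except (LandmarkError, InferenceError, RandomizationError) as exc:
        raise PipelineError("landmark-analysis", str(exc)) from exc

    audit = {"generator_marginals": realized_marginals(cohort),
             "arm_counts": allocation_summary(table, cohort).loc["Total"].to_dict()}
    artifacts: dict[str, str] = {}
    if config.output_dir is not None:
        artifacts = _write_artifacts(Path(config.output_dir), cohort, table,
                                     endpoints, results, stats,
                                     config.to_dict(), audit)
    return StudyResult(cohort=cohort, table=table, truncated=truncated,
                       endpoints=endpoints, results=results, stats=stats,
                       artifacts=artifacts)


def replay_from_registry(registry_path, allocation_path,
                         landmarks: Mapping[str, Optional[int]] = DEFAULT_LANDMARKS,
                         output_dir: Optional[str] = None,
                         strict: bool = True) -> StudyResult:
    """Run landmark + inference only, on existing registry/allocation files."""
    try:
        cohort = read_registry(registry_path, strict=strict)
    except RegistryError as exc:
        raise PipelineError("read-registry", str(exc)) from exc
    try:
        frame = pd.read_csv(allocation_path, dtype=str)
        table = AllocationTable.from_frame(frame)
    except (RandomizationError, OSError, pd.errors.ParserError) as exc:
        raise PipelineError("read-allocation", str(exc)) from exc
    try:
        endpoints, results, stats = analyze(cohort, table, landmarks)
        truncated = apply_landmark(cohort, table, landmarks)
    except (LandmarkError, InferenceError, RandomizationError) as exc:
        raise PipelineError("landmark-analysis", str(exc)) from exc

    audit = {"generator_marginals": realized_marginals(cohort)}
    artifacts: dict[str, str] = {}
    if output_dir is not None:
        artifacts = _write_artifacts(Path(output_dir), cohort, table, endpoints,
                                     results, stats,
                                     {"replay": {"registry": str(registry_path),
                                                 "allocation": str(allocation_path)}},
                                     audit)
    return StudyResult(cohort=cohort, table=table, truncated=truncated,
                       endpoints=endpoints, results=results, stats=stats,
                       artifacts=artifacts)


def replicate_significance(config: RunConfig, n_runs: int, seed: int = 1,
                           ) -> pd.DataFrame:
    """Sampling distribution of arm-vs-control tests over repeated studies.

    Runs the in-memory pipeline ``n_runs`` times with generator and
    randomization seeds derived deterministically from ``seed``; returns one
    row per (run, definition, arm) with the incidence z-test and N−1 χ²
    p-values and the incidence difference sign.
    """
    rows = []
    for i in range(n_runs):
        gen_seed = (seed * 1_000_003 + i) % (2 ** 31)
        rand_seed = (seed * 7_000_003 + i) % (2 ** 31)
        cfg = replace(config, generator=config.generator.with_seed(gen_seed),
                      randomization_seed=rand_seed, output_dir=None)
        cohort = generate_cohort(cfg.generator)
        table = allocate(cohort, block_size=cfg.block_size, seed=cfg.randomization_seed,
                         truncate_to_balance=cfg.truncate_to_balance)
        truncated = apply_landmark(cohort, table, cfg.landmarks)
        endpoints = endpoint_table(truncated)
        comps, _, _ = _comparisons(endpoints)
        for c in comps:
            if c.statistic_name != "rate_z":
                continue
            rows.append({
                "run": i,
                "crbsi_definition": c.arm_summary.crbsi_definition,
                "arm": c.arm_summary.arm,
                "p_value": c.p_value,
                "arm_below_control": (c.arm_summary.incidence_per_1000
                                      < c.control_summary.incidence_per_1000),
            })
    return pd.DataFrame(rows)
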