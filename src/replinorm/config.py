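"""Run configuration: parsing, validation, and the end-to-end pipeline.

A run config is a YAML (or JSON) document with sections ``norms``,
``environment``, ``design``, ``criteria``, ``simulation``, ``gradient`` and
``output``, plus a top-level integer ``seed`` and a ``task`` selecting what
the pipeline does:

* ``multilab`` — simulate a multi-lab dataset, summarize it per lab, and run
  RLM inference with the moment-estimated GxE variance;
* ``gradient`` — build the environmental-gradient study collection and run
  the conditional-effect regression;
* ``coverage`` — run the classical-vs-RLM coverage experiment.

Every run has an explicit integer seed; unknown keys anywhere are rejected
with the offending field path.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .errors import ConfigError
from .norms import (
    EnvironmentDistribution,
    ReactionNorm,
    flat_norm,
    gaussian_environment,
    linear_norm,
    logistic_norm,
    quadratic_norm,
    tabulated_environment,
    tabulated_norm,
    uniform_environment,
)
from .replication import DEFAULT_L, DEFAULT_Z, conditional_effect_regression
from .rlm import coverage_experiment, estimate_gxe_variance, rlm_contrast
from .simulate import (
    StudyDesign,
    make_gradient_fixture,
    results_to_frame,
    simulate_multilab,
    summarize_labs,
)

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_TASKS = ("multilab", "gradient", "coverage")


def _reject_unknown(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


def _as_float(value: Any, path: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}: expected a number, got {value!r}") from None


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (structure mirrors the YAML document)."""

    seed: int
    task: str
    norms: tuple[dict, ...]
    environment: dict
    design: dict | None = None
    criteria: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    gradient: dict | None = None
    output: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "seed": self.seed,
            "task": self.task,
            "norms": [dict(n) for n in self.norms],
            "environment": dict(self.environment),
            "criteria": dict(self.criteria),
            "simulation": dict(self.simulation),
            "output": dict(self.output),
        }
        if self.design is not None:
            out["design"] = dict(self.design)
        if self.gradient is not None:
            out["gradient"] = dict(self.gradient)
        return out

    def serialize(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    # -- materialization -------------------------------------------------

    def build_norms(self) -> dict[str, ReactionNorm]:
        norms: dict[str, ReactionNorm] = {}
        for i, spec in enumerate(self.norms):
            path = f"norms[{i}]"
            label = spec["genotype"]
            shape = spec["shape"]
            params = spec.get("params", {})
            domain = tuple(spec["domain"]) if "domain" in spec else (-math.inf, math.inf)
            try:
                if shape == "flat":
                    norm = flat_norm(params["value"], label, domain)
                elif shape == "linear":
                    norm = linear_norm(params["intercept"], params["slope"], label, domain)
                elif shape == "quadratic":
                    norm = quadratic_norm(params["a"], params["b"], params["c"], label, domain)
                elif shape == "logistic":
                    norm = logistic_norm(params["lower"], params["upper"],
                                         params["midpoint"], params["scale"], label, domain)
                elif shape == "tabulated":
                    norm = tabulated_norm(params["x"], params["y"], label)
                else:
                    raise ConfigError(f"{path}.shape: unknown shape {shape!r}")
            except KeyError as exc:
                raise ConfigError(f"{path}.params: missing parameter {exc}") from None
            if label in norms:
                raise ConfigError(f"{path}: duplicate genotype label {label!r}")
            norms[label] = norm
        return norms

    def build_environment(self) -> EnvironmentDistribution:
        family = self.environment["family"]
        params = self.environment.get("params", {})
        try:
            if family == "gaussian":
                return gaussian_environment(params["mu"], params["sigma"])
            if family == "uniform":
                return uniform_environment(params["lo"], params["hi"])
            if family == "tabulated":
                return tabulated_environment(params["x"], params["density"])
        except KeyError as exc:
            raise ConfigError(f"environment.params: missing parameter {exc}") from None
        raise ConfigError(f"environment.family: unknown family {family!r}")

    def build_design(self) -> StudyDesign:
        if self.design is None:
            raise ConfigError("design: section required for this task")
        norms = self.build_norms()
        d = self.design
        genotypes = []
        for label in d["genotypes"]:
            if label not in norms:
                raise ConfigError(
                    f"design.genotypes: genotype {label!r} is not defined in norms"
                )
            genotypes.append(norms[label])
        return StudyDesign(
            n_labs=int(d["n_labs"]),
            n_per_arm=int(d["n_per_arm"]),
            genotypes=tuple(genotypes),
            standardization=d.get("standardization", "heterogenized"),
            within_noise_sd=_as_float(d.get("within_noise_sd", 1.0), "design.within_noise_sd"),
            small_effect_sd=_as_float(d.get("small_effect_sd", 0.0), "design.small_effect_sd"),
            delta0=_as_float(d.get("delta0", 0.0), "design.delta0"),
            delta1=_as_float(d.get("delta1", 0.0), "design.delta1"),
        )

    @property
    def z(self) -> float:
        return float(self.criteria.get("z", DEFAULT_Z))

    @property
    def L(self) -> float:
        return float(self.criteria.get("L", DEFAULT_L))

    @property
    def confidence(self) -> float:
        return float(self.criteria.get("confidence", 0.95))


def _validate(raw: Any, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    _reject_unknown(raw, {"seed", "task", "norms", "environment", "design",
                          "criteria", "simulation", "gradient", "output"}, source)
    if "seed" not in raw or not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
        raise ConfigError("seed: an explicit integer seed is required "
                          "(wall-clock seeding is not supported)")
    task = raw.get("task", "multilab")
    if task not in _TASKS:
        raise ConfigError(f"task: must be one of {_TASKS}, got {task!r}")
    norms_raw = raw.get("norms", [])
    if not isinstance(norms_raw, list):
        raise ConfigError("norms: must be a list")
    for i, spec in enumerate(norms_raw):
        if not isinstance(spec, dict):
            raise ConfigError(f"norms[{i}]: must be a mapping")
        _reject_unknown(spec, {"genotype", "shape", "params", "domain"}, f"norms[{i}]")
        for req in ("genotype", "shape"):
            if req not in spec:
                raise ConfigError(f"norms[{i}].{req}: required")
    env = raw.get("environment")
    if not isinstance(env, dict) or "family" not in env:
        raise ConfigError("environment: mapping with a 'family' key required")
    _reject_unknown(env, {"family", "params"}, "environment")
    design = raw.get("design")
    if design is not None:
        _reject_unknown(design, {"n_labs", "n_per_arm", "genotypes", "standardization",
                                 "within_noise_sd", "small_effect_sd",
                                 "delta0", "delta1"}, "design")
        for req in ("n_labs", "n_per_arm", "genotypes"):
            if req not in design:
                raise ConfigError(f"design.{req}: required")
    criteria = raw.get("criteria", {})
    _reject_unknown(criteria, {"z", "L", "confidence"}, "criteria")
    simulation = raw.get("simulation", {})
    _reject_unknown(simulation, {"n_replicates"}, "simulation")
    gradient = raw.get("gradient")
    if gradient is not None:
        _reject_unknown(gradient, {"n_studies", "x_range", "delta0", "delta1",
                                   "se_per_study", "n_per_arm"}, "gradient")
    output = raw.get("output", {})
    _reject_unknown(output, {"dir"}, "output")

    config = RunConfig(
        seed=raw["seed"], task=task,
        norms=tuple(norms_raw), environment=env, design=design,
        criteria=criteria, simulation=simulation, gradient=gradient,
        output=output,
    )
    # materialize once so cross-references and parameters fail at load time
    config.build_norms()
    config.build_environment()
    if task in ("multilab", "coverage"):
        config.build_design()
    return config


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON ({exc})") from exc
    return _validate(raw, str(path))


def parse_config(text: str) -> RunConfig:
    """Validate a configuration given as a YAML/JSON string."""
    return _validate(yaml.safe_load(text), "<string>")


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured task and write its outputs plus a manifest.

    Returns the manifest (seed, package version, config hash, output paths).
    Identical configs produce byte-identical outputs; on failure any
    partially written outputs are removed.
    """
    out = Path(out_dir if out_dir is not None else config.output.get("dir", "replinorm_out"))
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        written.append(p)
        return p

    try:
        if config.task == "multilab":
            design = config.build_design()
            env = config.build_environment()
            data = simulate_multilab(design, env, config.seed)
            emit("dataset.csv", data.to_csv)
            results = summarize_labs(data)
            emit("summaries.csv",
                 lambda p: results_to_frame(results).to_csv(p, index=False))
            payload: dict[str, Any] = {}
            if design.n_labs >= 3:
                s2_gxe, components = estimate_gxe_variance(data)
                payload["s2_gxe_estimate"] = s2_gxe
                payload["components"] = components
                payload["contrasts"] = [
                    rlm_contrast(r, s2_gxe, config.confidence).to_dict()
                    for r in results
                ]
            emit("rlm.json", lambda p: _json_dump(payload, p))
        elif config.task == "gradient":
            g = dict(config.gradient or {})
            studies = make_gradient_fixture(
                n_studies=int(g.get("n_studies", 25)),
                x_range=tuple(g.get("x_range", (18.0, 30.0))),
                delta0=float(g.get("delta0", 0.0)),
                delta1=float(g.get("delta1", 0.25)),
                se_per_study=float(g.get("se_per_study", 0.5)),
                seed=config.seed,
                n_per_arm=int(g.get("n_per_arm", 10)),
            )
            emit("studies.csv",
                 lambda p: results_to_frame(studies).to_csv(p, index=False))
            fit = conditional_effect_regression(studies, z=config.z)
            emit("gradient_regression.json", lambda p: _json_dump({
                "slope": fit.slope, "intercept": fit.intercept,
                "slope_se": fit.slope_se, "intercept_se": fit.intercept_se,
                "success_rate": fit.success_rate,
                "success": [bool(s) for s in fit.success],
            }, p))
        elif config.task == "coverage":
            design = config.build_design()
            env = config.build_environment()
            n_replicates = int(config.simulation.get("n_replicates", 1000))
            table = coverage_experiment(design, env, n_replicates,
                                        seed=config.seed,
                                        confidence=config.confidence)
            emit("coverage.csv", lambda p: table.to_csv(p, index=False))
        else:  # pragma: no cover - guarded at validation
            raise ConfigError(f"unknown task {config.task!r}")

        config_hash = hashlib.sha256(config.serialize().encode("utf-8")).hexdigest()
        manifest = {
            "seed": config.seed,
            "task": config.task,
            "package_version": __version__,
            "config_sha256": config_hash,
            "outputs": sorted(p.name for p in written),
        }
        _json_dump(manifest, out / "manifest.json")
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
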