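"""One-command orchestration: read or simulate inputs, fit, write a report.

The config (a YAML mapping or plain dict) either points at the three input
files or embeds a simulation scenario:

    inputs:
      matrix: counts.csv
      hierarchy: hierarchy.yaml     # or two-column CSV
      traits: traits.csv            # optional -> TD-only analysis
    # or:
    simulate:
      seed: 1
      niche_breadth: 0.5
      ...                           # any GradientScenario field
    null:
      n_perm: 999
      stats: [alpha2, beta2, gamma]
      models: [binary, abundance]
    convention: mean-then-correct
    biomass_bins: 2
    output_dir: results/run1

All results are pure functions of (inputs, config, seed); logging goes to
stderr, outputs to files under ``output_dir``.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .data import read_community_matrix, read_hierarchy, read_trait_table
from .model import DiversityModel, DiversityResults
from .simulate import GradientScenario, generate

__all__ = ["AnalysisReport", "run"]


def _log(msg: str) -> None:
    print(f"[divrao] {msg}", file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class AnalysisReport:
    results: DiversityResults
    manifest: dict
    config: dict

    def to_dict(self) -> dict:
        return {
            "software": {"name": "divrao", "version": __version__},
            "manifest": self.manifest,
            "config": self.config,
            **self.results.to_dict(),
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        self.results.partition_frame().to_csv(outdir / "partition.csv", index=False)
        self.results.beta_frame().to_csv(outdir / "beta.csv", index=False)
        if self.results.null_results:
            self.results.null_frame().to_csv(outdir / "null.csv", index=False)
        return outdir / "report.json"


def run(config: dict | str | Path) -> AnalysisReport:
    """Execute the full analysis described by ``config``."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    manifest: dict = {}

    if "simulate" in config:
        sc = GradientScenario(**config.get("simulate", {}))
        _log(f"simulating scenario (seed {sc.seed})")
        matrix, traits, hierarchy, truth = generate(sc)
        manifest["simulated"] = {"seed": sc.seed, "scenario": sc.to_dict()}
        outdir = config.get("output_dir")
        if outdir:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            matrix.to_csv(out / "matrix.csv")
            traits.to_csv(out / "traits.csv")
            hierarchy.to_frame().to_csv(out / "hierarchy.csv", index=False)
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
    elif "inputs" in config:
        paths = config["inputs"]
        _log(f"reading inputs from {paths['matrix']}")
        matrix = read_community_matrix(paths["matrix"])
        hierarchy = read_hierarchy(paths["hierarchy"])
        traits = read_trait_table(paths["traits"]) if paths.get("traits") else None
        if traits is None:
            _log("no trait table: functional stages skipped")
        manifest["inputs"] = {
            k: {"path": str(v), "sha256": _sha256(Path(v))}
            for k, v in paths.items() if v
        }
    else:
        raise ValueError("config needs an 'inputs' or 'simulate' section")

    null_cfg = config.get("null", {})
    model = DiversityModel(
        matrix,
        hierarchy,
        traits=traits,
        convention=config.get("convention", "mean-then-correct"),
        biomass_bins=config.get("biomass_bins", 2),
    )
    _log("fitting partitions, decompositions and null models")
    results = model.fit(
        n_null=null_cfg.get("n_perm", 999),
        seed=null_cfg.get("seed", config.get("seed", 0)),
        null_stats=tuple(null_cfg.get("stats", ("alpha2", "beta2", "gamma"))),
        null_models=tuple(null_cfg.get("models", ("binary", "abundance"))),
    )
    report = AnalysisReport(results=results, manifest=manifest, config=dict(config))
    outdir = config.get("output_dir")
    if outdir:
        path = report.write(outdir)
        _log(f"report written to {path}")
    return report
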