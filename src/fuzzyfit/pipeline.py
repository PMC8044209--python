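"""Stage orchestration: run a multi-stage analysis from a single YAML config.

A pipeline is an ordered list of stages; each stage names its type, inputs,
outputs and parameters.  Outputs are written under the run's output directory
and a manifest (input checksums, parameters, package version, per-stage
runtimes) proves determinism: re-running the same config and seed reproduces
byte-identical outputs.

The ``demo`` recipe is the end-to-end fuzzy-binding demonstration: simulate a
multi-state truth, build PRE profiles, scan ensemble sizes 1..n and report the
minimal adequate and plateau sizes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ensemble as ens
from . import simulate as sim
from .nmr_io import write_peak_list, write_profile, write_structure
from .pre import pre_profile

log = logging.getLogger("fuzzyfit")

_PKG_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline description."""

    seed: int
    out_dir: Path
    stages: list = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(seed=int(raw.get("seed", 0)),
                  out_dir=Path(raw.get("out_dir", "fuzzyfit_out")),
                  stages=list(raw.get("stages", [])),
                  log_level=str(raw.get("log_level", "INFO")))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.stages:
            raise PipelineError("pipeline has no stages")
        names = set()
        for st in self.stages:
            if "type" not in st:
                raise PipelineError(f"stage without a type: {st}")
            if st["type"] not in _STAGES:
                raise PipelineError(f"unknown stage type {st['type']!r}")
            name = st.get("name", st["type"])
            if name in names:
                raise PipelineError(f"duplicate stage name {name!r}")
            names.add(name)
            for f in st.get("inputs", []):
                if f not in names and not Path(f).exists():
                    raise PipelineError(
                        f"stage {name!r}: input file {f!r} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage implementations.  Each takes (config, stage_params, context) and
# returns a dict of result metadata; large artefacts go to files in out_dir.

def _stage_simulate_pre(cfg: PipelineConfig, params: dict, ctx: dict) -> dict:
    truth = sim.SyntheticTruth(
        seed=int(params.get("seed", cfg.seed)),
        true_n_states=int(params.get("true_n_states", 3)),
        partner_size=int(params.get("partner_size", 60)),
        intensity_noise=float(params.get("intensity_noise", sim.DEFAULT_INTENSITY_NOISE)),
        saturations=tuple(params.get("saturations", sim.DEFAULT_SATURATIONS)),
    )
    pairs = sim.simulate_pre(truth)
    ctx["truth"], ctx["pre_pairs"] = truth, pairs
    out = cfg.out_dir
    truth.to_json(out / "truth.json")
    write_structure(truth.partner, out / "partner.pdb")
    write_structure(truth.ligand, out / "ligand.pdb")
    files = ["truth.json", "partner.pdb", "ligand.pdb"]
    for label_id, (para, dia) in pairs.items():
        write_peak_list(para, out / f"{label_id}_para.list")
        write_peak_list(dia, out / f"{label_id}_dia.list")
        files += [f"{label_id}_para.list", f"{label_id}_dia.list"]
    return {"n_sites": len(pairs), "outputs": files}


def _stage_pre_profile(cfg: PipelineConfig, params: dict, ctx: dict) -> dict:
    truth, pairs = ctx["truth"], ctx["pre_pairs"]
    profiles = []
    files = []
    for site, sat in zip(truth.label_sites, truth.saturations):
        para, dia = pairs[site.label_id]
        prof = pre_profile(para, dia, site, saturation=sat)
        profiles.append(prof)
        fname = f"pre_{site.label_id}.tsv"
        write_profile(prof.data, cfg.out_dir / fname,
                      comment=f"PRE profile, label {site.label_id}, "
                              f"saturation {sat:g}; ratio I_para/I_dia, R2* per "
                              f"median-I_dia-normalized intensity")
        files.append(fname)
    ctx["pre_profiles"] = profiles
    return {"n_profiles": len(profiles), "outputs": files}


def _stage_ensemble_scan(cfg: PipelineConfig, params: dict, ctx: dict) -> dict:
    truth = ctx["truth"]
    fit_cfg = ens.EnsembleFitConfig(**params.get("fit_config", {}))
    scan = ens.ensemble_size_scan(
        ctx["pre_profiles"], truth.partner, truth.ligand,
        sizes=params.get("sizes", range(1, 7)),
        replicates=int(params.get("replicates", 10)),
        starting_models=int(params.get("starting_models", 4)),
        seed=int(params.get("seed", cfg.seed)),
        params=truth.forward_params, config=fit_cfg)
    ctx["scan"] = scan
    write_profile(scan.summary, cfg.out_dir / "energy_summary.tsv",
                  comment="box-plot statistics of ensemble energies per size")
    best_size = scan.minimal_adequate_size or max(scan.models)
    best = min(scan.models[best_size], key=lambda m: m.total_energy)
    write_structure(ens.posed_structures(truth.partner, truth.ligand, best),
                    cfg.out_dir / "best_ensemble.pdb")
    return {
        "minimal_adequate_size": scan.minimal_adequate_size,
        "plateau_size": scan.plateau_size,
        "adequacy_rule": scan.adequacy_rule,
        "adequacy_threshold": scan.adequacy_threshold,
        "n_restraints": scan.n_restraints,
        "outputs": ["energy_summary.tsv", "best_ensemble.pdb"],
    }


def _stage_report(cfg: PipelineConfig, params: dict, ctx: dict) -> dict:
    scan = ctx.get("scan")
    report = {
        "minimal_adequate_size": scan.minimal_adequate_size if scan else None,
        "plateau_size": scan.plateau_size if scan else None,
    }
    with open(cfg.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return {**report, "outputs": ["report.json"]}


_STAGES = {
    "simulate_pre": _stage_simulate_pre,
    "pre_profile": _stage_pre_profile,
    "ensemble_scan": _stage_ensemble_scan,
    "report": _stage_report,
}


def run_pipeline(config) -> dict:
    """Execute a pipeline; returns (and writes) the run manifest.

    ``config`` may be a PipelineConfig, a dict, or a path to a YAML file.
    A failing stage aborts the run with the stage named; earlier outputs are
    retained.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "fuzzyfit", "version": _PKG_VERSION,
                "seed": config.seed, "stages": []}
    ctx: dict = {}
    for st in config.stages:
        name = st.get("name", st["type"])
        log.info("stage %s (%s) starting", name, st["type"])
        t0 = time.perf_counter()
        try:
            result = _STAGES[st["type"]](config, st.get("params", {}), ctx)
        except Exception as exc:
            _write_manifest(config, manifest)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        entry = {"name": name, "type": st["type"], "params": st.get("params", {}),
                 "runtime_s": round(dt, 3), "result": {k: v for k, v in result.items()
                                                       if k != "outputs"}}
        entry["outputs"] = {
            f: _sha256(config.out_dir / f) for f in result.get("outputs", [])}
        manifest["stages"].append(entry)
        log.info("stage %s done in %.2fs", name, dt)
    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: PipelineConfig, manifest: dict) -> None:
    with open(config.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def demo(seed: int, out_dir, sizes=range(1, 7), replicates: int = 10,
         starting_models: int = 4, true_n_states: int = 3,
         fit_config: dict | None = None) -> dict:
    """End-to-end fuzzy-binding demonstration.

    Simulates a ``true_n_states`` truth, builds PRE profiles for three label
    sites, scans ensemble sizes and reports the minimal adequate and plateau
    sizes in the manifest.
    """
    cfg = {
        "seed": int(seed),
        "out_dir": str(out_dir),
        "stages": [
            {"name": "simulate", "type": "simulate_pre",
             "params": {"true_n_states": true_n_states}},
            {"name": "profiles", "type": "pre_profile", "params": {}},
            {"name": "scan", "type": "ensemble_scan",
             "params": {"sizes": list(sizes), "replicates": replicates,
                        "starting_models": starting_models,
                        **({"fit_config": fit_config} if fit_config else {})}},
            {"name": "report", "type": "report", "params": {}},
        ],
    }
    return run_pipeline(cfg)
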