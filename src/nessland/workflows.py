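"""Seeded end-to-end experiment driver.

A single :class:`ExperimentConfig` (YAML/JSON-serializable dict) describes a
full run: define the system, simulate steady samples, build the enhanced set,
train the potential, evaluate against a reference, optionally construct the
reduced landscape.  ``run_landscape`` executes the pipeline into a run
directory containing the resolved config, all artifacts, and a metrics
report; reruns with the same config are byte-identical.
``run_benchmark_table`` repeats a run over several seeds and tabulates
mean +/- s.d. of the error metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import evaluation as ev
from .potential import TrainingConfig, estimate_epr, train_potential
from .reduction import ReducedSpec, marginalize_potential, train_reduced_potential
from .simulate import (SampleSet, analytic_sample_set, enhance_by_larger_noise,
                       enhance_by_perturbation, simulate_ensemble)
from .systems import DynamicalSystem, system_from_config

__all__ = ["ExperimentConfig", "run_landscape", "run_benchmark_table"]


@dataclass
class ExperimentConfig:
    """Resolved configuration of one landscape-construction experiment."""

    system: dict
    simulation: dict
    training: dict
    enhancement: Optional[dict] = None
    evaluation: Optional[dict] = None
    reduction: Optional[dict] = None
    output_dir: str = "runs/run"

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _build_enhanced(system: DynamicalSystem, samples: SampleSet,
                    sim_cfg: dict, enh_cfg: Optional[dict]) -> Optional[SampleSet]:
    if not enh_cfg:
        return None
    kind = enh_cfg.get("kind", "larger_noise")
    if kind == "larger_noise":
        D_prime = enh_cfg.get("D_prime")
        if D_prime is None:
            D_prime = enh_cfg.get("factor", 2.0) * sim_cfg["D"]
        return enhance_by_larger_noise(
            system, D_prime=D_prime,
            n_traj=enh_cfg.get("n_traj", sim_cfg["n_traj"]),
            t_final=enh_cfg.get("t_final", sim_cfg["t_final"]),
            dt=enh_cfg.get("dt", sim_cfg["dt"]),
            init=sim_cfg.get("init"),
            seed=enh_cfg.get("seed", sim_cfg.get("seed", 0) + 1),
            D=sim_cfg["D"])
    if kind == "perturbation":
        return enhance_by_perturbation(
            samples, sigma=enh_cfg["sigma"],
            seed=enh_cfg.get("seed", sim_cfg.get("seed", 0) + 1),
            system=system)
    raise ValueError(f"unknown enhancement kind {kind!r}")


def _reference_for(system: DynamicalSystem, eval_cfg: dict, D: float):
    source = eval_cfg.get("reference", "analytic")
    if source == "analytic":
        if eval_cfg.get("domain") is not None:
            return ev.analytic_reference_2d(
                system, D, eval_cfg["domain"],
                resolution=eval_cfg.get("resolution", 201))
        if system.analytic_potential is None:
            raise ValueError("no analytic potential available")
        return system.analytic_potential
    if source == "fpe_fem":
        return ev.solve_fpe_reference_2d(
            system, D, grid_resolution=eval_cfg.get("resolution", 201),
            domain=eval_cfg.get("domain"))
    raise ValueError(f"unknown reference source {source!r}")


def run_landscape(config: ExperimentConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.json")
    stage = "define_system"
    try:
        system = system_from_config(config.system)
        D = config.simulation["D"]

        stage = "simulate"
        sim = dict(config.simulation)
        samples = simulate_ensemble(
            system, D=D, n_traj=sim["n_traj"], t_final=sim["t_final"],
            dt=sim["dt"], init=sim.get("init"), seed=sim.get("seed", 0))
        samples.save(outdir / "samples")

        stage = "enhance"
        enhanced = _build_enhanced(system, samples, sim, config.enhancement)
        if enhanced is not None:
            enhanced.save(outdir / "enhanced_samples")

        stage = "train"
        tcfg = TrainingConfig(D=D, **config.training)
        model, trace = train_potential(system, samples, enhanced, tcfg)
        model.save(outdir / "model.json")
        trace.to_csv(outdir / "loss_trace.csv", index=False)

        stage = "evaluate"
        report = {
            "method": "single EPR" if tcfg.lambda2 == 0 else "enhanced EPR",
            "D": D, "N": len(samples),
            "epr_estimate": estimate_epr(model, samples, system),
        }
        ecfg = config.evaluation or {}
        if ecfg:
            reference = _reference_for(system, ecfg, D)
            eval_points = None
            if ecfg.get("eval_samples"):
                eval_points = analytic_sample_set(
                    system, D, int(ecfg["eval_samples"]),
                    seed=ecfg.get("seed", 1234)).states
            tm = ecfg.get("threshold_mult", 20.0)
            report["rRMSE"] = ev.rrmse(model.value, reference, D,
                                       threshold_mult=tm, eval_points=eval_points)
            report["rMAE"] = ev.rmae(model.value, reference, D,
                                     threshold_mult=tm, eval_points=eval_points)

        stage = "reduce"
        if config.reduction:
            rcfg = dict(config.reduction)
            spec = ReducedSpec(z_indices=tuple(rcfg["z_indices"]),
                               reduced_domain=rcfg["domain"],
                               grid=rcfg.get("grid", 64))
            rmodel, rforce, rtrace = train_reduced_potential(
                system, samples, spec, tcfg, enhanced_samples=enhanced)
            rmodel.save(outdir / "reduced_model.json")
            grid = marginalize_potential(model.value, samples, spec, D)
            _save_grid_csv(grid, outdir / "reduced_marginalized.csv")

        (outdir / "metrics.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\n{exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir


def _save_grid_csv(grid, path):
    import pandas as pd
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    pd.DataFrame({"z1": X.ravel(), "z2": Y.ravel(),
                  "value": grid.values.ravel()}).to_csv(path, index=False)


def run_benchmark_table(config: ExperimentConfig, seeds=None,
                        out_csv: Optional[str] = None):
    """Repeat the run over several seeds; tabulate mean +/- s.d. of metrics.

    ``seeds`` must contain at least two entries (default: 0..4).
    """
    import pandas as pd

    if seeds is None:
        seeds = list(range(5))
    if len(seeds) < 2:
        raise ValueError("benchmarking requires at least 2 seeds")
    rows = []
    for s in seeds:
        cfg = ExperimentConfig(**json.loads(json.dumps(config.to_dict())))
        cfg.simulation["seed"] = s
        cfg.training = dict(cfg.training, seed=s)
        cfg.output_dir = str(Path(config.output_dir) / f"seed{s}")
        try:
            rundir = run_landscape(cfg)
            rows.append({"seed": s, **json.loads(
                (rundir / "metrics.json").read_text())})
        except RuntimeError as exc:  # record, keep the table going
            rows.append({"seed": s, "error": str(exc)})
    df = pd.DataFrame(rows)
    summary = {}
    for col in ("rRMSE", "rMAE", "epr_estimate"):
        if col in df:
            summary[col + "_mean"] = float(df[col].mean())
            summary[col + "_sd"] = float(df[col].std(ddof=1))
    table = pd.DataFrame([summary])
    if out_csv:
        df.to_csv(Path(out_csv).with_suffix(".runs.csv"), index=False)
        table.to_csv(out_csv, index=False)
    return df, table
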