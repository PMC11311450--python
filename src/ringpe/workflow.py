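"""High-level pipeline: state point -> replicas -> metrics -> phase label."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import analysis, classify, dynamics
from .config import SimulationConfig


def run_state_point(config: SimulationConfig) -> list[dynamics.Trajectory]:
    """Simulate ``n_runs`` independent replicas of one (b, C_S) point."""
    sol = config.solution()
    params = config.forcefield()
    integ = config.integrator
    trajs = []
    run_seeds = np.random.SeedSequence(integ.seed).generate_state(
        integ.n_runs + 1)[1:] % (2**31 - 1)
    for run, rseed in enumerate(run_seeds):
        rng = np.random.default_rng(int(rseed))
        system = dynamics.initialize_system(
            config.n_monomer, config.counterions, sol.n_salt,
            config.box_length, r0=config.r0,
            temperature=integ.temperature, rng=rng)
        integ_run = replace(integ, seed=int(rseed))
        meta = {"b": config.bending, "c_s": config.c_s, "run": run,
                "seed": int(rseed), "n_salt": sol.n_salt}
        trajs.append(dynamics.run_simulation(system, params, integ_run, meta=meta))
    return trajs


def summarize_state_point(trajs: list[dynamics.Trajectory]) -> dict:
    """Pooled run-level metrics over all replicas of a state point."""
    all_metrics = []
    for traj in trajs:
        all_metrics.extend(analysis.analyze_trajectory(traj))
    return analysis.trajectory_summary(all_metrics)


def classify_state_point(trajs: list[dynamics.Trajectory],
                         params: classify.ClassifierParams | None = None
                         ) -> classify.PhaseLabel:
    """Majority phase label over every production snapshot of every replica."""
    params = params or classify.ClassifierParams()
    labels = []
    for traj in trajs:
        for frame in traj.frames:
            mono = analysis.unwrap_ring(frame[:traj.n_monomer], traj.box_length)
            labels.append(classify.classify_metrics(
                analysis.analyze_monomers(mono), traj.n_monomer, params).label)
    return classify.classify_run(labels)
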