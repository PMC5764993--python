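"""Run configuration: YAML loading, validation, and run manifests.

A run config is a flat YAML document with a ``game`` section (the
:class:`~condpunish.game.GameParams` fields), an ``experiment`` name,
and an experiment-specific section.  All game-parameter invariants are
enforced at load time so a bad config fails before any computation.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .game import GameParams

__all__ = ["RunConfig", "RunManifest", "load_config", "run_experiment", "write_manifest"]

_EXPERIMENTS = (
    "trajectory",
    "basin",
    "fixation",
    "stationary",
    "simulate_wm",
    "simulate_lattice",
)


@dataclass
class RunConfig:
    game: GameParams
    experiment: str
    options: dict[str, Any] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=lambda: [0])
    out_dir: Path = Path(".")


@dataclass
class RunManifest:
    """Reproducibility record written next to every output file."""

    config: dict[str, Any]
    seeds: list[int]
    version: str
    started: str
    checksums: dict[str, str] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises ``ValueError`` naming the violated invariant for any
    out-of-range game parameter (e.g. ``r`` outside ``(1, G)`` or a
    non-integer threshold ``H``).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    game_section = raw.get("game", {})
    if not isinstance(game_section, dict):
        raise ValueError("'game' section must be a mapping")
    game = GameParams(**game_section)  # GameParams validates its invariants
    experiment = raw.get("experiment")
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"experiment must be one of {_EXPERIMENTS}, got {experiment!r}")
    seeds = raw.get("seeds", [0])
    if isinstance(seeds, int):
        seeds = [seeds]
    if not (isinstance(seeds, list) and all(isinstance(s, int) for s in seeds)):
        raise ValueError("seeds must be an integer or a list of integers")
    options = raw.get("options", {})
    if not isinstance(options, dict):
        raise ValueError("'options' section must be a mapping")
    out_dir = Path(raw.get("out_dir", "."))
    return RunConfig(game=game, experiment=experiment, options=options, seeds=seeds, out_dir=out_dir)


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Dispatch a validated config to the appropriate module and write artifacts.

    Multi-seed experiments aggregate mean and run-to-run standard
    deviation.  Returns the manifest path; any module-level flag
    (unresolved trajectories, non-converged lattice runs) is recorded in
    the summary and raises ``RuntimeError`` after artifacts are written.
    """
    import json

    import numpy as np

    from . import __version__
    from .finite import EvoParams, PopulationCounts, embedded_markov_chain, simulate_wellmixed
    from .game import Strategy
    from .lattice import equilibrium_frequencies, init_lattice, run_mcs
    from .replicator import face_basin_fraction, integrate

    out = Path(out_dir) if out_dir is not None else config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    opts = config.options
    outputs: list[Path] = []
    problems: list[str] = []

    if config.experiment == "trajectory":
        traj = integrate(
            tuple(opts.get("x0", (0.25, 0.25, 0.25, 0.25))),
            config.game,
            t_max=float(opts.get("t_max", 2000.0)),
        )
        path = out / "trajectory.tsv"
        with path.open("w") as fh:
            fh.write("t\tx\ty\tz\tw\n")
            np.savetxt(fh, np.column_stack([traj.times, traj.states]), delimiter="\t", fmt="%.10g")
        outputs.append(path)
        if traj.terminal_class.value == "unresolved":
            problems.append("trajectory unresolved")
    elif config.experiment == "basin":
        face = tuple(opts.get("face", "CDPM"))
        summaries = []
        for seed in config.seeds:
            res = face_basin_fraction(
                config.game,
                face,
                n_samples=int(opts.get("n_samples", 10_000)),
                seed=seed,
                sampler=opts.get("sampler", "uniform"),
            )
            summaries.append(res)
            if res.unresolved:
                problems.append(f"seed {seed}: {res.unresolved} unresolved")
        fracs = [r.cooperative_fraction for r in summaries]
        path = out / "basin.json"
        path.write_text(
            json.dumps(
                {
                    "cooperative_fraction_mean": float(np.mean(fracs)),
                    "cooperative_fraction_sd": float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0,
                    "per_seed": [
                        {
                            "cooperative_fraction": r.cooperative_fraction,
                            "defection_fraction": r.defection_fraction,
                            "unresolved": r.unresolved,
                            "n_samples": r.n_samples,
                            "seed": r.seed,
                        }
                        for r in summaries
                    ],
                },
                indent=2,
            )
            + "\n"
        )
        outputs.append(path)
    elif config.experiment == "stationary":
        P, pi, reducible = embedded_markov_chain(
            config.game, int(opts.get("N", 100)), float(opts.get("s", 2.0))
        )
        path = out / "stationary.json"
        path.write_text(
            json.dumps(
                {
                    "transition_matrix": P.tolist(),
                    "stationary": dict(zip("CDPM", pi.tolist())),
                    "reducible": reducible,
                },
                indent=2,
            )
            + "\n"
        )
        outputs.append(path)
    elif config.experiment == "simulate_wm":
        N = int(opts.get("N", 100))
        base, rem = divmod(N, 4)
        init = PopulationCounts(base + (rem > 0), base + (rem > 1), base + (rem > 2), base)
        for seed in config.seeds:
            evo = EvoParams(
                s=float(opts.get("s", 2.0)),
                mu=float(opts.get("mu", 1e-3)),
                n_steps=int(opts.get("n_steps", 100_000)),
                seed=seed,
            )
            series = simulate_wellmixed(config.game, evo, init)
            path = out / f"wellmixed_seed{seed}.tsv"
            with path.open("w") as fh:
                fh.write("step\tX\tY\tZ\tW\n")
                np.savetxt(
                    fh,
                    np.column_stack([np.arange(series.shape[0]), series]),
                    delimiter="\t",
                    fmt="%d",
                )
            outputs.append(path)
    elif config.experiment == "simulate_lattice":
        codes = [Strategy[name] for name in opts.get("strategies", "CDPM")]
        results = []
        for seed in config.seeds:
            state = init_lattice(int(opts.get("L", 100)), tuple(codes), seed=seed)
            res = run_mcs(
                state,
                config.game,
                float(opts.get("s", 2.0)),
                int(opts.get("n_mcs", 20_000)),
                seed=seed,
            )
            results.append(res)
            path = out / f"freqs_seed{seed}.tsv"
            with path.open("w") as fh:
                fh.write("mcs\tf_C\tf_D\tf_P\tf_M\n")
                np.savetxt(
                    fh,
                    np.column_stack([np.arange(res.frequencies.shape[0]), res.frequencies]),
                    delimiter="\t",
                    fmt="%.10g",
                )
            outputs.append(path)
        mean, sd, converged = equilibrium_frequencies(results)
        path = out / "equilibrium.json"
        path.write_text(
            json.dumps(
                {
                    "mean_frequencies": dict(zip("CDPM", mean.tolist())),
                    "run_to_run_sd": dict(zip("CDPM", sd.tolist())),
                    "converged": converged,
                },
                indent=2,
            )
            + "\n"
        )
        outputs.append(path)
        if not all(converged):
            problems.append("non-converged lattice runs")
    elif config.experiment == "fixation":
        from .finite import fixation_probability

        resident = Strategy[opts.get("resident", "D")]
        mutant = Strategy[opts.get("mutant", "P")]
        N = int(opts.get("N", 100))
        s = float(opts.get("s", 2.0))
        rho = fixation_probability(resident, mutant, config.game, N, s)
        path = out / "fixation.json"
        path.write_text(
            json.dumps(
                {
                    "resident": resident.name,
                    "mutant": mutant.name,
                    "N": N,
                    "s": s,
                    "rho": rho,
                    "neutral": 1.0 / N,
                },
                indent=2,
            )
            + "\n"
        )
        outputs.append(path)
    else:
        raise ValueError(f"run_experiment does not handle {config.experiment!r}")

    manifest = write_manifest(out, config, outputs, __version__)
    if problems:
        raise RuntimeError("; ".join(problems))
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: Path, config: RunConfig, outputs: list[Path], version: str
) -> Path:
    """Write a JSON manifest echoing parameters, seeds and output checksums."""
    manifest = RunManifest(
        config={
            "game": vars(config.game),
            "experiment": config.experiment,
            "options": config.options,
        },
        seeds=config.seeds,
        version=version,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        checksums={p.name: _sha256(p) for p in outputs},
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(vars(manifest), indent=2, default=str) + "\n")
    return path
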