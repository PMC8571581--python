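"""Reproducible experiment orchestration and tidy table output.

Encodes the standard sweeps — invasion phase diagrams over essentiality
and group size, evolved-trait heatmaps, the relatedness sweep, and the
random-control comparison — at two scale presets:

- ``paper``: populations of ~10^4 cells, 10^5 generations, 10
  replicates (the full study conditions; hours of compute).
- ``desk``: populations of ~2000 cells, 2x10^4 generations, 5
  replicates on coarse axes; the package's default working scale for
  tests and quick exploration.

All outputs are UTF-8 TSV with a leading ``#`` comment line echoing the
full configuration and master seed, so any table can be regenerated
from its own header.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .analytic import InvasionMode, ess_random_closed, phase_grid
from .params import ModelParams
from .simulate import ExperimentResult, SimConfig, run_experiment

__all__ = [
    "PRESETS",
    "ExperimentSpec",
    "write_table",
    "read_table",
    "run_spec",
    "bridge_report",
    "heatmap_table",
    "relatedness_sweep",
]

PRESETS: dict[str, dict] = {
    "paper": {
        "target_pop_size": 10_000,
        "generations": 100_000,
        "replicates": 10,
    },
    "desk": {
        "target_pop_size": 2_000,
        "generations": 20_000,
        "replicates": 5,
    },
}

KINDS = ("phase_figure", "heatmap_figure", "relatedness_sweep", "control_comparison")


@dataclass(frozen=True)
class ExperimentSpec:
    """A declarative description of one sweep.

    ``fixed`` holds scalar model/simulation settings (epsilon, theta, n,
    l, ...); ``axes`` holds swept values keyed by parameter name.
    """

    kind: str
    fixed: Mapping[str, object]
    axes: Mapping[str, tuple]
    out_dir: str
    seed: int = 0
    preset: str = "desk"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {tuple(PRESETS)}")


def _meta_line(meta: Mapping[str, object]) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    return "# " + json.dumps(meta, default=default, sort_keys=True)


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object]) -> Path:
    """Write a tidy TSV with a one-line JSON config header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_line(meta) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (frame, meta)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
    df = pd.read_csv(path, sep="\t", comment="#")
    return df, meta


def _sim_config(fixed: Mapping[str, object], preset: str, seed: int, **over) -> SimConfig:
    fixed = dict(fixed)
    params = ModelParams(
        l=int(fixed.pop("l")),
        m=int(fixed.pop("m")),
        epsilon=float(fixed.pop("epsilon")),
        theta=float(fixed.pop("theta", 0.025)),
    )
    kwargs = {**PRESETS[preset], **fixed, **over}
    return SimConfig(params=params, seed=seed, **kwargs)


def bridge_report(params: ModelParams, sim_result: ExperimentResult) -> pd.DataFrame:
    """Analytical ESS vs evolved helper target for the random control.

    ``sim_result`` must come from an ``s_locked_at_zero`` run with the
    same parameters; the deviation column is |analytical - simulated|.
    """
    if not sim_result.config.s_locked_at_zero:
        raise ValueError("bridge_report requires an s_locked_at_zero run")
    q_star = ess_random_closed(params).q_star
    q_sim = float(sim_result.per_replicate["mean_q"].mean())
    p_sim = float(sim_result.per_replicate["mean_P"].mean())
    return pd.DataFrame(
        [
            {
                "l": params.l,
                "m": params.m,
                "n": params.n,
                "epsilon": params.epsilon,
                "theta": params.theta,
                "q_star_analytic": q_star,
                "mean_q_sim": q_sim,
                "mean_P_sim": p_sim,
                "deviation": abs(q_star - q_sim),
                "replicates": len(sim_result.per_replicate),
            }
        ]
    )


def heatmap_table(
    l: int,
    epsilon_axis,
    n_axis,
    preset: str = "desk",
    seed: int = 0,
    theta: float = 0.025,
    **config_over,
) -> pd.DataFrame:
    """Evolved coordination and helping over an essentiality x size grid.

    One row per valid (epsilon, n) cell with across-replicate means and
    SEs of the trailing-window trait averages; the simulation analog of
    the phase-diagram axes.
    """
    rows = []
    for n in n_axis:
        if n % l != 0:
            continue
        for eps in epsilon_axis:
            cfg = _sim_config(
                {"l": l, "m": n // l, "epsilon": eps, "theta": theta},
                preset,
                seed,
                **config_over,
            )
            res = run_experiment(cfg, keep_trajectories=False)
            summ = res.summary().set_index("quantity")
            rows.append(
                {
                    "l": l,
                    "n": n,
                    "epsilon": eps,
                    "theta": theta,
                    "mean_s": summ.loc["mean_s", "mean"],
                    "se_s": summ.loc["mean_s", "se"],
                    "mean_P": summ.loc["mean_P", "mean"],
                    "se_P": summ.loc["mean_P", "se"],
                    "replicates": cfg.replicates,
                }
            )
    return pd.DataFrame(rows)


def relatedness_sweep(
    l_values,
    n: int,
    epsilon: float,
    preset: str = "desk",
    seed: int = 0,
    theta: float = 0.025,
    **config_over,
) -> tuple[pd.DataFrame, dict[int, ExperimentResult]]:
    """Evolved helping and coordination across founder numbers at fixed n.

    Every ``l`` must divide ``n``. Returns the tidy summary plus the raw
    per-l experiment results (for variance analysis).
    """
    for l in l_values:
        if n % l != 0:
            raise ValueError(f"group size n={n} is not divisible by l={l}")
    rows = []
    results: dict[int, ExperimentResult] = {}
    for l in l_values:
        cfg = _sim_config(
            {"l": l, "m": n // l, "epsilon": epsilon, "theta": theta},
            preset,
            seed,
            **config_over,
        )
        res = run_experiment(cfg)
        results[l] = res
        summ = res.summary().set_index("quantity")
        rows.append(
            {
                "l": l,
                "relatedness": 1.0 / l,
                "n": n,
                "epsilon": epsilon,
                "theta": theta,
                "mean_q": summ.loc["mean_q", "mean"],
                "mean_s": summ.loc["mean_s", "mean"],
                "se_s": summ.loc["mean_s", "se"],
                "mean_P": summ.loc["mean_P", "mean"],
                "se_P": summ.loc["mean_P", "se"],
                "replicates": cfg.replicates,
            }
        )
    return pd.DataFrame(rows), results


def run_spec(spec: ExperimentSpec) -> list[Path]:
    """Dispatch one experiment spec and write its tables.

    Idempotent for a given seed; partially written outputs are removed
    if the run fails.
    """
    out = Path(spec.out_dir)
    written: list[Path] = []
    meta = {
        "kind": spec.kind,
        "fixed": dict(spec.fixed),
        "axes": {k: list(v) for k, v in spec.axes.items()},
        "preset": spec.preset,
        "seed": spec.seed,
    }
    try:
        if spec.kind == "phase_figure":
            theta = float(spec.fixed.get("theta", 0.025))
            mode = InvasionMode(spec.fixed.get("mode", "resident_q"))
            for l in spec.axes.get("l", (1,)):
                grid = phase_grid(
                    int(l), theta, spec.axes["epsilon"], spec.axes["n"], mode
                )
                written.append(
                    write_table(grid.table, out / f"phase_l{l}.tsv", {**meta, "l": l})
                )
        elif spec.kind == "heatmap_figure":
            df = heatmap_table(
                int(spec.fixed["l"]),
                spec.axes["epsilon"],
                spec.axes["n"],
                preset=spec.preset,
                seed=spec.seed,
                theta=float(spec.fixed.get("theta", 0.025)),
            )
            written.append(write_table(df, out / "heatmap.tsv", meta))
        elif spec.kind == "relatedness_sweep":
            df, _ = relatedness_sweep(
                spec.axes["l"],
                int(spec.fixed["n"]),
                float(spec.fixed["epsilon"]),
                preset=spec.preset,
                seed=spec.seed,
                theta=float(spec.fixed.get("theta", 0.025)),
            )
            written.append(write_table(df, out / "relatedness.tsv", meta))
        elif spec.kind == "control_comparison":
            rows = []
            for locked in (True, False):
                cfg = _sim_config(
                    spec.fixed, spec.preset, spec.seed, s_locked_at_zero=locked
                )
                res = run_experiment(cfg, keep_trajectories=False)
                summ = res.summary().set_index("quantity")
                rows.append(
                    {
                        "scenario": "s_locked_at_zero" if locked else "s_free",
                        "mean_q": summ.loc["mean_q", "mean"],
                        "mean_s": summ.loc["mean_s", "mean"],
                        "mean_P": summ.loc["mean_P", "mean"],
                        "se_P": summ.loc["mean_P", "se"],
                    }
                )
            written.append(write_table(pd.DataFrame(rows), out / "control.tsv", meta))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
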