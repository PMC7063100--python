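"""Tabular output: per-trial trajectory tables and run summaries.

Trajectories are written as delimiter-separated text with a header row and
10 significant digits — small (2,000 rows) and diff-able. Each run's summary
is a YAML document embedding the fully resolved model spec and the tool
version, so a result file always carries enough metadata to re-run it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .analytics import ConvergenceReport, FixedPointReport, fixed_point
from .simulator import Ensemble, Trajectory

__all__ = ["write_trajectory", "write_ensemble", "write_summary", "read_trajectory"]

_FLOAT_FMT = "%.10g"
_DELIMS = {"csv": ",", "tsv": "\t"}


def _delim(fmt: str) -> str:
    try:
        return _DELIMS[fmt]
    except KeyError:
        raise ValueError(f"unknown format {fmt!r} (use csv or tsv)") from None


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str = "csv") -> Path:
    """Write one trajectory as a per-trial table; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_dataframe().to_csv(
        path, sep=_delim(fmt), index=False, float_format=_FLOAT_FMT
    )
    return path


def read_trajectory(path: str | Path, fmt: str = "csv") -> pd.DataFrame:
    """Read a trajectory table back into a DataFrame."""
    return pd.read_csv(path, sep=_delim(fmt))


def write_ensemble(
    ensemble: Ensemble, out_dir: str | Path, fmt: str = "csv"
) -> list[Path]:
    """Write one table per seed plus a cross-seed summary table keyed by trial."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj in ensemble.trajectories:
        paths.append(
            write_trajectory(traj, out_dir / f"trajectory_seed{traj.seed}.{fmt}", fmt)
        )
    summary_path = out_dir / f"ensemble_summary.{fmt}"
    ensemble.summary_dataframe().to_csv(
        summary_path, sep=_delim(fmt), index=False, float_format=_FLOAT_FMT
    )
    paths.append(summary_path)
    return paths


def write_summary(
    path: str | Path,
    *,
    spec,
    seeds: list[int],
    terminal_mean_q_follow: Optional[float] = None,
    terminal_mean_q_random: Optional[float] = None,
    convergence: Optional[ConvergenceReport] = None,
    fixed_points: Optional[FixedPointReport] = None,
    extra: Optional[dict] = None,
) -> Path:
    """Write a structured key-value run summary (YAML) with the config echo."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fixed_points is None:
        fixed_points = fixed_point(spec)
    doc: dict = {
        "tool": {"name": "gazerl", "version": __version__},
        "spec": spec.model_dump(mode="json"),
        "state_distribution": "normal clipped to [0, 1]",
        "seeds": list(seeds),
        "fixed_points": {
            "naive_follow": fixed_points.naive_follow,
            "naive_random": fixed_points.naive_random,
            "weighted_follow": fixed_points.weighted_follow,
            "weighted_random": fixed_points.weighted_random,
            "expected_state": fixed_points.expected_state,
            "method": fixed_points.method,
        },
    }
    if terminal_mean_q_follow is not None:
        doc["terminal_mean_q_follow"] = terminal_mean_q_follow
    if terminal_mean_q_random is not None:
        doc["terminal_mean_q_random"] = terminal_mean_q_random
    if convergence is not None:
        doc["convergence"] = {
            "delta": convergence.delta,
            "tail_window": convergence.tail_window,
            "median_trial": convergence.median,
            "iqr": list(convergence.iqr),
            "frac_not_converged": convergence.frac_not_converged,
        }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path
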