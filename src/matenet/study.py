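"""Sensitivity study of the assortativity metrics over population axes.

Runs replicate batches of uniform random networks along three axes —
population size (6x6, 20x20, 80x80 at density 0.5), sex ratio (10x50,
30x30, 50x10 at density 0.5) and mating density (0.25, 0.5, 0.75 at
20x20) — scores each replicate with the full metric report, and summarises
metric-vs-parameter Spearman and metric-vs-metric Pearson correlations.

Replicates whose metrics are undefined are kept as NA rows with a reason
code and dropped only from the analyses that involve the affected metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import metric_report, nodf
from .network_core import MatingNetwork
from .simulator import (
    InfeasibleConfigError,
    SimulationConfig,
    random_mating_network,
    sample_incidence,
)

__all__ = [
    "AXES",
    "METRIC_COLUMNS",
    "ExperimentResult",
    "run_axis_experiment",
    "run_full_study",
    "metric_parameter_correlation",
    "metric_metric_correlation",
    "nodf_null_zscore",
]

METRIC_COLUMNS = ["r_newman_u", "r_newman_d", "nodf", "scic_corr", "scic_slope"]

# axis -> (ordered (m, f, density) levels, numeric level encoding)
# size is coded as total individuals, sex ratio as males/females, density
# as the proportion itself.
AXES: dict[str, list[tuple[int, int, float]]] = {
    "size": [(6, 6, 0.5), (20, 20, 0.5), (80, 80, 0.5)],
    "sex_ratio": [(10, 50, 0.5), (30, 30, 0.5), (50, 10, 0.5)],
    "density": [(20, 20, 0.25), (20, 20, 0.5), (20, 20, 0.75)],
}

_AXIS_INDEX = {name: i for i, name in enumerate(AXES)}


def _level_value(axis: str, m: int, f: int, density: float) -> float:
    if axis == "size":
        return float(m + f)
    if axis == "sex_ratio":
        return m / f
    return density


@dataclass(frozen=True)
class ExperimentResult:
    """Tidy per-replicate metric table plus run metadata."""

    data: pd.DataFrame
    reps: int
    base_seed: int

    def metric_frame(self) -> pd.DataFrame:
        return self.data[["axis", "level", "replicate"] + METRIC_COLUMNS]


def replicate_seed(base_seed: int, axis: str, level_index: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed, reproducible in isolation."""
    return np.random.SeedSequence((base_seed, _AXIS_INDEX[axis], level_index, replicate))


def score_network(net: MatingNetwork) -> dict:
    """One tidy row fragment: metric values (NaN when undefined) + reasons."""
    rep = metric_report(net)
    row: dict = {}
    for name in METRIC_COLUMNS:
        mv = getattr(rep, name)
        row[name] = mv.value if mv.is_defined else np.nan
        row[f"{name}_reason"] = None if mv.is_defined else mv.reason
    return row


def run_axis_experiment(axis: str, reps: int, base_seed: int = 0) -> ExperimentResult:
    """Score ``reps`` random networks at every level of one axis."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {sorted(AXES)}, got {axis!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for level_index, (m, f, density) in enumerate(AXES[axis]):
        cfg = SimulationConfig(n_males=m, n_females=f, mating_density=density)
        for rep_i in range(reps):
            seed_seq = replicate_seed(base_seed, axis, level_index, rep_i)
            rng = np.random.default_rng(seed_seq)
            net = random_mating_network(cfg, rng=rng)
            row = {
                "axis": axis,
                "level": _level_value(axis, m, f, density),
                "n_males": m,
                "n_females": f,
                "density_param": density,
                "replicate": rep_i,
                "seed": f"({base_seed},{_AXIS_INDEX[axis]},{level_index},{rep_i})",
            }
            row.update(score_network(net))
            rows.append(row)
    return ExperimentResult(data=pd.DataFrame(rows), reps=reps, base_seed=base_seed)


def run_full_study(reps: int, base_seed: int = 0) -> ExperimentResult:
    """All three axes in one tidy table."""
    frames = [run_axis_experiment(axis, reps, base_seed).data for axis in AXES]
    return ExperimentResult(
        data=pd.concat(frames, ignore_index=True), reps=reps, base_seed=base_seed
    )


def metric_parameter_correlation(res: ExperimentResult) -> pd.DataFrame:
    """Spearman rho of each metric against its axis parameter, pooled over
    levels; NA rows are dropped per metric."""
    out = []
    for axis, grp in res.data.groupby("axis", sort=False):
        for metric in METRIC_COLUMNS:
            sub = grp[["level", metric]].dropna()
            if len(sub) < 2:
                out.append(
                    {"axis": axis, "metric": metric, "spearman_rho": np.nan,
                     "n": len(sub), "reason": "all-na"}
                )
                continue
            if sub[metric].nunique() < 2 or sub["level"].nunique() < 2:
                out.append(
                    {"axis": axis, "metric": metric, "spearman_rho": np.nan,
                     "n": len(sub), "reason": "zero-variance"}
                )
                continue
            rho = stats.spearmanr(sub["level"], sub[metric]).statistic
            out.append(
                {"axis": axis, "metric": metric, "spearman_rho": float(rho),
                 "n": len(sub), "reason": None}
            )
    return pd.DataFrame(out)


def metric_metric_correlation(res: ExperimentResult, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson r between metrics, per axis level."""
    out = []
    for (axis, level), grp in res.data.groupby(["axis", "level"], sort=False):
        for a_i, metric_a in enumerate(METRIC_COLUMNS):
            for metric_b in METRIC_COLUMNS[a_i:]:
                sub = grp[[metric_a, metric_b]].dropna()
                n = len(sub)
                if metric_a == metric_b:
                    r = 1.0 if n else np.nan
                elif (
                    n < min_pairs
                    or sub[metric_a].nunique() < 2
                    or sub[metric_b].nunique() < 2
                ):
                    r = np.nan
                else:
                    r = float(stats.pearsonr(sub[metric_a], sub[metric_b]).statistic)
                out.append(
                    {"axis": axis, "level": level, "metric_a": metric_a,
                     "metric_b": metric_b, "pearson_r": r, "n": n}
                )
    return pd.DataFrame(out)


def nodf_null_zscore(
    net: MatingNetwork, n_null: int = 1000, seed: int | None = None
) -> float:
    """Z-score of the network's NODF against its uniform null model.

    The null holds m, f and the edge count fixed and requires every
    individual to mate, matching the simulator's distribution.  Returns
    NaN when the null has zero spread (e.g. a complete matrix, whose null
    space is a single state).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    m, f, e = net.n_males, net.n_females, net.n_edges
    if e < max(m, f):
        raise InfeasibleConfigError(
            f"null model infeasible: E = {e} < max(m, f) = {max(m, f)}"
        )
    obs = nodf(net).value
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_null)
    for i in range(n_null):
        inc, _ = sample_incidence(m, f, e, rng)
        null_vals[i] = nodf(MatingNetwork(incidence=inc)).value
    sd = null_vals.std()
    if sd == 0:
        return float("nan")
    return float((obs - null_vals.mean()) / sd)


def plot_experiment(res: ExperimentResult, outdir) -> list[str]:
    """Diagnostic scatterplots of each metric against its axis parameter."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for axis, grp in res.data.groupby("axis", sort=False):
        fig, axs = plt.subplots(1, len(METRIC_COLUMNS), figsize=(4 * len(METRIC_COLUMNS), 3.5))
        for ax, metric in zip(np.atleast_1d(axs), METRIC_COLUMNS):
            sub = grp[["level", metric]].dropna()
            jitter = (np.random.default_rng(0).random(len(sub)) - 0.5) * 0.05
            ax.plot(sub["level"] * (1 + jitter), sub[metric], ".", alpha=0.2, ms=3)
            ax.set_xlabel(axis)
            ax.set_ylabel(metric)
        fig.tight_layout()
        path = outdir / f"scatter_{axis}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))
    return written
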