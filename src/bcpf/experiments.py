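"""Ensemble runner, parameter sweeps and threshold estimators.

Everything here is a pure function of (spec, base seed): per-run seeds are
derived as ``base_seed + k`` (mod 2^31) with ``k`` a global run counter over
the sweep grid, so re-executing a spec reproduces every number.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigurationError, Params
from .dynamics import RunResult, run, run_bc_baseline
from .observables import (
    check_hyperplane_separation,
    check_segregation_1d,
    clique_size_difference,
)

MODELS = ("bcpf", "bc", "ltd", "ctd")
_MODEL_RULES = {"bcpf": "preferential", "ltd": "random", "ctd": "constrained"}


@dataclass(frozen=True)
class SweepSpec:
    """A parameter sweep: base parameters, value grids, runs per cell."""

    base: Params
    grids: dict[str, Sequence] = field(default_factory=dict)
    runs: int = 8
    base_seed: int = 0
    model: str = "bcpf"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.runs < 1:
            raise ConfigurationError("runs must be >= 1")
        for name, grid in self.grids.items():
            if len(list(grid)) == 0:
                raise ConfigurationError(f"empty grid for {name!r}")

    @property
    def cells(self) -> list[dict]:
        names = list(self.grids)
        out = []
        for combo in itertools.product(*(self.grids[n] for n in names)):
            out.append(dict(zip(names, combo)))
        return out or [{}]


def execute_run(params: Params, model: str = "bcpf", **kwargs) -> RunResult:
    """Run one realization of the requested model variant."""
    if model == "bc":
        return run_bc_baseline(params, **kwargs)
    return run(params.replace(flip_rule=_MODEL_RULES[model]), **kwargs)


def summarize_run(result: RunResult) -> dict:
    """Flat per-run record used for aggregation and JSON-lines output."""
    rec = result.to_record()
    rec.pop("params")
    rec.pop("flip_counts")
    rec["bipolar"] = None
    rec["s_dif"] = None
    rec["segregated"] = None
    rec["separable"] = None
    rec["clique_opinion_lo"] = None
    rec["clique_opinion_hi"] = None
    if result.cliques is not None:
        c1, c2 = result.cliques
        rec["bipolar"] = bool(len(c2) > 0)
        rec["s_dif"] = clique_size_difference(result.cliques)
        x = result.final_state.opinions.values
        if len(c2) > 0:
            if result.params.n_issues == 1:
                rec["segregated"] = check_segregation_1d(result.final_state, result.cliques)
                means = sorted([float(x[c1].mean()), float(x[c2].mean())])
                rec["clique_opinion_lo"], rec["clique_opinion_hi"] = means
            else:
                rec["separable"] = check_hyperplane_separation(x, result.cliques)
    return rec


def _derived_params(spec: SweepSpec, cell: dict, seed: int) -> Params:
    return spec.base.replace(seed=seed, **cell)


def _cell_runs(spec: SweepSpec, cell: dict, cell_index: int) -> list[dict]:
    recs = []
    for r in range(spec.runs):
        seed = (spec.base_seed + cell_index * spec.runs + r) % (2**31)
        params = _derived_params(spec, cell, seed)
        result = execute_run(params, spec.model, record_series=False)
        rec = summarize_run(result)
        rec.update({f"grid_{k}": v for k, v in cell.items()})
        rec["cell"] = cell_index
        rec["run"] = r
        recs.append(rec)
    return recs


def _aggregate_cell(cell: dict, recs: list[dict], spec: SweepSpec) -> dict:
    absorbed = [r for r in recs if r["termination"] == "absorbed"]
    n = len(recs)

    def _mean(key, pool):
        vals = [r[key] for r in pool if r[key] is not None and not _isnan(r[key])]
        return float(np.mean(vals)) if vals else float("nan")

    def _isnan(v):
        return isinstance(v, float) and math.isnan(v)

    tb = [r["T_balance_steps"] for r in absorbed]
    row = dict(cell)
    row.update(
        n_runs=n,
        absorbed_frac=len(absorbed) / n,
        t_typ_steps=float(np.median(tb)) if len(absorbed) >= max(1, n / 2) else float("nan"),
        t_typ_rounds=(
            float(np.median([r["T_balance_rounds"] for r in absorbed]))
            if len(absorbed) >= max(1, n / 2)
            else float("nan")
        ),
        mean_n_op=_mean("N_op", absorbed),
        min_n_op=min((r["N_op"] for r in absorbed), default=None),
        max_n_op=max((r["N_op"] for r in absorbed), default=None),
        mean_d_minus=_mean("D_minus", absorbed),
        mean_clique_opinion_lo=_mean("clique_opinion_lo", absorbed),
        mean_clique_opinion_hi=_mean("clique_opinion_hi", absorbed),
        mean_s_dif=_mean("s_dif", absorbed),
        frac_bipolar=_mean("bipolar", absorbed),
        frac_allfriends=(
            float(np.mean([not r["bipolar"] for r in absorbed if r["bipolar"] is not None]))
            if absorbed
            else float("nan")
        ),
        frac_segregated=_mean("segregated", absorbed),
        frac_separable=_mean("separable", absorbed),
    )
    return row


@dataclass
class EnsembleSummary:
    """Aggregated sweep output: one table row per grid cell, plus the
    flat per-run records behind it."""

    spec: SweepSpec
    table: pd.DataFrame
    per_run: list[dict]

    def sdif_values(self, cell_index: int) -> np.ndarray:
        vals = [
            r["s_dif"]
            for r in self.per_run
            if r["cell"] == cell_index and r["s_dif"] is not None
        ]
        return np.asarray(vals, dtype=float)

    def write(self, summary_csv=None, per_run_jsonl=None) -> None:
        if summary_csv is not None:
            self.table.to_csv(summary_csv, index=False)
        if per_run_jsonl is not None:
            with open(per_run_jsonl, "w") as fh:
                for rec in self.per_run:
                    fh.write(json.dumps(rec) + "\n")


def run_ensemble(spec: SweepSpec) -> EnsembleSummary:
    """Execute every (cell, run) of the sweep and aggregate per cell.

    Runs hitting the round cap are recorded (not fatal) and excluded from
    medians and means; the absorbed fraction is always reported.
    """
    per_run: list[dict] = []
    rows = []
    for ci, cell in enumerate(spec.cells):
        recs = _cell_runs(spec, cell, ci)
        per_run.extend(recs)
        rows.append(_aggregate_cell(cell, recs, spec))
    return EnsembleSummary(spec, pd.DataFrame(rows), per_run)


def sdif_histogram(values: np.ndarray, bin_width: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Frequency histogram of clique-size differences in percent-point bins."""
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return counts / max(1, len(values)), edges


def estimate_Ttyp(params: Params, n_runs: int, model: str = "bcpf", base_seed: int = 0) -> dict:
    """Median time to social balance over seeded runs, in steps and rounds.

    If fewer than half the runs absorb, the median is undefined (NaN) and
    flagged; capped runs are also summarized via a censored median that
    counts them at the cap, which lower-bounds the true value.
    """
    spec = SweepSpec(base=params, grids={}, runs=n_runs, base_seed=base_seed, model=model)
    recs = _cell_runs(spec, {}, 0)
    balanced = [r["T_balance_steps"] for r in recs if r["T_balance_steps"] is not None]
    cap = params.max_rounds * params.steps_per_round
    censored = [r["T_balance_steps"] if r["T_balance_steps"] is not None else cap for r in recs]
    frac = len(balanced) / n_runs
    ok = frac >= 0.5
    return {
        "median_steps": float(np.median(balanced)) if ok else float("nan"),
        "median_rounds": (
            float(np.median(balanced)) / params.steps_per_round if ok else float("nan")
        ),
        "censored_median_steps": float(np.median(censored)),
        "balanced_frac": frac,
        "defined": ok,
        "n_runs": n_runs,
    }


def estimate_consensus_threshold(
    params: Params,
    model: str,
    eps_grid: Sequence[float],
    runs: int = 8,
    base_seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Smallest grid epsilon at which every run reaches the consensus state.

    For the pure bounded-confidence baseline (``model="bc"``) the criterion
    is a single surviving opinion (N_op = 1); for the coupled model
    (``model="bcpf"``) it is one opinion per clique (N_op = 2) in every
    absorbed run.  Returns ``inf`` ("above grid") when no grid value
    qualifies; the per-cell table is returned alongside.
    """
    eps_grid = list(eps_grid)
    if any(b < a for a, b in zip(eps_grid, eps_grid[1:])):
        raise ConfigurationError("eps_grid must be ascending")
    target = 1 if model == "bc" else 2
    rows = []
    threshold = float("inf")
    for ci, eps in enumerate(eps_grid):
        spec = SweepSpec(
            base=params.replace(epsilon=float(eps)),
            grids={},
            runs=runs,
            base_seed=base_seed + ci * runs,
            model=model,
        )
        recs = _cell_runs(spec, {}, 0)
        absorbed = [r for r in recs if r["termination"] == "absorbed"]
        n_ops = [r["N_op"] for r in absorbed]
        if model == "bc":
            qualifies = len(absorbed) == len(recs) and all(v == target for v in n_ops)
        else:
            # metastable runs can out-wait any cap; the criterion is over the
            # runs that did absorb
            qualifies = len(absorbed) > 0 and all(v == target for v in n_ops)
        rows.append(
            {
                "epsilon": float(eps),
                "n_runs": len(recs),
                "absorbed_frac": len(absorbed) / len(recs),
                "max_n_op": max(n_ops, default=None),
                "min_n_op": min(n_ops, default=None),
                "all_consensus": qualifies,
            }
        )
        if qualifies:
            threshold = float(eps)
            break
    return threshold, pd.DataFrame(rows)


@dataclass(frozen=True)
class PThresholdEstimate:
    """Estimated critical flip probability between the bipolar and
    all-friends absorbing classes."""

    p_critical: float | None
    interval: tuple[float, float]
    monotone: bool
    table: pd.DataFrame


def estimate_p_threshold(
    params: Params,
    p_grid: Sequence[float],
    runs: int = 8,
    base_seed: int = 0,
) -> PThresholdEstimate:
    """Classify each grid p's absorbed runs as bipolar or all-friends and
    return the midpoint between the largest all-bipolar p and the smallest
    all-all-friends p.  ``p_grid`` must be ascending and exclude 0.5 (the
    critical point has no guaranteed absorbing class)."""
    p_grid = [float(v) for v in p_grid]
    if any(b < a for a, b in zip(p_grid, p_grid[1:])):
        raise ConfigurationError("p_grid must be ascending")
    if any(v == 0.5 for v in p_grid):
        raise ConfigurationError("p_grid must exclude the critical point 0.5")
    rows = []
    for ci, p in enumerate(p_grid):
        spec = SweepSpec(
            base=params.replace(p=p),
            grids={},
            runs=runs,
            base_seed=base_seed + ci * runs,
            model="bcpf",
        )
        recs = _cell_runs(spec, {}, 0)
        verdicts = [r["bipolar"] for r in recs if r["bipolar"] is not None]
        if verdicts and all(verdicts):
            cls = "bipolar"
        elif verdicts and not any(verdicts):
            cls = "all_friends"
        else:
            cls = "mixed"
        rows.append({"p": p, "class": cls, "n_classified": len(verdicts)})
    table = pd.DataFrame(rows)
    bip = [r["p"] for r in rows if r["class"] == "bipolar"]
    allf = [r["p"] for r in rows if r["class"] == "all_friends"]
    lo = max(bip) if bip else p_grid[0]
    hi = min(allf) if allf else p_grid[-1]
    monotone = all(
        r["class"] == "bipolar" for r in rows if r["p"] <= lo
    ) and all(r["class"] == "all_friends" for r in rows if r["p"] >= hi)
    p_crit = (lo + hi) / 2.0 if monotone and bip and allf and lo < hi else None
    return PThresholdEstimate(p_crit, (lo, hi), monotone, table)
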