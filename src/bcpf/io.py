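"""Plain-text interchange formats.

Network CSV: header ``i,j,sign``, one row per unordered pair with i < j,
sign in {-1, 1}.  Opinion CSV: header ``agent,x_1,...,x_F``, one row per
agent.  Run records are JSON; per-round series are CSV with columns
``round,t,F_unbal,D_plus,D_minus,N_op``.  Agent indices are 0-based
everywhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, OpinionMatrix, SignedNetwork, SystemState
from .dynamics import RunResult


def write_network_csv(network: SignedNetwork, path) -> None:
    iu = np.triu_indices(network.n, k=1)
    df = pd.DataFrame({"i": iu[0], "j": iu[1], "sign": network.signs[iu]})
    df.to_csv(path, index=False)


def read_network_csv(path) -> SignedNetwork:
    df = pd.read_csv(path)
    if list(df.columns) != ["i", "j", "sign"]:
        raise ConfigurationError(f"network CSV must have header i,j,sign, got {list(df.columns)}")
    n = int(max(df["i"].max(), df["j"].max())) + 1
    s = np.zeros((n, n), dtype=np.int8)
    for i, j, sign in df.itertuples(index=False):
        if i >= j:
            raise ConfigurationError("network CSV rows must satisfy i < j")
        s[i, j] = s[j, i] = sign
    expected = n * (n - 1) // 2
    if len(df) != expected:
        raise ConfigurationError(
            f"incomplete network: {len(df)} rows for N={n} (expected {expected})"
        )
    return SignedNetwork(s)


def write_opinions_csv(opinions: OpinionMatrix, path) -> None:
    cols = {"agent": np.arange(opinions.n)}
    for f in range(opinions.n_issues):
        cols[f"x_{f + 1}"] = opinions.values[:, f]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_opinions_csv(path) -> OpinionMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "agent" or not all(
        c == f"x_{k + 1}" for k, c in enumerate(df.columns[1:])
    ):
        raise ConfigurationError(
            f"opinion CSV must have header agent,x_1,...,x_F, got {list(df.columns)}"
        )
    df = df.sort_values("agent")
    if not np.array_equal(df["agent"].to_numpy(), np.arange(len(df))):
        raise ConfigurationError("opinion CSV must list agents 0..N-1 exactly once")
    return OpinionMatrix(df.iloc[:, 1:].to_numpy(dtype=float))


def load_state(network_path, opinions_path) -> SystemState:
    """Assemble a user-supplied initial state from the two CSV files."""
    return SystemState.create(read_network_csv(network_path), read_opinions_csv(opinions_path))


def write_run_record(result: RunResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_record(), indent=2) + "\n")


def write_series_csv(result: RunResult, path) -> None:
    if result.series is None:
        raise ConfigurationError("run was executed without series recording")
    result.series.to_csv(path, index=False)
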