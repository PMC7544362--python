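"""Partition-similarity measures and the synthetic benchmark experiments.

Three benchmarks probe detector accuracy on DCP samples against the planted
partition (measured by the adjusted Rand index), and a quality-validation
experiment checks that the no-ground-truth measures (DCPM and the Monte Carlo
p-value) track the ARI, summarized by Kendall's tau rank correlations.
All experiments emit tidy pandas DataFrames, one row per (graph, detector).
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.metrics import adjusted_rand_score

from .graph import BLOCK_NAMES, DCPParams, Partition, sample_dcp
from .quality import DETECTORS, dcpm, monte_carlo_test

DEFAULT_DETECTORS = ("degree", "hits", "advhits", "maxlike")


def adjusted_rand_index(p: Partition | np.ndarray, q: Partition | np.ndarray) -> float:
    """Chance-corrected partition agreement in [-1, 1] (permutation model).

    1 iff the partitions are identical up to label renaming; approximately 0
    for independent random labelings.
    """
    a = p.labels if isinstance(p, Partition) else np.asarray(p)
    b = q.labels if isinstance(q, Partition) else np.asarray(q)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same node set")
    return float(adjusted_rand_score(a, b))


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation in [-1, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall's tau is undefined for a constant vector")
    return float(kendalltau(x, y).statistic)


def derive_seed(master: int, *key) -> int:
    """Deterministic per-cell seed from a master seed and a parameter key."""
    digest = zlib.crc32(repr(key).encode("utf8"))
    state = np.random.SeedSequence([int(master) % (2**31), digest]).generate_state(1)
    return int(state[0] % (2**31))


def _detector_rows(
    graph, planted: Partition, detectors: Iterable[str], master: int, *key
) -> list[dict]:
    rows = []
    for name in detectors:
        det = DETECTORS[name]
        part = det(graph, seed=derive_seed(master, "det", name, *key))
        rows.append(
            {
                "detector": name,
                "ari": adjusted_rand_index(part, planted),
                "dcpm": dcpm(graph, part),
            }
        )
    return rows


def run_benchmark1(
    p_grid: Sequence[float],
    sizes: Sequence[int] = (100, 100, 100, 100),
    reps: int = 50,
    detectors: Sequence[str] = DEFAULT_DETECTORS,
    seed: int = 0,
) -> pd.DataFrame:
    """One-parameter benchmark on ``DCP(1/2 + p, 1/2 - p)`` with fixed sizes."""
    records = []
    for p in p_grid:
        params = DCPParams(tuple(sizes), 0.5 + p, 0.5 - p)
        for rep in range(reps):
            gseed = derive_seed(seed, "b1", round(float(p), 10), rep)
            graph, planted = sample_dcp(params, seed=gseed)
            for row in _detector_rows(graph, planted, detectors, seed, "b1", round(float(p), 10), rep):
                records.append(
                    {"benchmark": 1, "p": float(p), "p1": params.p1, "p2": params.p2,
                     "rep": rep, "graph_seed": gseed, **row}
                )
    return pd.DataFrame.from_records(records)


def run_benchmark2(
    p1_grid: Sequence[float],
    ratio_grid: Sequence[float],
    sizes: Sequence[int] = (100, 100, 100, 100),
    reps: int = 50,
    detectors: Sequence[str] = DEFAULT_DETECTORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-parameter sweep over ``p1`` and the noise ratio ``p2/p1 in [0, 1)``."""
    records = []
    for p1 in p1_grid:
        for ratio in ratio_grid:
            if not 0.0 <= ratio < 1.0:
                raise ValueError("ratios must lie in [0, 1)")
            params = DCPParams(tuple(sizes), float(p1), float(p1) * float(ratio))
            key = (round(float(p1), 10), round(float(ratio), 10))
            for rep in range(reps):
                gseed = derive_seed(seed, "b2", *key, rep)
                graph, planted = sample_dcp(params, seed=gseed)
                for row in _detector_rows(graph, planted, detectors, seed, "b2", *key, rep):
                    records.append(
                        {"benchmark": 2, "p1": params.p1, "p2": params.p2,
                         "ratio": float(ratio), "rep": rep, "graph_seed": gseed, **row}
                    )
    return pd.DataFrame.from_records(records)


def run_benchmark3(
    p: float = 0.1,
    base_size: int = 100,
    size_ratios: Sequence[float] = tuple(2.0**k for k in range(-3, 4)),
    varied_set: str = "Pout",
    reps: int = 50,
    detectors: Sequence[str] = DEFAULT_DETECTORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Set-size sensitivity: one set scaled by each ratio, others fixed."""
    if varied_set not in BLOCK_NAMES:
        raise ValueError(f"varied_set must be one of {BLOCK_NAMES}")
    vary = BLOCK_NAMES.index(varied_set)
    records = []
    for ratio in size_ratios:
        sizes = [base_size] * 4
        sizes[vary] = int(round(ratio * base_size))
        params = DCPParams(tuple(sizes), 0.5 + p, 0.5 - p)
        key = (varied_set, round(float(ratio), 10))
        for rep in range(reps):
            gseed = derive_seed(seed, "b3", *key, rep)
            graph, planted = sample_dcp(params, seed=gseed)
            for row in _detector_rows(graph, planted, detectors, seed, "b3", *key, rep):
                records.append(
                    {"benchmark": 3, "p": float(p), "varied_set": varied_set,
                     "ratio": float(ratio), "sizes": tuple(sizes), "rep": rep,
                     "graph_seed": gseed, **row}
                )
    return pd.DataFrame.from_records(records)


def quality_validation(
    p_values: Sequence[float] = (0.1, 0.04, 0.02),
    networks_per_p: int = 20,
    null_replicates: int | None = 250,
    detectors: Sequence[str] = ("hits", "advhits", "maxlike"),
    sizes: Sequence[int] = (100, 100, 100, 100),
    null_models: Sequence[str] = ("er", "config"),
    seed: int = 0,
) -> pd.DataFrame:
    """Quality-measure validation: ARI, DCPM and Monte Carlo p-values per row.

    For each signal level ``p`` and network, every detector contributes one
    row with its ARI against the planted partition, its DCPM, and (when
    ``null_replicates`` is set) Monte Carlo p-values under the requested null
    models.  Pass ``null_replicates=None`` to skip the (expensive) tests and
    study only the DCPM/ARI relationship.
    """
    records = []
    for p in p_values:
        params = DCPParams(tuple(sizes), 0.5 + p, 0.5 - p)
        for net in range(networks_per_p):
            key = (round(float(p), 10), net)
            gseed = derive_seed(seed, "qv", *key)
            graph, planted = sample_dcp(params, seed=gseed)
            for name in detectors:
                det = DETECTORS[name]
                dseed = derive_seed(seed, "qvdet", name, *key)
                part = det(graph, seed=dseed)
                row = {
                    "p": float(p),
                    "network": net,
                    "graph_seed": gseed,
                    "detector": name,
                    "ari": adjusted_rand_index(part, planted),
                    "dcpm": dcpm(graph, part),
                }
                if null_replicates:
                    for null in null_models:
                        res = monte_carlo_test(
                            graph,
                            name,
                            null_model=null,
                            replicates=int(null_replicates),
                            seed=derive_seed(seed, "qvmc", name, null, *key),
                        )
                        row[f"{null}_p"] = res.p_value
                records.append(row)
    return pd.DataFrame.from_records(records)


def kendall_summaries(table: pd.DataFrame) -> dict[str, float]:
    """Kendall tau summaries of a quality-validation table.

    Always reports ``tau_dcpm_ari`` over all rows; if ER/config p-value
    columns are present also reports their correlations with ARI and DCPM,
    and the DCPM-ARI correlation restricted to rows significant (p < 0.05)
    under both null models.
    """
    def _tau(x, y):
        try:
            return kendall_tau(x, y)
        except ValueError:  # constant column: correlation undefined
            return float("nan")

    out = {"tau_dcpm_ari": _tau(table["dcpm"], table["ari"])}
    if "er_p" in table:
        out["tau_erp_ari"] = _tau(table["er_p"], table["ari"])
        out["tau_dcpm_erp"] = _tau(table["dcpm"], table["er_p"])
    if "er_p" in table and "config_p" in table:
        sig = table[(table["er_p"] < 0.05) & (table["config_p"] < 0.05)]
        if len(sig) >= 2:
            out["tau_dcpm_ari_significant"] = _tau(sig["dcpm"], sig["ari"])
    return out


def results_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def summary_to_json(table: pd.DataFrame, path: str | Path) -> None:
    """Per-cell mean ARI/DCPM, grouped over replicates, as a JSON report."""
    group_cols = [
        c for c in ("benchmark", "p", "p1", "p2", "ratio", "varied_set", "detector")
        if c in table.columns
    ]
    means = (
        table.groupby(group_cols, dropna=False)[["ari", "dcpm"]]
        .mean()
        .reset_index()
        .to_dict(orient="records")
    )
    Path(path).write_text(json.dumps(means, indent=2))
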