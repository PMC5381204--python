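"""Benchmarking model selection against native structures.

A benchmark table has one row per target: protein length, decoy-set size,
the best TM-score present anywhere in the decoy set, one column of
``model1`` TM-scores per selection method, and a random-pick baseline.
The published 56-target small-protein benchmark ships with the package
(:func:`load_reference_table`) so the aggregate statistics can be
recomputed without any decoy download; synthetic benchmarks are produced
by :func:`run_benchmark` on generated ensembles.

The significance machinery is the equal-sample-size two-sample Student
t-test with pooled variance (2n - 2 degrees of freedom, two-sided p).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .clustering import (SpickerParams, kmeans, kmeans_plusplus, select_models,
                         sk_means, spicker_cluster)
from .metrics import DistanceMatrix, pairwise_distances, tm_score
from .structures import DecoyEnsemble

__all__ = [
    "BenchmarkTable",
    "TTestResult",
    "load_reference_table",
    "score_against_native",
    "random_baseline",
    "count_ge_reference",
    "column_mean",
    "t_test_equal_n",
    "run_benchmark",
    "aggregate_report",
]

logger = logging.getLogger(__name__)

#: column roles every benchmark table carries besides per-method scores
META_COLUMNS = ("target", "length", "size", "best", "random")


@dataclass(frozen=True)
class TTestResult:
    """Equal-n pooled-variance Student t-test outcome."""

    t_statistic: float
    p_value: float
    n_per_group: int

    @property
    def df(self) -> int:
        return 2 * self.n_per_group - 2


class BenchmarkTable:
    """Per-target TM-scores of selected models, one column per method."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in ("target",) if c not in frame.columns]
        if missing:
            raise ValueError(f"benchmark table lacks required columns: {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def methods(self) -> List[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(f"no column {name!r} in benchmark table")
        col = self.frame[name]
        bad = col.isna()
        if bad.any():
            row = self.frame.loc[bad.idxmax(), "target"]
            raise ValueError(f"missing {name!r} value for target {row!r}")
        return col.to_numpy(dtype=float)

    def filter_size_below(self, max_size: int) -> "BenchmarkTable":
        """Subgroup with decoy-set size strictly below ``max_size``."""
        return BenchmarkTable(self.frame[self.frame["size"] < max_size])

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "BenchmarkTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def load_reference_table() -> BenchmarkTable:
    """The packaged 56-target small-protein benchmark (TM-scores of model1
    per method, as published)."""
    ref = importlib.resources.files("decoyclust.data").joinpath("table1.tsv")
    with importlib.resources.as_file(ref) as path:
        return BenchmarkTable.from_tsv(path)


def score_against_native(ensemble: DecoyEnsemble, model_index: int) -> float:
    """TM-score of one member against the ensemble's native structure."""
    if ensemble.native is None:
        raise ValueError("ensemble has no native structure to score against")
    return tm_score(ensemble.members[model_index], ensemble.native).score


def random_baseline(ensemble: DecoyEnsemble, rng: np.random.Generator) -> int:
    """Uniform random member index — the no-information selection baseline."""
    return int(rng.integers(len(ensemble.members)))


def count_ge_reference(table: BenchmarkTable, method: str, reference: str) -> int:
    """Number of targets where ``method`` scores at least as well as
    ``reference`` (ties count)."""
    return int(np.sum(table.column(method) >= table.column(reference)))


def column_mean(table: BenchmarkTable, method: str) -> float:
    """Arithmetic mean TM-score of a method's column."""
    return float(np.mean(table.column(method)))


def t_test_equal_n(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sample Student t-test with pooled variance, equal sample sizes.

    With n observations per group,
    ``t = (mean_a - mean_b) / sqrt(s_p^2 * 2/n)`` where
    ``s_p^2 = (s_a^2 + s_b^2) / 2`` (unbiased variances), on ``2n - 2``
    degrees of freedom; the p-value is two-sided.  Identical samples give
    ``t = 0, p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
        raise ValueError("the equal-n t-test needs two 1-D samples of the same size")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = 0.5 * (np.var(a, ddof=1) + np.var(b, ddof=1))
    denom = np.sqrt(sp2 * 2.0 / n)
    if denom == 0.0:
        t = 0.0 if np.mean(a) == np.mean(b) else np.inf * np.sign(np.mean(a) - np.mean(b))
    else:
        t = float((np.mean(a) - np.mean(b)) / denom)
    df = 2 * n - 2
    p = float(2.0 * _sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TTestResult(float(t), min(1.0, p), n)


#: method name -> callable(DistanceMatrix, seed) -> Clustering
def _default_methods(k: int, spicker_params: SpickerParams,
                     max_iter: int) -> Dict[str, Callable]:
    def _kmeans(D: DistanceMatrix, seed: int):
        rng = np.random.default_rng(seed)
        # classical K-means: uniform random distinct initial centers
        seeds = rng.choice(D.n, size=min(k, D.n), replace=False)
        return kmeans(D, seeds, max_iter=max_iter)

    return {
        "kmeans_pp": lambda D, seed: kmeans_plusplus(
            D, K=min(k, D.n), max_iter=max_iter, rng=np.random.default_rng(seed)),
        "sk_means": lambda D, seed: sk_means(D, spicker_params, max_iter=max_iter),
        "kmeans": _kmeans,
        "spicker": lambda D, seed: spicker_cluster(D, spicker_params),
    }


def run_benchmark(ensembles: Sequence[DecoyEnsemble], seed: int = 0,
                  metric: str = "rmsd", k: int = 5,
                  spicker_params: SpickerParams = SpickerParams(),
                  max_iter: int = 100) -> BenchmarkTable:
    """Cluster each ensemble with every method, select model1, score vs native.

    Per-target failures are logged and the target skipped; the run
    continues.  ``best`` is the maximum TM-score over all members, so on
    tables produced here every per-method score is bounded by ``best``.
    """
    methods = _default_methods(k, spicker_params, max_iter)
    rows = []
    for i, ens in enumerate(ensembles):
        if ens.native is None:
            logger.warning("target %s has no native; skipped", ens.target_id)
            continue
        try:
            D = pairwise_distances(ens, metric)
            all_scores = np.array([score_against_native(ens, j)
                                   for j in range(len(ens.members))])
            row = {
                "target": ens.target_id,
                "length": ens.n_residues,
                "size": len(ens.members),
                "best": float(all_scores.max()),
            }
            for name, fn in methods.items():
                clustering = fn(D, seed + i)
                model1 = select_models(clustering, D, n_models=1)[0]
                row[name] = float(all_scores[model1])
            rng = np.random.default_rng(seed + i)
            row["random"] = float(all_scores[random_baseline(ens, rng)])
            rows.append(row)
        except Exception:
            logger.exception("target %s failed; skipped", ens.target_id)
    if not rows:
        raise ValueError("no targets produced a benchmark row")
    return BenchmarkTable(pd.DataFrame(rows))


def aggregate_report(table: BenchmarkTable, reference: str = "spicker",
                     size_subgroup: Optional[int] = 520) -> Dict[str, object]:
    """The benchmark's aggregate block: per-method means, counts of targets
    at or above the reference method, and equal-n t-tests of each method
    against the random baseline (full table and, optionally, the small-
    decoy-set subgroup)."""
    out: Dict[str, object] = {
        "n_targets": len(table),
        "means": {m: column_mean(table, m) for m in table.methods + ["best", "random"]
                  if m in table.frame.columns},
        "counts_ge_reference": {
            m: count_ge_reference(table, m, reference)
            for m in table.methods if m != reference
        },
        "reference": reference,
    }
    if "random" in table.frame.columns:
        out["t_vs_random"] = {
            m: t_test_equal_n(table.column(m), table.column("random"))
            for m in table.methods
        }
        if size_subgroup is not None:
            sub = table.filter_size_below(size_subgroup)
            if len(sub) >= 2:
                out["n_targets_small"] = len(sub)
                out["t_vs_random_small"] = {
                    m: t_test_equal_n(sub.column(m), sub.column("random"))
                    for m in sub.methods
                }
    return out


def render_report(report: Dict[str, object]) -> str:
    """Plain-text rendering of :func:`aggregate_report` output."""
    lines = [f"targets: {report['n_targets']}"]
    lines.append("mean TM-score of model1:")
    for m, v in report["means"].items():  # type: ignore[union-attr]
        lines.append(f"  {m:<12s} {v:.4f}")
    ref = report["reference"]
    lines.append(f"targets with TM >= {ref}:")
    for m, v in report["counts_ge_reference"].items():  # type: ignore[union-attr]
        lines.append(f"  {m:<12s} {v} / {report['n_targets']}")
    if "t_vs_random" in report:
        lines.append("equal-n t-test vs random baseline (t, two-sided p):")
        for m, r in report["t_vs_random"].items():  # type: ignore[union-attr]
            lines.append(f"  {m:<12s} t={r.t_statistic:+.3f}  p={r.p_value:.4f}")
    if "t_vs_random_small" in report:
        lines.append(f"subgroup: decoy size < 520 ({report['n_targets_small']} targets):")
        for m, r in report["t_vs_random_small"].items():  # type: ignore[union-attr]
            lines.append(f"  {m:<12s} t={r.t_statistic:+.3f}  p={r.p_value:.4f}")
    return "\n".join(lines)
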