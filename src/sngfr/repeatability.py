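"""Repeatability and workflow-comparison statistics.

Repeated manual analysis of the same glomerulus yields a small set of snGFR
replicates per dataset; the repeatability metric is the coefficient of
variation (CV, relative SD = 100·SD/mean, with the sample n−1 SD), aggregated
across datasets as the *unweighted* mean of per-dataset CVs. Workflows are
compared by the mean ± SD of per-dataset means and a two-sample
Kolmogorov–Smirnov test of the pooled result vectors.

A published repeatability summary for 15 glomeruli analysed five times with
both the two-point and the continuous workflow ships with the package
(``load_reference_summary``) for validation and as the worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatTable",
    "summarize_dataset",
    "aggregate_cv",
    "workflow_summary",
    "ks_two_sample",
    "load_reference_summary",
    "PREVIOUS",
    "EXTENDED",
]

PREVIOUS = "previous"
EXTENDED = "extended"


def summarize_dataset(values: Sequence[float]) -> tuple[float, float, float | None]:
    """(mean, sample SD, relative SD %) of one dataset's replicates.

    The SD uses the n−1 denominator. With a zero mean the relative SD is
    undefined and returned as None.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("at least 2 replicates required for an SD")
    if not np.all(np.isfinite(v)):
        raise ValueError("replicate values must be finite")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    rel = None if mean == 0 else 100.0 * sd / mean
    return mean, sd, rel


def aggregate_cv(relative_sds: Sequence[float]) -> float:
    """Mean CV: the unweighted mean of per-dataset relative SDs (%)."""
    r = np.asarray(relative_sds, dtype=float)
    if r.size < 1:
        raise ValueError("at least one dataset required")
    return float(r.mean())


def workflow_summary(dataset_means: Sequence[float]) -> tuple[float, float]:
    """(mean, sample SD) over the per-dataset mean snGFRs of one workflow."""
    m = np.asarray(dataset_means, dtype=float)
    if m.size < 2:
        raise ValueError("at least 2 dataset means required")
    return float(m.mean()), float(m.std(ddof=1))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: (D, p).

    D = sup |ECDF_x − ECDF_y|. The p-value is computed exactly for small
    samples (n·m ≤ 10⁴) and asymptotically otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RepeatTable:
    """Replicated snGFR measurements keyed by (dataset id, workflow)."""

    datasets: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def add(self, dataset_id: str, workflow: str, values: Sequence[float]) -> None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("each dataset needs at least 2 replicates")
        self.datasets[(dataset_id, workflow)] = v

    def workflows(self) -> list[str]:
        return sorted({w for _, w in self.datasets})

    def per_dataset_summary(self, workflow: str) -> pd.DataFrame:
        rows = []
        for (ds, wf), v in sorted(self.datasets.items()):
            if wf != workflow:
                continue
            mean, sd, rel = summarize_dataset(v)
            rows.append(
                {
                    "dataset_id": ds,
                    "workflow": wf,
                    "mean_sngfr_nl_min": mean,
                    "sd_nl_min": sd,
                    "relative_sd_percent": rel,
                }
            )
        if not rows:
            raise ValueError(f"no datasets for workflow {workflow!r}")
        return pd.DataFrame(rows)

    def mean_cv(self, workflow: str) -> float:
        summ = self.per_dataset_summary(workflow)
        return aggregate_cv(summ["relative_sd_percent"].dropna().to_numpy())

    def summary(self, workflow: str) -> tuple[float, float]:
        summ = self.per_dataset_summary(workflow)
        return workflow_summary(summ["mean_sngfr_nl_min"].to_numpy())

    def pooled(self, workflow: str) -> np.ndarray:
        vals = [v for (_, wf), v in sorted(self.datasets.items()) if wf == workflow]
        if not vals:
            raise ValueError(f"no datasets for workflow {workflow!r}")
        return np.concatenate(vals)

    @classmethod
    def from_long_csv(cls, path) -> "RepeatTable":
        """Long format: dataset_id, workflow, replicate, sngfr_nl_min."""
        df = pd.read_csv(path)
        needed = {"dataset_id", "workflow", "sngfr_nl_min"}
        if not needed <= set(df.columns):
            raise ValueError(f"replicate CSV must have columns {sorted(needed)}")
        table = cls()
        for (ds, wf), grp in df.groupby(["dataset_id", "workflow"]):
            table.add(str(ds), str(wf), grp["sngfr_nl_min"].to_numpy())
        return table


def load_reference_summary() -> pd.DataFrame:
    """The bundled per-dataset repeatability summary (15 glomeruli × 2 workflows).

    Columns: dataset_id, workflow ('previous' two-point / 'extended'
    continuous), mean_sngfr_nl_min, sd_nl_min, relative_sd_percent. Each
    summary row condenses five repeated manual analyses of one glomerulus.
    """
    with resources.files("sngfr").joinpath("data/repeatability_summary.csv").open() as fh:
        return pd.read_csv(fh)
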