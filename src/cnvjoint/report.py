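"""Diagnostics and run reporting: genomic inflation, QQ points, Manhattan
tables, and the structured run report.

The genomic inflation factor lambda is the genomic-control median ratio:
p-values are converted to 1-df chi-square quantiles (multi-df joint tests
are first collapsed to their p-value, then transformed through the 1-df
quantile -- the usual convention) and the median statistic is divided by the
null chi-square(1) median (~0.4549).  lambda < 1 marks a conservative test,
as the GRAMMAR screen is; lambda > 1 marks inflation, e.g. uncorrected
stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def _check_pvalues(p_values) -> np.ndarray:
    p = np.asarray(pd.Series(p_values).to_numpy(), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    if p.size < 100:
        logger.warning("only %d p-values; inflation estimate is unstable", p.size)
    return p


def genomic_inflation_lambda(p_values) -> float:
    """Median-based genomic inflation factor of a p-value vector."""
    p = _check_pvalues(p_values)
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / _CHI2_1_MEDIAN)


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p pairs for a QQ plot.

    expected_i = -log10((i - 0.5) / n) against the ascending order
    statistics of the observed p-values, both returned largest-last.
    """
    p = _check_pvalues(p_values)
    n = p.size
    observed = -np.log10(np.sort(p)[::-1])
    expected = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
    return expected, observed


def manhattan_table(results: pd.DataFrame, stage: str = "auto") -> pd.DataFrame:
    """Genome-ordered table of -log10 p suitable for Manhattan plotting.

    ``stage`` selects 'stage1', 'stage2' or 'auto' (stage 2 where present,
    stage 1 otherwise).  A per-chromosome cumulative offset column supports
    a single genome-wide x axis.
    """
    if results.empty:
        raise ValidationError("empty results table")
    df = results.copy()
    if stage == "auto":
        p = pd.to_numeric(df.get("stage2_p"), errors="coerce")
        p = p.fillna(pd.to_numeric(df["stage1_p"], errors="coerce"))
        df["stage"] = np.where(df.get("stage2_p").notna(), "stage2", "stage1")
    else:
        p = pd.to_numeric(df[f"{stage}_p"], errors="coerce")
        df["stage"] = stage
    df["neg_log10_p"] = -np.log10(p.clip(lower=np.nextafter(0, 1)))
    num = pd.to_numeric(df["chrom"], errors="coerce").fillna(10_000)
    df = df.assign(_cr=num).sort_values(["_cr", "pos"], kind="mergesort")
    offset = 0
    offsets = {}
    for c, grp in df.groupby("_cr", sort=True):
        offsets[c] = offset
        offset += int(grp["pos"].max()) + 1
    df["offset"] = df["_cr"].map(offsets)
    df["genome_pos"] = df["offset"] + df["pos"]
    cols = ["chrom", "pos", "offset", "genome_pos", "neg_log10_p", "stage"]
    if "significant" in df.columns:
        cols.append("significant")
    if "marker_id" in df.columns:
        cols.insert(0, "marker_id")
    return df[cols].reset_index(drop=True)


@dataclass
class RunReport:
    """Stage-wise counts, inflation factors and log lines for one run."""

    config: dict = field(default_factory=dict)
    seed: int | None = None
    counts: dict = field(default_factory=dict)
    lambda_stage1: float | None = None
    lambda_stage2: float | None = None
    stage1_cutoff: float | None = None
    lines: list = field(default_factory=list)

    def count(self, stage: str, **kw) -> None:
        self.counts.setdefault(stage, {}).update(kw)

    def log(self, message: str) -> None:
        self.lines.append(message)
        logger.info(message)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "counts": self.counts,
            "lambda_stage1": self.lambda_stage1,
            "lambda_stage2": self.lambda_stage2,
            "stage1_cutoff": self.stage1_cutoff,
            "config": {k: v for k, v in self.config.items()},
            "log": list(self.lines),
        }

    def to_text(self) -> str:
        d = self.to_dict()
        out = ["run report", "=========="]
        out.append(f"seed: {d['seed']}")
        for stage, kv in d["counts"].items():
            pairs = ", ".join(f"{k}={v}" for k, v in kv.items())
            out.append(f"{stage}: {pairs}")
        for key in ("lambda_stage1", "lambda_stage2", "stage1_cutoff"):
            if d[key] is not None:
                out.append(f"{key}: {d[key]:.4g}")
        out.extend(f"| {line}" for line in d["log"])
        return "\n".join(out) + "\n"


def write_results(results: pd.DataFrame, path) -> None:
    """Serialize a results table (TSV, 6 significant digits for reals)."""
    out = results.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else "%.6g" % v)
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    if "stage2_df" in df.columns:
        df["stage2_df"] = df["stage2_df"].astype("Int64")
    return df


def plot_qq(p_values, ax=None):
    """Thin matplotlib veneer over :func:`qq_points` (untested plumbing)."""
    import matplotlib.pyplot as plt

    expected, observed = qq_points(p_values)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(expected, observed, ".", ms=3)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    return ax


def plot_manhattan(results, stage="auto", ax=None):
    """Thin matplotlib veneer over :func:`manhattan_table` (untested)."""
    import matplotlib.pyplot as plt

    tab = manhattan_table(results, stage=stage)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for i, (c, grp) in enumerate(tab.groupby("chrom", sort=False)):
        ax.plot(grp["genome_pos"], grp["neg_log10_p"], ".", ms=2,
                color="C0" if i % 2 == 0 else "C1")
    ax.set_xlabel("genome position")
    ax.set_ylabel("-log10 p")
    return ax
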