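"""Correlation reporting and screening statistics.

The computed imaging metrics are compared against clinical and
radiologist-scored variables with Spearman's rank correlation, corrected
for multiple testing by the Benjamini-Hochberg step-up procedure; the
report prints the data-derived critical p-value and masks non-significant
cells in the heatmap.  Grubbs and D'Agostino screens flag outliers and
non-normal distributions for the descriptive tables — screening only,
nothing is removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "GrubbsResult",
    "NormalityResult",
    "CorrelationReport",
    "spearman",
    "bh_adjust",
    "grubbs_screen",
    "normality_screen",
    "correlation_report",
]


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    ok: bool
    reason: str = ""


@dataclass(frozen=True)
class GrubbsResult:
    index: int | None       # index of the flagged extreme value, or None
    statistic: float
    critical: float
    ok: bool
    reason: str = ""


@dataclass(frozen=True)
class NormalityResult:
    p: float
    ok: bool
    reason: str = ""


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y, exact: bool = False) -> SpearmanResult:
    """Midrank-tied Spearman rho with pairwise deletion of missing values.

    The p-value uses the t approximation on n-2 degrees of freedom; with
    ``exact=True`` and n <= 8, a full-enumeration permutation p-value is
    computed instead (useful at tiny n where the approximation is poor).
    """
    xv, yv = _complete_pairs(x, y)
    n = len(xv)
    if n < 4:
        return SpearmanResult(np.nan, np.nan, n, False, "fewer than 4 complete pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return SpearmanResult(np.nan, np.nan, n, False, "zero variance")
    rho, p = sps.spearmanr(xv, yv)
    if exact and n <= 8:
        ry = sps.rankdata(yv)
        rx = sps.rankdata(xv)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return SpearmanResult(float(rho), float(p), n, True)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns ``(flags, critical_p)``: the critical p is the largest sorted
    p_(k) with p_(k) <= alpha * k / m (0 if none), and a test is flagged
    significant iff its p-value is <= that critical value.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    ks = np.arange(1, m + 1)
    passing = order[order <= alpha * ks / m]
    critical_p = float(passing[-1]) if passing.size else 0.0
    return p <= critical_p, critical_p


def grubbs_screen(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs screen.

    G = max |x_i - mean| / sd is compared with the t-based critical value;
    the extreme index is reported (never removed).  Requires at least 7
    non-missing values and nonzero variance.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 7:
        return GrubbsResult(None, np.nan, np.nan, False, "fewer than 7 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(None, np.nan, np.nan, False, "zero variance")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / sd)
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    crit = float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))
    return GrubbsResult(i if G > crit else None, G, crit, True)


def normality_screen(values) -> NormalityResult:
    """D'Agostino-Pearson omnibus (skewness + kurtosis) normality p-value.

    Used to choose between mean +/- SD and median (IQR) in descriptive
    reporting; requires at least 8 values.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 8:
        return NormalityResult(np.nan, False, "fewer than 8 values")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.normaltest(x)
    return NormalityResult(float(p), True)


@dataclass(frozen=True)
class CorrelationReport:
    """Long-format Spearman matrix with BH significance flags."""

    table: pd.DataFrame     # columns: metric, variable, rho, p, n, significant
    critical_p: float
    alpha: float

    def pivot(self, value: str = "rho") -> pd.DataFrame:
        return self.table.pivot(index="metric", columns="variable", values=value)

    def plot_heatmap(self, path=None, annotate: bool = True):
        """Heatmap of rho with non-significant cells masked."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rho = self.pivot("rho")
        sig = self.pivot("significant").astype(bool)
        data = np.ma.masked_where(~sig.to_numpy(), rho.to_numpy(dtype=float))
        fig, ax = plt.subplots(
            figsize=(1.0 + 0.6 * rho.shape[1], 1.0 + 0.5 * rho.shape[0]))
        im = ax.imshow(data, vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(rho.shape[1]), rho.columns, rotation=90)
        ax.set_yticks(range(rho.shape[0]), rho.index)
        if annotate:
            for i in range(rho.shape[0]):
                for j in range(rho.shape[1]):
                    if sig.iloc[i, j]:
                        ax.text(j, i, f"{rho.iloc[i, j]:.2f}",
                                ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        ax.set_title(f"critical p = {self.critical_p:.4g} "
                     f"(BH, alpha = {self.alpha})", fontsize=9)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig


def correlation_report(metrics: pd.DataFrame, clinical: pd.DataFrame,
                       alpha: float = 0.05, id_col: str = "patient_id",
                       metric_cols=None, variable_cols=None
                       ) -> CorrelationReport:
    """Spearman cross-correlation of metrics vs clinical variables with BH FDR.

    Tables are joined on ``id_col``; every (metric, variable) pair is one
    test, missing values are dropped pairwise, and the BH family is the
    whole set of computable pairs.
    """
    if id_col not in metrics.columns or id_col not in clinical.columns:
        raise ValueError(f"both tables need an {id_col!r} column")
    merged = metrics.merge(clinical, on=id_col, how="inner",
                           suffixes=("", "_clin"))
    if merged.empty:
        raise ValueError("no overlapping patients between metrics and clinical tables")
    if metric_cols is None:
        metric_cols = [c for c in metrics.columns if c != id_col
                       and np.issubdtype(metrics[c].dtype, np.number)]
    if variable_cols is None:
        variable_cols = [c for c in clinical.columns if c != id_col
                         and np.issubdtype(clinical[c].dtype, np.number)]

    rows = []
    for m in metric_cols:
        mc = m if m in merged.columns else f"{m}_clin"
        for v in variable_cols:
            vc = v if v in merged.columns else f"{v}_clin"
            res = spearman(merged[mc], merged[vc])
            rows.append({"metric": m, "variable": v, "rho": res.rho,
                         "p": res.p, "n": res.n, "computable": res.ok})
    table = pd.DataFrame(rows)
    computable = table["computable"].to_numpy()
    if not computable.any():
        raise ValueError("no computable correlations")
    flags = np.zeros(len(table), dtype=bool)
    flags[computable], critical_p = bh_adjust(
        table.loc[computable, "p"].to_numpy(), alpha=alpha)
    table["significant"] = flags
    return CorrelationReport(table=table, critical_p=critical_p, alpha=alpha)
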