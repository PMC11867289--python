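"""Paired cohort comparison: normal breathing versus hyperventilation.

Eight healthy volunteers were scanned twice, once breathing normally
(normocapnia, N) and once during guided spontaneous hyperventilation
(hypocapnia, H).  The per-subject whole-brain values of MTT, the apparent
oxygen extraction index (AOEF), venous baseline SNR, arterial delay and the
end-tidal CO2 levels are shipped as package fixtures and can be replaced by
any user CSV with the same columns.

The analysis mirrors standard small-sample paired methodology: Shapiro-Wilk
normality screening, a paired t-test for MTT/AOEF/SNR, an exact two-sided
Wilcoxon signed-rank test for the (non-normal) delay differences, a
Bonferroni family-wise gate at alpha/4, within-condition Pearson/regression
analysis against ETCO2, and descriptive change summaries.  "Average
increase" is reported as the mean of per-subject H/N ratios (the ratio of
column means is also provided, since the two conventions differ most for
the skewed delay values).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "paired_t_test",
    "wilcoxon_signed_rank_exact",
    "shapiro_wilk",
    "bonferroni_gate",
    "pearson_with_regression",
    "change_summaries",
    "PairedCohort",
    "PairedCohortResults",
]

_FIXTURE_SHA256 = {
    "table1_etco2.csv": "7ea70837298a69150a12ae89950bf6a599be6dd7d31feae8b027d896e33bf54d",
    "table3_params.csv": "dba8b22176792d8b82b3fe10d3ea410aa5304c4e7e191a6e1ebf096043c2235a",
}

#: paired parameters: column stem -> human name
PARAMS = {"mtt": "MTT [s]", "aoef": "AOEF [a.u.]", "snr": "Venous SNR [a.u.]", "delta": "Delay [s]"}

_COLUMNS = {
    "mtt": ("mtt_n_s", "mtt_h_s"),
    "aoef": ("aoef_n", "aoef_h"),
    "snr": ("snr_n", "snr_h"),
    "delta": ("delta_n_s", "delta_h_s"),
    "etco2": ("etco2_n_kpa", "etco2_h_kpa"),
}


def _fixture_path(name: str) -> Path:
    path = resources.files("dscbezier").joinpath("data", name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} is corrupted (sha256 mismatch)")
    return Path(str(path))


@dataclass(frozen=True)
class CohortTable:
    """Per-subject paired values for both breathing conditions."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {c for pair in _COLUMNS.values() for c in pair} | {"subject"}
        missing = needed - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
        for pair in _COLUMNS.values():
            for col in pair:
                if self.data[col].isna().any():
                    raise ValueError(f"missing pairs in column {col}")
                if (self.data[col] <= 0).any():
                    raise ValueError(f"non-positive value in column {col}")

    @classmethod
    def from_fixture(cls) -> "CohortTable":
        """The packaged study tables (checksummed on load)."""
        t1 = pd.read_csv(_fixture_path("table1_etco2.csv"))
        t3 = pd.read_csv(_fixture_path("table3_params.csv"))
        return cls(t1.merge(t3, on="subject"))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        """Read a user cohort CSV (one merged table or the fixture layout)."""
        return cls(pd.read_csv(path))

    def pair(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(normal-breathing, hyperventilation) columns of a parameter."""
        cn, ch = _COLUMNS[name]
        return self.data[cn].to_numpy(float), self.data[ch].to_numpy(float)

    @property
    def n(self) -> int:
        return len(self.data)


# -- elementary tests --------------------------------------------------------


def paired_t_test(x, y) -> tuple[float, float, int]:
    """Classical paired t-test on the differences y - x.

    Returns ``(t, two-sided p, df)`` with df = n - 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = y - x
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue), x.size - 1


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of 2*W over all 2^n sign assignments (exact, via DP).

    ``ranks2`` are the doubled ranks (integers even with midrank ties).
    The dynamic program multiplies out prod_i (1 + z^r_i), which enumerates
    every sign assignment exactly.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    The statistic is W+, the rank sum of positive differences y - x (midranks
    for ties); the two-sided p-value is 2 * min(P(W <= w), P(W >= w)) from
    the exact null distribution over all 2^n equally likely sign
    assignments, capped at 1.  Zero differences are dropped with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("need paired samples of equal length")
    d = y - x
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    if np.any(d == 0):
        warnings.warn("dropping zero differences before ranking", stacklevel=2)
        d = d[d != 0]
    n = d.size
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25 only")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    ranks2 = np.round(2 * ranks).astype(int)
    counts = _signed_rank_distribution(ranks2)
    total = float(2**n)
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_plus, float(p)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (scipy implementation: AS R94
    approximation of the coefficients and p-value)."""
    x = np.asarray(x, float)
    if not 3 <= x.size <= 50:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 50 here")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def bonferroni_gate(p_values, alpha: float = 0.05, m: int | None = None) -> np.ndarray:
    """Family-wise significance flags: p < alpha / m (strict inequality)."""
    p_values = np.asarray(p_values, float)
    m = p_values.size if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    return p_values < alpha / m


def pearson_with_regression(x, y) -> dict:
    """Pearson correlation plus least-squares line.

    Returns ``{"r", "slope", "intercept", "p"}``; p is the two-sided
    p-value from the t transform of r (n - 2 df).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    lr = stats.linregress(x, y)
    return {
        "r": float(lr.rvalue),
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "p": float(lr.pvalue),
    }


def change_summaries(table: CohortTable) -> pd.DataFrame:
    """Descriptive change statistics per parameter.

    For each paired parameter: the two column means and SDs, the mean and
    median of per-subject H/N ratios, and the ratio of column means.  The
    ``*_pct`` columns express the ratios as percent change.
    """
    rows = []
    for name in PARAMS:
        n_vals, h_vals = table.pair(name)
        ratios = h_vals / n_vals
        mean_ratio = float(ratios.mean())
        ratio_of_means = float(h_vals.mean() / n_vals.mean())
        rows.append(
            {
                "param": name,
                "mean_n": float(n_vals.mean()),
                "mean_h": float(h_vals.mean()),
                "sd_n": float(n_vals.std(ddof=1)),
                "sd_h": float(h_vals.std(ddof=1)),
                "mean_subject_ratio": mean_ratio,
                "mean_subject_ratio_pct": 100.0 * (mean_ratio - 1.0),
                "ratio_of_means": ratio_of_means,
                "ratio_of_means_pct": 100.0 * (ratio_of_means - 1.0),
                "median_subject_ratio": float(np.median(ratios)),
            }
        )
    return pd.DataFrame(rows).set_index("param")


def central_volume_mtt_factor(cbv_ratio: float, cbf_ratio: float) -> float:
    """MTT change factor implied by the central volume theorem.

    MTT = CBV/CBF, so relative changes combine as
    MTT_H/MTT_N = (CBV_H/CBV_N) / (CBF_H/CBF_N).
    """
    if cbf_ratio <= 0 or cbv_ratio <= 0:
        raise ValueError("ratios must be > 0")
    return cbv_ratio / cbf_ratio


def velocity_reduction_from_delay_prolongation(delay_ratio: float) -> float:
    """Fractional arterial velocity reduction implied by a delay prolongation.

    For a fixed travel distance, velocity is inversely proportional to the
    arrival delay: v_H/v_N = delta_N/delta_H, so the reduction is
    1 - 1/delay_ratio.
    """
    if delay_ratio <= 0:
        raise ValueError("delay_ratio must be > 0")
    return 1.0 - 1.0 / delay_ratio


# -- model / results objects -------------------------------------------------


class PairedCohort:
    """Paired-comparison model for a two-condition cohort table.

    ``fit()`` runs the full statistical battery and returns a
    :class:`PairedCohortResults`.
    """

    def __init__(self, table: CohortTable | None = None, alpha: float = 0.05):
        self.table = table if table is not None else CohortTable.from_fixture()
        self.alpha = float(alpha)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PairedCohort":
        return cls(CohortTable.from_csv(path), **kwargs)

    def fit(self, pooled_regression: bool = False) -> "PairedCohortResults":
        table = self.table
        tests = []
        for name in PARAMS:
            n_vals, h_vals = table.pair(name)
            w_stat, w_p = shapiro_wilk(h_vals - n_vals)
            if name == "delta":
                stat, p = wilcoxon_signed_rank_exact(n_vals, h_vals)
                test = "wilcoxon_exact"
                df = np.nan
            else:
                stat, p, df = paired_t_test(n_vals, h_vals)
                test = "paired_t"
            tests.append(
                {
                    "param": name,
                    "test": test,
                    "statistic": stat,
                    "df": df,
                    "p": p,
                    "shapiro_w": w_stat,
                    "shapiro_p": w_p,
                }
            )
        tests = pd.DataFrame(tests).set_index("param")
        m = len(tests)
        tests["significant"] = bonferroni_gate(tests["p"].to_numpy(), self.alpha, m)

        et_n, et_h = table.pair("etco2")
        correlations = []
        for name in PARAMS:
            n_vals, h_vals = table.pair(name)
            for cond, et, vals in (("normocapnia", et_n, n_vals), ("hypocapnia", et_h, h_vals)):
                rec = pearson_with_regression(et, vals)
                correlations.append({"param": name, "condition": cond, **rec})
            if pooled_regression:
                rec = pearson_with_regression(
                    np.concatenate([et_n, et_h]), np.concatenate([n_vals, h_vals])
                )
                correlations.append({"param": name, "condition": "pooled", **rec})
        correlations = pd.DataFrame(correlations).set_index(["param", "condition"])

        return PairedCohortResults(
            model=self,
            tests=tests,
            summaries=change_summaries(table),
            correlations=correlations,
            alpha=self.alpha,
            m=m,
        )


@dataclass
class PairedCohortResults:
    """Fitted cohort comparison: tests, change summaries, correlations."""

    model: PairedCohort
    tests: pd.DataFrame
    summaries: pd.DataFrame
    correlations: pd.DataFrame
    alpha: float
    m: int

    def summary(self) -> str:
        lines = [
            "Paired cohort comparison: normal breathing (N) vs hyperventilation (H)",
            f"n = {self.model.table.n} subjects; Bonferroni gate alpha/m = "
            f"{self.alpha}/{self.m} = {self.alpha / self.m:.4g}",
            "",
            "Hypothesis tests",
            "----------------",
        ]
        for name, row in self.tests.iterrows():
            lines.append(
                f"{PARAMS[name]:<18} {row['test']:<14} stat={row['statistic']:8.4f} "
                f"p={row['p']:.4g} {'significant' if row['significant'] else 'n.s.'} "
                f"(Shapiro-Wilk p={row['shapiro_p']:.3g})"
            )
        lines += ["", "Change summaries", "----------------"]
        for name, row in self.summaries.iterrows():
            lines.append(
                f"{PARAMS[name]:<18} mean N={row['mean_n']:7.3f}  mean H={row['mean_h']:7.3f}  "
                f"mean subj. ratio={row['mean_subject_ratio']:.3f} "
                f"({row['mean_subject_ratio_pct']:+.1f} %)  "
                f"ratio of means={row['ratio_of_means']:.3f} "
                f"({row['ratio_of_means_pct']:+.1f} %)"
            )
        lines += ["", "ETCO2 correlations (within condition)", "-------------------------------------"]
        for (name, cond), row in self.correlations.iterrows():
            lines.append(
                f"{PARAMS[name]:<18} {cond:<12} r={row['r']:+.3f} p={row['p']:.4g} "
                f"slope={row['slope']:+.3f}"
            )
        return "\n".join(lines)

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tests.to_csv(outdir / "tests.csv")
        self.summaries.to_csv(outdir / "change_summaries.csv")
        self.correlations.to_csv(outdir / "correlations.csv")
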