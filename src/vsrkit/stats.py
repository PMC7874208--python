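"""Group-level statistics for per-cycle VSR metrics.

Genotype groups are compared the way the assay's figures are starred: an
omnibus fixed-effects two-factor ANOVA (genotype x cycle, larvae as
replicates) per metric, plus per-cycle two-group contrasts whose p-values
are Benjamini–Hochberg adjusted across the cycles of that metric.  The BH
step-up adjustment is implemented from its definition; the ANOVA and the
normality screens lean on statsmodels/scipy.

The repeated-measures structure (the same larva contributes every cycle)
is deliberately ignored, matching the fixed-effects analysis the assay
uses; see the methods note for why that is a statistical limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import normal_ad

from .errors import InsufficientDataError, MissingCellError

__all__ = [
    "StatsResult",
    "bh_adjust",
    "compare_groups",
    "normality_screen",
    "stars",
]

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(q: float) -> str:
    """Significance stars at adjusted-p thresholds 0.05 / 0.01 / 0.001."""
    for level, mark in STAR_LEVELS:
        if q < level:
            return mark
    return ""


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    For sorted p-values p(1) <= ... <= p(m),
    ``q(i) = min_{j >= i} (m * p(j) / j)`` clipped to 1.  NaN entries (from
    degenerate contrasts) are passed through untouched and do not count
    toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[finite] = out
    return q


@dataclass
class StatsResult:
    """Two-factor omnibus effects plus BH-adjusted per-cycle contrasts."""

    metric: str
    anova: pd.DataFrame  # rows: genotype, cycle, interaction, residual
    contrasts: pd.DataFrame  # per-cycle: means, sems, p_raw, q_bh, stars

    @property
    def genotype_p(self) -> float:
        return float(self.anova.loc["genotype", "PR(>F)"])

    @property
    def n_significant_cycles(self) -> int:
        return int((self.contrasts["q_bh"] < 0.05).sum())


def _validate_table(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    required = {"larva_id", "genotype", "cycle_index", metric}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"group table lacks columns: {sorted(missing)}")
    d = df.dropna(subset=[metric]).copy()
    if d.duplicated(["larva_id", "cycle_index"]).any():
        raise ValueError("each (larva, cycle) may appear at most once per metric")
    genotypes = sorted(d["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need at least 2 genotypes to compare")
    if d["cycle_index"].nunique() < 2:
        raise ValueError("need at least 2 cycles to compare")
    counts = d.groupby("genotype")["larva_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 larvae per genotype")
    cells = d.groupby(["genotype", "cycle_index"]).size().unstack(fill_value=0)
    if (cells == 0).any().any():
        empty = [
            (g, c) for g in cells.index for c in cells.columns if cells.loc[g, c] == 0
        ]
        raise MissingCellError(f"empty genotype x cycle cells: {empty[:5]}")
    return d


def compare_groups(table: pd.DataFrame, metric: str) -> StatsResult:
    """Compare genotype groups on one per-cycle metric.

    ``table`` is tidy: one row per (larva, cycle) with columns ``larva_id``,
    ``genotype``, ``cycle_index`` and the metric.  With two genotypes the
    per-cycle contrasts are Welch t-tests; with more, one-way F-tests.
    The contrast family for BH adjustment is the set of cycles within this
    metric.  Deterministic given the table.
    """
    d = _validate_table(table, metric)
    d = d.rename(columns={metric: "value"})
    model = smf.ols("value ~ C(genotype) * C(cycle_index)", data=d).fit()
    an = sm.stats.anova_lm(model, typ=2)
    an = an.rename(
        index={
            "C(genotype)": "genotype",
            "C(cycle_index)": "cycle",
            "C(genotype):C(cycle_index)": "interaction",
            "Residual": "residual",
        }
    )

    genotypes = sorted(d["genotype"].unique())
    rows = []
    for cyc, g in d.groupby("cycle_index", sort=True):
        samples = [
            g.loc[g["genotype"] == geno, "value"].to_numpy() for geno in genotypes
        ]
        if len(genotypes) == 2:
            a, b = samples
            if np.var(a) == 0 and np.var(b) == 0:
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            else:
                p = float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = float(scipy.stats.f_oneway(*samples).pvalue)
        row = {"cycle_index": cyc, "p_raw": p}
        for geno, s in zip(genotypes, samples):
            row[f"mean_{geno}"] = float(np.mean(s))
            row[f"sem_{geno}"] = float(scipy.stats.sem(s)) if len(s) > 1 else np.nan
        rows.append(row)
    contrasts = pd.DataFrame(rows)
    contrasts["q_bh"] = bh_adjust(contrasts["p_raw"].to_numpy())
    contrasts["stars"] = [stars(q) if np.isfinite(q) else "" for q in contrasts["q_bh"]]
    return StatsResult(metric=metric, anova=an, contrasts=contrasts)


def normality_screen(values) -> dict[str, float]:
    """P-values of four normality tests on one sample (report-only).

    Anderson–Darling, D'Agostino–Pearson, Shapiro–Wilk, and a
    Kolmogorov–Smirnov test against a normal with the sample's moments.
    Tests that cannot run at the given n report NaN rather than failing the
    screen; nothing is gated on the outcome.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise InsufficientDataError(
            f"normality screening needs at least 3 values, got {len(x)}"
        )
    out: dict[str, float] = {}
    try:
        out["anderson_darling"] = float(normal_ad(x)[1])
    except Exception:
        out["anderson_darling"] = float("nan")
    try:
        out["dagostino_pearson"] = float(scipy.stats.normaltest(x).pvalue)
    except Exception:
        out["dagostino_pearson"] = float("nan")
    try:
        out["shapiro_wilk"] = float(scipy.stats.shapiro(x).pvalue)
    except Exception:
        out["shapiro_wilk"] = float("nan")
    sd = x.std(ddof=1)
    if sd > 0:
        out["kolmogorov_smirnov"] = float(
            scipy.stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue
        )
    else:
        out["kolmogorov_smirnov"] = float("nan")
    return out
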