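"""Group-level inference and brain-behavior correlation.

Network metrics are residualized for age and gender before a one-way
ANOVA across the three groups; the seven global measures use a
Bonferroni family of 7, nodal/modular measures use Benjamini-Hochberg
FDR, and the three brain-behavior partial-correlation families use the
fixed Bonferroni denominators 40 (regional metrics), 8 (inter-module
connectivity) and 64 (edgewise connectivity). Post hoc contrasts are
pooled-variance two-sample t-tests; gender frequencies are compared by
a Pearson chi-square test without continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .nbs import pooled_t

logger = logging.getLogger(__name__)

#: The a-priori Bonferroni families: seven global graph metrics; 40
#: regional, 8 inter-module, and 64 edgewise correlation tests.
BONFERRONI_FAMILIES = {"global_metrics": 7, "regional": 40, "intermodule": 8, "rsfc": 64}


@dataclass
class GroupComparisonResult:
    metric: str
    f: float
    p: float
    correction: str
    threshold: float | None
    significant: bool
    posthoc: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    partial_r: float
    p: float
    n: int
    family_size: int | None = None

    @property
    def significant(self) -> bool:
        if self.family_size is None:
            return self.p < 0.05
        return self.p < 0.05 / self.family_size


def encode_gender(gender: np.ndarray) -> np.ndarray:
    """Deterministic 0/1 coding (M=0, F=1)."""
    g = np.asarray(gender)
    if g.dtype.kind in "if":
        return g.astype(float)
    return (g == "F").astype(float)


def residualize(values: np.ndarray, age: np.ndarray, gender: np.ndarray) -> np.ndarray:
    """OLS residuals of a metric on [intercept, age, gender(0/1)],
    pooled across all subjects. Constant covariate columns are dropped
    with a warning."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing metric values")
    cols = [np.ones(len(values))]
    for name, col in (("age", np.asarray(age, float)), ("gender", encode_gender(gender))):
        if np.isnan(col).any():
            raise ValueError(f"missing {name} covariate")
        if np.ptp(col) == 0:
            logger.warning("covariate %s is constant; dropped from the design", name)
            continue
        cols.append(col)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def oneway_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need at least 2 groups with at least 2 members each")
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def gender_chisq(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a groups x 2
    gender contingency table."""
    counts = np.asarray(counts)
    if (counts < 0).any() or counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        raise ValueError("contingency table needs nonnegative entries and positive margins")
    chi2, p, _, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


@dataclass
class CorrectionResult:
    method: str
    reject: np.ndarray
    threshold: float | None
    family_size: int | None
    p_adjusted: np.ndarray | None = None


def correct(
    p_values: np.ndarray,
    method: str = "bonferroni",
    family_size: int | None = None,
    q: float = 0.05,
) -> CorrectionResult:
    """Multiple-comparison decisions.

    Bonferroni compares each p to ``q / family_size`` with the family
    size fixed a priori (it may exceed the number of tests actually
    run, as when a correction family is declared in advance); FDR is
    Benjamini-Hochberg at level ``q``.
    """
    p_values = np.asarray(p_values, dtype=float)
    if ((p_values < 0) | (p_values > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if method == "bonferroni":
        if family_size is None:
            family_size = len(p_values)
        if family_size <= 0:
            raise ValueError("family_size must be positive")
        if family_size < len(p_values):
            logger.warning(
                "Bonferroni family size %d is smaller than the %d tests supplied",
                family_size,
                len(p_values),
            )
        thr = q / family_size
        return CorrectionResult("bonferroni", p_values < thr, thr, family_size)
    if method == "fdr":
        reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
        return CorrectionResult("fdr", reject, None, None, p_adjusted=p_adj)
    raise ValueError("method must be 'bonferroni' or 'fdr'")


def partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
    family_size: int | None = None,
) -> CorrelationResult:
    """Partial Pearson correlation controlling for covariates.

    Computed as the correlation of the OLS residuals of x and y on the
    covariates; p from the t distribution with n - 2 - q degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(x):
        cov = cov.T
    n, n_cov = cov.shape
    if len(x) != n or len(y) != n:
        raise ValueError("x, y and covariates must align")
    if n <= n_cov + 2:
        raise ValueError("need n > number of covariates + 2")
    keep = [k for k in range(n_cov) if np.ptp(cov[:, k]) > 0]
    design = np.column_stack([np.ones(n), cov[:, keep]])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate residual variance")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - len(keep)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(x_name, y_name, r, p, n, family_size)


def pairwise_posthoc(
    values: np.ndarray, groups: np.ndarray
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pooled-variance two-sample t for every group pair."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [str(g) for g in np.unique(groups)]
    out = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            t, p = pooled_t(values[groups == a], values[groups == b])
            out[(a, b)] = (t, p)
    return out


def group_metric_anova(
    metrics: pd.DataFrame,
    groups: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    correction: str = "bonferroni",
    family_size: int | None = None,
) -> list[GroupComparisonResult]:
    """Residualize -> one-way ANOVA -> correction -> post hoc, for each
    metric column of ``metrics`` (one row per subject)."""
    names = list(metrics.columns)
    if family_size is None and correction == "bonferroni":
        family_size = len(names)
    resids = {m: residualize(metrics[m].to_numpy(), age, gender) for m in names}
    fps = {m: oneway_anova(resids[m], groups) for m in names}
    pvals = np.array([fps[m][1] for m in names])
    corr = correct(pvals, method="fdr" if correction == "fdr" else "bonferroni",
                   family_size=family_size)
    results = []
    for k, m in enumerate(names):
        f, p = fps[m]
        sig = bool(corr.reject[k])
        res = GroupComparisonResult(
            metric=m,
            f=f,
            p=p,
            correction=corr.method,
            threshold=corr.threshold,
            significant=sig,
        )
        if sig:
            res.posthoc = pairwise_posthoc(resids[m], groups)
        results.append(res)
    return results


def comparison_table(results: list[GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "metric": r.metric,
            "F": r.f,
            "p": r.p,
            "correction": r.correction,
            "threshold": r.threshold,
            "significant": r.significant,
        }
        for (a, b), (t, p) in r.posthoc.items():
            row[f"t_{a}_vs_{b}"] = t
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
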