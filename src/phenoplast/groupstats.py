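"""Two-way fixed-effects ANOVA of trait values (Treatment x Family with an
additive block term) and the accompanying assumption checks.

Simplification, documented: split-plot error strata are not modelled; block
enters as an additive fixed effect and every F-test uses the residual mean
square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitTable

logger = logging.getLogger(__name__)


@dataclass
class AssumptionReport:
    shapiro_w: float
    shapiro_p: float
    levene_stat: float
    levene_p: float


@dataclass
class AnovaResult:
    trait: str
    phase: str
    table: pd.DataFrame  # rows Treatment, Family, T x F, Block, Residuals
    assumptions: AssumptionReport | None  # None when residuals are degenerate


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels).tolist(), key=str)
    cols = [(labels == lv).astype(float) for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((labels.size, 0))), levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(table: TraitTable, trait: str, phase: str) -> AnovaResult:
    """Sequential ANOVA with terms Treatment, Family, Treatment x Family and
    Block, each tested against the residual mean square.

    Requires at least two observations in every family x treatment cell.
    """
    df = table.subset(phase=phase, trait=trait)
    if df.empty:
        raise ValueError(f"no observations for trait {trait} at phase {phase}")
    counts = df.groupby(["family", "treatment"], observed=True).size()
    fams = df["family"].unique()
    for fam in fams:
        for trt in ("WW", "WS"):
            n = int(counts.get((fam, trt), 0))
            if n < 2:
                raise ValueError(
                    f"cell family={fam}, treatment={trt} has {n} observation(s); need >= 2"
                )

    y = df["value"].to_numpy(float)
    trt = df["treatment"].to_numpy()
    fam = df["family"].to_numpy()
    blk = df["block"].to_numpy().astype(str)

    d_t, _ = _dummies(trt)
    d_f, _ = _dummies(fam)
    d_b, _ = _dummies(blk)
    d_tf = np.column_stack(
        [d_t[:, i] * d_f[:, j] for i in range(d_t.shape[1]) for j in range(d_f.shape[1])]
    ) if d_t.shape[1] and d_f.shape[1] else np.empty((y.size, 0))

    one = np.ones((y.size, 1))
    X_t = np.hstack([one, d_t])
    X_tf_ = np.hstack([X_t, d_f])
    X_int = np.hstack([X_tf_, d_tf])
    X_full = np.hstack([X_int, d_b])

    rss0 = float(((y - y.mean()) ** 2).sum())
    rss1, rss2, rss3, rss4 = (_rss(X, y) for X in (X_t, X_tf_, X_int, X_full))
    ss = np.array([rss0 - rss1, rss1 - rss2, rss2 - rss3, rss3 - rss4, rss4])
    dfs = np.array(
        [
            d_t.shape[1],
            d_f.shape[1],
            d_tf.shape[1],
            d_b.shape[1],
            y.size - X_full.shape[1],
        ]
    )
    if dfs[-1] <= 0:
        raise ValueError("no residual degrees of freedom")
    ms = np.divide(ss, dfs, out=np.full(5, np.nan), where=dfs > 0)
    f_vals = np.append(ms[:4] / ms[4], np.nan)
    p_vals = np.array(
        [stats.f.sf(f_vals[i], dfs[i], dfs[4]) if dfs[i] > 0 else np.nan for i in range(4)]
        + [np.nan]
    )
    out = pd.DataFrame(
        {"df": dfs, "sum_sq": ss, "mean_sq": ms, "F": f_vals, "p": p_vals},
        index=["Treatment", "Family", "Treatment x Family", "Block", "Residuals"],
    )
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]

    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    groups = np.char.add(np.char.add(fam.astype(str), ":"), trt.astype(str))
    try:
        report = check_assumptions(resid, groups)
    except ValueError as exc:  # degenerate residuals (tiny toy tables)
        logger.warning("assumption checks unavailable: %s", exc)
        report = None
    return AnovaResult(trait=trait, phase=phase, table=out, assumptions=report)


def levene_median(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brown-Forsythe variant of Levene's test: one-way ANOVA on absolute
    deviations from group medians."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    z = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    if all(np.all(zi == 0) for zi in z):
        raise ValueError("zero deviations in every group: Levene statistic undefined")
    n = np.array([zi.size for zi in z], dtype=float)
    means = np.array([zi.mean() for zi in z])
    grand = np.concatenate(z).mean()
    n_tot = n.sum()
    k = len(z)
    ss_between = float((n * (means - grand) ** 2).sum())
    ss_within = float(sum(((zi - m) ** 2).sum() for zi, m in zip(z, means)))
    if ss_within == 0:
        raise ValueError("zero within-group variance of deviations")
    stat = (ss_between / (k - 1)) / (ss_within / (n_tot - k))
    p = float(stats.f.sf(stat, k - 1, n_tot - k))
    return float(stat), p


def check_assumptions(residuals: np.ndarray, groups: np.ndarray) -> AssumptionReport:
    """Shapiro-Wilk normality on the residuals and a median-centered Levene
    test for homoscedasticity across the given groups."""
    residuals = np.asarray(residuals, float)
    if residuals.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.ptp(residuals) == 0:
        raise ValueError("constant residual vector: tests undefined")
    labels = np.asarray(groups)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two groups")
    w, p_w = stats.shapiro(residuals)
    grouped = [residuals[labels == lv] for lv in np.unique(labels)]
    stat, p_l = levene_median(grouped)
    return AssumptionReport(float(w), float(p_w), stat, p_l)


def anova_by_trait(
    table: TraitTable, traits: list[str], phase: str
) -> dict[str, AnovaResult]:
    return {t: two_way_anova(table, t, phase) for t in traits}
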