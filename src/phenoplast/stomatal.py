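"""Family-specific log-linear model of stomatal conductance vs predawn water
potential.

The model regresses ``-ln(g_wv)`` on water potential with a common intercept
and slope plus per-family increments::

    -ln(y_fj) = a0 + a_f + (b0 + b_f) x_fj + e_fj

Outputs are the sequential (Type I) ANOVA table in the fixed term order
water potential, family, interaction; composite per-family coefficients
``alpha(f) = a0 + a_f`` and ``beta(f) = b0 + b_f`` with t-based 95%
confidence intervals; and compact letters grouping families whose intervals
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitTable


class SingularFitError(ValueError):
    """A family lacks the data needed to identify its coefficients."""


def _family_sort_key(code: str):
    return (0, int(code)) if code.isdigit() else (1, code)


@dataclass
class LogLinearFit:
    families: list[str]
    reference: str
    params: np.ndarray  # [a0, b0, a_f increments..., b_f increments...]
    cov: np.ndarray
    df_resid: int
    sigma2: float
    rss: float
    n_obs: int
    coef_table: pd.DataFrame  # per-family composite alpha/beta with CIs
    # retained model inputs for the sequential ANOVA
    y: np.ndarray
    psi: np.ndarray
    family: np.ndarray

    def predict_gwv(self, family: str, psi: float) -> float:
        """Invert the model: expected conductance for one family at ``psi``."""
        row = self.coef_table.loc[self.coef_table["family"] == family]
        if row.empty:
            raise KeyError(f"unknown family {family}")
        a, b = float(row["alpha"].iloc[0]), float(row["beta"].iloc[0])
        return float(np.exp(-(a + b * psi)))


def _design(psi: np.ndarray, family: np.ndarray, families: list[str]) -> np.ndarray:
    # columns: 1, psi, family dummies (non-reference), psi x dummies
    k = len(families)
    n = psi.size
    X = np.empty((n, 2 * k))
    X[:, 0] = 1.0
    X[:, 1] = psi
    for j, fam in enumerate(families[1:]):
        d = (family == fam).astype(float)
        X[:, 2 + j] = d
        X[:, 2 + (k - 1) + j] = d * psi
    return X


def fit_gwv_psi(gwv: np.ndarray, psi: np.ndarray, family: np.ndarray) -> LogLinearFit:
    """Ordinary least squares of ``-ln(g_wv)`` on water potential with
    family-specific intercepts and slopes (array-level entry point)."""
    gwv = np.asarray(gwv, float)
    psi = np.asarray(psi, float)
    family = np.asarray(family).astype(str)
    if np.any(gwv <= 0):
        raise ValueError("g_wv must be strictly positive before the log transform")
    families = sorted(np.unique(family), key=_family_sort_key)
    if len(families) < 1:
        raise ValueError("no families in input")
    for fam in families:
        sel = family == fam
        if sel.sum() < 2:
            raise SingularFitError(f"family {fam} has fewer than 2 observations")
        if np.ptp(psi[sel]) == 0:
            raise SingularFitError(f"family {fam} has degenerate water-potential spread")

    y = -np.log(gwv)
    X = _design(psi, family, families)
    k = len(families)
    n = y.size
    df_resid = n - 2 * k
    if df_resid <= 0:
        raise SingularFitError("not enough observations for the interaction model")
    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError("design matrix is rank deficient")
    resid = y - X @ params
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)

    tcrit = stats.t.ppf(0.975, df_resid)
    rows = []
    for j, fam in enumerate(families):
        if j == 0:
            ia, ib = 0, 1
            a = params[0]
            b = params[1]
            var_a = cov[0, 0]
            var_b = cov[1, 1]
        else:
            ia = 2 + (j - 1)
            ib = 2 + (k - 1) + (j - 1)
            a = params[0] + params[ia]
            b = params[1] + params[ib]
            var_a = cov[0, 0] + cov[ia, ia] + 2 * cov[0, ia]
            var_b = cov[1, 1] + cov[ib, ib] + 2 * cov[1, ib]
        se_a, se_b = np.sqrt(var_a), np.sqrt(var_b)
        rows.append(
            {
                "family": fam,
                "alpha": a,
                "alpha_se": se_a,
                "alpha_lo": a - tcrit * se_a,
                "alpha_hi": a + tcrit * se_a,
                "beta": b,
                "beta_se": se_b,
                "beta_lo": b - tcrit * se_b,
                "beta_hi": b + tcrit * se_b,
            }
        )
    coef_table = pd.DataFrame(rows)
    return LogLinearFit(
        families=families,
        reference=families[0],
        params=params,
        cov=cov,
        df_resid=df_resid,
        sigma2=sigma2,
        rss=rss,
        n_obs=n,
        coef_table=coef_table,
        y=y,
        psi=psi,
        family=family,
    )


def fit_loglinear(table: TraitTable) -> LogLinearFit:
    """Fit on every stress-phase seedling with a paired conductance and
    water-potential observation."""
    df = table.subset(phase="stress")
    wide = df.pivot_table(
        index=["seedling_id", "family"], columns="trait", values="value", aggfunc="first"
    )
    for col in ("g_wv", "Psi_pd"):
        if col not in wide.columns:
            raise ValueError(f"stress phase lacks {col} observations")
    wide = wide.dropna(subset=["g_wv", "Psi_pd"])
    fam = wide.index.get_level_values("family").to_numpy()
    return fit_gwv_psi(wide["g_wv"].to_numpy(), wide["Psi_pd"].to_numpy(), fam)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def sequential_anova(fit: LogLinearFit) -> pd.DataFrame:
    """Type I sums of squares in the order water potential, family,
    interaction; F-tests against the residual mean square."""
    y, psi, family = fit.y, fit.psi, fit.family
    families = fit.families
    k = len(families)
    n = y.size
    X_full = _design(psi, family, families)
    X0 = X_full[:, :1]
    X1 = X_full[:, :2]
    X2 = np.concatenate([X_full[:, :2], X_full[:, 2 : 2 + (k - 1)]], axis=1)
    rss0, rss1, rss2, rss3 = _rss(X0, y), _rss(X1, y), _rss(X2, y), fit.rss
    ss = np.array([rss0 - rss1, rss1 - rss2, rss2 - rss3, rss3])
    df = np.array([1, k - 1, k - 1, fit.df_resid])
    ms = ss / df
    with np.errstate(invalid="ignore"):
        f_vals = np.array([ms[0] / ms[3], ms[1] / ms[3], ms[2] / ms[3], np.nan])
    p_vals = np.array(
        [stats.f.sf(f_vals[i], df[i], df[3]) for i in range(3)] + [np.nan]
    )
    return pd.DataFrame(
        {"df": df, "sum_sq": ss, "mean_sq": ms, "F": f_vals, "p": p_vals},
        index=["Psi_pd", "Family", "Psi_pd x Family", "Residuals"],
    )


def letter_groups(
    estimates: dict[str, float], cis: dict[str, tuple[float, float]]
) -> dict[str, str]:
    """Compact letter display from confidence-interval overlap.

    Families are ordered by point estimate; each maximal set of mutually
    overlapping intervals receives the next letter, so two families share a
    letter exactly when their intervals overlap (closed intervals pairwise
    intersect iff they share a common point).
    """
    if set(estimates) != set(cis):
        raise ValueError("estimates and CIs must cover the same families")
    for fam, (lo, hi) in cis.items():
        if lo > hi:
            raise ValueError(f"malformed interval for family {fam}: low > high")
    fams = sorted(estimates, key=lambda f: estimates[f])
    lows = np.array([cis[f][0] for f in fams])
    highs = np.array([cis[f][1] for f in fams])
    # candidate cliques: intervals covering each left endpoint
    cliques: list[tuple[int, ...]] = []
    for p in sorted(lows):
        members = tuple(np.flatnonzero((lows <= p) & (highs >= p)))
        if members and not any(set(members) <= set(c) for c in cliques):
            cliques = [c for c in cliques if not set(c) < set(members)]
            cliques.append(members)
    cliques.sort(key=lambda c: min(estimates[fams[i]] for i in c))
    letters = {f: "" for f in fams}
    for rank, clique in enumerate(cliques):
        letter = _letter(rank)
        for i in clique:
            letters[fams[i]] += letter
    return letters


def _letter(rank: int) -> str:
    out = ""
    rank += 1
    while rank:
        rank, rem = divmod(rank - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def coefficient_report(fit: LogLinearFit) -> pd.DataFrame:
    """Coefficient table with letter groups for alpha and beta appended."""
    tab = fit.coef_table.copy()
    est_a = dict(zip(tab["family"], tab["alpha"]))
    ci_a = {r["family"]: (r["alpha_lo"], r["alpha_hi"]) for _, r in tab.iterrows()}
    est_b = dict(zip(tab["family"], tab["beta"]))
    ci_b = {r["family"]: (r["beta_lo"], r["beta_hi"]) for _, r in tab.iterrows()}
    tab["alpha_letters"] = tab["family"].map(letter_groups(est_a, ci_a))
    tab["beta_letters"] = tab["family"].map(letter_groups(est_b, ci_b))
    return tab
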