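"""Relative-distance indices of phenotypic plasticity (PP) and post-drought
recovery (RE), and the permutation test for among-family differences.

For one family and trait, with values ``x`` observed under one watering
treatment and ``x'`` under the other, the index is the mean over all
cross-treatment observation pairs of ``|x' - x| / (x' + x)``.  It is 0 when
the two treatments are indistinguishable (no plasticity / complete recovery)
and 1 at maximal divergence.  Traits measured on an all-negative scale
(e.g. water potentials, carbon isotope ratios) are negated before pairing so
that the bound [0, 1] holds; mixed-sign traits are rejected.

PP is the index on end-of-stress measurements, RE the same formula on
post-recovery measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import TraitTable

logger = logging.getLogger(__name__)

KINDS = ("PP", "RE")
_KIND_PHASE = {"PP": "stress", "RE": "recovery"}


class MixedSignError(ValueError):
    """Values of both signs: the relative-distance index is undefined."""


@dataclass
class PairwiseDistanceSet:
    """All cross-treatment pairs behind one index value."""

    x_ww: np.ndarray
    x_ws: np.ndarray
    r: np.ndarray  # relative distance of each retained pair, in [0, 1]
    n_pairs: int
    n_dropped: int  # zero-denominator pairs
    family: str | None = None
    trait: str | None = None
    phase: str | None = None


@dataclass
class IndexResult:
    family: str
    trait: str
    kind: str  # PP | RE
    value: float
    n_pairs: int
    se: float | None = None  # bootstrap standard error over pairs


@dataclass
class IndexMatrix:
    """Families x (kind-trait) index values, columns labelled ``PP-<trait>``
    / ``RE-<trait>``."""

    matrix: pd.DataFrame
    results: list[IndexResult]


def _normalize_signs(ww: np.ndarray, ws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.concatenate([ww, ws])
    has_pos = bool((pooled > 0).any())
    has_neg = bool((pooled < 0).any())
    if has_pos and has_neg:
        raise MixedSignError("mixed-sign values: relative-distance index undefined")
    if has_neg:
        return -ww, -ws
    return ww, ws


def pair_relative_distances(ww: np.ndarray, ws: np.ndarray) -> np.ndarray:
    """Dense (n_WS x n_WW) matrix of |x_ws - x_ww| / (x_ws + x_ww) after sign
    normalization; zero-denominator pairs are NaN."""
    ww, ws = _normalize_signs(np.asarray(ww, float), np.asarray(ws, float))
    num = np.abs(ws[:, None] - ww[None, :])
    den = ws[:, None] + ww[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r


def relative_distance_index(
    values_ww, values_ws
) -> tuple[float, PairwiseDistanceSet]:
    """Mean relative distance over all cross-treatment pairs.

    Raises :class:`MixedSignError` on mixed-sign input and ``ValueError``
    when no value is available for a treatment or every pair has a zero
    denominator.
    """
    ww = np.asarray(values_ww, dtype=float)
    ws = np.asarray(values_ws, dtype=float)
    if ww.size == 0 or ws.size == 0:
        raise ValueError("need at least one value per treatment")
    r = pair_relative_distances(ww, ws)
    flat = r.ravel()
    kept = flat[~np.isnan(flat)]
    n_dropped = int(np.isnan(flat).sum())
    if kept.size == 0:
        raise ValueError("all pairs dropped (zero denominators): index undefined")
    value = float(kept.mean())
    return value, PairwiseDistanceSet(
        x_ww=ww, x_ws=ws, r=kept, n_pairs=int(kept.size), n_dropped=n_dropped
    )


def _bootstrap_se(r: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    idx = rng.integers(0, r.size, size=(n_boot, r.size))
    return float(r[idx].mean(axis=1).std(ddof=1))


def indices_per_family(
    table: TraitTable,
    kind: str,
    n_boot_se: int = 0,
    seed: int | None = None,
) -> IndexMatrix:
    """One index per (family, trait) with both treatments present.

    Pairs are pooled across blocks within each family.  A family missing one
    treatment entirely yields a missing cell with a logged warning.  When
    ``n_boot_se > 0`` a bootstrap-over-pairs standard error is attached.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    phase = _KIND_PHASE[kind]
    df = table.subset(phase=phase)
    if df.empty:
        raise ValueError(f"no {phase}-phase observations in table")
    rng = np.random.default_rng(seed)
    results: list[IndexResult] = []
    families = sorted(df["family"].unique(), key=_family_key)
    traits = sorted(df["trait"].unique())
    cells: dict[str, dict[str, float]] = {f: {} for f in families}
    for trait in traits:
        tdf = df[df["trait"] == trait]
        for fam in families:
            fdf = tdf[tdf["family"] == fam]
            ww = fdf.loc[fdf["treatment"] == "WW", "value"].to_numpy()
            ws = fdf.loc[fdf["treatment"] == "WS", "value"].to_numpy()
            if ww.size == 0 or ws.size == 0:
                logger.warning(
                    "family %s missing a treatment for trait %s; cell left missing", fam, trait
                )
                cells[fam][f"{kind}-{trait}"] = np.nan
                continue
            value, pairs = relative_distance_index(ww, ws)
            se = _bootstrap_se(pairs.r, n_boot_se, rng) if n_boot_se else None
            results.append(IndexResult(fam, trait, kind, value, pairs.n_pairs, se))
            cells[fam][f"{kind}-{trait}"] = value
    matrix = pd.DataFrame.from_dict(cells, orient="index")
    matrix.index.name = "family"
    return IndexMatrix(matrix, results)


def build_index_matrix(
    table: TraitTable, kinds=("PP", "RE"), n_boot_se: int = 0, seed: int | None = None
) -> IndexMatrix:
    """Concatenate PP and RE matrices column-wise (the clustering input)."""
    parts = [indices_per_family(table, k, n_boot_se=n_boot_se, seed=seed) for k in kinds]
    matrix = pd.concat([p.matrix for p in parts], axis=1)
    results = [r for p in parts for r in p.results]
    return IndexMatrix(matrix, results)


def _family_key(code: str):
    return (0, int(code)) if code.isdigit() else (1, code)


# ---------------------------------------------------------------------------
# among-family permutation test


def _group_f_stat(
    r: np.ndarray,
    valid: np.ndarray,
    m_ws: np.ndarray,
    m_ww: np.ndarray,
) -> float:
    """One-way F on pair distances grouped by family.

    ``m_ws``/``m_ww`` are (k x n) family-indicator matrices; group sums are
    bilinear forms so the statistic is a handful of einsums.
    """
    n_g = np.einsum("fi,ij,fj->f", m_ws, valid, m_ww)
    s_g = np.einsum("fi,ij,fj->f", m_ws, r, m_ww)
    q_g = np.einsum("fi,ij,fj->f", m_ws, r * r, m_ww)
    n_tot = n_g.sum()
    k = n_g.size
    grand = s_g.sum() / n_tot
    between = float((s_g**2 / n_g).sum() - n_tot * grand**2)
    within = float(q_g.sum() - (s_g**2 / n_g).sum())
    if within <= 0:
        return np.inf if between > 0 else 0.0
    return (between / (k - 1)) / (within / (n_tot - k))


def family_permutation_test(
    values_ww: np.ndarray,
    fam_ww: np.ndarray,
    values_ws: np.ndarray,
    fam_ws: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for among-family differences in the index.

    Observed statistic: between-family over within-family mean square of the
    per-pair relative distances.  The null distribution permutes seedling
    family labels within each treatment and recomputes all pairs; the p-value
    is ``(1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    fam_ww = np.asarray(fam_ww)
    fam_ws = np.asarray(fam_ws)
    values_ww = np.asarray(values_ww, float)
    values_ws = np.asarray(values_ws, float)
    fams = np.unique(np.concatenate([fam_ww, fam_ws]))
    if fams.size < 2:
        raise ValueError("need at least two families")
    for f in fams:
        n_pairs = int((fam_ww == f).sum()) * int((fam_ws == f).sum())
        if n_pairs < 2:
            raise ValueError(f"family {f} has fewer than 2 cross-treatment pairs")

    r = pair_relative_distances(values_ww, values_ws)
    valid = (~np.isnan(r)).astype(float)
    r = np.nan_to_num(r, nan=0.0)

    def masks(lw: np.ndarray, ls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (ls[None, :] == fams[:, None]).astype(float), (
            lw[None, :] == fams[:, None]
        ).astype(float)

    m_ws, m_ww = masks(fam_ww, fam_ws)
    observed = _group_f_stat(r, valid, m_ws, m_ww)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        pw = rng.permutation(fam_ww)
        ps = rng.permutation(fam_ws)
        m_ws, m_ww = masks(pw, ps)
        if _group_f_stat(r, valid, m_ws, m_ww) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return observed, p


def family_difference_test(
    table: TraitTable,
    trait: str,
    kind: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Table-level wrapper of :func:`family_permutation_test` for one trait."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    df = table.subset(phase=_KIND_PHASE[kind], trait=trait)
    if df.empty:
        raise ValueError(f"no observations for trait {trait} at the {kind} phase")
    ww = df[df["treatment"] == "WW"]
    ws = df[df["treatment"] == "WS"]
    return family_permutation_test(
        ww["value"].to_numpy(),
        ww["family"].to_numpy(),
        ws["value"].to_numpy(),
        ws["family"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
    )
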