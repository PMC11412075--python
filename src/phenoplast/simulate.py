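"""Synthetic split-plot drought experiment generator.

Emulates a greenhouse trial in which open-pollinated families are grown under
two watering regimes (well-watered ``WW`` vs water-stressed ``WS``) in two
blocks, measured once at the end of the stress period for every trait in the
vocabulary and once more after rewatering for the gas-exchange traits.

The generative model mirrors the analysis assumptions:

* stomatal conductance follows a family-specific log-linear dose-response to
  predawn water potential: ``g_wv = exp(-(alpha_f + beta_f * psi + eps))``
  with ``eps ~ Normal(0, sigma)``;
* every other stress-phase trait is family mean + treatment effect (with
  family x treatment interaction) + additive block effect + Gaussian noise;
* recovery-phase WS values regress toward the family WW mean by a
  family-specific recovery fraction ``rho`` (1 = full recovery).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .traits import (
    GAS_EXCHANGE_TRAITS,
    POSITIVE,
    TRAITS,
    TraitTable,
    derive_traits,
)

#: family codes used when a 16-family design is requested (opaque labels,
#: deliberately non-consecutive)
DEFAULT_FAMILY_CODES = (
    "1", "2", "4", "5", "7", "9", "10", "11",
    "12", "13", "15", "16", "17", "19", "21", "22",
)

#: default family-specific dose-response coefficient ranges
ALPHA_RANGE = (0.63, 1.41)
BETA_RANGE = (-1.50, -0.77)

# per-trait generator defaults: (baseline mean, family spread, mean treatment
# effect, interaction spread, residual sd, block effect)
_BASE = {
    "A_area":   (11.0, 2.0, -6.0, 1.5, 1.0, 0.3),
    "Phi_PSII": (0.72, 0.04, -0.25, 0.06, 0.03, 0.01),
    "SLA":      (20.0, 3.0, -1.5, 1.0, 1.5, 0.4),
    "N_m":      (2.2, 0.3, 0.1, 0.1, 0.15, 0.05),
    "C_m":      (47.0, 1.0, 0.5, 0.3, 0.8, 0.2),
    "d13C":     (-28.0, 0.8, 1.2, 0.4, 0.5, 0.1),
    "d15N":     (0.8, 0.5, -0.1, 0.2, 0.3, 0.05),
    "RGR_T1":   (4.5e-3, 1.0e-3, -2.0e-3, 5e-4, 8e-4, 1e-4),
    "RGR_T2":   (3.5e-3, 1.0e-3, -2.2e-3, 6e-4, 8e-4, 1e-4),
}

#: traits re-measured after rewatering, with default recovery-fraction ranges
_RECOVERY_RHO = {
    "A_area": (0.6, 1.0),
    "A_mass": (0.6, 1.0),
    "g_wv": (0.2, 0.6),  # stomatal conductance recovers poorly
    "Phi_PSII": (0.7, 1.0),
}
_RECOVERY_SIGMA = {"A_area": 1.0, "A_mass": 25.0, "g_wv": 0.02, "Phi_PSII": 0.03}

_POSITIVE_FLOOR = 1e-6

# sign-class-"any" traits are truncated at a small positive floor so the
# relative-distance index (undefined on mixed-sign samples) stays computable
_GENERATOR_FLOOR = {"d15N": 0.01, "N_m": 0.1, "C_m": 1.0, "RGR_T1": 1e-5, "RGR_T2": 1e-5}


def family_codes(n_families: int) -> tuple[str, ...]:
    """Opaque family labels; the first 16 follow the default code list."""
    codes = list(DEFAULT_FAMILY_CODES[:n_families])
    nxt = 23
    while len(codes) < n_families:
        codes.append(str(nxt))
        nxt += 1
    return tuple(codes)


@dataclass(frozen=True)
class ExperimentDesign:
    """Split-plot layout: replicates x families x {WW, WS} x blocks."""

    n_families: int = 16
    replicates: int = 5
    blocks: int = 2
    stress_cycles: int = 11
    cycle_days: int = 7  # 6 days deprivation + 1 day rehydration

    def __post_init__(self):
        if self.n_families < 1 or self.replicates < 1 or self.blocks < 1:
            raise ValueError("design counts must be >= 1")

    @property
    def total_seedlings(self) -> int:
        return self.replicates * self.n_families * 2 * self.blocks

    @property
    def interval_days(self) -> dict[str, float]:
        """Days spanned by the growth intervals T1 (cycles 1-5), T2 (5-11), Tot."""
        t1 = 4 * self.cycle_days
        t2 = 6 * self.cycle_days
        return {"T1": t1, "T2": t2, "Tot": t1 + t2}


@dataclass
class FamilyProfile:
    """Generative parameters for one family."""

    family: str
    alpha: float
    beta: float
    gwv_sigma: float
    psi_ww: tuple[float, float]  # (mean, sd) of WW predawn water potential
    psi_ws: tuple[float, float]  # (low, high) uniform range under WS
    mu: dict[str, float] = field(default_factory=dict)
    tau: dict[str, float] = field(default_factory=dict)  # WS effect per trait
    sigma: dict[str, float] = field(default_factory=dict)
    block_effect: dict[str, float] = field(default_factory=dict)
    rho: dict[str, float] = field(default_factory=dict)  # recovery fraction
    rec_sigma: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for trait, r in self.rho.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"recovery fraction for {trait} outside [0, 1]: {r}")


def default_profiles(design: ExperimentDesign, seed: int) -> list[FamilyProfile]:
    """Reproducible profiles with genuine among-family variation.

    Family means, interactions, dose-response coefficients and recovery
    fractions are all spread across families, so that true plasticity and
    recovery differ among them.
    """
    if design.n_families < 2:
        if design.n_families < 1:
            raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    profiles = []
    block_effect = {t: p[5] for t, p in _BASE.items()}
    for fam in family_codes(design.n_families):
        mu, tau, sigma = {}, {}, {}
        for trait, (base, spread, t_eff, t_spread, sd, _b) in _BASE.items():
            mu[trait] = base + rng.uniform(-spread, spread)
            tau[trait] = t_eff + rng.uniform(-t_spread, t_spread)
            sigma[trait] = sd
        rho = {t: rng.uniform(lo, hi) for t, (lo, hi) in _RECOVERY_RHO.items()}
        profiles.append(
            FamilyProfile(
                family=fam,
                alpha=rng.uniform(*ALPHA_RANGE),
                beta=rng.uniform(*BETA_RANGE),
                gwv_sigma=0.45,
                psi_ww=(-0.4, 0.1),
                psi_ws=(-3.3, -0.8),
                mu=mu,
                tau=tau,
                sigma=sigma,
                block_effect=block_effect,
                rho=rho,
                rec_sigma=dict(_RECOVERY_SIGMA),
            )
        )
    return profiles


def null_profiles(design: ExperimentDesign) -> list[FamilyProfile]:
    """Deterministic no-effect profiles: zero noise, no treatment or block
    effects, full recovery and a degenerate water-potential distribution
    shared by both treatments.  Downstream plasticity and recovery indices
    are exactly zero on the resulting tables."""
    profiles = []
    for fam in family_codes(design.n_families):
        profiles.append(
            FamilyProfile(
                family=fam,
                alpha=1.0,
                beta=-1.0,
                gwv_sigma=0.0,
                psi_ww=(-0.4, 0.0),
                psi_ws=(-0.4, -0.4),
                mu={t: p[0] for t, p in _BASE.items()},
                tau={t: 0.0 for t in _BASE},
                sigma={t: 0.0 for t in _BASE},
                block_effect={t: 0.0 for t in _BASE},
                rho={t: 1.0 for t in _RECOVERY_RHO},
                rec_sigma={t: 0.0 for t in _RECOVERY_RHO},
            )
        )
    return profiles


def _clip_sign(trait: str, values: np.ndarray) -> np.ndarray:
    sign = TRAITS[trait].sign
    if sign == POSITIVE:
        return np.maximum(values, _POSITIVE_FLOOR)
    if sign == "non_positive":
        return np.minimum(values, 0.0)
    return values


def simulate(
    design: ExperimentDesign,
    profiles: list[FamilyProfile] | None = None,
    seed: int = 0,
) -> TraitTable:
    """Draw one full experiment as a validated :class:`TraitTable`.

    Identical ``(design, profiles, seed)`` give bit-identical tables.
    """
    if profiles is None:
        profiles = default_profiles(design, seed)
    by_family = {p.family: p for p in profiles}
    codes = family_codes(design.n_families)
    missing = [f for f in codes if f not in by_family]
    if missing:
        raise ValueError(f"profiles missing for families: {missing}")
    for p in profiles:
        p.validate()

    rng = np.random.default_rng(seed)
    days = design.interval_days
    rows: list[tuple] = []

    def add(sid, fam, block, trt, phase, trait, value):
        rows.append((sid, fam, block, trt, phase, trait, float(value)))

    stress_store: dict[tuple[str, str], float] = {}  # (seedling_id, trait)
    seedling_meta: list[tuple[str, str, int, str]] = []

    for fam in codes:
        prof = by_family[fam]
        for trt in ("WW", "WS"):
            for block in range(1, design.blocks + 1):
                for rep in range(1, design.replicates + 1):
                    sid = f"F{fam}-{trt}-B{block}-R{rep}"
                    seedling_meta.append((sid, fam, block, trt))
                    # predawn water potential
                    if trt == "WW":
                        mean, sd = prof.psi_ww
                        psi = mean + sd * rng.standard_normal()
                        psi = min(psi, -0.05)
                    else:
                        lo, hi = prof.psi_ws
                        psi = rng.uniform(lo, hi) if hi > lo else lo
                    add(sid, fam, block, trt, "stress", "Psi_pd", psi)
                    # stomatal conductance from the log-linear dose-response
                    eps = prof.gwv_sigma * rng.standard_normal()
                    gwv = float(np.exp(-(prof.alpha + prof.beta * psi + eps)))
                    gwv = max(gwv, _POSITIVE_FLOOR)
                    add(sid, fam, block, trt, "stress", "g_wv", gwv)
                    stress_store[(sid, "g_wv")] = gwv
                    # remaining measured traits: additive effects model
                    ws = 1.0 if trt == "WS" else 0.0
                    b2 = 1.0 if block == 2 else 0.0
                    vals = {}
                    for trait in _BASE:
                        v = (
                            prof.mu[trait]
                            + prof.tau[trait] * ws
                            + prof.block_effect[trait] * b2
                            + prof.sigma[trait] * rng.standard_normal()
                        )
                        v = float(_clip_sign(trait, np.asarray(v)))
                        if trait in _GENERATOR_FLOOR:
                            v = max(v, _GENERATOR_FLOOR[trait])
                        vals[trait] = v
                    # total-interval growth respects log additivity
                    t1, t2 = days["T1"], days["T2"]
                    vals["RGR_Tot"] = (vals["RGR_T1"] * t1 + vals["RGR_T2"] * t2) / (t1 + t2)
                    for trait, v in vals.items():
                        add(sid, fam, block, trt, "stress", trait, v)
                        stress_store[(sid, trait)] = v

    stress = TraitTable.from_dataframe(
        pd.DataFrame(rows, columns=["seedling_id", "family", "block", "treatment", "phase", "trait", "value"])
    )
    stress = derive_traits(stress)  # adds A_mass, iWUE, PNUE at the stress phase
    for _, r in stress.data[stress.data["trait"] == "A_mass"].iterrows():
        stress_store[(r["seedling_id"], "A_mass")] = r["value"]

    # family-level WW anchors for the recovery phase
    sdf = stress.data
    ww_mean = (
        sdf[(sdf["treatment"] == "WW") & (sdf["trait"].isin(_RECOVERY_RHO))]
        .groupby(["family", "trait"], observed=True)["value"]
        .mean()
    )

    rec_rows: list[tuple] = []
    for sid, fam, block, trt in seedling_meta:
        prof = by_family[fam]
        for trait in ("A_area", "A_mass", "g_wv", "Phi_PSII"):
            anchor = float(ww_mean.loc[(fam, trait)])
            noise = prof.rec_sigma[trait] * rng.standard_normal()
            if trt == "WW":
                v = anchor + noise
            else:
                v = anchor + (1.0 - prof.rho[trait]) * (stress_store[(sid, trait)] - anchor) + noise
            v = float(_clip_sign(trait, np.asarray(v)))
            rec_rows.append((sid, fam, block, trt, "recovery", trait, v))

    combined = pd.concat(
        [stress.data, pd.DataFrame(rec_rows, columns=list(stress.data.columns))],
        ignore_index=True,
    )
    table = TraitTable.from_dataframe(combined)
    return derive_traits(table)  # adds recovery-phase iWUE; idempotent elsewhere


def profiles_to_yaml(profiles: list[FamilyProfile], path) -> None:
    payload = [asdict(p) for p in profiles]
    for p in payload:
        p["psi_ww"] = list(p["psi_ww"])
        p["psi_ws"] = list(p["psi_ws"])
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def profiles_from_yaml(path) -> list[FamilyProfile]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    profiles = []
    for p in payload:
        p["psi_ww"] = tuple(p["psi_ww"])
        p["psi_ws"] = tuple(p["psi_ws"])
        profiles.append(FamilyProfile(**p))
    return profiles
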