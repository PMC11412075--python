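"""Trait vocabulary, tidy observation tables and derived-trait arithmetic.

All pipeline stages exchange a single currency: a long-format table with one
row per (seedling, phase, trait) observation.  This module owns the schema,
its validation rules, CSV round-tripping and the purely arithmetic derived
traits (mass-based photosynthesis, intrinsic water-use efficiency,
nitrogen-use efficiency and basal-area relative growth rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA = ("seedling_id", "family", "block", "treatment", "phase", "trait", "value")
TREATMENTS = ("WW", "WS")
PHASES = ("stress", "recovery")

#: sign classes
POSITIVE = "positive"
NON_POSITIVE = "non_positive"
ANY = "any"


@dataclass(frozen=True)
class Trait:
    """One entry of the trait vocabulary."""

    name: str
    units: str
    sign: str  # POSITIVE | NON_POSITIVE | ANY


TRAITS: dict[str, Trait] = {
    t.name: t
    for t in (
        Trait("A_area", "umol m-2 s-1", POSITIVE),
        Trait("A_mass", "nmol g-1 s-1", POSITIVE),
        Trait("g_wv", "mol m-2 s-1", POSITIVE),
        Trait("iWUE", "umol mol-1", POSITIVE),
        Trait("PNUE", "umol gN-1 s-1", POSITIVE),
        Trait("Phi_PSII", "dimensionless", POSITIVE),
        Trait("SLA", "m2 kg-1", POSITIVE),
        Trait("N_m", "%", ANY),
        Trait("C_m", "%", ANY),
        Trait("d13C", "permil", NON_POSITIVE),
        Trait("d15N", "permil", ANY),
        Trait("Psi_pd", "MPa", NON_POSITIVE),
        Trait("RGR_T1", "day-1", ANY),
        Trait("RGR_T2", "day-1", ANY),
        Trait("RGR_Tot", "day-1", ANY),
    )
}

#: traits re-measured after the rewatering (recovery) period
GAS_EXCHANGE_TRAITS = ("A_area", "A_mass", "g_wv", "iWUE", "Phi_PSII")

#: derived trait -> parent traits required on the same seedling and phase
DERIVED_PARENTS = {
    "A_mass": ("A_area", "SLA"),
    "iWUE": ("A_area", "g_wv"),
    "PNUE": ("A_mass", "N_m"),
}


class SchemaError(ValueError):
    """The file or frame does not match the documented schema."""


class ValidationError(ValueError):
    """An observation violates a table invariant."""


@dataclass
class DesignSummary:
    counts: pd.DataFrame  # index family, columns (treatment, block)
    balanced: bool
    replicates: int | None  # common count per cell when balanced


@dataclass
class TraitTable:
    """Validated collection of per-seedling observations.

    ``data`` is a long-format frame with the columns in :data:`SCHEMA`.
    ``n_dropped`` counts rows discarded during lenient validation.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, strict: bool = True) -> "TraitTable":
        """Validate ``frame`` against all table invariants.

        In strict mode the first violation raises :class:`ValidationError`
        naming the offending row; in lenient mode offending rows are dropped
        and the count is logged.
        """
        missing = [c for c in SCHEMA if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = frame.loc[:, list(SCHEMA)].copy()
        df["seedling_id"] = df["seedling_id"].astype(str)
        df["family"] = df["family"].astype(str)
        df["block"] = pd.to_numeric(df["block"], errors="coerce").astype("Int64")
        value = pd.to_numeric(df["value"], errors="coerce")

        reasons = pd.Series("", index=df.index, dtype=object)

        def flag(mask: pd.Series, reason: str) -> None:
            fresh = mask & (reasons == "")
            reasons[fresh] = reason

        flag(value.isna() & df["value"].notna(), "non-numeric value")
        flag(~np.isfinite(value.fillna(np.nan)), "non-finite value")
        flag(~df["treatment"].isin(TREATMENTS), "unknown treatment")
        flag(~df["phase"].isin(PHASES), "unknown phase")
        flag(~df["trait"].isin(TRAITS), "trait not in vocabulary")

        sign = df["trait"].map(lambda t: TRAITS[t].sign if t in TRAITS else ANY)
        flag((sign == POSITIVE) & ~(value > 0), "strictly-positive trait with value <= 0")
        flag((sign == NON_POSITIVE) & (value > 0), "non-positive trait with value > 0")
        flag(
            (df["phase"] == "recovery") & ~df["trait"].isin(GAS_EXCHANGE_TRAITS),
            "recovery phase restricted to gas-exchange traits",
        )
        flag(df.duplicated(["seedling_id", "phase", "trait"], keep="first"),
             "duplicate (seedling_id, phase, trait)")

        bad = reasons != ""
        if bad.any():
            if strict:
                idx = reasons[bad].index[0]
                raise ValidationError(f"row {idx}: {reasons[idx]}")
            logger.warning("dropping %d invalid rows during lenient validation", int(bad.sum()))
        df["value"] = value
        kept = df.loc[~bad].reset_index(drop=True)
        kept["block"] = kept["block"].astype(int)
        return cls(kept, n_dropped=int(bad.sum()))

    def design_summary(self) -> DesignSummary:
        """Replicate counts per family x treatment x block cell."""
        counts = (
            self.data.drop_duplicates("seedling_id")
            .groupby(["family", "treatment", "block"], observed=True)
            .size()
            .unstack(["treatment", "block"], fill_value=0)
        )
        values = counts.to_numpy().ravel()
        balanced = bool(len(values) > 0 and (values == values[0]).all())
        if not balanced:
            logger.warning("unbalanced design: replicate counts differ across cells")
        return DesignSummary(counts, balanced, int(values[0]) if balanced else None)

    def subset(self, phase: str | None = None, trait: str | None = None) -> pd.DataFrame:
        df = self.data
        if phase is not None:
            df = df[df["phase"] == phase]
        if trait is not None:
            df = df[df["trait"] == trait]
        return df


def read_trait_table(path: str | Path, strict: bool = True) -> TraitTable:
    """Read a trait table CSV and validate it.

    The header must match ``seedling_id,family,block,treatment,phase,trait,value``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path, dtype={"seedling_id": str, "family": str}, float_precision="round_trip"
    )
    return TraitTable.from_dataframe(frame, strict=strict)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write a table to CSV at full float precision (lossless round trip)."""
    table.data.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def _pivot_wide(df: pd.DataFrame) -> pd.DataFrame:
    keys = ["seedling_id", "family", "block", "treatment", "phase"]
    return df.pivot_table(index=keys, columns="trait", values="value", aggfunc="first")


def derive_traits(table: TraitTable) -> TraitTable:
    """Append derived gas-exchange traits where their parents are present.

    A_mass [nmol g-1 s-1] = A_area [umol m-2 s-1] x SLA [m2 kg-1];
    iWUE [umol mol-1] = A_area / g_wv;
    PNUE [umol gN-1 s-1] = A_mass / (10 x N_m) with N_m in percent.

    Idempotent: observations already present are never recomputed.  Seedlings
    with ``g_wv == 0`` are skipped for iWUE with a logged warning.
    """
    wide = _pivot_wide(table.data)
    new_rows: list[pd.DataFrame] = []

    def _available(col: str) -> pd.Series:
        if col in wide.columns:
            return wide[col]
        return pd.Series(np.nan, index=wide.index)

    # order matters: PNUE consumes A_mass computed in the same pass
    a_area, sla = _available("A_area"), _available("SLA")
    a_mass = _available("A_mass")
    fill = a_mass.isna() & a_area.notna() & sla.notna()
    a_mass = a_mass.where(~fill, a_area * sla)
    _append_derived(new_rows, wide, "A_mass", a_mass, fill)

    g_wv = _available("g_wv")
    zero_gwv = g_wv == 0
    if zero_gwv.any():
        logger.warning("skipping iWUE for %d seedling(s) with g_wv == 0", int(zero_gwv.sum()))
    iwue = _available("iWUE")
    fill = iwue.isna() & a_area.notna() & g_wv.notna() & ~zero_gwv
    iwue = iwue.where(~fill, a_area / g_wv.replace(0, np.nan))
    _append_derived(new_rows, wide, "iWUE", iwue, fill)

    n_m = _available("N_m")
    pnue = _available("PNUE")
    fill = pnue.isna() & a_mass.notna() & n_m.notna() & (n_m > 0)
    pnue = pnue.where(~fill, a_mass / (10.0 * n_m))
    _append_derived(new_rows, wide, "PNUE", pnue, fill)

    if not new_rows:
        return TraitTable(table.data.copy(), table.n_dropped)
    combined = pd.concat([table.data] + new_rows, ignore_index=True)
    return TraitTable.from_dataframe(combined)


def _append_derived(
    out: list[pd.DataFrame], wide: pd.DataFrame, trait: str, values: pd.Series, mask: pd.Series
) -> None:
    if not mask.any():
        return
    rows = values[mask].rename("value").reset_index()
    rows["trait"] = trait
    out.append(rows[list(SCHEMA)])


def compute_rgr(d_start, d_end, days):
    """Relative growth rate of stem basal area from collar diameters.

    RGR = (ln(area_end) - ln(area_start)) / days = 2 (ln d_end - ln d_start) / days;
    the pi/4 area factor cancels in the log difference.  Accepts scalars or
    arrays; diameters must be > 0 and ``days`` > 0.
    """
    d_start = np.asarray(d_start, dtype=float)
    d_end = np.asarray(d_end, dtype=float)
    days_arr = np.asarray(days, dtype=float)
    if np.any(d_start <= 0) or np.any(d_end <= 0):
        raise ValueError("diameters must be strictly positive")
    if np.any(days_arr <= 0):
        raise ValueError("days must be strictly positive")
    out = 2.0 * (np.log(d_end) - np.log(d_start)) / days_arr
    if out.ndim == 0:
        return float(out)
    return out
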