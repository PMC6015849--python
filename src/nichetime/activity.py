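"""Activity-period scoring, strictness calls and time-shifter identification.

Each species carries a usage class for day, twilight and night:
0 = period not used, 1 = primarily/frequently used, 2 = occasionally/rarely
used. Hawks and allies (Accipitriformes) and falcons (Falconiformes) are
ancestrally day-active; owls (Strigiformes) are ancestrally night-active.
A species is *strict* when it keeps exclusively to its order's typical
period (twilight counts as part of the night for owls, but not as part of
the day for the diurnal orders). Time-shifters are species active outside
the typical period; the call is defined only for Accipitriformes and
Strigiformes because falcons have a mixed ancestral state.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ORDERS",
    "ActivityProfile",
    "StrictnessCall",
    "ShifterCall",
    "classify_strictness",
    "is_time_shifter",
    "tabulate_order_summary",
    "classify_table",
    "read_species_table",
]

ORDERS = ("Accipitriformes", "Strigiformes", "Falconiformes")
SHIFTER_ORDERS = ("Accipitriformes", "Strigiformes")
_VALID_CLASSES = {0, 1, 2}


class UnknownOrderError(ValueError):
    pass


class UnsupportedOrderError(ValueError):
    """Shifter calls are undefined for orders with a mixed ancestral state."""


@dataclass(frozen=True)
class ActivityProfile:
    """Per-species activity usage classes plus order and metadata."""

    species_id: str
    order: str
    day: int = 0
    twilight: int = 0
    night: int = 0
    body_length_cm: float | None = None
    migratory: bool = False

    def __post_init__(self):
        if self.order not in ORDERS:
            raise UnknownOrderError(f"unknown order {self.order!r}")
        for period in ("day", "twilight", "night"):
            v = getattr(self, period)
            if v not in _VALID_CLASSES:
                raise ValueError(f"{period} class must be 0, 1 or 2; got {v!r}")
        if 1 not in (self.day, self.twilight, self.night):
            raise ValueError(f"{self.species_id}: at least one period must be "
                             "primary (class 1)")


@dataclass(frozen=True)
class StrictnessCall:
    category: str  # 'strict' | 'non_strict'

    @property
    def is_strict(self) -> bool:
        return self.category == "strict"


@dataclass(frozen=True)
class ShifterCall:
    is_shifter: bool
    size_group: str = "not_applicable"  # 'small' | 'large' | 'not_applicable'


def classify_strictness(profile: ActivityProfile) -> StrictnessCall:
    """Strictly diurnal (hawks/falcons) or strictly nocturnal-incl-twilight (owls).

    Diurnal orders: strict iff exclusively day-active (no twilight, no night
    use of any class). Owls: strict iff no day use and some night use —
    twilight activity does not break an owl's strictness, so exclusively
    crepuscular owls are non-strict.
    """
    if profile.order in ("Accipitriformes", "Falconiformes"):
        strict = profile.day > 0 and profile.twilight == 0 and profile.night == 0
    elif profile.order == "Strigiformes":
        strict = profile.day == 0 and profile.night > 0
    else:  # pragma: no cover - guarded by ActivityProfile
        raise UnknownOrderError(profile.order)
    return StrictnessCall("strict" if strict else "non_strict")


def is_time_shifter(profile: ActivityProfile,
                    size_threshold_cm: float = 30.0) -> ShifterCall:
    """Call a species a time-shifter (active outside its typical period).

    Hawks: any twilight or night use (class 1 or 2). Owls: any species that
    is not strictly nocturnal (day use of any class, or exclusively
    crepuscular). Falcons are rejected: their ancestral state is mixed, so
    the direction of a shift is undefined.
    """
    if profile.order == "Falconiformes":
        raise UnsupportedOrderError(
            "time-shifter calls are undefined for Falconiformes (mixed "
            "ancestral activity state; order excluded from shifter analyses)")
    if profile.order == "Accipitriformes":
        shifter = profile.twilight > 0 or profile.night > 0
        size_group = "not_applicable"
    elif profile.order == "Strigiformes":
        shifter = not classify_strictness(profile).is_strict
        if profile.body_length_cm is None:
            size_group = "not_applicable"
        else:
            size_group = ("small" if profile.body_length_cm < size_threshold_cm
                          else "large")
    else:  # pragma: no cover
        raise UnknownOrderError(profile.order)
    return ShifterCall(is_shifter=shifter, size_group=size_group)


def _profiles_to_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    rows = [{"species_id": p.species_id, "order": p.order, "day": p.day,
             "twilight": p.twilight, "night": p.night,
             "body_length_cm": p.body_length_cm, "migratory": p.migratory}
            for p in profiles]
    return pd.DataFrame(rows)


def _iter_profiles(table: pd.DataFrame):
    for rec in table.to_dict("records"):
        yield ActivityProfile(
            species_id=str(rec["species_id"]), order=rec["order"],
            day=int(rec["day"]), twilight=int(rec["twilight"]),
            night=int(rec["night"]),
            body_length_cm=(None if pd.isna(rec.get("body_length_cm"))
                            else float(rec["body_length_cm"])),
            migratory=bool(rec.get("migratory", False)))


def classify_table(table) -> pd.DataFrame:
    """Add strictness and shifter columns to a species table.

    Adds ``strict`` (bool), ``shifter`` (boolean; <NA> for Falconiformes)
    and ``size_group`` columns.
    """
    df = _profiles_to_frame(table).copy()
    strict, shifter, size_group = [], [], []
    for p in _iter_profiles(df):
        strict.append(classify_strictness(p).is_strict)
        if p.order == "Falconiformes":
            shifter.append(pd.NA)
            size_group.append("not_applicable")
        else:
            call = is_time_shifter(p)
            shifter.append(call.is_shifter)
            size_group.append(call.size_group)
    df["strict"] = strict
    df["shifter"] = pd.array(shifter, dtype="boolean")
    df["size_group"] = size_group
    return df


def tabulate_order_summary(profiles) -> pd.DataFrame:
    """Per-order counts of day-active, night-active, strict and shifter species.

    Day-/night-active means any use (class 1 or 2). Percentages are rounded
    to the nearest integer. Shifter counts are NA for Falconiformes.
    """
    df = classify_table(profiles)
    if df.empty:
        raise ValueError("empty species collection")
    rows = []
    for order, sub in df.groupby("order", sort=True):
        n = len(sub)
        day_active = int((sub["day"] > 0).sum())
        night_active = int((sub["night"] > 0).sum())
        n_strict = int(sub["strict"].sum())
        if order == "Falconiformes":
            n_shift = pd.NA
            pct_shift = pd.NA
        else:
            n_shift = int(sub["shifter"].fillna(False).sum())
            pct_shift = round(100 * n_shift / n)
        rows.append({
            "order": order, "n": n,
            "day_active": day_active,
            "pct_day_active": round(100 * day_active / n),
            "night_active": night_active,
            "pct_night_active": round(100 * night_active / n),
            "strict": n_strict, "non_strict": n - n_strict,
            "shifters": n_shift, "pct_shifters": pct_shift,
        })
    return pd.DataFrame(rows).set_index("order")


def read_species_table(path) -> pd.DataFrame:
    """Read the species trait CSV (species_id, order, day, twilight, night,
    body_length_cm, migratory)."""
    df = pd.read_csv(path)
    required = {"species_id", "order", "day", "twilight", "night"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    if "migratory" in df.columns:
        df["migratory"] = df["migratory"].astype(int).astype(bool)
    else:
        df["migratory"] = False
    if df["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in species table")
    return df
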