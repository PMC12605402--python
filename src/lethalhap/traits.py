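"""Derivation of analysis-ready phenotypes from raw records.

Stillbirth: each calving is 0 for a dead calf (stillborn, died during
calving, died within 24 h) and 1 for a live calf; abortions and twin
calvings are excluded, parities are capped, and dams must be older than 19
and younger than 37 months at first calving.

Fertility: per cow-lactation service period (lactations 0-3) the traits are
conception rate (CR), calving interval (CI), interval from first to last
insemination (IFL) and number of inseminations per service period (AIS),
with the record-editing interval limits applied exactly:

    age at first calving 550-1100 d, CI 280-600 d, age at first
    insemination 270-900 d, calving to first insemination 20-230 d,
    IFL 0-365 d, calving to last insemination 20-365 d, gestation
    260-302 d, AIS 1-8.

NRR56: 1 if the cow was not re-inseminated within 56 days of her first
insemination, 0 if re-inseminated on days 3-55; re-inseminations less than
3 days after the previous one are removed, as are records whose
first-insemination-to-calving interval is below 266 days.

Month arithmetic: age in months is floor(days / 30.4375).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("lethalhap")

DAYS_PER_MONTH = 30.4375

STILLBIRTH_OUTCOMES = frozenset({"stillborn", "died_during_calving", "died_within_24h"})
VALID_OUTCOMES = STILLBIRTH_OUTCOMES | {"abortion", "live"}

TRAIT_RANGES = {
    "SB": (0, 1),
    "CR": (0, 1),
    "NRR56": (0, 1),
    "INF": (0, 1),
    "CI": (280, 600),
    "AIS": (1, 8),
    "IFL": (0, 365),
}


class TraitError(Exception):
    pass


def age_months(birth: pd.Series, at: pd.Series) -> pd.Series:
    days = (at - birth).dt.days
    return np.floor(days / DAYS_PER_MONTH).astype(int)


# ---------------------------------------------------------------------------
# stillbirth
# ---------------------------------------------------------------------------

def derive_stillbirth(
    calvings: pd.DataFrame,
    birth_dates: dict | pd.Series,
    max_parity: int = 4,
) -> pd.DataFrame:
    """Stillbirth trait table: one row per surviving calving.

    value = 1 live / 0 dead.  ``max_parity`` is the highest 0-based parity
    retained (4 keeps five calvings per dam as used for haplotype effects;
    3 keeps four as used for GWAS).  ``birth_dates`` maps dam id -> birth
    date for the first-calving age filter (strictly more than 19 and
    strictly less than 37 months, i.e. 20-36 whole months).
    """
    unknown = set(calvings["outcome"]) - VALID_OUTCOMES
    if unknown:
        raise TraitError(f"unknown outcome categories: {sorted(unknown)}")
    recs = calvings[calvings["outcome"] != "abortion"].copy()
    recs = recs[~recs["twin"]]
    recs = recs[recs["parity"] <= max_parity]

    bd = pd.Series(birth_dates) if isinstance(birth_dates, dict) else birth_dates
    bd = pd.to_datetime(bd)
    first = recs[recs["parity"] == 0].groupby("dam")["date"].min()
    # dams with no retained first calving cannot be age-checked; drop them
    recs = recs[recs["dam"].isin(first.index)]
    dams = first.index.intersection(bd.index)
    afc = age_months(bd.loc[dams], first.loc[dams])
    ok_dams = set(afc[(afc >= 20) & (afc <= 36)].index)
    recs = recs[recs["dam"].isin(ok_dams)]

    out = pd.DataFrame(
        {
            "animal": recs["calf"].to_numpy(),
            "trait": "SB",
            "value": (~recs["outcome"].isin(STILLBIRTH_OUTCOMES)).astype(int).to_numpy(),
            "parity": recs["parity"].to_numpy(),
            "dam": recs["dam"].to_numpy(),
            "sire": recs["sire"].to_numpy(),
            "calf": recs["calf"].to_numpy(),
            "calf_sex": recs["calf_sex"].to_numpy(),
            "date": recs["date"].to_numpy(),
            "year": recs["date"].dt.year.to_numpy(),
            "month": recs["date"].dt.month.to_numpy(),
            "year_month": recs["date"].dt.strftime("%Y-%m").to_numpy(),
        }
    )
    if "herd" in recs.columns:
        out["herd"] = recs["herd"].to_numpy()
    dam_age = age_months(bd.reindex(recs["dam"]).set_axis(recs.index), recs["date"])
    out["age_of_dam"] = dam_age.to_numpy()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# service periods
# ---------------------------------------------------------------------------

def _service_periods(inseminations: pd.DataFrame, calvings: pd.DataFrame):
    """Yield per cow-lactation service periods.

    Periods are delimited by the cow's own calvings; inseminations after the
    last calving form a final open period.  Lactation = number of calvings
    before the period.
    """
    calv_by_cow = {
        cow: grp.sort_values("date")["date"].tolist()
        for cow, grp in calvings.groupby("dam")
    }
    for cow, grp in inseminations.groupby("cow"):
        grp = grp.sort_values("date")
        calv_dates = calv_by_cow.get(cow, [])
        bounds = [pd.Timestamp.min] + calv_dates + [pd.Timestamp.max]
        for lact in range(len(bounds) - 1):
            lo, hi = bounds[lact], bounds[lact + 1]
            inseg = grp[(grp["date"] > lo) & (grp["date"] <= hi)]
            if inseg.empty:
                continue
            next_calving = hi if hi != pd.Timestamp.max else None
            prev_calving = lo if lo != pd.Timestamp.min else None
            yield cow, lact, inseg, prev_calving, next_calving


def _dedupe_close(inseg: pd.DataFrame, min_gap_days: int = 3) -> pd.DataFrame:
    """Drop inseminations less than ``min_gap_days`` after the previous kept one."""
    keep = []
    last = None
    for idx, row in inseg.iterrows():
        if last is None or (row["date"] - last).days >= min_gap_days:
            keep.append(idx)
            last = row["date"]
    return inseg.loc[keep]


# ---------------------------------------------------------------------------
# fertility traits
# ---------------------------------------------------------------------------

def derive_fertility(
    inseminations: pd.DataFrame,
    calvings: pd.DataFrame,
    birth_dates: dict | pd.Series,
) -> pd.DataFrame:
    """CR / CI / IFL / AIS trait table from insemination and calving records.

    Only lactations 0-3 are used; lactation 2 (3) records are dropped when
    lactation 1 (1 or 2) information is missing.  CR = 1 iff IFL is 0-4 days
    and the cow calved 260-302 days after the first insemination; CR = 0
    when IFL >= 5 days with a calving, or when inseminated but never calved.
    The gestation filter (260-302 d) is applied against the conception
    (last) insemination.
    """
    bd = pd.to_datetime(pd.Series(birth_dates) if isinstance(birth_dates, dict) else birth_dates)
    known = set(calvings["dam"]) | set(bd.index)
    missing_cows = set(inseminations["cow"]) - known - set(bd.index)
    if missing_cows:
        logger.warning("%d cows in inseminations without birth date; skipped", len(missing_cows))

    rows = []
    seen_lactations: dict = {}
    for cow, lact, inseg, prev_calving, next_calving in _service_periods(
        inseminations, calvings
    ):
        if lact > 3:
            continue
        if cow not in bd.index:
            continue
        birth = bd[cow]
        first = inseg["date"].min()
        last = inseg["date"].max()
        ais = len(inseg)
        ifl = (last - first).days

        if lact == 0 and not (270 <= (first - birth).days <= 900):
            continue
        if prev_calving is not None:
            if not (20 <= (first - prev_calving).days <= 230):
                continue
            if not (20 <= (last - prev_calving).days <= 365):
                continue
        if not (0 <= ifl <= 365):
            continue
        if not (1 <= ais <= 8):
            continue
        if next_calving is not None:
            gestation = (next_calving - last).days
            if not (260 <= gestation <= 302):
                continue
            if lact == 0 and not (550 <= (next_calving - birth).days <= 1100):
                continue

        if next_calving is not None:
            days_to_calving = (next_calving - first).days
            if ifl <= 4 and 260 <= days_to_calving <= 302:
                cr = 1
            else:
                cr = 0
        else:
            cr = 0  # inseminated but never calved

        covars = {
            "animal": cow,
            "parity": lact,
            "year": first.year,
            "month": first.month,
            "age_months": int(np.floor((first - birth).days / DAYS_PER_MONTH)),
            "technician": inseg.iloc[0]["technician"],
        }
        if "herd" in inseg.columns:
            covars["herd"] = inseg.iloc[0]["herd"]
        seen_lactations.setdefault(cow, set()).add(lact)
        rows.append({**covars, "trait": "CR", "value": cr})
        rows.append({**covars, "trait": "IFL", "value": ifl})
        rows.append({**covars, "trait": "AIS", "value": ais})
        if prev_calving is not None and next_calving is not None:
            ci = (next_calving - prev_calving).days
            if 280 <= ci <= 600:
                rows.append({**covars, "trait": "CI", "value": ci})

    table = pd.DataFrame(rows)
    if table.empty:
        return table
    # drop lactation-2/3 records when earlier lactation information missing
    def _has_earlier(row):
        lacts = seen_lactations.get(row["animal"], set())
        if row["parity"] == 2:
            return 1 in lacts
        if row["parity"] == 3:
            return {1, 2}.issubset(lacts)
        return True

    keep = table.apply(_has_earlier, axis=1)
    table = table[keep].reset_index(drop=True)
    cols = ["animal", "trait", "value", "parity", "year", "month", "age_months", "technician"]
    cols += [c for c in table.columns if c not in cols]
    return table[cols]


def derive_nrr56(inseminations: pd.DataFrame, calvings: pd.DataFrame) -> pd.DataFrame:
    """NRR56 trait table, one row per cow-lactation service period."""
    rows = []
    for cow, lact, inseg, prev_calving, next_calving in _service_periods(
        inseminations, calvings
    ):
        if lact > 3:
            continue
        inseg = _dedupe_close(inseg)
        first = inseg["date"].min()
        if next_calving is not None and (next_calving - first).days < 266:
            continue
        later = inseg["date"][inseg["date"] > first]
        days = (later - first).dt.days
        # after the <3-day dedupe every return is >= 3 days out, so the
        # 3-55 inclusive rule is exactly "returned within 56 days"
        value = 0 if ((days >= 3) & (days <= 55)).any() else 1
        row = {
            "animal": cow,
            "trait": "NRR56",
            "value": value,
            "parity": lact,
            "year": first.year,
            "month": first.month,
            "technician": inseg.iloc[0]["technician"],
            "date": first,
        }
        if "herd" in inseg.columns:
            row["herd"] = inseg.iloc[0]["herd"]
        if "sire" in inseg.columns:
            row["sire"] = inseg.iloc[0]["sire"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# class-size and infertility
# ---------------------------------------------------------------------------

def enforce_class_minimum(
    table: pd.DataFrame, class_fields: list, min_n: int = 10
) -> pd.DataFrame:
    """Iteratively drop records in fixed-effect classes below ``min_n`` until
    every class over every field satisfies the minimum (fixed point)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    out = table
    changed = True
    while changed and len(out):
        changed = False
        for field in class_fields:
            counts = out[field].map(out[field].value_counts())
            keep = counts >= min_n
            if not keep.all():
                out = out[keep]
                changed = True
    if len(out) == 0:
        logger.warning("enforce_class_minimum removed every record")
    return out.reset_index(drop=True)


def derive_infertility(calvings: pd.DataFrame, cullings: pd.DataFrame) -> pd.DataFrame:
    """Binary infertility phenotype: 0 for cows culled for infertility that
    never calved, 1 for cows that calved; all other cows are absent."""
    calved = pd.unique(calvings["dam"])
    infertile = cullings.loc[
        (cullings["reason"] == "infertility") & ~cullings["cow"].isin(calved), "cow"
    ]
    rows = [{"animal": c, "trait": "INF", "value": 1, "parity": 0} for c in calved]
    rows += [{"animal": c, "trait": "INF", "value": 0, "parity": 0} for c in pd.unique(infertile)]
    return pd.DataFrame(rows, columns=["animal", "trait", "value", "parity"])
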