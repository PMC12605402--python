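"""Candidate-haplotype effect models.

Two validation routes for a putative recessive lethal:

* a logistic regression of calf survival (1 = live, 0 = dead) on the
  probability that the conceptus is homozygous for the haplotype, computed
  from parental / grand-parental carrier status, with parity, calf sex and
  calving year-month as covariates;
* a linear mixed model of NRR56 (non-return rate at day 56) on the mating
  type defined by service-sire and maternal-grand-sire carrier status, with
  a pedigree additive cow effect, compared against the closed-form extra
  insemination-failure expected for a fully penetrant recessive lethal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import mixed
from .data_io import Pedigree

logger = logging.getLogger("lethalhap")


class EffectModelError(Exception):
    pass


class SeparationError(EffectModelError):
    """Complete separation or degenerate design in the logistic fit."""


# ---------------------------------------------------------------------------
# conceptus homozygosity probability
# ---------------------------------------------------------------------------

def p_hom_fetus(
    sire_carrier: int,
    dam_carrier: int | None,
    mgs_carrier: int | None,
    dam_genotyped: bool,
) -> float:
    """Probability the conceptus is homozygous for the candidate haplotype.

    Dam route (dam genotyped):   0.5 * sire * 0.5 * dam   = 0.25 * sire * dam
    MGS route (dam ungenotyped): 0.5 * sire * 0.25 * mgs  = 0.125 * sire * mgs
    """
    if sire_carrier not in (0, 1):
        raise ValueError("carrier status must be 0 or 1")
    if dam_genotyped:
        if dam_carrier not in (0, 1):
            raise ValueError("dam carrier status must be 0 or 1 when genotyped")
        return 0.25 * sire_carrier * dam_carrier
    if mgs_carrier not in (0, 1):
        raise EffectModelError(
            "record unusable: neither dam nor maternal grand sire genotyped"
        )
    return 0.125 * sire_carrier * mgs_carrier


def hom_fetus_records(
    calvings: pd.DataFrame, carrier_status: dict, pedigree: Pedigree
) -> pd.DataFrame:
    """Attach P(hom fetus) to calving records for one haplotype.

    ``carrier_status`` maps genotyped animal id -> bool.  Records where
    neither (sire, dam) nor (sire, MGS) are genotyped are dropped, as are
    records with an ungenotyped sire.
    """
    rows = []
    for _, rec in calvings.iterrows():
        sire, dam = rec["sire"], rec["dam"]
        if sire not in carrier_status:
            continue
        if dam in carrier_status:
            p = p_hom_fetus(int(carrier_status[sire]), int(carrier_status[dam]), None, True)
        else:
            mgs = pedigree.maternal_grand_sire_of(rec["calf"]) if rec["calf"] in pedigree else None
            if mgs is None or mgs not in carrier_status:
                continue
            p = p_hom_fetus(int(carrier_status[sire]), None, int(carrier_status[mgs]), False)
        row = rec.to_dict()
        row["p_hom_fetus"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stillbirth logistic model
# ---------------------------------------------------------------------------

def merge_sparse_year_months(year_month: pd.Series, min_n: int = 5) -> pd.Series:
    """Merge calendar-month cells with fewer than ``min_n`` records into the
    neighbouring month within the same year, keeping the design full rank on
    small synthetic datasets."""
    counts = year_month.value_counts()
    mapping = {}
    by_year: dict[str, list] = {}
    for ym in sorted(counts.index):
        by_year.setdefault(ym.rsplit("-", 1)[0], []).append(ym)
    for year, months in by_year.items():
        group: list = []
        total = 0
        for ym in months:
            group.append(ym)
            total += counts[ym]
            if total >= min_n:
                for g in group:
                    mapping[g] = group[0]
                group, total = [], 0
        if group:  # fold the trailing small cells into the previous group
            target = mapping.get(months[len(months) - len(group) - 1], group[0]) if len(months) > len(group) else group[0]
            for g in group:
                mapping[g] = target
    return year_month.map(mapping)


def fit_stillbirth_logistic(records: pd.DataFrame, min_cell: int = 5) -> dict:
    """Maximum-likelihood logistic regression (IRLS) of survival on
    P(hom fetus) with parity, calf sex and year-month covariates.

    Outcome is 1 for a live calf, 0 for a dead one, so a lethal haplotype
    yields ``beta < 0``; ``or_stillbirth = exp(-beta)`` is reported to keep
    the direction unambiguous.  Wald z and two-sided p.  Raises
    :class:`SeparationError` on degenerate designs; complete separation is
    flagged with ``p`` set to NaN.
    """
    import statsmodels.api as sm

    if (records["p_hom_fetus"] <= 0).all():
        raise SeparationError("no record with positive P(hom fetus); beta inestimable")
    y = records["value"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError("outcome is constant")
    parts = [np.ones((len(records), 1))]
    labels = ["intercept"]
    for term in ("parity", "calf_sex"):
        if term in records.columns and records[term].nunique() > 1:
            Xc, lab = mixed.dummy_encode(records[term].astype(str), term)
            parts.append(Xc)
            labels.extend(lab)
    if "year_month" in records.columns and records["year_month"].nunique() > 1:
        ym = merge_sparse_year_months(records["year_month"].astype(str), min_n=min_cell)
        if ym.nunique() > 1:
            Xc, lab = mixed.dummy_encode(ym, "year_month")
            parts.append(Xc)
            labels.extend(lab)
    parts.append(records["p_hom_fetus"].to_numpy(dtype=float).reshape(-1, 1))
    labels.append("p_hom_fetus")
    X = np.column_stack(parts)
    X, labels, dropped = mixed._drop_aliased(X, labels)
    if "p_hom_fetus" not in labels:
        raise SeparationError("P(hom fetus) aliased with other covariates")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=50, tol=1e-8)
    except Exception as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    j = labels.index("p_hom_fetus")
    beta = float(res.params[j])
    se = float(res.bse[j])
    separated = (not np.isfinite(se)) or se > 1e3 or abs(beta) > 50
    if separated:
        logger.warning("complete separation suspected for P(hom fetus) effect")
        z = p = float("nan")
    else:
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
    return {
        "beta": beta,
        "se": se,
        "z": z,
        "p": p,
        "or_stillbirth": float(np.exp(-beta)) if abs(beta) < 500 else float("inf"),
        "n": len(records),
        "n_informative": int((records["p_hom_fetus"] > 0).sum()),
        "converged": bool(res.converged),
        "separated": separated,
        "dropped": dropped,
    }


# ---------------------------------------------------------------------------
# mating types and insemination failure
# ---------------------------------------------------------------------------

def classify_mating_type(sire_carrier: bool, mgs_carrier: bool) -> int:
    """(NC,NC)->1, (NC,C)->2, (C,NC)->3, (C,C)->4."""
    return 1 + 2 * int(bool(sire_carrier)) + int(bool(mgs_carrier))


def mating_type_records(
    nrr: pd.DataFrame, carrier_status: dict, pedigree: Pedigree
) -> pd.DataFrame:
    """Attach the mating type (service sire x maternal grand sire of the
    cow) to NRR56 records; rows where either status is unknown are skipped.

    ``nrr`` needs columns: cow (or animal), sire (service sire), nrr56,
    parity, year.
    """
    cow_col = "cow" if "cow" in nrr.columns else "animal"
    rows = []
    for _, rec in nrr.iterrows():
        sire = rec["sire"]
        if sire not in carrier_status:
            continue
        cow = rec[cow_col]
        if cow not in pedigree:
            continue
        mgs = pedigree.sire_of(cow)
        if mgs is None or mgs not in carrier_status:
            continue
        row = rec.to_dict()
        row["cow"] = cow
        row["mating_type"] = classify_mating_type(carrier_status[sire], carrier_status[mgs])
        rows.append(row)
    return pd.DataFrame(rows)


def background_failure(records: pd.DataFrame) -> float:
    """Background insemination-failure rate f: the weighted mean failure
    rate (1 - NRR56) over mating types 1 and 2, weighted by record count."""
    sub = records[records["mating_type"].isin((1, 2))]
    if sub.empty or sub["mating_type"].nunique() < 2:
        raise EffectModelError("mating types 1 and 2 must both be non-empty")
    return float(1.0 - sub["nrr56"].astype(float).mean())


@dataclass
class ExpectedFailureCurve:
    p: float
    f: float
    extra_failure: tuple  # indexed by mating type 1..4

    def __getitem__(self, mating_type: int) -> float:
        return self.extra_failure[mating_type - 1]


def expected_extra_failure(p: float, f: float) -> ExpectedFailureCurve:
    """Theoretical extra insemination failure per mating type for a fully
    penetrant recessive lethal at haplotype frequency ``p`` with background
    failure ``f``: (1) 0, (2) 0, (3) 0.25 p (1-f),
    (4) 0.25 * 0.5/(1 - 0.5 p) * (1-f)."""
    if not 0.0 < p < 0.5:
        raise ValueError("haplotype frequency must be in (0, 0.5)")
    if not 0.0 <= f <= 1.0:
        raise ValueError("background failure must be in [0, 1]")
    t3 = 0.25 * p * (1.0 - f)
    t4 = 0.25 * (0.5 / (1.0 - 0.5 * p)) * (1.0 - f)
    return ExpectedFailureCurve(p=p, f=f, extra_failure=(0.0, 0.0, t3, t4))


def fit_nrr56_mixed(
    records: pd.DataFrame,
    pedigree: Pedigree,
    varcomp: dict | None = None,
    reml_tol: float = 1e-4,
) -> pd.DataFrame:
    """Linear mixed model of NRR56 on parity, year and mating type with a
    pedigree additive cow effect (u ~ N(0, A s2u)).

    Mating type 4 is the reference level, so the reported BLUEs are directly
    deviations from type 4, with standard errors from the inverse of the MME
    coefficient matrix.  ``varcomp`` supplies {"animal": s2u, "residual":
    s2e}; when None both are estimated by AI-REML.
    """
    if (records["mating_type"] == 4).sum() == 0:
        raise EffectModelError("mating type 4 (reference level) is empty")
    data = records.copy()
    # force type 4 first so treatment coding makes it the reference
    data["mating_type"] = pd.Categorical(
        data["mating_type"].astype(int), categories=[4, 1, 2, 3]
    ).remove_unused_categories()
    data = data.sort_values("mating_type", kind="stable").reset_index(drop=True)
    spec = mixed.ModelSpec(
        response="nrr56",
        fixed_terms=[t for t in ("parity", "year") if data[t].nunique() > 1] + ["mating_type"],
        random_terms=[("animal", "cow", "pedigree-additive")],
    )
    data["mating_type"] = data["mating_type"].astype(int).astype(str)
    y, X, labels, terms, dropped = mixed.build_design(data, spec, pedigree=pedigree)
    if varcomp is None:
        vc, _ = mixed.reml(y, X, terms, tol=reml_tol)
    else:
        if varcomp["animal"] <= 0:
            # model collapses to ordinary least squares
            vc = mixed.VarianceComponents(
                {"animal": 1e-10, "residual": varcomp["residual"]}
            )
        else:
            vc = mixed.VarianceComponents(dict(varcomp))
    fit = mixed.solve_blup(y, X, terms, vc, fixed_labels=labels)
    out = []
    counts = data["mating_type"].value_counts()
    for mt in (1, 2, 3):
        label = f"mating_type[{mt}]"
        if label not in labels:
            continue
        est = fit.fixed_effect(label)
        se = float(fit.fixed_se([label])[0])
        z = est / se
        out.append(
            {
                "mating_type": mt,
                "n": int(counts.get(str(mt), 0)),
                "effect": est,
                "se": se,
                "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)),
            }
        )
    table = pd.DataFrame(out)
    table.attrs["n_type4"] = int(counts.get("4", 0))
    table.attrs["varcomp"] = vc.values
    table.attrs["dropped_fixed"] = dropped
    return table
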