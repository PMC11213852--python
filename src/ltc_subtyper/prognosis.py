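"""Longitudinal analyses: mortality and 2-year care-need deterioration.

Follow-up runs from the index certification until death, loss to follow-up
(removal from the insurance registry) or the administrative end of
observation.  The module provides:

* per-cluster mortality rates per 100 person-years with exact Poisson CIs;
* Kaplan–Meier survival and Nelson-Aalen cumulative-hazard curves;
* Cox proportional-hazards regression (Efron ties) contrasting each
  subtype against a reference cluster, optionally adjusted for age, sex
  and initial care-need level (entered as categorical indicators);
* the 2-year care-need outcome classification — improved / no change /
  deteriorated / dead / alive-without-reassessment / lost — restricted to
  participants enrolled early enough to have 24 months of potential
  follow-up; and
* deterioration odds ratios under the primary definition and two
  sensitivity variants, unadjusted (2×2 cross-product with Woolf CIs) or
  via logistic regression.

Variant definitions (the event always excludes those lost to follow-up):

* ``primary``  — event = deteriorated or dead; the alive-not-reassessed are
  kept as non-events (their level is assumed unchanged);
* ``sens1``    — as primary but the alive-not-reassessed are excluded;
* ``sens2``    — deaths are additionally excluded; event = deteriorated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from scipy import stats

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 365.25 / 12.0

OUTCOME_CATEGORIES = [
    "improved",
    "no_change",
    "deteriorated",
    "dead",
    "not_reassessed",
    "lost",
]

VARIANTS = ("primary", "sens1", "sens2")
ADJUSTMENTS = ("none", "model1", "model2")


@dataclass
class EffectEstimate:
    contrast: object  # cluster vs reference
    estimate: float  # HR or OR
    ci_low: float
    ci_high: float
    adjustment: str


@dataclass
class FollowUp:
    """Per-person follow-up: survival time plus the reassessment sequence."""

    table: pd.DataFrame  # person_id, index_month, time_months, event
    reassessments: pd.DataFrame  # person_id, months_since_index, care_level


def build_followup(
    cohort: pd.DataFrame,
    certifications: pd.DataFrame,
    registry: pd.DataFrame,
    study_end: pd.Period,
) -> FollowUp:
    """Assemble the follow-up table for the cohort.

    ``study_end`` is the administrative end of observation (month); a person
    certified in month t is censored at ``study_end − t`` months unless dead
    or disenrolled earlier.
    """
    reg = registry.copy()
    for col in ("death_date", "disenrollment_date"):
        reg[col] = pd.to_datetime(reg[col], errors="coerce")
    reg = reg.set_index("person_id")
    certs = certifications.copy()
    certs["certification_date"] = pd.to_datetime(certs["certification_date"])
    lvl = certs["care_need_level"].astype(str)
    certs = certs.loc[lvl.isin(list("12345"))]
    certs["care_need_level"] = certs["care_need_level"].astype(int)
    certs_by = dict(tuple(certs.groupby("person_id", sort=False)))

    rows, reassess_rows = [], []
    for rec in cohort.itertuples(index=False):
        person = rec.person_id
        index_month = pd.Period(rec.index_month, freq="M")
        index_date = index_month.start_time
        admin_t = float((study_end - index_month).n)
        person_reg = reg.loc[person]
        t_death = np.inf
        if pd.notna(person_reg["death_date"]):
            t_death = (
                pd.Timestamp(person_reg["death_date"]) - index_date
            ).days / DAYS_PER_MONTH
        t_lost = np.inf
        if pd.notna(person_reg["disenrollment_date"]):
            t_lost = (
                pd.Timestamp(person_reg["disenrollment_date"]) - index_date
            ).days / DAYS_PER_MONTH
        t = min(t_death, t_lost, admin_t)
        if t_death <= min(t_lost, admin_t):
            event = "death"
        elif t_lost <= admin_t:
            event = "lost"
        else:
            event = "admin"
        rows.append((person, str(index_month), max(t, 0.0), event))

        pc = certs_by.get(person)
        if pc is not None:
            for crec in pc.sort_values("certification_date").itertuples(index=False):
                months = (
                    pd.Timestamp(crec.certification_date) - index_date
                ).days / DAYS_PER_MONTH
                if months > 0:
                    reassess_rows.append((person, months, int(crec.care_need_level)))

    table = pd.DataFrame(
        rows, columns=["person_id", "index_month", "time_months", "event"]
    )
    reassessments = pd.DataFrame(
        reassess_rows, columns=["person_id", "months_since_index", "care_level"]
    )
    return FollowUp(table=table, reassessments=reassessments)


def followup_from_tables(
    certifications: pd.DataFrame,
    registry: pd.DataFrame,
    study_end: pd.Period,
) -> pd.DataFrame:
    """Vectorized survival-only follow-up table (no reassessment sequences).

    Index = each person's first certification; suitable for large simulation
    studies where only death/censoring times are needed.
    """
    certs = certifications.copy()
    certs["certification_date"] = pd.to_datetime(certs["certification_date"])
    first = certs.groupby("person_id")["certification_date"].min().sort_index()
    reg = registry.set_index("person_id").loc[first.index]
    idx_month = first.dt.to_period("M")
    admin_t = (study_end.ordinal - idx_month.map(lambda p: p.ordinal)).astype(float)
    t_death = (
        pd.to_datetime(reg["death_date"], errors="coerce") - first
    ).dt.days / DAYS_PER_MONTH
    t_lost = (
        pd.to_datetime(reg["disenrollment_date"], errors="coerce") - first
    ).dt.days / DAYS_PER_MONTH
    td = t_death.fillna(np.inf).to_numpy()
    tl = t_lost.fillna(np.inf).to_numpy()
    ta = admin_t.to_numpy()
    time_months = np.minimum(np.minimum(td, tl), ta)
    event = np.where(td <= np.minimum(tl, ta), "death", np.where(tl <= ta, "lost", "admin"))
    return pd.DataFrame(
        {
            "person_id": first.index,
            "index_month": idx_month.astype(str).to_numpy(),
            "time_months": np.maximum(time_months, 0.0),
            "event": event,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mortality

def person_time_rates(followup_table: pd.DataFrame, labels) -> pd.DataFrame:
    """Deaths per 100 person-years per cluster, with exact Poisson 95% CIs."""
    labels = np.asarray(labels)
    rows = []
    for cluster in np.unique(labels):
        sub = followup_table.loc[labels == cluster]
        deaths = int((sub["event"] == "death").sum())
        py = float(sub["time_months"].sum()) / 12.0
        if py <= 0:
            rows.append((cluster, deaths, py, np.nan, np.nan, np.nan))
            continue
        rate = 100.0 * deaths / py
        lo = 0.0 if deaths == 0 else 100.0 * stats.chi2.ppf(0.025, 2 * deaths) / 2 / py
        hi = 100.0 * stats.chi2.ppf(0.975, 2 * deaths + 2) / 2 / py
        rows.append((cluster, deaths, py, rate, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["cluster", "deaths", "person_years", "rate_per_100py", "ci_low", "ci_high"],
    )


def km_estimate(followup_table: pd.DataFrame, labels) -> Dict[object, pd.DataFrame]:
    """Kaplan–Meier survival curves per cluster (time, estimate, 95% CI)."""
    return _fit_curves(followup_table, labels, KaplanMeierFitter, "KM_estimate")


def nelson_aalen(followup_table: pd.DataFrame, labels) -> Dict[object, pd.DataFrame]:
    """Nelson-Aalen cumulative-hazard curves per cluster."""
    return _fit_curves(followup_table, labels, NelsonAalenFitter, "NA_estimate")


def _fit_curves(followup_table, labels, fitter_cls, column) -> Dict[object, pd.DataFrame]:
    labels = np.asarray(labels)
    out = {}
    for cluster in np.unique(labels):
        sub = followup_table.loc[labels == cluster]
        fitter = fitter_cls()
        fitter.fit(sub["time_months"], event_observed=sub["event"] == "death")
        est = (
            fitter.survival_function_
            if column == "KM_estimate"
            else fitter.cumulative_hazard_
        )
        ci = fitter.confidence_interval_
        df = pd.DataFrame(
            {
                "time_months": est.index.to_numpy(),
                "estimate": est.iloc[:, 0].to_numpy(),
                "ci_low": ci.iloc[:, 0].to_numpy(),
                "ci_high": ci.iloc[:, 1].to_numpy(),
            }
        )
        out[cluster] = df
    return out


def choose_reference(labels, roles: Optional[Dict[object, str]] = None):
    """Largest cluster; when subtype roles are annotated, the largest cluster
    not named 'unspecified'."""
    labels = np.asarray(labels)
    clusters, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    for idx in order:
        c = clusters[idx]
        if roles is not None and str(roles.get(c, "")).startswith("unspecified"):
            continue
        return c
    return clusters[order[0]]


def cox_ph(
    followup_table: pd.DataFrame,
    labels,
    covariates: Optional[pd.DataFrame] = None,
    reference=None,
    roles: Optional[Dict[object, str]] = None,
) -> List[EffectEstimate]:
    """Cox PH hazard ratios of each cluster vs the reference (Efron ties).

    ``covariates``: optional per-person frame with ``age`` (linear years),
    ``sex`` and ``care_level`` (categorical 1–5, entered as indicators for
    levels 2–5 vs 1).  Omit for unadjusted contrasts.
    """
    labels = np.asarray(labels)
    if reference is None:
        reference = choose_reference(labels, roles)
    clusters = [c for c in np.unique(labels) if c != reference]
    if not clusters:
        raise ValueError("need at least 2 clusters")

    df = pd.DataFrame(
        {
            "time": followup_table["time_months"].to_numpy(dtype=float),
            "event": (followup_table["event"] == "death").to_numpy(dtype=int),
        }
    )
    # avoid zero-length durations in the partial likelihood
    df.loc[df["time"] <= 0, "time"] = 1e-6
    cluster_cols = []
    for c in clusters:
        col = f"cluster_{c}"
        df[col] = (labels == c).astype(int)
        cluster_cols.append(col)
    adjustment = "unadjusted"
    if covariates is not None:
        df["age"] = covariates["age"].to_numpy(dtype=float)
        df["sex_female"] = (covariates["sex"] == "female").to_numpy(dtype=int)
        for lev in (2, 3, 4, 5):
            df[f"care_level_{lev}"] = (
                covariates["care_level"].to_numpy(dtype=int) == lev
            ).astype(int)
        adjustment = "age+sex+care_level"

    n_events = int(df["event"].sum())
    if n_events < df.shape[1] - 2:
        raise ValueError("fewer events than model parameters")
    fitter = CoxPHFitter()
    # tight Newton tolerance: small-sample partial likelihoods are flat
    fitter.fit(df, duration_col="time", event_col="event",
               fit_options={"precision": 1e-9})
    out = []
    ci = fitter.confidence_intervals_
    for c, col in zip(clusters, cluster_cols):
        out.append(
            EffectEstimate(
                contrast=(c, reference),
                estimate=float(np.exp(fitter.params_[col])),
                ci_low=float(np.exp(ci.loc[col].iloc[0])),
                ci_high=float(np.exp(ci.loc[col].iloc[1])),
                adjustment=adjustment,
            )
        )
    return out


# ---------------------------------------------------------------------------
# 2-year care-need deterioration

def classify_outcomes(
    followup: FollowUp,
    cohort: pd.DataFrame,
    horizon_months: int = 24,
    enrollment_cutoff: Optional[pd.Period] = None,
    closest_rule: str = "within",
) -> pd.DataFrame:
    """Per-person outcome category at the horizon.

    Participants indexed after ``enrollment_cutoff`` are dropped (they cannot
    have a full horizon of potential observation).  ``closest_rule``:
    ``"within"`` uses the latest reassessment in ``(0, horizon]``;
    ``"nearest"`` uses the reassessment closest to the horizon, allowing
    overshoot.
    """
    if horizon_months <= 0:
        raise ValueError("horizon_months must be positive")
    if closest_rule not in ("within", "nearest"):
        raise ValueError("closest_rule must be 'within' or 'nearest'")
    ft = followup.table.set_index("person_id")
    reassess_by = dict(tuple(followup.reassessments.groupby("person_id", sort=False)))
    rows = []
    for rec in cohort.itertuples(index=False):
        person = rec.person_id
        index_month = pd.Period(rec.index_month, freq="M")
        if enrollment_cutoff is not None and index_month > enrollment_cutoff:
            continue
        frec = ft.loc[person]
        t, event = float(frec["time_months"]), frec["event"]
        if event == "lost" and t <= horizon_months:
            category = "lost"
        elif event == "death" and t <= horizon_months:
            category = "dead"
        else:
            pr = reassess_by.get(person)
            level = None
            if pr is not None and len(pr):
                tt = pr["months_since_index"].to_numpy()
                if closest_rule == "within":
                    mask = tt <= horizon_months
                    if mask.any():
                        level = int(
                            pr["care_level"].to_numpy()[mask][np.argmax(tt[mask])]
                        )
                else:
                    level = int(
                        pr["care_level"].to_numpy()[np.argmin(np.abs(tt - horizon_months))]
                    )
            if level is None:
                category = "not_reassessed"
            elif level > rec.care_level:
                category = "deteriorated"
            elif level < rec.care_level:
                category = "improved"
            else:
                category = "no_change"
        rows.append(
            (
                person,
                category,
                rec.age,
                rec.sex,
                rec.care_level,
                getattr(rec, "n_comorbidities", np.nan),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["person_id", "category", "age", "sex", "care_level", "n_comorbidities"],
    )


def careneed_outcome_table(per_person: pd.DataFrame, labels) -> pd.DataFrame:
    """Aggregate per-person categories to per-cluster counts.

    The six counts partition each cluster of the restricted cohort.
    """
    labels = np.asarray(labels)
    if len(labels) != len(per_person):
        raise ValueError("labels must align with the per-person outcome frame")
    rows = []
    for cluster in np.unique(labels):
        sub = per_person.loc[labels == cluster]
        counts = [int((sub["category"] == cat).sum()) for cat in OUTCOME_CATEGORIES]
        rows.append((cluster, len(sub), *counts))
    table = pd.DataFrame(rows, columns=["cluster", "n", *OUTCOME_CATEGORIES])
    assert (table[OUTCOME_CATEGORIES].sum(axis=1) == table["n"]).all()
    return table


def _variant_counts(row: pd.Series, variant: str) -> Tuple[int, int]:
    """(events, non_events) for one cluster row of an outcome-count table."""
    if variant == "primary":
        events = row["deteriorated"] + row["dead"]
        non = row["improved"] + row["no_change"] + row["not_reassessed"]
    elif variant == "sens1":
        events = row["deteriorated"] + row["dead"]
        non = row["improved"] + row["no_change"]
    elif variant == "sens2":
        events = row["deteriorated"]
        non = row["improved"] + row["no_change"]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return int(events), int(non)


def or_from_counts(
    outcome_table: pd.DataFrame, variant: str = "primary", reference=None
) -> List[EffectEstimate]:
    """Unadjusted odds ratios from a per-cluster outcome-count table.

    The 2×2 cross-product OR of each cluster vs the reference, with Woolf
    (log-OR normal) 95% CIs; the lost are always excluded, and the variant
    fixes the event definition and denominators.  A zero cell yields a
    missing estimate with a warning.
    """
    table = outcome_table.set_index("cluster")
    if reference is None:
        reference = table["n"].idxmax()
    e0, n0 = _variant_counts(table.loc[reference], variant)
    out = []
    for cluster in table.index:
        if cluster == reference:
            continue
        e1, n1 = _variant_counts(table.loc[cluster], variant)
        if 0 in (e0, n0, e1, n1):
            warnings.warn(
                f"zero cell in 2x2 table for cluster {cluster!r}; OR undefined"
            )
            out.append(
                EffectEstimate((cluster, reference), np.nan, np.nan, np.nan, "none")
            )
            continue
        or_ = (e1 / n1) / (e0 / n0)
        se = np.sqrt(1 / e1 + 1 / n1 + 1 / e0 + 1 / n0)
        z = stats.norm.ppf(0.975)
        out.append(
            EffectEstimate(
                contrast=(cluster, reference),
                estimate=float(or_),
                ci_low=float(np.exp(np.log(or_) - z * se)),
                ci_high=float(np.exp(np.log(or_) + z * se)),
                adjustment="none",
            )
        )
    return out


def deterioration_or(
    per_person: pd.DataFrame,
    labels,
    variant: str = "primary",
    adjustment: str = "none",
    reference=None,
    roles: Optional[Dict[object, str]] = None,
) -> List[EffectEstimate]:
    """Odds ratios for 2-year care-need deterioration, per cluster vs reference.

    ``adjustment``: ``"none"`` → 2×2 cross-product OR with Woolf CI;
    ``"model1"`` → logistic regression adjusted for age, sex, initial care
    level; ``"model2"`` → model1 plus the number of comorbidities.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")
    labels = np.asarray(labels)
    if reference is None:
        reference = choose_reference(labels, roles)

    df = per_person.copy()
    df["cluster"] = labels
    df = df.loc[df["category"] != "lost"]
    if variant in ("sens1", "sens2"):
        df = df.loc[df["category"] != "not_reassessed"]
    if variant == "sens2":
        df = df.loc[df["category"] != "dead"]
        df["y"] = (df["category"] == "deteriorated").astype(int)
    else:
        df["y"] = df["category"].isin(["deteriorated", "dead"]).astype(int)

    if adjustment == "none":
        counts = (
            df.groupby("cluster")["y"]
            .agg(events="sum", total="count")
            .assign(non_events=lambda t: t["total"] - t["events"])
        )
        table = pd.DataFrame(
            {
                "cluster": counts.index,
                "n": counts["total"].to_numpy(),
                "improved": 0,
                "no_change": counts["non_events"].to_numpy(),
                "deteriorated": counts["events"].to_numpy(),
                "dead": 0,
                "not_reassessed": 0,
                "lost": 0,
            }
        )
        return or_from_counts(table, variant="sens2", reference=reference)

    import statsmodels.api as sm

    clusters = [c for c in np.unique(df["cluster"]) if c != reference]
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    cluster_cols = []
    for c in clusters:
        col = f"cluster_{c}"
        X[col] = (df["cluster"] == c).astype(float)
        cluster_cols.append(col)
    X["age"] = df["age"].astype(float)
    X["sex_female"] = (df["sex"] == "female").astype(float)
    for lev in (2, 3, 4, 5):
        X[f"care_level_{lev}"] = (df["care_level"].astype(int) == lev).astype(float)
    if adjustment == "model2":
        X["n_comorbidities"] = df["n_comorbidities"].astype(float)

    model = sm.Logit(df["y"].to_numpy(), X)
    res = model.fit(disp=False, maxiter=200)
    z = stats.norm.ppf(0.975)
    out = []
    for c, col in zip(clusters, cluster_cols):
        beta, se = res.params[col], res.bse[col]
        out.append(
            EffectEstimate(
                contrast=(c, reference),
                estimate=float(np.exp(beta)),
                ci_low=float(np.exp(beta - z * se)),
                ci_high=float(np.exp(beta + z * se)),
                adjustment=adjustment,
            )
        )
    return out
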