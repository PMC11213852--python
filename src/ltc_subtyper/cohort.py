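"""Cohort construction from linked claims, certification and registry tables.

Builds the analysis cohort of older adults at their *first* long-term-care
certification: flags the 22 diseases from claims in the 6-calendar-month
look-back window ending at (and including) the index month, applies the
eligibility rules (care level 1–5 at first certification, age ≥ 65 at index,
alive at the start of services), and derives the comorbidity co-occurrence
network.

Exclusions are applied in a fixed priority order and tallied per reason, so
``screened − included`` always equals the tally total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .diseases import DISEASES, N_DISEASES, DiseaseMap, validate_disease_map

logger = logging.getLogger(__name__)

#: Exclusion reasons in priority order (mutually exclusive; first match wins).
EXCLUSION_REASONS = (
    "no_certification",
    "support_level_only",
    "age_under_65",
    "died_before_start",
)

CARE_LEVELS = {"1", "2", "3", "4", "5"}


@dataclass
class ExclusionTally:
    screened: int
    included: int
    counts: Dict[str, int] = field(default_factory=dict)

    def total_excluded(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# Readers — the same CSV dialect the synthetic generator writes.

def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "diagnosis_code": str})
    df["service_month"] = pd.PeriodIndex(df["service_month"].astype(str), freq="M")
    return df


def read_certifications(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "care_need_level": str})
    df["certification_date"] = pd.to_datetime(df["certification_date"])
    return df


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "sex": str})
    for col in ("birth_date", "death_date", "disenrollment_date"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# Disease flagging

def _compile_map(disease_map: DiseaseMap) -> List[Tuple[str, Tuple[str, ...]]]:
    validate_disease_map(disease_map)
    return [(name, tuple(disease_map[name])) for name in DISEASES]


def _code_flags(code: str, compiled) -> np.ndarray:
    out = np.zeros(N_DISEASES, dtype=bool)
    for i, (_, prefixes) in enumerate(compiled):
        if code.startswith(prefixes):
            out[i] = True
    return out


def flag_diseases(
    claims: pd.DataFrame,
    disease_map: DiseaseMap,
    index_month: pd.Period,
    lookback_months: int = 6,
) -> np.ndarray:
    """22 booleans for one person: any matching claim in the look-back window.

    The window is the ``lookback_months`` calendar months ending at (and
    including) ``index_month``, i.e. ``[index − lookback + 1, index]``.
    """
    compiled = _compile_map(disease_map)
    flags = np.zeros(N_DISEASES, dtype=bool)
    if len(claims) == 0:
        return flags
    start = index_month - (lookback_months - 1)
    months = pd.PeriodIndex(claims["service_month"], freq="M")
    in_window = (months >= start) & (months <= index_month)
    for code in claims.loc[np.asarray(in_window), "diagnosis_code"]:
        flags |= _code_flags(str(code), compiled)
    return flags


def _completed_years(index_date: pd.Timestamp, birth_date: pd.Timestamp) -> int:
    return (
        index_date.year
        - birth_date.year
        - ((index_date.month, index_date.day) < (birth_date.month, birth_date.day))
    )


def _first_certifications(certifications: pd.DataFrame) -> pd.DataFrame:
    """One row per person: earliest certification; same-date ties keep the
    highest care level (support-level records rank below any care level)."""
    df = certifications.copy()
    lvl = df["care_need_level"].astype(str)
    df["_care_level"] = np.where(lvl.isin(CARE_LEVELS), lvl, "0").astype(int)
    df = df.rename(columns={"_care_level": "care_level_int"})
    df = df.sort_values(
        ["person_id", "certification_date", "care_level_int"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    first = df.groupby("person_id", sort=True).first().reset_index()
    n_ties = (
        df.groupby(["person_id", "certification_date"]).size().gt(1).groupby("person_id").any()
    ).sum()
    if n_ties:
        logger.info("same-date certification ties resolved for %d persons", n_ties)
    return first


def build_cohort(
    claims: pd.DataFrame,
    certifications: pd.DataFrame,
    registry: pd.DataFrame,
    disease_map: DiseaseMap,
    *,
    index_start: Optional[pd.Period] = None,
    index_end: Optional[pd.Period] = None,
    lookback_months: int = 6,
    min_age: int = 65,
) -> Tuple[pd.DataFrame, ExclusionTally, pd.DataFrame]:
    """Build the analysis cohort.

    Returns ``(cohort, tally, rejects)``: one cohort row per included person
    (demographics, index month, initial care level, the 22 disease flags and
    their sum), an :class:`ExclusionTally`, and a rejects report of persons
    present in certifications but absent from the registry.
    """
    compiled = _compile_map(disease_map)
    certifications = certifications.copy()
    certifications["certification_date"] = pd.to_datetime(
        certifications["certification_date"]
    )
    first = _first_certifications(certifications)
    screened = len(first)

    registry = registry.copy()
    for col in ("birth_date", "death_date", "disenrollment_date"):
        registry[col] = pd.to_datetime(registry[col], errors="coerce")
    reg = registry.set_index("person_id")
    missing_mask = ~first["person_id"].isin(reg.index)
    rejects = first.loc[missing_mask, ["person_id", "certification_date"]].copy()
    if len(rejects):
        logger.warning(
            "%d persons in certifications are absent from the registry; "
            "listed in the rejects report",
            len(rejects),
        )
    first = first.loc[~missing_mask]

    # pre-index claims by person for flagging
    claims_by_person = (
        dict(tuple(claims.groupby("person_id", sort=False))) if len(claims) else {}
    )
    empty_claims = claims.iloc[0:0]

    counts = {r: 0 for r in EXCLUSION_REASONS}
    rows = []
    for rec in first.itertuples(index=False):
        person = rec.person_id
        cert_date = pd.Timestamp(rec.certification_date)
        index_month = pd.Period(cert_date, freq="M")
        if (index_start is not None and index_month < index_start) or (
            index_end is not None and index_month > index_end
        ):
            counts["no_certification"] += 1
            continue
        level = int(rec.care_level_int)
        if level not in (1, 2, 3, 4, 5):
            counts["support_level_only"] += 1
            continue
        person_reg = reg.loc[person]
        age = _completed_years(cert_date, pd.Timestamp(person_reg["birth_date"]))
        if age < min_age:
            counts["age_under_65"] += 1
            continue
        death = person_reg["death_date"]
        if pd.notna(death) and pd.Timestamp(death) < cert_date:
            counts["died_before_start"] += 1
            continue
        flags = _flag_fast(
            claims_by_person.get(person, empty_claims),
            compiled,
            index_month,
            lookback_months,
        )
        rows.append(
            (person, age, person_reg["sex"], str(index_month), level, *flags.astype(int))
        )

    cohort = pd.DataFrame(
        rows,
        columns=["person_id", "age", "sex", "index_month", "care_level", *DISEASES],
    )
    if len(cohort):
        cohort["n_comorbidities"] = cohort[DISEASES].sum(axis=1)
    else:
        cohort["n_comorbidities"] = pd.Series(dtype=int)
    tally = ExclusionTally(screened=screened, included=len(cohort), counts=counts)
    assert tally.total_excluded() + len(cohort) + len(rejects) == screened
    return cohort, tally, rejects


def _flag_fast(claims, compiled, index_month, lookback_months) -> np.ndarray:
    flags = np.zeros(N_DISEASES, dtype=bool)
    if len(claims) == 0:
        return flags
    start = index_month - (lookback_months - 1)
    months = pd.PeriodIndex(claims["service_month"], freq="M")
    in_window = np.asarray((months >= start) & (months <= index_month))
    for code in set(claims.loc[in_window, "diagnosis_code"].astype(str)):
        flags |= _code_flags(code, compiled)
    return flags


# ---------------------------------------------------------------------------
# Comorbidity co-occurrence network

def cooccurrence_network(cohort: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Node sizes (marginal disease counts) and pairwise co-occurrence edges.

    Edge weight = number of participants with both diseases; zero-weight
    edges are omitted, so there are 22 nodes and at most C(22, 2) edges.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    F = cohort[DISEASES].to_numpy(dtype=int)
    joint = F.T @ F
    nodes = pd.DataFrame({"disease": DISEASES, "count": np.diag(joint)})
    rows = []
    for i in range(N_DISEASES):
        for j in range(i + 1, N_DISEASES):
            if joint[i, j] > 0:
                rows.append((DISEASES[i], DISEASES[j], int(joint[i, j])))
    edges = pd.DataFrame(rows, columns=["disease_a", "disease_b", "count"])
    return nodes, edges


def to_networkx(nodes: pd.DataFrame, edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for rec in nodes.itertuples(index=False):
        g.add_node(rec.disease, count=int(rec.count))
    for rec in edges.itertuples(index=False):
        g.add_edge(rec.disease_a, rec.disease_b, weight=int(rec.count))
    return g


def plot_network(nodes: pd.DataFrame, edges: pd.DataFrame, path) -> None:
    """Basic spring-layout rendering of the comorbidity network."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = to_networkx(nodes, edges)
    pos = nx.spring_layout(g, seed=0)
    sizes = [20 + 3 * g.nodes[v]["count"] for v in g]
    widths = [0.2 + 3 * g.edges[e]["weight"] / max(1, nodes["count"].max()) for e in g.edges]
    fig, ax = plt.subplots(figsize=(9, 7))
    nx.draw_networkx(g, pos, ax=ax, node_size=sizes, width=widths, font_size=6)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
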