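"""Subtype characterization: observed/expected ratios, exclusivity, summaries.

For cluster i and disease d:

* prevalence  prev_{i,d} = n_{i,d} / n_i
* observed/expected ratio  OE_{i,d} = prev_{i,d} / prev_d  (cluster
  prevalence over whole-cohort prevalence)
* exclusivity  excl_{i,d} = n_{i,d} / n_d  (share of all carriers of d
  that fall in cluster i)

A disease is flagged as *characteristic* of a cluster when OE ≥ 2 or
exclusivity ≥ 25% (inclusive thresholds; the disjunction is the default
rule, a conjunction is available).  Clusters with no flagged disease are
legitimate — that is the "unspecified" pattern.

Two conservation identities hold by construction and are exposed for
checking: the size-weighted mean of OE across clusters is 1 for every
disease with at least one case, and exclusivities sum to 1 across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .diseases import DISEASES

logger = logging.getLogger(__name__)


@dataclass
class SubtypeProfile:
    prevalence: pd.DataFrame  # clusters × diseases
    observed_expected: pd.DataFrame
    exclusivity: pd.DataFrame
    cluster_sizes: pd.Series
    flagged: Dict[object, Dict[str, str]]  # cluster -> {disease: reason}


def _counts(flags: pd.DataFrame, labels) -> tuple:
    labels = np.asarray(labels)
    F = flags[DISEASES] if set(DISEASES) <= set(flags.columns) else flags
    clusters = np.unique(labels)
    n_by = pd.Series({c: int((labels == c).sum()) for c in clusters})
    count = pd.DataFrame(
        {c: F.loc[labels == c].sum(axis=0) for c in clusters}
    ).T  # clusters × diseases
    return F, clusters, n_by, count


def observed_expected(flags: pd.DataFrame, labels) -> pd.DataFrame:
    """O/E table (clusters × diseases); diseases with no case are missing."""
    F, clusters, n_by, count = _counts(flags, labels)
    overall = F.sum(axis=0) / len(F)
    prev = count.div(n_by, axis=0)
    oe = prev.div(overall, axis=1)
    oe.loc[:, overall == 0] = np.nan
    return oe


def exclusivity(flags: pd.DataFrame, labels) -> pd.DataFrame:
    """Exclusivity table (clusters × diseases); zero-case diseases missing."""
    F, clusters, n_by, count = _counts(flags, labels)
    total = F.sum(axis=0)
    excl = count.div(total, axis=1)
    excl.loc[:, total == 0] = np.nan
    return excl


def flag_characteristics(
    oe: pd.DataFrame,
    excl: pd.DataFrame,
    oe_threshold: float = 2.0,
    excl_threshold: float = 0.25,
    rule: str = "or",
) -> Dict[object, Dict[str, str]]:
    """Characteristic diseases per cluster with the reason for each flag.

    Reasons are ``"OE>=2"``, ``"exclusivity>=25%"`` or ``"both"`` (labels
    follow the configured thresholds).  Thresholds are inclusive.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    if not oe.index.equals(excl.index) or not oe.columns.equals(excl.columns):
        raise ValueError("O/E and exclusivity tables are not aligned")
    flagged: Dict[object, Dict[str, str]] = {}
    for cluster in oe.index:
        entry: Dict[str, str] = {}
        for disease in oe.columns:
            hit_oe = oe.loc[cluster, disease] >= oe_threshold
            hit_ex = excl.loc[cluster, disease] >= excl_threshold
            ok = (hit_oe and hit_ex) if rule == "and" else (hit_oe or hit_ex)
            if ok:
                if hit_oe and hit_ex:
                    entry[disease] = "both"
                elif hit_oe:
                    entry[disease] = f"OE>={oe_threshold:g}"
                else:
                    entry[disease] = f"exclusivity>={100 * excl_threshold:g}%"
        flagged[cluster] = entry
    return flagged


def profile_clusters(
    flags: pd.DataFrame,
    labels,
    oe_threshold: float = 2.0,
    excl_threshold: float = 0.25,
    rule: str = "or",
) -> SubtypeProfile:
    """Full characterization bundle for a hard partition."""
    F, clusters, n_by, count = _counts(flags, labels)
    prev = count.div(n_by, axis=0)
    oe = observed_expected(flags, labels)
    excl = exclusivity(flags, labels)
    flagged = flag_characteristics(oe, excl, oe_threshold, excl_threshold, rule)
    return SubtypeProfile(
        prevalence=prev,
        observed_expected=oe,
        exclusivity=excl,
        cluster_sizes=n_by,
        flagged=flagged,
    )


AGE_BANDS = [(65, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, 200)]


def _band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}" if hi < 150 else f">={lo}"


def summarize_clusters(cohort: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster baseline summary with group-comparison p-values.

    Continuous rows (age, number of comorbidities) show median (IQR) and a
    Kruskal–Wallis p-value; categorical rows (age band, sex, initial care
    level) show n (%) and a chi-square p-value (no continuity correction).
    Empty clusters are excluded with a warning.
    """
    labels = np.asarray(labels)
    clusters = [c for c in np.unique(labels) if (labels == c).sum() > 0]
    if len(clusters) < 2:
        raise ValueError("need at least 2 non-empty clusters")
    groups = {c: cohort.loc[labels == c] for c in clusters}

    rows = []

    def continuous_row(name: str, col: str) -> None:
        samples = [g[col].to_numpy(dtype=float) for g in groups.values()]
        stat, p = stats.kruskal(*samples)
        cells = {"variable": name, "p_value": p}
        overall = cohort[col]
        cells["overall"] = _median_iqr(overall)
        for c, g in groups.items():
            cells[str(c)] = _median_iqr(g[col])
        rows.append(cells)

    def categorical_rows(name: str, series_fn, levels) -> None:
        table = np.array(
            [[int((series_fn(g) == lev).sum()) for lev in levels] for g in groups.values()]
        ).T  # levels × clusters
        keep = table.sum(axis=1) > 0
        stat, p, _, _ = stats.chi2_contingency(table[keep], correction=False)
        for li, lev in enumerate(levels):
            cells = {"variable": f"{name}: {lev}", "p_value": p if li == 0 else np.nan}
            overall_n = int(table[li].sum())
            cells["overall"] = _n_pct(overall_n, len(cohort))
            for ci, (c, g) in enumerate(groups.items()):
                cells[str(c)] = _n_pct(int(table[li, ci]), len(g))
            rows.append(cells)

    continuous_row("age, median (IQR)", "age")

    def age_band(g):
        return g["age"].map(
            lambda a: next(
                _band_label(lo, hi) for lo, hi in AGE_BANDS if lo <= a <= hi
            )
        )

    categorical_rows(
        "age band", age_band, [_band_label(lo, hi) for lo, hi in AGE_BANDS]
    )
    categorical_rows("sex", lambda g: g["sex"], ["female", "male"])
    categorical_rows("care level", lambda g: g["care_level"], [1, 2, 3, 4, 5])
    continuous_row("n comorbidities, median (IQR)", "n_comorbidities")

    return pd.DataFrame(rows)


def _median_iqr(x) -> str:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def _n_pct(n: int, total: int) -> str:
    pct = 100.0 * n / total if total else 0.0
    return f"{n} ({pct:.1f})"


def check_conservation(
    flags: pd.DataFrame, labels, atol: float = 1e-9
) -> None:
    """Assert the two conservation identities; raises AssertionError if violated."""
    F, clusters, n_by, count = _counts(flags, labels)
    n = len(F)
    oe = observed_expected(flags, labels)
    excl = exclusivity(flags, labels)
    weights = n_by / n
    for disease in F.columns:
        if F[disease].sum() == 0:
            continue
        assert abs(float((weights * oe[disease]).sum()) - 1.0) < atol
        assert abs(float(excl[disease].sum()) - 1.0) < atol
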