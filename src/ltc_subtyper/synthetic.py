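"""Synthetic linked claims / certification / registry generator.

Real municipal long-term-care data are restricted, so the pipeline is
exercised end-to-end on a synthetic cohort with *planted* structure:

* a latent-class comorbidity model — each participant belongs to one of
  ``n_clusters`` subtypes, and given the subtype the 22 disease flags are
  independent Bernoulli draws with subtype-specific prevalences (a few
  "signature" diseases at high prevalence, the rest at a low background
  rate; one subtype is uniformly low, the "unspecified" analogue);
* exponential survival with a proportional-hazards structure — monthly
  hazard ``baseline_hazard * exp(log_hazard_ratio[cluster])``;
* a periodic care-need reassessment process — intervals drawn uniformly
  from 3–24 months, each reassessment moving the level down/same/up with
  subtype-specific probabilities;
* administrative censoring at the study end and optional loss to
  follow-up, modelled as removal from the insurance registry at a uniform
  random month.

The generator emits the three relational tables the cohort builder ingests
(claims with month-granularity service dates, care-need certifications,
insurance registry) together with a :class:`SyntheticTruth` record of the
planted labels and hazards, for parameter-recovery testing.

All randomness is drawn from per-person streams keyed by ``(seed,
person_id)``, so enlarging the cohort never perturbs existing participants
and identical parameters give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diseases import DISEASES, N_DISEASES, REPRESENTATIVE_CODES

#: First month of the index window (first certifications are placed from here).
STUDY_START = pd.Period("2014-10", "M")
#: Claims data begin 6 months earlier so the look-back window is always covered.
CLAIMS_START = STUDY_START - 6

LOOKBACK_MONTHS = 6
DAYS_PER_MONTH = 365.25 / 12.0

#: Default subtype names, mirroring the clinical subtypes the pipeline targets.
DEFAULT_CLUSTER_NAMES = [
    "musculoskeletal_sensory",
    "cardiac",
    "neurological",
    "respiratory_cancer",
    "insulin_dependent_diabetes",
    "unspecified",
]

#: Signature diseases per default subtype (the planted cluster structure).
DEFAULT_SIGNATURES: Dict[str, List[str]] = {
    "musculoskeletal_sensory": [
        "other_arthropathies",
        "dorsopathies",
        "visual_impairment",
        "hearing_impairment",
    ],
    "cardiac": [
        "ischemic_heart_disease",
        "arrhythmia",
        "heart_failure",
        "other_cardiac",
    ],
    "neurological": [
        "hemorrhagic_stroke",
        "ischemic_stroke",
        "other_cerebrovascular",
        "dementia",
        "parkinsons",
    ],
    "respiratory_cancer": ["cancer", "copd", "pneumonia", "other_lrt"],
    "insulin_dependent_diabetes": [
        "insulin_dependent_diabetes",
        "non_insulin_dependent_diabetes",
    ],
    "unspecified": [],
}


class ParameterError(ValueError):
    """Raised when GeneratorParams fail validation; names the offending field."""


@dataclass
class AgeDistribution:
    """Truncated-normal integer ages, with a per-cluster mean shift."""

    cluster_means: Sequence[float]
    sd: float = 6.0
    min_age: int = 65
    max_age: int = 105


@dataclass
class GeneratorParams:
    n_participants: int
    n_clusters: int = 6
    mixing_proportions: np.ndarray = None
    disease_prevalence: np.ndarray = None  # (n_clusters, 22)
    age_distribution: AgeDistribution = None
    female_probability: np.ndarray = None  # per cluster
    care_level_probs: np.ndarray = None  # (n_clusters, 5), levels 1..5
    baseline_hazard: float = 0.009  # deaths per person-month
    log_hazard_ratios: np.ndarray = None  # per cluster
    reassessment_interval_months: Tuple[int, int] = (3, 24)  # uniform integer
    transition_probs: np.ndarray = None  # (n_clusters, 3): improve/stay/deteriorate
    admin_censor_months: int = 78  # study end, months after STUDY_START
    lost_probability: float = 0.01
    seed: int = 0
    index_window_months: int = 54  # first certifications spread over this window
    noise_claim_probability: float = 0.05  # out-of-window claim per disease
    cluster_names: Optional[Sequence[str]] = None

    def validate(self) -> "GeneratorParams":
        if self.cluster_names is None:
            self.cluster_names = [f"cluster_{i + 1}" for i in range(self.n_clusters)]
        c = self.n_clusters
        if self.n_participants < 0:
            raise ParameterError("n_participants must be >= 0")
        if c < 1:
            raise ParameterError("n_clusters must be >= 1")
        mix = np.asarray(self.mixing_proportions, dtype=float)
        if mix.shape != (c,):
            raise ParameterError(f"mixing_proportions must have shape ({c},)")
        if abs(mix.sum() - 1.0) > 1e-12 or (mix < 0).any():
            raise ParameterError("mixing_proportions must be a simplex vector")
        prev = np.asarray(self.disease_prevalence, dtype=float)
        if prev.shape != (c, N_DISEASES):
            raise ParameterError(
                f"disease_prevalence must have shape ({c}, {N_DISEASES})"
            )
        if (prev < 0).any() or (prev > 1).any():
            raise ParameterError("disease_prevalence entries must be in [0, 1]")
        fem = np.asarray(self.female_probability, dtype=float)
        if fem.shape != (c,) or (fem < 0).any() or (fem > 1).any():
            raise ParameterError("female_probability must be c probabilities")
        care = np.asarray(self.care_level_probs, dtype=float)
        if care.shape != (c, 5):
            raise ParameterError(f"care_level_probs must have shape ({c}, 5)")
        if (care < 0).any() or np.abs(care.sum(axis=1) - 1.0).max() > 1e-12:
            raise ParameterError("care_level_probs rows must sum to 1")
        if not self.baseline_hazard > 0:
            raise ParameterError("baseline_hazard must be > 0")
        lhr = np.asarray(self.log_hazard_ratios, dtype=float)
        if lhr.shape != (c,):
            raise ParameterError(f"log_hazard_ratios must have shape ({c},)")
        lo, hi = self.reassessment_interval_months
        if not (3 <= lo <= hi <= 24):
            raise ParameterError(
                "reassessment_interval_months must satisfy 3 <= lo <= hi <= 24"
            )
        trans = np.asarray(self.transition_probs, dtype=float)
        if trans.shape != (c, 3):
            raise ParameterError(f"transition_probs must have shape ({c}, 3)")
        if (trans < 0).any() or np.abs(trans.sum(axis=1) - 1.0).max() > 1e-12:
            raise ParameterError("transition_probs rows must sum to 1")
        if not (0 <= self.lost_probability <= 1):
            raise ParameterError("lost_probability must be in [0, 1]")
        if self.admin_censor_months <= self.index_window_months:
            raise ParameterError(
                "admin_censor_months must exceed index_window_months"
            )
        ad = self.age_distribution
        if ad is None or len(ad.cluster_means) != c:
            raise ParameterError("age_distribution needs one mean per cluster")
        if ad.min_age < 60:
            raise ParameterError("age_distribution.min_age must be >= 60")
        if len(self.cluster_names) != c:
            raise ParameterError("cluster_names must have one name per cluster")
        return self


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-person cluster index and per-cluster log-HRs."""

    true_labels: np.ndarray  # (n,) integer cluster indices, 0-based
    true_log_hazard_ratios: np.ndarray  # (n_clusters,)
    cluster_names: Sequence[str]
    true_flags: Optional[np.ndarray] = None  # (n, 22) drawn disease flags


class CohortBundle(NamedTuple):
    claims: pd.DataFrame
    certifications: pd.DataFrame
    registry: pd.DataFrame
    truth: SyntheticTruth


def default_params(n_participants: int = 2000, seed: int = 0) -> GeneratorParams:
    """Default study conditions: 6 subtypes × 22 diseases.

    Mixing proportions, female fractions, care-level distributions and
    hazard ratios are set to the scale of a real municipal cohort of older
    adults starting long-term care; signature diseases have prevalence 0.90
    within their own subtype against a 0.05 background, and the
    "unspecified" subtype has no signatures.
    """
    names = list(DEFAULT_CLUSTER_NAMES)
    c = len(names)
    mix = np.array([1025, 729, 765, 421, 371, 1337], dtype=float)
    mix /= mix.sum()
    prev = np.full((c, N_DISEASES), 0.05)
    for i, name in enumerate(names):
        for disease in DEFAULT_SIGNATURES[name]:
            prev[i, DISEASES.index(disease)] = 0.90
    params = GeneratorParams(
        n_participants=n_participants,
        n_clusters=c,
        mixing_proportions=mix,
        disease_prevalence=prev,
        age_distribution=AgeDistribution(
            cluster_means=[84, 85, 83, 83, 80, 82], sd=6.0, min_age=65, max_age=105
        ),
        female_probability=np.array([0.758, 0.627, 0.573, 0.359, 0.461, 0.610]),
        care_level_probs=np.array(
            [
                [0.534, 0.272, 0.108, 0.070, 0.016],
                [0.465, 0.281, 0.143, 0.081, 0.030],
                [0.537, 0.252, 0.106, 0.080, 0.025],
                [0.406, 0.252, 0.159, 0.135, 0.048],
                [0.350, 0.210, 0.140, 0.210, 0.090],
                [0.599, 0.227, 0.083, 0.066, 0.025],
            ]
        ),
        baseline_hazard=0.009,
        log_hazard_ratios=np.log([1.0, 1.46, 0.97, 2.55, 1.48, 0.95]),
        transition_probs=np.array(
            [
                [0.25, 0.47, 0.28],
                [0.25, 0.41, 0.34],
                [0.16, 0.45, 0.39],
                [0.23, 0.41, 0.36],
                [0.30, 0.45, 0.25],
                [0.14, 0.43, 0.43],
            ]
        ),
        seed=seed,
        cluster_names=names,
    )
    return params.validate()


def _person_rng(seed: int, pid: int) -> np.random.Generator:
    # (seed, person) keyed stream: adding participants never perturbs others
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(pid,)))


_CLAIMS_COLS = ["person_id", "service_month", "diagnosis_code"]
_CERT_COLS = ["person_id", "certification_date", "care_need_level"]
_REG_COLS = ["person_id", "birth_date", "sex", "death_date", "disenrollment_date"]


def _fmt_person(pid: int) -> str:
    return f"P{pid:06d}"


def generate_cohort(params: GeneratorParams) -> CohortBundle:
    """Draw a full synthetic bundle (claims, certifications, registry, truth)."""
    params.validate()
    n = params.n_participants
    c = params.n_clusters
    codes = [REPRESENTATIVE_CODES[d] for d in DISEASES]
    lo, hi = params.reassessment_interval_months
    ad = params.age_distribution

    claims_rows: List[tuple] = []
    cert_rows: List[tuple] = []
    reg_rows: List[tuple] = []
    labels = np.empty(n, dtype=int)
    flag_matrix = np.zeros((n, N_DISEASES), dtype=bool)

    for pid in range(n):
        rng = _person_rng(params.seed, pid)
        person = _fmt_person(pid)
        k = int(rng.choice(c, p=params.mixing_proportions))
        labels[pid] = k

        offset = int(rng.integers(0, params.index_window_months))
        index_month = STUDY_START + offset
        index_date = index_month.start_time.date()

        age = int(
            np.clip(
                round(rng.normal(ad.cluster_means[k], ad.sd)), ad.min_age, ad.max_age
            )
        )
        extra_months = int(rng.integers(0, 12))
        birth_month = index_month - (age * 12 + extra_months)
        sex = "female" if rng.random() < params.female_probability[k] else "male"
        level = int(rng.choice(5, p=params.care_level_probs[k])) + 1

        # disease flags -> one in-window claim per flagged disease
        flags = rng.random(N_DISEASES) < params.disease_prevalence[k]
        flag_matrix[pid] = flags
        for d in np.flatnonzero(flags):
            month = index_month - int(rng.integers(0, LOOKBACK_MONTHS))
            claims_rows.append((person, str(month), codes[d]))
        # noise claims strictly before the look-back window (never change flags)
        noisy = rng.random(N_DISEASES) < params.noise_claim_probability
        for d in np.flatnonzero(noisy):
            month = index_month - LOOKBACK_MONTHS - int(rng.integers(0, 6))
            if month >= CLAIMS_START:
                claims_rows.append((person, str(month), codes[d]))

        horizon = params.admin_censor_months - offset  # months of potential follow-up
        hazard = params.baseline_hazard * np.exp(params.log_hazard_ratios[k])
        t_death = float(rng.exponential(1.0 / hazard))
        t_lost = np.inf
        if rng.random() < params.lost_probability:
            t_lost = int(rng.integers(1, horizon + 1))

        end = min(t_death, t_lost, horizon)
        death_date = ""
        disenroll_date = ""
        if t_death <= min(t_lost, horizon):
            death_date = (
                index_month.start_time + pd.Timedelta(days=t_death * DAYS_PER_MONTH)
            ).date().isoformat()
        elif t_lost <= horizon:
            disenroll_date = (index_month + int(t_lost)).start_time.date().isoformat()

        reg_rows.append(
            (
                person,
                birth_month.start_time.date().isoformat(),
                sex,
                death_date,
                disenroll_date,
            )
        )

        cert_rows.append((person, index_date.isoformat(), level))
        t, lvl = 0, level
        while True:
            t += int(rng.integers(lo, hi + 1))
            if t >= end:
                break
            move = int(rng.choice(3, p=params.transition_probs[k]))
            if move == 0:
                lvl = max(1, lvl - 1)
            elif move == 2:
                lvl = min(5, lvl + 1)
            cert_rows.append(
                (person, (index_month + t).start_time.date().isoformat(), lvl)
            )

    claims = pd.DataFrame(claims_rows, columns=_CLAIMS_COLS)
    certifications = pd.DataFrame(cert_rows, columns=_CERT_COLS)
    registry = pd.DataFrame(reg_rows, columns=_REG_COLS)
    truth = SyntheticTruth(
        true_labels=labels,
        true_log_hazard_ratios=np.asarray(params.log_hazard_ratios, dtype=float),
        cluster_names=list(params.cluster_names),
        true_flags=flag_matrix,
    )
    return CohortBundle(claims, certifications, registry, truth)


def generate_two_cities(
    params_a: GeneratorParams, params_b: GeneratorParams
) -> Tuple[CohortBundle, CohortBundle]:
    """Two independent bundles sharing disease definitions (replication design)."""
    params_a.validate()
    params_b.validate()
    return generate_cohort(params_a), generate_cohort(params_b)


def write_bundle(bundle: CohortBundle, outdir) -> Dict[str, Path]:
    """Write the bundle as four CSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": outdir / "claims.csv",
        "certifications": outdir / "certifications.csv",
        "registry": outdir / "registry.csv",
        "truth": outdir / "truth.csv",
    }
    bundle.claims.to_csv(paths["claims"], index=False)
    bundle.certifications.to_csv(paths["certifications"], index=False)
    bundle.registry.to_csv(paths["registry"], index=False)
    truth_df = pd.DataFrame(
        {
            "person_id": [_fmt_person(i) for i in range(len(bundle.truth.true_labels))],
            "true_cluster": bundle.truth.true_labels,
            "true_cluster_name": [
                bundle.truth.cluster_names[k] for k in bundle.truth.true_labels
            ],
        }
    )
    truth_df.to_csv(paths["truth"], index=False)
    return paths


def planted_selection_params(
    n_participants: int = 2000,
    seed: int = 0,
    signature_prevalence: float = 0.90,
    background_prevalence: float = 0.05,
) -> GeneratorParams:
    """Balanced 6-cluster design for cluster-number recovery studies.

    Equal mixing; the six clusters carry disjoint signature blocks covering
    all 22 diseases (sizes 4,4,4,4,3,3).  Unlike :func:`default_params` —
    whose mixing proportions and signature counts mirror a real cohort and
    include a background-only "unspecified" subtype whose central position
    the Xie-Beni separation term penalizes — every planted cluster here is
    well separated, which is the regime in which validity indices are
    expected to identify the planted number.
    """
    c = 6
    prev = np.full((c, N_DISEASES), background_prevalence)
    blocks = [(0, 4), (4, 8), (8, 12), (12, 16), (16, 19), (19, 22)]
    for i, (a, b) in enumerate(blocks):
        prev[i, a:b] = signature_prevalence
    params = GeneratorParams(
        n_participants=n_participants,
        n_clusters=c,
        mixing_proportions=np.full(c, 1.0 / c),
        disease_prevalence=prev,
        age_distribution=AgeDistribution(cluster_means=[83] * c),
        female_probability=np.full(c, 0.6),
        care_level_probs=np.tile(np.array([0.5, 0.25, 0.12, 0.09, 0.04]), (c, 1)),
        baseline_hazard=0.009,
        log_hazard_ratios=np.zeros(c),
        transition_probs=np.tile(np.array([0.2, 0.5, 0.3]), (c, 1)),
        seed=seed,
    )
    return params.validate()


def two_cluster_survival_params(
    n_participants: int,
    hazard_ratio: float = 1.8,
    baseline_hazard: float = 0.012,
    seed: int = 0,
) -> GeneratorParams:
    """A minimal two-cluster design for survival parameter-recovery studies.

    Disease prevalences are zero (no claims are needed), follow-up is long,
    and the second cluster carries the planted hazard ratio.
    """
    c = 2
    params = GeneratorParams(
        n_participants=n_participants,
        n_clusters=c,
        mixing_proportions=np.array([0.5, 0.5]),
        disease_prevalence=np.zeros((c, N_DISEASES)),
        age_distribution=AgeDistribution(cluster_means=[83, 83]),
        female_probability=np.array([0.6, 0.6]),
        care_level_probs=np.tile(
            np.array([0.5, 0.25, 0.12, 0.09, 0.04]), (c, 1)
        ),
        baseline_hazard=baseline_hazard,
        log_hazard_ratios=np.array([0.0, np.log(hazard_ratio)]),
        transition_probs=np.tile(np.array([0.2, 0.5, 0.3]), (c, 1)),
        lost_probability=0.0,
        noise_claim_probability=0.0,
        seed=seed,
    )
    return params.validate()
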