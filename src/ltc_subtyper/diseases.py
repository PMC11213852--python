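"""The 22 comorbidities used for subtyping, and diagnosis-code maps.

The Japanese Ministry of Health, Labour and Welfare lists 22 diseases
considered to potentially trigger the initiation of long-term care; every
participant is described by 22 binary flags, one per disease, derived from
ICD-10 diagnosis codes in medical claims.

A :class:`DiseaseMap` maps each disease name to a set of ICD-10 code
*prefixes*; a claim matches a disease when its diagnosis code starts with any
of the prefixes.  The default map shipped with the package uses standard
ICD-10 chapter prefixes and is an editable approximation — replace it with
your own code list (YAML, ``disease: [prefix, ...]``) for real analyses.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Dict, List

import yaml

#: Canonical ordering of the 22 diseases; all flag matrices use this order.
DISEASES: List[str] = [
    "hemorrhagic_stroke",
    "ischemic_stroke",
    "other_cerebrovascular",
    "ischemic_heart_disease",
    "arrhythmia",
    "heart_failure",
    "other_cardiac",
    "cancer",
    "copd",
    "pneumonia",
    "other_lrt",
    "rheumatoid_arthritis",
    "other_arthropathies",
    "dorsopathies",
    "dementia",
    "parkinsons",
    "insulin_dependent_diabetes",
    "non_insulin_dependent_diabetes",
    "visual_impairment",
    "hearing_impairment",
    "femur_fracture",
    "other_fractures",
]

N_DISEASES = len(DISEASES)

DiseaseMap = Dict[str, List[str]]

_PREFIX_RE = re.compile(r"^[A-Z0-9]+$")

# One representative ICD-10 code per disease.  The synthetic generator emits
# exactly these codes, so the generator's map and the claims it writes are
# consistent by construction.
REPRESENTATIVE_CODES: Dict[str, str] = {
    "hemorrhagic_stroke": "I61",
    "ischemic_stroke": "I63",
    "other_cerebrovascular": "I67",
    "ischemic_heart_disease": "I25",
    "arrhythmia": "I48",
    "heart_failure": "I50",
    "other_cardiac": "I42",
    "cancer": "C80",
    "copd": "J44",
    "pneumonia": "J18",
    "other_lrt": "J40",
    "rheumatoid_arthritis": "M06",
    "other_arthropathies": "M19",
    "dorsopathies": "M54",
    "dementia": "F03",
    "parkinsons": "G20",
    "insulin_dependent_diabetes": "E10",
    "non_insulin_dependent_diabetes": "E11",
    "visual_impairment": "H54",
    "hearing_impairment": "H90",
    "femur_fracture": "S72",
    "other_fractures": "S52",
}


class DiseaseMapError(ValueError):
    """Raised when a disease map fails validation."""


def validate_disease_map(disease_map: DiseaseMap) -> DiseaseMap:
    """Check a disease map: exactly the 22 canonical names, valid prefixes."""
    names = set(disease_map)
    expected = set(DISEASES)
    if names != expected:
        missing = sorted(expected - names)
        extra = sorted(names - expected)
        raise DiseaseMapError(
            f"disease map must contain exactly the 22 canonical diseases; "
            f"missing={missing}, unexpected={extra}"
        )
    for name, prefixes in disease_map.items():
        if not prefixes:
            raise DiseaseMapError(f"disease {name!r} has an empty prefix list")
        for p in prefixes:
            if not _PREFIX_RE.match(p):
                raise DiseaseMapError(
                    f"disease {name!r}: prefix {p!r} must be uppercase alphanumeric"
                )
    return disease_map


def generator_disease_map() -> DiseaseMap:
    """Disease map matching the synthetic generator's representative codes."""
    return {name: [code] for name, code in REPRESENTATIVE_CODES.items()}


def load_disease_map(path) -> DiseaseMap:
    """Load and validate a disease → prefix-list map from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DiseaseMapError(f"{path}: expected a mapping of disease -> prefix list")
    dm = {str(k): [str(p) for p in v] for k, v in raw.items()}
    return validate_disease_map(dm)


def default_disease_map() -> DiseaseMap:
    """The editable default ICD-10 prefix map shipped with the package.

    These are standard chapter-level prefixes per disease (e.g. femur
    fracture ⊇ ``S72``) and should be reviewed against the code list used by
    your claims system before real analyses.
    """
    ref = resources.files("ltc_subtyper").joinpath("data/disease_codes.yaml")
    with resources.as_file(ref) as path:
        return load_disease_map(path)
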