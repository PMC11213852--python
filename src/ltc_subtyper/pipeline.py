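"""One-command orchestration of the full subtyping pipeline.

Stages: cohort construction → MCA embedding → cluster-number selection →
consensus fuzzy c-means → subtype characterization → prognosis analyses.
Every artifact is written under the output directory together with a
manifest recording all effective parameters — including every default that
filled an unset field, so the analytically influential unstated choices
(MCA dimensionality, fuzzifier, candidate cluster numbers, consensus
scheme, horizon reading) are always visible in the outputs.  A rerun with
the same configuration reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment

from . import __version__
from .cohort import build_cohort, cooccurrence_network, read_certifications, read_claims, read_registry
from .diseases import DISEASES, default_disease_map, generator_disease_map, load_disease_map
from .fuzzy import consensus_fcm, hard_assign, select_c
from .mca import mca_fit, write_embedding
from .profiles import profile_clusters, summarize_clusters
from .prognosis import (
    VARIANTS,
    build_followup,
    careneed_outcome_table,
    choose_reference,
    classify_outcomes,
    cox_ph,
    deterioration_or,
    km_estimate,
    nelson_aalen,
    person_time_rates,
)
from .synthetic import STUDY_START, default_params, generate_cohort, write_bundle

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    # inputs: either a synthetic spec or three table paths
    synthetic: Optional[dict] = None  # {"n_participants": ..., "seed": ...}
    claims_path: Optional[str] = None
    certifications_path: Optional[str] = None
    registry_path: Optional[str] = None
    disease_map: str = "generator"  # "generator" | "default" | path to YAML
    lookback_months: int = 6
    mca_dim_rule: object = "scree"  # "scree" | int d | float cumulative-inertia threshold
    mca_benzecri: bool = False
    fuzzifier: float = 2.0
    c_candidates: Sequence[int] = tuple(range(2, 11))
    n_clusters: Optional[int] = None  # fixed c skips selection
    runs_per_c: int = 5
    consensus_runs: int = 100
    horizon_months: int = 24
    admin_censor_months: int = 78
    closest_rule: str = "within"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config field 'seed' is mandatory")
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        if self.synthetic is None:
            for name in ("claims_path", "certifications_path", "registry_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config field {name!r} is required "
                                     "unless 'synthetic' is given")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file: {p}")
        if self.disease_map not in ("generator", "default") and not Path(
            self.disease_map
        ).exists():
            raise FileNotFoundError(f"disease_map: no such file: {self.disease_map}")
        return self


def _effective_params(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)
    out["c_candidates"] = list(config.c_candidates)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": _effective_params(config),
        "diseases": list(DISEASES),
        "stages": [],
    }

    def stage(name):
        t0 = time.time()
        logger.info("stage %s: start", name)

        def done():
            # timings go to the log only, keeping the report byte-reproducible
            report["stages"].append(name)
            logger.info("stage %s: done in %.1fs", name, time.time() - t0)

        return done

    # ---- inputs ----------------------------------------------------------
    done = stage("inputs")
    if config.synthetic is not None:
        params = default_params(
            n_participants=int(config.synthetic.get("n_participants", 2000)),
            seed=int(config.synthetic.get("seed", config.seed)),
        )
        bundle = generate_cohort(params)
        write_bundle(bundle, outdir / "inputs")
        claims, certifications, registry = (
            bundle.claims,
            bundle.certifications,
            bundle.registry,
        )
        admin_censor = params.admin_censor_months
        report["synthetic"] = {
            "n_participants": params.n_participants,
            "seed": params.seed,
        }
    else:
        claims = read_claims(config.claims_path)
        certifications = read_certifications(config.certifications_path)
        registry = read_registry(config.registry_path)
        admin_censor = config.admin_censor_months
    if config.disease_map == "generator":
        dmap = generator_disease_map()
    elif config.disease_map == "default":
        dmap = default_disease_map()
    else:
        dmap = load_disease_map(config.disease_map)
    done()

    # ---- cohort ----------------------------------------------------------
    done = stage("cohort")
    try:
        cohort, tally, rejects = build_cohort(
            claims,
            certifications,
            registry,
            dmap,
            lookback_months=config.lookback_months,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("cohort", str(exc)) from exc
    if len(cohort) == 0:
        raise PipelineError("cohort", "no participants after exclusions")
    cohort.to_csv(outdir / "cohort.csv", index=False)
    pd.DataFrame(
        [{"screened": tally.screened, "included": tally.included, **tally.counts}]
    ).to_csv(outdir / "exclusions.csv", index=False)
    rejects.to_csv(outdir / "rejects.csv", index=False)
    nodes, edges = cooccurrence_network(cohort)
    nodes.to_csv(outdir / "network_nodes.csv", index=False)
    edges.to_csv(outdir / "network_edges.csv", index=False)
    report["cohort"] = {
        "screened": tally.screened,
        "included": tally.included,
        "exclusions": tally.counts,
    }
    done()

    # ---- MCA -------------------------------------------------------------
    done = stage("mca")
    embedding = mca_fit(
        cohort[DISEASES], config.mca_dim_rule, benzecri=config.mca_benzecri
    )
    write_embedding(
        embedding,
        cohort["person_id"],
        outdir / "embedding.csv",
        outdir / "eigenvalues.csv",
    )
    report["mca"] = {
        "kept_dims": embedding.kept_dims,
        "cumulative_inertia": float(
            np.cumsum(embedding.inertia_share)[embedding.kept_dims - 1]
        ),
        "dropped_diseases": list(embedding.dropped_diseases),
    }
    done()

    # ---- clustering ------------------------------------------------------
    done = stage("clustering")
    X = embedding.coordinates
    if config.n_clusters is not None:
        chosen_c = int(config.n_clusters)
        selection = None
    else:
        selection = select_c(
            X,
            c_candidates=config.c_candidates,
            runs_per_c=config.runs_per_c,
            m=config.fuzzifier,
            seed=config.seed,
        )
        chosen_c = selection.chosen_c
        pd.DataFrame(
            {
                "c": selection.candidates,
                "objective": selection.objectives,
                "xie_beni": selection.xie_beni_values,
            }
        ).to_csv(outdir / "selection.csv", index=False)
    partition = consensus_fcm(
        X,
        chosen_c,
        n_runs=config.consensus_runs,
        m=config.fuzzifier,
        seed=config.seed,
    )
    labels = hard_assign(partition)
    membership = pd.DataFrame(
        partition.membership,
        columns=[f"cluster_{i + 1}" for i in range(chosen_c)],
    )
    membership.insert(0, "person_id", cohort["person_id"].to_numpy())
    membership.to_csv(outdir / "membership.csv", index=False)
    pd.DataFrame(
        {"person_id": cohort["person_id"], "cluster": labels}
    ).to_csv(outdir / "labels.csv", index=False)
    sizes = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    report["clustering"] = {
        "chosen_c": chosen_c,
        "cluster_sizes": sizes,
        "consensus_runs": config.consensus_runs,
    }
    if selection is not None:
        report["clustering"]["xie_beni"] = dict(
            zip(selection.candidates, selection.xie_beni_values)
        )
    done()

    # ---- characterization ------------------------------------------------
    done = stage("characterization")
    profile = profile_clusters(cohort[DISEASES], labels)
    # Fig.2-shaped export: diseases × clusters, prevalence with flag marks
    fig2 = profile.prevalence.T.copy()
    fig2.columns = [f"cluster_{c}" for c in fig2.columns]
    for c, flagged in profile.flagged.items():
        fig2[f"cluster_{c}_flag"] = [
            flagged.get(d, "") for d in fig2.index
        ]
    fig2.index.name = "disease"
    fig2.to_csv(outdir / "prevalence_matrix.csv")
    profile.observed_expected.to_csv(outdir / "observed_expected.csv")
    profile.exclusivity.to_csv(outdir / "exclusivity.csv")
    summary = summarize_clusters(cohort, labels)
    summary.to_csv(outdir / "cluster_summary.csv", index=False)
    report["characterization"] = {
        "flagged": {str(c): d for c, d in profile.flagged.items()}
    }
    roles = {
        c: ("unspecified" if not profile.flagged[c] else "subtype")
        for c in profile.flagged
    }
    done()

    # ---- prognosis -------------------------------------------------------
    done = stage("prognosis")
    study_end = STUDY_START + admin_censor
    followup = build_followup(cohort, certifications, registry, study_end)
    rates = person_time_rates(followup.table, labels)
    reference = choose_reference(labels, roles)
    covariates = cohort[["age", "sex", "care_level"]]
    hr_unadj = cox_ph(followup.table, labels, None, reference=reference)
    hr_adj = cox_ph(followup.table, labels, covariates, reference=reference)
    table2 = rates.copy()
    for name, ests in (("unadjusted_hr", hr_unadj), ("adjusted_hr", hr_adj)):
        col, lo, hi = [], [], []
        bymap = {e.contrast[0]: e for e in ests}
        for c in table2["cluster"]:
            if c == reference:
                col.append(1.0), lo.append(np.nan), hi.append(np.nan)
            else:
                e = bymap[c]
                col.append(e.estimate), lo.append(e.ci_low), hi.append(e.ci_high)
        table2[name] = col
        table2[f"{name}_low"] = lo
        table2[f"{name}_high"] = hi
    table2.to_csv(outdir / "mortality_table.csv", index=False)
    for nm, curves in (("km", km_estimate(followup.table, labels)),
                       ("na", nelson_aalen(followup.table, labels))):
        frames = []
        for c, df in curves.items():
            df = df.copy()
            df.insert(0, "cluster", c)
            frames.append(df)
        pd.concat(frames).to_csv(outdir / f"{nm}_curves.csv", index=False)

    cutoff = study_end - config.horizon_months
    per_person = classify_outcomes(
        followup,
        cohort,
        horizon_months=config.horizon_months,
        enrollment_cutoff=cutoff,
        closest_rule=config.closest_rule,
    )
    label_by_person = pd.Series(labels, index=cohort["person_id"])
    sub_labels = label_by_person.loc[per_person["person_id"]].to_numpy()
    outcome_table = careneed_outcome_table(per_person, sub_labels)
    outcome_table.to_csv(outdir / "careneed_outcomes.csv", index=False)
    or_rows = []
    for variant in VARIANTS:
        for adjustment in ("none", "model1", "model2"):
            ests = deterioration_or(
                per_person,
                sub_labels,
                variant=variant,
                adjustment=adjustment,
                reference=reference,
            )
            for e in ests:
                or_rows.append(
                    {
                        "variant": variant,
                        "adjustment": adjustment,
                        "cluster": e.contrast[0],
                        "reference": e.contrast[1],
                        "odds_ratio": e.estimate,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                    }
                )
    or_table = pd.DataFrame(or_rows)
    or_table.to_csv(outdir / "deterioration_or.csv", index=False)
    report["prognosis"] = {
        "reference_cluster": int(reference),
        "mortality_rates": rates.to_dict(orient="records"),
        "adjusted_hr": {
            str(e.contrast[0]): [e.estimate, e.ci_low, e.ci_high] for e in hr_adj
        },
        "deterioration_or": or_rows,
        "restricted_n": int(len(per_person)),
    }
    done()

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(
            {"version": __version__, "parameters": report["parameters"]},
            fh,
            indent=2,
            sort_keys=True,
            default=_jsonify,
        )
    logger.info("pipeline complete: %s", report_path)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Two-city replication comparison

def compare_cities(report_a: dict, report_b: dict) -> dict:
    """Match flagged-disease sets across two runs and score the replication.

    Clusters are matched one-to-one by maximal Jaccard overlap of their
    flagged disease sets (Hungarian assignment); returns the per-match
    Jaccard similarities and their mean.
    """
    if report_a.get("diseases") != report_b.get("diseases"):
        raise ValueError("reports use different disease lists")
    fa = {k: set(v) for k, v in report_a["characterization"]["flagged"].items()}
    fb = {k: set(v) for k, v in report_b["characterization"]["flagged"].items()}
    ka, kb = sorted(fa), sorted(fb)
    J = np.zeros((len(ka), len(kb)))
    for i, a in enumerate(ka):
        for j, b in enumerate(kb):
            union = fa[a] | fb[b]
            J[i, j] = (len(fa[a] & fb[b]) / len(union)) if union else 1.0
    rows, cols = linear_sum_assignment(-J)
    matches = [
        {
            "cluster_a": ka[i],
            "cluster_b": kb[j],
            "jaccard": float(J[i, j]),
            "flagged_a": sorted(fa[ka[i]]),
            "flagged_b": sorted(fb[kb[j]]),
        }
        for i, j in zip(rows, cols)
    ]
    return {
        "matches": matches,
        "mean_jaccard": float(np.mean([m["jaccard"] for m in matches])),
    }
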