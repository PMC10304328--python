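"""End-to-end orchestration: simulate -> reduce -> cluster -> fit -> report.

A single run is driven by a :class:`RunConfig`; one root seed fans out
to stage-specific deterministic sub-seeds so that stages can be rerun
alone.  Every intermediate artifact is persisted to the output
directory, and rerunning with an identical config reproduces identical
outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SynthConfig
from .factors import (
    FactorModel,
    average_person_indicators,
    fit_factor_model,
    loading_report,
    score_rows,
    select_n_factors,
    vss_curve,
)
from .gee import GEEFit, RiskTable, build_design, fit_gee, odds_table, risk_table
from .grouping import ClusterModel, fit_kmeans, silhouette_curve
from .io import read_claims, read_facilities, write_claims, write_facilities, write_table
from .synth import GroundTruth, simulate

log = logging.getLogger("snfrisk")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`SynthConfig`) or the pair
    ``claims_path``/``facilities_path`` must be provided.
    """

    simulate: SynthConfig | None = None
    claims_path: str | None = None
    facilities_path: str | None = None
    k_patient: int | str = 12  # paper-style pinned default, or "auto"
    k_snf: int | str = 3
    k_patient_candidates: tuple[int, ...] = tuple(range(2, 16))
    k_snf_candidates: tuple[int, ...] = tuple(range(1, 7))
    vss_complexity: int = 1
    n_groups: int | str = "auto"
    K_candidates: tuple[int, ...] = tuple(range(2, 9))
    n_restarts: int = 50
    outcomes: tuple[str, ...] = ("rehosp60", "death60")
    adjusted: tuple[bool, ...] = (False, True)
    cov_type: str = "nested"
    loading_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.claims_path is not None and self.facilities_path is not None
        if (self.simulate is None) == (not has_paths):
            raise ValueError(
                "provide exactly one of a simulate block or claims/facility paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SynthConfig(**raw["simulate"])
        for key in ("k_patient_candidates", "k_snf_candidates", "K_candidates",
                    "outcomes", "adjusted"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0])).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Artifacts and summaries of one pipeline run."""

    out_dir: Path
    patient_model: FactorModel
    snf_model: FactorModel
    cluster_model: ClusterModel
    fits: dict[tuple[str, bool], GEEFit]
    risk_tables: dict[tuple[str, bool], RiskTable]
    provenance: dict = field(default_factory=dict)
    ground_truth: GroundTruth | None = None

    def summary(self) -> dict:
        return {
            "n_patient_factors": self.patient_model.n_factors,
            "n_snf_factors": self.snf_model.n_factors,
            "n_groups": self.cluster_model.K,
            "group_sizes": {int(k): int(v)
                            for k, v in self.cluster_model.group_sizes().items()},
            "mean_silhouette": self.cluster_model.mean_silhouette,
            "silhouette_by_K": self.cluster_model.silhouette_by_K,
            "patient_vss_by_k": self.patient_model.vss_by_k,
            "snf_vss_by_k": self.snf_model.vss_by_k,
            "models": {
                f"{outcome}_{'adjusted' if adj else 'unadjusted'}": {
                    "rho_state": fit.rho_state,
                    "rho_person": fit.rho_person,
                    "n_obs": fit.n_obs,
                    "wald_p": self.risk_tables[(outcome, adj)]
                    .wald.set_index("factor")["p"].to_dict(),
                }
                for (outcome, adj), fit in self.fits.items()
            },
            "provenance": self.provenance,
        }


def _resolve_k(value, X, candidates, complexity):
    curve = {}
    if value == "auto":
        k = select_n_factors(X, candidates, complexity=complexity)
        curve = vss_curve(X, candidates, complexity=complexity)
    else:
        k = int(value)
    return k, curve


def run_pipeline(config: RunConfig, out_dir) -> RunReport:
    """Execute all stages in order, persisting every intermediate artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except Exception as err:
        log.error("pipeline failed: %s", err)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> RunReport:
    root = np.random.SeedSequence(config.seed)
    seed_sim, seed_cluster = root.spawn(2)

    truth = None
    if config.simulate is not None:
        log.info("stage simulate: generating synthetic claims")
        sim_seed = int(seed_sim.generate_state(1)[0] % (2**31))
        claims, facilities, truth = simulate(config.simulate, seed=sim_seed)
        write_claims(claims, out / "claims.csv")
        write_facilities(facilities, out / "facilities.csv")
        truth.to_json(out / "ground_truth.json")
    else:
        log.info("stage read: loading claims and facility tables")
        claims = read_claims(config.claims_path)
        facilities = read_facilities(config.facilities_path)

    # --- dimension reduction -------------------------------------------------
    log.info("stage reduce: factor analysis of patient and facility variables")
    averaged = average_person_indicators(claims)
    k_pat, pat_curve = _resolve_k(config.k_patient, averaged,
                                  config.k_patient_candidates, config.vss_complexity)
    patient_model = fit_factor_model(averaged, k_pat)
    patient_model.vss_by_k = pat_curve

    fac_vars = facilities.drop(columns=["snf_id"])
    k_snf, snf_curve = _resolve_k(config.k_snf, fac_vars,
                                  config.k_snf_candidates, config.vss_complexity)
    snf_model = fit_factor_model(fac_vars, k_snf)
    snf_model.vss_by_k = snf_curve

    patient_model.to_json(out / "patient_model.json")
    snf_model.to_json(out / "snf_model.json")
    write_table(loading_report(patient_model, config.loading_threshold),
                out / "patient_loadings.csv")
    write_table(loading_report(snf_model, config.loading_threshold),
                out / "snf_loadings.csv")

    indicator_cols = patient_model.variable_names
    claim_scores = score_rows(patient_model, claims[indicator_cols])
    snf_scores = score_rows(snf_model, fac_vars)
    snf_scores.index = facilities["snf_id"].to_numpy()
    claim_scores.insert(0, "claim_id", claims["claim_id"].to_numpy())
    write_table(claim_scores, out / "claim_scores.csv")
    claim_scores = claim_scores.drop(columns="claim_id")
    snf_out = snf_scores.copy()
    snf_out.insert(0, "snf_id", snf_out.index)
    write_table(snf_out, out / "snf_scores.csv")

    # --- categorization ------------------------------------------------------
    log.info("stage cluster: k-means grouping of facilities")
    cluster_seed = int(seed_cluster.generate_state(1)[0] % (2**31))
    sil_curve: dict[int, float] = {}
    if config.n_groups == "auto":
        sil_curve = silhouette_curve(snf_scores, config.K_candidates,
                                     seed=cluster_seed, n_restarts=config.n_restarts)
        K = max(sil_curve, key=lambda k: (sil_curve[k], -k))
    else:
        K = int(config.n_groups)
    cluster_model = fit_kmeans(snf_scores, K, seed=cluster_seed,
                               n_restarts=config.n_restarts)
    cluster_model.silhouette_by_K = sil_curve
    cluster_model.to_json(out / "cluster_model.json")
    labels = cluster_model.labels.rename_axis("snf_id").reset_index()
    write_table(labels, out / "snf_groups.csv")

    # --- risk prediction -----------------------------------------------------
    log.info("stage fit: GEE risk models")
    fits: dict[tuple[str, bool], GEEFit] = {}
    tables: dict[tuple[str, bool], RiskTable] = {}
    for outcome in config.outcomes:
        for adjusted in config.adjusted:
            design = build_design(claims, claim_scores, cluster_model.labels,
                                  outcome, controls_on=adjusted)
            fit = fit_gee(design, cov_type=config.cov_type)
            rt = risk_table(fit, design)
            tag = f"{outcome}_{'adjusted' if adjusted else 'unadjusted'}"
            fit.to_json(out / f"gee_{tag}.json")
            rt.to_json(out / f"risks_{tag}.json")
            write_table(rt.frame, out / f"risks_{tag}.csv")
            write_table(odds_table(fit).reset_index(names="term"),
                        out / f"odds_{tag}.csv")
            fits[(outcome, adjusted)] = fit
            tables[(outcome, adjusted)] = rt
            log.info("fitted %s (rho_state=%.4f, rho_person=%.4f)",
                     tag, fit.rho_state, fit.rho_person)

    provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "snfrisk_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    report = RunReport(
        out_dir=out,
        patient_model=patient_model,
        snf_model=snf_model,
        cluster_model=cluster_model,
        fits=fits,
        risk_tables=tables,
        provenance=provenance,
        ground_truth=truth,
    )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.summary(), fh, indent=2, default=float)
    return report
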