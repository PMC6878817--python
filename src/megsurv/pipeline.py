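"""End-to-end orchestration: discovery then prognostic evaluation.

These functions are the programmatic face of the command-line interface
and of the test suite's end-to-end runs.  Each takes an explicit
configuration object so every threshold and permutation count is recorded
in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import search as sg
from . import survival as sv
from .io import AlterationMatrix, ClinicalTable, align

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DiscoveryOutput", "PrognosisOutput",
           "run_discovery", "run_prognosis"]


@dataclass
class RunConfig:
    """All tunable parameters of the two-stage analysis."""

    max_set_size: int = 5            # K, largest gene-set size searched
    beam_width: int = 20
    n_perm_gnh: int = 200            # permutations for the global-null test
    n_perm_expand: int = 200         # permutations per expansion calibration
    n_perm_survival: int = 1000      # permutations for the adjusted log-rank p
    alpha: float = 0.05
    fpr_target: float = 0.05         # expansion false-positive target
    min_feature_count: int = 2       # drop features mutated in fewer patients
    entry: float = 0.05              # stepwise entry (score test)
    stay: float = 0.10               # stepwise retention (Wald test)
    horizon_months: float | None = 60.0
    age_cut: float = 50.0
    min_group_frac: float = 0.10
    cutoff_override: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DiscoveryOutput:
    search: sg.SearchResult
    gnh: sg.GnhResult
    collection: sg.MegsCollection
    network: object


@dataclass
class PrognosisOutput:
    univariate: list[sv.CoxFit]
    multivariable: sv.CoxFit
    stratification: sv.RiskStratification | None
    profile_names: list[str]
    screened_in: list[str] = field(default_factory=list)


def run_discovery(matrix: AlterationMatrix, config: RunConfig) -> DiscoveryOutput:
    """Beam search, global-null permutation test, model selection, network."""
    cache = sg.ScoreCache()
    result = sg.multipath_search(matrix, K=config.max_set_size,
                                 beam_width=config.beam_width, cache=cache,
                                 min_count=config.min_feature_count)
    gnh = sg.gnh_test(matrix, K=config.max_set_size,
                      beam_width=config.beam_width,
                      n_perm=config.n_perm_gnh, seed=config.seed,
                      cache=cache, min_count=config.min_feature_count)
    logger.info("GNH: theta=%.4g global_p=%.4g Q=%s",
                gnh.theta, gnh.global_p, gnh.q_values)
    if gnh.global_p < config.alpha:
        collection = sg.model_selection(
            matrix, result, gnh, alpha=config.alpha,
            K=config.max_set_size, n_perm=config.n_perm_expand,
            fpr_target=config.fpr_target, seed=config.seed + 1,
            cache=cache, min_count=config.min_feature_count)
    else:
        logger.info("global null not rejected; no sets reported")
        collection = sg.MegsCollection(sets=[], p0_by_size={},
                                       alpha=config.alpha)
    network = sg.build_network(collection)
    return DiscoveryOutput(search=result, gnh=gnh, collection=collection,
                           network=network)


def run_prognosis(matrix: AlterationMatrix, clinical: ClinicalTable,
                  gene_sets: list[list[str]],
                  config: RunConfig) -> PrognosisOutput:
    """Profile transform, univariate screen, stepwise model, LOOCV strata.

    Each discovered gene set becomes a binary profile covariate; profiles
    passing the univariate screen at ``alpha`` compete with age and gender
    in the stepwise model; the final model's covariates drive the risk
    stratification.  Raises if no profile passes the screen.
    """
    matrix, clinical = align(matrix, clinical)
    profile_names = []
    extra = {} if clinical.extra is None else dict(
        (c, clinical.extra[c].to_numpy()) for c in clinical.extra.columns)
    for i, genes in enumerate(gene_sets):
        name = f"megs_{i + 1}"
        extra[name] = sv.megs_profile(matrix, list(genes)).astype(float)
        profile_names.append(name)
    clinical = ClinicalTable(
        patient_ids=clinical.patient_ids, time=clinical.time,
        event=clinical.event, age=clinical.age, gender=clinical.gender,
        extra=pd.DataFrame(extra, index=clinical.patient_ids))

    base_covs = [c for c in ("age", "gender")
                 if getattr(clinical, c) is not None]
    univariate = []
    screened: list[str] = []
    for name in base_covs + profile_names:
        fit = sv.fit_cox(clinical, [name], config.horizon_months,
                         config.age_cut)
        univariate.append(fit)
        if name in profile_names and fit.p[0] < config.alpha:
            screened.append(name)
    if not screened:
        raise ValueError("no gene-set profile passed the univariate screen")

    multivariable = sv.stepwise_cox(
        clinical, base_covs + screened, entry=config.entry, stay=config.stay,
        horizon_months=config.horizon_months, age_cut=config.age_cut)

    stratification = sv.loocv_stratify(
        clinical, multivariable.names, n_perm=config.n_perm_survival,
        seed=config.seed + 2, horizon_months=config.horizon_months,
        age_cut=config.age_cut, min_group_frac=config.min_group_frac,
        cutoff_override=config.cutoff_override)
    return PrognosisOutput(univariate=univariate,
                           multivariable=multivariable,
                           stratification=stratification,
                           profile_names=profile_names,
                           screened_in=screened)
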