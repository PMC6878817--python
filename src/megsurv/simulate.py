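"""Synthetic alteration matrices with planted mutually exclusive gene sets
and matched proportional-hazards survival data.

The generator draws each patient row from the same two-component mixture
the discovery statistics fit: with probability ``gamma`` the patient is
*covered* and exactly one member gene mutates (gene ``k`` with probability
``pi_k / sum(pi)``, background suppressed); otherwise the member genes
mutate independently at their background rates.  Passenger genes are
independent Bernoulli columns throughout.  Survival times follow a
baseline exponential or Weibull hazard scaled by ``exp(sum beta_j x_j)``
with independent censoring.

Every public entry point takes one integer seed; internal streams are
split deterministically so fixtures are reproducible across platforms.
The ground truth (who was covered, which member fired, the planted
coefficients) is returned as a separate sidecar dictionary that the
discovery and survival code never sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlterationMatrix, ClinicalTable

__all__ = [
    "PlantedMegsSpec",
    "SurvivalSpec",
    "simulate_matrix",
    "simulate_survival",
    "make_gbm_like_fixture",
]


@dataclass
class PlantedMegsSpec:
    """One planted MEGS plus independent passenger genes."""

    members: list[str]
    gamma: float
    pi: list[float]
    n_patients: int
    passengers: list[str] = field(default_factory=list)
    passenger_rates: list[float] = field(default_factory=list)
    # The mixture's exclusive component multiplies the fired gene's rate by
    # the background terms of the remaining genes, so a covered patient can
    # still carry background mutations on non-fired members.  That is the
    # default; background_leak=False suppresses them (exactly one mutation
    # per covered patient), a stricter exclusivity than the fitted model.
    background_leak: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if len(self.pi) != len(self.members):
            raise ValueError("pi must have one rate per member")
        if any(not 0.0 < r < 1.0 for r in self.pi):
            raise ValueError("member background rates must lie in (0, 1)")
        if len(self.passenger_rates) != len(self.passengers):
            raise ValueError("one rate per passenger required")
        if any(not 0.0 < r < 1.0 for r in self.passenger_rates):
            raise ValueError("passenger rates must lie in (0, 1)")


@dataclass
class SurvivalSpec:
    """Proportional-hazards generative model for event times."""

    baseline_rate: float = 0.05          # exponential rate per month
    weibull_shape: float | None = None   # None = exponential
    coefficients: dict[str, float] = field(default_factory=dict)
    censor_max_months: float | None = 80.0   # uniform(0, max) censoring
    censor_rate: float | None = None         # exponential censoring instead
    horizon_months: float | None = None      # truncate follow-up

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if self.weibull_shape is not None and self.weibull_shape <= 0:
            raise ValueError("Weibull shape must be positive")


def _planted_columns(spec: PlantedMegsSpec, rng: np.random.Generator):
    """Member columns plus the coverage/fired-gene ground truth."""
    N, m = spec.n_patients, len(spec.members)
    pi = np.asarray(spec.pi, dtype=float)
    covered = rng.random(N) < spec.gamma
    fired = np.full(N, -1)
    vals = np.zeros((N, m), dtype=np.int8)

    bg = (rng.random((N, m)) < pi).astype(np.int8)
    vals[~covered] = bg[~covered]
    if covered.any():
        p = pi / pi.sum()
        fired[covered] = rng.choice(m, size=int(covered.sum()), p=p)
        vals[covered, fired[covered]] = 1
        if spec.background_leak:
            leak = bg[covered]
            vals[covered] |= leak
    return vals, covered, fired


def simulate_matrix(spec: PlantedMegsSpec, seed: int):
    """Alteration matrix drawn from the planted mixture.

    Returns (matrix, truth) where ``truth`` records per-patient coverage
    and fired member, and the generating parameters.
    """
    rng = np.random.default_rng(seed)
    vals_m, covered, fired = _planted_columns(spec, rng)
    vals_p = (rng.random((spec.n_patients, len(spec.passengers)))
              < np.asarray(spec.passenger_rates, dtype=float)).astype(np.int8)
    values = np.concatenate([vals_m, vals_p], axis=1)
    labels = list(spec.members) + list(spec.passengers)
    ids = [f"PT{i:04d}" for i in range(spec.n_patients)]
    matrix = AlterationMatrix(patient_ids=ids, feature_labels=labels,
                              values=values)
    truth = {
        "members": list(spec.members),
        "gamma": spec.gamma,
        "pi": list(map(float, spec.pi)),
        "covered": covered.astype(int).tolist(),
        "fired_member": fired.tolist(),
        "seed": seed,
    }
    return matrix, truth


def simulate_survival(covariates: pd.DataFrame, spec: SurvivalSpec,
                      seed: int) -> ClinicalTable:
    """Event times under the proportional-hazards model of ``spec``.

    ``covariates`` is indexed by patient id; every key of
    ``spec.coefficients`` must be one of its columns.  Columns named
    ``age``/``gender`` populate the dedicated clinical fields, all others
    go to ``extra``.
    """
    rng = np.random.default_rng(seed)
    N = len(covariates)
    eta = np.zeros(N)
    for name, beta in spec.coefficients.items():
        if name not in covariates.columns:
            raise KeyError(f"coefficient for unknown covariate {name!r}")
        x = covariates[name].to_numpy(dtype=float)
        if name == "age":          # hazard acts on the dichotomized scale
            x = (x >= 50).astype(float)
        eta += beta * x
    scale = np.exp(eta)

    u = rng.random(N)
    if spec.weibull_shape is None:
        t_event = -np.log(u) / (spec.baseline_rate * scale)
    else:
        k = spec.weibull_shape
        t_event = (-np.log(u) / (spec.baseline_rate * scale)) ** (1.0 / k)

    if spec.censor_rate is not None:
        t_cens = rng.exponential(1.0 / spec.censor_rate, N)
    elif spec.censor_max_months is not None:
        t_cens = rng.uniform(0.0, spec.censor_max_months, N)
    else:
        t_cens = np.full(N, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if spec.horizon_months is not None:
        event = np.where(time > spec.horizon_months, 0, event)
        time = np.minimum(time, spec.horizon_months)
    time = np.maximum(time, 1e-3)
    if event.sum() == 0:
        import warnings
        warnings.warn("simulated dataset contains no events")

    return ClinicalTable(
        patient_ids=[str(i) for i in covariates.index],
        time=time,
        event=event,
        age=(covariates["age"].to_numpy(dtype=float)
             if "age" in covariates.columns else None),
        gender=(covariates["gender"].to_numpy(dtype=float)
                if "gender" in covariates.columns else None),
        extra=covariates.drop(columns=[c for c in ("age", "gender")
                                       if c in covariates.columns]),
    )


# Fixture layout: three planted MEGSs among passengers, with a survival
# effect attached to the first set's mutation profile.  Shapes and rates
# emulate a glioblastoma alteration panel: 261 patients, planted sets of
# sizes 3/3/4, ~6% passenger rates, ~81% of patients dying within the
# 5-year horizon.  The sets are disjoint and their coverage mechanisms are
# independent, so each is the unique exclusive structure on its own genes
# and recovery is well defined; genes of different sets co-occur freely,
# which is what stops the search from merging them.
FIXTURE_N = 261
FIXTURE_SETS = (
    {"members": ("S1A(D)", "S1B(A)", "S1C"), "gamma": 0.75},
    {"members": ("S2A", "S2B(A)", "S2C"), "gamma": 0.70},
    {"members": ("S3A", "S3B", "S3C(D)", "S3D(A)"), "gamma": 0.65},
)
FIXTURE_N_PASSENGERS = 27
FIXTURE_PASSENGER_RATE = 0.06
FIXTURE_MEMBER_PI = 0.04
FIXTURE_HR = 1.9
FIXTURE_BASELINE = 0.031


def make_gbm_like_fixture(seed: int):
    """A full synthetic study: matrix, clinical table and truth sidecar.

    Three disjoint MEGSs (sizes 3, 3, 4) are planted among independent
    passengers, each drawn from the exclusivity mixture with its own
    coverage; survival carries a planted hazard ratio on the first set's
    profile plus age and gender effects, tuned so roughly 81% of patients
    die within 5 years.
    """
    rng = np.random.default_rng(seed)
    N = FIXTURE_N

    blocks = []
    all_members: list[str] = []
    for s in FIXTURE_SETS:
        m = len(s["members"])
        covered = rng.random(N) < s["gamma"]
        vals = (rng.random((N, m)) < FIXTURE_MEMBER_PI).astype(np.int8)
        fired = rng.integers(0, m, size=int(covered.sum()))
        vals[np.flatnonzero(covered), fired] = 1
        blocks.append(vals)
        all_members.extend(s["members"])
    values = np.concatenate(blocks, axis=1)

    passengers = [f"PASS{j:02d}" for j in range(FIXTURE_N_PASSENGERS)]
    vals_p = (rng.random((N, FIXTURE_N_PASSENGERS))
              < FIXTURE_PASSENGER_RATE).astype(np.int8)
    matrix = AlterationMatrix(
        patient_ids=[f"PT{i:04d}" for i in range(N)],
        feature_labels=all_members + passengers,
        values=np.concatenate([values, vals_p], axis=1),
    )

    prognostic = list(FIXTURE_SETS[0]["members"])
    profile = (matrix.columns(prognostic).max(axis=1) > 0).astype(float)
    age = rng.uniform(21, 89, N)
    gender = (rng.random(N) < 0.65).astype(float)
    cov = pd.DataFrame({"age": age, "gender": gender, "megs": profile},
                       index=matrix.patient_ids)
    surv_spec = SurvivalSpec(
        baseline_rate=FIXTURE_BASELINE,
        coefficients={"megs": float(np.log(FIXTURE_HR)),
                      "age": 0.45, "gender": 0.30},
        censor_max_months=90.0,
    )
    clinical = simulate_survival(cov, surv_spec,
                                 seed=int(rng.integers(2 ** 31)))

    truth = {
        "planted_sets": [sorted(s["members"]) for s in FIXTURE_SETS],
        "prognostic_set": sorted(prognostic),
        "hr": FIXTURE_HR,
        "coefficients": surv_spec.coefficients,
        "gammas": [s["gamma"] for s in FIXTURE_SETS],
        "seed": seed,
    }
    return matrix, clinical, truth
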