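"""Vancomycin clearance model with lognormal inter-individual variability.

The structural model for an adult patient is

    CL = θ_base · e^η1  +  θ_renal_max · (1 − exp(−k_clcr · e^η2 · CLcr)) · f(age)

with CL in L/h, CLcr in mL/min, and f(age) = age_coef^(age / age_ref) a
maturation/decline factor (age_coef < 1 makes clearance decrease with age).
η1 ~ N(0, ω1²) and η2 ~ N(0, ω2²) are per-patient random effects, so e^η is
lognormal with median 1. The population ("typical patient") prediction is
the model at η = 0.

Published fixed effects: θ_base = 1.71 L/h, θ_renal_max = 8.31 L/h,
k_clcr = 0.0113 per mL/min, age_coef = 0.475, age_ref = 72 y,
ω1 = 0.415, ω2 = 0.381.

Random effects can be drawn directly from the two normals or via a
Hamiltonian Monte Carlo kernel on the same target density; the two methods
agree in distribution and ``direct`` is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, StateError

AGE_TERMS = ("power", "ratio_power", "linear")


@dataclass(frozen=True)
class PPKParams:
    """Fixed effects and random-effect SDs of the clearance model.

    ``age_term`` selects the algebraic form of the age factor:
    ``power`` (default) is age_coef^(age/age_ref); ``ratio_power`` is
    (age/age_ref)^age_coef; ``linear`` is age_coef·age/age_ref. Only the
    default corresponds to the published model; the alternatives exist so the
    parse of the age covariate can be swapped without touching callers.
    """

    theta_base: float = 1.71          # L/h
    theta_renal_max: float = 8.31     # L/h
    k_clcr: float = 0.0113            # per (mL/min)
    age_coef: float = 0.475
    age_ref: float = 72.0             # years
    omega1: float = 0.415
    omega2: float = 0.381
    age_term: str = "power"

    def __post_init__(self) -> None:
        for name in ("theta_base", "theta_renal_max", "k_clcr", "age_coef", "age_ref"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.omega1 < 0 or self.omega2 < 0:
            raise ConfigurationError("omega1/omega2 must be >= 0")
        if self.age_term not in AGE_TERMS:
            raise ConfigurationError(f"age_term must be one of {AGE_TERMS}")

    def age_factor(self, age):
        age = np.asarray(age, dtype=float)
        if self.age_term == "power":
            return self.age_coef ** (age / self.age_ref)
        if self.age_term == "ratio_power":
            return (age / self.age_ref) ** self.age_coef
        return self.age_coef * age / self.age_ref


@dataclass(frozen=True)
class RandomEffects:
    """One patient's random-effect pair (η1, η2)."""

    eta1: float = 0.0
    eta2: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta1) and math.isfinite(self.eta2)):
            raise DomainError("random effects must be finite")


@dataclass(frozen=True)
class HMCOptions:
    """Tuning of the HMC kernel.

    ``step_size=None`` resolves to 0.7·min(ω1, ω2); the leapfrog count per
    transition is drawn uniformly from {1..max_leapfrog} when ``jitter`` is
    set (avoids resonant trajectories in the Gaussian target), otherwise it
    is ``max_leapfrog`` every transition.
    """

    step_size: float | None = None
    max_leapfrog: int = 15
    burn_in: int = 1000
    jitter: bool = True

    def __post_init__(self) -> None:
        if self.step_size is not None and self.step_size <= 0:
            raise ConfigurationError("HMC step_size must be > 0")
        if self.max_leapfrog < 1:
            raise ConfigurationError("max_leapfrog must be >= 1")
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")


@dataclass(frozen=True)
class EtaSample:
    """An ordered batch of random-effect draws plus sampler diagnostics."""

    draws: np.ndarray                 # shape (n, 2): columns eta1, eta2
    method: str
    seed: int
    acceptance_rate: float | None = None

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != 2:
            raise StateError("draws must have shape (n, 2)")
        if self.acceptance_rate is not None and not 0 <= self.acceptance_rate <= 1:
            raise StateError("acceptance rate must lie in [0, 1]")

    def __len__(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": np.arange(len(self)), "eta1": self.draws[:, 0], "eta2": self.draws[:, 1]}
        )


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------

def clearance(clcr, age, eta: RandomEffects | None = None, params: PPKParams | None = None):
    """Individual vancomycin clearance (L/h) for given covariates and η.

    Vectorized over ``clcr``/``age``. With η = (0, 0) this is the population
    prediction. Strictly increasing in CLcr (saturating towards
    θ_base·e^η1 + θ_renal_max·f(age)) and, under the default age factor,
    strictly decreasing in age.
    """
    params = params or PPKParams()
    eta = eta or RandomEffects()
    clcr = np.asarray(clcr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(clcr < 0):
        raise DomainError("creatinine clearance must be >= 0")
    if np.any(age <= 0):
        raise DomainError("age must be > 0")
    renal = params.theta_renal_max * (
        1.0 - np.exp(-params.k_clcr * np.exp(eta.eta2) * clcr)
    )
    cl = params.theta_base * np.exp(eta.eta1) + renal * params.age_factor(age)
    if cl.ndim == 0:
        return float(cl)
    return cl


def population_prediction(patients, params: PPKParams | None = None):
    """PPK typical-value prediction (η = 0) for a cohort frame or one record.

    Accepts a cohort DataFrame (returns an ndarray aligned with its rows) or
    a single :class:`~vancoml.cohort.PatientRecord` (returns a float).
    """
    params = params or PPKParams()
    if isinstance(patients, pd.DataFrame):
        if "clcr_mL_min" not in patients.columns or patients["clcr_mL_min"].isna().any():
            raise StateError("cohort is missing creatinine clearance")
        return clearance(
            patients["clcr_mL_min"].to_numpy(), patients["age_years"].to_numpy(), None, params
        )
    if patients.clcr_mL_min is None or np.isnan(patients.clcr_mL_min):
        raise StateError("patient is missing creatinine clearance")
    return clearance(patients.clcr_mL_min, patients.age_years, None, params)


# ---------------------------------------------------------------------------
# Random-effect sampling
# ---------------------------------------------------------------------------

def _log_density_grad(q: np.ndarray, omega_sq: np.ndarray):
    """Potential energy U = η1²/(2ω1²) + η2²/(2ω2²) and its gradient."""
    return 0.5 * float(np.sum(q * q / omega_sq)), q / omega_sq


def hmc_transition(
    state: RandomEffects,
    params: PPKParams,
    step_size: float,
    n_leapfrog: int,
    rng: np.random.Generator | int,
) -> tuple[RandomEffects, bool]:
    """One HMC transition targeting the (η1, η2) prior.

    Draws standard-normal momenta, integrates Hamilton's equations with
    ``n_leapfrog`` leapfrog steps of size ``step_size``, and accepts the
    endpoint by a Metropolis correction on the energy error. Returns the new
    state and whether the proposal was accepted. Deterministic for a fixed
    ``rng`` state.
    """
    if step_size <= 0:
        raise ConfigurationError("step_size must be > 0")
    if n_leapfrog < 1:
        raise ConfigurationError("n_leapfrog must be >= 1")
    if params.omega1 <= 0 or params.omega2 <= 0:
        raise ConfigurationError("HMC requires omega1, omega2 > 0 (use method='direct')")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    omega_sq = np.array([params.omega1**2, params.omega2**2])

    q = np.array([state.eta1, state.eta2], dtype=float)
    p = rng.standard_normal(2)
    u0, grad = _log_density_grad(q, omega_sq)
    h0 = u0 + 0.5 * float(p @ p)

    p = p - 0.5 * step_size * grad
    for step in range(n_leapfrog):
        q = q + step_size * p
        _, grad = _log_density_grad(q, omega_sq)
        if step < n_leapfrog - 1:
            p = p - step_size * grad
    p = p - 0.5 * step_size * grad

    u1 = _log_density_grad(q, omega_sq)[0]
    h1 = u1 + 0.5 * float(p @ p)
    accept = rng.random() < math.exp(min(0.0, h0 - h1))
    if accept:
        return RandomEffects(float(q[0]), float(q[1])), True
    return state, False


def sample_etas(
    n: int,
    method: str = "direct",
    seed: int = 0,
    params: PPKParams | None = None,
    hmc_opts: HMCOptions | None = None,
) -> EtaSample:
    """Draw ``n`` i.i.d.-in-expectation random-effect pairs.

    ``direct`` draws straight from N(0, ω1²) × N(0, ω2²). ``hmc`` runs a
    single Hamiltonian Monte Carlo chain on the same density (burn-in
    discarded, no thinning); its marginals agree with direct draws in
    distribution. Both are reproducible for a fixed seed.
    """
    if n < 0:
        raise ConfigurationError(f"draw count must be >= 0, got {n}")
    params = params or PPKParams()
    if method == "direct":
        rng = np.random.default_rng(seed)
        draws = np.column_stack(
            [rng.normal(0.0, params.omega1, n), rng.normal(0.0, params.omega2, n)]
        )
        return EtaSample(draws=draws, method="direct", seed=seed)
    if method != "hmc":
        raise ConfigurationError(f"unknown sampling method {method!r}")

    if params.omega1 == 0 or params.omega2 == 0:
        raise ConfigurationError("HMC requires omega1, omega2 > 0 (use method='direct')")
    opts = hmc_opts or HMCOptions()
    step = opts.step_size if opts.step_size is not None else 0.7 * min(params.omega1, params.omega2)
    rng = np.random.default_rng(seed)
    state = RandomEffects(0.0, 0.0)
    draws = np.empty((n, 2))
    accepted = 0
    total = n + opts.burn_in
    for i in range(total):
        n_leap = int(rng.integers(1, opts.max_leapfrog + 1)) if opts.jitter else opts.max_leapfrog
        state, ok = hmc_transition(state, params, step, n_leap, rng)
        accepted += ok
        if i >= opts.burn_in:
            draws[i - opts.burn_in] = (state.eta1, state.eta2)
    rate = accepted / total if total else None
    return EtaSample(draws=draws, method="hmc", seed=seed, acceptance_rate=rate)


def simulate_individual_cl(
    cohort: pd.DataFrame, etas: EtaSample, params: PPKParams | None = None
) -> pd.DataFrame:
    """Realize each patient's individual clearance from their η draw.

    Returns a copy of the cohort with ``cl_true_L_h`` populated:
    cl_true[i] = clearance(clcr[i], age[i], η[i]). This realized value is the
    single ground truth per patient — it serves both as the ML training label
    and as the clearance against which predictions are evaluated.
    """
    params = params or PPKParams()
    if len(etas) != len(cohort):
        raise StateError(f"{len(etas)} eta draws for {len(cohort)} patients")
    out = cohort.copy()
    clcr = cohort["clcr_mL_min"].to_numpy()
    age = cohort["age_years"].to_numpy()
    renal = params.theta_renal_max * (
        1.0 - np.exp(-params.k_clcr * np.exp(etas.draws[:, 1]) * clcr)
    )
    out["cl_true_L_h"] = params.theta_base * np.exp(etas.draws[:, 0]) + renal * params.age_factor(age)
    return out
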