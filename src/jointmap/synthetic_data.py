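"""Synthetic cohorts with the model's exact generative structure.

Because the underlying survey microdata are not distributable, every
downstream component is exercised on synthetic cohorts drawn from the
shared-component model itself: spatially structured fields on a district
graph, disease-specific fields and heterogeneity, logistic outcome
probabilities, and covariates whose marginals emulate the survey's
descriptive table (two-thirds female, median age 56, ~68% urban, obesity
above 40%, correlated household asset indicators, ...).

The default geography is a 4 x 13 rook lattice standing in for the 52
South African districts, partitioned into 9 "provinces" with the real
provincial sample sizes; outcome intercepts are calibrated so marginal
prevalences land near the survey's 23.2% (hypertension) and 12.2%
(diabetes).

Scenarios
---------
``sage-like``     survey-scale calibration, moderate shared field
``strong-shared`` dominant shared field, weak specific fields
``no-shared``     shared field identically zero
``null``          all fields and covariate effects zero
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .areal_graph import DistrictGraph, build_lattice_graph, sample_icar
from .scm_model import (
    ModelSpec,
    McmcSettings,
    ParameterState,
    fraction_explained_state,
    linear_predictors,
)

__all__ = [
    "GeneratorParams",
    "SyntheticTruth",
    "make_scenario",
    "default_graph",
    "generate_covariates",
    "simulate_outcomes",
    "simulate_cohort",
    "allocate_districts",
]

SCENARIOS = ("sage-like", "strong-shared", "no-shared", "null")

#: provincial sample sizes of the emulated survey and the real number of
#: districts in each province (9 provinces, 52 districts, n = 2761)
PROVINCES = (
    ("Eastern Cape", 522, 8),
    ("Free State", 216, 5),
    ("Gauteng", 528, 5),
    ("Kwa-Zulu Natal", 450, 11),
    ("Mpumalanga", 142, 3),
    ("North West", 318, 4),
    ("Northern Cape", 93, 5),
    ("Northern Province", 175, 5),
    ("Western Cape", 317, 6),
)

_PREV_TARGETS = (0.232, 0.122)
_DEFAULT_COVS = ("age_c", "female", "urban")
_DEFAULT_BETA1 = (0.30, 0.40, -0.25)
_DEFAULT_BETA2 = (0.35, 0.30, 0.20)

# marginals emulating the survey's descriptive table
_P_FEMALE = 0.669
_P_URBAN = 0.681
_P_EMPLOYED = 0.345
_P_SALT = 0.694
_P_VIGPA = 0.133
_P_ALCOHOL = 0.190
_P_TOBACCO = 0.175
_P_GOVT = 0.347
_AGE_MU, _AGE_SIGMA = float(np.log(56.0)), 0.371  # median 56, IQR ~ (44, 72)
_N_ASSETS = 12


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth generating parameters for one scenario."""

    scenario: str
    shared: bool
    alpha: tuple[float, float]
    beta1: tuple[float, ...]
    beta2: tuple[float, ...]
    covariates1: tuple[str, ...]
    covariates2: tuple[str, ...]
    log_delta: float
    sd_shared: float
    sd_spec1: float
    sd_spec2: float
    sd_eps1: float
    sd_eps2: float
    n_total: int
    province_totals: tuple[tuple[str, int, int], ...] = PROVINCES


@dataclass
class SyntheticTruth:
    """Realised generating state, reproducible from the recorded seed."""

    params: GeneratorParams
    state: ParameterState
    seed: int
    district_effects: pd.DataFrame = field(repr=False)
    fraction_explained: tuple[float, float] = (np.nan, np.nan)


def default_graph() -> DistrictGraph:
    """The 4 x 13 rook lattice standing in for the 52 districts."""
    return build_lattice_graph(4, 13)


def _snake_order(rows: int, cols: int) -> list[int]:
    order = []
    for c in range(cols):
        rng_rows = range(rows) if c % 2 == 0 else range(rows - 1, -1, -1)
        for r in rng_rows:
            order.append(r * cols + c)
    return order


def province_map(graph: DistrictGraph) -> pd.Series:
    """Assign each district to one of the 9 provinces.

    On the default lattice the assignment follows a snake path through the
    columns so provinces are contiguous blocks; on an arbitrary graph the
    districts are split in id order, proportionally to the real counts.
    """
    J = graph.n_districts
    if J == 52 and graph.n_edges == 87:
        order = _snake_order(4, 13)
    else:
        order = list(range(J))
    counts = np.array([c for _, _, c in PROVINCES], dtype=float)
    sizes = np.floor(counts / counts.sum() * J).astype(int)
    sizes[sizes == 0] = 1
    while sizes.sum() < J:
        sizes[int(np.argmax(counts / np.maximum(sizes, 1)))] += 1
    while sizes.sum() > J:
        sizes[int(np.argmax(sizes))] -= 1
    labels = np.empty(J, dtype=object)
    pos = 0
    for (name, _, _), size in zip(PROVINCES, sizes):
        for k in order[pos : pos + size]:
            labels[k] = name
        pos += size
    return pd.Series(labels, index=list(graph.district_ids), name="province")


def allocate_districts(
    params: GeneratorParams, graph: DistrictGraph, seed: int
) -> np.ndarray:
    """Multinomial allocation of persons to districts.

    Each province's sample total is split uniformly at random over its
    districts (district-level sample sizes of the emulated survey are not
    published), after scaling province totals to the scenario's ``n_total``.
    """
    rng = np.random.default_rng(seed)
    prov = province_map(graph)
    scale = params.n_total / sum(t for _, t, _ in PROVINCES)
    counts = np.zeros(graph.n_districts, dtype=np.int64)
    for name, total, _ in PROVINCES:
        idx = np.flatnonzero((prov == name).to_numpy())
        if idx.size == 0:
            continue
        n_p = max(idx.size, int(round(total * scale)))
        alloc = rng.multinomial(n_p, np.full(idx.size, 1.0 / idx.size))
        alloc[alloc == 0] = 1
        counts[idx] += alloc
    return counts


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_covariates(
    graph: DistrictGraph, n_per_district: np.ndarray, seed: int
) -> pd.DataFrame:
    """Covariate table (no outcomes yet) with survey-like marginals.

    Covariates are mutually independent apart from the household asset
    indicators, which load on one latent wealth factor so the first
    principal component of the assets is meaningful.
    """
    n_per_district = np.asarray(n_per_district, dtype=np.int64)
    if n_per_district.shape != (graph.n_districts,) or (n_per_district < 1).any():
        raise ValueError("need a count >= 1 for every district")
    rng = np.random.default_rng(seed)
    n = int(n_per_district.sum())
    district = np.repeat(np.arange(graph.n_districts), n_per_district)
    prov = province_map(graph)

    # log-age truncated so ages stay in a plausible adult range
    log_age = _trunc_normal(
        rng, _AGE_MU, _AGE_SIGMA, np.log(18.0), np.log(95.0), n
    )
    age = np.exp(log_age)
    female = (rng.random(n) < _P_FEMALE).astype(int)
    urban = (rng.random(n) < _P_URBAN).astype(int)
    schooling = np.clip(np.round(rng.normal(9.6, 3.6, n)), 0, 18).astype(int)
    height = _trunc_normal(rng, 160.0, 8.5, 140.0, 200.0, n)
    bmi = np.exp(rng.normal(3.35, 0.23, n))  # ~3% underweight, ~42% obese
    weight = bmi * (height / 100.0) ** 2
    whtr = _trunc_normal(rng, 0.60, 0.085, 0.35, 1.0, n)
    waist = whtr * height

    wealth_latent = rng.normal(0.0, 1.0, n)
    asset_cuts = np.linspace(-1.5, 1.5, _N_ASSETS)
    assets = {
        f"asset_{m + 1:02d}": (
            rng.random(n) < 1.0 / (1.0 + np.exp(-(asset_cuts[m] + 1.2 * wealth_latent)))
        ).astype(int)
        for m in range(_N_ASSETS)
    }

    width = len(str(n - 1))
    table = pd.DataFrame(
        {
            "person_id": [f"p{i:0{width}d}" for i in range(n)],
            "district_id": [graph.district_ids[j] for j in district],
            "province": [prov.iloc[j] for j in district],
            "age": age,
            "age_c": (age - 60.0) / 10.0,
            "sex": np.where(female == 1, "female", "male"),
            "female": female,
            "residence": np.where(urban == 1, "urban", "rural"),
            "urban": urban,
            "schooling_years": schooling,
            "employed": (rng.random(n) < _P_EMPLOYED).astype(int),
            "weight_kg": weight,
            "height_cm": height,
            "waist_cm": waist,
            **assets,
            "salt_at_table": (rng.random(n) < _P_SALT).astype(int),
            "vigorous_pa": (rng.random(n) < _P_VIGPA).astype(int),
            "ever_alcohol": (rng.random(n) < _P_ALCOHOL).astype(int),
            "ever_tobacco": (rng.random(n) < _P_TOBACCO).astype(int),
            "govt_support": (rng.random(n) < _P_GOVT).astype(int),
        }
    )
    return table


def _covariate_moments(
    beta: np.ndarray, covariates: tuple[str, ...]
) -> tuple[float, float]:
    """Mean and variance of beta'X under the covariate generator.

    Computed once from a large fixed-seed reference sample of the generator
    (deterministic; independent of the cohort being simulated).
    """
    global _MOMENT_TABLE
    if _MOMENT_TABLE is None:
        g = build_lattice_graph(1, 2)
        _MOMENT_TABLE = generate_covariates(
            g, np.array([20_000, 20_000]), seed=987_654_321
        )
    if len(covariates) == 0:
        return 0.0, 0.0
    X = _MOMENT_TABLE.loc[:, list(covariates)].to_numpy(dtype=float)
    z = X @ np.asarray(beta, dtype=float)
    return float(z.mean()), float(z.var())


_MOMENT_TABLE: pd.DataFrame | None = None
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)


def _calibrate_alpha(target: float, m: float, v: float) -> float:
    """Solve E[sigmoid(a + Z)] = target with Z ~ N(m, v) (Gauss-Hermite)."""

    def marginal(a: float) -> float:
        eta = a + m + np.sqrt(max(v, 0.0)) * _GH_NODES
        p = 1.0 / (1.0 + np.exp(-eta))
        return float(p @ _GH_WEIGHTS) / float(_GH_WEIGHTS.sum()) - target

    return brentq(marginal, -15.0, 15.0)


def make_scenario(
    name: str,
    n_total: int = 2761,
    mcmc: McmcSettings | None = None,
) -> tuple[ModelSpec, GeneratorParams]:
    """Model specification and generating parameters for a named scenario.

    Intercepts are calibrated so the implied marginal prevalences match the
    scenario targets (23.2% and 12.2% for the survey-like scenarios),
    integrating the logistic link over the covariate and latent-field
    variation.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; options: {SCENARIOS}")
    if name == "null":
        betas1: tuple[float, ...] = (0.0,) * len(_DEFAULT_COVS)
        betas2: tuple[float, ...] = (0.0,) * len(_DEFAULT_COVS)
        sd_shared, sd_spec, sd_eps, log_delta, shared = 0.0, 0.0, 0.0, 0.0, False
    elif name == "no-shared":
        betas1, betas2 = _DEFAULT_BETA1, _DEFAULT_BETA2
        sd_shared, sd_spec, sd_eps, log_delta, shared = 0.0, 0.3, 0.2, 0.0, False
    elif name == "sage-like":
        betas1, betas2 = _DEFAULT_BETA1, _DEFAULT_BETA2
        sd_shared, sd_spec, sd_eps = 0.5, 0.3, 0.2
        log_delta, shared = float(np.log(1.3)), True
    else:  # strong-shared
        betas1, betas2 = _DEFAULT_BETA1, _DEFAULT_BETA2
        sd_shared, sd_spec, sd_eps = 1.0, 0.15, 0.10
        log_delta, shared = float(np.log(1.3)), True

    g1 = float(np.exp(log_delta))
    alphas = []
    for k, (betas, target) in enumerate(
        [(betas1, _PREV_TARGETS[0]), (betas2, _PREV_TARGETS[1])]
    ):
        m, v = _covariate_moments(np.array(betas), _DEFAULT_COVS)
        gk = g1 if k == 0 else 1.0 / g1
        v_latent = (gk * sd_shared) ** 2 + sd_spec**2 + sd_eps**2
        alphas.append(_calibrate_alpha(target, m, v + v_latent))

    spec = ModelSpec(
        shared=shared,
        covariates1=_DEFAULT_COVS,
        covariates2=_DEFAULT_COVS,
        mcmc=mcmc or McmcSettings(),
    )
    params = GeneratorParams(
        scenario=name, shared=shared, alpha=(alphas[0], alphas[1]),
        beta1=betas1, beta2=betas2,
        covariates1=_DEFAULT_COVS, covariates2=_DEFAULT_COVS,
        log_delta=log_delta, sd_shared=sd_shared,
        sd_spec1=sd_spec, sd_spec2=sd_spec,
        sd_eps1=sd_eps, sd_eps2=sd_eps, n_total=int(n_total),
    )
    return spec, params


def _icar_tau_for_sd(graph: DistrictGraph, sd: float) -> float:
    """Precision making the average marginal ICAR standard deviation = sd."""
    lam, _ = np.linalg.eigh(graph.laplacian())
    pos = lam > 1e-9 * max(lam.max(), 1.0)
    mean_var = float(np.sum(1.0 / lam[pos])) / graph.n_districts
    return mean_var / (sd * sd)


def _draw_bp_readings(rng, y_htn: np.ndarray) -> pd.DataFrame:
    """Blood-pressure readings and medication flags consistent with y_htn.

    Cases are measured-high with probability 0.85, otherwise detected via
    self-report plus current medication; the three sequential readings
    average exactly to the drawn person mean.
    """
    n = y_htn.size
    mean_sbp = _trunc_normal(rng, 124.0, 10.0, 95.0, 139.2, n)
    mean_dbp = _trunc_normal(rng, 78.0, 8.0, 55.0, 89.2, n)
    self_report = np.zeros(n, dtype=int)
    on_meds = np.zeros(n, dtype=int)
    cases = np.flatnonzero(y_htn == 1)
    measured = cases[rng.random(cases.size) < 0.85]
    treated = np.setdiff1d(cases, measured)
    mean_sbp[measured] = _trunc_normal(rng, 155.0, 12.0, 140.5, 220.0, measured.size)
    mean_dbp[measured] = _trunc_normal(rng, 92.0, 10.0, 60.0, 130.0, measured.size)
    self_report[treated] = 1
    on_meds[treated] = 1
    r1 = rng.normal(0.0, 3.0, n)
    r2 = rng.normal(0.0, 3.0, n)
    return pd.DataFrame(
        {
            "sbp1": mean_sbp + r1, "sbp2": mean_sbp + r2, "sbp3": mean_sbp - r1 - r2,
            "dbp1": mean_dbp + r1 * 0.5, "dbp2": mean_dbp + r2 * 0.5,
            "dbp3": mean_dbp - (r1 + r2) * 0.5,
            "self_report_htn": self_report,
            "on_antihypertensives": on_meds,
        }
    )


def simulate_outcomes(
    table: pd.DataFrame,
    params: GeneratorParams,
    graph: DistrictGraph,
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw latent fields and both outcomes; record the realised truth.

    Runs the shared-component model forward: structured fields from the
    intrinsic Gaussian prior, heterogeneity iid normal, outcomes Bernoulli
    with logistic probabilities.  Also emits blood-pressure readings and
    medication flags consistent with the hypertension outcome.
    """
    rng = np.random.default_rng(seed)
    J = graph.n_districts

    def icar_field(sd: float) -> tuple[np.ndarray, float]:
        if sd <= 0.0:
            return np.zeros(J), 1e6
        tau = _icar_tau_for_sd(graph, sd)
        return sample_icar(graph, tau, rng), tau

    u, tau_u = icar_field(params.sd_shared)
    u1, tau_u1 = icar_field(params.sd_spec1)
    u2, tau_u2 = icar_field(params.sd_spec2)
    eps1 = rng.normal(0.0, params.sd_eps1, J) if params.sd_eps1 > 0 else np.zeros(J)
    eps2 = rng.normal(0.0, params.sd_eps2, J) if params.sd_eps2 > 0 else np.zeros(J)
    state = ParameterState(
        alpha=np.array(params.alpha),
        beta1=np.array(params.beta1), beta2=np.array(params.beta2),
        u_shared=u, u_spec1=u1, u_spec2=u2, eps1=eps1, eps2=eps2,
        log_delta=params.log_delta,
        tau_shared=tau_u, tau_spec1=tau_u1, tau_spec2=tau_u2,
        tau_eps1=1.0 / params.sd_eps1**2 if params.sd_eps1 > 0 else 1e6,
        tau_eps2=1.0 / params.sd_eps2**2 if params.sd_eps2 > 0 else 1e6,
    )
    spec = ModelSpec(
        shared=params.shared,
        covariates1=params.covariates1, covariates2=params.covariates2,
    )
    probs = linear_predictors(state, table, graph, spec)
    pi = probs.pi
    out = table.copy()
    out["y_htn"] = (rng.random(len(out)) < pi[:, 0]).astype(int)
    out["y_dm"] = (rng.random(len(out)) < pi[:, 1]).astype(int)
    bp = _draw_bp_readings(rng, out["y_htn"].to_numpy())
    out = pd.concat([out.reset_index(drop=True), bp], axis=1)

    g1, g2 = state.gammas
    district_effects = pd.DataFrame(
        {
            "district_id": list(graph.district_ids),
            "u_shared": u, "u_spec1": u1, "u_spec2": u2,
            "eps1": eps1, "eps2": eps2,
            "total1": g1 * u * params.shared + u1 + eps1,
            "total2": g2 * u * params.shared + u2 + eps2,
        }
    )
    frac = fraction_explained_state(state) if params.shared else (0.0, 0.0)
    truth = SyntheticTruth(
        params=params, state=state, seed=int(seed),
        district_effects=district_effects, fraction_explained=frac,
    )
    return out, truth


def simulate_cohort(
    scenario: str,
    seed: int,
    graph: DistrictGraph | None = None,
    n_total: int = 2761,
    mcmc: McmcSettings | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth, DistrictGraph, ModelSpec]:
    """One-call scenario simulation: allocate, generate, simulate."""
    graph = graph or default_graph()
    spec, params = make_scenario(scenario, n_total=n_total, mcmc=mcmc)
    counts = allocate_districts(params, graph, seed)
    table = generate_covariates(graph, counts, seed + 1)
    table, truth = simulate_outcomes(table, params, graph, seed + 2)
    return table, truth, graph, spec
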