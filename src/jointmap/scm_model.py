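"""Joint spatial model for two binary conditions over districts.

Two nested model variants are defined on the log-odds scale for person ``i``
in district ``j`` and disease ``k`` (k = 1: hypertension, 2: diabetes):

* without a shared component::

      logit pi_ijk = alpha_k + beta_k' x_ij + U_jk + eps_jk

* with a shared component (the shared-component model)::

      logit pi_ij1 = alpha_1 + beta_1' x_ij + gamma_1 * U_j + U_j1 + eps_j1
      logit pi_ij2 = alpha_2 + beta_2' x_ij + gamma_2 * U_j + U_j2 + eps_j2

``U_j`` is a single spatially structured latent field common to both
diseases (a proxy for unmeasured, spatially patterned common risk factors);
``U_jk`` are disease-specific structured fields, and ``eps_jk`` unstructured
district heterogeneity.  The risk gradients are tied as
``gamma_1 = exp(log_delta)``, ``gamma_2 = exp(-log_delta)`` so that
``gamma_1 * gamma_2 = 1`` exactly — without this constraint the scale of
``U`` and the gammas are confounded.

Priors (all configurable): Normal(0, sd 10) on intercepts and coefficients,
Normal(0, sd 0.5) on ``log_delta``, Gamma(0.5, 0.0005) on every precision,
ICAR (intrinsic Besag) on structured fields, iid Normal on heterogeneity —
the weakly-informative conventions of BUGS-era hierarchical disease mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .areal_graph import DistrictGraph, icar_log_density, icar_pairwise_penalty

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "ModelSpec",
    "ParameterState",
    "ProbabilitySurface",
    "gamma_from_delta",
    "design_matrix",
    "district_index",
    "linear_predictors",
    "bernoulli_log_likelihood",
    "log_prior",
    "log_posterior",
    "fraction_explained",
    "fraction_explained_state",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the weakly-informative default priors."""

    sd_alpha: float = 10.0
    sd_beta: float = 10.0
    sd_log_delta: float = 0.5
    prec_shape: float = 0.5
    prec_rate: float = 0.0005

    def __post_init__(self):
        for name in ("sd_alpha", "sd_beta", "sd_log_delta", "prec_shape", "prec_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 2
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    adapt_interval: int = 50

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1 or self.adapt_interval < 1:
            raise ValueError("thin and adapt_interval must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass(frozen=True)
class ModelSpec:
    """Model variant, per-disease design columns, priors and MCMC settings.

    ``covariates1``/``covariates2`` name the columns of the individual table
    entering each disease's linear predictor (the two diseases may use
    different covariate sets).  ``shared=False`` selects the joint model
    without the shared component.
    """

    shared: bool = True
    covariates1: tuple[str, ...] = ()
    covariates2: tuple[str, ...] = ()
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["covariates1"] = list(self.covariates1)
        d["covariates2"] = list(self.covariates2)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        if isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(io.StringIO(source))
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls(
            shared=bool(d.get("shared", True)),
            covariates1=tuple(d.get("covariates1", ())),
            covariates2=tuple(d.get("covariates2", ())),
            priors=PriorSpec(**d.get("priors", {})),
            mcmc=McmcSettings(**d.get("mcmc", {})),
        )

    def without_shared(self) -> "ModelSpec":
        return replace(self, shared=False)


def gamma_from_delta(log_delta: float) -> tuple[float, float]:
    """Risk gradients (gamma_1, gamma_2) = (exp(d), 1/exp(d)).

    The product is the identity by construction (up to one floating-point
    rounding); the tie removes the scale confounding between the gammas and
    the shared field.
    """
    g1 = float(np.exp(log_delta))
    return g1, 1.0 / g1


@dataclass
class ParameterState:
    """One full set of model unknowns.

    Structured fields satisfy the per-component sum-to-zero constraint;
    ``gamma_1 * gamma_2 = 1`` holds by construction through ``log_delta``.
    """

    alpha: np.ndarray          # (2,)
    beta1: np.ndarray          # (p1,)
    beta2: np.ndarray          # (p2,)
    u_shared: np.ndarray       # (J,)
    u_spec1: np.ndarray        # (J,)
    u_spec2: np.ndarray        # (J,)
    eps1: np.ndarray           # (J,)
    eps2: np.ndarray           # (J,)
    log_delta: float = 0.0
    tau_shared: float = 1.0
    tau_spec1: float = 1.0
    tau_spec2: float = 1.0
    tau_eps1: float = 1.0
    tau_eps2: float = 1.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        for name in ("beta1", "beta2", "u_shared", "u_spec1", "u_spec2", "eps1", "eps2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def gammas(self) -> tuple[float, float]:
        return gamma_from_delta(self.log_delta)

    def validate(self, graph: DistrictGraph, tol: float = 1e-8) -> None:
        J = graph.n_districts
        for name in ("u_shared", "u_spec1", "u_spec2", "eps1", "eps2"):
            if getattr(self, name).shape != (J,):
                raise ValueError(f"{name} has wrong length (expected {J})")
        for name in ("tau_shared", "tau_spec1", "tau_spec2", "tau_eps1", "tau_eps2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("u_shared", "u_spec1", "u_spec2"):
            u = getattr(self, name)
            for c in range(graph.n_components):
                s = float(u[graph.component_labels == c].sum())
                if abs(s) > tol:
                    raise ValueError(
                        f"{name} violates sum-to-zero on component {c} (sum={s:.3g})"
                    )

    @classmethod
    def zeros(cls, J: int, p1: int, p2: int) -> "ParameterState":
        return cls(
            alpha=np.zeros(2), beta1=np.zeros(p1), beta2=np.zeros(p2),
            u_shared=np.zeros(J), u_spec1=np.zeros(J), u_spec2=np.zeros(J),
            eps1=np.zeros(J), eps2=np.zeros(J),
        )


@dataclass(frozen=True)
class ProbabilitySurface:
    """Per-person linear predictors and probabilities, one column per disease."""

    eta: np.ndarray  # (n, 2)

    @property
    def pi(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.eta))


def design_matrix(table: pd.DataFrame, columns: tuple[str, ...]) -> np.ndarray:
    """Covariate matrix (no intercept column; the intercept is alpha_k)."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"covariate columns not in table: {missing}")
    if not columns:
        return np.empty((len(table), 0))
    return table.loc[:, list(columns)].to_numpy(dtype=float)


def district_index(table: pd.DataFrame, graph: DistrictGraph) -> np.ndarray:
    """Map each person's district id to its graph index; unknown id is an error."""
    try:
        return np.array(
            [graph.index_of(str(d)) for d in table["district_id"]], dtype=np.int64
        )
    except KeyError as exc:
        raise KeyError(f"district id {exc} not present in the graph") from None


def linear_predictors(
    state: ParameterState,
    table: pd.DataFrame,
    graph: DistrictGraph,
    spec: ModelSpec,
) -> ProbabilitySurface:
    """Evaluate eta_ijk (and hence pi_ijk) for every person and both diseases."""
    X1 = design_matrix(table, spec.covariates1)
    X2 = design_matrix(table, spec.covariates2)
    d = district_index(table, graph)
    g1, g2 = state.gammas
    off1 = state.u_spec1 + state.eps1
    off2 = state.u_spec2 + state.eps2
    if spec.shared:
        off1 = off1 + g1 * state.u_shared
        off2 = off2 + g2 * state.u_shared
    eta1 = state.alpha[0] + X1 @ state.beta1 + off1[d]
    eta2 = state.alpha[1] + X2 @ state.beta2 + off2[d]
    return ProbabilitySurface(eta=np.column_stack([eta1, eta2]))


def bernoulli_log_likelihood(probs: ProbabilitySurface, table: pd.DataFrame) -> float:
    """Joint Bernoulli log-likelihood over persons and both diseases.

    Evaluated on the linear-predictor scale, y*eta - log(1 + exp(eta)),
    which is stable for arbitrarily large |eta|.
    """
    y = table.loc[:, ["y_htn", "y_dm"]].to_numpy(dtype=float)
    eta = probs.eta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = x.size
    return float(-0.5 * n * _LOG_2PI - n * np.log(sd) - 0.5 * np.sum(x * x) / sd**2)


def _iid_normal_prec_logpdf_sum(x: np.ndarray, tau: float) -> float:
    n = x.size
    return float(0.5 * n * (np.log(tau) - _LOG_2PI) - 0.5 * tau * np.sum(x * x))


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    from scipy.special import gammaln

    return float(
        shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    )


def log_prior(state: ParameterState, graph: DistrictGraph, spec: ModelSpec) -> float:
    """Sum of all prior log-densities (ICAR terms up to their constant)."""
    pr = spec.priors
    total = 0.0
    total += _normal_logpdf_sum(state.alpha, pr.sd_alpha)
    total += _normal_logpdf_sum(state.beta1, pr.sd_beta)
    total += _normal_logpdf_sum(state.beta2, pr.sd_beta)
    total += icar_log_density(state.u_spec1, state.tau_spec1, graph)
    total += icar_log_density(state.u_spec2, state.tau_spec2, graph)
    total += _iid_normal_prec_logpdf_sum(state.eps1, state.tau_eps1)
    total += _iid_normal_prec_logpdf_sum(state.eps2, state.tau_eps2)
    for tau in (state.tau_spec1, state.tau_spec2, state.tau_eps1, state.tau_eps2):
        total += _gamma_logpdf(tau, pr.prec_shape, pr.prec_rate)
    if spec.shared:
        total += icar_log_density(state.u_shared, state.tau_shared, graph)
        total += _gamma_logpdf(state.tau_shared, pr.prec_shape, pr.prec_rate)
        total += _normal_logpdf_sum(np.array([state.log_delta]), pr.sd_log_delta)
    return total


def log_posterior(
    state: ParameterState,
    table: pd.DataFrame,
    graph: DistrictGraph,
    spec: ModelSpec,
) -> float:
    probs = linear_predictors(state, table, graph, spec)
    return bernoulli_log_likelihood(probs, table) + log_prior(state, graph, spec)


def _fraction_one_draw(
    u: np.ndarray, uk: np.ndarray, ek: np.ndarray, gamma: float, include_eps: bool
) -> float:
    shared_part = gamma * u
    total = shared_part + uk + (ek if include_eps else 0.0)
    denom = float(np.var(total))
    if denom == 0.0:
        return np.nan
    return float(np.var(shared_part)) / denom


def fraction_explained_state(
    state: ParameterState, include_eps: bool = True
) -> tuple[float, float]:
    """Fraction of across-district log-odds variance due to the shared field,
    for a single parameter state (e.g. a simulator's truth draw)."""
    g1, g2 = state.gammas
    f1 = _fraction_one_draw(state.u_shared, state.u_spec1, state.eps1, g1, include_eps)
    f2 = _fraction_one_draw(state.u_shared, state.u_spec2, state.eps2, g2, include_eps)
    return f1, f2


def fraction_explained(samples, include_eps: bool = True) -> pd.DataFrame:
    """Posterior summary of the per-disease shared-variance fractions.

    For each retained draw and disease k the fraction is
    Var_j(gamma_k U_j) / Var_j(gamma_k U_j + U_jk + eps_jk) with empirical
    variances across districts.  The ratio is not clipped to [0, 1]; values
    are reported exactly as computed.  Returns a frame indexed by disease
    with posterior median and equal-tailed 95% interval.
    """
    if not samples.spec.shared:
        raise ValueError("fraction_explained requires shared-component samples")
    u = samples.flat("u_shared")        # (ndraws, J)
    ld = samples.flat("log_delta")[:, 0]
    rows = {}
    for k, (uk_name, ek_name) in enumerate(
        [("u_spec1", "eps1"), ("u_spec2", "eps2")], start=1
    ):
        uk = samples.flat(uk_name)
        ek = samples.flat(ek_name)
        gam = np.exp(ld if k == 1 else -ld)[:, None]
        shared_part = gam * u
        total = shared_part + uk + (ek if include_eps else 0.0)
        f = np.var(shared_part, axis=1) / np.var(total, axis=1)
        rows[f"disease{k}"] = {
            "median": float(np.median(f)),
            "lower": float(np.percentile(f, 2.5)),
            "upper": float(np.percentile(f, 97.5)),
        }
    return pd.DataFrame(rows).T


def recenter_field(
    state: ParameterState, which: str, graph: DistrictGraph
) -> ParameterState:
    """Re-centre a structured field to sum-to-zero, transferring the mean
    into the intercept(s) so the likelihood is unchanged (connected graphs).

    For the shared field the transfer is gamma_k * mean into each alpha_k.
    """
    if graph.n_components != 1:
        raise ValueError("exact re-centering transfer requires a connected graph")
    import copy

    st = copy.deepcopy(state)
    if which == "u_shared":
        m = st.u_shared.mean()
        st.u_shared = st.u_shared - m
        g1, g2 = st.gammas
        st.alpha = st.alpha + np.array([g1 * m, g2 * m])
    elif which == "u_spec1":
        m = st.u_spec1.mean()
        st.u_spec1 = st.u_spec1 - m
        st.alpha = st.alpha + np.array([m, 0.0])
    elif which == "u_spec2":
        m = st.u_spec2.mean()
        st.u_spec2 = st.u_spec2 - m
        st.alpha = st.alpha + np.array([0.0, m])
    else:
        raise ValueError(f"unknown structured field {which!r}")
    return st


def icar_precision_posterior(
    field_values: np.ndarray, graph: DistrictGraph, shape: float, rate: float
) -> tuple[float, float]:
    """Conjugate Gamma(shape', rate') for an ICAR field's precision."""
    J, C = graph.n_districts, graph.n_components
    return shape + 0.5 * (J - C), rate + 0.5 * icar_pairwise_penalty(field_values, graph)
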