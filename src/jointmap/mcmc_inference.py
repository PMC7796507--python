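"""MCMC fitting, convergence diagnostics, DIC, and posterior summaries.

:func:`run_chain` drives the compiled Metropolis-within-Gibbs kernel and
returns a :class:`PosteriorSamples` container (chain x draw arrays per
parameter block).  Model comparison uses the deviance information
criterion DIC = Dbar + pD with pD = Dbar - Dhat, where Dhat plugs in the
posterior mean of the per-person linear predictors.  Split-R-hat and
effective sample sizes are delegated to ArviZ (rank-normalised split R-hat,
Geyer-truncated autocorrelation ESS).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .areal_graph import DistrictGraph, icar_pairwise_penalty
from .scm_model import (
    ModelSpec,
    ParameterState,
    ProbabilitySurface,
    bernoulli_log_likelihood,
    design_matrix,
    district_index,
    fraction_explained,
)
from . import _mcmc_core

__all__ = [
    "PosteriorSamples",
    "DICResult",
    "FitResult",
    "run_chain",
    "update_precision_gibbs",
    "deviance",
    "compute_dic",
    "diagnostics",
    "summarize_fit",
    "save_samples",
    "load_samples",
]

_BLOCK_NAMES = (
    "alpha_beta1", "alpha_beta2", "u_shared", "u_spec1", "u_spec2",
    "eps1", "eps2", "log_delta",
)

_TAU_NAMES = ("tau_shared", "tau_spec1", "tau_spec2", "tau_eps1", "tau_eps2")


@dataclass
class PosteriorSamples:
    """Chain-indexed posterior draws for every parameter block.

    ``blocks[name]`` has shape (chains, draws) for scalars and
    (chains, draws, dim) for vectors.  With ``shared=False`` the
    ``u_shared``, ``log_delta`` and ``tau_shared`` blocks are absent.
    """

    blocks: dict[str, np.ndarray]
    acceptance: pd.DataFrame
    spec: ModelSpec
    seed: int
    district_ids: tuple[str, ...]

    @property
    def n_chains(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.blocks.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated, always 2-D (total draws, dim)."""
        arr = self.blocks[name]
        if arr.ndim == 2:
            return arr.reshape(-1, 1)
        return arr.reshape(arr.shape[0] * arr.shape[1], arr.shape[2])

    def state_at(self, chain: int, draw: int) -> ParameterState:
        b = self.blocks
        J = len(self.district_ids)
        zeros = np.zeros(J)
        return ParameterState(
            alpha=b["alpha"][chain, draw],
            beta1=b["beta1"][chain, draw] if b["beta1"].size else np.empty(0),
            beta2=b["beta2"][chain, draw] if b["beta2"].size else np.empty(0),
            u_shared=b["u_shared"][chain, draw] if "u_shared" in b else zeros,
            u_spec1=b["u_spec1"][chain, draw],
            u_spec2=b["u_spec2"][chain, draw],
            eps1=b["eps1"][chain, draw],
            eps2=b["eps2"][chain, draw],
            log_delta=float(b["log_delta"][chain, draw]) if "log_delta" in b else 0.0,
            tau_shared=float(b["tau_shared"][chain, draw]) if "tau_shared" in b else 1.0,
            tau_spec1=float(b["tau_spec1"][chain, draw]),
            tau_spec2=float(b["tau_spec2"][chain, draw]),
            tau_eps1=float(b["tau_eps1"][chain, draw]),
            tau_eps2=float(b["tau_eps2"][chain, draw]),
        )


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion decomposition (lower DIC is better)."""

    dbar: float
    dhat: float

    @property
    def pd(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


@dataclass
class FitResult:
    """Posterior summaries ready for reporting and mapping.

    ``coefficients``: adjusted odds ratios (exp posterior medians with 95%
    equal-tailed credible intervals).  ``districts``: per-district exp-scale
    medians of the shared contribution gamma_k*U, the specific field U_k
    and their sum, joinable to any geometry by district id.
    """

    coefficients: pd.DataFrame
    districts: pd.DataFrame
    fraction: pd.DataFrame | None
    dic: DICResult | None
    diagnostics: pd.DataFrame | None = field(default=None)

    def to_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.coefficients.to_csv(directory / "coefficients.csv")
        self.districts.to_csv(directory / "districts.csv", index=False)
        if self.fraction is not None:
            self.fraction.to_csv(directory / "fraction_explained.csv")
        if self.diagnostics is not None:
            self.diagnostics.to_csv(directory / "diagnostics.csv")


def _chain_seed(seed: int, chain: int) -> int:
    return int((int(seed) + 100_003 * (chain + 1)) % (2**31 - 1))


def run_chain(
    spec: ModelSpec,
    table: pd.DataFrame,
    graph: DistrictGraph,
    seed: int,
    init_alpha: np.ndarray | None = None,
) -> PosteriorSamples:
    """Fit the model by Metropolis-within-Gibbs MCMC.

    Chains are run sequentially with seeds derived from ``seed``; draws are
    bitwise reproducible.  Intercepts initialise at the empirical logit of
    each outcome's prevalence, coefficients and fields at zero, precisions
    at 10.  The graph must be connected (exact re-centering transfer of the
    structured fields into the intercepts relies on it).
    """
    if graph.n_components != 1:
        raise ValueError("run_chain requires a connected district graph")
    for col in ("y_htn", "y_dm", "district_id"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    y1 = table["y_htn"].to_numpy(dtype=float)
    y2 = table["y_dm"].to_numpy(dtype=float)
    if not (0 < y1.mean() < 1 and 0 < y2.mean() < 1):
        raise ValueError("each outcome needs both classes present")
    X1 = np.ascontiguousarray(design_matrix(table, spec.covariates1))
    X2 = np.ascontiguousarray(design_matrix(table, spec.covariates2))
    d = district_index(table, graph)
    J = graph.n_districts
    order = np.argsort(d, kind="stable").astype(np.int64)
    counts = np.bincount(d, minlength=J)
    dptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    nbr_indptr, nbr_idx = graph.adjacency_csr()

    if init_alpha is None:
        init_alpha = np.array(
            [np.log(y1.mean() / (1 - y1.mean())), np.log(y2.mean() / (1 - y2.mean()))]
        )
    mc = spec.mcmc
    block_arrays: dict[str, list[np.ndarray]] = {}
    rates = []
    for c in range(mc.chains):
        out = _mcmc_core.run_chain_core(
            y1, y2, X1, X2, d, order, dptr, nbr_indptr, nbr_idx,
            bool(spec.shared),
            spec.priors.sd_alpha, spec.priors.sd_beta, spec.priors.sd_log_delta,
            spec.priors.prec_shape, spec.priors.prec_rate,
            np.asarray(init_alpha, dtype=float), 10.0,
            mc.iterations, mc.burn_in, mc.thin, mc.adapt_interval,
            _chain_seed(seed, c),
        )
        (alpha, beta1, beta2, u, u1, u2, e1, e2, ld, taus, rate) = out
        chain_blocks = {
            "alpha": alpha, "beta1": beta1, "beta2": beta2,
            "u_spec1": u1, "u_spec2": u2, "eps1": e1, "eps2": e2,
            "tau_spec1": taus[:, 1], "tau_spec2": taus[:, 2],
            "tau_eps1": taus[:, 3], "tau_eps2": taus[:, 4],
        }
        if spec.shared:
            chain_blocks["u_shared"] = u
            chain_blocks["log_delta"] = ld
            chain_blocks["tau_shared"] = taus[:, 0]
        for k, v in chain_blocks.items():
            block_arrays.setdefault(k, []).append(v)
        rates.append(rate)

    blocks = {k: np.stack(v) for k, v in block_arrays.items()}
    acceptance = pd.DataFrame(
        np.vstack(rates), columns=list(_BLOCK_NAMES),
        index=[f"chain{c}" for c in range(mc.chains)],
    )
    if not spec.shared:
        acceptance = acceptance.drop(columns=["u_shared", "log_delta"])
    return PosteriorSamples(
        blocks=blocks, acceptance=acceptance, spec=spec, seed=int(seed),
        district_ids=graph.district_ids,
    )


def update_precision_gibbs(
    field_values: np.ndarray,
    structure: str,
    prior_shape: float,
    prior_rate: float,
    rng: np.random.Generator,
    graph: DistrictGraph | None = None,
) -> float:
    """One conjugate Gibbs draw for a field's precision.

    ``structure="icar"``: Gamma(shape + (J - C)/2, rate + penalty/2) with
    the Besag pairwise penalty; ``structure="iid"``: Gamma(shape + J/2,
    rate + sum(u^2)/2).
    """
    u = np.asarray(field_values, dtype=float)
    if structure == "icar":
        if graph is None:
            raise ValueError("icar structure requires the district graph")
        a = prior_shape + 0.5 * (graph.n_districts - graph.n_components)
        b = prior_rate + 0.5 * icar_pairwise_penalty(u, graph)
    elif structure == "iid":
        a = prior_shape + 0.5 * u.size
        b = prior_rate + 0.5 * float(np.sum(u * u))
    else:
        raise ValueError("structure must be 'icar' or 'iid'")
    return float(rng.gamma(shape=a, scale=1.0 / b))


def deviance(probs: ProbabilitySurface, table: pd.DataFrame) -> float:
    """Bernoulli deviance, -2 times the joint log-likelihood."""
    return -2.0 * bernoulli_log_likelihood(probs, table)


def _eta_draws(
    samples: PosteriorSamples,
    table: pd.DataFrame,
    graph: DistrictGraph,
    spec: ModelSpec,
):
    """Yield (eta1, eta2) arrays of shape (chunk, n) over all retained draws."""
    X1 = design_matrix(table, spec.covariates1)
    X2 = design_matrix(table, spec.covariates2)
    d = district_index(table, graph)
    alpha = samples.flat("alpha")
    beta1 = samples.flat("beta1")
    beta2 = samples.flat("beta2")
    u1 = samples.flat("u_spec1")
    u2 = samples.flat("u_spec2")
    e1 = samples.flat("eps1")
    e2 = samples.flat("eps2")
    if spec.shared:
        u = samples.flat("u_shared")
        ld = samples.flat("log_delta")[:, 0]
    N = alpha.shape[0]
    chunk = max(1, min(256, N))
    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        off1 = u1[lo:hi] + e1[lo:hi]
        off2 = u2[lo:hi] + e2[lo:hi]
        if spec.shared:
            g1 = np.exp(ld[lo:hi])[:, None]
            off1 = off1 + g1 * u[lo:hi]
            off2 = off2 + (1.0 / g1) * u[lo:hi]
        eta1 = alpha[lo:hi, 0:1] + beta1[lo:hi] @ X1.T + off1[:, d]
        eta2 = alpha[lo:hi, 1:2] + beta2[lo:hi] @ X2.T + off2[:, d]
        yield eta1, eta2


def compute_dic(
    samples: PosteriorSamples,
    table: pd.DataFrame,
    graph: DistrictGraph,
    spec: ModelSpec | None = None,
) -> DICResult:
    """DIC with the plug-in deviance evaluated at the posterior mean of the
    per-person linear predictors (well-defined under re-centering)."""
    spec = spec or samples.spec
    N = samples.flat("alpha").shape[0]
    if N < 50:
        raise ValueError(f"need at least 50 retained draws, have {N}")
    y = table.loc[:, ["y_htn", "y_dm"]].to_numpy(dtype=float)
    dev_sum = 0.0
    eta_mean = np.zeros((len(table), 2))
    for eta1, eta2 in _eta_draws(samples, table, graph, spec):
        ll = (
            np.sum(y[:, 0] * eta1 - np.logaddexp(0.0, eta1), axis=1)
            + np.sum(y[:, 1] * eta2 - np.logaddexp(0.0, eta2), axis=1)
        )
        dev_sum += float(np.sum(-2.0 * ll))
        eta_mean[:, 0] += eta1.sum(axis=0)
        eta_mean[:, 1] += eta2.sum(axis=0)
    dbar = dev_sum / N
    eta_mean /= N
    dhat = deviance(ProbabilitySurface(eta=eta_mean), table)
    return DICResult(dbar=dbar, dhat=dhat)


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat (rank normalised) and bulk ESS per scalar parameter.

    R-hat needs at least two chains; with a single chain it is reported as
    NaN (unavailable) and only ESS is meaningful.
    """
    import arviz as az

    rows = []
    multi = samples.n_chains >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in samples.blocks.items():
            scalar = arr.ndim == 2
            if scalar:
                arr = arr[:, :, None]
            ds = az.convert_to_dataset(arr)
            rhat = az.rhat(ds)["x"].values.ravel() if multi else np.full(arr.shape[2], np.nan)
            ess = az.ess(ds)["x"].values.ravel()
            for j in range(arr.shape[2]):
                label = name if scalar else f"{name}[{j}]"
                rows.append(
                    {"parameter": label, "rhat": float(rhat[j]), "ess": float(ess[j])}
                )
    return pd.DataFrame(rows).set_index("parameter")


def _exp_median_ci(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = np.exp(np.median(draws, axis=0))
    lo = np.exp(np.percentile(draws, 2.5, axis=0))
    hi = np.exp(np.percentile(draws, 97.5, axis=0))
    return med, lo, hi


def summarize_fit(
    samples: PosteriorSamples,
    graph: DistrictGraph,
    table: pd.DataFrame | None = None,
    dic: DICResult | None = None,
    run_diagnostics: bool = False,
) -> FitResult:
    """Posterior summaries: adjusted odds ratios and district odds surfaces.

    Coefficient rows are exp-scale posterior medians with equal-tailed 95%
    credible intervals (adjusted odds ratios).  District rows report, for
    each disease, exp-scale medians of the shared contribution gamma_k*U,
    the specific field U_k, and their sum.
    """
    spec = samples.spec
    rows = []
    for k, (bname, covs) in enumerate(
        [("beta1", spec.covariates1), ("beta2", spec.covariates2)], start=1
    ):
        draws = samples.flat(bname)
        if draws.shape[1] == 0:
            continue
        med, lo, hi = _exp_median_ci(draws)
        for j, cov in enumerate(covs):
            rows.append(
                {"disease": f"disease{k}", "covariate": cov,
                 "aOR": med[j], "lower": lo[j], "upper": hi[j]}
            )
    coefficients = pd.DataFrame(
        rows, columns=["disease", "covariate", "aOR", "lower", "upper"]
    ).set_index(["disease", "covariate"]) if rows else pd.DataFrame(
        columns=["disease", "covariate", "aOR", "lower", "upper"]
    )

    dist_rows = {"district_id": list(samples.district_ids)}
    u1 = samples.flat("u_spec1")
    u2 = samples.flat("u_spec2")
    if spec.shared:
        u = samples.flat("u_shared")
        ld = samples.flat("log_delta")[:, 0][:, None]
        shared1 = np.exp(ld) * u
        shared2 = np.exp(-ld) * u
    else:
        shared1 = np.zeros_like(u1)
        shared2 = np.zeros_like(u2)
    for k, (sh, uk) in enumerate([(shared1, u1), (shared2, u2)], start=1):
        dist_rows[f"shared_odds_{k}"] = np.exp(np.median(sh, axis=0))
        dist_rows[f"specific_odds_{k}"] = np.exp(np.median(uk, axis=0))
        dist_rows[f"total_odds_{k}"] = np.exp(np.median(sh + uk, axis=0))
    districts = pd.DataFrame(dist_rows)

    fraction = fraction_explained(samples) if spec.shared else None
    diag = diagnostics(samples) if run_diagnostics else None
    return FitResult(
        coefficients=coefficients, districts=districts, fraction=fraction,
        dic=dic, diagnostics=diag,
    )


def save_samples(samples: PosteriorSamples, prefix) -> None:
    """Persist draws as long-format CSV plus a JSON metadata sidecar."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for name, arr in samples.blocks.items():
        if arr.ndim == 2:
            arr = arr[:, :, None]
        C, D, P = arr.shape
        chain = np.repeat(np.arange(C), D * P)
        draw = np.tile(np.repeat(np.arange(D), P), C)
        comp = np.tile(np.arange(P), C * D)
        frames.append(
            pd.DataFrame(
                {"block": name, "chain": chain, "draw": draw,
                 "component": comp, "value": arr.reshape(-1)}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        prefix.with_suffix(".csv"), index=False
    )
    meta = {
        "seed": samples.seed,
        "district_ids": list(samples.district_ids),
        "spec": samples.spec.to_yaml(),
        "acceptance": samples.acceptance.to_dict(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_samples(prefix) -> PosteriorSamples:
    from pathlib import Path

    prefix = Path(prefix)
    long = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    spec = ModelSpec.from_yaml(meta["spec"])
    blocks = {}
    for name, grp in long.groupby("block"):
        C = grp["chain"].max() + 1
        D = grp["draw"].max() + 1
        P = grp["component"].max() + 1
        arr = np.empty((C, D, P))
        arr[grp["chain"], grp["draw"], grp["component"]] = grp["value"]
        blocks[name] = arr[:, :, 0] if P == 1 and name in (
            "log_delta", "tau_shared", "tau_spec1", "tau_spec2",
            "tau_eps1", "tau_eps2",
        ) else arr
    acceptance = pd.DataFrame(meta["acceptance"])
    return PosteriorSamples(
        blocks=blocks, acceptance=acceptance, spec=spec,
        seed=int(meta["seed"]), district_ids=tuple(meta["district_ids"]),
    )
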