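"""Pre-spatial covariate screening: logistic regression with backward
elimination.

Before the spatial models are fitted, each disease's candidate covariates
are screened with an ordinary multiple logistic regression and pure
backward elimination at a retention threshold of p = 0.1: the model is
refitted after removing, one at a time, the non-forced covariate with the
largest p-value above the threshold.  Demographic covariates selected a
priori (typically age and sex) are supplied as a forced set that is never
dropped.  Multi-column categorical covariates can be declared as blocks,
which are tested and dropped jointly with a Wald chi-square.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import qr

logger = logging.getLogger(__name__)

__all__ = ["CoefficientFit", "fit_logistic", "backward_eliminate"]


@dataclass
class CoefficientFit:
    """Maximum-likelihood logistic fit (IRLS / Newton-Raphson)."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    cov: np.ndarray = field(repr=False, default=None)
    message: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.log_likelihood

    def wald_block_p(self, cols: list[int]) -> float:
        """Wald chi-square p-value for a block of coefficients being zero."""
        b = self.coef[cols]
        V = self.cov[np.ix_(cols, cols)]
        stat = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(stat, df=len(cols)))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_design(X: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting: the trailing pivots name the collinear columns
        _, _, piv = qr(X, mode="economic", pivoting=True)
        culprits = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular design; collinear columns: {culprits}")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: tuple[str, ...] | None = None,
    max_iter: int = 100,
) -> CoefficientFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    ``X`` must already contain its intercept column.  Convergence when the
    largest score component falls below 1e-8 or the relative log-likelihood
    change below 1e-10, capped at ``max_iter`` Newton steps.  Wald p-values
    use the normal approximation.  Quasi-separated fits (some |beta| > 15
    with still-rising likelihood) are flagged non-converged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    if y.min() < 0 or y.max() > 1 or not np.isin(y, [0, 1]).all():
        raise ValueError("y must be binary 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("y must contain both outcome classes")
    _check_design(X, names)

    beta = np.zeros(p)
    ll_old = _loglik(X @ beta, y)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            message = "information matrix singular during IRLS"
            break
        beta = beta + step
        ll = _loglik(X @ beta, y)
        if np.max(np.abs(score)) < 1e-8 or abs(ll - ll_old) <= 1e-10 * max(1.0, abs(ll_old)):
            ll_old = ll
            converged = True
            break
        if np.max(np.abs(beta)) > 15.0 and ll > ll_old:
            ll_old = ll
            message = "possible perfect separation (|beta| > 15, likelihood rising)"
            break
        ll_old = ll

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    if message:
        logger.warning("fit_logistic: %s", message)
    return CoefficientFit(
        names=tuple(names), coef=beta, se=se, p_values=p_values,
        log_likelihood=ll_old, converged=converged, n_iter=it, cov=cov,
        message=message,
    )


def _block_map(
    names: tuple[str, ...], groups: dict[str, str] | None
) -> dict[str, list[int]]:
    """Map block label -> column indices; ungrouped columns are singletons."""
    groups = groups or {}
    blocks: dict[str, list[int]] = {}
    for j, nm in enumerate(names):
        blocks.setdefault(groups.get(nm, nm), []).append(j)
    return blocks


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    names: tuple[str, ...],
    threshold: float = 0.1,
    forced: set[str] | frozenset[str] = frozenset(),
    groups: dict[str, str] | None = None,
    criterion: str = "wald",
) -> tuple[list[str], CoefficientFit]:
    """Backward elimination of covariates from a logistic model.

    At each step the non-forced covariate (or declared block) with the
    largest p-value above ``threshold`` is dropped — one per iteration,
    ties broken by column order — and the model refitted; elimination stops
    when every remaining non-forced p-value is at or below the threshold.
    The intercept (column named ``intercept``) and ``forced`` covariates
    are never dropped.  A drop that causes quasi-separation in the refit
    is rolled back and the covariate retained with a warning.

    ``criterion`` is ``"wald"`` (default; block Wald chi-square) or
    ``"lr"`` (likelihood-ratio test against the model without the block).

    Returns the retained covariate names (including forced and intercept)
    and the final fit.  Deterministic given inputs and column order.
    """
    if criterion not in ("wald", "lr"):
        raise ValueError("criterion must be 'wald' or 'lr'")
    X = np.asarray(X, dtype=float)
    names = tuple(names)
    forced = set(forced) | {"intercept"}
    unknown = forced - set(names) - {"intercept"}
    if unknown:
        raise ValueError(f"forced covariates not in design: {sorted(unknown)}")

    current = list(names)
    while True:
        idx = [names.index(nm) for nm in current]
        fit = fit_logistic(X[:, idx], y, tuple(current))
        blocks = _block_map(tuple(current), groups)
        worst_label, worst_p = None, threshold
        for label, cols in blocks.items():
            if label == "intercept" or all(current[c] in forced for c in cols):
                continue
            if any(current[c] in forced for c in cols):
                continue
            if criterion == "wald":
                p = fit.wald_block_p(cols)
            else:
                reduced = [c for c in range(len(current)) if c not in cols]
                red_fit = fit_logistic(
                    X[:, [idx[c] for c in reduced]], y,
                    tuple(current[c] for c in reduced),
                )
                lr = 2.0 * (fit.log_likelihood - red_fit.log_likelihood)
                p = float(stats.chi2.sf(max(lr, 0.0), df=len(cols)))
            if p > worst_p:
                worst_label, worst_p = label, p
        if worst_label is None:
            return current, fit
        drop_cols = set(blocks[worst_label])
        candidate = [nm for c, nm in enumerate(current) if c not in drop_cols]
        cand_idx = [names.index(nm) for nm in candidate]
        cand_fit = fit_logistic(X[:, cand_idx], y, tuple(candidate))
        if cand_fit.message.startswith("possible perfect separation"):
            warnings.warn(
                f"dropping {worst_label!r} causes separation; retained instead",
                stacklevel=2,
            )
            forced |= {current[c] for c in drop_cols}
            continue
        logger.info("dropped %r (p=%.4g)", worst_label, worst_p)
        current = candidate
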