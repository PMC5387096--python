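"""Dyadic multilevel logistic actor-partner model.

Both partners' interval-by-interval behavior occurrences are stacked into one
long table with two records per dyad and interval (t >= 2): the dependent
variable is the occurrence (1) of a member's own behavior at t, predicted by
the member's own lagged behavior (actor effect, effect-coded +/-1), the
partner's lagged other behavior (partner effect, +/-1), their product, and a
sex dummy (0 = reference member) moderating all three — eight fixed effects
in total.  Dyad-level random effects on a chosen subset of terms capture
between-couple heterogeneity with an unstructured covariance.

Estimation maximizes the Laplace-approximated marginal likelihood: for each
dyad the random-effect vector is profiled out at its conditional mode (inner
Newton iterations, vectorized across dyads), and the fixed effects plus the
log-Cholesky factor of the random-effect covariance are optimized by
quasi-Newton.  Fixed-effect standard errors come from the finite-difference
Hessian of the marginal log-likelihood.  Competing random structures are
compared by BIC with the number of dyads as the sample size (level-2 units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .seqdata import Dataset

FIXED_TERMS = ("intercept", "ae", "pe", "ae_pe", "sex", "ae_sex", "pe_sex", "ae_pe_sex")
RANDOM_TERMS = FIXED_TERMS  # any fixed term may get a dyad-level random effect
DEFAULT_RANDOM_CANDIDATES = (
    (),
    ("intercept",),
    ("intercept", "ae"),
    ("intercept", "ae", "pe"),
    ("intercept", "ae", "pe", "ae_pe"),
)


class ConvergenceError(RuntimeError):
    pass


def build_long(dataset: Dataset) -> pd.DataFrame:
    """Stack a dataset into the long format of the multilevel model.

    For each dyad and each t = 2..T_obs two records are emitted: one for the
    reference member (sex = 0, behavior stream B) and one for the other member
    (sex = 1, stream A).  ``dv`` is the member's own behavior at t (occurrence
    = 1); ``ae`` and ``pe`` are the effect-coded (+/-1) own and partner
    behaviors at t-1.  A dyad of length T contributes 2*(T-1) records.
    """
    frames = []
    for pair in dataset.pairs:
        if pair.t_obs < 2:
            warnings.warn(f"dyad {pair.dyad_id}: fewer than 2 intervals, skipped", stacklevel=2)
            continue
        a, b = pair.seq_a, pair.seq_b
        t = np.arange(2, pair.t_obs + 1)
        ca, cb = 2 * a - 1, 2 * b - 1  # effect coding of lagged behavior
        frames.append(
            pd.DataFrame(
                {
                    "dyad_id": pair.dyad_id,
                    "t": np.concatenate([t, t]),
                    "sex": np.repeat([0, 1], len(t)),
                    "dv": np.concatenate([b[1:], a[1:]]),
                    "ae": np.concatenate([cb[:-1], ca[:-1]]),
                    "pe": np.concatenate([ca[:-1], cb[:-1]]),
                }
            )
        )
    if not frames:
        raise ValueError("no usable dyads")
    return pd.concat(frames, ignore_index=True)


def design_matrix(records: pd.DataFrame, terms=FIXED_TERMS) -> np.ndarray:
    """Columns for the requested model terms from a long-format table."""
    cols = {
        "intercept": np.ones(len(records)),
        "ae": records["ae"].to_numpy(float),
        "pe": records["pe"].to_numpy(float),
        "ae_pe": records["ae"].to_numpy(float) * records["pe"].to_numpy(float),
        "sex": records["sex"].to_numpy(float),
    }
    cols["ae_sex"] = cols["ae"] * cols["sex"]
    cols["pe_sex"] = cols["pe"] * cols["sex"]
    cols["ae_pe_sex"] = cols["ae_pe"] * cols["sex"]
    return np.column_stack([cols[t] for t in terms])


@dataclass
class MLMResult:
    """Fitted multilevel logistic model."""

    fixed: pd.DataFrame  # term, estimate, se, z, p
    fixed_cov: np.ndarray  # covariance of the fixed-effect estimates
    random_spec: tuple[str, ...]
    random_cov: np.ndarray  # covariance of the included random effects
    random_corr: np.ndarray
    loglik: float
    bic: float
    n_obs: int
    n_dyads: int
    converged: bool
    n_free_params: int = 0

    @property
    def gamma(self) -> np.ndarray:
        return self.fixed["estimate"].to_numpy()


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from a log-diagonal parameter vector."""
    chol = np.zeros((q, q))
    idx = np.tril_indices(q)
    vals = theta.copy()
    chol[idx] = vals
    chol[np.diag_indices(q)] = np.exp(np.diag(chol))
    return chol


def _n_cov_params(q: int) -> int:
    return q * (q + 1) // 2


class _LaplaceObjective:
    """Negative Laplace marginal log-likelihood, vectorized across dyads.

    Dyads are grouped by record count so the inner Newton solve for the
    conditional random-effect modes runs as batched linear algebra.
    """

    def __init__(self, x: np.ndarray, z: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        x, z, y, groups = x[order], z[order], y[order], groups[order]
        self.q = z.shape[1]
        self.batches = []
        uniq, starts = np.unique(groups, return_index=True)
        bounds = np.append(starts, len(groups))
        sizes = np.diff(bounds)
        for size in np.unique(sizes):
            sel = np.nonzero(sizes == size)[0]
            xb = np.stack([x[bounds[i] : bounds[i + 1]] for i in sel])
            zb = np.stack([z[bounds[i] : bounds[i + 1]] for i in sel])
            yb = np.stack([y[bounds[i] : bounds[i + 1]] for i in sel])
            self.batches.append(
                {"x": xb, "z": zb, "y": yb, "b": np.zeros((len(sel), self.q))}
            )
        self.n_dyads = len(uniq)

    def __call__(self, theta: np.ndarray, gamma_dim: int) -> float:
        gamma = theta[:gamma_dim]
        chol = _chol_from_theta(theta[gamma_dim:], self.q)
        sigma_inv = np.linalg.inv(chol @ chol.T + 1e-12 * np.eye(self.q))
        logdet_sigma = 2.0 * np.log(np.diag(chol)).sum()
        total = 0.0
        for batch in self.batches:
            xb, zb, yb = batch["x"], batch["z"], batch["y"]
            b = batch["b"].copy()
            xg = xb @ gamma  # (J, n)

            def h_val(bb):
                eta = xg + np.einsum("jnq,jq->jn", zb, bb)
                ll = (yb * eta - np.logaddexp(0.0, eta)).sum(axis=1)
                pen = 0.5 * np.einsum("jq,qp,jp->j", bb, sigma_inv, bb)
                return ll - pen, eta

            h, eta = h_val(b)
            for _ in range(60):  # Newton for the conditional modes
                mu = 1.0 / (1.0 + np.exp(-eta))
                grad = np.einsum("jnq,jn->jq", zb, yb - mu) - b @ sigma_inv
                w = mu * (1.0 - mu)
                hess = np.einsum("jnq,jn,jnp->jqp", zb, w, zb) + sigma_inv[None]
                step = np.linalg.solve(hess, grad[:, :, None])[:, :, 0]
                if np.abs(grad).max() < 1e-9:
                    break
                # step-halving keeps h non-decreasing per dyad
                scale = np.ones(len(b))
                for _half in range(30):
                    b_new = b + scale[:, None] * step
                    h_new, eta_new = h_val(b_new)
                    worse = h_new < h - 1e-12
                    if not worse.any():
                        break
                    scale[worse] *= 0.5
                b, h, eta = b_new, h_new, eta_new
            batch["b"] = b  # warm start for the next objective evaluation
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            hess = np.einsum("jnq,jn,jnp->jqp", zb, w, zb) + sigma_inv[None]
            sign, logdet_h = np.linalg.slogdet(hess)
            total += (h - 0.5 * logdet_sigma - 0.5 * logdet_h).sum()
        return -total


def _plain_logistic_negll(theta, x, y):
    eta = x @ theta
    return -(y * eta - np.logaddexp(0.0, eta)).sum()


def _plain_logistic_grad(theta, x, y):
    mu = 1.0 / (1.0 + np.exp(-(x @ theta)))
    return x.T @ (mu - y)


def _fd_hessian(fun, x0: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    p = len(x0)
    hess = np.empty((p, p))
    f0 = fun(x0)
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                hess[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / steps[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej) - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return hess


def fit_glmm(
    records: pd.DataFrame,
    random_spec: tuple[str, ...] = ("intercept", "ae", "pe"),
    bic_n: str = "dyads",
    maxiter: int = 300,
) -> MLMResult:
    """Fit the mixed logistic actor-partner model by Laplace marginal ML.

    ``random_spec`` names the terms with dyad-level random effects (any subset
    of the fixed terms, unstructured covariance).  With an empty spec the fit
    is ordinary pooled logistic regression.  ``bic_n`` chooses the BIC sample
    size: 'dyads' (level-2 units, default) or 'records'.
    """
    random_spec = tuple(random_spec)
    for term in random_spec:
        if term not in RANDOM_TERMS:
            raise ValueError(f"unknown random term {term!r}")
    if bic_n not in ("dyads", "records"):
        raise ValueError("bic_n must be 'dyads' or 'records'")
    x = design_matrix(records)
    y = records["dv"].to_numpy(float)
    groups = pd.factorize(records["dyad_id"])[0]
    n_dyads = int(groups.max()) + 1
    if n_dyads < 2:
        raise ValueError("need at least 2 dyads")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    p = x.shape[1]
    q = len(random_spec)
    n_bic = n_dyads if bic_n == "dyads" else len(records)

    # starting values from the pooled logistic fit
    start = optimize.minimize(
        _plain_logistic_negll,
        np.zeros(p),
        args=(x, y),
        jac=_plain_logistic_grad,
        method="BFGS",
        options={"maxiter": 500},
    )
    gamma0 = start.x

    if q == 0:
        mu = 1.0 / (1.0 + np.exp(-(x @ gamma0)))
        w = mu * (1.0 - mu)
        cov = np.linalg.inv(x.T @ (x * w[:, None]))
        loglik = -float(start.fun)
        se = np.sqrt(np.diag(cov))
        z = gamma0 / se
        fixed = pd.DataFrame(
            {
                "term": FIXED_TERMS,
                "estimate": gamma0,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )
        return MLMResult(
            fixed=fixed,
            fixed_cov=cov,
            random_spec=(),
            random_cov=np.zeros((0, 0)),
            random_corr=np.zeros((0, 0)),
            loglik=loglik,
            bic=-2 * loglik + p * np.log(n_bic),
            n_obs=len(records),
            n_dyads=n_dyads,
            converged=bool(start.success),
            n_free_params=p,
        )

    z_mat = design_matrix(records, random_spec)
    obj = _LaplaceObjective(x, z_mat, y, groups)
    theta0 = np.concatenate([gamma0, _theta_start(q)])
    res = optimize.minimize(
        lambda th: obj(th, p),
        theta0,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"GLMM optimization did not converge: {res.message}", stacklevel=2)
    theta = res.x
    chol = _chol_from_theta(theta[p:], q)
    sigma = chol @ chol.T
    sd = np.sqrt(np.diag(sigma))
    for k, term in enumerate(random_spec):
        if sigma[k, k] < 1e-8:
            warnings.warn(f"random effect for {term!r} has boundary variance", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = sigma / np.outer(np.maximum(sd, 1e-12), np.maximum(sd, 1e-12))

    hess = _fd_hessian(lambda th: obj(th, p), theta)
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)
    fixed_cov = cov_all[:p, :p]
    se = np.sqrt(np.maximum(np.diag(fixed_cov), 0.0))
    gamma = theta[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, gamma / se, np.nan)
    fixed = pd.DataFrame(
        {
            "term": FIXED_TERMS,
            "estimate": gamma,
            "se": se,
            "z": zstat,
            "p": 2 * stats.norm.sf(np.abs(zstat)),
        }
    )
    loglik = -float(res.fun)
    k_free = p + _n_cov_params(q)
    return MLMResult(
        fixed=fixed,
        fixed_cov=fixed_cov,
        random_spec=random_spec,
        random_cov=sigma,
        random_corr=corr,
        loglik=loglik,
        bic=-2 * loglik + k_free * np.log(n_bic),
        n_obs=len(records),
        n_dyads=n_dyads,
        converged=converged,
        n_free_params=k_free,
    )


def _theta_start(q: int) -> np.ndarray:
    # log-Cholesky layout: tril entries row-wise, diagonal on the log scale
    theta = np.zeros(_n_cov_params(q))
    pos = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                theta[pos] = np.log(0.3)  # modest starting SD
            pos += 1
    return theta


def select_random_structure(
    records: pd.DataFrame,
    candidates=DEFAULT_RANDOM_CANDIDATES,
    bic_n: str = "dyads",
) -> tuple[MLMResult, pd.DataFrame]:
    """Fit each candidate random-effect subset and pick the lowest BIC.

    Candidates that fail to fit are excluded from the comparison with the
    failure reason recorded in the table.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = []
    fits: list[MLMResult | None] = []
    for spec in candidates:
        try:
            fit = fit_glmm(records, tuple(spec), bic_n=bic_n)
            fits.append(fit)
            rows.append(
                {
                    "random_spec": "+".join(spec) if spec else "(none)",
                    "loglik": fit.loglik,
                    "n_free_params": fit.n_free_params,
                    "bic": fit.bic,
                    "converged": fit.converged,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - candidate excluded with reason
            fits.append(None)
            rows.append(
                {
                    "random_spec": "+".join(spec) if spec else "(none)",
                    "loglik": np.nan,
                    "n_free_params": np.nan,
                    "bic": np.nan,
                    "converged": False,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    ok = [i for i, f in enumerate(fits) if f is not None]
    if not ok:
        raise ConvergenceError("all candidate random structures failed to fit")
    best_i = min(ok, key=lambda i: fits[i].bic)
    return fits[best_i], table


def sex_specific_effects(result: MLMResult) -> dict[str, pd.DataFrame]:
    """Per-member fixed effects implied by the sex-moderated parameterization.

    The reference member's (sex = 0) logit, actor, partner and interaction
    effects are gamma_0..gamma_3; the other member's are the sums
    gamma_0+gamma_4, .., gamma_3+gamma_7.  Standard errors of the sums come
    from the delta method on the fixed-effect covariance.
    """
    gamma = result.gamma
    cov = result.fixed_cov
    names = ("logit", "actor", "partner", "interaction")
    ref = pd.DataFrame(
        {
            "effect": names,
            "estimate": gamma[:4],
            "se": np.sqrt(np.diag(cov)[:4]),
        }
    )
    est = gamma[:4] + gamma[4:]
    se = np.sqrt(
        np.array([cov[i, i] + cov[i + 4, i + 4] + 2 * cov[i, i + 4] for i in range(4)])
    )
    other = pd.DataFrame({"effect": names, "estimate": est, "se": se})
    return {"reference": ref, "other": other}
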