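"""Bayesian linear mixed regression of repeated trust/distrust ratings.

Model:  rating ~ Condition * queryCount + (1 | participant), with a Gaussian
likelihood on the 1-7 ratings.  The five query time points enter through
planned contrasts: a user-supplied weight matrix is converted to design
columns by the generalized-inverse convention, so that each fitted
coefficient estimates exactly the weighted comparison of time-point means
its contrast row specifies.  The default scheme compares (1 vs 2),
(1,2 vs 3), (3 vs 4,5) and (4 vs 5) -- a step-change layout that localises a
drop (trust) or rise (distrust) at the third query and probes for recovery
afterwards.

Priors are weakly informative on the 1-7 scale: Normal(0, 5) on all fixed
effects, half-Normal(0, 5) on the random-intercept and residual SDs.  The
sampler is a Gibbs scheme with conjugate updates for coefficients and random
intercepts and adaptive random-walk Metropolis on the two log-SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .sdt import ESS_THRESHOLD, RHAT_THRESHOLD

TABLE_WEIGHTS = np.array([
    [-1, 1, 0, 0, 0],
    [-1, -1, 2, 0, 0],
    [0, 0, 2, -1, -1],
    [0, 0, 0, 1, -1],
], dtype=float)

CONDITION_CODES = {"distrust": 0.0, "information-only": 1.0}


@dataclass(frozen=True)
class ContrastScheme:
    """Planned-contrast weight matrix over the five query time points."""

    weights: np.ndarray = field(default_factory=lambda: TABLE_WEIGHTS.copy())

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4, 5):
            raise ValueError(f"weight matrix must be 4 x 5, got {w.shape}")
        if not np.allclose(w.sum(axis=1), 0.0):
            raise ValueError("every contrast row must sum to zero")
        if np.linalg.matrix_rank(w) != 4:
            raise ValueError("contrast rows must be linearly independent")
        object.__setattr__(self, "weights", w)

    def hypothesis_matrix(self) -> np.ndarray:
        """Intercept row (grand mean) stacked on the contrast rows."""
        return np.vstack([np.full(5, 0.2), self.weights])

    def coding(self) -> np.ndarray:
        """5 x 5 design coding: row t gives the regressors of time point t.

        The inverse of the hypothesis matrix, so that the coefficient vector
        equals the hypothesis matrix applied to the time-point means -- i.e.
        coefficient k literally estimates contrast k.
        """
        return np.linalg.inv(self.hypothesis_matrix())


class RegressionSpec(BaseModel):
    """Response item, coding choices, priors and MCMC settings."""

    item: str = "trust"
    timepoint_coding: str = Field(default="contrasts", pattern="^(contrasts|categorical)$")
    condition_coding: str = Field(default="indicator", pattern="^(indicator|centered)$")
    coef_prior_sd: float = Field(default=5.0, gt=0)
    sd_prior_scale: float = Field(default=5.0, gt=0)
    chains: int = Field(default=4, gt=0)
    draws: int = Field(default=10_000, gt=0)
    tune: int = Field(default=2_000, ge=0)
    seed: int = 0

    @property
    def retained(self) -> int:
        return self.draws - self.tune


def build_design_matrix(
    records: pd.DataFrame,
    scheme: ContrastScheme | None = None,
    item: str = "trust",
    timepoint_coding: str = "contrasts",
    condition_coding: str = "indicator",
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix, response vector and participant index for one item.

    The condition regressor is 1 for information-only and 0 for distrust
    (``indicator``; a positive Condition coefficient then means higher
    ratings under information-only), or +/-0.5 (``centered``).  Returns
    ``(X, y, participant_labels)`` with X rows aligned to the records of the
    chosen item, sorted by participant and time point.
    """
    if scheme is None:
        scheme = ContrastScheme()
    sub = records[records["item"] == item].copy()
    if sub.empty:
        raise ValueError(f"no records for item {item!r}")
    sub = sub.sort_values(["participant_id", "timepoint"]).reset_index(drop=True)
    counts = sub.groupby("participant_id")["timepoint"].agg(["count", "nunique"])
    bad = counts[(counts["count"] != 5) | (counts["nunique"] != 5)]
    if len(bad):
        raise ValueError(
            f"participants without exactly one rating at each of the 5 time "
            f"points: {list(bad.index)}")

    t_idx = sub["timepoint"].to_numpy(int) - 1
    if timepoint_coding == "contrasts":
        coding = scheme.coding()
        Z = coding[t_idx, 1:]
        znames = [f"contrast{k}" for k in range(1, 5)]
    elif timepoint_coding == "categorical":
        Z = np.zeros((len(sub), 4))
        for k in range(1, 5):  # treatment coding, time point 1 as reference
            Z[:, k - 1] = (t_idx == k).astype(float)
        znames = [f"timepoint{k + 1}" for k in range(1, 5)]
    else:
        raise ValueError(f"unknown timepoint coding {timepoint_coding!r}")

    cond_raw = sub["condition"].map(CONDITION_CODES)
    if cond_raw.isna().any():
        bad_levels = sorted(set(sub["condition"]) - set(CONDITION_CODES))
        raise ValueError(f"unknown condition label(s): {bad_levels}")
    cond = cond_raw.to_numpy(float)
    if condition_coding == "centered":
        cond = cond - 0.5

    X = pd.DataFrame({"Intercept": np.ones(len(sub)), "Condition": cond})
    for j, name in enumerate(znames):
        X[name] = Z[:, j]
    for j, name in enumerate(znames):
        X[f"Condition:{name}"] = cond * Z[:, j]
    y = sub["rating"].to_numpy(float)
    return X, y, sub["participant_id"].to_numpy()


@dataclass
class RegressionPosterior:
    """Posterior draws for the mixed regression."""

    coef_names: list[str]
    beta: np.ndarray       # (chains, retained, p)
    sigma_u: np.ndarray    # (chains, retained)
    sigma: np.ndarray      # (chains, retained)
    item: str
    diagnostics: pd.DataFrame = field(repr=False, default=None)
    converged: bool = True

    def coefficient_draws(self, name: str) -> np.ndarray:
        j = self.coef_names.index(name)
        return self.beta[:, :, j].reshape(-1)

    def summary(self) -> pd.DataFrame:
        return summarize_coefficients(self)


def summarize_coefficients(posterior: RegressionPosterior) -> pd.DataFrame:
    """Per-coefficient mean, posterior SD and equal-tailed 95% CI."""
    rows = []
    items = [(n, posterior.coefficient_draws(n)) for n in posterior.coef_names]
    items += [("sd(Intercept|participant)", posterior.sigma_u.reshape(-1)),
              ("sigma", posterior.sigma.reshape(-1))]
    for name, draws in items:
        lo, hi = np.quantile(draws, [0.025, 0.975])
        rows.append({"coefficient": name, "Estimate": float(draws.mean()),
                     "Est.Error": float(draws.std(ddof=1)),
                     "l-95% CI": float(lo), "u-95% CI": float(hi)})
    return pd.DataFrame(rows)


def fit_mixed_regression(
    records: pd.DataFrame,
    spec: RegressionSpec | None = None,
    scheme: ContrastScheme | None = None,
) -> RegressionPosterior:
    """Gibbs sampler for the random-intercept regression of one rating item."""
    if spec is None:
        spec = RegressionSpec()
    X_df, y, pids = build_design_matrix(
        records, scheme, spec.item, spec.timepoint_coding, spec.condition_coding)
    labels, p_idx = np.unique(pids, return_inverse=True)
    conds = records[records["item"] == spec.item].groupby("participant_id")["condition"].first()
    if conds.nunique() < 2 or conds.value_counts().min() < 2:
        raise ValueError("need at least 2 participants in each condition")

    X = X_df.to_numpy(float)
    n, p = X.shape
    J = len(labels)
    nj = np.bincount(p_idx, minlength=J).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    # per-participant row sums of X and of y, for cheap cross terms
    S = np.zeros((J, p))
    np.add.at(S, p_idx, X)
    y_sums = np.bincount(p_idx, weights=y, minlength=J)

    kept = spec.retained
    ch = spec.chains
    out_beta = np.empty((ch, kept, p))
    out_su = np.empty((ch, kept))
    out_s = np.empty((ch, kept))

    prior_prec = np.eye(p) / spec.coef_prior_sd**2
    tau = spec.sd_prior_scale

    root = np.random.SeedSequence(spec.seed)
    for c, ss in enumerate(root.spawn(ch)):
        rng = np.random.default_rng(ss)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta = beta + 0.1 * rng.standard_normal(p)
        # floor on both SDs: keeps the sampler finite on degenerate
        # (zero-residual) data; 1e-3 is negligible on a 1-7 rating scale
        floor = np.log(1e-3)
        log_s = max(np.log(max(np.std(y - X @ beta), 0.5)), floor)
        log_su = np.log(0.5)
        step_s, step_su = 0.1, 0.3
        acc_s = acc_su = 0

        def marginal_logpost(ls, lsu, ssr, r_sums):
            # random intercepts integrated out: per participant the residual
            # covariance is s2*I + su2*J, whose determinant and inverse are
            # closed-form, so the SDs never see the u-funnel
            s2 = np.exp(2 * ls)
            su2 = np.exp(2 * lsu)
            denom = s2 + nj * su2
            logdet = float(((nj - 1) * 2 * ls + np.log(denom)).sum())
            quad = ssr / s2 - float((su2 / (s2 * denom)) @ r_sums**2)
            # half-Normal(tau) priors on both SDs, plus log-scale Jacobians
            return (-0.5 * (logdet + quad)
                    - s2 / (2 * tau**2) - su2 / (2 * tau**2) + ls + lsu)

        for it in range(spec.draws):
            s2 = np.exp(2 * log_s)
            su2 = np.exp(2 * log_su)

            # fixed effects against the marginal (GLS) likelihood; the random
            # intercepts stay integrated out, which decorrelates the intercept
            # from the participant effects
            w = su2 / (s2 * (s2 + nj * su2))
            prec = XtX / s2 - S.T @ (w[:, None] * S) + prior_prec
            rhs = Xty / s2 - S.T @ (w * y_sums)
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

            # SDs: adaptive MH on the log scale against the collapsed target
            resid = y - X @ beta
            r_sums = y_sums - S @ beta
            ssr = float(resid @ resid)
            cur = marginal_logpost(log_s, log_su, ssr, r_sums)
            prop = log_s + step_s * rng.standard_normal()
            if prop >= floor:
                new = marginal_logpost(prop, log_su, ssr, r_sums)
                if np.log(rng.random()) < new - cur:
                    log_s, cur = prop, new
                    acc_s += 1
            prop = log_su + step_su * rng.standard_normal()
            if prop >= floor:
                new = marginal_logpost(log_s, prop, ssr, r_sums)
                if np.log(rng.random()) < new - cur:
                    log_su = prop
                    acc_su += 1

            if it < spec.tune:
                if (it + 1) % 50 == 0:
                    step_s *= np.exp(acc_s / 50 - 0.44)
                    step_su *= np.exp(acc_su / 50 - 0.44)
                    step_s = float(np.clip(step_s, 1e-3, 2.0))
                    step_su = float(np.clip(step_su, 1e-3, 2.0))
                    acc_s = acc_su = 0
            else:
                j = it - spec.tune
                out_beta[c, j] = beta
                out_su[c, j] = np.exp(log_su)
                out_s[c, j] = np.exp(log_s)

    post = RegressionPosterior(
        coef_names=list(X_df.columns),
        beta=out_beta, sigma_u=out_su, sigma=out_s, item=spec.item,
    )
    post.diagnostics, post.converged = _diagnose_regression(post)
    if not post.converged:
        warnings.warn(
            "mixed regression did not reach split-R-hat <= 1.01 / ESS >= 400 "
            "on all coefficients; inspect posterior.diagnostics",
            RuntimeWarning,
        )
    return post


def _diagnose_regression(post: RegressionPosterior) -> tuple[pd.DataFrame, bool]:
    idata = az.from_dict(posterior={
        "beta": post.beta, "sigma_u": post.sigma_u, "sigma": post.sigma,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rows = []
    for name in ("beta", "sigma_u", "sigma"):
        r = np.atleast_1d(rhat[name].values)
        e = np.atleast_1d(ess[name].values)
        for k in range(r.size):
            label = post.coef_names[k] if name == "beta" else name
            rows.append({"parameter": label, "rhat": float(r[k]),
                         "ess_bulk": float(e[k])})
    table = pd.DataFrame(rows)
    single_chain = post.beta.shape[0] < 2
    ok = bool((single_chain or (table["rhat"] <= RHAT_THRESHOLD).all())
              and (table["ess_bulk"] >= ESS_THRESHOLD).all())
    return table, ok


def selfreport_means(records: pd.DataFrame, item: str) -> pd.Series:
    """Per-participant mean rating over the five time points (for correlations)."""
    sub = records[records["item"] == item]
    if sub.empty:
        raise ValueError(f"no records for item {item!r}")
    return sub.groupby("participant_id")["rating"].mean()
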