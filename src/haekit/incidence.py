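"""Poisson random-intercept model of HAE counts and incidence estimates.

The outcome is the per-player-match count of HAEs above a magnitude
threshold.  Fixed effects are position and the logarithm of playing time
(a free coefficient by default, with an option to treat it as a fixed
offset); crossed random intercepts on player and fixture capture
between-player and between-fixture heterogeneity:

    count_ij ~ Poisson(mu_ij),
    log mu_ij = x_ij' beta + beta_t * log(minutes_ij) + u_player(i) + v_fixture(j),
    u ~ N(0, sigma_p^2),  v ~ N(0, sigma_f^2).

The marginal likelihood integrates the crossed random effects by a
Laplace approximation (inner Newton for the joint random-effect mode,
dense Cholesky of the joint precision); the outer maximisation over
(beta, log sigma_p, log sigma_f) uses L-BFGS-B.  One model is fitted per
metric-threshold combination.

Incidence estimates are reported under two exposure denominators: per
full-match equivalent (80 min) and per position- (or player-) median
playing time, as ``exp`` of the linear predictor with random effects at
zero, with Wald intervals mapped through the log link.  Individual
estimates shift the position mean by the player's random-intercept mode
and widen the interval by its conditional standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

__all__ = [
    "FitError",
    "IncidenceFit",
    "IncidenceEstimate",
    "laplace_loglik",
    "fit_poisson_glmm",
    "estimate_incidence",
    "individual_incidence",
    "position_median_minutes",
    "player_median_minutes",
]

_Z95 = 1.959963984540054


class FitError(RuntimeError):
    """Model failed to converge; carries the final gradient norm."""


@dataclass
class IncidenceFit:
    """Fitted Poisson GLMM for one metric-threshold combination."""

    threshold: tuple[str, float]
    beta: pd.Series                     # named fixed effects
    vcov_beta: np.ndarray
    sigma_player: float
    sigma_fixture: float
    player_modes: pd.Series             # random-intercept modes
    player_cond_sd: pd.Series           # conditional sds of the modes
    fixture_modes: pd.Series
    player_position: pd.Series          # position of each player in the fit
    loglik: float
    grad_norm: float
    converged: bool
    offset_time: bool
    positions: list[str] = field(default_factory=list)
    degenerate_zero: bool = False


@dataclass(frozen=True)
class IncidenceEstimate:
    label: str                           # position or player id
    denominator: str                     # 'full_match_80' or 'median_playing_time'
    minutes: float
    mean: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

def _inner_mode(y, X_beta_eta0, pi, fi, qp, qf, dp, df_, b0=None,
                tol=1e-10, max_iter=100):
    """Newton mode of the joint random-effect posterior.

    ``X_beta_eta0`` is the fixed-effect part of the linear predictor
    (including any offset).  Returns (b_hat, H) where H is the negative
    Hessian (joint precision) at the mode, ordered (players, fixtures).
    """
    q = qp + qf
    b = np.zeros(q) if b0 is None else b0.copy()
    prior_prec = np.concatenate([np.full(qp, 1.0 / dp), np.full(qf, 1.0 / df_)])
    fi_off = fi + qp
    for _ in range(max_iter):
        eta = X_beta_eta0 + b[pi] + b[fi_off]
        mu = np.exp(np.clip(eta, -700, 700))
        resid = y - mu
        grad = -prior_prec * b
        np.add.at(grad, pi, resid)
        np.add.at(grad, fi_off, resid)
        H = np.zeros((q, q))
        wp = np.zeros(qp); np.add.at(wp, pi, mu)
        wf = np.zeros(qf); np.add.at(wf, fi, mu)
        H[np.arange(qp), np.arange(qp)] = wp
        H[qp + np.arange(qf), qp + np.arange(qf)] = wf
        np.add.at(H, (pi, fi_off), mu)
        H[:qp, qp:] = H[:qp, qp:]
        H[qp:, :qp] = H[:qp, qp:].T
        H[np.arange(q), np.arange(q)] += prior_prec
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the joint objective does not decrease
        f0 = (y * eta - mu).sum() - 0.5 * (prior_prec * b * b).sum()
        scale = 1.0
        for _ in range(30):
            b_new = b + scale * step
            eta_n = X_beta_eta0 + b_new[pi] + b_new[fi_off]
            mu_n = np.exp(np.clip(eta_n, -700, 700))
            f1 = (y * eta_n - mu_n).sum() - 0.5 * (prior_prec * b_new * b_new).sum()
            if f1 >= f0 - 1e-12:
                break
            scale *= 0.5
        b = b + scale * step
        if np.abs(grad).max() < tol:
            break
    return b, H


def laplace_loglik(y, eta_fixed, pi, fi, qp, qf, sigma_p, sigma_f, b0=None):
    """Laplace-approximated marginal log-likelihood.

    ``eta_fixed`` is the fixed-effect linear predictor per row; ``pi`` /
    ``fi`` are integer player and fixture indices.  Returns
    ``(loglik, b_hat)``.  The approximation is exact as both sigmas
    approach zero (it collapses to the plain Poisson log-likelihood).
    """
    dp = max(sigma_p, 1e-8) ** 2
    df_ = max(sigma_f, 1e-8) ** 2
    b, H = _inner_mode(y, eta_fixed, pi, fi, qp, qf, dp, df_, b0=b0)
    eta = eta_fixed + b[pi] + b[fi + qp]
    mu = np.exp(np.clip(eta, -700, 700))
    prior_prec = np.concatenate([np.full(qp, 1.0 / dp), np.full(qf, 1.0 / df_)])
    joint = ((y * eta - mu - gammaln(y + 1.0)).sum()
             - 0.5 * (prior_prec * b * b).sum())
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, b
    logdet_d = qp * np.log(dp) + qf * np.log(df_)
    return joint - 0.5 * logdet_d - 0.5 * logdet_h, b


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, offset_time: bool):
    positions = sorted(df["position"].unique())
    ref = positions[0]
    cols = ["(Intercept)"] + [f"position[{p}]" for p in positions[1:]]
    X = [np.ones(len(df))]
    for p in positions[1:]:
        X.append((df["position"] == p).to_numpy(float))
    log_m = np.log(df["playing_time"].to_numpy(float))
    offset = np.zeros(len(df))
    if offset_time:
        offset = log_m
    else:
        cols.append("log_minutes")
        X.append(log_m)
    return np.column_stack(X), cols, offset, positions, ref


def fit_poisson_glmm(
    counts: pd.DataFrame,
    count_col: str,
    threshold: tuple[str, float] | None = None,
    offset_time: bool = False,
    fix_sigmas: tuple[float, float] | None = None,
    grad_tol: float = 1e-3,
) -> IncidenceFit:
    """Fit the Poisson GLMM for one count column.

    ``counts`` needs columns player_id, fixture_id, position,
    playing_time and ``count_col``.  Requires at least two players and
    two fixtures.  ``fix_sigmas`` pins the random-intercept sds
    (``(0, 0)`` reduces the model to a plain Poisson regression).
    All-zero counts yield a degenerate zero-rate fit (with a warning)
    rather than an intercept at -infinity.
    """
    df = counts.reset_index(drop=True)
    y = df[count_col].to_numpy(float)
    players = sorted(df["player_id"].unique())
    fixtures = sorted(df["fixture_id"].unique())
    if len(players) < 2 or len(fixtures) < 2:
        raise FitError("need at least 2 players and 2 fixtures")
    X, cols, offset, positions, _ = _design(df, offset_time)
    player_pos = df.groupby("player_id")["position"].first().reindex(players)

    if not y.any():
        warnings.warn("all counts are zero: returning a degenerate zero-rate fit")
        k = X.shape[1]
        return IncidenceFit(
            threshold=threshold or ("", np.nan),
            beta=pd.Series(np.full(k, -np.inf), index=cols),
            vcov_beta=np.zeros((k, k)), sigma_player=0.0, sigma_fixture=0.0,
            player_modes=pd.Series(0.0, index=players),
            player_cond_sd=pd.Series(0.0, index=players),
            fixture_modes=pd.Series(0.0, index=fixtures),
            player_position=player_pos, loglik=0.0, grad_norm=0.0,
            converged=True, offset_time=offset_time, positions=positions,
            degenerate_zero=True)

    pi = pd.Categorical(df["player_id"], categories=players).codes.astype(int)
    fi = pd.Categorical(df["fixture_id"], categories=fixtures).codes.astype(int)
    qp, qf = len(players), len(fixtures)

    # plain Poisson GLM start values
    import statsmodels.api as sm
    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    beta0 = glm.fit().params
    k = X.shape[1]

    state = {"b": None}
    fixed = None if fix_sigmas is None else np.maximum(fix_sigmas, 0.0)

    def nll(theta):
        beta = theta[:k]
        if fixed is not None:
            sp, sf = fixed
        else:
            sp, sf = np.exp(theta[k]), np.exp(theta[k + 1])
        ll, b = laplace_loglik(y, X @ beta + offset, pi, fi, qp, qf, sp, sf,
                               b0=state["b"])
        state["b"] = b
        return -ll

    theta0 = np.concatenate([beta0, [np.log(0.3), np.log(0.3)]])
    bounds = [(None, None)] * k + [(-5.0, 2.0), (-5.0, 2.0)]
    if fixed is not None:
        bounds[k] = bounds[k + 1] = (np.log(0.3), np.log(0.3))
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x
    grad_norm = float(np.abs(res.jac).max()) if res.jac is not None else np.nan
    if not res.success and grad_norm > grad_tol:
        raise FitError(f"Poisson GLMM did not converge: |grad|_inf = {grad_norm:.3g}")

    beta = theta[:k]
    if fixed is not None:
        sp, sf = float(fixed[0]), float(fixed[1])
    else:
        sp, sf = float(np.exp(theta[k])), float(np.exp(theta[k + 1]))
    ll, b_hat = laplace_loglik(y, X @ beta + offset, pi, fi, qp, qf, sp, sf,
                               b0=state["b"])
    # conditional sds of the random-effect modes from the joint precision
    dp, dfx = max(sp, 1e-8) ** 2, max(sf, 1e-8) ** 2
    _, H = _inner_mode(y, X @ beta + offset, pi, fi, qp, qf, dp, dfx, b0=b_hat)
    cond_var = np.diag(np.linalg.inv(H))

    free = np.ones(theta.size, dtype=bool)
    if fixed is not None:
        free[k:] = False
    else:
        free[k:] = theta[k:] > -4.5  # log-sigmas pinned at the lower bound
    vcov = _vcov_from_hessian(nll, theta, free=free)
    return IncidenceFit(
        threshold=threshold or ("", np.nan),
        beta=pd.Series(beta, index=cols),
        vcov_beta=vcov[:k, :k],
        sigma_player=sp, sigma_fixture=sf,
        player_modes=pd.Series(b_hat[:qp], index=players),
        player_cond_sd=pd.Series(np.sqrt(np.maximum(cond_var[:qp], 0.0)), index=players),
        fixture_modes=pd.Series(b_hat[qp:], index=fixtures),
        player_position=player_pos,
        loglik=float(ll), grad_norm=grad_norm, converged=True,
        offset_time=offset_time, positions=positions)


def _vcov_from_hessian(nll, theta, rel_step=1e-4, free=None):
    """Covariance of the estimates from a central-difference Hessian.

    ``free`` is a boolean mask of parameters to differentiate over;
    parameters at a boundary (e.g. a variance component estimated at its
    lower bound) are excluded — their curvature is one-sided and would
    make the Hessian numerically singular — and get zero rows/columns.
    """
    n = theta.size
    idx = np.flatnonzero(free) if free is not None else np.arange(n)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.zeros((idx.size, idx.size))
    f0 = nll(theta)
    for a, i in enumerate(idx):
        for b, j in enumerate(idx[a:], start=a):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[a, a] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h[i] ** 2
            else:
                H[a, b] = H[b, a] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    out = np.zeros((n, n))
    out[np.ix_(idx, idx)] = V
    return out


# ---------------------------------------------------------------------------
# Estimates
# ---------------------------------------------------------------------------

def _safe_exp(eta: float) -> float:
    """exp on the link scale, saturating instead of overflowing for the
    very wide intervals of near-degenerate fits."""
    return float(np.exp(min(eta, 700.0)))


def _linear_predictor_row(fit: IncidenceFit, position: str, minutes: float):
    if position not in fit.positions:
        raise KeyError(f"position {position!r} not present in the fit "
                       f"(have {fit.positions})")
    x = np.zeros(len(fit.beta))
    names = list(fit.beta.index)
    x[names.index("(Intercept)")] = 1.0
    key = f"position[{position}]"
    if key in names:
        x[names.index(key)] = 1.0
    log_m = np.log(minutes)
    extra = 0.0
    if fit.offset_time:
        extra = log_m
    else:
        x[names.index("log_minutes")] = log_m
    return x, extra


def estimate_incidence(fit: IncidenceFit, minutes: float, position: str,
                       denominator: str = "median_playing_time") -> IncidenceEstimate:
    """Position-level incidence per ``minutes`` of play (random effects 0)."""
    if fit.degenerate_zero:
        return IncidenceEstimate(position, denominator, minutes, 0.0, 0.0, 0.0)
    x, extra = _linear_predictor_row(fit, position, minutes)
    eta = float(x @ fit.beta.to_numpy() + extra)
    se = float(np.sqrt(max(x @ fit.vcov_beta @ x, 0.0)))
    return IncidenceEstimate(position, denominator, minutes,
                             _safe_exp(eta),
                             _safe_exp(eta - _Z95 * se),
                             _safe_exp(eta + _Z95 * se))


def individual_incidence(fit: IncidenceFit, player_id: str,
                         player_median_minutes: float) -> IncidenceEstimate:
    """Player-level incidence: position mean shifted by the player's
    random-intercept mode, at the player's own median playing time.

    The interval combines fixed-effect uncertainty with the conditional
    sd of the player intercept.
    """
    if player_id not in fit.player_modes.index:
        raise KeyError(f"unknown player {player_id!r}")
    if fit.degenerate_zero:
        return IncidenceEstimate(player_id, "median_playing_time",
                                 player_median_minutes, 0.0, 0.0, 0.0)
    position = fit.player_position.loc[player_id]
    x, extra = _linear_predictor_row(fit, position, player_median_minutes)
    eta = float(x @ fit.beta.to_numpy() + extra + fit.player_modes.loc[player_id])
    var = float(x @ fit.vcov_beta @ x) + float(fit.player_cond_sd.loc[player_id]) ** 2
    se = np.sqrt(max(var, 0.0))
    return IncidenceEstimate(player_id, "median_playing_time", player_median_minutes,
                             _safe_exp(eta),
                             _safe_exp(eta - _Z95 * se),
                             _safe_exp(eta + _Z95 * se))


def position_median_minutes(player_matches: pd.DataFrame) -> pd.Series:
    """Season median playing time per position."""
    return player_matches.groupby("position")["playing_time"].median()


def player_median_minutes(player_matches: pd.DataFrame) -> pd.Series:
    """Median playing time per player across their recorded matches."""
    return player_matches.groupby("player_id")["playing_time"].median()
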