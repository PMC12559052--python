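"""Ordinal mixed model of per-involvement maximum HAE magnitude.

Each (wear-period, non-sequential) tackle involvement contributes one
ordered outcome per metric: the band of the threshold grid containing
the maximum magnitude of its linked HAEs, with ``no recorded HAEs``
as the lowest category (assumed not to have exceeded the sensor
trigger), a sub-lowest recorded band below the first grid threshold, and
an open top band above the last.  A proportional-odds cumulative logit
model with a ball-carrier/tackler role effect and random intercepts for
fixture, player-within-fixture and tackle event is fitted by
Laplace-approximated maximum likelihood (sparse inner Newton over the
random effects, L-BFGS-B outer over cutpoints, role effect and
variance components):

    P(Y_i <= k) = logistic(theta_k - beta * carrier_i - b_fix - b_pf - b_te).

Group exceedance probabilities are obtained by a parametric bootstrap:
parameter vectors are drawn from the asymptotic normal of the fit (in
the ordering-preserving transformed space), random effects are
marginalised by Monte-Carlo integration over their fitted distribution,
and P(max > threshold | role) is summarised by its mean and percentile
interval over draws.  Individual probabilities are simple per-player
proportions computed outside the model, restricted to players with more
than 15 involvements in both roles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu
from scipy.special import expit

from .config import AnalysisConfig, ThresholdGrid
from .incidence import FitError
from .linking import NO_HAE

__all__ = [
    "OrdinalData",
    "OrdinalFit",
    "build_ordinal_outcome",
    "fit_clmm",
    "exceedance_probabilities",
    "individual_probabilities",
    "simulate_ordinal_outcomes",
]

_ROLE_CARRIER = "ball-carrier"


# ---------------------------------------------------------------------------
# Outcome construction
# ---------------------------------------------------------------------------

def band_labels(thresholds: tuple[float, ...], unit: str = "") -> list[str]:
    """Ordered category labels: NO_HAE, sub-lowest, bands, open top."""
    t = list(thresholds)
    labels = [NO_HAE, f"<= {t[0]:g}{unit} (recorded)"]
    labels += [f"({a:g}, {b:g}]{unit}" for a, b in zip(t[:-1], t[1:])]
    labels.append(f"> {t[-1]:g}{unit}")
    return labels


def build_ordinal_outcome(
    involvements: pd.DataFrame, grid: ThresholdGrid, metric: str,
) -> pd.DataFrame:
    """One ordered outcome per involvement for one metric.

    Requires the per-involvement maxima (``max_<metric>`` columns, NaN
    meaning no linked HAEs).  Bands are half-open, upper-inclusive:
    a 25 g maximum falls in (10, 25], a 27 g maximum in (25, 40].
    Involvements outside wear periods are dropped when an ``in_wear``
    column is present.
    """
    thresholds = grid.for_metric(metric)
    col = f"max_{metric}"
    if col not in involvements.columns:
        raise KeyError(f"missing per-involvement maxima column {col!r}")
    df = involvements
    if "in_wear" in df.columns:
        df = df[df["in_wear"]]
    df = df.reset_index(drop=True)
    vals = df[col].to_numpy(float)
    if (vals[~np.isnan(vals)] < 0).any():
        raise ValueError(f"negative per-involvement maxima in {col}")
    # category 0 = NO_HAE; category 1 + j = exactly j thresholds strictly
    # exceeded, so a value equal to a threshold stays in the band below
    cat = np.where(np.isnan(vals), 0,
                   1 + np.sum(vals[:, None] > np.asarray(thresholds)[None, :], axis=1))
    labels = band_labels(thresholds)
    out = pd.DataFrame({
        "involvement_id": df["involvement_id"],
        "metric": metric,
        "category": cat.astype(int),
        "category_label": [labels[c] for c in cat.astype(int)],
        "role": df["role"],
        "player_id": df["player_id"],
        "fixture_id": df["fixture_id"],
        "tackle_event_id": df["tackle_event_id"],
    })
    out.attrs["labels"] = labels
    out.attrs["thresholds"] = tuple(thresholds)
    return out


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class OrdinalData:
    """Integer-coded design for the cumulative-link mixed model."""

    y: np.ndarray               # category index per row, 0..K-1
    x: np.ndarray               # 1.0 for ball-carrier
    groups: list[np.ndarray]    # integer group index per row, per RE term
    group_sizes: list[int]
    n_categories: int
    labels: list[str]
    upper_bounds: list[float]   # upper bound of the category below cutpoint k


@dataclass
class OrdinalFit:
    cutpoints: np.ndarray
    beta_role: float            # ball-carrier shift toward higher categories
    sigmas: tuple[float, ...]   # (fixture, player-in-fixture, tackle-event)
    vcov_transformed: np.ndarray
    theta_transformed: np.ndarray
    labels: list[str]
    upper_bounds: list[float]
    loglik: float
    grad_norm: float
    converged: bool
    re_structure: str = "nested"
    merged_categories: list[str] = field(default_factory=list)
    fixed_sigmas: tuple[float, float, float] | None = None


def _encode(outcomes: pd.DataFrame, re_structure: str = "nested") -> OrdinalData:
    labels = outcomes.attrs.get("labels")
    thresholds = outcomes.attrs.get("thresholds")
    y = outcomes["category"].to_numpy(int)
    # drop globally-empty categories (merge into the band above)
    present = np.sort(np.unique(y))
    # label/threshold metadata only applies when categories are the
    # canonical 0..K-1 band indices (not after arbitrary monotone
    # relabelling, which leaves the fit itself unchanged)
    canonical = labels is not None and present.max() < len(labels)
    merged = []
    if canonical and len(present) < len(labels):
        merged = [labels[k] for k in range(len(labels)) if k not in present]
        if merged:
            warnings.warn(f"empty categories merged upward: {merged}")
    remap = {old: new for new, old in enumerate(present)}
    y = np.array([remap[v] for v in y])
    labels = ([labels[k] for k in present] if canonical
              else [f"cat{k}" for k in present])
    # upper bound of category k (for mapping thresholds to cutpoints)
    ubs = []
    if canonical and thresholds is not None:
        all_ub = [0.0, *thresholds, np.inf]
        ubs = [all_ub[k] for k in present][:-1]
    x = (outcomes["role"] == _ROLE_CARRIER).to_numpy(float)
    if re_structure == "nested":
        keys = [outcomes["fixture_id"].astype(str),
                outcomes["fixture_id"].astype(str) + ":" + outcomes["player_id"].astype(str),
                outcomes["tackle_event_id"].astype(str)]
    elif re_structure == "crossed":
        keys = [outcomes["fixture_id"].astype(str),
                outcomes["player_id"].astype(str),
                outcomes["tackle_event_id"].astype(str)]
    else:
        raise ValueError("re_structure must be 'nested' or 'crossed'")
    groups, sizes = [], []
    for k in keys:
        codes, uniq = pd.factorize(k, sort=True)
        groups.append(codes.astype(int))
        sizes.append(len(uniq))
    return OrdinalData(y=y, x=x, groups=groups, group_sizes=sizes,
                       n_categories=len(present), labels=labels,
                       upper_bounds=ubs)


def _obs_derivs(y, eta, cutpoints):
    """Per-row loglik, first and negative second derivative wrt eta."""
    theta = np.concatenate([[-np.inf], cutpoints, [np.inf]])
    u2 = theta[y + 1] - eta
    u1 = theta[y] - eta
    F2, F1 = expit(u2), expit(u1)
    f2 = F2 * (1.0 - F2)
    f1 = F1 * (1.0 - F1)
    P = np.clip(F2 - F1, 1e-300, 1.0)
    dl = (f1 - f2) / P
    fp2 = f2 * (1.0 - 2.0 * F2)
    fp1 = f1 * (1.0 - 2.0 * F1)
    d2l = (fp2 - fp1) / P - dl * dl
    return np.log(P), dl, np.maximum(-d2l, 1e-12)


def _sparse_mode(data: OrdinalData, cutpoints, beta, prior_var,
                 b0=None, tol=1e-9, max_iter=60):
    """Newton mode of the random-effect posterior; returns (b, logdet H, ll_parts)."""
    offsets = np.concatenate([[0], np.cumsum(data.group_sizes)])[:-1]
    q = int(sum(data.group_sizes))
    cols = [g + o for g, o in zip(data.groups, offsets)]
    prior_prec = np.concatenate([
        np.full(s, 1.0 / max(v, 1e-10))
        for s, v in zip(data.group_sizes, prior_var)])
    b = np.zeros(q) if b0 is None or b0.size != q else b0.copy()
    eta_fixed = beta * data.x

    def joint(bvec):
        eta = eta_fixed + sum(bvec[c] for c in cols)
        lp, _, _ = _obs_derivs(data.y, eta, cutpoints)
        return lp.sum() - 0.5 * (prior_prec * bvec * bvec).sum()

    f0 = joint(b)
    logdet = 0.0
    for _ in range(max_iter):
        eta = eta_fixed + sum(b[c] for c in cols)
        lp, dl, w = _obs_derivs(data.y, eta, cutpoints)
        grad = -prior_prec * b
        for c in cols:
            np.add.at(grad, c, dl)
        rows_idx, cols_idx, vals = [], [], []
        for ci in cols:
            for cj in cols:
                rows_idx.append(ci); cols_idx.append(cj); vals.append(w)
        H = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(q, q)).tocsc()
        H = H + sparse.diags(prior_prec, format="csc")
        lu = splu(H)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        if np.abs(grad).max() < tol:
            break
        step = lu.solve(grad)
        scale = 1.0
        for _ in range(30):
            f1 = joint(b + scale * step)
            if f1 >= f0 - 1e-12:
                break
            scale *= 0.5
        b = b + scale * step
        f0 = f1
    eta = eta_fixed + sum(b[c] for c in cols)
    lp, _, _ = _obs_derivs(data.y, eta, cutpoints)
    joint_ll = lp.sum() - 0.5 * (prior_prec * b * b).sum()
    logdet_d = float(sum(s * np.log(max(v, 1e-10))
                         for s, v in zip(data.group_sizes, prior_var)))
    return b, joint_ll - 0.5 * logdet_d - 0.5 * logdet


def _unpack(theta, k_cut):
    cut = np.empty(k_cut)
    cut[0] = theta[0]
    if k_cut > 1:
        cut[1:] = cut[0] + np.cumsum(np.exp(theta[1:k_cut]))
    beta = theta[k_cut]
    sigmas = np.exp(theta[k_cut + 1:])
    return cut, beta, sigmas


def fit_clmm(
    outcomes: pd.DataFrame,
    re_structure: str = "nested",
    fix_sigmas: tuple[float, float, float] | None = None,
    grad_tol: float = 5e-3,
) -> OrdinalFit:
    """Fit the cumulative-link mixed model by Laplace ML.

    ``outcomes`` is the frame from :func:`build_ordinal_outcome` (both
    roles must be present and at least two categories realised).
    ``fix_sigmas`` pins the random-effect sds (``(0, 0, 0)`` reduces the
    model to a plain proportional-odds regression).
    """
    if outcomes["role"].nunique() < 2:
        raise FitError("both roles must be present")
    data = _encode(outcomes, re_structure)
    K = data.n_categories
    if K < 2:
        raise FitError("need at least two realised outcome categories")
    k_cut = K - 1
    # start: marginal cumulative logits
    freq = np.bincount(data.y, minlength=K) / data.y.size
    cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
    cut0 = np.log(cum / (1 - cum))
    cut0 = np.maximum.accumulate(cut0)
    cut0[1:] = np.maximum(cut0[1:], cut0[:-1] + 1e-3)
    theta0 = np.concatenate([
        [cut0[0]], np.log(np.maximum(np.diff(cut0), 1e-3)),
        [0.0],
        np.log([0.3, 0.3, 0.3]),
    ])

    state = {"b": np.zeros(0)}
    fixed = None if fix_sigmas is None else np.asarray(fix_sigmas, float)

    def nll(theta):
        cut, beta, sigmas = _unpack(theta, k_cut)
        if fixed is not None:
            sigmas = fixed
        prior_var = np.maximum(sigmas, 1e-5) ** 2
        b, ll = _sparse_mode(data, cut, beta, prior_var, b0=state["b"])
        state["b"] = b
        return -ll

    n_par = k_cut + 1 + 3
    bounds = [(None, None)] * (k_cut + 1) + [(-5.0, 2.0)] * 3
    if fixed is not None:
        bounds = [(None, None)] * (k_cut + 1) + [(np.log(0.3), np.log(0.3))] * 3
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 600, "ftol": 1e-11, "gtol": 1e-7})
    theta = res.x
    grad_norm = float(np.abs(res.jac).max()) if res.jac is not None else np.nan
    if not res.success and grad_norm > grad_tol:
        raise FitError(f"CLMM did not converge: |grad|_inf = {grad_norm:.3g}")
    cut, beta, sigmas = _unpack(theta, k_cut)
    if fixed is not None:
        sigmas = fixed
    free = np.ones(theta.size, dtype=bool)
    if fixed is not None:
        free[k_cut + 1:] = False
    else:
        free[k_cut + 1:] = theta[k_cut + 1:] > -4.5  # boundary sigmas
    vcov = _numeric_vcov(nll, theta, free=free)
    labels_all = outcomes.attrs.get("labels") or []
    merged = [l for l in labels_all if l not in data.labels]
    return OrdinalFit(
        cutpoints=cut, beta_role=float(beta),
        sigmas=tuple(float(s) for s in sigmas),
        vcov_transformed=vcov, theta_transformed=theta,
        labels=data.labels, upper_bounds=data.upper_bounds,
        loglik=float(-res.fun), grad_norm=grad_norm, converged=True,
        re_structure=re_structure, merged_categories=merged,
        fixed_sigmas=None if fix_sigmas is None else tuple(fix_sigmas))


def _numeric_vcov(nll, theta, rel_step=2e-4, free=None):
    """Inverse central-difference Hessian; fixed or boundary parameters
    get zero rows/columns (their bootstrap draws stay at the estimate)."""
    n = theta.size
    idx = np.flatnonzero(free) if free is not None else np.arange(n)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.zeros((idx.size, idx.size))
    f0 = nll(theta)
    for a, i in enumerate(idx):
        for b_, j in enumerate(idx[a:], start=a):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[a, a] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h[i] ** 2
            else:
                H[a, b_] = H[b_, a] = (
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
# Exceedance probabilities
# ---------------------------------------------------------------------------

def _cutpoint_for_threshold(fit: OrdinalFit, threshold: float) -> int:
    for k, ub in enumerate(fit.upper_bounds):
        if np.isclose(ub, threshold):
            return k
    raise KeyError(
        f"threshold {threshold:g} has no matching band boundary "
        f"(bounds: {fit.upper_bounds})")


def exceedance_probabilities(
    fit: OrdinalFit,
    thresholds: tuple[float, ...],
    metric: str = "",
    n_boot: int = 2000,
    re_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Parametric-bootstrap P(max magnitude > threshold | role).

    Parameter vectors are drawn from N(theta_hat, vcov) in the
    transformed space (so cutpoint ordering is preserved); for each draw
    the random effects are integrated out by Monte Carlo over their
    fitted normal distribution; the estimate is the mean over draws and
    the interval the 2.5/97.5 percentiles.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be unstable")
    rng = np.random.default_rng(seed)
    k_cut = fit.cutpoints.size
    theta = fit.theta_transformed
    V = fit.vcov_transformed
    # ensure positive semi-definite draw covariance
    w, Q = np.linalg.eigh((V + V.T) / 2.0)
    Lv = Q @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    draws = theta[None, :] + rng.standard_normal((n_boot, theta.size)) @ Lv.T
    z = rng.standard_normal(re_draws)

    rows = []
    for threshold in thresholds:
        try:
            k = _cutpoint_for_threshold(fit, threshold)
        except KeyError:
            # no outcome ever exceeded this threshold: the band boundary was
            # merged away and the ML exceedance is degenerate at zero
            for role in (_ROLE_CARRIER, "tackler"):
                rows.append({"role": role, "metric": metric, "threshold": threshold,
                             "probability": 0.0, "ci_low": 0.0, "ci_high": 0.0,
                             "boundary_observed": False,
                             "n_boot": n_boot, "seed": seed})
            continue
        for role, xval in ((_ROLE_CARRIER, 1.0), ("tackler", 0.0)):
            probs = np.empty(n_boot)
            for i in range(n_boot):
                cut, beta, sigmas = _unpack(draws[i], k_cut)
                if fit.fixed_sigmas is not None:
                    sigmas = np.asarray(fit.fixed_sigmas)
                s_tot = float(np.sqrt(np.sum(np.square(sigmas))))
                b = z * s_tot
                probs[i] = float(np.mean(expit(-(cut[k] - beta * xval - b))))
            rows.append({
                "role": role, "metric": metric, "threshold": threshold,
                "probability": float(probs.mean()),
                "ci_low": float(np.percentile(probs, 2.5)),
                "ci_high": float(np.percentile(probs, 97.5)),
                "boundary_observed": True,
                "n_boot": n_boot, "seed": seed,
            })
    return pd.DataFrame(rows)


def band_probabilities(
    fit: OrdinalFit, n_boot: int = 2000, re_draws: int = 500, seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap probability of the maximum falling in each ordinal band."""
    rng = np.random.default_rng(seed)
    k_cut = fit.cutpoints.size
    theta = fit.theta_transformed
    w, Q = np.linalg.eigh((fit.vcov_transformed + fit.vcov_transformed.T) / 2.0)
    Lv = Q @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    draws = theta[None, :] + rng.standard_normal((n_boot, theta.size)) @ Lv.T
    z = rng.standard_normal(re_draws)
    rows = []
    for role, xval in ((_ROLE_CARRIER, 1.0), ("tackler", 0.0)):
        band = np.empty((n_boot, k_cut + 1))
        for i in range(n_boot):
            cut, beta, sigmas = _unpack(draws[i], k_cut)
            if fit.fixed_sigmas is not None:
                sigmas = np.asarray(fit.fixed_sigmas)
            s_tot = float(np.sqrt(np.sum(np.square(sigmas))))
            cum = expit(cut[:, None] - beta * xval - z[None, :] * s_tot).mean(axis=1)
            cum = np.concatenate([[0.0], cum, [1.0]])
            band[i] = np.diff(cum)
        for k in range(k_cut + 1):
            rows.append({
                "role": role, "category_label": fit.labels[k],
                "probability": float(band[:, k].mean()),
                "ci_low": float(np.percentile(band[:, k], 2.5)),
                "ci_high": float(np.percentile(band[:, k], 97.5)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Individual proportions (outside the model)
# ---------------------------------------------------------------------------

def individual_probabilities(
    involvements: pd.DataFrame,
    grid: ThresholdGrid,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-player exceedance proportions, by role and threshold.

    Simple division: involvements whose maximum strictly exceeds the
    threshold over all measured involvements of that player and role.
    Only players with strictly more than ``min_involvements_individual``
    (default 15) involvements in *both* roles are reported.
    """
    cfg = cfg or AnalysisConfig()
    df = involvements
    if "in_wear" in df.columns:
        df = df[df["in_wear"]]
    counts = df.groupby(["player_id", "role"]).size().unstack(fill_value=0)
    for role in (_ROLE_CARRIER, "tackler"):
        if role not in counts:
            counts[role] = 0
    eligible = counts[(counts[_ROLE_CARRIER] > cfg.min_involvements_individual)
                      & (counts["tackler"] > cfg.min_involvements_individual)].index
    rows = []
    for player in sorted(eligible):
        for role in (_ROLE_CARRIER, "tackler"):
            sub = df[(df["player_id"] == player) & (df["role"] == role)]
            n = len(sub)
            for metric in ("pla", "paa", "rvci"):
                vals = sub[f"max_{metric}"].to_numpy(float)
                for threshold in grid.for_metric(metric):
                    k = int(np.nansum(vals > threshold))
                    rows.append({
                        "player_id": player, "role": role, "metric": metric,
                        "threshold": threshold, "n_involvements": n,
                        "n_exceeding": k, "proportion": k / n if n else np.nan,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model-based simulation (recovery-test oracle input)
# ---------------------------------------------------------------------------

def simulate_ordinal_outcomes(
    n_fixtures: int,
    players_per_fixture: int,
    involvements_per_player: int,
    cutpoints: np.ndarray,
    beta_role: float,
    sigmas: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ordinal outcomes directly from the cumulative-link model.

    Half of each player's involvements are as ball-carrier.  Tackle
    events are singletons (one observed involvement each), fixtures and
    player-within-fixture groups share their drawn intercepts.  The
    ``attrs`` carry synthetic band labels so the frame feeds
    :func:`fit_clmm` directly.
    """
    rng = np.random.default_rng(seed)
    cutpoints = np.asarray(cutpoints, float)
    K = cutpoints.size + 1
    rows = []
    for f in range(n_fixtures):
        b_f = rng.normal(0, sigmas[0]) if sigmas[0] > 0 else 0.0
        for p in range(players_per_fixture):
            b_pf = rng.normal(0, sigmas[1]) if sigmas[1] > 0 else 0.0
            for i in range(involvements_per_player):
                b_te = rng.normal(0, sigmas[2]) if sigmas[2] > 0 else 0.0
                carrier = i % 2 == 0
                eta = beta_role * carrier + b_f + b_pf + b_te
                cum = expit(cutpoints - eta)
                u = rng.random()
                y = int(np.searchsorted(cum, u))
                rows.append({
                    "involvement_id": f"I{len(rows):06d}",
                    "metric": "pla", "category": y,
                    "category_label": f"cat{y}",
                    "role": _ROLE_CARRIER if carrier else "tackler",
                    "player_id": f"P{p:03d}", "fixture_id": f"F{f:03d}",
                    "tackle_event_id": f"E{len(rows):06d}",
                })
    out = pd.DataFrame(rows)
    out.attrs["labels"] = [f"cat{k}" for k in range(K)]
    out.attrs["thresholds"] = tuple(float(k) for k in range(1, K - 1))
    return out
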