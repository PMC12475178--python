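"""Multilevel probit estimation of orientation response biases.

The analysis model for the binary clockwise/counterclockwise judgement is

    P(right) = Phi(eta),    eta = b0 + b1*T + b2*F + b3*S + b4*F:S + u_p

with categorical predictors T (test offset), F (adaptor condition, the
baseline sessions carrying the sentinel level -999), S (standard
orientation) and their F:S interaction, and a Gaussian random intercept u_p
per participant.  The conditional intercept of a condition cell (F, S) —
eta evaluated at the zero-offset reference level with the random effect at
zero — is the probit-scale response bias for that cell; subtracting the
baseline cell at the same standard isolates the bias attributable to
adaptation.

Estimation is maximum likelihood with Gauss-Hermite quadrature over the
random intercept (analytic gradient, L-BFGS-B); standard errors come from
the numerically differentiated observed information.  A second,
descriptive uncertainty — the between-observer standard error of mean
predicted responses per cell — is provided by :func:`prediction_se`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
from scipy import optimize
from scipy.special import log_ndtr, roots_hermitenorm
from scipy.stats import chi2, norm

import statsmodels.api as sm

from .design import BASELINE, relative_standard

logger = logging.getLogger(__name__)

__all__ = ["BiasFit", "ConditionBias", "FitError", "fit_bias_model",
           "conditional_bias", "subtract_baseline", "prediction_se",
           "quality_check", "cell_bias_table"]


class FitError(RuntimeError):
    """Model fitting failed; the message carries optimizer diagnostics."""


@dataclass
class ConditionBias:
    """Conditional bias of one (adaptor, standard) cell."""

    adaptor: float
    standard: float
    rel_standard: float | None
    bias: float          # probit scale
    se: float            # Wald SE from the observed information
    bias_deg: float      # degree equivalent: bias / fitted slope per degree
    baseline_subtracted: bool = False
    p_value: float | None = None


@dataclass
class BiasFit:
    """A fitted multilevel probit bias model."""

    params: np.ndarray           # fixed effects followed by sigma_u
    names: list
    cov: np.ndarray              # covariance of the full parameter vector
    loglik: float
    design_info: object          # patsy design info for prediction rows
    col_keep: np.ndarray         # mask of design columns retained in the fit
    data: pd.DataFrame
    eta: np.ndarray              # per-trial linear predictor (pop. level)
    participant_effects: pd.Series  # posterior-mean random intercepts
    predictions: np.ndarray      # per-trial P(right) incl. participant effect
    slope_per_degree: float      # local probit slope from adjacent offsets

    @property
    def beta(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def sigma_u(self) -> float:
        return float(self.params[-1])

    def cell_row(self, adaptor: float, standard: float) -> np.ndarray:
        """Design row for a cell at the zero-offset reference level."""
        frame = pd.DataFrame({"offset_deg": [0.0],
                              "adaptor_deg": [float(adaptor)],
                              "standard_deg": [float(standard)]})
        (row,) = patsy.build_design_matrices([self.design_info], frame)
        return np.asarray(row)[0][self.col_keep]


_FORMULA = ("C(offset_deg, Treatment({t_ref})) "
            "+ C(adaptor_deg, Treatment({f_ref})) "
            "* C(standard_deg, Treatment({s_ref}))")


def _design_matrix(trials: pd.DataFrame, t_ref, f_ref, s_ref):
    formula = _FORMULA.format(t_ref=t_ref, f_ref=f_ref, s_ref=s_ref)
    mat = patsy.dmatrix(formula, trials, return_type="dataframe")
    return mat


def _gh_nodes(k: int = 21):
    """Probabilists' Gauss-Hermite nodes/weights for N(0,1) expectations."""
    z, w = roots_hermitenorm(k)
    w = w / np.sqrt(2 * np.pi)
    return z, w


def _loglik_and_grad(theta, X, s, groups, n_groups, z, w):
    """Marginal log-likelihood and analytic gradient.

    theta = [beta, sigma]; s = 2y - 1; groups are 0..n_groups-1 codes.
    The integral over each participant's intercept is a weighted sum over
    quadrature nodes of exp(sum_j log Phi(s_j (x_j'beta + sigma z_k))).
    """
    beta, sigma = theta[:-1], theta[-1]
    eta = X @ beta
    K = len(z)
    a = s[None, :] * (eta[None, :] + sigma * z[:, None])  # K x N
    logphi = log_ndtr(a)
    # per (group, node) sums of log Phi
    ll_gk = np.zeros((K, n_groups))
    for k in range(K):
        ll_gk[k] = np.bincount(groups, weights=logphi[k], minlength=n_groups)
    # log L_g = logsumexp_k(log w_k + ll_gk)
    lw = np.log(w)[:, None] + ll_gk
    m = lw.max(axis=0)
    L = np.exp(lw - m[None, :])
    sumL = L.sum(axis=0)
    loglik = float(np.sum(m + np.log(sumL)))
    # posterior node weights per group
    post = L / sumL[None, :]                       # K x G
    # inverse Mills ratio phi/Phi at each (k, j)
    ratio = np.exp(norm.logpdf(a) - logphi)        # K x N
    wj = post[:, groups]                           # K x N
    cj = np.einsum("kj,kj->j", wj, ratio * s[None, :])
    gbeta = X.T @ cj
    gsigma = float(np.einsum("kj,kj,k->", wj, ratio * s[None, :], z))
    return loglik, np.concatenate([gbeta, [gsigma]])


def _fit_ml(X, y, groups, n_groups, start, gh_points=21, tol=1e-12,
            pin_sigma=False):
    s = 2.0 * y - 1.0
    z, w = _gh_nodes(gh_points)

    def negll(theta):
        ll, g = _loglik_and_grad(theta, X, s, groups, n_groups, z, w)
        return -ll, -g

    # with a single participant the intercept and the random effect are
    # confounded; pin sigma_u at ~0 so the fit is an ordinary probit
    sigma_bounds = (1e-8, 1e-8) if pin_sigma else (1e-6, None)
    bounds = [(None, None)] * (X.shape[1]) + [sigma_bounds]
    res = optimize.minimize(negll, start, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 1000, "ftol": tol,
                                     "gtol": 1e-8})
    if not res.success and "ABNORMAL" in str(res.message):
        raise FitError(f"multilevel probit fit failed: {res.message}")
    if not np.all(np.isfinite(res.x)) or np.abs(res.x[:-1]).max() > 50:
        raise FitError(
            "non-finite or diverging coefficients (possible separation); "
            f"max |beta| = {np.abs(res.x[:-1]).max():.3g}")
    return res, z, w, s


def _observed_information(theta, X, s, groups, n_groups, z, w):
    """Numerical Jacobian of the analytic gradient (central differences)."""
    p = len(theta)
    H = np.zeros((p, p))
    for i in range(p):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _loglik_and_grad(tp, X, s, groups, n_groups, z, w)
        _, gm = _loglik_and_grad(tm, X, s, groups, n_groups, z, w)
        H[i] = (gp - gm) / (2 * h)
    return -0.5 * (H + H.T)  # symmetrised observed information


def fit_bias_model(trials: pd.DataFrame, t_ref: float = 0.0,
                   f_ref: float = BASELINE, s_ref: float | None = None,
                   gh_points: int = 21) -> BiasFit:
    """Fit the multilevel probit bias model to completed trials.

    Uses the baseline-eligible trials (baseline session plus the
    no-feedback practice trials flagged for the baseline dataset) and all
    adaptation main trials; requires every modelled (F, S) cell non-empty
    and, for a random-intercept fit, at least 2 participants (with a single
    participant the model collapses to an ordinary probit regression,
    sigma_u pinned at ~0).

    Reference levels of the categorical predictors are configurable; cell
    biases from :func:`conditional_bias` are invariant to that choice.
    """
    df = trials.loc[trials["response"].notna()].copy()
    if "include_in_baseline" in df.columns and "phase" in df.columns:
        keep = (df["phase"] == "main") | df["include_in_baseline"].astype(bool)
        df = df.loc[keep]
    if df.empty:
        raise ValueError("no completed trials to fit")
    cells = df.groupby(["adaptor_deg", "standard_deg"]).size()
    empty_msg = [c for c, n in cells.items() if n == 0]
    if empty_msg:
        raise ValueError(f"empty design cells: {empty_msg}")
    if s_ref is None:
        s_ref = float(np.sort(df["standard_deg"].unique())[0])

    Xdf = _design_matrix(df, t_ref, f_ref, s_ref)
    X_full = Xdf.to_numpy()
    # Partially counterbalanced cohorts leave dummy columns empty or
    # collinear (an adaptor only ever seen with two of the standards).
    # Restrict to an independent column basis (pivoted QR); predictions for
    # observed cells are estimable and unaffected by the basis choice.
    _, R, piv = scipy.linalg.qr(X_full, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > diag[0] * 1e-10))
    col_keep = np.zeros(X_full.shape[1], dtype=bool)
    col_keep[np.sort(piv[:rank])] = True
    X = X_full[:, col_keep]
    names_kept = [n for n, k in zip(Xdf.columns, col_keep) if k]
    y = df["response"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(df["participant"])
    n_groups = len(uniques)
    single = n_groups < 2

    glm = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Probit()))
    glm_fit = glm.fit()
    start = np.concatenate([glm_fit.params, [1e-8 if single else 0.3]])

    res, z, w, s = _fit_ml(X, y, codes, n_groups, start, gh_points,
                           pin_sigma=single)
    theta = res.x
    info = _observed_information(theta, X, s, codes, n_groups, z, w)
    try:
        if single:  # sigma_u is pinned, not estimated
            cov = np.zeros_like(info)
            cov[:-1, :-1] = np.linalg.inv(info[:-1, :-1])
        else:
            cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)

    beta = theta[:-1]
    sigma = theta[-1]
    eta = X @ beta

    # posterior-mean random intercepts and per-trial predictions
    a = s[None, :] * (eta[None, :] + sigma * z[:, None])
    ll_gk = np.vstack([np.bincount(codes, weights=row, minlength=n_groups)
                       for row in log_ndtr(a)])
    lw = np.log(w)[:, None] + ll_gk
    post = np.exp(lw - lw.max(axis=0)[None, :])
    post /= post.sum(axis=0)[None, :]
    u_hat = sigma * (post * z[:, None]).sum(axis=0)
    participant_effects = pd.Series(u_hat, index=list(uniques),
                                    name="u_hat")
    predictions = norm.cdf(eta + u_hat[codes])

    slope = _slope_per_degree(names_kept, beta, t_ref)

    logger.info("multilevel probit: %d trials, %d participants, "
                "loglik=%.2f, sigma_u=%.3f", len(df), n_groups,
                -res.fun, sigma)
    return BiasFit(params=theta, names=names_kept + ["sigma_u"],
                   cov=cov, loglik=-res.fun,
                   design_info=Xdf.design_info, col_keep=col_keep,
                   data=df, eta=eta,
                   participant_effects=participant_effects,
                   predictions=predictions, slope_per_degree=slope)


def _slope_per_degree(names, beta, t_ref) -> float:
    """Local probit slope per degree from the adjacent offset levels.

    T is categorical, so a degree scale is derived from the contrast of the
    offset levels nearest zero (+-2.5 deg by default).
    """
    levels = {}
    for name, b in zip(names, beta):
        if name.startswith("C(offset_deg"):
            lv = float(name.split("[T.")[1].rstrip("]"))
            levels[lv] = b
    levels[float(t_ref)] = 0.0
    offs = np.array(sorted(levels))
    vals = np.array([levels[o] for o in offs])
    pos = offs[offs > 0].min()
    neg = offs[offs < 0].max()
    return float((levels[pos] - levels[neg]) / (pos - neg))


def conditional_bias(fit: BiasFit, adaptor: float, standard: float
                     ) -> ConditionBias:
    """Probit-scale bias of cell (F, S): eta at the zero-offset reference.

    Population level (random effect at zero).  Raises for cells absent from
    the fitted data.
    """
    observed = set(map(tuple, fit.data[["adaptor_deg", "standard_deg"]]
                       .drop_duplicates().to_numpy()))
    if (float(adaptor), float(standard)) not in observed:
        raise ValueError(f"cell (F={adaptor}, S={standard}) not in the data")
    row = fit.cell_row(adaptor, standard)
    bias = float(row @ fit.beta)
    cvec = np.concatenate([row, [0.0]])
    se = float(np.sqrt(cvec @ fit.cov @ cvec))
    rel = (relative_standard(standard, adaptor)
           if adaptor != BASELINE else None)
    return ConditionBias(adaptor=float(adaptor), standard=float(standard),
                         rel_standard=rel, bias=bias, se=se,
                         bias_deg=bias / fit.slope_per_degree)


def subtract_baseline(fit: BiasFit, biases: list[ConditionBias]
                      ) -> list[ConditionBias]:
    """Remove the baseline bias at the same standard from each adaptor cell.

    The returned biases carry adaptor-relative standard labels and Wald
    p-values for the contrast (adaptation cell minus baseline cell), the
    quantity interpreted as adaptation-attributable response bias.  The
    baseline cells themselves map to exactly 0.
    """
    out = []
    for cb in biases:
        base_row = fit.cell_row(BASELINE, cb.standard)
        try:
            row = fit.cell_row(cb.adaptor, cb.standard)
        except Exception as exc:  # pragma: no cover
            raise ValueError(f"missing cell for {cb}") from exc
        if not _cell_in_data(fit, BASELINE, cb.standard):
            raise ValueError(
                f"no baseline cell for standard {cb.standard}")
        c = row - base_row
        bias = float(c @ fit.beta)
        cvec = np.concatenate([c, [0.0]])
        se = float(np.sqrt(cvec @ fit.cov @ cvec))
        pval = (float(2 * norm.sf(abs(bias) / se)) if se > 0
                else (1.0 if bias == 0 else 0.0))
        out.append(ConditionBias(
            adaptor=cb.adaptor, standard=cb.standard,
            rel_standard=cb.rel_standard, bias=bias, se=se,
            bias_deg=bias / fit.slope_per_degree,
            baseline_subtracted=True, p_value=pval))
    return out


def _cell_in_data(fit: BiasFit, adaptor, standard) -> bool:
    d = fit.data
    return bool(((d["adaptor_deg"] == adaptor)
                 & (d["standard_deg"] == standard)).any())


def cell_bias_table(fit: BiasFit, subtract: bool = True) -> pd.DataFrame:
    """Tidy table of conditional biases for every adaptation cell."""
    cells = (fit.data.loc[fit.data["adaptor_deg"] != BASELINE,
                          ["adaptor_deg", "standard_deg"]]
             .drop_duplicates().sort_values(["adaptor_deg", "standard_deg"]))
    biases = [conditional_bias(fit, f, s)
              for f, s in cells.itertuples(index=False)]
    if subtract:
        biases = subtract_baseline(fit, biases)
    rows = [{"adaptor_deg": b.adaptor, "standard_deg": b.standard,
             "rel_standard_deg": b.rel_standard, "bias_probit": b.bias,
             "se": b.se, "bias_deg": b.bias_deg, "p_value": b.p_value,
             "pred_se": prediction_se(fit, b.adaptor, b.standard)
             if _n_observers(fit, b.adaptor, b.standard) > 1 else np.nan}
            for b in biases]
    return pd.DataFrame(rows)


def _n_observers(fit: BiasFit, adaptor, standard) -> int:
    d = fit.data
    m = (d["adaptor_deg"] == adaptor) & (d["standard_deg"] == standard)
    return d.loc[m, "participant"].nunique()


def prediction_se(fit: BiasFit, adaptor: float, standard: float) -> float:
    """Between-observer SE of mean predicted responses in a cell.

    Averages the model's per-trial response predictions within the cell for
    each observer, then takes the standard error of those means across
    observers — the descriptive uncertainty used for visualising fits.
    """
    d = fit.data
    mask = ((d["adaptor_deg"] == float(adaptor))
            & (d["standard_deg"] == float(standard))).to_numpy()
    if not mask.any():
        raise ValueError(f"cell (F={adaptor}, S={standard}) not in the data")
    sub = pd.DataFrame({"participant": d.loc[mask, "participant"],
                        "p": fit.predictions[mask]})
    means = sub.groupby("participant")["p"].mean()
    if len(means) < 2:
        raise ValueError("prediction SE undefined with a single observer")
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def quality_check(baseline_trials: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Likelihood-ratio data-quality check for one participant's baseline.

    Fits an intercept-only and an intercept+slope binomial model (logit
    link) to response vs offset; the statistic is twice the log-likelihood
    difference, referred to chi-square with 1 df.  Passes iff p < alpha,
    i.e. the psychometric function fits significantly better than chance.
    """
    df = baseline_trials.loc[baseline_trials["response"].notna()]
    if df["offset_deg"].nunique() < 2:
        raise ValueError("need >= 2 offset levels for the quality check")
    y = df["response"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        return {"pass": False, "p": 1.0, "statistic": 0.0,
                "note": "all responses identical; slope unidentifiable"}
    x = df["offset_deg"].to_numpy(dtype=float)
    null = sm.GLM(y, np.ones((len(y), 1)),
                  family=sm.families.Binomial()).fit()
    full = sm.GLM(y, sm.add_constant(x),
                  family=sm.families.Binomial()).fit()
    stat = 2.0 * (full.llf - null.llf)
    p = float(1.0 - chi2.cdf(max(stat, 0.0), df=1))
    return {"pass": bool(p < alpha), "p": p, "statistic": float(stat)}
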