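"""Mixed-effects behavioral models for the cue-integration task.

Four per-trial regressions, all with session-level random intercepts and
slopes (independent variance components), estimated by maximum likelihood:

* choice model — choice on face direction, better-object side, and their
  interaction, fit per block;
* accuracy/congruency model — accuracy on an incongruency indicator;
* stimulation accuracy model — accuracy on an active-vs-sham indicator,
  optionally with incongruency and its interaction;
* stimulation choice model — choice on a cue direction, the stimulation
  indicator, and their interaction.

Significance of each coefficient is an F test with Satterthwaite
denominator degrees of freedom, computed from the curvature of the
profiled likelihood over the variance parameters.  When that curvature
matrix (the variance-parameter Hessian) is not positive definite — which
happens when a variance component collapses to the boundary — the model is
refit with every term as a fixed effect, and the result is flagged.

Side variables are coded -1/+1 (left/right) and the binary response is
-1/+1 under the default linear-probability link (the identity-link form the
coefficient magnitudes are reported in) or 0/1 under the optional logistic
link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .task import ParameterError, TrialRecord, _side_sign

__all__ = [
    "FixedEffect",
    "MixedModelResult",
    "fit_choice_model",
    "fit_accuracy_congruency_model",
    "fit_tus_accuracy_model",
    "fit_tus_choice_model",
    "check_model_diagnostics",
    "likelihood_ratio_test",
]


@dataclass(frozen=True)
class FixedEffect:
    estimate: float
    ci95_halfwidth: float
    f_stat: float
    df: tuple[float, float]
    p: float


@dataclass
class MixedModelResult:
    """Fitted model summary with diagnostics.

    ``fell_back_to_fixed`` is set only when the variance-parameter Hessian
    was not positive definite (or random effects were inestimable) and the
    model was refit with fixed effects only.
    """

    model: str
    fixed_effects: dict[str, FixedEffect]
    random_effect_sds: dict[str, float]
    loglik: float
    converged: bool
    hessian_pd: bool
    fell_back_to_fixed: bool
    n_obs: int
    n_sessions: int
    n_params: int
    link: str = "linear"
    df_method: str = "satterthwaite"
    ks_p: float | None = None
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


# ---------------------------------------------------------------------------
# likelihood machinery for the Satterthwaite approximation


@dataclass(frozen=True)
class _BlockStats:
    """Per-session sufficient statistics (the random design equals X)."""

    G: np.ndarray  # X'X
    Xy: np.ndarray  # X'y
    yy: float  # y'y
    n: int


def _split_blocks(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> list[_BlockStats]:
    blocks = []
    for g in pd.unique(groups):
        m = groups == g
        Xs, ys = X[m], y[m]
        blocks.append(_BlockStats(Xs.T @ Xs, Xs.T @ ys, float(ys @ ys), len(ys)))
    return blocks


def _gls_pieces(theta: np.ndarray, blocks: list[_BlockStats]):
    """Sum of X'V^-1 X, X'V^-1 y, y'V^-1 y and sum log|V| via Woodbury.

    theta = (sigma2, d_1..d_q); V_s = sigma2 I + X_s diag(d) X_s'.  All
    linear algebra happens in the q-dimensional random-effect space, which
    keeps the likelihood cheap and stable even at boundary variances.
    """
    sigma2, d = theta[0], theta[1:]
    q = len(d)
    XtVX = np.zeros((q, q))
    XtVy = np.zeros(q)
    yVy = 0.0
    logdet = 0.0
    eye = np.eye(q)
    for b in blocks:
        S = d[:, None] * b.G  # D G
        A = sigma2 * eye + S.T  # (sigma2 I + G D); K = A^{-1}
        sign, ld = np.linalg.slogdet(eye + S / sigma2)
        if sign <= 0:
            raise np.linalg.LinAlgError("non-PD marginal covariance")
        logdet += b.n * np.log(sigma2) + ld
        KXy = np.linalg.solve(A, b.Xy)
        XtVX += (b.G - b.G @ (d[:, None] * np.linalg.solve(A, b.G))) / sigma2
        XtVy += (b.Xy - b.G @ (d * KXy)) / sigma2
        yVy += (b.yy - b.Xy @ (d * KXy)) / sigma2
    return XtVX, XtVy, yVy, logdet


def _beta_cov(theta: np.ndarray, blocks: list[_BlockStats]) -> tuple[np.ndarray, np.ndarray]:
    """GLS beta and its covariance at variance parameters theta."""
    XtVX, XtVy, _, _ = _gls_pieces(theta, blocks)
    C = np.linalg.inv((XtVX + XtVX.T) / 2)
    return C @ XtVy, C


def _profiled_loglik(theta: np.ndarray, blocks: list[_BlockStats]) -> float:
    """ML log-likelihood with the fixed effects profiled out by GLS."""
    if theta[0] <= 0 or np.any(theta[1:] < 0) or not np.all(np.isfinite(theta)):
        return -np.inf
    try:
        XtVX, XtVy, yVy, logdet = _gls_pieces(theta, blocks)
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return -np.inf
    quad = yVy - 2 * beta @ XtVy + beta @ XtVX @ beta
    n = sum(b.n for b in blocks)
    return -0.5 * (logdet + quad + n * np.log(2 * np.pi))


def _num_hessian(f, x: np.ndarray, step: float = 1e-3) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * step**2)
    return H


def _num_gradient(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    h = np.maximum(np.abs(x) * rel_step, 1e-12)
    g = np.empty(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def _satterthwaite(
    theta: np.ndarray,
    blocks: list[_BlockStats],
    theta_cov: np.ndarray,
    free: np.ndarray,
) -> list[tuple[float, float]]:
    """Per-coefficient (se, denominator df) at the ML variance estimates.

    df_j = 2 f^2 / Var(f) with f = [C(theta)]_jj, Var(f) by the delta
    method over the covariance of the free (interior) variance parameters —
    the lmerTest recipe; boundary components carry no uncertainty.
    """
    _, C = _beta_cov(theta, blocks)
    p = C.shape[0]
    idx = np.flatnonzero(free)
    out = []
    for j in range(p):
        fval = C[j, j]

        def f_of_free(sub: np.ndarray, j=j) -> float:
            th = theta.copy()
            th[idx] = sub
            return _beta_cov(th, blocks)[1][j, j]

        g = _num_gradient(f_of_free, theta[idx])
        var_f = float(g @ theta_cov @ g)
        df = 2 * fval**2 / var_f if var_f > 0 else np.inf
        out.append((float(np.sqrt(fval)), float(df)))
    return out


# ---------------------------------------------------------------------------
# fitting


def _ols_result(
    model: str, y: np.ndarray, X: np.ndarray, names: Sequence[str], n_sessions: int, link: str
) -> MixedModelResult:
    fit = sm.OLS(y, X).fit()
    fe: dict[str, FixedEffect] = {}
    df2 = float(fit.df_resid)
    for j, name in enumerate(names):
        est = float(fit.params[j])
        se = float(fit.bse[j])
        f = (est / se) ** 2 if se > 0 else np.inf
        p = float(st.f.sf(f, 1, df2)) if np.isfinite(f) else 0.0
        hw = float(st.t.ppf(0.975, df2) * se)
        fe[name] = FixedEffect(est, hw, float(f), (1.0, df2), p)
    return MixedModelResult(
        model=model,
        fixed_effects=fe,
        random_effect_sds={},
        loglik=float(fit.llf),
        converged=True,
        hessian_pd=False,
        fell_back_to_fixed=True,
        n_obs=len(y),
        n_sessions=n_sessions,
        n_params=len(names) + 1,
        link=link,
        df_method="residual",
        residuals=np.asarray(fit.resid),
    )


def _fit_lmm(
    model: str,
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    groups: np.ndarray,
) -> MixedModelResult:
    """ML fit with per-session random effects on every column of X."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    sessions = pd.unique(groups)
    if len(sessions) < 2:
        warnings.warn("single session: random effects inestimable, fitting fixed effects only")
        return _ols_result(model, y, X, names, len(sessions), "linear")

    free = MixedLMParams.from_components(
        fe_params=np.ones(X.shape[1]), cov_re=np.eye(X.shape[1])
    )
    # statsmodels supplies the starting point; the profiled-likelihood
    # refinement below is the arbiter of the optimum (the lbfgs convergence
    # flag is unreliable near boundary variance components)
    theta = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mlm = MixedLM(y, X, groups=groups, exog_re=X)
            fit = mlm.fit(reml=False, free=free, method="lbfgs", maxiter=500)
        theta = np.concatenate([[fit.scale], np.diag(fit.cov_re)])
        if not (np.all(np.isfinite(theta)) and theta[0] > 0):
            theta = None
    except (np.linalg.LinAlgError, ValueError):
        theta = None
    if theta is None:
        # crude start from the pooled OLS residual variance
        resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = float(resid0 @ resid0 / max(len(y) - X.shape[1], 1))
        theta = np.concatenate([[s2], np.full(X.shape[1], s2 / 10)])

    blocks = _split_blocks(y, X, np.asarray(groups))
    hessian_pd = False
    theta_cov = None
    free = None
    try:
        if theta[0] < 1e-12 * max(float(np.var(y)), 1e-12):
            raise np.linalg.LinAlgError("degenerate residual variance")
        # refine in log-variance space (scale-free steps, no boundary
        # crossings); variance components that collapse toward zero are
        # pinned to the boundary and excluded from the curvature
        from scipy.optimize import minimize

        lam0 = np.log(np.maximum(theta, 1e-10))
        opt = minimize(
            lambda lam: -_profiled_loglik(np.exp(lam), blocks),
            lam0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
        )
        theta = np.exp(opt.x)
        if not np.isfinite(opt.fun) or theta[0] < 1e-12 * max(float(np.var(y)), 1e-12):
            raise np.linalg.LinAlgError("degenerate refined optimum")
        boundary = theta[1:] < 1e-6 * theta[0]
        theta[1:][boundary] = 0.0
        free = np.concatenate([[True], ~boundary])  # sigma2 always free
        idx = np.flatnonzero(free)

        def ll_of_free(lam_sub: np.ndarray) -> float:
            th = theta.copy()
            th[idx] = np.exp(lam_sub)
            return _profiled_loglik(th, blocks)

        H = _num_hessian(ll_of_free, np.log(theta[idx]))
        eig = np.linalg.eigvalsh(-H)
        if np.all(np.isfinite(eig)) and eig.min() > 1e-6 * max(1.0, eig.max()):
            hessian_pd = True
            cov_lam = np.linalg.inv(-(H + H.T) / 2)
            theta_cov = (theta[idx][:, None] * cov_lam) * theta[idx][None, :]
    except (np.linalg.LinAlgError, ValueError, FloatingPointError, OverflowError):
        hessian_pd = False
    if not hessian_pd or np.all(theta[1:] == 0):
        # every component at the boundary or ill-posed curvature: drop all
        # random effects at once rather than prune stepwise
        return _ols_result(model, y, X, names, len(sessions), "linear")
    satt = _satterthwaite(theta, blocks, theta_cov, free)
    beta, _ = _beta_cov(theta, blocks)
    fe: dict[str, FixedEffect] = {}
    for j, name in enumerate(names):
        est = float(beta[j])
        se, df2 = satt[j]
        f = (est / se) ** 2 if se > 0 else np.inf
        p = float(st.f.sf(f, 1, df2))
        hw = float(st.t.ppf(0.975, df2) * se) if np.isfinite(df2) else float(st.norm.ppf(0.975) * se)
        fe[name] = FixedEffect(est, hw, float(f), (1.0, float(df2)), p)
    re_sds = {name: float(np.sqrt(max(theta[1 + j], 0.0))) for j, name in enumerate(names)}
    resid = y - X @ beta
    return MixedModelResult(
        model=model,
        fixed_effects=fe,
        random_effect_sds=re_sds,
        loglik=float(_profiled_loglik(theta, blocks)),
        converged=True,
        hessian_pd=True,
        fell_back_to_fixed=False,
        n_obs=len(y),
        n_sessions=len(sessions),
        n_params=2 * len(names) + 1,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# data preparation


def _frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        if not t.valid or t.choice in (None, "none"):
            continue
        rows.append(
            dict(
                session=t.session_id,
                condition=t.condition,
                face=_side_sign(t.face_direction),
                object=_side_sign(t.better_object_side),
                choice=_side_sign(t.choice),
                accuracy=t.accuracy,
                incongruent=0 if t.congruent else 1,
                tus_site=t.tus_site,
                rt=t.rt,
            )
        )
    return pd.DataFrame(rows)


def fit_choice_model(
    trials: Sequence[TrialRecord],
    condition: str | None = None,
    link: str = "linear",
    terms: Sequence[str] | None = None,
) -> MixedModelResult:
    """Choice on face direction, better-object side and their interaction.

    Per-session random intercept and slopes.  Default identity link with
    choice coded -1/+1; ``link='logistic'`` fits a fixed-effects logistic
    regression (choice coded 0/1) and falls back to the linear link under
    complete separation.  ``terms`` selects a subset of the slope terms
    (e.g. only the reliable cue) for nested-model comparisons.
    """
    df = _frame(trials)
    if condition is not None:
        df = df[df.condition == condition]
    if df.empty:
        raise ParameterError("no usable trials")
    all_cols = {
        "face": df.face,
        "object": df.object,
        "face:object": df.face * df.object,
    }
    terms = list(terms) if terms is not None else list(all_cols)
    unknown = set(terms) - set(all_cols)
    if unknown:
        raise ParameterError(f"unknown model terms {sorted(unknown)}")
    X = np.column_stack([np.ones(len(df))] + [all_cols[t] for t in terms])
    names = ["intercept"] + terms
    if link == "logistic":
        y01 = (df.choice.to_numpy() + 1) // 2
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                fit = sm.Logit(y01, X).fit(disp=0)
        except Exception:
            warnings.warn("separation or non-convergence under logistic link; using linear link")
            return fit_choice_model(trials, condition, link="linear")
        fe = {}
        for j, name in enumerate(names):
            est, se = float(fit.params[j]), float(fit.bse[j])
            f = (est / se) ** 2 if se > 0 else np.inf
            fe[name] = FixedEffect(
                est, float(st.norm.ppf(0.975) * se), float(f), (1.0, np.inf), float(st.chi2.sf(f, 1))
            )
        return MixedModelResult(
            model="choice",
            fixed_effects=fe,
            random_effect_sds={},
            loglik=float(fit.llf),
            converged=True,
            hessian_pd=True,
            fell_back_to_fixed=True,
            n_obs=len(df),
            n_sessions=df.session.nunique(),
            n_params=len(names),
            link="logistic",
            df_method="wald",
            residuals=np.asarray(y01 - fit.predict(X)),
        )
    return _fit_lmm("choice", df.choice.to_numpy(float), X, names, df.session.to_numpy())


def fit_accuracy_congruency_model(trials: Sequence[TrialRecord]) -> MixedModelResult:
    """Accuracy on an incongruency indicator (0 congruent, 1 incongruent)."""
    df = _frame(trials)
    if df.empty or df.accuracy.isna().any():
        raise ParameterError("accuracy must be set on all usable trials")
    if df.incongruent.nunique() < 2:
        raise ParameterError("congruency is constant; incongruency effect inestimable")
    X = np.column_stack([np.ones(len(df)), df.incongruent])
    return _fit_lmm(
        "accuracy~congruency",
        df.accuracy.to_numpy(float),
        X,
        ["intercept", "incongruent"],
        df.session.to_numpy(),
    )


def _tus_frame(trials: Sequence[TrialRecord], site: str) -> pd.DataFrame:
    df = _frame(trials)
    if site not in set(df.tus_site) or df.empty:
        raise ParameterError(f"no trials from active site {site!r}")
    if "sham" not in set(df.tus_site):
        raise ParameterError("sham sessions required as the reference")
    df = df[df.tus_site.isin(["sham", site])].copy()
    df["roi"] = (df.tus_site == site).astype(float)
    return df


def fit_tus_accuracy_model(
    trials: Sequence[TrialRecord],
    site: str,
    trial_subset: str | None = None,
    with_interaction: bool = False,
) -> MixedModelResult:
    """Accuracy on the active-vs-sham indicator (0 sham, 1 active).

    ``trial_subset`` restricts to congruent or incongruent trials; with
    ``with_interaction`` the incongruency main effect and its interaction
    with stimulation are added instead of subsetting.
    """
    df = _tus_frame(trials, site)
    if with_interaction:
        X = np.column_stack([np.ones(len(df)), df.roi, df.incongruent, df.roi * df.incongruent])
        names = ["intercept", "roi", "incongruent", "roi:incongruent"]
    else:
        if trial_subset is not None:
            if trial_subset not in ("congruent", "incongruent"):
                raise ParameterError(f"unknown trial subset {trial_subset!r}")
            df = df[df.incongruent == (1 if trial_subset == "incongruent" else 0)]
        X = np.column_stack([np.ones(len(df)), df.roi])
        names = ["intercept", "roi"]
    if df.empty:
        raise ParameterError("no trials left after subsetting")
    return _fit_lmm("accuracy~roi", df.accuracy.to_numpy(float), X, names, df.session.to_numpy())


def fit_tus_choice_model(
    trials: Sequence[TrialRecord], site: str, cue: str = "face"
) -> MixedModelResult:
    """Choice on a cue direction, stimulation, and their interaction.

    The cue x stimulation interaction measures how active stimulation
    changes that cue's leverage on choice.
    """
    if cue not in ("face", "object"):
        raise ParameterError(f"cue must be 'face' or 'object', got {cue!r}")
    df = _tus_frame(trials, site)
    c = df[cue].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), c, df.roi, c * df.roi])
    names = ["intercept", cue, "roi", f"{cue}:roi"]
    return _fit_lmm("choice~cue*roi", df.choice.to_numpy(float), X, names, df.session.to_numpy())


# ---------------------------------------------------------------------------
# diagnostics


def check_model_diagnostics(
    result: MixedModelResult, residuals: np.ndarray | None = None
) -> MixedModelResult:
    """Annotate a fit with a Kolmogorov-Smirnov normality p-value.

    The Hessian-fallback rule is applied at fit time; this records the
    residual-normality diagnostic.  Because the null mean and variance are
    estimated from the residuals themselves, the Lilliefors form of the KS
    test is used (the plain KS null would be far too conservative).
    """
    r = np.asarray(residuals if residuals is not None else result.residuals, dtype=float)
    if r.size == 0:
        raise ParameterError("no residuals available")
    if np.ptp(r) == 0:
        return replace(result, ks_p=0.0)
    from statsmodels.stats.diagnostic import kstest_normal

    _, pvalue = kstest_normal(r, dist="norm")
    return replace(result, ks_p=float(pvalue))


def likelihood_ratio_test(
    full: MixedModelResult, reduced: MixedModelResult
) -> tuple[float, int, float]:
    """Likelihood-ratio comparison of a full model against a nested one.

    Returns (statistic, df, p).  The reduced model's fixed-effect terms must
    be a subset of the full model's, and both models must have been
    estimated with the same random-effects treatment (a mixed fit is not
    comparable to a fixed-effects fallback fit).
    """
    if not set(reduced.fixed_effects) <= set(full.fixed_effects):
        raise ParameterError("models are not nested: reduced terms not a subset of full terms")
    if full.fell_back_to_fixed != reduced.fell_back_to_fixed:
        raise ParameterError(
            "models were estimated with different random-effects structures; "
            "refit so both are mixed or both are fixed-effects"
        )
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ParameterError("full model has no extra parameters over the reduced model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    return float(stat), int(df), float(st.chi2.sf(max(stat, 0.0), df))
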