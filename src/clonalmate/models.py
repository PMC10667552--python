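"""GBLUP and extended-GBLUP: REML variance components, mixed-model
equations, and progeny prediction.

The additive-only model is

    y = X beta + u + eps,                u ~ N(0, G_A sigma2_A)

and the extended model adds dominance deviations d ~ N(0, G_D sigma2_D),
additive-additive deviations t ~ N(0, G_AA sigma2_AA), and the
genome-wide heterozygosity of each clone as a fixed covariate with slope
b.  Every clone has one adjusted record, so the random-effect incidence
matrix is the identity.

Variance components are estimated by average-information REML with
EM-style safeguarding: a quasi-Newton step using the AI matrix, halved
when it leaves the parameter space, and components driven to the lower
bound are pinned at ``floor_factor * var(y)`` and flagged (the breeding
literature reports such estimates as "~ 0").  The REML log-likelihood is

    logL = -1/2 [ log|V| + log|X'V^-1 X| + y' P y ]

with V = sum_i sigma2_i G_i + sigma2_eps I and P the REML projection.

Given components, effects solve the standard mixed-model equations; for
unphenotyped progeny each random component is extended by conditional
expectation through the progeny x training relationship blocks:
u_progeny = G_pt G_tt^-1 u_train, and the clonal value is
g = u + d + t + b * Het.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .containers import DegenerateInputError, DimensionError
from .relationships import CrossBlockGRMs

RANDOM_TERMS = ("additive", "dominance", "epistatic")


class REMLConvergenceError(RuntimeError):
    """AI-REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class VarianceComponents:
    """REML variance components on the trait scale."""

    components: dict[str, float]          # per random term
    residual: float
    se: dict[str, float] = field(default_factory=dict)
    residual_se: float = float("nan")
    converged: bool = True
    boundary: dict[str, bool] = field(default_factory=dict)
    log_likelihood: float = float("nan")
    n_iterations: int = 0

    @classmethod
    def from_values(cls, sigma2_A: float, sigma2_eps: float,
                    sigma2_D: float = 0.0,
                    sigma2_AA: float = 0.0) -> "VarianceComponents":
        comps = {"additive": sigma2_A}
        if sigma2_D or sigma2_AA:
            comps["dominance"] = sigma2_D
            comps["epistatic"] = sigma2_AA
        return cls(components=comps, residual=sigma2_eps)

    @property
    def sigma2_A(self) -> float:
        return self.components.get("additive", 0.0)

    @property
    def sigma2_D(self) -> float:
        return self.components.get("dominance", 0.0)

    @property
    def sigma2_AA(self) -> float:
        return self.components.get("epistatic", 0.0)

    @property
    def sigma2_eps(self) -> float:
        return self.residual

    @property
    def phenotypic_variance(self) -> float:
        return sum(self.components.values()) + self.residual


@dataclass
class MMEFit:
    """Solutions of the mixed-model equations for one model.

    ``component_weights`` holds sigma2_i * V^-1 (y - X beta) per random
    term — the vector that extends each component to unphenotyped
    individuals through their relationship block.
    """

    model: str                            # "GBLUP" | "e-GBLUP"
    beta_hat: np.ndarray
    solutions: dict[str, np.ndarray]      # per random term
    b_hat: float                          # heterozygosity slope (0 if absent)
    log_likelihood: float
    varcomps: VarianceComponents
    het_col: int | None = None
    het_center: float = 0.0               # training-mean Het the slope is centered on
    mme_residual: float = float("nan")
    component_weights: dict[str, np.ndarray] | None = None

    @property
    def u_hat(self) -> np.ndarray:
        return self.solutions["additive"]

    @property
    def d_hat(self) -> np.ndarray | None:
        return self.solutions.get("dominance")

    @property
    def t_hat(self) -> np.ndarray | None:
        return self.solutions.get("epistatic")


def _as_design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise DimensionError("covariate rows do not match phenotype length")
    return x


def _chol_logdet_inv(a: np.ndarray, jitter: float = 0.0):
    try:
        c, low = cho_factor(a + (jitter * np.eye(len(a)) if jitter else 0.0),
                            lower=True)
    except np.linalg.LinAlgError:
        c, low = cho_factor(a + 1e-6 * np.trace(a) / len(a) * np.eye(len(a)),
                            lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv = cho_solve((c, low), np.eye(len(a)))
    return logdet, inv


def fit_reml(y, covariates, grm_list, names=None,
             max_iter: int = 100, tol: float = 1e-6,
             floor_factor: float = 1e-6,
             verbose: bool = False) -> tuple[VarianceComponents, MMEFit]:
    """Estimate variance components by AI-REML and solve the MME.

    ``grm_list`` holds 1 matrix (additive-only) or 3 (additive,
    dominance, epistatic, in that order); ``covariates`` is the fixed
    design including the intercept (a lone intercept if None).  Column 1
    is taken as the heterozygosity covariate when the design has more
    than one column and ``names`` has length 3.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    vary = float(np.var(y))
    if vary <= 0.0:
        raise DegenerateInputError("phenotype has zero variance")
    k = len(grm_list)
    if names is None:
        names = list(RANDOM_TERMS[:k]) if k <= 3 else [f"g{i}" for i in range(k)]
    x = _as_design(covariates, n)
    grms = [np.asarray(g, dtype=float) for g in grm_list]
    for g in grms:
        if g.shape != (n, n):
            raise DimensionError("GRM dimension does not match phenotypes")

    floor = floor_factor * vary
    theta = np.full(k + 1, vary / (k + 1))
    pinned = np.zeros(k + 1, dtype=bool)
    trajectory: list[float] = []
    logl_prev = -np.inf
    ai = None
    free = ~pinned

    for it in range(1, max_iter + 1):
        v = theta[k] * np.eye(n)
        for i in range(k):
            v += theta[i] * grms[i]
        logdet_v, vinv = _chol_logdet_inv(v)
        xtvx = x.T @ vinv @ x
        logdet_xtvx, xtvx_inv = _chol_logdet_inv(xtvx)
        vinv_x = vinv @ x
        p_mat = vinv - vinv_x @ xtvx_inv @ vinv_x.T
        py = p_mat @ y
        logl = -0.5 * (logdet_v + logdet_xtvx + float(y @ py))
        trajectory.append(logl)
        if verbose:
            print(f"iter {it}: logL={logl:.6f} theta={theta}")

        # scores and AI matrix over all components (residual last)
        v_list = [g @ py for g in grms] + [py]
        score = np.empty(k + 1)
        for i in range(k + 1):
            g_i = grms[i] if i < k else None
            tr_pg = float(np.sum(p_mat * g_i)) if i < k else float(np.trace(p_mat))
            score[i] = -0.5 * (tr_pg - float(py @ v_list[i]))
        pv = [p_mat @ vi for vi in v_list]
        ai = 0.5 * np.array([[float(v_list[i] @ pv[j]) for j in range(k + 1)]
                             for i in range(k + 1)])

        if abs(logl - logl_prev) < tol and it > 1:
            break
        logl_prev = logl

        free = ~pinned
        delta = np.zeros(k + 1)
        try:
            delta[free] = np.linalg.solve(ai[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            # EM fallback step
            for i in np.flatnonzero(free):
                tr_pg = (float(np.sum(p_mat * grms[i])) if i < k
                         else float(np.trace(p_mat)))
                delta[i] = theta[i] ** 2 * (float(py @ v_list[i]) - tr_pg) / n
        step = 1.0
        proposal = theta + delta
        for _ in range(8):
            if np.all(proposal[free] >= floor):
                break
            step *= 0.5
            proposal = theta + step * delta
        newly = free & (proposal < floor)
        if newly.any():
            proposal[newly] = floor
            pinned |= newly
        theta = proposal
    else:
        raise REMLConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", trajectory)

    # standard errors from the inverse AI matrix over free components
    se = np.full(k + 1, np.nan)
    free = ~pinned
    if free.any():
        try:
            se[free] = np.sqrt(np.diag(
                np.linalg.inv(ai[np.ix_(free, free)])))
        except np.linalg.LinAlgError:
            pass

    vc = VarianceComponents(
        components={names[i]: float(theta[i]) for i in range(k)},
        residual=float(theta[k]),
        se={names[i]: float(se[i]) for i in range(k)},
        residual_se=float(se[k]),
        converged=True,
        boundary={names[i]: bool(pinned[i]) for i in range(k)},
        log_likelihood=float(trajectory[-1]),
        n_iterations=len(trajectory),
    )
    fit = solve_mme(y, x, grms, vc, names=names,
                    model="GBLUP" if k == 1 else "e-GBLUP")
    return vc, fit


def solve_mme(y, covariates, grm_list, varcomps: VarianceComponents,
              names=None, model: str | None = None,
              het_col: int | None = None,
              ridge: float = 1e-8,
              method: str = "gls") -> MMEFit:
    """Solve the mixed-model equations at given variance components.

    Random terms whose variance sits on the boundary floor are dropped
    (their solutions are zero).  Two equivalent routes:

    ``method='gls'`` (default): beta by generalized least squares with
    V = sum sigma2_i G_i + sigma2_eps I, then u_i = sigma2_i G_i V^-1
    (y - X beta).  These are the unique MME solutions whenever the G_i
    are invertible, and remain well defined when a G is singular or
    indefinite (as the unbiased-diagonal additive GRM of an
    excess-heterozygosity population is).

    ``method='mme'``: assemble and solve the explicit coefficient
    system (with Z = I)

        [ X'X   X'   ...           ]          [ X'y ]
        [ X     I + G_i^-1 l_i ... ]  sol  =  [  y  ],  l_i = s2_eps/s2_i

    with G^-1 via Cholesky after a ridge of ``ridge`` on the diagonal.
    Requires (near-)PD relationship matrices; used as a cross-check.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    x = _as_design(covariates, n)
    p = x.shape[1]
    k = len(grm_list)
    if names is None:
        names = list(RANDOM_TERMS[:k]) if k <= 3 else [f"g{i}" for i in range(k)]
    sig = [varcomps.components[nm] for nm in names]
    active = [i for i in range(k)
              if not varcomps.boundary.get(names[i], False) and sig[i] > 0]
    s2e = varcomps.residual
    if s2e <= 0:
        raise DegenerateInputError("residual variance must be positive")
    grms = [np.asarray(g, dtype=float) for g in grm_list]

    if het_col is None and p > 1 and k == 3:
        het_col = 1

    if method == "gls":
        v = s2e * np.eye(n)
        for i in active:
            v += sig[i] * grms[i]
        _, vinv = _chol_logdet_inv(v)
        xtvx = x.T @ vinv @ x
        try:
            beta = np.linalg.solve(xtvx, x.T @ (vinv @ y))
        except np.linalg.LinAlgError as err:
            raise DegenerateInputError("singular fixed-effect system") from err
        vinv_r = vinv @ (y - x @ beta)
        solutions = {names[i]: np.zeros(n) for i in range(k)}
        weights = {names[i]: np.zeros(n) for i in range(k)}
        for i in active:
            weights[names[i]] = sig[i] * vinv_r
            solutions[names[i]] = grms[i] @ weights[names[i]]
        resid = float("nan")
        sol_beta = beta
    elif method == "mme":
        ka = len(active)
        dim = p + ka * n
        c = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        c[:p, :p] = x.T @ x
        rhs[:p] = x.T @ y
        eye = np.eye(n)
        for a, i in enumerate(active):
            r0 = p + a * n
            c[:p, r0:r0 + n] = x.T
            c[r0:r0 + n, :p] = x
            rhs[r0:r0 + n] = y
            for b_idx in range(ka):
                c[r0:r0 + n, p + b_idx * n:p + (b_idx + 1) * n] = eye
            _, ginv = _chol_logdet_inv(grms[i], jitter=ridge)
            c[r0:r0 + n, r0:r0 + n] = eye + ginv * (s2e / sig[i])
        try:
            sol = np.linalg.solve(c, rhs)
        except np.linalg.LinAlgError as err:
            raise DegenerateInputError("singular MME coefficient matrix") from err
        resid = float(np.max(np.abs(c @ sol - rhs)))
        scale = max(1.0, float(np.max(np.abs(rhs))))
        if resid > 1e-6 * scale:
            warnings.warn(f"MME residual {resid:.2e} above tolerance")
        sol_beta = sol[:p]
        solutions = {names[i]: np.zeros(n) for i in range(k)}
        for a, i in enumerate(active):
            solutions[names[i]] = sol[p + a * n:p + (a + 1) * n]
        weights = None
    else:
        raise ValueError(f"unknown method {method!r}")

    b_hat = float(sol_beta[het_col]) if het_col is not None else 0.0
    return MMEFit(
        model=model or ("GBLUP" if k == 1 else "e-GBLUP"),
        beta_hat=sol_beta,
        solutions=solutions,
        b_hat=b_hat,
        log_likelihood=varcomps.log_likelihood,
        varcomps=varcomps,
        het_col=het_col,
        mme_residual=resid,
        component_weights=weights,
    )


def predict_progeny(fit: MMEFit, blocks: CrossBlockGRMs,
                    progeny_het: np.ndarray | None = None,
                    progeny_ids=None,
                    ridge: float = 1e-8) -> pd.DataFrame:
    """Predict progeny components by conditional expectation.

    Each random component extends to progeny as G_pt G_tt^-1 a_train,
    computed through the fit's stored weights sigma2_i V^-1 (y - X beta)
    (algebraically the same composition, defined even when G_tt is not
    invertible); the clonal value adds the fitted heterozygosity term.
    The GEBV of a progeny is its u_hat alone.
    """
    train = blocks.train
    het = blocks.progeny_het if progeny_het is None else np.asarray(progeny_het)
    n_prog = blocks.a_block.shape[0]
    if blocks.a_block.shape[1] != len(fit.u_hat):
        raise DimensionError("cross blocks do not match training solutions")

    def extend(block: np.ndarray, g_train: np.ndarray, name: str,
               a_hat: np.ndarray) -> np.ndarray:
        if not np.any(a_hat):
            return np.zeros(n_prog)
        if fit.component_weights is not None:
            return block @ fit.component_weights[name]
        c, low = cho_factor(g_train + ridge * np.eye(len(g_train)), lower=True)
        return block @ cho_solve((c, low), a_hat)

    u_p = extend(blocks.a_block, train.g_additive, "additive", fit.u_hat)
    d_p = (extend(blocks.d_block, train.g_dominance, "dominance", fit.d_hat)
           if fit.d_hat is not None else np.zeros(n_prog))
    t_p = (extend(blocks.aa_block, train.g_epistatic, "epistatic", fit.t_hat)
           if fit.t_hat is not None else np.zeros(n_prog))
    het_term = fit.b_hat * (het - fit.het_center)
    out = pd.DataFrame({
        "u_hat": u_p, "d_hat": d_p, "t_hat": t_p,
        "het_term": het_term,
        "g_hat": u_p + d_p + t_p + het_term,
    })
    if progeny_ids is not None:
        out.insert(0, "clone_id", list(progeny_ids))
    return out


@dataclass(frozen=True)
class HeritabilityReport:
    """Variance ratios on the phenotypic and total-genetic scales."""

    h2: float                 # sigma2_A / sigma2_P
    d2: float                 # sigma2_D / sigma2_P
    E2: float                 # sigma2_AA / sigma2_P
    dominance_to_additive: float
    genetic_shares: tuple[float, float, float]   # (A, D, AA) / sigma2_G
    sigma2_P: float
    sigma2_G: float


def heritability_report(varcomps: VarianceComponents) -> HeritabilityReport:
    """Heritability and variance-ratio summary of a fit."""
    s2a, s2d, s2aa = (varcomps.sigma2_A, varcomps.sigma2_D,
                      varcomps.sigma2_AA)
    s2p = varcomps.phenotypic_variance
    if s2p <= 0:
        raise DegenerateInputError("phenotypic variance must be positive")
    s2g = s2a + s2d + s2aa
    shares = ((s2a / s2g, s2d / s2g, s2aa / s2g) if s2g > 0
              else (float("nan"),) * 3)
    return HeritabilityReport(
        h2=s2a / s2p, d2=s2d / s2p, E2=s2aa / s2p,
        dominance_to_additive=(s2d / s2a if s2a > 0 else float("inf")),
        genetic_shares=shares, sigma2_P=s2p, sigma2_G=s2g,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    p_value: float
    significant: bool
    df: int


def likelihood_ratio_test(logl_full: float, logl_reduced: float,
                          df: int = 1, alpha: float = 0.05) -> LRTResult:
    """LRT of the extended against the additive-only model.

    df defaults to 1 (the convention of comparing against chi2(1));
    pass the true parameter difference to change it.  A negative
    difference is floored at zero with a warning (nested models).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (logl_full - logl_reduced)
    if stat < 0.0:
        warnings.warn("full-model log-likelihood below reduced model; "
                      "statistic floored at 0")
        stat = 0.0
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=float(stat), p_value=p,
                     significant=p < alpha, df=df)


def broad_sense_h2(sigma2_g: float, sigma2_eps: float,
                   replicates: int) -> float:
    """Entry-mean broad-sense heritability sigma2_g / (sigma2_g +
    sigma2_eps / r)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    denom = sigma2_g + sigma2_eps / replicates
    if denom <= 0:
        raise DegenerateInputError("zero denominator")
    return sigma2_g / denom
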