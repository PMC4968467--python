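"""Mixed-model inference for the tracking-error analysis.

The response (log tracking error) is modelled with a Gaussian linear mixed
model containing a random intercept per participant:

    y = X beta + Z b + e,   b ~ N(0, sigma_b^2 I_q),   e ~ N(0, sigma_e^2 I_n)

fitted by maximum likelihood (not REML: every reported comparison is a
deviance test, and AIC values come from the same ML fits).  The likelihood
is profiled over the variance ratio lambda = sigma_b^2 / sigma_e^2: for
fixed lambda both beta and sigma_e^2 have closed-form GLS solutions, so the
fit reduces to a one-dimensional deterministic optimization.  Singular
fits (lambda = 0) are permitted and flagged.

Fixed-effect structure: group size ("number") enters as an orthogonal
polynomial (degree 1 or 2), coloration (3 levels) and contrast (2 levels)
as treatment-coded factors with alphabetical reference levels, plus any
subset of their interactions.  Nested models are compared with
likelihood-ratio tests against a chi-square distribution, and the factor
of interest is probed with Tukey-type all-pairwise contrasts whose
family-wise adjustment integrates the joint normal distribution of the
contrast statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "ModelFit",
    "TestResult",
    "ContrastResult",
    "orthogonal_poly",
    "build_design",
    "fit_lmm",
    "lrt",
    "model_ladder",
    "tukey_posthoc",
    "within_subject_ci",
    "MAIN_EFFECTS",
    "FULL_TERMS",
]

FULL_TERMS = ("N", "C", "K", "N:C", "N:K", "C:K", "N:C:K")
MAIN_EFFECTS = ("N", "C", "K")


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def orthogonal_poly(x: Sequence[float], degree: int) -> np.ndarray:
    """Orthonormal polynomial basis over the observed x (R ``poly()`` style).

    Returns an (n, degree) array whose columns are mutually orthogonal,
    each with unit norm, orthogonal to the constant, and spanning
    centred x, x^2, ... in increasing degree.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.unique(x).size <= degree:
        raise ValueError(f"need more than {degree} distinct values for a "
                         f"degree-{degree} basis")
    xc = x - x.mean()
    V = np.vander(xc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # Fix signs so the linear column increases with x.
    Q = Q * np.sign(np.diag(R))
    return Q[:, 1:]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one model in the ladder.

    ``terms`` uses the shorthand N (number polynomial), C (coloration),
    K (contrast) and colon-joined interactions; ``poly_degree`` applies to
    every appearance of N.
    """

    terms: tuple[str, ...] = FULL_TERMS
    poly_degree: int = 2
    response: str = "log_error"

    def __post_init__(self) -> None:
        bad = set(self.terms) - set(FULL_TERMS)
        if bad:
            raise ValueError(f"unknown model terms: {sorted(bad)}")
        if self.poly_degree not in (1, 2):
            raise ValueError("poly_degree must be 1 or 2")

    def drop(self, *terms: str) -> "ModelSpec":
        return ModelSpec(terms=tuple(t for t in self.terms if t not in terms),
                         poly_degree=self.poly_degree, response=self.response)


def _factor_dummies(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Treatment coding, reference = first level in alphabetical order."""
    levels = sorted(values.unique())
    cols = [np.asarray(values == lev, dtype=float) for lev in levels[1:]]
    names = [f"{name}[{lev}]" for lev in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(values), 0)), names)


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 raw_poly: bool = False) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effects design matrix (with intercept) for a spec.

    ``raw_poly=True`` uses raw centred powers of set size instead of the
    orthogonal basis; the fitted likelihood is invariant to this choice.
    """
    n = len(data)
    if raw_poly:
        xc = data["set_size"].to_numpy(dtype=float)
        xc = xc - xc.mean()
        P = np.column_stack([xc**d for d in range(1, spec.poly_degree + 1)])
    else:
        P = orthogonal_poly(data["set_size"].to_numpy(), spec.poly_degree)
    p_names = [f"number^{d}" for d in range(1, spec.poly_degree + 1)]
    C, c_names = _factor_dummies(data["coloration"], "coloration")
    K, k_names = _factor_dummies(data["contrast"], "contrast")

    blocks: dict[str, tuple[np.ndarray, list[str]]] = {
        "N": (P, p_names), "C": (C, c_names), "K": (K, k_names),
    }

    def interact(*keys: str) -> tuple[np.ndarray, list[str]]:
        mats = [blocks[k][0] for k in keys]
        names = [blocks[k][1] for k in keys]
        out_cols, out_names = [], []

        def rec(i, col, name):
            if i == len(mats):
                out_cols.append(col)
                out_names.append(":".join(name))
                return
            for j in range(mats[i].shape[1]):
                rec(i + 1, col * mats[i][:, j], name + [names[i][j]])

        rec(0, np.ones(n), [])
        return np.column_stack(out_cols), out_names

    X_cols: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["(Intercept)"]
    for term in spec.terms:
        M, nm = interact(*term.split(":"))
        X_cols.append(M)
        names.extend(nm)
    return np.hstack(X_cols), names


# --------------------------------------------------------------------------
# profiled-ML fitting
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted random-intercept LMM (maximum likelihood)."""

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    param_names: list[str]
    var_participant: float
    var_resid: float
    loglik: float
    n_params: int  # fixed effects + 2 variance components
    nobs: int
    converged: bool
    singular: bool
    spec: ModelSpec | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])


def _profile_pieces(X, y, g, q, lam):
    """GLS quantities for V = I + lam * Z Z' using the group structure.

    Returns (beta, XtVinvX, rss_v, logdetV).  Costs O(n p^2) via
    Woodbury: Vinv = I - Z diag(lam/(1+lam*n_i)) Z'.
    """
    n, p = X.shape
    counts = np.bincount(g, minlength=q).astype(float)
    c = lam / (1.0 + lam * counts)  # (q,)
    GX = np.zeros((q, p))
    np.add.at(GX, g, X)
    Gy = np.zeros(q)
    np.add.at(Gy, g, y)
    XtVX = X.T @ X - (GX * c[:, None]).T @ GX
    XtVy = X.T @ y - GX.T @ (c * Gy)
    ytVy = y @ y - Gy @ (c * Gy)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy
    logdet = np.sum(np.log1p(lam * counts))
    return beta, XtVX, rss, logdet


def _profile_loglik(X, y, g, q, lam):
    n = len(y)
    _, _, rss, logdet = _profile_pieces(X, y, g, q, lam)
    sigma2 = rss / n
    return -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    X: np.ndarray | None = None,
    names: list[str] | None = None,
    group: str = "participant",
    var_ratio: float | None = None,
    raw_poly: bool = False,
) -> ModelFit:
    """Fit the random-intercept LMM by profiled maximum likelihood.

    ``data`` needs the response column, the grouping column and (when a
    :class:`ModelSpec` is given) the design factors.  A pre-built design
    may be supplied through ``X``/``names`` instead of ``spec``.
    ``var_ratio`` fixes lambda = sigma_b^2/sigma_e^2 (0 reduces the model
    to OLS); otherwise lambda is profiled out with a bounded scalar search
    on log lambda, with the boundary lambda = 0 checked explicitly.
    """
    if spec is not None:
        X, names = build_design(data, spec, raw_poly=raw_poly)
        y = data[spec.response].to_numpy(dtype=float)
    else:
        if X is None or names is None:
            raise ValueError("provide either spec or a prebuilt X with names")
        y = data["log_error"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(data[group], sort=True)
    q = len(uniques)
    if q < 2:
        raise ValueError("need at least two participants for a random intercept")
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("more parameters than observations")

    converged = True
    if var_ratio is not None:
        lam = float(var_ratio)
    else:
        # Deterministic bounded search on log-lambda; tolerance tight
        # enough that the profiled deviance is resolved to ~1e-10.
        res = optimize.minimize_scalar(
            lambda phi: -_profile_loglik(X, y, codes, q, np.exp(phi)),
            bounds=(-30.0, 15.0), method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        converged = bool(res.success)
        lam = float(np.exp(res.x))
        if _profile_loglik(X, y, codes, q, 0.0) >= -res.fun:
            lam = 0.0

    beta, XtVX, rss, logdet = _profile_pieces(X, y, codes, q, lam)
    sigma2_e = rss / n
    loglik = -0.5 * (n * (np.log(2.0 * np.pi * sigma2_e) + 1.0) + logdet)
    cov = sigma2_e * np.linalg.inv(XtVX)
    return ModelFit(
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        cov_params=cov,
        param_names=list(names),
        var_participant=lam * sigma2_e,
        var_resid=float(sigma2_e),
        loglik=float(loglik),
        n_params=p + 2,
        nobs=n,
        converged=converged,
        singular=(lam == 0.0),
        spec=spec,
    )


# --------------------------------------------------------------------------
# likelihood-ratio ladder
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """A likelihood-ratio comparison of two nested ML fits."""

    label: str
    chi2: float
    df: int
    p: float
    aic_full: float
    aic_reduced: float


def lrt(full: ModelFit, reduced: ModelFit, label: str = "") -> TestResult:
    """Deviance test: 2 * (loglik_full - loglik_reduced) ~ chi2(df).

    The reduced model must be nested in the full one (checked by fixed-
    effect column names) and fitted to the same rows.
    """
    if full.nobs != reduced.nobs:
        raise ValueError("models fitted to different numbers of rows")
    extra = set(reduced.param_names) - set(full.param_names)
    if extra:
        raise ValueError(f"models are not nested; reduced-only terms: {sorted(extra)}")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model must have at least as many parameters")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    # df = 0 (identical specs) degenerates to chi2 == 0, p == 1.
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 < 1e-8 else 0.0)
    return TestResult(label=label, chi2=float(chi2), df=df, p=p,
                      aic_full=full.aic, aic_reduced=reduced.aic)


def model_ladder(
    data: pd.DataFrame, group: str = "participant", response: str = "log_error"
) -> tuple[pd.DataFrame, dict[str, ModelFit]]:
    """Run the full stepwise deviance-test sequence.

    Order: (1) quadratic vs linear group-size polynomial in the
    all-interactions model; (2) drop the three-way interaction; (3) drop
    coloration x contrast; (4) drop contrast x number; (5) drop
    coloration x number; (6-8) each main effect deleted in turn from the
    main-effects model.  Interactions are discarded as they fail, as in a
    classical backward model-simplification ladder.

    Returns the table of test results and the fitted models keyed by name.
    """
    def fit(terms, degree):
        return fit_lmm(data, ModelSpec(terms=tuple(terms), poly_degree=degree,
                                       response=response), group=group)

    fits: dict[str, ModelFit] = {}
    rows: list[TestResult] = []

    full_quad = fit(FULL_TERMS, 2)
    full_lin = fit(FULL_TERMS, 1)
    fits["full_quadratic"] = full_quad
    fits["full_linear"] = full_lin
    rows.append(lrt(full_quad, full_lin, "number quadratic vs linear"))

    spec = ModelSpec(terms=FULL_TERMS, poly_degree=2, response=response)
    current = full_quad
    for term, label in [("N:C:K", "three-way interaction"),
                        ("C:K", "coloration x contrast"),
                        ("N:K", "contrast x number"),
                        ("N:C", "coloration x number")]:
        spec = spec.drop(term)
        reduced = fit_lmm(data, spec, group=group)
        fits[f"drop {term}"] = reduced
        rows.append(lrt(current, reduced, label))
        current = reduced

    main = fit(MAIN_EFFECTS, 2)
    fits["main_effects"] = main
    for term, label in [("C", "coloration main effect"),
                        ("N", "number main effect"),
                        ("K", "contrast main effect")]:
        reduced = fit(tuple(t for t in MAIN_EFFECTS if t != term), 2)
        fits[f"main minus {term}"] = reduced
        rows.append(lrt(main, reduced, label))

    table = pd.DataFrame([r.__dict__ for r in rows])
    return table, fits


# --------------------------------------------------------------------------
# post hoc contrasts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """One pairwise comparison with its family-adjusted p-value."""

    label: str
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


def tukey_posthoc(
    fit: ModelFit,
    factor: str = "coloration",
    levels: Sequence[str] = ("binary", "orthogonal", "parallel"),
    seed: int = 0,
) -> list[ContrastResult]:
    """All pairwise contrasts of a treatment-coded factor's levels.

    Estimates and their covariance come from the fitted fixed-effects
    covariance; z = estimate / SE.  The family-wise adjusted p-value of
    contrast i is 1 - P(max_j |Z_j| <= |z_i|) under the joint normal law
    of the contrast statistics (single-step Tukey-type adjustment,
    evaluated by quasi-Monte-Carlo integration of the multivariate normal
    with a fixed seed).  The normal rather than t reference is used,
    matching z-statistic reporting.
    """
    dummy_names = [f"{factor}[{lev}]" for lev in levels[1:]]
    if any(nm not in fit.param_names for nm in dummy_names):
        raise ValueError(f"factor {factor!r} (levels {list(levels)}) not in model")

    p = len(fit.params)
    rows, labels = [], []
    idx = {lev: fit.param_names.index(f"{factor}[{lev}]") for lev in levels[1:]}
    for i in range(1, len(levels)):
        for j in range(i):
            L = np.zeros(p)
            L[idx[levels[i]]] = 1.0
            if levels[j] != levels[0]:
                L[idx[levels[j]]] = -1.0
            rows.append(L)
            labels.append(f"{levels[i]} - {levels[j]}")
    L = np.vstack(rows)

    est = L @ fit.params
    V = L @ fit.cov_params @ L.T
    se = np.sqrt(np.diag(V))
    z = est / se
    R = V / np.outer(se, se)
    mvn = sps.multivariate_normal(mean=np.zeros(len(z)), cov=R,
                                  allow_singular=True, seed=seed)
    results = []
    for k, (lab, e, s, zk) in enumerate(zip(labels, est, se, z)):
        a = abs(zk)
        inside = float(mvn.cdf(np.full(len(z), a),
                               lower_limit=np.full(len(z), -a)))
        p_adj = min(max(1.0 - inside, 0.0), 1.0)
        p_un = 2.0 * float(sps.norm.sf(a))
        results.append(ContrastResult(label=lab, estimate=float(e), se=float(s),
                                      z=float(zk), p_unadjusted=p_un,
                                      p_adjusted=max(p_adj, p_un)))
    return results


# --------------------------------------------------------------------------
# within-subject confidence intervals
# --------------------------------------------------------------------------

def within_subject_ci(
    cells: pd.DataFrame,
    value: str = "mean_error_px",
    level: float = 0.95,
    condition_keys: Sequence[str] = ("coloration", "contrast", "set_size"),
) -> pd.DataFrame:
    """Cousineau-Morey within-subject confidence intervals per condition.

    Each participant's scores are recentred on the grand mean (removing
    between-subject level differences), the per-condition SE of the
    normalized scores is computed, inflated by the Morey bias-correction
    factor sqrt(C / (C - 1)) for C conditions, and scaled by the
    two-sided t quantile with (n_participants - 1) df.  Requires a
    complete participant x condition table.
    """
    keys = list(condition_keys)
    wide = cells.pivot_table(index="participant", columns=keys, values=value)
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"incomplete cells for conditions: {missing}")
    C = wide.shape[1]
    if C < 2:
        raise ValueError("within-subject correction undefined for a single condition")
    n = wide.shape[0]
    norm = wide.sub(wide.mean(axis=1), axis=0) + wide.to_numpy().mean()
    se = norm.std(axis=0, ddof=1) / np.sqrt(n)
    morey = np.sqrt(C / (C - 1.0))
    tq = sps.t.ppf(0.5 + level / 2.0, n - 1)
    out = pd.DataFrame({"mean": wide.mean(axis=0),
                        "ci_halfwidth": se * morey * tq}).reset_index()
    return out
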