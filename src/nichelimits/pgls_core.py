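"""Phylogenetic generalized least squares with selectable correlation models.

The regression is y = β0 + β1·1[C4] + ε with ε ~ N(0, σ²·C), where C is one
of five correlation structures derived from the working phylogeny:

* ``INDEPENDENT`` — identity (no phylogenetic correlation);
* ``BROWNIAN`` — the tree's variance–covariance matrix V (shared root-to-MRCA
  path lengths);
* ``PAGEL_LAMBDA`` — V with off-diagonals multiplied by λ ∈ [0, 1];
* ``GRAFEN_RHO`` — node heights from descendant-tip counts,
  h = (n_desc − 1)/(n − 1), raised to ρ; cov(i, j) = 1 − h(MRCA)^ρ, unit
  diagonal (input branch lengths are ignored, the classical definition);
* ``ACDC_G`` — accelerating/decelerating rates: a branch running from relative
  depth d1 to d2 (root = 0, total height T) is stretched to
  (T/ln g)·(g^{d2/T} − g^{d1/T}); g = 1 is the Brownian limit.

The transformation parameter, where present, is profiled by maximum
likelihood (coarse grid then bounded scalar search). Models are compared by
AIC with k = fixed coefficients + 1 (σ²) + 1 if a transformation parameter is
estimated. The β1 test uses the unbiased residual scale e'V⁻¹e/(n−p) and a
two-sided t on n − 2 degrees of freedom, so that with a known correct V the
statistic is exactly t-distributed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .backbone_tree import _node_depths
from .errors import SingularCovarianceError

log = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


class Family(Enum):
    INDEPENDENT = "independent"
    BROWNIAN = "brownian"
    PAGEL_LAMBDA = "pagel_lambda"
    GRAFEN_RHO = "grafen_rho"
    ACDC_G = "acdc_g"


FAMILY_ORDER = (
    Family.INDEPENDENT,
    Family.BROWNIAN,
    Family.PAGEL_LAMBDA,
    Family.GRAFEN_RHO,
    Family.ACDC_G,
)

# Search bounds for the transformation parameter; ρ and g are profiled on a
# log scale for conditioning.
THETA_BOUNDS = {
    Family.PAGEL_LAMBDA: (0.0, 1.0),
    Family.GRAFEN_RHO: (1e-3, 10.0),
    Family.ACDC_G: (0.01, 100.0),
}
_LOG_SCALE = {Family.GRAFEN_RHO, Family.ACDC_G}


@dataclass(frozen=True)
class CorrelationModel:
    family: Family
    theta: float | None = None

    def __post_init__(self):
        if self.family in THETA_BOUNDS:
            lo, hi = THETA_BOUNDS[self.family]
            if self.theta is None or not lo <= self.theta <= hi:
                raise ValueError(
                    f"{self.family.value} parameter must lie in [{lo}, {hi}], "
                    f"got {self.theta}"
                )
        elif self.theta is not None:
            raise ValueError(f"{self.family.value} takes no parameter")


class TreeData:
    """Array form of a phylogeny for fast repeated covariance construction."""

    def __init__(self, tree: dendropy.Tree):
        depths = _node_depths(tree)
        leaves = list(tree.leaf_node_iter())
        self.labels: list[str] = [l.taxon.label for l in leaves]
        index = {l: i for i, l in enumerate(self.labels)}
        self.n = n = len(leaves)

        edges_d1, edges_d2, rows = [], [], []
        self.mrca_nleaves = np.ones((n, n))
        for node in tree.preorder_node_iter():
            tips = np.array([index[l.taxon.label] for l in node.leaf_iter()])
            if node is not tree.seed_node:
                edges_d1.append(depths[node.parent_node])
                edges_d2.append(depths[node])
                row = np.zeros(n)
                row[tips] = 1.0
                rows.append(row)
            self.mrca_nleaves[np.ix_(tips, tips)] = len(tips)

        self.edge_d1 = np.asarray(edges_d1)
        self.edge_d2 = np.asarray(edges_d2)
        self.edge_len = self.edge_d2 - self.edge_d1
        self.B = np.asarray(rows)  # (n_edges, n) tip-descent incidence
        self.T = float(max(depths[l] for l in leaves))
        self.V = (self.B * self.edge_len[:, None]).T @ self.B

    @classmethod
    def ensure(cls, tree) -> "TreeData":
        return tree if isinstance(tree, TreeData) else cls(tree)


def transform_vcv(V: np.ndarray | None, tree, model: CorrelationModel) -> np.ndarray:
    """Correlation/covariance structure for one model.

    ``V`` (the Brownian VCV) is used directly for INDEPENDENT/BROWNIAN/PAGEL;
    GRAFEN_RHO and ACDC_G are recomputed from the tree, which may be a
    ``dendropy.Tree`` or a prebuilt :class:`TreeData`.
    """
    td = TreeData.ensure(tree) if tree is not None else None
    if V is None:
        V = td.V
    V = np.asarray(V, dtype=float)
    fam = model.family
    if fam is Family.INDEPENDENT:
        return np.eye(V.shape[0])
    if fam is Family.BROWNIAN:
        return V.copy()
    if fam is Family.PAGEL_LAMBDA:
        out = model.theta * V
        np.fill_diagonal(out, np.diag(V))
        return out
    if fam is Family.GRAFEN_RHO:
        h = (td.mrca_nleaves - 1.0) / max(td.n - 1.0, 1.0)
        out = 1.0 - h ** model.theta
        np.fill_diagonal(out, 1.0)
        return out
    # ACDC_G
    g = model.theta
    if abs(g - 1.0) < 1e-9:
        return td.V.copy()
    lg = math.log(g)
    lens = (td.T / lg) * (g ** (td.edge_d2 / td.T) - g ** (td.edge_d1 / td.T))
    return (td.B * lens[:, None]).T @ td.B


def build_design(states: Sequence[str]) -> np.ndarray:
    """n×2 design: intercept column and a C4 indicator, in input order."""
    states = list(states)
    uniq = set(states)
    if uniq - {"C3", "C4"}:
        raise ValueError(f"unknown state(s): {uniq - {'C3', 'C4'}}")
    if len(uniq) < 2:
        raise ValueError("contrast requires both states")
    X = np.ones((len(states), 2))
    X[:, 1] = [1.0 if s == "C4" else 0.0 for s in states]
    return X


@dataclass
class GLSResult:
    beta: np.ndarray
    cov_beta: np.ndarray  # based on the unbiased scale e'V^-1 e/(n-p)
    sigma2: float  # ML: /n; REML: /(n-p)
    log_likelihood: float
    n: int
    p: int


def gls_fit(y, X, V, method: str = "ML") -> GLSResult:
    """Generalized least squares via Cholesky factorisation of V.

    β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y; the log-likelihood is the multivariate-normal
    value profiled over β and σ² (REML includes the −½log|XᵀV⁻¹X| term).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise SingularCovarianceError(
            f"covariance structure is not positive definite ({exc})"
        ) from exc
    d = np.diag(c)
    if d.min() <= 0 or d.min() / d.max() < 1e-12:
        raise SingularCovarianceError("covariance structure is numerically singular")
    logdet_V = 2.0 * float(np.sum(np.log(d)))
    Vi_X = cho_solve((c, low), X, check_finite=False)
    Vi_y = cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError("design is singular under this structure") from exc
    e = y - X @ beta
    q = float(e @ cho_solve((c, low), e, check_finite=False))
    q = max(q, 1e-300)
    XtViX_inv = np.linalg.inv(XtViX)
    cov_beta = (q / (n - p)) * XtViX_inv
    if method == "ML":
        sigma2 = q / n
        ll = -0.5 * (n * LOG2PI + n * math.log(sigma2) + logdet_V + n)
    elif method == "REML":
        sigma2 = q / (n - p)
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        ll = -0.5 * (
            (n - p) * LOG2PI
            + (n - p) * math.log(sigma2)
            + logdet_V
            + logdet_XtViX
            + (n - p)
        )
    else:
        raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
    return GLSResult(beta, cov_beta, sigma2, ll, n, p)


@dataclass
class PGLSFit:
    model: CorrelationModel
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    sigma2: float
    log_likelihood: float
    aic: float
    p_value: float
    n: int
    k: int
    method: str
    at_boundary: bool = False

    @property
    def mean_c3(self) -> float:
        return self.beta0

    @property
    def mean_c4(self) -> float:
        return self.beta0 + self.beta1


def _n_params(family: Family) -> int:
    return 3 + (1 if family in THETA_BOUNDS else 0)


def _finish_fit(res: GLSResult, model: CorrelationModel, method: str,
                at_boundary: bool = False) -> PGLSFit:
    k = _n_params(model.family)
    se = np.sqrt(np.diag(res.cov_beta))
    tstat = res.beta[1] / se[1]
    df = res.n - 2
    p = 2.0 * float(stats.t.sf(abs(tstat), df))
    return PGLSFit(
        model=model,
        beta0=float(res.beta[0]),
        beta1=float(res.beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        sigma2=res.sigma2,
        log_likelihood=res.log_likelihood,
        aic=2.0 * k - 2.0 * res.log_likelihood,
        p_value=p,
        n=res.n,
        k=k,
        method=method,
        at_boundary=at_boundary,
    )


N_STARTS = 5  # coarse profile grid before the bounded local search
THETA_RTOL = 1e-6


def fit_pgls(y, X, tree, family: Family, method: str = "ML") -> PGLSFit:
    """Fit one correlation family, profiling its parameter if it has one."""
    td = TreeData.ensure(tree)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if family not in THETA_BOUNDS:
        model = CorrelationModel(family)
        res = gls_fit(y, X, transform_vcv(td.V, td, model), method)
        return _finish_fit(res, model, method)

    lo, hi = THETA_BOUNDS[family]
    logscale = family in _LOG_SCALE

    def to_theta(u: float) -> float:
        return math.exp(u) if logscale else u

    ulo, uhi = (math.log(lo), math.log(hi)) if logscale else (lo, hi)

    def nll(u: float) -> float:
        theta = min(max(to_theta(u), lo), hi)
        try:
            res = gls_fit(y, X, transform_vcv(td.V, td, CorrelationModel(family, theta)), method)
        except SingularCovarianceError:
            return np.inf
        return -res.log_likelihood

    grid = np.linspace(ulo, uhi, N_STARTS)
    vals = np.array([nll(u) for u in grid])
    if not np.isfinite(vals).any():
        raise SingularCovarianceError(
            f"{family.value}: covariance singular over the whole parameter range"
        )
    i = int(np.nanargmin(vals))
    lo_u = grid[max(i - 1, 0)]
    hi_u = grid[min(i + 1, N_STARTS - 1)]
    opt = optimize.minimize_scalar(
        nll, bounds=(lo_u, hi_u), method="bounded",
        options={"xatol": THETA_RTOL * (uhi - ulo)},
    )
    u_best, f_best = opt.x, opt.fun
    if vals[i] < f_best:  # keep the grid point if the local search regressed
        u_best, f_best = grid[i], vals[i]
    theta = min(max(to_theta(float(u_best)), lo), hi)
    span = uhi - ulo
    at_boundary = (
        min(abs(float(u_best) - ulo), abs(uhi - float(u_best))) < 1e-6 * span
    )
    if at_boundary:
        log.warning("%s: profile optimum at parameter boundary (theta=%.4g)",
                    family.value, theta)
    model = CorrelationModel(family, theta)
    res = gls_fit(y, X, transform_vcv(td.V, td, model), method)
    return _finish_fit(res, model, method, at_boundary)


@dataclass
class ModelSelection:
    fits: dict[Family, PGLSFit]
    failures: dict[Family, str]
    best: PGLSFit
    agreement: bool  # every model with ΔAIC<=10 agrees on significance & sign

    @property
    def ranked(self) -> list[PGLSFit]:
        order = {f: i for i, f in enumerate(FAMILY_ORDER)}
        return sorted(
            self.fits.values(), key=lambda f: (f.aic, f.k, order[f.model.family])
        )


DELTA_AIC_AGREEMENT = 10.0


def model_suite(y, X, tree, method: str = "ML", alpha: float = 0.05) -> ModelSelection:
    """Fit all five families; select by lowest AIC; check ΔAIC≤10 agreement.

    Ties are broken toward fewer parameters, then the fixed family order.
    The agreement flag is true iff every fitted model within ΔAIC ≤ 10 of the
    best agrees with the best on significance at ``alpha`` and on the sign of
    the C4 − C3 difference.
    """
    td = TreeData.ensure(tree)
    fits: dict[Family, PGLSFit] = {}
    failures: dict[Family, str] = {}
    for family in FAMILY_ORDER:
        try:
            fits[family] = fit_pgls(y, X, td, family, method)
        except (SingularCovarianceError, ValueError) as exc:
            failures[family] = str(exc)
            log.warning("family %s failed: %s", family.value, exc)
    if not fits:
        raise SingularCovarianceError("every correlation family failed to fit")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    best = min(fits.values(), key=lambda f: (f.aic, f.k, order[f.model.family]))
    agreement = True
    for fit in fits.values():
        if fit.aic - best.aic <= DELTA_AIC_AGREEMENT:
            same_sig = (fit.p_value <= alpha) == (best.p_value <= alpha)
            same_sign = np.sign(fit.beta1) == np.sign(best.beta1)
            if not (same_sig and same_sign):
                agreement = False
    return ModelSelection(fits, failures, best, agreement)


def estimated_means(fit: PGLSFit) -> tuple[float, float, float, float]:
    """(mean_C3, mean_C4, difference, p): β0, β0+β1, β1, two-sided p on β1."""
    return fit.beta0, fit.beta0 + fit.beta1, fit.beta1, fit.p_value
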