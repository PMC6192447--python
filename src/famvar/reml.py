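"""Restricted maximum likelihood for variance-component models.

Fits y ~ N(X beta, sum_c sigma2_c M_c + sigma2_e I) by average-information
(AI) REML with an EM first step and step-halving safeguards, reports
variance fractions with delta-method standard errors, performs one-tailed
boundary likelihood-ratio tests (50:50 mixture of a point mass at zero
and chi-square with 1 df), and runs backward stepwise selection over the
component set.

The same quadratic-form engine drives the bivariate model (see
:mod:`famvar.bivariate`): a model is a list of ``_Design`` objects, each
contributing ``theta_i * (placed blocks)`` to the covariance matrix, so
the parameter enters V linearly and the AI matrix is
``0.5 * y'P D_i P D_j P y`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
VARIANCE_FLOOR_SCALE = 1e-6


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """A variance-component model: subset of {G,K,F,S,C} plus fixed effects."""

    components: str
    fixed_effects: tuple[str, ...] = ("age", "sex", "MDS1", "MDS2", "MDS3", "MDS4")

    def __post_init__(self) -> None:
        if len(set(self.components)) != len(self.components):
            raise ValueError("duplicate components in model code")
        bad = set(self.components) - set("GKFSC")
        if bad:
            raise ValueError(f"unknown components {sorted(bad)}; allowed: G K F S C")


@dataclass
class FitResult:
    """REML estimates for one model.

    ``fractions`` are component variances divided by the total phenotypic
    variance (sum of all estimated variances including the residual);
    ``ses`` are their delta-method standard errors from the inverse
    average-information matrix. ``h2n`` is the narrow-sense heritability
    h2_g + h2_p when both genetic matrices are in the model.
    """

    components: tuple[str, ...]
    variances: dict[str, float]
    fractions: dict[str, float]
    ses: dict[str, float]
    logL: float
    n_used: int
    converged: bool
    identifiable: bool = True
    n_iter: int = 0
    at_floor: tuple[str, ...] = ()
    beta: np.ndarray | None = None
    cov_theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def h2n(self) -> float | None:
        if "G" in self.fractions and "K" in self.fractions:
            return self.fractions["G"] + self.fractions["K"]
        return None


@dataclass
class LRTResult:
    statistic: float
    p: float
    df_boundary: bool = True


# ---------------------------------------------------------------------------
# Design blocks and the AI-REML engine
# ---------------------------------------------------------------------------


class _Design:
    """One covariance parameter's contribution to V.

    ``placements`` is a list of ``(rows, cols, M)``; off-diagonal blocks
    (rows is not cols) are mirrored automatically so the total
    contribution stays symmetric. ``rows``/``cols`` are integer index
    arrays into the stacked observation vector, or ``None`` for "all".
    """

    def __init__(self, placements, name: str = "", is_variance: bool = True):
        self.placements = [
            (r if r is None else np.asarray(r), c if c is None else np.asarray(c), M)
            for r, c, M in placements
        ]
        self.name = name
        self.is_variance = is_variance

    def add_to(self, V: np.ndarray, theta: float) -> None:
        for r, c, M in self.placements:
            if r is None:
                V += theta * M
            else:
                V[np.ix_(r, c)] += theta * M
                if r is not c:
                    V[np.ix_(c, r)] += theta * M.T

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v)
        for r, c, M in self.placements:
            if r is None:
                out += M @ v
            else:
                out[r] += M @ v[c]
                if r is not c:
                    out[c] += M.T @ v[r]
        return out

    def trace_with(self, P: np.ndarray) -> float:
        s = 0.0
        for r, c, M in self.placements:
            if r is None:
                s += float(np.sum(P * M))
            else:
                block = P[np.ix_(r, c)]
                s += float(np.sum(block * M)) * (1.0 if r is c else 2.0)
        return s


def _sym_inv_cholesky(V):
    """(V^{-1}, log det V) via Cholesky + LAPACK dpotri."""
    c, info = linalg.lapack.dpotrf(V, lower=1, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError(f"covariance matrix not positive definite (dpotrf info={info})")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    vi, info = linalg.lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed (info={info})")
    Vinv = np.tril(vi) + np.tril(vi, -1).T
    return Vinv, logdet


def _reml_pieces(y, X, V):
    """Restricted log-likelihood and projection pieces at a given V."""
    n, p = X.shape
    Vinv, logdet_V = _sym_inv_cholesky(V)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    beta = linalg.cho_solve(cx, X.T @ (Vinv @ y), check_finite=False)
    P = Vinv - ViX @ linalg.cho_solve(cx, ViX.T, check_finite=False)
    Py = P @ y
    ll = -0.5 * (logdet_V + logdet_X + float(y @ Py) + (n - p) * np.log(2 * np.pi))
    return ll, P, Py, beta


def _loglik_only(y, X, V):
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Viy = linalg.cho_solve((c, low), y, check_finite=False)
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ ViX
    cx = linalg.cho_factor(XtViX, lower=True, check_finite=False)
    logdet_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    beta = linalg.cho_solve(cx, X.T @ Viy, check_finite=False)
    yPy = float(y @ Viy) - float((X.T @ Viy) @ beta)
    return -0.5 * (logdet_V + logdet_X + yPy + (n - p) * np.log(2 * np.pi))


def _assemble(designs, theta, n):
    V = np.zeros((n, n))
    for d, t in zip(designs, theta):
        d.add_to(V, t)
    return V


def ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    designs: list[_Design],
    theta0: np.ndarray,
    floor: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Maximize the restricted likelihood over theta (V linear in theta).

    Variance parameters are kept at or above ``floor``; covariance
    parameters are unconstrained but every proposed step must keep V
    positive definite (enforced by step halving). The first iteration
    uses the EM update when all parameters are variances; subsequent
    iterations take average-information steps with step halving whenever
    the likelihood would decrease.

    Returns ``(theta, logL, AI, converged, n_iter)``.
    """
    n = len(y)
    theta = np.asarray(theta0, dtype=float).copy()
    is_var = np.array([d.is_variance for d in designs])
    theta[is_var] = np.maximum(theta[is_var], floor)
    k = len(designs)

    ll = -np.inf
    AI = np.eye(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = _assemble(designs, theta, n)
        ll_new, P, Py, _ = _reml_pieces(y, X, V)
        q = [d.matvec(Py) for d in designs]
        u = [P @ qi for qi in q]
        yPDPy = np.array([float(Py @ qi) for qi in q])
        trPD = np.array([d.trace_with(P) for d in designs])
        score = 0.5 * (yPDPy - trPD)
        AI = 0.5 * np.array([[float(q[i] @ u[j]) for j in range(k)] for i in range(k)])

        if np.isfinite(ll) and abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

        if it == 1 and is_var.all():
            # EM first step: monotone, keeps the parameter space
            delta = theta**2 * (yPDPy - trPD) / n
            theta = np.maximum(theta + delta, floor)
            continue

        # active-set AI step: parameters pinned at the floor whose score
        # points further downhill are frozen, so they do not contaminate
        # the Newton direction of the free parameters
        pinned = is_var & (theta <= floor * (1 + 1e-9)) & (score <= 0)
        free = ~pinned
        if not free.any():
            converged = True
            break
        sub = AI[np.ix_(free, free)]
        sf = score[free]

        # candidate ascent directions, most informative first: plain AI
        # (Newton) step, ridge-regularized AI (handles the exactly singular
        # AI that degenerate models produce), and a scaled gradient
        directions = []
        try:
            directions.append(np.linalg.solve(sub, sf))
        except np.linalg.LinAlgError:
            pass
        ridge = 1e-8 * max(float(np.abs(np.diag(sub)).max()), 1.0)
        for lam in (ridge, ridge * 1e4):
            try:
                directions.append(np.linalg.solve(sub + lam * np.eye(sub.shape[0]), sf))
            except np.linalg.LinAlgError:
                pass
        grad_scale = float(np.trace(sub)) / sub.shape[0]
        if grad_scale > 0:
            directions.append(sf / grad_scale)
        if is_var.all():
            directions.append((theta**2 * (yPDPy - trPD) / n)[free])  # EM step

        accepted = False
        for delta_free in directions:
            delta = np.zeros(k)
            delta[free] = delta_free
            step = 1.0
            for _ in range(25):
                cand = theta + step * delta
                cand[is_var] = np.maximum(cand[is_var], floor)
                try:
                    ll_cand = _loglik_only(y, X, _assemble(designs, cand, n))
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if np.isfinite(ll_cand) and ll_cand >= ll - 1e-10:
                    theta = cand
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            converged = True  # no uphill direction found: at a (constrained) optimum
            break

    return theta, ll, AI, converged, it


# ---------------------------------------------------------------------------
# Public univariate interface
# ---------------------------------------------------------------------------


def _prepare_xy(y, X):
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not (X == 1.0).all(axis=0).any():
            X = np.column_stack([np.ones(len(y)), X])
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("y and X must be complete cases (drop missing rows first)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is singular")
    return y, X


def _fraction_ses(theta: np.ndarray, cov_theta: np.ndarray) -> np.ndarray:
    """Delta-method SEs of theta_i / sum(theta)."""
    S = theta.sum()
    k = len(theta)
    J = (np.eye(k) * S - theta[:, None]) / S**2  # d f_i / d theta_j at row i
    return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", J, cov_theta, J), 0.0))


def reml_fit(
    y,
    X=None,
    matrices=(),
    ids: list[str] | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    start: dict[str, float] | None = None,
) -> FitResult:
    """Univariate variance-component REML fit.

    ``matrices`` is a sequence of :class:`~famvar.matrices.RelationshipMatrix`;
    a residual (identity) component is always included implicitly. When
    ``ids`` is given (or ``y`` is a pandas Series with an index), each
    matrix is re-ordered to match; otherwise matrices must already align
    with ``y``'s order. ``start`` optionally warm-starts the optimizer
    with per-component variances (keyed by matrix kind / 'residual').
    """
    if isinstance(y, pd.Series) and ids is None:
        ids = list(y.index)
    y, X = _prepare_xy(y, X)
    n, p = X.shape

    aligned, names = [], []
    for rm in matrices:
        names.append(rm.kind)
        vals = rm.align(ids) if ids is not None else rm.values
        if vals.shape[0] != n:
            raise ValueError(
                f"matrix {rm.kind} has {vals.shape[0]} individuals but y has {n}; "
                "supply ids for alignment"
            )
        aligned.append(vals)
    if len(set(names)) != len(names):
        raise ValueError("duplicate matrix kinds supplied")
    if n <= p + len(aligned):
        raise ValueError("not enough observations for the requested model")

    # OLS residual variance anchors the floor and starting values
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    var_y = float(resid @ resid) / (n - p)

    if not aligned:
        logdet_XtX = np.linalg.slogdet(X.T @ X)[1]
        ll = -0.5 * ((n - p) * np.log(var_y) + logdet_XtX + (n - p) + (n - p) * np.log(2 * np.pi))
        return FitResult(
            components=(),
            variances={"residual": var_y},
            fractions={"residual": 1.0},
            ses={"residual": 0.0},
            logL=float(ll),
            n_used=n,
            converged=True,
            beta=np.linalg.lstsq(X, y, rcond=None)[0],
        )

    designs = [_Design([(None, None, M)], name=nm) for nm, M in zip(names, aligned)]
    designs.append(_Design([(None, None, np.eye(n))], name="residual"))
    floor = VARIANCE_FLOOR_SCALE * var_y
    if start is not None:
        theta0 = np.array(
            [start.get(nm, var_y / len(designs)) for nm in names + ["residual"]]
        )
    else:
        theta0 = np.full(len(designs), var_y / len(designs))
    theta, ll, AI, converged, n_iter = ai_reml(
        y, X, designs, theta0, floor, tol=tol, max_iter=max_iter
    )

    identifiable = True
    for M in aligned:
        if np.abs(M - np.eye(n)).max() < 1e-10:
            identifiable = False  # indistinguishable from the residual
    try:
        cov_theta = np.linalg.inv(AI)
        if np.linalg.cond(AI) > 1e12:
            identifiable = False
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(AI)
        identifiable = False

    all_names = names + ["residual"]
    fractions = theta / theta.sum()
    ses = _fraction_ses(theta, cov_theta)
    at_floor = tuple(nm for nm, t in zip(all_names, theta) if t <= floor * (1 + 1e-9))
    V = _assemble(designs, theta, n)
    _, _, _, beta = _reml_pieces(y, X, V)
    return FitResult(
        components=tuple(names),
        variances=dict(zip(all_names, theta)),
        fractions=dict(zip(all_names, fractions)),
        ses=dict(zip(all_names, ses)),
        logL=float(ll),
        n_used=n,
        converged=converged,
        identifiable=identifiable,
        n_iter=n_iter,
        at_floor=at_floor,
        beta=beta,
        cov_theta=cov_theta,
    )


# ---------------------------------------------------------------------------
# Boundary LRT and backward selection
# ---------------------------------------------------------------------------


def lrt_component(full: FitResult, reduced: FitResult) -> LRTResult:
    """One-tailed boundary LRT for the single component dropped in ``reduced``.

    The null value sits on the parameter-space boundary (a variance of
    zero), so the statistic is referred to a 50:50 mixture of a point
    mass at zero and chi-square(1): p = 0.5 * P(chi2_1 > stat).
    """
    extra = set(full.components) - set(reduced.components)
    if not set(reduced.components) <= set(full.components) or len(extra) != 1:
        raise ValueError(
            f"reduced model {reduced.components} must drop exactly one component "
            f"of the full model {full.components}"
        )
    stat = max(0.0, 2.0 * (full.logL - reduced.logL))
    p = 0.5 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return LRTResult(statistic=stat, p=p)


def backward_select(
    y,
    X=None,
    matrices: dict[str, "RelationshipMatrix"] | None = None,
    ids: list[str] | None = None,
    alpha: float = 0.05,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
):
    """Backward stepwise selection over variance components.

    Starting from the model with every supplied matrix, each round tests
    every current component with a drop-one LRT; if any p >= alpha the
    single component with the largest p (ties broken toward the smaller
    estimated fraction) is removed and the procedure repeats until all
    remaining components are significant.

    Returns ``(ModelSpec, FitResult, trace)`` where ``trace`` records each
    round's fits and removal decision.
    """
    matrices = dict(matrices or {})
    order = [k for k in "GKFSC" if k in matrices] or list(matrices)

    def fit_for(comps: list[str], warm: FitResult | None = None) -> FitResult:
        start = None
        if warm is not None:
            # reassign the dropped component's variance to the residual
            start = {c: warm.variances[c] for c in comps}
            extra = sum(v for c, v in warm.variances.items()
                        if c not in comps and c != "residual")
            start["residual"] = warm.variances["residual"] + extra
        return reml_fit(y, X, [matrices[c] for c in comps], ids=ids,
                        tol=tol, max_iter=max_iter, start=start)

    current = list(order)
    full_fit = fit_for(current)
    trace = []
    reduced_cache: dict[tuple[str, ...], FitResult] = {}
    while current:
        tests = {}
        for c in current:
            rest = tuple(x for x in current if x != c)
            if rest not in reduced_cache:
                reduced_cache[rest] = fit_for(list(rest), warm=full_fit)
            tests[c] = lrt_component(full_fit, reduced_cache[rest])
        round_rec = {
            "components": "".join(current),
            "logL": full_fit.logL,
            "fractions": dict(full_fit.fractions),
            "p_values": {c: t.p for c, t in tests.items()},
        }
        not_sig = {c: t.p for c, t in tests.items() if t.p >= alpha}
        if not not_sig:
            round_rec["removed"] = None
            trace.append(round_rec)
            break
        worst_p = max(not_sig.values())
        worst = [c for c, pv in not_sig.items() if pv == worst_p]
        drop = min(worst, key=lambda c: full_fit.fractions[c]) if len(worst) > 1 else worst[0]
        round_rec["removed"] = drop
        trace.append(round_rec)
        current = [c for c in current if c != drop]
        full_fit = reduced_cache[tuple(current)]
        reduced_cache = {}

    spec = ModelSpec("".join(current), fixed_effects=())
    return spec, full_fit, trace


def report_table(fits: dict[str, FitResult], pvalues: dict[str, dict[str, float]] | None = None):
    """Render per-model variance fractions as '0.14 (0.03)' cells.

    ``fits`` maps a model code (e.g. 'GK', 'GKFSC') to its FitResult;
    ``pvalues`` optionally maps model code -> component -> LRT p, marking
    significant cells with an asterisk. Returns a DataFrame (one row per
    model) and also attaches machine-readable numbers in ``df.attrs``.
    """
    rows = {}
    raw = {}
    for code, fit in fits.items():
        row = {}
        for c in "GKFSC":
            if c in fit.fractions:
                cell = f"{fit.fractions[c]:.2f} ({fit.ses[c]:.2f})"
                if pvalues and pvalues.get(code, {}).get(c, 1.0) < 0.05:
                    cell += "*"
                row[c] = cell
            else:
                row[c] = ""
        row["logL"] = round(fit.logL, 2)
        row["n"] = fit.n_used
        rows[code] = row
        raw[code] = {
            "fractions": dict(fit.fractions),
            "ses": dict(fit.ses),
            "logL": fit.logL,
            "n": fit.n_used,
            "converged": fit.converged,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["raw"] = raw
    return df
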