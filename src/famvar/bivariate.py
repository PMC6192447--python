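"""Bivariate REML: genetic correlations between two traits.

Stacks the two trait vectors and models the 2N x 2N covariance with a
2 x 2 (co)variance structure per component — common-SNP genetic (G),
pedigree-associated genetic (K) and residual — so that nine parameters
(v1, v2, c12 per component) are estimated by the same average-information
engine as the univariate model. Genetic correlations are recovered as
r = c12 / sqrt(v1 * v2) with delta-method standard errors, and tested by
a likelihood-ratio against the model with that component's covariance
fixed at zero.

Individuals missing one trait are retained for the other (unbalanced
design); residual covariance applies only to individuals observed for
both traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .matrices import RelationshipMatrix
from .reml import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    LRTResult,
    VARIANCE_FLOOR_SCALE,
    _Design,
    ai_reml,
)


@dataclass
class BivariateFit:
    """Bivariate REML estimates.

    ``correlations[c]`` is (r, se) for component c in {'G', 'K'};
    ``variances[c]`` is (v1, v2, c12). A correlation whose underlying
    variances sit at the zero floor is reported as None in
    ``correlations`` and named in ``undefined``; a correlation whose
    unconstrained optimum left [-1, 1] is clamped and named in
    ``clamped``.
    """

    components: tuple[str, ...]
    variances: dict[str, tuple[float, float, float]]
    fractions: dict[str, tuple[float, float]]
    fraction_ses: dict[str, tuple[float, float]]
    correlations: dict[str, tuple[float, float] | None]
    logL: float
    n1: int
    n2: int
    converged: bool
    undefined: tuple[str, ...] = ()
    clamped: tuple[str, ...] = ()
    theta: np.ndarray | None = None
    cov_theta: np.ndarray | None = None

    @property
    def r_G(self):
        rg = self.correlations.get("G")
        return None if rg is None else rg[0]

    @property
    def r_K(self):
        rk = self.correlations.get("K")
        return None if rk is None else rk[0]


def _stack_designs(comp_mats, ids1, ids2, both1, both2, n1, n2):
    """Per-component designs on the stacked (n1 + n2) observation vector."""
    designs = []
    rows1 = np.arange(n1)
    rows2 = n1 + np.arange(n2)
    for name, rm in comp_mats:
        if rm is None:  # residual
            M11, M22 = np.eye(n1), np.eye(n2)
            M12 = np.zeros((n1, n2))
            M12[both1, both2] = 1.0
        else:
            M11 = rm.align(ids1)
            M22 = rm.align(ids2)
            full = rm.align(list(ids1) + list(ids2))
            M12 = full[:n1, n1:]
        designs.append(_Design([(rows1, rows1, M11)], name=f"v1_{name}"))
        designs.append(_Design([(rows2, rows2, M22)], name=f"v2_{name}"))
        designs.append(
            _Design([(rows1, rows2, M12)], name=f"c_{name}", is_variance=False)
        )
    return designs


def _build_inputs(y1, y2, X, G, K):
    if not isinstance(y1, pd.Series) or not isinstance(y2, pd.Series):
        raise TypeError("y1 and y2 must be pandas Series indexed by individual id")
    y1 = y1.dropna()
    y2 = y2.dropna()
    ids1, ids2 = list(y1.index), list(y2.index)
    n1, n2 = len(ids1), len(ids2)
    pos2 = {i: k for k, i in enumerate(ids2)}
    both1 = np.array([k for k, i in enumerate(ids1) if i in pos2], dtype=int)
    both2 = np.array([pos2[ids1[k]] for k in both1], dtype=int)

    if X is None:
        X1 = pd.DataFrame(index=ids1)
        X2 = pd.DataFrame(index=ids2)
    else:
        X1, X2 = X.loc[ids1], X.loc[ids2]
    # separate fixed effects per trait (block-diagonal design)
    p = X1.shape[1] + 1
    Xs = np.zeros((n1 + n2, 2 * p))
    Xs[:n1, 0] = 1.0
    Xs[n1:, p] = 1.0
    if p > 1:
        Xs[:n1, 1:p] = X1.to_numpy(dtype=float)
        Xs[n1:, p + 1:] = X2.to_numpy(dtype=float)
    ys = np.concatenate([y1.to_numpy(dtype=float), y2.to_numpy(dtype=float)])
    comp_mats = [("G", G)] + ([("K", K)] if K is not None else []) + [("E", None)]
    designs = _stack_designs(comp_mats, ids1, ids2, both1, both2, n1, n2)
    return ys, Xs, designs, comp_mats, n1, n2


def bivariate_fit(
    y1: pd.Series,
    y2: pd.Series,
    X: pd.DataFrame | None = None,
    G: RelationshipMatrix | None = None,
    K: RelationshipMatrix | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    fix_zero: tuple[str, ...] = (),
) -> BivariateFit:
    """Fit the bivariate model and report per-component correlations.

    ``y1``/``y2`` are trait Series indexed by individual id (missing
    values dropped per trait); ``X`` holds covariate columns indexed by
    id. ``fix_zero`` names components whose cross-trait covariance is
    constrained to zero (used by the correlation LRT).
    """
    if G is None:
        raise ValueError("the G matrix is required")
    ys, Xs, designs, comp_mats, n1, n2 = _build_inputs(y1, y2, X, G, K)

    free = [d for d in designs if not (
        (not d.is_variance) and d.name.removeprefix("c_") in fix_zero
    )]
    vy = float(np.var(ys))
    k_comp = len(comp_mats)
    theta0 = np.array([
        vy / k_comp if d.is_variance else 0.0 for d in free
    ])
    floor = VARIANCE_FLOOR_SCALE * vy
    theta, ll, AI, converged, _ = ai_reml(ys, Xs, free, theta0, floor,
                                          tol=tol, max_iter=max_iter)
    try:
        cov_theta = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(AI)

    names = [d.name for d in free]
    est = dict(zip(names, theta))
    variances, correlations = {}, {}
    undefined, clamped = [], []
    for name, _rm in comp_mats:
        v1 = est[f"v1_{name}"]
        v2 = est[f"v2_{name}"]
        c12 = est.get(f"c_{name}", 0.0)
        variances[name] = (v1, v2, c12)
        if name == "E":
            continue
        if v1 <= floor * (1 + 1e-9) or v2 <= floor * (1 + 1e-9):
            correlations[name] = None
            undefined.append(name)
            continue
        r = c12 / np.sqrt(v1 * v2)
        if abs(r) > 1.0:
            r = float(np.clip(r, -1.0, 1.0))
            clamped.append(name)
        # delta method on (v1, v2, c12)
        i1, i2 = names.index(f"v1_{name}"), names.index(f"v2_{name}")
        if f"c_{name}" in names:
            ic = names.index(f"c_{name}")
            grad = np.zeros(len(names))
            grad[i1] = -0.5 * c12 / (v1**1.5 * v2**0.5)
            grad[i2] = -0.5 * c12 / (v2**1.5 * v1**0.5)
            grad[ic] = 1.0 / np.sqrt(v1 * v2)
            se = float(np.sqrt(max(grad @ cov_theta @ grad, 0.0)))
        else:
            se = float("nan")
        correlations[name] = (float(r), se)

    # per-trait variance fractions (variance / trait total)
    tot1 = sum(variances[nm][0] for nm, _ in comp_mats)
    tot2 = sum(variances[nm][1] for nm, _ in comp_mats)
    fractions, fr_ses = {}, {}
    for name, _rm in comp_mats:
        v1, v2, _ = variances[name]
        fractions[name] = (v1 / tot1, v2 / tot2)
        i1, i2 = names.index(f"v1_{name}"), names.index(f"v2_{name}")
        fr_ses[name] = (
            _fraction_se_single(theta, cov_theta, names, "v1_", name, tot1),
            _fraction_se_single(theta, cov_theta, names, "v2_", name, tot2),
        )
    return BivariateFit(
        components=tuple(nm for nm, _ in comp_mats if nm != "E"),
        variances=variances,
        fractions=fractions,
        fraction_ses=fr_ses,
        correlations=correlations,
        logL=float(ll),
        n1=n1,
        n2=n2,
        converged=converged,
        undefined=tuple(undefined),
        clamped=tuple(clamped),
        theta=theta,
        cov_theta=cov_theta,
    )


def _fraction_se_single(theta, cov_theta, names, prefix, comp, total):
    """Delta-method SE of v_comp / total over that trait's variance params."""
    grad = np.zeros(len(names))
    own = names.index(f"{prefix}{comp}")
    for j, nm in enumerate(names):
        if nm.startswith(prefix):
            grad[j] = (float(j == own) * total - theta[own]) / total**2
    return float(np.sqrt(max(grad @ cov_theta @ grad, 0.0)))


def lrt_correlation(
    fit: BivariateFit,
    component: str,
    y1: pd.Series,
    y2: pd.Series,
    X: pd.DataFrame | None = None,
    G: RelationshipMatrix | None = None,
    K: RelationshipMatrix | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LRTResult:
    """One-tailed LRT of a genetic correlation against zero covariance.

    Refits with the named component's cross-trait covariance fixed at 0;
    the statistic 2(logL_full - logL_0) is referred to the one-tailed
    half-chi-square convention used for the variance-component tests.
    """
    if component not in ("G", "K"):
        raise ValueError("component must be 'G' or 'K'")
    constrained = bivariate_fit(
        y1, y2, X, G, K, tol=tol, max_iter=max_iter, fix_zero=(component,)
    )
    if not constrained.converged:
        return LRTResult(statistic=float("nan"), p=float("nan"))
    stat = max(0.0, 2.0 * (fit.logL - constrained.logL))
    p = 0.5 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return LRTResult(statistic=stat, p=p)
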