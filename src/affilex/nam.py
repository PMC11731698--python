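"""Two-mode linear network autocorrelation model (NAM) for user engagement.

Model::

    y = rho * W y + X beta + gamma * D + eps,   eps ~ N(0, sigma^2 I)

where ``y`` is posting frequency, ``W`` the row-normalized coaffiliation
matrix with zero diagonal (so that ``W y`` is exactly the affiliation
exposure vector), ``X`` the persona design matrix with a leading intercept
column, and ``D`` the per-user count of affiliated speech acts — included as
a control so that the autocorrelation parameter is not underestimated by
degree effects.

Estimation is maximum likelihood via the concentrated (profile) likelihood:
for fixed rho, ``z = (I - rho W) y`` is regressed on ``[X, D]`` by least
squares, giving closed forms for beta, gamma and sigma^2; the resulting
one-dimensional profile is maximized over rho by bounded scalar search on
the open admissible interval ``(1/lambda_min, 1/lambda_max)`` spanned by the
eigenvalues of W.  The log-Jacobian ``log|det(I - rho W)|`` is computed from
the precomputed eigenvalue spectrum as ``sum_i log|1 - rho lambda_i|``.
Standard errors come from the inverse of a numerically differentiated
observed-information matrix of the full log-likelihood at the optimum;
p-values are two-sided normal.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, DesignError, SingularityError
from .network import CoaffiliationMatrix

_LARGE = 1e6  # stands in for an unbounded interval endpoint
_DELTA = 1e-6  # offset keeping the search strictly inside the open interval


@dataclasses.dataclass
class WeightMatrix:
    """Row-normalized, zero-diagonal interaction weight matrix."""

    W: np.ndarray
    users: Optional[list[str]] = None
    derivation: str = "row_normalized_coaffiliation"


def row_normalize(C: Union[CoaffiliationMatrix, np.ndarray]) -> WeightMatrix:
    """Row-normalize a coaffiliation matrix into the model's W.

    ``W[i, j] = C[i, j] / sum_{j'!=i} C[i, j']`` with a zero diagonal;
    isolate rows stay entirely zero.  By construction ``W @ y`` equals the
    affiliation exposure of ``y`` for every non-isolated user.
    """
    if isinstance(C, CoaffiliationMatrix):
        users = C.users
        M = C.C
    else:
        users, M = None, np.asarray(C)
    off = M.astype(float).copy()
    np.fill_diagonal(off, 0.0)
    sums = off.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(sums > 0, off / sums, 0.0)
    return WeightMatrix(W=W, users=users)


def _as_w(W) -> np.ndarray:
    return W.W if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)


def w_eigenvalues(W) -> np.ndarray:
    """Real eigenvalue spectrum of W.

    For W derived by row-normalizing a symmetric coaffiliation matrix the
    spectrum is real (W is similar to a symmetric matrix on the non-isolate
    block; isolate rows contribute zeros).  A non-negligible imaginary part
    signals a W outside this family and is rejected.
    """
    Wm = _as_w(W)
    # W from a symmetric C is diagonally similar to the elementwise-symmetric
    # sqrt(W o W^T); the symmetric eigenproblem is markedly more accurate.
    if np.array_equal(Wm > 0, Wm.T > 0) and np.all(Wm >= 0):
        return np.sort(np.linalg.eigvalsh(np.sqrt(Wm * Wm.T)))
    lam = np.linalg.eigvals(Wm)
    if np.abs(lam.imag).max(initial=0.0) > 1e-8:
        raise ValueError("W has genuinely complex eigenvalues; expected a "
                         "row-normalized symmetric-coaffiliation weight matrix")
    return np.sort(lam.real)


def admissible_interval(W, eigvals: Optional[np.ndarray] = None,
                        delta: float = _DELTA) -> tuple[float, float]:
    """Open interval of rho for which I - rho*W is guaranteed nonsingular."""
    lam = w_eigenvalues(W) if eigvals is None else eigvals
    lmax = lam.max(initial=0.0)
    lmin = lam.min(initial=0.0)
    hi = 1.0 / lmax - delta if lmax > 0 else _LARGE
    lo = 1.0 / lmin + delta if lmin < 0 else -_LARGE
    return (lo, hi)


def log_det_term(rho: float, eigvals: np.ndarray) -> float:
    """log|det(I - rho W)| = sum_i log|1 - rho lambda_i|."""
    vals = 1.0 - rho * eigvals
    if np.any(vals == 0.0):
        raise SingularityError(f"I - rho*W singular at rho={rho}")
    return float(np.log(np.abs(vals)).sum())


def nam_loglik(
    rho: float,
    beta: np.ndarray,
    gamma: float,
    sigma2: float,
    y: np.ndarray,
    W,
    X: np.ndarray,
    D: np.ndarray,
    eigvals: Optional[np.ndarray] = None,
) -> float:
    """Full Gaussian log-likelihood of the network autocorrelation model."""
    Wm = _as_w(W)
    if eigvals is None:
        eigvals = w_eigenvalues(Wm)
    lo, hi = admissible_interval(Wm, eigvals, delta=0.0)
    if not (lo < rho < hi):
        raise SingularityError(f"rho={rho} outside admissible interval ({lo}, {hi})")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    resid = (y - rho * (Wm @ y)) - np.asarray(X, float) @ np.asarray(beta, float) \
        - float(gamma) * np.asarray(D, float)
    return (
        -0.5 * n * np.log(2.0 * np.pi * sigma2)
        + log_det_term(rho, eigvals)
        - 0.5 * (resid @ resid) / sigma2
    )


def _design(X: np.ndarray, D: Optional[np.ndarray], names: Optional[Sequence[str]]):
    X = np.asarray(X, dtype=float)
    if names is None:
        names = ["intercept"] + [f"x{j}" for j in range(1, X.shape[1])]
    if D is None:  # degree control omitted
        M = X
        names = list(names)
    else:
        M = np.column_stack([X, np.asarray(D, dtype=float).reshape(-1)])
        names = list(names) + ["sas_affiliated"]
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify offending columns from near-zero pivots of a QR factorization
        _, R = np.linalg.qr(M)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        raise DesignError(f"design matrix [X, D] is rank deficient "
                          f"(rank {rank} < {M.shape[1]}); collinear columns: {bad}")
    return M, names


def profile_fit(rho: float, y: np.ndarray, W, M: np.ndarray,
                eigvals: np.ndarray):
    """Closed-form (theta, sigma2, profile loglik) at a fixed rho."""
    Wm = _as_w(W)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    z = y - rho * (Wm @ y)
    theta, *_ = np.linalg.lstsq(M, z, rcond=None)
    resid = z - M @ theta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = (-0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
          + log_det_term(rho, eigvals))
    return theta, sigma2, ll


@dataclasses.dataclass
class NamFit:
    """Maximum-likelihood fit of the network autocorrelation model."""

    rho: float
    rho_se: float
    rho_p: float
    coef: pd.DataFrame  # per-covariate estimate / se / p; last row is D's gamma
    sigma2: float
    loglik: float
    n: int
    rho_interval: tuple[float, float]
    converged: bool
    n_isolates: int = 0
    label: Optional[str] = None
    profile_trace: Optional[list[tuple[float, float]]] = None

    @property
    def beta(self) -> pd.DataFrame:
        return self.coef.iloc[:-1]

    @property
    def gamma(self) -> float:
        return float(self.coef["estimate"].iloc[-1])

    @property
    def gamma_se(self) -> float:
        return float(self.coef["se"].iloc[-1])

    @property
    def gamma_p(self) -> float:
        return float(self.coef["p"].iloc[-1])

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "rho": self.rho,
            "rho_se": self.rho_se,
            "rho_p": self.rho_p,
            "coef": {
                name: {
                    "estimate": float(r["estimate"]),
                    "se": float(r["se"]),
                    "p": float(r["p"]),
                }
                for name, r in self.coef.iterrows()
            },
            "coef_order": list(self.coef.index),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n": self.n,
            "n_isolates": self.n_isolates,
            "rho_interval": list(self.rho_interval),
            "converged": self.converged,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "NamFit":
        coef = pd.DataFrame(
            [d["coef"][name] for name in d["coef_order"]],
            index=d["coef_order"],
        )[["estimate", "se", "p"]]
        return cls(
            rho=d["rho"], rho_se=d["rho_se"], rho_p=d["rho_p"], coef=coef,
            sigma2=d["sigma2"], loglik=d["loglik"], n=d["n"],
            rho_interval=tuple(d["rho_interval"]), converged=d["converged"],
            n_isolates=d.get("n_isolates", 0), label=d.get("label"),
        )

    @classmethod
    def from_json(cls, path) -> "NamFit":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _num_hessian(f, x0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x0 = np.asarray(x0, dtype=float)
    p = x0.size
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_nam(
    y,
    W,
    X,
    D,
    names: Optional[Sequence[str]] = None,
    rho: Optional[float] = None,
    label: Optional[str] = None,
    xatol: float = 1e-10,
) -> NamFit:
    """Fit the model by profile maximum likelihood.

    Parameters
    ----------
    y : outcome vector (posting frequency), length n.
    W : weight matrix (``WeightMatrix`` or array), zero diagonal.
    X : n-by-h design with leading intercept column.
    D : per-user affiliated-act count (diagonal of the coaffiliation
        matrix); ``None`` drops the degree control from the design.
    names : covariate names for X's columns.
    rho : if given, rho is held fixed (no search); the remaining parameters
        keep their closed forms.  ``rho=0.0`` reduces exactly to ordinary
        least squares of y on [X, D].
    """
    Wm = _as_w(W)
    y = np.asarray(y, dtype=float).reshape(-1)
    n = y.shape[0]
    M, cnames = _design(X, D, names)
    if n <= M.shape[1] + 1:
        raise DesignError(f"n={n} too small for {M.shape[1]} coefficients")
    eigvals = w_eigenvalues(Wm)
    lo, hi = admissible_interval(Wm, eigvals)
    n_isolates = int((np.abs(Wm).sum(axis=1) == 0).sum())

    trace: list[tuple[float, float]] = []

    def neg_profile(r: float) -> float:
        _, _, ll = profile_fit(r, y, Wm, M, eigvals)
        trace.append((float(r), float(ll)))
        return -ll

    if rho is None:
        res = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded",
            options={"xatol": xatol, "maxiter": 500},
        )
        if not res.success:
            raise ConvergenceError(
                f"profile-likelihood search failed: {res.message}", trace=trace
            )
        rho_hat = float(res.x)
        converged = True
    else:
        if not (lo - _DELTA <= rho <= hi + _DELTA):
            raise SingularityError(f"fixed rho={rho} outside admissible interval")
        rho_hat = float(rho)
        converged = True

    theta, sigma2, ll = profile_fit(rho_hat, y, Wm, M, eigvals)

    # observed information at the MLE over (rho, theta..., sigma2)
    def full_ll(params: np.ndarray) -> float:
        r = params[0]
        th = params[1:-1]
        s2 = params[-1]
        if not (lo - _DELTA < r < hi + _DELTA) or s2 <= 0:
            return -np.inf
        resid = (y - r * (Wm @ y)) - M @ th
        return (-0.5 * n * np.log(2.0 * np.pi * s2)
                + log_det_term(r, eigvals)
                - 0.5 * (resid @ resid) / s2)

    x_hat = np.concatenate([[rho_hat], theta, [sigma2]])
    H = _num_hessian(full_ll, x_hat)
    try:
        cov = np.linalg.inv(-H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(x_hat.size, np.nan)

    def pval(est, se):
        if not np.isfinite(se) or se <= 0:
            return np.nan
        return float(2.0 * stats.norm.sf(abs(est) / se))

    rho_se = float(ses[0])
    coef = pd.DataFrame(
        {
            "estimate": theta,
            "se": ses[1:-1],
            "p": [pval(e, s) for e, s in zip(theta, ses[1:-1])],
        },
        index=cnames,
    )
    return NamFit(
        rho=rho_hat,
        rho_se=rho_se,
        rho_p=pval(rho_hat, rho_se),
        coef=coef,
        sigma2=sigma2,
        loglik=float(ll),
        n=n,
        rho_interval=(lo, hi),
        converged=converged,
        n_isolates=n_isolates,
        label=label,
        profile_trace=trace or None,
    )


def simulate_nam(
    W,
    X,
    D,
    rho: float,
    beta,
    gamma: float,
    sigma: float,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Draw one outcome vector from the model: y = (I - rho W)^-1 (X beta + gamma D + eps).

    Deterministic given the seed (or an explicit Generator).
    """
    Wm = _as_w(W)
    n = Wm.shape[0]
    lo, hi = admissible_interval(Wm, delta=0.0)
    if not (lo < rho < hi):
        raise SingularityError(f"rho={rho} at or beyond interval endpoints ({lo}, {hi})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    mean = np.asarray(X, float) @ np.asarray(beta, float) \
        + float(gamma) * np.asarray(D, float).reshape(-1)
    return np.linalg.solve(np.eye(n) - rho * Wm, mean + eps)
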