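"""Recursive exponentially weighted N-way PLS (REW-NPLS).

The estimator never stores observations.  Its sufficient statistics are
the exponentially weighted *raw* accumulators

    cxx_raw ← λ·cxx_raw + Xbᵀ Xb        (matricized epochs)
    cxy_raw ← λ·cxy_raw + Xbᵀ Yb

together with the running first/second moments of X and Y
(:mod:`rewnpls.normalization`).  Centered, variance-scaled covariance
matrices are derived *exactly* from these at extraction time:

    C_XX = (cxx_raw − N_eff·μx μxᵀ) / (σx σxᵀ)
    C_XY = (cxy_raw − N_eff·μx μyᵀ) / (σx σyᵀ)

so the recentring tracks the continuously updated normalization without
approximation — at λ = 1 the derived covariances equal those of the
pooled standardized data, for any batch partition.

Factor extraction runs the covariance-only kernel-PLS recursion, with the
projection direction of each factor supplied by a rank-one PARAFAC of the
(deflated) cross-covariance tensor rather than a plain singular vector —
this is what constrains each factor to be multilinear in the input modes.
All intermediate models B¹…B^Fmax are retained, which is what makes the
online factor-number selection of :mod:`rewnpls.recursive_validation`
possible at no extra cost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .normalization import DEFAULT_EPS, RunningMoments, mean_std, update_moments
from .tensor_ops import fold, matricize_obs, rank_one_parafac, vec_outer

__all__ = [
    "CovarianceState",
    "Factor",
    "ModelStack",
    "init_state",
    "update",
    "extract_factors",
    "predict",
]

logger = logging.getLogger(__name__)

#: relative degenerate-direction guard: factor f is rejected when
#: r_fᵀ C_XX r_f ≤ EPS_TT_REL · trace(C_XX)
EPS_TT_REL = 1e-12


@dataclass(frozen=True)
class CovarianceState:
    """Sufficient statistics of the streaming estimator."""

    x_shape: tuple[int, ...]
    y_shape: tuple[int, ...]
    lam: float
    x_moments: RunningMoments
    y_moments: RunningMoments
    cxx_raw: np.ndarray
    cxy_raw: np.ndarray
    n_updates: int = 0
    scale_y: bool = True
    eps: float = DEFAULT_EPS

    @property
    def i_dim(self) -> int:
        return int(np.prod(self.x_shape))

    @property
    def j_dim(self) -> int:
        return int(np.prod(self.y_shape))

    def normalization(self):
        """Current effective (μx, σx_eff, μy, σy_eff), flattened.

        Standard deviations are floored at ``eps``; when Y scaling is
        disabled the Y deviations are all ones (Y is still centered).
        """
        mu_x, sd_x = mean_std(self.x_moments)
        mu_y, sd_y = mean_std(self.y_moments)
        mu_x = mu_x.reshape(-1, order="F")
        sd_x = np.maximum(sd_x.reshape(-1, order="F"), self.eps)
        mu_y = mu_y.reshape(-1, order="F")
        if self.scale_y:
            sd_y = np.maximum(sd_y.reshape(-1, order="F"), self.eps)
        else:
            sd_y = np.ones(self.j_dim)
        return mu_x, sd_x, mu_y, sd_y

    def centered_covariances(self) -> tuple[np.ndarray, np.ndarray]:
        """Exactly recentred, scaled C_XX and C_XY at the current moments."""
        mu_x, sd_x, mu_y, sd_y = self.normalization()
        n_eff = self.x_moments.n_eff
        cxx = (self.cxx_raw - n_eff * np.outer(mu_x, mu_x)) / np.outer(sd_x, sd_x)
        cxy = (self.cxy_raw - n_eff * np.outer(mu_x, mu_y)) / np.outer(sd_x, sd_y)
        return cxx, cxy


@dataclass(frozen=True)
class Factor:
    """One extracted factor of the kernel recursion."""

    x_vectors: list[np.ndarray]  # unit-norm input-mode projectors w¹…wⁿ
    y_vectors: list[np.ndarray]  # unit-norm output-mode PARAFAC vectors
    r: np.ndarray  # weight vector (length I)
    p: np.ndarray  # X loading (length I)
    q: np.ndarray  # Y loading (length J, un-normalized)
    tt: float


@dataclass(frozen=True)
class ModelStack:
    """All intermediate models B¹…B^Fmax plus the normalization snapshot."""

    x_shape: tuple[int, ...]
    y_shape: tuple[int, ...]
    f_max: int
    factors: tuple[Factor, ...] = ()
    b_mats: tuple[np.ndarray, ...] = ()  # length f_max once fitted
    mu_x: np.ndarray | None = None
    sigma_x: np.ndarray | None = None  # eps-floored
    mu_y: np.ndarray | None = None
    sigma_y: np.ndarray | None = None  # ones when Y scaling is off
    n_updates: int = 0

    @property
    def n_valid(self) -> int:
        """Number of non-degenerate factors actually extracted."""
        return len(self.factors)

    @property
    def is_empty(self) -> bool:
        return self.n_updates == 0

    def _check_f(self, f: int) -> int:
        if self.is_empty:
            raise ValueError("model stack is empty: no update has been applied yet")
        if not 1 <= f <= self.f_max:
            raise ValueError(f"factor index {f} outside 1..{self.f_max}")
        if f > self.n_valid:
            warnings.warn(
                f"requested {f} factors but extraction truncated at "
                f"{self.n_valid}; using the last valid model",
                RuntimeWarning,
                stacklevel=3,
            )
            return max(self.n_valid, 1)
        return f

    def coef_matrix(self, f: int) -> np.ndarray:
        """B^f on the standardized scale, matricized (I × J)."""
        f = self._check_f(f)
        return self.b_mats[f - 1]

    def coef_tensor(self, f: int) -> np.ndarray:
        """B^f on the standardized scale as an (I₁…I_n, J₁…J_m) tensor."""
        return fold(self.coef_matrix(f), self.x_shape, self.y_shape)

    def denormalized(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        """(B̃^f, Y₀^f) mapping raw inputs to raw outputs, matricized.

        B̃ = B · σY/σX coordinatewise and Y₀ = μY − μX·B̃, so that
        predict(X) = X·B̃ + Y₀ on non-centered data.
        """
        b = self.coef_matrix(f)
        b_tilde = b * (self.sigma_y[None, :] / self.sigma_x[:, None])
        y0 = self.mu_y - self.mu_x @ b_tilde
        return b_tilde, y0

    def denormalized_tensor(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        b_tilde, y0 = self.denormalized(f)
        return (
            fold(b_tilde, self.x_shape, self.y_shape),
            fold(y0, (), self.y_shape),
        )


def init_state(
    x_shape,
    y_shape,
    lam: float = 1.0,
    f_max: int = 20,
    scale_y: bool = True,
    eps: float = DEFAULT_EPS,
) -> tuple[CovarianceState, ModelStack]:
    """Fresh (all-zero) covariance state and empty model stack."""
    x_shape = tuple(int(s) for s in x_shape)
    y_shape = tuple(int(s) for s in y_shape)
    if any(s < 1 for s in x_shape + y_shape):
        raise ValueError("all mode sizes must be >= 1")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"forgetting factor must lie in [0, 1], got {lam}")
    if f_max < 1:
        raise ValueError(f"f_max must be >= 1, got {f_max}")
    i_dim = int(np.prod(x_shape))
    j_dim = int(np.prod(y_shape))
    state = CovarianceState(
        x_shape=x_shape,
        y_shape=y_shape,
        lam=lam,
        x_moments=RunningMoments(shape=x_shape, lam=lam),
        y_moments=RunningMoments(shape=y_shape, lam=lam),
        cxx_raw=np.zeros((i_dim, i_dim)),
        cxy_raw=np.zeros((i_dim, j_dim)),
        scale_y=scale_y,
        eps=eps,
    )
    stack = ModelStack(x_shape=x_shape, y_shape=y_shape, f_max=f_max)
    return state, stack


def extract_factors(
    cxx: np.ndarray,
    cxy: np.ndarray,
    x_shape,
    y_shape,
    f_max: int,
    warm_start: tuple[Factor, ...] | None = None,
    als_tol: float = 1e-9,
    als_max_iter: int = 100,
    init_policy: str = "cold",
) -> tuple[tuple[Factor, ...], tuple[np.ndarray, ...]]:
    """Covariance-only kernel recursion producing all intermediate models.

    For f = 1…f_max:

    1. reshape the deflated C_XY into an (n+m)-mode tensor and take its
       rank-one PARAFAC (warm-started from the same factor's previous
       projectors when available); the vectorized outer product of the
       input-mode vectors is the projection direction w_f;
    2. orthogonalize against previous loadings:
       r_f = w_f − Σ_{j<f} (p_jᵀ w_f)·r_j;
    3. tt_f = r_fᵀ C_XX r_f — a nonpositive/negligible value marks a
       degenerate direction and truncates the stack at f−1 factors;
    4. p_f = C_XX r_f / tt_f and q_f = C_XYᵀ r_f / tt_f;
    5. deflate C_XY ← C_XY − tt_f · p_f q_fᵀ;
    6. B^f = B^{f−1} + r_f q_fᵀ.

    Returns the factor records and all f_max coefficient matrices; after a
    truncation the later B^f alias the last valid model.

    ``init_policy`` governs how each factor's ALS is initialized.  The
    rank-one objective is non-convex, so the initialization selects among
    stationary points:

    - ``"cold"`` (default): deterministic start from the leading singular
      vectors of the single-mode unfoldings.  The extracted models are a
      function of the covariances alone, so any batch partition of the
      same data yields the same models.
    - ``"warm"``: continue from ``warm_start`` projectors when available —
      the fastest, path-dependent tracking mode.
    - ``"best"``: run both and keep the stationary point with the higher
      objective (cold preferred on ties).
    """
    if init_policy not in ("cold", "warm", "best"):
        raise ValueError(f"unknown init_policy {init_policy!r}")
    x_shape = tuple(x_shape)
    y_shape = tuple(y_shape)
    i_dim = int(np.prod(x_shape))
    j_dim = int(np.prod(y_shape))
    n_x = len(x_shape)
    eps_tt = EPS_TT_REL * max(np.trace(cxx), np.finfo(float).tiny)

    deflated = cxy.copy()
    factors: list[Factor] = []
    b = np.zeros((i_dim, j_dim))
    b_mats: list[np.ndarray] = []

    for f in range(f_max):
        if not np.any(deflated):
            logger.info("C_XY exhausted after %d factors; truncating", f)
            break
        c_tensor = fold(deflated, x_shape, y_shape)
        init = None
        if (
            init_policy != "cold"
            and warm_start is not None
            and f < len(warm_start)
        ):
            init = list(warm_start[f].x_vectors) + list(warm_start[f].y_vectors)
        if init is None:
            comp = rank_one_parafac(c_tensor, n_x, tol=als_tol, max_iter=als_max_iter)
        elif init_policy == "warm":
            comp = rank_one_parafac(
                c_tensor, n_x, init=init, tol=als_tol, max_iter=als_max_iter
            )
        else:  # best of both stationary points, cold preferred on ties
            comp = rank_one_parafac(c_tensor, n_x, tol=als_tol, max_iter=als_max_iter)
            warm = rank_one_parafac(
                c_tensor, n_x, init=init, tol=als_tol, max_iter=als_max_iter
            )
            if warm.scale > comp.scale * (1.0 + 1e-9):
                comp = warm
        if comp.degenerate:
            logger.info("degenerate PARAFAC at factor %d; truncating", f + 1)
            break
        w = vec_outer(comp.x_vectors)
        r = w.copy()
        for prev in factors:
            r -= (prev.p @ w) * prev.r
        tt = float(r @ cxx @ r)
        if tt <= eps_tt:
            logger.info(
                "degenerate direction at factor %d (tt=%.3e <= %.3e); truncating",
                f + 1,
                tt,
                eps_tt,
            )
            break
        p = cxx @ r / tt
        q = deflated.T @ r / tt
        deflated = deflated - tt * np.outer(p, q)
        b = b + np.outer(r, q)
        factors.append(
            Factor(
                x_vectors=[v.copy() for v in comp.x_vectors],
                y_vectors=[v.copy() for v in comp.y_vectors],
                r=r,
                p=p,
                q=q,
                tt=tt,
            )
        )
        b_mats.append(b.copy())

    if not b_mats:  # fully degenerate: the zero model at every f
        b_mats = [b.copy()]
    while len(b_mats) < f_max:  # alias truncated models to the last valid one
        b_mats.append(b_mats[-1])
    return tuple(factors), tuple(b_mats)


def update(
    state: CovarianceState,
    stack: ModelStack,
    xb: np.ndarray,
    yb: np.ndarray,
    als_tol: float = 1e-9,
    als_max_iter: int = 100,
    init_policy: str = "cold",
) -> tuple[CovarianceState, ModelStack]:
    """Fold one batch into the estimator and refit all intermediate models.

    Moments are updated first; the raw cross-product accumulators absorb
    the batch; the centered covariances are derived and the factor
    extraction is rerun.  With the default ``init_policy="cold"`` the new
    models depend on the accumulated covariances only; ``"warm"``/"best"``
    reuse the previous stack's projectors as ALS starts (see
    :func:`extract_factors`).  The inputs are unmodified (new state and
    stack are returned).
    """
    xb = np.asarray(xb, dtype=float)
    yb = np.asarray(yb, dtype=float)
    if xb.ndim == 1:
        xb = xb[:, None]
    if yb.ndim == 1:
        yb = yb[:, None]
    if xb.shape[0] != yb.shape[0]:
        raise ValueError("X and Y batches disagree on the observation count")
    if tuple(xb.shape[1:]) != state.x_shape or tuple(yb.shape[1:]) != state.y_shape:
        raise ValueError(
            f"batch shapes {xb.shape[1:]}/{yb.shape[1:]} do not match state "
            f"{state.x_shape}/{state.y_shape}"
        )
    if xb.shape[0] == 0:
        logger.info("empty batch: decaying accumulators by lambda=%g", state.lam)
        new_state = replace(
            state,
            x_moments=update_moments(state.x_moments, xb),
            y_moments=update_moments(state.y_moments, yb),
            cxx_raw=state.lam * state.cxx_raw,
            cxy_raw=state.lam * state.cxy_raw,
            n_updates=state.n_updates + 1,
        )
        return new_state, replace(stack, n_updates=stack.n_updates + 1)
    if not (np.all(np.isfinite(xb)) and np.all(np.isfinite(yb))):
        raise ValueError("batch contains non-finite values")

    x_moments = update_moments(state.x_moments, xb)
    y_moments = update_moments(state.y_moments, yb)
    xm = matricize_obs(xb)
    ym = matricize_obs(yb)
    new_state = replace(
        state,
        x_moments=x_moments,
        y_moments=y_moments,
        cxx_raw=state.lam * state.cxx_raw + xm.T @ xm,
        cxy_raw=state.lam * state.cxy_raw + xm.T @ ym,
        n_updates=state.n_updates + 1,
    )

    cxx, cxy = new_state.centered_covariances()
    warm = stack.factors if stack.factors else None
    factors, b_mats = extract_factors(
        cxx,
        cxy,
        state.x_shape,
        state.y_shape,
        stack.f_max,
        warm_start=warm,
        als_tol=als_tol,
        als_max_iter=als_max_iter,
        init_policy=init_policy,
    )
    mu_x, sd_x, mu_y, sd_y = new_state.normalization()
    new_stack = ModelStack(
        x_shape=state.x_shape,
        y_shape=state.y_shape,
        f_max=stack.f_max,
        factors=factors,
        b_mats=b_mats,
        mu_x=mu_x,
        sigma_x=sd_x,
        mu_y=mu_y,
        sigma_y=sd_y,
        n_updates=new_state.n_updates,
    )
    return new_state, new_stack


def _predict_mat(stack: ModelStack, x_mat: np.ndarray, f: int) -> np.ndarray:
    b_tilde, y0 = stack.denormalized(f)
    return x_mat @ b_tilde + y0


def predict(stack: ModelStack, x_raw: np.ndarray, f: int) -> np.ndarray:
    """Apply the f-factor model to non-centered data.

    Computes ``X·B̃^f + Y₀^f`` — algebraically identical to standardizing
    X, contracting with B^f and de-standardizing the result.  Returns a
    tensor of shape ``N × J₁ × … × J_m``.
    """
    x_raw = np.asarray(x_raw, dtype=float)
    if x_raw.ndim == 1:
        x_raw = x_raw[:, None]
    if tuple(x_raw.shape[1:]) != stack.x_shape:
        raise ValueError(
            f"input coordinate shape {x_raw.shape[1:]} != model {stack.x_shape}"
        )
    if not np.all(np.isfinite(x_raw)):
        raise ValueError("prediction input contains non-finite values")
    y_mat = _predict_mat(stack, matricize_obs(x_raw), f)
    n = x_raw.shape[0]
    return np.moveaxis(
        y_mat.T.reshape(stack.y_shape + (n,), order="F"), -1, 0
    )
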