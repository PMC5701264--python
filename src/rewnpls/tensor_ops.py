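"""Multilinear primitives shared by all estimator modules.

Tensors are plain :class:`numpy.ndarray` objects.  Every routine in this
package that flattens a group of tensor modes into a single axis uses one
fixed vectorization convention: **the first listed mode varies fastest**
(column-major within the group).  Under this convention
``vec(a ∘ b) = kron(b, a)``, and the matricized covariance recursion in
:mod:`rewnpls.rew_npls` agrees elementwise with the multilinear contraction
it implements.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

__all__ = [
    "RankOneFactor",
    "contract_obs",
    "unfold",
    "fold",
    "vec_outer",
    "matricize_obs",
    "rank_one_parafac",
]


@dataclass
class RankOneFactor:
    """A rank-one (n+m)-way component ``scale · w¹∘…∘wⁿ∘q¹∘…∘q^m``.

    ``x_vectors`` are unit-norm mode vectors over the input modes and carry
    the sign convention (first nonzero entry nonnegative); ``y_vectors``
    are unit-norm output-mode vectors, the first of which absorbs the sign
    needed to keep ``scale`` nonnegative.  ``degenerate`` marks an all-zero
    input tensor, for which canonical basis vectors are returned.
    """

    x_vectors: list[np.ndarray]
    y_vectors: list[np.ndarray]
    scale: float
    degenerate: bool = False
    n_iterations: int = 0

    @property
    def vectors(self) -> list[np.ndarray]:
        return list(self.x_vectors) + list(self.y_vectors)

    def reconstruct(self) -> np.ndarray:
        """Materialize the rank-one tensor this factor represents."""
        out = reduce(np.multiply.outer, self.vectors)
        return self.scale * out


def contract_obs(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Contract two observation tensors over their shared first mode.

    ``result[i..., j...] = Σ_l X[l, i...] · Y[l, j...]`` — the mode-1
    tensor product producing the cross-covariance tensor C_XY (and C_XX
    when called with ``Y = X``).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"observation modes differ: X has {X.shape[0]}, Y has {Y.shape[0]}"
        )
    return np.tensordot(X, Y, axes=(0, 0))


def _check_partition(ndim: int, row_modes, col_modes) -> None:
    seen = list(row_modes) + list(col_modes)
    if sorted(seen) != list(range(ndim)):
        raise IndexError(
            f"row_modes {list(row_modes)} + col_modes {list(col_modes)} "
            f"must partition modes 0..{ndim - 1}"
        )


def unfold(C: np.ndarray, row_modes, col_modes) -> np.ndarray:
    """Matricize ``C`` with the fixed first-listed-mode-fastest convention.

    Within each index group the first listed mode varies fastest, so the
    unfolding is the Fortran-order reshape of the permuted tensor.
    """
    C = np.asarray(C)
    row_modes = list(row_modes)
    col_modes = list(col_modes)
    _check_partition(C.ndim, row_modes, col_modes)
    nrow = int(np.prod([C.shape[k] for k in row_modes], initial=1))
    ncol = int(np.prod([C.shape[k] for k in col_modes], initial=1))
    return np.transpose(C, row_modes + col_modes).reshape((nrow, ncol), order="F")


def fold(M: np.ndarray, row_shapes, col_shapes) -> np.ndarray:
    """Inverse of :func:`unfold` for modes listed in natural order.

    Reassembles a tensor of shape ``row_shapes + col_shapes`` from its
    ``unfold(C, range(nr), range(nr, nr+nc))`` matricization.
    """
    shape = tuple(row_shapes) + tuple(col_shapes)
    return np.asarray(M).reshape(shape, order="F")


def vec_outer(vectors) -> np.ndarray:
    """Vectorize an outer product of vectors under the fixed convention.

    ``vec(v¹∘…∘vᵏ)`` with the first vector's index varying fastest, i.e.
    ``kron(vᵏ, …, kron(v², v¹))``.
    """
    return reduce(lambda acc, v: np.kron(v, acc), vectors)


def matricize_obs(X: np.ndarray) -> np.ndarray:
    """Flatten the coordinate modes of an observation tensor to one axis.

    Maps ``N × I₁ × … × I_n`` to ``N × (I₁·…·I_n)`` so that row ``l``
    equals ``vec(X[l])`` under the package vectorization convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X[:, None]
    n = X.shape[0]
    coord = list(range(1, X.ndim))
    return unfold(X, coord, [0]).T.reshape(n, -1)


def _svd_init(C: np.ndarray) -> list[np.ndarray]:
    # leading left singular vector of each single-mode unfolding, via the
    # small mode-sized Gram matrix
    vs = []
    for k in range(C.ndim):
        A = np.moveaxis(C, k, 0).reshape(C.shape[k], -1)
        G = A @ A.T
        w, V = np.linalg.eigh(G)
        vs.append(V[:, -1].copy())
    return vs


def _contract_all_but(C: np.ndarray, vectors, k: int) -> np.ndarray:
    cur = C
    for j in sorted((i for i in range(C.ndim) if i != k), reverse=True):
        cur = np.tensordot(cur, vectors[j], axes=([j], [0]))
    return cur


def _sign_fix(v: np.ndarray) -> int:
    nz = np.nonzero(np.abs(v) > 1e-12 * max(np.max(np.abs(v)), 1e-300))[0]
    if nz.size and v[nz[0]] < 0:
        return -1
    return 1


def rank_one_parafac(
    C: np.ndarray,
    n_x_modes: int,
    init: RankOneFactor | list[np.ndarray] | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> RankOneFactor:
    """Best rank-one multilinear approximation of ``C`` by ALS.

    Alternates over modes, each step replacing one mode vector by the
    contraction of ``C`` with all other (unit-norm) mode vectors; the
    objective ``⟨C, w¹∘…∘q^m⟩`` is non-decreasing across sweeps.  For an
    order-2 tensor this is the power iteration for the dominant singular
    pair.  Stops when the relative objective change falls below ``tol``
    or after ``max_iter`` sweeps.

    ``init`` warm-starts the iteration (previous projectors of the same
    factor during streaming); the cold start uses the leading singular
    vector of each single-mode unfolding.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("rank_one_parafac requires finite input")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= n_x_modes <= C.ndim:
        raise ValueError("n_x_modes out of range")

    if not np.any(C):
        vs = [np.eye(s)[:, 0] for s in C.shape]
        return RankOneFactor(vs[:n_x_modes], vs[n_x_modes:], 0.0, degenerate=True)

    if init is None:
        vs = _svd_init(C)
    else:
        vecs = init.vectors if isinstance(init, RankOneFactor) else list(init)
        vs = []
        for k, v in enumerate(vecs):
            v = np.asarray(v, dtype=float)
            nrm = np.linalg.norm(v)
            vs.append(v / nrm if nrm > 0 else np.eye(C.shape[k])[:, 0])

    obj = 0.0
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for k in range(C.ndim):
            v = _contract_all_but(C, vs, k)
            nrm = np.linalg.norm(v)
            if nrm == 0.0:
                # collapsed onto a null direction; keep previous vector
                continue
            vs[k] = v / nrm
        new_obj = float(np.dot(_contract_all_but(C, vs, C.ndim - 1), vs[-1]))
        if abs(new_obj - obj) <= tol * max(abs(new_obj), np.finfo(float).tiny):
            obj = new_obj
            break
        obj = new_obj

    scale = obj
    x_vecs = [v.copy() for v in vs[:n_x_modes]]
    y_vecs = [v.copy() for v in vs[n_x_modes:]]
    # sign convention on input-mode vectors; residual sign absorbed by the
    # first output-mode vector (or the scale when there is none)
    sign = 1
    for i, v in enumerate(x_vecs):
        s = _sign_fix(v)
        x_vecs[i] = s * v
        sign *= s
    for i in range(1, len(y_vecs)):
        s = _sign_fix(y_vecs[i])
        y_vecs[i] = s * y_vecs[i]
        sign *= s
    scale *= sign
    if scale < 0:
        if y_vecs:
            y_vecs[0] = -y_vecs[0]
            scale = -scale
        else:
            scale = -scale
            x_vecs[-1] = -x_vecs[-1]
    return RankOneFactor(x_vecs, y_vecs, float(scale), n_iterations=n_it)
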