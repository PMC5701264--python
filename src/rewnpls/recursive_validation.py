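"""Online selection of the factor-number hyper-parameter.

Each incoming batch is used as a held-out test set for *all* intermediate
models B¹…B^Fmax from before the batch is folded into the estimator.
Per-factor prediction errors are accumulated with a forgetting factor γ,

    e^f ← γ·e^f + ERROR(Ŷ^f, Y),

and the current optimum is F* = argmin_f e^f (smallest index on ties —
parsimony).  The apply-before-update ordering is enforced through the
update counter that :mod:`rewnpls.rew_npls` stamps on every model stack.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rew_npls import ModelStack
from .tensor_ops import matricize_obs

__all__ = ["RVState", "ModelHandle", "OrderingError", "rv_update", "select_model", "batch_error"]

ERROR_KINDS = ("mse", "nmse")


class OrderingError(RuntimeError):
    """The apply/update ordering contract of the streaming loop was violated."""


@dataclass(frozen=True)
class RVState:
    """Exponentially weighted per-factor prediction errors and current F*."""

    f_max: int
    gamma: float = 1.0
    error_kind: str = "mse"
    errors: np.ndarray | None = None
    batches_seen: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"forgetting factor must lie in [0, 1], got {self.gamma}")
        if self.error_kind not in ERROR_KINDS:
            raise ValueError(f"error_kind must be one of {ERROR_KINDS}")
        if self.errors is None:
            object.__setattr__(self, "errors", np.zeros(self.f_max))
        elif len(self.errors) != self.f_max:
            raise ValueError("errors vector length must equal f_max")

    @property
    def f_star(self) -> int:
        """argmin of the accumulated errors, smallest index on ties."""
        return int(np.argmin(self.errors)) + 1


@dataclass(frozen=True)
class ModelHandle:
    """Reference to the selected model inside a stack (no copies)."""

    f: int
    stack: ModelStack
    cold_start: bool = False

    @property
    def coef_tensor(self) -> np.ndarray:
        return self.stack.coef_tensor(self.f)

    @property
    def denormalized(self) -> tuple[np.ndarray, np.ndarray]:
        return self.stack.denormalized_tensor(self.f)


def batch_error(
    predicted: np.ndarray,
    observed: np.ndarray,
    kind: str = "mse",
    sigma_y: np.ndarray | None = None,
) -> float:
    """Squared prediction error averaged over epochs and output coordinates.

    ``nmse`` divides each output coordinate's squared error by its running
    variance (from the model's normalization snapshot), making the error —
    and therefore the selected F* — invariant to the scale of Y.
    """
    pred = matricize_obs(np.asarray(predicted, dtype=float))
    obs = matricize_obs(np.asarray(observed, dtype=float))
    sq = np.square(pred - obs)
    if kind == "nmse":
        if sigma_y is None:
            raise ValueError("nmse requires the running sigma_y")
        sq = sq / np.square(sigma_y)[None, :]
    elif kind != "mse":
        raise ValueError(f"error kind must be one of {ERROR_KINDS}")
    return float(sq.mean())


def rv_update(
    rv: RVState, stack: ModelStack, xb: np.ndarray, yb: np.ndarray
) -> RVState:
    """Score all intermediate models on a new batch, before the update.

    ``stack`` must be the model fitted on the data seen *before* this
    batch; the handshake with the estimator's update counter rejects a
    stack that has already absorbed it.
    """
    if stack.is_empty:
        raise OrderingError(
            "no model to validate yet: apply at least one covariance update "
            "before the first rv_update (recursive validation starts at the "
            "second batch)"
        )
    if stack.n_updates != rv.batches_seen + 1:
        raise OrderingError(
            f"ordering violation: stack has absorbed {stack.n_updates} batches "
            f"but recursive validation has scored {rv.batches_seen}; rv_update "
            "must run on each batch before rew_npls.update"
        )
    xb = np.asarray(xb, dtype=float)
    yb = np.asarray(yb, dtype=float)
    if xb.shape[0] == 0:
        raise ValueError("rv_update requires a nonempty batch")

    x_mat = matricize_obs(xb if xb.ndim > 1 else xb[:, None])
    y_mat = matricize_obs(yb if yb.ndim > 1 else yb[:, None])
    errs = np.empty(rv.f_max)
    sigma_x = stack.sigma_x
    sigma_y = stack.sigma_y
    # models beyond a truncation alias the last valid one and share its error
    n_eval = max(1, min(stack.n_valid, rv.f_max))
    for f in range(1, n_eval + 1):
        b_tilde = stack.b_mats[f - 1] * (sigma_y[None, :] / sigma_x[:, None])
        pred = x_mat @ b_tilde + (stack.mu_y - stack.mu_x @ b_tilde)
        sq = np.square(pred - y_mat)
        if rv.error_kind == "nmse":
            sq = sq / np.square(sigma_y)[None, :]
        errs[f - 1] = sq.mean()
    errs[n_eval:] = errs[n_eval - 1]
    return replace(
        rv,
        errors=rv.gamma * rv.errors + errs,
        batches_seen=rv.batches_seen + 1,
    )


def select_model(rv: RVState, stack: ModelStack) -> ModelHandle:
    """Hand back the model with the currently optimal factor number.

    Before the first scored batch there is no error evidence; the
    single-factor model is returned with ``cold_start=True``.
    """
    if stack.is_empty:
        raise ValueError("model stack is empty: nothing to select from")
    if rv.batches_seen == 0:
        return ModelHandle(f=1, stack=stack, cold_start=True)
    return ModelHandle(f=rv.f_star, stack=stack)
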