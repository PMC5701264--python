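import numpy as np
import pytest

import rewnpls as rw


def run_stream(
    spec: rw.StreamSpec,
    lam: float = 1.0,
    gamma: float = 1.0,
    f_max: int = 10,
    error_kind: str = "mse",
    als_tol: float = 1e-9,
    als_max_iter: int = 100,
    record=None,
):
    """Drive the full streaming protocol (validate, then update) on a spec.

    ``record(batch, rv, stack_pre_update)`` is called per batch after the
    validation step.  Returns (truth, state, stack, rv).
    """
    truth = rw.make_truth(spec)
    state, stack = rw.init_state(spec.x_shape, spec.y_shape, lam=lam, f_max=f_max)
    rv = rw.RVState(f_max=f_max, gamma=gamma, error_kind=error_kind)
    for batch in rw.gen_batches(spec, truth):
        if not stack.is_empty:
            rv = rw.rv_update(rv, stack, batch.x, batch.y)
        if record is not None:
            record(batch, rv, stack)
        state, stack = rw.update(
            state, stack, batch.x, batch.y, als_tol=als_tol, als_max_iter=als_max_iter
        )
    return truth, state, stack, rv


def nipals_pls2(x_std: np.ndarray, y_std: np.ndarray, n_factors: int,
                tol: float = 1e-14, max_iter: int = 20000):
    """Textbook NIPALS PLS2 oracle on standardized data matrices.

    Iterates scores to convergence and deflates both X and Y by the score
    t — an independent, data-matrix route to the same coefficients the
    covariance-kernel recursion produces.  Returns [B¹ … B^F] on the
    standardized scale.
    """
    x = x_std.copy()
    y = y_std.copy()
    ws, ps, qs, bs = [], [], [], []
    for _ in range(n_factors):
        u = y[:, int(np.argmax((y**2).sum(axis=0)))]
        for _ in range(max_iter):
            w = x.T @ u
            w /= np.linalg.norm(w)
            t = x @ w
            q = y.T @ t / (t @ t)
            u_new = y @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= tol * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        t = x @ w
        p = x.T @ t / (t @ t)
        c = y.T @ t / (t @ t)
        x = x - np.outer(t, p)
        y = y - np.outer(t, c)
        ws.append(w)
        ps.append(p)
        qs.append(c)
        wm, pm, qm = map(np.column_stack, (ws, ps, qs))
        bs.append(wm @ np.linalg.solve(pm.T @ wm, qm.T))
    return bs


def standardized(a: np.ndarray) -> np.ndarray:
    m = rw.matricize_obs(a)
    return (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
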