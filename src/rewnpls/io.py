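"""HDF5 persistence for batches, models and raw signals, plus TSV traces.

One container format binds the modules: a *batches* file holds the paired
observation tensors (and, for synthetic streams, the planted truth), a
*model* file holds everything needed to resume or apply an estimator —
raw accumulators, moments, projectors, all intermediate coefficient
matrices and provenance attributes — and a *signals* file holds raw
multichannel time series with their sampling rate.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .normalization import RunningMoments
from .recursive_validation import RVState
from .rew_npls import CovarianceState, Factor, ModelStack
from .synthetic import GroundTruth, ObservationBatch

__all__ = [
    "save_batches",
    "load_batches",
    "load_truth_b",
    "save_model",
    "load_model",
    "save_signals",
    "load_signals",
    "write_rv_trace",
]


def save_batches(
    path,
    batches,
    x_shape,
    y_shape,
    truth: GroundTruth | None = None,
    test_batch: ObservationBatch | None = None,
) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "rewnpls-batches"
        h5.attrs["version"] = __version__
        h5.attrs["x_shape"] = np.asarray(x_shape, dtype=np.int64)
        h5.attrs["y_shape"] = np.asarray(y_shape, dtype=np.int64)
        n = 0
        for batch in batches:
            g = h5.create_group(f"batch_{batch.index:05d}")
            g.create_dataset("X", data=batch.x)
            g.create_dataset("Y", data=batch.y)
            n += 1
        h5.attrs["n_batches"] = n
        if truth is not None:
            tg = h5.create_group("truth")
            tg.create_dataset("B_mat", data=truth.b_mat(0))
            if truth.spec.drift is not None:
                tg.create_dataset("B_mat_final", data=truth.b_mat(truth.spec.n_batches - 1))
        if test_batch is not None:
            tg = h5.create_group("test")
            tg.create_dataset("X", data=test_batch.x)
            tg.create_dataset("Y", data=test_batch.y)


def load_batches(path):
    """Yield (x_shape, y_shape) then each ObservationBatch, in index order."""
    with h5py.File(path, "r") as h5:
        x_shape = tuple(int(s) for s in h5.attrs["x_shape"])
        y_shape = tuple(int(s) for s in h5.attrs["y_shape"])
        names = sorted(k for k in h5 if k.startswith("batch_"))
        batches = [
            ObservationBatch(
                index=int(name.split("_")[1]),
                x=h5[name]["X"][()],
                y=h5[name]["Y"][()],
            )
            for name in names
        ]
        test = None
        if "test" in h5:
            test = ObservationBatch(index=-1, x=h5["test/X"][()], y=h5["test/Y"][()])
    return x_shape, y_shape, batches, test


def load_truth_b(path) -> np.ndarray | None:
    with h5py.File(path, "r") as h5:
        if "truth" in h5:
            key = "B_mat_final" if "B_mat_final" in h5["truth"] else "B_mat"
            return h5["truth"][key][()]
    return None


def _save_moments(group, moments: RunningMoments) -> None:
    group.attrs["n_eff"] = moments.n_eff
    group.attrs["lam"] = moments.lam
    group.attrs["shape"] = np.asarray(moments.shape, dtype=np.int64)
    group.create_dataset("sum", data=moments.sum)
    group.create_dataset("sum_sq", data=moments.sum_sq)


def _load_moments(group) -> RunningMoments:
    return RunningMoments(
        shape=tuple(int(s) for s in group.attrs["shape"]),
        lam=float(group.attrs["lam"]),
        n_eff=float(group.attrs["n_eff"]),
        sum=group["sum"][()],
        sum_sq=group["sum_sq"][()],
    )


def save_model(
    path,
    state: CovarianceState,
    stack: ModelStack,
    rv: RVState | None = None,
) -> None:
    """Serialize the full estimator (resumable) to a single HDF5 file."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "rewnpls-model"
        h5.attrs["version"] = __version__
        h5.attrs["lam"] = state.lam
        h5.attrs["f_max"] = stack.f_max
        h5.attrs["x_shape"] = np.asarray(state.x_shape, dtype=np.int64)
        h5.attrs["y_shape"] = np.asarray(state.y_shape, dtype=np.int64)
        h5.attrs["n_updates"] = state.n_updates
        h5.attrs["scale_y"] = state.scale_y
        h5.attrs["eps"] = state.eps

        sg = h5.create_group("state")
        sg.create_dataset("cxx_raw", data=state.cxx_raw)
        sg.create_dataset("cxy_raw", data=state.cxy_raw)
        _save_moments(sg.create_group("x_moments"), state.x_moments)
        _save_moments(sg.create_group("y_moments"), state.y_moments)

        mg = h5.create_group("stack")
        mg.attrs["n_updates"] = stack.n_updates
        mg.attrs["n_valid"] = stack.n_valid
        if not stack.is_empty:
            mg.create_dataset("b_mats", data=np.stack(stack.b_mats))
            mg.create_dataset("mu_x", data=stack.mu_x)
            mg.create_dataset("sigma_x", data=stack.sigma_x)
            mg.create_dataset("mu_y", data=stack.mu_y)
            mg.create_dataset("sigma_y", data=stack.sigma_y)
            for i, fac in enumerate(stack.factors):
                fg = mg.create_group(f"factor_{i:04d}")
                fg.create_dataset("r", data=fac.r)
                fg.create_dataset("p", data=fac.p)
                fg.create_dataset("q", data=fac.q)
                fg.attrs["tt"] = fac.tt
                for k, v in enumerate(fac.x_vectors):
                    fg.create_dataset(f"w_{k}", data=v)
                for k, v in enumerate(fac.y_vectors):
                    fg.create_dataset(f"qv_{k}", data=v)

        if rv is not None:
            rg = h5.create_group("rv")
            rg.attrs["gamma"] = rv.gamma
            rg.attrs["error_kind"] = rv.error_kind
            rg.attrs["batches_seen"] = rv.batches_seen
            rg.create_dataset("errors", data=rv.errors)


def load_model(path):
    """Inverse of :func:`save_model`; returns (state, stack, rv or None)."""
    with h5py.File(path, "r") as h5:
        x_shape = tuple(int(s) for s in h5.attrs["x_shape"])
        y_shape = tuple(int(s) for s in h5.attrs["y_shape"])
        f_max = int(h5.attrs["f_max"])
        sg = h5["state"]
        state = CovarianceState(
            x_shape=x_shape,
            y_shape=y_shape,
            lam=float(h5.attrs["lam"]),
            x_moments=_load_moments(sg["x_moments"]),
            y_moments=_load_moments(sg["y_moments"]),
            cxx_raw=sg["cxx_raw"][()],
            cxy_raw=sg["cxy_raw"][()],
            n_updates=int(h5.attrs["n_updates"]),
            scale_y=bool(h5.attrs["scale_y"]),
            eps=float(h5.attrs["eps"]),
        )
        mg = h5["stack"]
        if int(mg.attrs["n_updates"]) == 0:
            stack = ModelStack(x_shape=x_shape, y_shape=y_shape, f_max=f_max)
        else:
            factors = []
            for i in range(int(mg.attrs["n_valid"])):
                fg = mg[f"factor_{i:04d}"]
                xs = [fg[f"w_{k}"][()] for k in range(len(x_shape))]
                ys = [fg[f"qv_{k}"][()] for k in range(len(y_shape))]
                factors.append(
                    Factor(
                        x_vectors=xs,
                        y_vectors=ys,
                        r=fg["r"][()],
                        p=fg["p"][()],
                        q=fg["q"][()],
                        tt=float(fg.attrs["tt"]),
                    )
                )
            stack = ModelStack(
                x_shape=x_shape,
                y_shape=y_shape,
                f_max=f_max,
                factors=tuple(factors),
                b_mats=tuple(mg["b_mats"][()]),
                mu_x=mg["mu_x"][()],
                sigma_x=mg["sigma_x"][()],
                mu_y=mg["mu_y"][()],
                sigma_y=mg["sigma_y"][()],
                n_updates=int(mg.attrs["n_updates"]),
            )
        rv = None
        if "rv" in h5:
            rg = h5["rv"]
            rv = RVState(
                f_max=f_max,
                gamma=float(rg.attrs["gamma"]),
                error_kind=str(rg.attrs["error_kind"]),
                errors=rg["errors"][()],
                batches_seen=int(rg.attrs["batches_seen"]),
            )
    return state, stack, rv


def save_signals(path, signals: np.ndarray, fs: float) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "rewnpls-signals"
        ds = h5.create_dataset("signals", data=np.atleast_2d(signals))
        ds.attrs["fs"] = fs


def load_signals(path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as h5:
        ds = h5["signals"]
        return ds[()], float(ds.attrs["fs"])


def write_rv_trace(path, rows, f_max: int) -> None:
    """Append-style TSV log: batch index, e¹…e^Fmax, current F*."""
    path = Path(path)
    header = "batch\t" + "\t".join(f"e{f}" for f in range(1, f_max + 1)) + "\tf_star\n"
    with open(path, "w") as fh:
        fh.write(header)
        for batch_idx, errors, f_star in rows:
            err_s = "\t".join(format(e, ".10g") for e in errors)
            fh.write(f"{batch_idx}\t{err_s}\t{f_star}\n")
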