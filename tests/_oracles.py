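"""Independent oracles used by the test suite.

Each oracle is implemented from first principles, without reusing the code
paths it checks: total variation by explicit difference loops, the gamma
index by exhaustive search over a globally upsampled reference, and the
LASSO-TV objective by a general-purpose bound-constrained quasi-Newton solve
of an equivalent smoothed problem.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize


def tv_brute_force(x: np.ndarray, flavor: str) -> float:
    """Total variation by explicit per-voxel difference loops."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for idx in np.ndindex(x.shape):
        diffs = []
        for axis in range(x.ndim):
            nxt = list(idx)
            nxt[axis] += 1
            if nxt[axis] < x.shape[axis]:
                diffs.append(x[tuple(nxt)] - x[idx])
            else:
                diffs.append(0.0)
        if flavor == "isotropic":
            total += np.sqrt(sum(d * d for d in diffs))
        else:
            total += sum(abs(d) for d in diffs)
    return total


def gamma_brute_force(
    ev: np.ndarray,
    rf: np.ndarray,
    spacing,
    dta: float,
    dd_frac: float,
    threshold_frac: float,
    search_radius_factor: float = 3.0,
    subdiv: int = 10,
) -> np.ndarray:
    """Exhaustive gamma search over a globally upsampled reference lattice.

    Both distributions share the same grid (spacing per axis, origin 0).
    Returns per-point gamma values with NaN below the low-dose threshold.
    Intended for small arrays only.
    """
    ev = np.asarray(ev, dtype=float)
    rf = np.asarray(rf, dtype=float)
    nd = ev.ndim
    spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, nd)
    axes = [np.arange(n) * s for n, s in zip(rf.shape, spacing)]
    interp = RegularGridInterpolator(axes, rf, method="linear")

    # global fine lattice: subdivide each reference voxel interval so the
    # step never exceeds dta/subdiv (original grid points stay in the set)
    fine_axes = []
    for ax, sp in zip(axes, spacing):
        if ax.size > 1:
            k = int(np.ceil(sp * subdiv / dta))
            step = sp / k
            fine_axes.append(np.arange((ax.size - 1) * k + 1) * step)
        else:
            fine_axes.append(ax)
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    fine_pts = np.stack([m.ravel() for m in mesh], axis=1)
    # the search set must contain the zero-displacement candidate, so add the
    # evaluation lattice itself
    coarse_axes = [np.arange(n) * s for n, s in zip(rf.shape, spacing)]
    cmesh = np.meshgrid(*coarse_axes, indexing="ij")
    coarse_pts = np.stack([m.ravel() for m in cmesh], axis=1)
    fine_pts = np.concatenate([fine_pts, coarse_pts], axis=0)
    fine_vals = interp(fine_pts)

    ref_max = rf.max()
    denom = dd_frac * ref_max
    radius = search_radius_factor * dta

    eval_axes = [np.arange(n) * s for n, s in zip(ev.shape, spacing)]
    eval_mesh = np.meshgrid(*eval_axes, indexing="ij")
    eval_pts = np.stack([m.ravel() for m in eval_mesh], axis=1)
    gamma = np.full(ev.size, np.nan)
    ev_flat = ev.ravel()
    ref_at_eval = interp(eval_pts)
    for i, (pt, de) in enumerate(zip(eval_pts, ev_flat)):
        if ref_at_eval[i] < threshold_frac * ref_max:
            continue
        d2 = ((fine_pts - pt) ** 2).sum(axis=1)
        near = d2 <= radius**2
        g2 = d2[near] / dta**2 + ((de - fine_vals[near]) / denom) ** 2
        gamma[i] = np.sqrt(g2.min())
    return gamma.reshape(ev.shape)


def _smoothed_tv_value_grad(x3: np.ndarray, flavor: str, eps: float):
    shape = x3.shape
    gs = []
    for axis in range(x3.ndim):
        g = np.zeros(shape)
        sl_lo = [slice(None)] * x3.ndim
        sl_hi = [slice(None)] * x3.ndim
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        g[tuple(sl_lo)] = x3[tuple(sl_hi)] - x3[tuple(sl_lo)]
        gs.append(g)

    def adjoint(ps):
        out = np.zeros(shape)
        for axis, pa in enumerate(ps):
            sl_cur = [slice(None)] * x3.ndim
            sl_prev = [slice(None)] * x3.ndim
            sl_cur[axis] = slice(1, None)
            sl_prev[axis] = slice(None, -1)
            out -= pa
            out[tuple(sl_cur)] += pa[tuple(sl_prev)]
        return out

    if flavor == "isotropic":
        nrm = np.sqrt(sum(g**2 for g in gs) + eps**2)
        value = nrm.sum() - eps * x3.size
        grad = adjoint([g / nrm for g in gs])
    else:
        nrms = [np.sqrt(g**2 + eps**2) for g in gs]
        value = sum(n.sum() for n in nrms) - x3.ndim * eps * x3.size
        grad = adjoint([g / n for g, n in zip(gs, nrms)])
    return value, grad


def lasso_tv_convex_oracle(
    A: np.ndarray,
    p: np.ndarray,
    alpha: float,
    beta: float,
    shape,
    flavor: str = "isotropic",
    eps_rel: float = 1e-9,
) -> float:
    """Attained objective of a general-purpose solve of the LASSO-TV problem.

    Minimizes the smoothed objective (Huber-like TV with a vanishing epsilon,
    whose value differs from the exact TV by at most alpha * ndim * m * eps)
    over x >= 0 with L-BFGS-B, then reports the *exact* objective at the
    solution.
    """
    A = np.asarray(A, dtype=float)
    p = np.asarray(p, dtype=float)
    m = A.shape[1]
    shape = tuple(shape)
    eps = eps_rel * max(np.abs(p).max(), 1.0)

    def fun(x):
        r = A @ x - p
        tv, dtv = _smoothed_tv_value_grad(x.reshape(shape), flavor, eps)
        f = 0.5 * r @ r + beta * x.sum() + alpha * tv
        g = A.T @ r + beta + alpha * dtv.ravel()
        return f, g

    res = minimize(fun, np.zeros(m), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * m,
                   options={"maxiter": 20000, "maxfun": 50000,
                            "ftol": 1e-16, "gtol": 1e-12})
    x = np.clip(res.x, 0.0, None)
    r = A @ x - p
    tv_exact = tv_brute_force(x.reshape(shape), flavor)
    return 0.5 * r @ r + beta * np.abs(x).sum() + alpha * tv_exact
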