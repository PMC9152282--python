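"""Shared oracle helpers for the test suite."""

import scipy.sparse as sp
from scipy.sparse.linalg import splu


def dense_operator(lines, n):
    """Dense mass-rate diffusion matrix built from the line conductances."""
    rows, cols, vals = [], [], []
    for a in range(3):
        order, ptr, ge = lines.order[a], lines.ptr[a], lines.gedge[a]
        for l in range(len(ptr) - 1):
            for q in range(ptr[l], ptr[l + 1] - 1):
                i, j = order[q], order[q + 1]
                g = ge[q]
                rows += [i, i, j, j]
                cols += [j, i, i, j]
                vals += [g, -g, g, -g]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def dense_cn_step(lines, volumes, u0, d, dt):
    """One dense Crank-Nicolson step on the same stencil (oracle)."""
    n = len(u0)
    A = d * sp.diags(1.0 / volumes) @ dense_operator(lines, n)
    eye = sp.identity(n, format="csc")
    return splu((eye - dt / 2 * A).tocsc()).solve((eye + dt / 2 * A) @ u0)


def dense_be_step(lines, volumes, u0, d, dt):
    """One dense backward-Euler step on the same stencil (oracle)."""
    n = len(u0)
    A = d * sp.diags(1.0 / volumes) @ dense_operator(lines, n)
    eye = sp.identity(n, format="csc")
    return splu((eye - dt * A).tocsc()).solve(u0)
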