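"""Low-level alternating-direction kernels for the auxin grid equation.

The transport operator along each grid axis is tridiagonal: for the
interface between points k and k+1, ``fp[k]`` is the transfer rate k -> k+1
and ``fm[k]`` the rate k+1 -> k (diffusion: symmetric; carrier-mediated
membrane transport: asymmetric).  Both the explicit application and the
implicit (I - w L) solve conserve mass exactly because every column of L
sums to zero.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def apply_lx(a, fpx, fmx, out):
    n, m = a.shape
    for i in range(n):
        for j in range(m):
            acc = 0.0
            if j > 0:
                acc += fpx[i, j - 1] * a[i, j - 1] - fmx[i, j - 1] * a[i, j]
            if j < m - 1:
                acc += fmx[i, j] * a[i, j + 1] - fpx[i, j] * a[i, j]
            out[i, j] = acc


@njit(cache=True)
def apply_ly(a, fpy, fmy, out):
    n, m = a.shape
    for i in range(n):
        for j in range(m):
            acc = 0.0
            if i > 0:
                acc += fpy[i - 1, j] * a[i - 1, j] - fmy[i - 1, j] * a[i, j]
            if i < n - 1:
                acc += fmy[i, j] * a[i + 1, j] - fpy[i, j] * a[i, j]
            out[i, j] = acc


@njit(cache=True)
def solve_x(rhs, fpx, fmx, w, out):
    """Thomas solve of (I - w Lx) out = rhs independently for every row."""
    n, m = rhs.shape
    cp = np.empty(m)
    dp = np.empty(m)
    for i in range(n):
        # diag[j] = 1 + w*(loss terms); sub[j] = -w*fpx[j-1]; sup[j] = -w*fmx[j]
        loss0 = fpx[i, 0] if m > 1 else 0.0
        b0 = 1.0 + w * loss0
        cp[0] = (-w * fmx[i, 0]) / b0 if m > 1 else 0.0
        dp[0] = rhs[i, 0] / b0
        for j in range(1, m):
            loss = fmx[i, j - 1]
            if j < m - 1:
                loss += fpx[i, j]
            bj = 1.0 + w * loss
            aj = -w * fpx[i, j - 1]
            denom = bj - aj * cp[j - 1]
            if j < m - 1:
                cp[j] = (-w * fmx[i, j]) / denom
            dp[j] = (rhs[i, j] - aj * dp[j - 1]) / denom
        out[i, m - 1] = dp[m - 1]
        for j in range(m - 2, -1, -1):
            out[i, j] = dp[j] - cp[j] * out[i, j + 1]


@njit(cache=True)
def solve_y(rhs, fpy, fmy, w, out, sink):
    """Thomas solve of (I - w (Ly - diag(sink))) out = rhs per column.

    ``sink`` is an additional per-point first-order loss (used for the
    shootward boundary outflow, which is stiff enough to need implicit
    treatment)."""
    n, m = rhs.shape
    cp = np.empty(n)
    dp = np.empty(n)
    for j in range(m):
        loss0 = sink[0, j]
        if n > 1:
            loss0 += fpy[0, j]
        b0 = 1.0 + w * loss0
        cp[0] = (-w * fmy[0, j]) / b0 if n > 1 else 0.0
        dp[0] = rhs[0, j] / b0
        for i in range(1, n):
            loss = fmy[i - 1, j] + sink[i, j]
            if i < n - 1:
                loss += fpy[i, j]
            bi = 1.0 + w * loss
            ai = -w * fpy[i - 1, j]
            denom = bi - ai * cp[i - 1]
            if i < n - 1:
                cp[i] = (-w * fmy[i, j]) / denom
            dp[i] = (rhs[i, j] - ai * dp[i - 1]) / denom
        out[n - 1, j] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            out[i, j] = dp[i] - cp[i] * out[i + 1, j]
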