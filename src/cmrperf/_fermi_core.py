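"""Compiled inner loops for Fermi-constrained deconvolution.

The model for a tissue curve is the discrete (Riemann-sum) convolution of
the AIF with a delayed Fermi impulse response

    h(t) = F / (1 + exp((t - delay - T0) / W))   for t >= delay, else 0.

For fixed (T0, W, delay) the least-squares amplitude F has a closed form
(the model is linear in F), so the nonlinear search runs over (T0, W)
only, with F profiled out subject to its bounds. Optimization is a
deterministic coarse grid over (T0, W) — shared across all candidate
delays through the shift structure of the convolution — followed by a
Nelder-Mead refinement per delay. Everything here is seed-free and
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F_MIN = 1e-12


@njit(cache=True)
def _model_conv(aif, dt, t0, w):
    """dt * conv(aif, h0) with the zero-delay unit-amplitude kernel."""
    n = aif.shape[0]
    h = np.empty(n)
    for j in range(n):
        x = (j * dt - t0) / w
        if x > 40.0:
            h[j] = 0.0
        elif x < -40.0:
            h[j] = 1.0
        else:
            h[j] = 1.0 / (1.0 + np.exp(x))
    # trapezoidal quadrature: half weight on the two endpoint samples,
    # which keeps the discrete model close to the continuous integral
    m = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(i + 1):
            s += aif[j] * h[i - j]
        s -= 0.5 * (aif[0] * h[i] + aif[i] * h[0])
        m[i] = s * dt
    return m


@njit(cache=True)
def _amp_sse(m, y, k, fmax):
    """Profiled amplitude and SSE for the model shifted by k samples."""
    n = y.shape[0]
    num = 0.0
    den = 0.0
    for i in range(k, n):
        num += m[i - k] * y[i]
        den += m[i - k] * m[i - k]
    if den <= 0.0:
        return F_MIN, 1e300
    a = num / den
    if a < F_MIN:
        a = F_MIN
    if a > fmax:
        a = fmax
    sse = 0.0
    for i in range(n):
        mi = m[i - k] if i >= k else 0.0
        d = y[i] - a * mi
        sse += d * d
    return a, sse


@njit(cache=True)
def _objective(aif, y, dt, t0, w, k, hi_t0, lo_w, hi_w, fmax):
    if t0 < 0.0 or t0 > hi_t0 or w < lo_w or w > hi_w:
        return 1e300, F_MIN
    m = _model_conv(aif, dt, t0, w)
    a, sse = _amp_sse(m, y, k, fmax)
    return sse, a


@njit(cache=True)
def _nelder_mead(aif, y, dt, k, t0_init, w_init, hi_t0, lo_w, hi_w, fmax, max_iter):
    """2-D Nelder-Mead on (T0, W) with bound penalties; returns F,T0,W,SSE."""
    p = np.empty((3, 2))
    f = np.empty(3)
    amp = np.empty(3)
    step_t = 0.15 * hi_t0 if hi_t0 > 0 else 1.0
    step_w = 0.3 * w_init + 0.1
    p[0, 0], p[0, 1] = t0_init, w_init
    p[1, 0] = t0_init + step_t if t0_init + step_t <= hi_t0 else t0_init - step_t
    p[1, 1] = w_init
    p[2, 0] = t0_init
    p[2, 1] = w_init + step_w if w_init + step_w <= hi_w else w_init - step_w
    for v in range(3):
        f[v], amp[v] = _objective(aif, y, dt, p[v, 0], p[v, 1], k, hi_t0, lo_w, hi_w, fmax)

    for _ in range(max_iter):
        # order vertices: best (0), worst (2)
        for a_ in range(2):
            for b_ in range(a_ + 1, 3):
                if f[b_] < f[a_]:
                    f[a_], f[b_] = f[b_], f[a_]
                    amp[a_], amp[b_] = amp[b_], amp[a_]
                    tmp0, tmp1 = p[a_, 0], p[a_, 1]
                    p[a_, 0], p[a_, 1] = p[b_, 0], p[b_, 1]
                    p[b_, 0], p[b_, 1] = tmp0, tmp1
        # convergence: tiny simplex or flat objective
        diam = abs(p[0, 0] - p[2, 0]) + abs(p[0, 1] - p[2, 1]) + abs(p[0, 0] - p[1, 0]) + abs(
            p[0, 1] - p[1, 1]
        )
        if diam < 1e-4 or (f[2] - f[0]) <= 1e-12 * (f[0] + 1e-30):
            break
        c0 = 0.5 * (p[0, 0] + p[1, 0])
        c1 = 0.5 * (p[0, 1] + p[1, 1])
        # reflection
        xr0 = c0 + (c0 - p[2, 0])
        xr1 = c1 + (c1 - p[2, 1])
        fr, ar = _objective(aif, y, dt, xr0, xr1, k, hi_t0, lo_w, hi_w, fmax)
        if fr < f[0]:
            # expansion
            xe0 = c0 + 2.0 * (c0 - p[2, 0])
            xe1 = c1 + 2.0 * (c1 - p[2, 1])
            fe, ae = _objective(aif, y, dt, xe0, xe1, k, hi_t0, lo_w, hi_w, fmax)
            if fe < fr:
                p[2, 0], p[2, 1], f[2], amp[2] = xe0, xe1, fe, ae
            else:
                p[2, 0], p[2, 1], f[2], amp[2] = xr0, xr1, fr, ar
        elif fr < f[1]:
            p[2, 0], p[2, 1], f[2], amp[2] = xr0, xr1, fr, ar
        else:
            # contraction
            if fr < f[2]:
                xc0 = c0 + 0.5 * (xr0 - c0)
                xc1 = c1 + 0.5 * (xr1 - c1)
            else:
                xc0 = c0 + 0.5 * (p[2, 0] - c0)
                xc1 = c1 + 0.5 * (p[2, 1] - c1)
            fc, ac = _objective(aif, y, dt, xc0, xc1, k, hi_t0, lo_w, hi_w, fmax)
            if fc < min(fr, f[2]):
                p[2, 0], p[2, 1], f[2], amp[2] = xc0, xc1, fc, ac
            else:
                # shrink toward best
                for v in range(1, 3):
                    p[v, 0] = p[0, 0] + 0.5 * (p[v, 0] - p[0, 0])
                    p[v, 1] = p[0, 1] + 0.5 * (p[v, 1] - p[0, 1])
                    f[v], amp[v] = _objective(
                        aif, y, dt, p[v, 0], p[v, 1], k, hi_t0, lo_w, hi_w, fmax
                    )
    best = 0
    for v in range(1, 3):
        if f[v] < f[best]:
            best = v
    return amp[best], p[best, 0], p[best, 1], f[best]


@njit(cache=True)
def _amp_sse_frac(m, y, g, fmax):
    """Profiled amplitude/SSE for a fractional shift of g samples
    (linear interpolation between integer shifts, zero before onset)."""
    n = y.shape[0]
    k = int(np.floor(g))
    frac = g - k
    num = 0.0
    den = 0.0
    for i in range(n):
        j = i - k
        mi = 0.0
        if j >= 1:
            mi = (1.0 - frac) * m[j] + frac * m[j - 1]
        elif j == 0:
            mi = (1.0 - frac) * m[0]
        num += mi * y[i]
        den += mi * mi
    if den <= 0.0:
        return F_MIN, 1e300
    a = num / den
    if a < F_MIN:
        a = F_MIN
    if a > fmax:
        a = fmax
    sse = 0.0
    for i in range(n):
        j = i - k
        mi = 0.0
        if j >= 1:
            mi = (1.0 - frac) * m[j] + frac * m[j - 1]
        elif j == 0:
            mi = (1.0 - frac) * m[0]
        d = y[i] - a * mi
        sse += d * d
    return a, sse


@njit(cache=True)
def _objective3(aif, y, dt, delay, t0, w, lo_d, hi_d, hi_t0, lo_w, hi_w, fmax):
    if delay < lo_d or delay > hi_d or t0 < 0.0 or t0 > hi_t0 or w < lo_w or w > hi_w:
        return 1e300, F_MIN
    m = _model_conv(aif, dt, t0, w)
    a, sse = _amp_sse_frac(m, y, delay / dt, fmax)
    return sse, a


@njit(cache=True)
def refine_delay(aif, y, dt, d_init, t0_init, w_init, lo_d, hi_d, hi_t0, lo_w, hi_w, fmax, max_iter):
    """Local 3-parameter Nelder-Mead over (delay, T0, W) with the delay
    treated as continuous; returns F, delay, T0, W, SSE."""
    p = np.empty((4, 3))
    f = np.empty(4)
    amp = np.empty(4)
    steps = np.empty(3)
    steps[0] = 0.4 * dt
    steps[1] = 0.15 * hi_t0 if hi_t0 > 0 else 1.0
    steps[2] = 0.3 * w_init + 0.1
    lo = np.empty(3)
    hi = np.empty(3)
    lo[0], hi[0] = lo_d, hi_d
    lo[1], hi[1] = 0.0, hi_t0
    lo[2], hi[2] = lo_w, hi_w
    p[0, 0], p[0, 1], p[0, 2] = d_init, t0_init, w_init
    for v in range(3):
        for c in range(3):
            p[v + 1, c] = p[0, c]
        x = p[0, v] + steps[v]
        if x > hi[v]:
            x = p[0, v] - steps[v]
            if x < lo[v]:
                x = 0.5 * (lo[v] + hi[v])
        p[v + 1, v] = x
    for v in range(4):
        f[v], amp[v] = _objective3(
            aif, y, dt, p[v, 0], p[v, 1], p[v, 2], lo_d, hi_d, hi_t0, lo_w, hi_w, fmax
        )
    for _ in range(max_iter):
        # sort vertices by objective (insertion sort on 4 elements)
        for a_ in range(3):
            for b_ in range(a_ + 1, 4):
                if f[b_] < f[a_]:
                    f[a_], f[b_] = f[b_], f[a_]
                    amp[a_], amp[b_] = amp[b_], amp[a_]
                    for c in range(3):
                        p[a_, c], p[b_, c] = p[b_, c], p[a_, c]
        diam = 0.0
        for v in range(1, 4):
            for c in range(3):
                diam += abs(p[v, c] - p[0, c])
        if diam < 1e-4 or (f[3] - f[0]) <= 1e-12 * (f[0] + 1e-30):
            break
        cen = np.zeros(3)
        for v in range(3):
            for c in range(3):
                cen[c] += p[v, c] / 3.0
        xr = np.empty(3)
        for c in range(3):
            xr[c] = cen[c] + (cen[c] - p[3, c])
        fr, ar = _objective3(aif, y, dt, xr[0], xr[1], xr[2], lo_d, hi_d, hi_t0, lo_w, hi_w, fmax)
        if fr < f[0]:
            xe = np.empty(3)
            for c in range(3):
                xe[c] = cen[c] + 2.0 * (cen[c] - p[3, c])
            fe, ae = _objective3(
                aif, y, dt, xe[0], xe[1], xe[2], lo_d, hi_d, hi_t0, lo_w, hi_w, fmax
            )
            if fe < fr:
                for c in range(3):
                    p[3, c] = xe[c]
                f[3], amp[3] = fe, ae
            else:
                for c in range(3):
                    p[3, c] = xr[c]
                f[3], amp[3] = fr, ar
        elif fr < f[2]:
            for c in range(3):
                p[3, c] = xr[c]
            f[3], amp[3] = fr, ar
        else:
            xc = np.empty(3)
            if fr < f[3]:
                for c in range(3):
                    xc[c] = cen[c] + 0.5 * (xr[c] - cen[c])
            else:
                for c in range(3):
                    xc[c] = cen[c] + 0.5 * (p[3, c] - cen[c])
            fc, ac = _objective3(
                aif, y, dt, xc[0], xc[1], xc[2], lo_d, hi_d, hi_t0, lo_w, hi_w, fmax
            )
            if fc < min(fr, f[3]):
                for c in range(3):
                    p[3, c] = xc[c]
                f[3], amp[3] = fc, ac
            else:
                for v in range(1, 4):
                    for c in range(3):
                        p[v, c] = p[0, c] + 0.5 * (p[v, c] - p[0, c])
                    f[v], amp[v] = _objective3(
                        aif, y, dt, p[v, 0], p[v, 1], p[v, 2], lo_d, hi_d, hi_t0, lo_w, hi_w, fmax
                    )
    best = 0
    for v in range(1, 4):
        if f[v] < f[best]:
            best = v
    return amp[best], p[best, 0], p[best, 1], p[best, 2], f[best]


@njit(cache=True)
def fit_delay_grid(aif, y, dt, ks, t0_grid, w_grid, hi_t0, lo_w, hi_w, fmax, max_iter):
    """Fit the Fermi model at every candidate delay (in samples).

    Returns an (n_delays, 4) array of [F_amp, T0, W, SSE]. The coarse
    (T0, W) grid is evaluated once; each delay reuses the convolutions
    via the shift structure, then refines from its best grid point.
    """
    n = aif.shape[0]
    nk = ks.shape[0]
    out = np.empty((nk, 4))
    best_t0 = np.empty(nk)
    best_w = np.empty(nk)
    best_sse = np.full(nk, 1e301)
    for a_ in range(t0_grid.shape[0]):
        for b_ in range(w_grid.shape[0]):
            m = _model_conv(aif, dt, t0_grid[a_], w_grid[b_])
            for q in range(nk):
                k = ks[q]
                if k >= n:
                    continue
                _amp, sse = _amp_sse(m, y, k, fmax)
                if sse < best_sse[q]:
                    best_sse[q] = sse
                    best_t0[q] = t0_grid[a_]
                    best_w[q] = w_grid[b_]
    for q in range(nk):
        k = ks[q]
        if k >= n or best_sse[q] >= 1e300:
            out[q, 0] = F_MIN
            out[q, 1] = 0.0
            out[q, 2] = lo_w
            out[q, 3] = 1e300
            continue
        fa, t0b, wb, sse = _nelder_mead(
            aif, y, dt, k, best_t0[q], best_w[q], hi_t0, lo_w, hi_w, fmax, max_iter
        )
        out[q, 0] = fa
        out[q, 1] = t0b
        out[q, 2] = wb
        out[q, 3] = sse
    return out
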