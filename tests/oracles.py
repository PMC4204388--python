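"""Brute-force nested-loop reference implementations used as test oracles.

Everything here is written as plainly as possible — explicit loops over
center pixels, neighborhood offsets and patch pixels on symmetric-padded
arrays — and stays independent of the vectorized code paths it checks.
"""

import numpy as np


def pad_sym(img, pad):
    return np.pad(img, pad, mode="symmetric")


def weight_field(current, noisy, sigma, ps, ns, mode="js", js_norm="patch"):
    """(ns, ns, H, W) weights by direct evaluation of the weight formula."""
    H, W = current.shape
    r, Rn = ps // 2, ns // 2
    g = pad_sym(current, r + Rn)
    rp = pad_sym(np.asarray(noisy) - np.asarray(current), r)
    m = ps * ps if js_norm == "patch" else ns * ns
    out = np.zeros((ns, ns, H, W))
    for y in range(H):
        for x in range(W):
            if mode == "js":
                rsq = float(np.sum(rp[y : y + ps, x : x + ps] ** 2))
                if rsq == 0:
                    continue
                shrink = max(0.0, 1.0 - (m - 2) * sigma**2 / rsq)
            else:
                shrink = 1.0
            p0 = g[y + Rn : y + Rn + ps, x + Rn : x + Rn + ps]
            for dy in range(-Rn, Rn + 1):
                for dx in range(-Rn, Rn + 1):
                    if dy == 0 and dx == 0:
                        continue
                    pi = g[
                        y + Rn + dy : y + Rn + dy + ps,
                        x + Rn + dx : x + Rn + dx + ps,
                    ]
                    d2 = float(np.sum((p0 - pi) ** 2))
                    out[dy + Rn, dx + Rn, y, x] = shrink * np.exp(
                        -d2 / (2.0 * sigma**2)
                    )
    return out


def rho(image, weights, ps, ns):
    """Double sum of weight times squared patch difference of ``image``."""
    H, W = image.shape
    r, Rn = ps // 2, ns // 2
    g = pad_sym(image, r + Rn)
    total = 0.0
    for y in range(H):
        for x in range(W):
            p0 = g[y + Rn : y + Rn + ps, x + Rn : x + Rn + ps]
            for dy in range(-Rn, Rn + 1):
                for dx in range(-Rn, Rn + 1):
                    if dy == 0 and dx == 0:
                        continue
                    w = weights[dy + Rn, dx + Rn, y, x]
                    if w == 0:
                        continue
                    pi = g[
                        y + Rn + dy : y + Rn + dy + ps,
                        x + Rn + dx : x + Rn + dx + ps,
                    ]
                    total += w * float(np.sum((p0 - pi) ** 2))
    return total


def rho_gradient(image, weights, ps, ns):
    """Gradient by direct accumulation of each squared term's derivative,
    folded back through the symmetric padding."""
    H, W = image.shape
    r, Rn = ps // 2, ns // 2
    pad = r + Rn
    g = pad_sym(image, pad)
    gradpad = np.zeros_like(g)
    for y in range(H):
        for x in range(W):
            for dy in range(-Rn, Rn + 1):
                for dx in range(-Rn, Rn + 1):
                    if dy == 0 and dx == 0:
                        continue
                    w = weights[dy + Rn, dx + Rn, y, x]
                    if w == 0:
                        continue
                    for py in range(ps):
                        for px in range(ps):
                            ay, ax = y + pad - r + py, x + pad - r + px
                            by, bx = ay + dy, ax + dx
                            a = g[ay, ax] - g[by, bx]
                            gradpad[ay, ax] += 2.0 * w * a
                            gradpad[by, bx] -= 2.0 * w * a
    fold = np.zeros((H, W))
    idx = np.pad(np.arange(H * W).reshape(H, W), pad, mode="symmetric")
    for py in range(gradpad.shape[0]):
        for px in range(gradpad.shape[1]):
            fold.flat[idx[py, px]] += gradpad[py, px]
    return fold


def descent_step(current, noisy, sigma, ps, ns, lambda_step, inner_iters, mode="js"):
    """Hand-rolled frozen-weight gradient descent with explicit backtracking,
    evaluating rho directly at every trial point."""
    w = weight_field(current, noisy, sigma, ps, ns, mode=mode)
    f = np.asarray(current, dtype=float).copy()
    rho_f = rho(f, w, ps, ns)
    for _ in range(inner_iters):
        g = rho_gradient(f, w, ps, ns)
        gmax = np.abs(g).max()
        if gmax == 0:
            break
        step = lambda_step / gmax
        trial = f - step * g
        rho_t = rho(trial, w, ps, ns)
        halvings = 0
        while rho_t > rho_f and halvings < 60:
            step *= 0.5
            trial = f - step * g
            rho_t = rho(trial, w, ps, ns)
            halvings += 1
        if rho_t > rho_f:
            break
        f, rho_f = trial, rho_t
    return f


def reconstruct(coeffs, delta, sigma_init, sigma_decay, sigma_min, max_outer,
                inner_iters, lambda_step, conv_tol, ps, ns, mode="js",
                bootstrap=True):
    """Straight-line version of the full loop: spatial descent, unitary
    forward transform, per-coefficient radial clamp, inverse transform."""
    noisy = np.fft.ifft2(coeffs, norm="ortho").real
    f = noisy.copy()
    schedule = []
    s = sigma_init
    while s >= sigma_min and len(schedule) < max_outer:
        schedule.append(s)
        s *= sigma_decay
    for t, sigma in enumerate(schedule):
        level_mode = "conventional" if (t == 0 and bootstrap) else mode
        w = weight_field(f, noisy, sigma, ps, ns, mode=level_mode)
        active = w.any()
        f_reg = _descend_with_weights(f, w, lambda_step, inner_iters, ps, ns)
        C = np.fft.fft2(f_reg, norm="ortho")
        d = C - coeffs
        if delta == 0:
            C = coeffs.copy()
        else:
            mag = np.abs(d)
            scale = np.where(mag > delta, delta / np.where(mag > 0, mag, 1.0), 1.0)
            C = coeffs + d * scale
        f_new = np.fft.ifft2(C, norm="ortho").real
        denom = np.linalg.norm(f)
        rel = np.linalg.norm(f_new - f) / (denom if denom > 0 else 1.0)
        f = f_new
        if active and rel < conv_tol:
            break
    return f


def _descend_with_weights(f, w, lambda_step, inner_iters, ps, ns):
    f = f.copy()
    rho_f = rho(f, w, ps, ns)
    for _ in range(inner_iters):
        g = rho_gradient(f, w, ps, ns)
        gmax = np.abs(g).max()
        if gmax == 0:
            break
        step = lambda_step / gmax
        trial = f - step * g
        rho_t = rho(trial, w, ps, ns)
        halvings = 0
        while rho_t > rho_f and halvings < 60:
            step *= 0.5
            trial = f - step * g
            rho_t = rho(trial, w, ps, ns)
            halvings += 1
        if rho_t > rho_f:
            break
        f, rho_f = trial, rho_t
    return f
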