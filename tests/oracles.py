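"""Brute-force reference implementations used only by the test-suite.

Every function here recomputes a quantity by direct enumeration (double
loops, exhaustive pair scans, hand-expanded formulas) so the vectorized
library code can be checked against an independent path.
"""

import numpy as np


def voting_map_bruteforce(points, directions, g_d, scales):
    """O(pixels * voters) cone-voting accumulation, scalar math per pair."""
    H, W = g_d.shape
    V = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            total = 0.0
            for (m, n), (ux, uy) in zip(points, directions):
                dx, dy = x - m, y - n
                rho = np.hypot(dx, dy)
                for sc in scales:
                    if not (sc.r_min <= rho <= sc.r_max):
                        continue
                    if dx * ux + dy * uy < rho * np.cos(sc.delta):
                        continue
                    mu = 0.5 * (sc.r_min + sc.r_max)
                    k = (np.exp(-((dx - mu * ux) ** 2 + (dy - mu * uy) ** 2)
                                / (2 * sc.sigma ** 2))
                         / (2 * np.pi * sc.sigma ** 2))
                    total += k
            V[y, x] = total * g_d[y, x] / len(points)
    return V


def distance_map_bruteforce(fg):
    """Euclidean distance to the nearest background pixel by full scan."""
    H, W = fg.shape
    bg = np.argwhere(~fg)
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            if fg[y, x]:
                out[y, x] = np.sqrt(((bg - [y, x]) ** 2).sum(1).min())
    return out


def glcm_bruteforce(patch, mask, levels=32):
    """Pairwise co-occurrence statistics by explicit loops."""
    q = np.clip((patch.astype(float) / 256.0 * levels).astype(int),
                0, levels - 1)
    H, W = q.shape
    P = np.zeros((levels, levels))
    for y in range(H):
        for x in range(W):
            for dy, dx in ((0, 1), (1, 0)):
                yy, xx = y + dy, x + dx
                if yy >= H or xx >= W:
                    continue
                if not (mask[y, x] and mask[yy, xx]):
                    continue
                P[q[y, x], q[yy, xx]] += 1
                P[q[yy, xx], q[y, x]] += 1
    tot = P.sum()
    if tot == 0:
        return {"contrast": 0.0, "correlation": 0.0,
                "glcm_energy": 1.0, "homogeneity": 1.0}
    P /= tot
    contrast = energy = homog = 0.0
    mu = 0.0
    for i in range(levels):
        mu += i * P[i].sum()
    var = 0.0
    for i in range(levels):
        var += (i - mu) ** 2 * P[i].sum()
    corr_num = 0.0
    for i in range(levels):
        for j in range(levels):
            contrast += P[i, j] * (i - j) ** 2
            energy += P[i, j] ** 2
            homog += P[i, j] / (1 + (i - j) ** 2)
            corr_num += (i - mu) * (j - mu) * P[i, j]
    corr = corr_num / var if var > 1e-12 else 0.0
    return {"contrast": contrast, "correlation": corr,
            "glcm_energy": energy, "homogeneity": homog}


def lbp_hist_bruteforce(patch, mask):
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1)]
    H, W = patch.shape
    hist = np.zeros(8)
    n = 0
    for y in range(1, H - 1):
        for x in range(1, W - 1):
            ok = all(mask[y + dy, x + dx] for dy, dx in offsets) and mask[y, x]
            if not ok:
                continue
            code = 0
            for bit, (dy, dx) in enumerate(offsets):
                if patch[y + dy, x + dx] >= patch[y, x]:
                    code |= 1 << bit
            hist[code // 32] += 1
            n += 1
    return hist / n if n else hist


def tfcm_hist_bruteforce(patch, mask, eps=2.0):
    directions = [((0, -1), (0, 1)), ((1, -1), (-1, 1)),
                  ((-1, 0), (1, 0)), ((-1, -1), (1, 1))]

    def code(diff):
        if diff > eps:
            return 2
        if diff < -eps:
            return 0
        return 1

    H, W = patch.shape
    hist = np.zeros(8)
    n = 0
    for y in range(1, H - 1):
        for x in range(1, W - 1):
            if not mask[y, x]:
                continue
            tfn = 0
            ok = True
            for d, ((dy1, dx1), (dy2, dx2)) in enumerate(directions):
                if not (mask[y + dy1, x + dx1] and mask[y + dy2, x + dx2]):
                    ok = False
                    break
                s1 = code(patch[y + dy1, x + dx1] - patch[y, x])
                s2 = code(patch[y + dy2, x + dx2] - patch[y, x])
                tfn += (3 * s1 + s2) * 9 ** d
            if not ok:
                continue
            hist[min(tfn * 8 // 6561, 7)] += 1
            n += 1
    return hist / n if n else hist


def csac_bruteforce(patch3, mask):
    pairs = (((0, 0), (2, 2)), ((0, 1), (2, 1)),
             ((0, 2), (2, 0)), ((1, 0), (1, 2)))
    arr = np.asarray(patch3, float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    H, W, C = arr.shape
    out = []
    for ch in range(C):
        a_vals, b_vals = [], []
        for y in range(H - 2):
            for x in range(W - 2):
                if not all(mask[y + i, x + j] for i in range(3)
                           for j in range(3)):
                    continue
                for (y1, x1), (y2, x2) in pairs:
                    a_vals.append(arr[y + y1, x + x1, ch])
                    b_vals.append(arr[y + y2, x + x2, ch])
        if not a_vals:
            out.extend([0.0, 0.0, 0.0, 0.0])
            continue
        a = np.array(a_vals)
        b = np.array(b_vals)
        mu = np.concatenate([a, b]).mean()
        scov = ((a - mu) * (b - mu)).mean()
        var = (((a - mu) ** 2 + (b - mu) ** 2) / 2).mean()
        svr = scov / var if var > 1e-12 else 0.0
        wvar = ((a - b) ** 2 / 2).mean()
        bvar = ((a + b) / 2).var()
        out.extend([scov, svr, wvar, bvar])
    return np.array(out)


def partial_loglik_bruteforce(beta, X, time, event):
    """Direct risk-set enumeration of the Breslow partial log-likelihood."""
    eta = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll
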