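"""Independent brute-force oracles used by unit and acceptance tests.

Every function here evaluates a descriptor by direct enumeration (explicit
loops over pixel pairs, positions, or property pairs), sharing no code with
the package implementations they check.
"""

import numpy as np
from scipy import stats

LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def brute_glcm(q, dr, dc, levels=32):
    H, W = q.shape
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def brute_haralick13(p):
    n = p.shape[0]
    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mx = sum(i * px[i] for i in range(n))
    my = sum(j * py[j] for j in range(n))
    vx = sum((i - mx) ** 2 * px[i] for i in range(n))
    vy = sum((j - my) ** 2 * py[j] for j in range(n))
    asm = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * p[i][j] for i in range(n) for j in range(n))
    corr = (
        (sum(i * j * p[i][j] for i in range(n) for j in range(n)) - mx * my)
        / np.sqrt(vx * vy)
        if vx > 0 and vy > 0
        else 0.0
    )
    var = sum((i - mx) ** 2 * p[i][j] for i in range(n) for j in range(n))
    idm = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    psum = np.zeros(2 * n - 1)
    pdiff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    savg = sum(k * psum[k] for k in range(2 * n - 1))
    svar = sum((k - savg) ** 2 * psum[k] for k in range(2 * n - 1))
    ent = lambda q: -sum(v * np.log(v) for v in np.ravel(q) if v > 0)
    sent = ent(psum)
    entropy = ent(p)
    dmean = sum(k * pdiff[k] for k in range(n))
    dvar = sum((k - dmean) ** 2 * pdiff[k] for k in range(n))
    dent = ent(pdiff)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i][j] * np.log(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0
    )
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - entropy))))
    return np.array(
        [asm, contrast, corr, var, idm, savg, svar, sent, entropy, dvar, dent,
         imc1, imc2]
    )


def brute_lbp_hist(patch):
    H, W = patch.shape
    hist = np.zeros(256)
    for r in range(1, H - 1):
        for c in range(1, W - 1):
            code = 0
            for k, (dr, dc) in enumerate(LBP_OFFSETS):
                if patch[r + dr, c + dc] >= patch[r, c]:
                    code |= 1 << (7 - k)
            hist[code] += 1
    return hist / hist.sum()


def brute_dp_pssm(E, alpha=5):
    def mean_sign(vals, positive):
        sel = [v for v in vals if (v > 0 if positive else v < 0)]
        return sum(sel) / len(sel) if sel else 0.0

    out = [mean_sign(E[:, j], True) for j in range(20)]
    out += [mean_sign(E[:, j], False) for j in range(20)]
    for k in range(1, alpha + 1):
        diffs = [
            [E[i, j] - E[i + k, j] for i in range(E.shape[0] - k)] for j in range(20)
        ]
        out.extend(mean_sign(diffs[j], True) for j in range(20))
        out.extend(mean_sign(diffs[j], False) for j in range(20))
    return np.array(out)


def brute_aac_pssm(E):
    L = E.shape[0]
    return np.array([sum(E[i, j] for i in range(L)) / L for j in range(20)])


def brute_pssm_composition(E, seq, alphabet):
    out = np.zeros((20, 20))
    for a, letter in enumerate(alphabet):
        rows = [i for i, c in enumerate(seq) if c == letter]
        if rows:
            for j in range(20):
                out[a, j] = sum(E[i, j] for i in rows) / len(rows)
    return out.ravel()


def brute_pc_correlation(profiles, n_lags=3):
    """Pair-by-pair lagged Pearson correlations via scipy.stats.pearsonr."""
    L, n_props = profiles.shape
    out = []
    for p in range(n_props):
        for q in range(p + 1, n_props):
            for d in range(1, n_lags + 1):
                x, y = profiles[: L - d, p], profiles[d:, q]
                # constant segments (e.g. a charge scale over uncharged
                # residues) have zero variance; the convention defines r = 0
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    out.append(0.0)
                else:
                    out.append(stats.pearsonr(x, y)[0])
    return np.array(out)
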