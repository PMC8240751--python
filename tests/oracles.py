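"""Independent brute-force oracles for the texture features and statistics.

Everything here is deliberately slow and literal — nested loops over voxel
pairs, explicit run walks, full sign-pattern enumeration — so the fast
vectorized implementations can be checked against an unrelated code path.
"""

import itertools

import numpy as np

DIRECTIONS_13 = [
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and d > tuple(-c for c in d)
]


def glcm_brute(levels, mask, direction):
    """Symmetric normalized co-occurrence matrix by explicit pair listing."""
    nz, ny, nx = levels.shape
    pairs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + direction[0], y + direction[1], x + direction[2]
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                    pairs.append((levels[z, y, x], levels[z2, y2, x2]))
    if not pairs:
        return None
    k = int(levels.max())
    mat = np.zeros((k + 1, k + 1))
    for a, b in pairs:
        mat[a, b] += 1
        mat[b, a] += 1
    mat = mat[1:, 1:]
    return mat / mat.sum()


def glcm_features_brute(levels, mask):
    """13-direction mean contrast and dissimilarity from brute matrices."""
    contrasts, dissims = [], []
    for d in DIRECTIONS_13:
        mat = glcm_brute(levels, mask, d)
        if mat is None:
            continue
        k = mat.shape[0]
        c = sum((i - j) ** 2 * mat[i, j] for i in range(k) for j in range(k))
        s = sum(abs(i - j) * mat[i, j] for i in range(k) for j in range(k))
        contrasts.append(c)
        dissims.append(s)
    return float(np.mean(contrasts)), float(np.mean(dissims))


def glrlm_runs_brute(levels, mask, direction):
    """All maximal constant-level in-mask runs along one direction.

    Returns a list of (level, length). A voxel starts a run iff stepping
    backwards leaves the grid, the mask, or the level.
    """
    nz, ny, nx = levels.shape
    runs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                pz, py, px = z - direction[0], y - direction[1], x - direction[2]
                inside = 0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                if inside and mask[pz, py, px] and levels[pz, py, px] == levels[z, y, x]:
                    continue  # continuation, not a start
                length = 1
                cz, cy, cx = z, y, x
                while True:
                    cz, cy, cx = cz + direction[0], cy + direction[1], cx + direction[2]
                    if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
                        break
                    if not mask[cz, cy, cx] or levels[cz, cy, cx] != levels[z, y, x]:
                        break
                    length += 1
                runs.append((int(levels[z, y, x]), length))
    return runs


def glrlm_gln_brute(levels, mask):
    """13-direction mean GLN = sum_i (sum_j r(i,j))^2 / N_runs."""
    glns = []
    for d in DIRECTIONS_13:
        runs = glrlm_runs_brute(levels, mask, d)
        counts = {}
        for lev, _length in runs:
            counts[lev] = counts.get(lev, 0) + 1
        n = sum(counts.values())
        glns.append(sum(c**2 for c in counts.values()) / n)
    return float(np.mean(glns))


def wilcoxon_exact_brute(diffs):
    """Two-sided exact signed-rank p by full 2^n sign enumeration."""
    from scipy.stats import rankdata

    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    totals = [
        sum(r for r, pick in zip(ranks, signs) if pick)
        for signs in itertools.product((False, True), repeat=n)
    ]
    totals = np.asarray(totals)
    p_le = np.mean(totals <= w_obs + 1e-9)
    p_ge = np.mean(totals >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def chi2_ppf_bisect(q, dof, tol=1e-12):
    """Chi-squared quantile via bisection on the regularized gamma CDF."""
    from scipy.special import gammainc

    lo, hi = 0.0, 10.0 * dof + 100.0
    while gammainc(dof / 2, hi / 2) < q:
        hi *= 2
    for _ in range(200):
        mid = (lo + hi) / 2
        if gammainc(dof / 2, mid / 2) < q:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return (lo + hi) / 2


def dither_slice_reference(slice2d):
    """Literal transcription of Floyd-Steinberg error diffusion with
    border-renormalized weights (no error is lost off the slice edge)."""
    work = np.array(slice2d, dtype=float)
    ny, nx = work.shape
    out = np.zeros((ny, nx), dtype=np.uint8)
    offsets = ((0, 1, 7 / 16), (1, -1, 3 / 16), (1, 0, 5 / 16), (1, 1, 1 / 16))
    for y in range(ny):
        for x in range(nx):
            old = work[y, x]
            new = 1.0 if old >= 0.5 else 0.0
            out[y, x] = int(new)
            err = old - new
            live = [(y + dy, x + dx, w) for dy, dx, w in offsets
                    if 0 <= y + dy < ny and 0 <= x + dx < nx]
            total = sum(w for _, _, w in live)
            if total == 0:
                continue
            for yy, xx, w in live:
                work[yy, xx] += err * w / total
    return out
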