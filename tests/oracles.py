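"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (direct sums, explicit loops) kept
separate from the package code paths they validate.
"""

import numpy as np


def direct_nudft(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """O(N^2 * M) direct non-uniform DFT: s(k) = sum_x f(x) e^{-2 pi i k.x},
    pixel positions relative to the image center."""
    n0, n1 = image.shape
    r0 = np.arange(n0) - n0 // 2
    r1 = np.arange(n1) - n1 // 2
    k = coords.reshape(-1, 2)
    out = np.zeros(len(k), dtype=complex)
    for m, (ky, kx) in enumerate(k):
        phase = np.exp(-2j * np.pi * (ky * r0[:, None] + kx * r1[None, :]))
        out[m] = (image * phase).sum()
    return out.reshape(coords.shape[:2])


def bilinear(image: np.ndarray, r: float, c: float) -> float:
    """Pointwise bilinear interpolation."""
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, image.shape[0] - 1), min(c0 + 1, image.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return (
        image[r0, c0] * (1 - fr) * (1 - fc)
        + image[r1, c0] * fr * (1 - fc)
        + image[r0, c1] * (1 - fr) * fc
        + image[r1, c1] * fr * fc
    )


def brute_glcm(quantized: np.ndarray, levels: int, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pixel-pair
    enumeration."""
    dr, dc = offset
    P = np.zeros((levels, levels))
    h, w = quantized.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = quantized[r, c], quantized[r2, c2]
                P[a, b] += 1
                P[b, a] += 1
    return P / P.sum()


def brute_haralick_13(P: np.ndarray) -> np.ndarray:
    """The 13 classical GLCM statistics, computed with explicit loops."""
    L = P.shape[0]
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(L))
    var = sum((i - mu) ** 2 * px[i] for i in range(L))

    asm = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    corr = (
        sum((i - mu) * (j - mu) * P[i, j] for i in range(L) for j in range(L)) / var
        if var > 0
        else 0.0
    )
    ssq = sum((i - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))

    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]
    savg = sum(k * psum[k] for k in range(2 * L - 1))
    svar = sum((k - savg) ** 2 * psum[k] for k in range(2 * L - 1))
    sent = -sum(p * np.log2(p) for p in psum if p > 0)
    ent = -sum(P[i, j] * np.log2(P[i, j]) for i in range(L) for j in range(L) if P[i, j] > 0)
    davg = sum(k * pdiff[k] for k in range(L))
    dvar = sum((k - davg) ** 2 * pdiff[k] for k in range(L))
    dent = -sum(p * np.log2(p) for p in pdiff if p > 0)

    hx = -sum(p * np.log2(p) for p in px if p > 0)
    hxy1 = -sum(
        P[i, j] * np.log2(px[i] * px[j])
        for i in range(L)
        for j in range(L)
        if px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * np.log2(px[i] * px[j])
        for i in range(L)
        for j in range(L)
        if px[i] * px[j] > 0
    )
    imc1 = (ent - hxy1) / hx if hx > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - ent))))

    return np.array([asm, contrast, corr, ssq, idm, savg, svar, sent, ent, dvar, dent, imc1, imc2])
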