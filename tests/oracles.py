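"""Independent brute-force implementations of the window-feature formulas.

These transliterate each definition as nested loops, kept deliberately
separate from the vectorised implementations in qvmeth.features so the two
can be compared on random pileups.
"""

import numpy as np

from qvmeth.features import ALPHABET, WindowPileup

_IDX = {b: i for i, b in enumerate(ALPHABET)}


def brute_mean(Q):
    n, w = Q.shape
    out = np.zeros(w)
    for i in range(w):
        acc = 0.0
        for j in range(n):
            acc += Q[j, i]
        out[i] = acc / n
    return out


def brute_cov(Q):
    n, w = Q.shape
    M = brute_mean(Q)
    out = np.zeros((w, w))
    for p in range(w):
        for q in range(w):
            acc = 0.0
            for j in range(n):
                acc += (Q[j, p] - M[p]) * (Q[j, q] - M[q])
            out[p, q] = acc / (n - 1)
    return out


def _brute_sigma(Q, ddof=0):
    n, w = Q.shape
    M = brute_mean(Q)
    sig = np.zeros(w)
    for p in range(w):
        acc = 0.0
        for j in range(n):
            acc += (Q[j, p] - M[p]) ** 2
        sig[p] = np.sqrt(acc / (n - ddof))
    return sig


def brute_coskew(Q, ddof=0):
    n, w = Q.shape
    M = brute_mean(Q)
    sig = _brute_sigma(Q, ddof)
    out = np.zeros((w, w))
    for p in range(w):
        for q in range(w):
            if sig[p] == 0 or sig[q] == 0:
                continue
            acc = 0.0
            for j in range(n):
                acc += (Q[j, p] - M[p]) ** 2 * (Q[j, q] - M[q])
            out[p, q] = acc / (n * sig[p] ** 2 * sig[q])
    return out


def brute_cokurt(Q, ddof=0):
    n, w = Q.shape
    M = brute_mean(Q)
    sig = _brute_sigma(Q, ddof)
    out = np.zeros((w, w))
    for p in range(w):
        for q in range(w):
            if sig[p] == 0 or sig[q] == 0:
                continue
            acc = 0.0
            for j in range(n):
                acc += (Q[j, p] - M[p]) ** 2 * (Q[j, q] - M[q]) ** 2
            out[p, q] = acc / (n * sig[p] ** 2 * sig[q] ** 2)
    return out


def brute_error(R, T):
    """Joint error tensor via loops over reads and position pairs."""
    n, w = R.shape
    E = np.zeros((5, 5, w, w))
    for j in range(n):
        for p in range(w):
            s = R[j, p]
            if s == T[p]:
                continue
            for q in range(w):
                t = R[j, q]
                if t == T[q]:
                    continue
                E[_IDX[s], _IDX[t], p, q] += 1.0
    return E / n


def brute_error_full(R, T):
    """Fully literal five-deep loop over (s, t, p, q, j); small n only."""
    n, w = R.shape
    E = np.zeros((5, 5, w, w))
    for si, s in enumerate(ALPHABET):
        for ti, t in enumerate(ALPHABET):
            for p in range(w):
                for q in range(w):
                    acc = 0
                    for j in range(n):
                        acc += int(
                            (R[j, p] == s) and (R[j, q] == t)
                            and (T[p] != s) and (T[q] != t)
                        )
                    E[si, ti, p, q] = acc / n
    return E


def random_pileup(rng, n, flank=10, match_prob=0.8):
    """Random rectangular pileup with mostly reference-matching bases."""
    w = 2 * flank + 1
    T = "".join(rng.choice(list("ACGT"), size=w))
    R = np.empty((n, w), dtype="U1")
    for j in range(n):
        for i in range(w):
            if rng.random() < match_prob:
                R[j, i] = T[i]
            else:
                R[j, i] = ALPHABET[rng.integers(0, 5)]
    Q = rng.integers(1, 51, size=(n, w)).astype(float)
    return WindowPileup(chrom="c", center=1000, strand="+", flank=flank,
                        Q=Q, R=R, T=T)
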