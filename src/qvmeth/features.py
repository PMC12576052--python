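"""Window feature extraction: QV co-moments, joint error tensor, context code.

For a candidate cytosine, the n reads fully covering the 21 reference
positions centred on it (±10 bases, ``flank=10``) form a rectangular pileup:
a QV matrix ``Q`` (n × 21, Phred units) and a base matrix ``R`` over the
alphabet {A, C, G, T, D}, where D marks a deletion, plus the reference
context ``T``.  Five feature families are derived:

* ``mean``    — M_i = (1/n) Σ_j Q_ij                       (length 21)
* ``cov``     — V_pq = (1/(n−1)) Σ_j (Q_pj−M_p)(Q_qj−M_q)  (21 × 21)
* ``coskew``  — S_pq = Σ_j (Q_pj−M_p)²(Q_qj−M_q) / (n σ_p² σ_q)
* ``cokurt``  — K_pq = Σ_j (Q_pj−M_p)²(Q_qj−M_q)² / (n σ_p² σ_q²)
* ``error``   — E_stpq = (1/n) Σ_j I(R_pj=s) I(R_qj=t) I(T_p≠s) I(T_q≠t),
                a 5 × 5 × 21 × 21 tensor of pairwise joint error rates
* ``context`` — 2 bits per reference base: A→00, C→01, G→10, T→11

σ is the per-position spread of the QVs; by default the population standard
deviation (``sigma_ddof=0``), consistent with the 1/n prefactor of S and K.
Entries whose σ vanishes are set to 0 so feature vectors stay finite.

The families are flattened row-major, in the order above, into one fixed
layout of 12411 values for ``flank=10``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContextUnencodableError,
    EmptyPileupError,
    InsufficientDepthError,
    LayoutError,
)

#: Ordered read-base alphabet; index 4 ('D') is a deletion.
ALPHABET = "ACGTD"

#: 2-bit context code per reference base, high bit first.
CONTEXT_BITS = {"A": (0, 0), "C": (0, 1), "G": (1, 0), "T": (1, 1)}

LAYOUT_VERSION = "qv-moments-v1"

SEGMENT_ORDER = ("mean", "cov", "coskew", "cokurt", "error", "context")


@dataclass
class WindowPileup:
    """Rectangular pileup of reads over the window around one candidate site.

    ``Q`` and ``R`` are n × (2·flank+1); ``T`` is the reference context
    string (may be None while the pileup is being assembled).  Deleted
    positions carry base 'D' and the configured ``deletion_qv``.
    """

    chrom: str
    center: int
    strand: str
    flank: int
    Q: np.ndarray
    R: np.ndarray
    T: str | None = None

    def __post_init__(self) -> None:
        width = 2 * self.flank + 1
        self.Q = np.asarray(self.Q, dtype=float)
        self.R = np.asarray(self.R, dtype="U1")
        if self.Q.shape != self.R.shape:
            raise LayoutError(
                f"Q shape {self.Q.shape} != R shape {self.R.shape}"
            )
        if self.Q.ndim != 2 or self.Q.shape[1] != width:
            raise LayoutError(
                f"pileup must be n x {width}, got {self.Q.shape}"
            )
        if self.T is not None and len(self.T) != width:
            raise LayoutError(f"context length {len(self.T)} != {width}")

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def width(self) -> int:
        return 2 * self.flank + 1


@dataclass
class WindowMoments:
    """First- to fourth-order QV (co-)moments of one pileup window."""

    mean: np.ndarray
    cov: np.ndarray
    coskew: np.ndarray
    cokurt: np.ndarray
    std: np.ndarray


@dataclass
class ErrorTensor:
    """Pairwise joint sequencing-error rates, indexed (s, t, p, q)."""

    E: np.ndarray  # shape (5, 5, W, W)


def mean_qv(pileup: WindowPileup) -> np.ndarray:
    """Per-position mean QV, M_i = (1/n) Σ_j Q_ij."""
    if pileup.n == 0:
        raise EmptyPileupError("mean_qv requires at least one read")
    return pileup.Q.mean(axis=0)


def qv_std(pileup: WindowPileup, sigma_ddof: int = 0) -> np.ndarray:
    """Per-position QV spread σ_p used to standardise coskew/cokurt."""
    if pileup.n == 0:
        raise EmptyPileupError("qv_std requires at least one read")
    return pileup.Q.std(axis=0, ddof=sigma_ddof)


def qv_covariance(pileup: WindowPileup) -> np.ndarray:
    """QV covariance matrix with divisor n−1; symmetric."""
    n = pileup.n
    if n < 2:
        raise InsufficientDepthError("covariance requires n >= 2 reads")
    dev = pileup.Q - pileup.Q.mean(axis=0)
    return dev.T @ dev / (n - 1)


def qv_coskewness(pileup: WindowPileup, sigma_ddof: int = 0) -> np.ndarray:
    """QV coskewness matrix S_pq; asymmetric in general.

    Entries with σ_p = 0 or σ_q = 0 are set to 0.
    """
    n = pileup.n
    if n == 0:
        raise EmptyPileupError("coskewness requires at least one read")
    dev = pileup.Q - pileup.Q.mean(axis=0)
    sigma = pileup.Q.std(axis=0, ddof=sigma_ddof)
    num = (dev**2).T @ dev  # num[p, q] = Σ_j dev_pj² dev_qj
    denom = n * np.outer(sigma**2, sigma)
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def qv_cokurtosis(pileup: WindowPileup, sigma_ddof: int = 0) -> np.ndarray:
    """QV cokurtosis matrix K_pq; symmetric, entries ≥ 0.

    Entries with σ_p = 0 or σ_q = 0 are set to 0.
    """
    n = pileup.n
    if n == 0:
        raise EmptyPileupError("cokurtosis requires at least one read")
    dev2 = (pileup.Q - pileup.Q.mean(axis=0)) ** 2
    sigma2 = pileup.Q.var(axis=0, ddof=sigma_ddof)
    num = dev2.T @ dev2
    denom = n * np.outer(sigma2, sigma2)
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def compute_moments(pileup: WindowPileup, sigma_ddof: int = 0) -> WindowMoments:
    """All four QV (co-)moment families plus σ in one call."""
    return WindowMoments(
        mean=mean_qv(pileup),
        cov=qv_covariance(pileup),
        coskew=qv_coskewness(pileup, sigma_ddof=sigma_ddof),
        cokurt=qv_cokurtosis(pileup, sigma_ddof=sigma_ddof),
        std=qv_std(pileup, sigma_ddof=sigma_ddof),
    )


def joint_error_rates(pileup: WindowPileup) -> ErrorTensor:
    """Pairwise joint sequencing-error rate tensor.

    E_stpq is the fraction of reads simultaneously showing non-reference base
    s at window position p and non-reference base t at position q; positions
    matching the reference contribute nothing (structural zeros wherever
    s = T_p or t = T_q).
    """
    n = pileup.n
    if n == 0:
        raise EmptyPileupError("joint_error_rates requires at least one read")
    if pileup.T is None:
        raise LayoutError("pileup has no reference context attached")
    width = pileup.width
    T = np.array(list(pileup.T), dtype="U1")
    # ind[s, p, j] = 1 iff read j shows base s at p and s is not the reference
    ind = np.zeros((len(ALPHABET), width, n))
    for s_idx, base in enumerate(ALPHABET):
        ind[s_idx] = ((pileup.R.T == base) & (T[:, None] != base)).astype(float)
    E = np.einsum("spj,tqj->stpq", ind, ind) / n
    return ErrorTensor(E=E)


def encode_context(T: str) -> np.ndarray:
    """Binary context vector: 2 bits per base in window order, high bit first."""
    bits = np.empty(2 * len(T), dtype=np.int8)
    for i, base in enumerate(T):
        try:
            hi, lo = CONTEXT_BITS[base]
        except KeyError:
            raise ContextUnencodableError(
                f"base {base!r} at window offset {i} is not in ACGT"
            ) from None
        bits[2 * i] = hi
        bits[2 * i + 1] = lo
    return bits


@dataclass(frozen=True)
class FeatureLayout:
    """Fixed flattening scheme mapping feature families to vector spans."""

    flank: int = 10
    version: str = LAYOUT_VERSION

    @property
    def width(self) -> int:
        return 2 * self.flank + 1

    @property
    def segments(self) -> dict[str, tuple[int, int]]:
        """Mapping family -> (offset, length) in the flattened vector."""
        w = self.width
        a = len(ALPHABET)
        lengths = {
            "mean": w,
            "cov": w * w,
            "coskew": w * w,
            "cokurt": w * w,
            "error": a * a * w * w,
            "context": 2 * w,
        }
        out = {}
        offset = 0
        for name in SEGMENT_ORDER:
            out[name] = (offset, lengths[name])
            offset += lengths[name]
        return out

    @property
    def total_length(self) -> int:
        off, length = self.segments[SEGMENT_ORDER[-1]]
        return off + length

    def segment_slice(self, name: str) -> slice:
        offset, length = self.segments[name]
        return slice(offset, offset + length)

    def columns_for(self, families: list[str] | None) -> np.ndarray:
        """Column indices selecting the given families (None = all)."""
        if families is None:
            return np.arange(self.total_length)
        unknown = set(families) - set(SEGMENT_ORDER)
        if unknown:
            raise LayoutError(f"unknown feature families: {sorted(unknown)}")
        idx = [np.arange(*self.segment_slice(f).indices(self.total_length)[:2])
               for f in SEGMENT_ORDER if f in families]
        return np.concatenate(idx)


DEFAULT_LAYOUT = FeatureLayout()


@dataclass
class FeatureVector:
    """Flattened model input for one candidate locus."""

    values: np.ndarray
    layout_version: str = LAYOUT_VERSION
    layout: FeatureLayout = field(default_factory=FeatureLayout, repr=False)


def assemble_feature_vector(
    moments: WindowMoments,
    tensor: ErrorTensor,
    context_bits: np.ndarray,
    layout: FeatureLayout = DEFAULT_LAYOUT,
) -> FeatureVector:
    """Concatenate the five families row-major into the fixed layout."""
    w = layout.width
    a = len(ALPHABET)
    expected = {
        "mean": (w,),
        "cov": (w, w),
        "coskew": (w, w),
        "cokurt": (w, w),
        "error": (a, a, w, w),
        "context": (2 * w,),
    }
    arrays = {
        "mean": np.asarray(moments.mean, dtype=float),
        "cov": np.asarray(moments.cov, dtype=float),
        "coskew": np.asarray(moments.coskew, dtype=float),
        "cokurt": np.asarray(moments.cokurt, dtype=float),
        "error": np.asarray(tensor.E, dtype=float),
        "context": np.asarray(context_bits, dtype=float),
    }
    for name, arr in arrays.items():
        if arr.shape != expected[name]:
            raise LayoutError(
                f"segment {name!r}: expected shape {expected[name]}, "
                f"got {arr.shape}"
            )
    values = np.concatenate([arrays[name].ravel() for name in SEGMENT_ORDER])
    return FeatureVector(values=values, layout_version=layout.version,
                         layout=layout)


def extract_features(
    pileup: WindowPileup,
    sigma_ddof: int = 0,
    layout: FeatureLayout | None = None,
) -> FeatureVector:
    """Full feature vector for one pileup (moments + errors + context)."""
    if layout is None:
        layout = FeatureLayout(flank=pileup.flank)
    if pileup.T is None:
        raise LayoutError("pileup has no reference context attached")
    moments = compute_moments(pileup, sigma_ddof=sigma_ddof)
    tensor = joint_error_rates(pileup)
    bits = encode_context(pileup.T)
    return assemble_feature_vector(moments, tensor, bits, layout=layout)
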