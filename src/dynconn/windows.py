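"""Static and tapered sliding-window functional network connectivity.

The dynamic estimator slides a tapered window (a rectangle of the nominal
window size convolved with a Gaussian) along the filtered component time
courses at stride 1 and computes a taper-weighted Pearson correlation for
every component pair in each window.  Each window yields a vector of
P = R(R-1)/2 pairwise correlations in a fixed upper-triangle, row-major
ordering.  The static estimator (sFNC) is the plain Pearson correlation
over the full series, vectorized with the same pair ordering.

Note the window *support* is the full taper length (nominal rectangle
width plus the Gaussian tails, 33 timepoints at the defaults), which
determines the number of windows W = T - L + 1; the nominal "window size"
names the rectangle only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaperSpec:
    """Rectangle width (in TRs), Gaussian sigma, and kernel truncation."""

    rect_width: int = 15
    gauss_sigma: float = 3.0
    gauss_truncate_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if self.rect_width < 2:
            raise ValueError("rect_width must be >= 2")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be > 0")


@dataclass
class WindowedConnectivity:
    """Per-subject stack of windowed connectivity vectors."""

    subject_id: str
    window_starts: np.ndarray
    #: W x P matrix, P = R(R-1)/2
    vectors: np.ndarray
    #: ordered list of (i, j) component pairs, i < j, row-major upper triangle
    pair_index: list[tuple[int, int]] = field(repr=False)


def pair_index(n_components: int) -> list[tuple[int, int]]:
    """Fixed (i, j), i<j, row-major upper-triangle pair ordering."""
    iu, ju = np.triu_indices(n_components, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize(mat: np.ndarray) -> np.ndarray:
    """Upper triangle (k=1) of a symmetric matrix, row-major."""
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    return np.asarray(mat)[iu, ju]


def devectorize(vec: np.ndarray, n_components: int) -> np.ndarray:
    """Inverse of :func:`vectorize`, with unit diagonal."""
    mat = np.eye(n_components)
    iu, ju = np.triu_indices(n_components, k=1)
    mat[iu, ju] = vec
    mat[ju, iu] = vec
    return mat


def make_taper(spec: TaperSpec) -> np.ndarray:
    """Tapered window: rectangle convolved with a truncated Gaussian.

    Full discrete convolution of ``rect_width`` ones with a Gaussian kernel
    of length ``2*ceil(truncate*sigma) + 1``; the result is normalized to
    sum to 1 (length ``rect_width + 2*ceil(truncate*sigma)``).
    """
    half = int(math.ceil(spec.gauss_truncate_sigmas * spec.gauss_sigma))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / spec.gauss_sigma) ** 2)
    kernel /= kernel.sum()
    taper = np.convolve(np.ones(spec.rect_width), kernel, mode="full")
    return taper / taper.sum()


def sliding_window_starts(n_timepoints: int, taper_length: int) -> np.ndarray:
    """Stride-1, fully interior window start indices (0 .. T-L)."""
    if n_timepoints < taper_length:
        raise ValueError(
            f"series length {n_timepoints} shorter than window support {taper_length}"
        )
    return np.arange(n_timepoints - taper_length + 1)


def _weighted_corr_matrix(
    segments: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted correlation matrices for a stack of (L x R) segments.

    ``segments`` has shape (W, L, R); returns (corr (W, R, R), bad (W, R))
    where ``bad`` flags columns with zero weighted variance, whose
    correlations are set to 0.
    """
    mu = np.einsum("l,wlr->wr", weights, segments)
    centered = segments - mu[:, None, :]
    cov = np.einsum("wli,wlj->wij", centered * weights[None, :, None], centered)
    var = np.einsum("wii->wi", cov).copy()
    # zero weighted variance up to rounding, relative to the column's power
    power = np.einsum("l,wlr->wr", weights, segments**2)
    bad = var <= 1e-13 * np.maximum(power, 1e-300)
    var[bad] = 1.0
    denom = np.sqrt(var)
    corr = cov / (denom[:, :, None] * denom[:, None, :])
    if bad.any():
        corr = np.ascontiguousarray(corr)
        corr[np.broadcast_to(bad[:, :, None], corr.shape)] = 0.0
        corr[np.broadcast_to(bad[:, None, :], corr.shape)] = 0.0
    return np.clip(corr, -1.0, 1.0), bad


def weighted_correlation(segment: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Taper-weighted Pearson correlations for one window.

    Uses weighted means and weighted covariances; with equal weights this
    reduces exactly to the plain Pearson correlation on the segment.
    Values are clipped to [-1, 1] only to absorb floating-point rounding.
    Columns with zero weighted variance give correlation 0 with a warning.
    """
    seg = np.asarray(segment, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isfinite(seg).all():
        raise ValueError("non-finite values in segment")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if seg.shape[0] != w.shape[0]:
        raise ValueError("segment length and weight length differ")
    corr, bad = _weighted_corr_matrix(seg[None], w)
    if bad.any():
        logger.warning("zero weighted variance column(s); correlations set to 0")
    return vectorize(corr[0])


def compute_dfnc(
    timecourses: np.ndarray, spec: TaperSpec, subject_id: str = ""
) -> WindowedConnectivity:
    """Windowed connectivity for one subject's (filtered) T x R series."""
    x = np.asarray(timecourses, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in time courses")
    taper = make_taper(spec)
    starts = sliding_window_starts(x.shape[0], len(taper))
    # (W, R, L) -> (W, L, R)
    segs = sliding_window_view(x, len(taper), axis=0).transpose(0, 2, 1)
    corr, bad = _weighted_corr_matrix(np.ascontiguousarray(segs), taper)
    if bad.any():
        logger.warning(
            "subject %s: %d window/column pairs had zero weighted variance",
            subject_id,
            int(bad.sum()),
        )
    iu, ju = np.triu_indices(x.shape[1], k=1)
    vectors = corr[:, iu, ju]
    return WindowedConnectivity(
        subject_id=subject_id,
        window_starts=starts,
        vectors=vectors,
        pair_index=pair_index(x.shape[1]),
    )


def compute_sfnc(timecourses: np.ndarray) -> np.ndarray:
    """Static connectivity: plain Pearson correlation over the full series."""
    x = np.asarray(timecourses, dtype=float)
    n_t = x.shape[0]
    w = np.full(n_t, 1.0 / n_t)
    return weighted_correlation(x, w)
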