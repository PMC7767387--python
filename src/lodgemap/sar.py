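"""Dual-polarimetric SAR features from per-pixel 2x2 covariance matrices.

A dual-pol (VV, VH) acquisition is summarised per pixel by the Hermitian
covariance matrix

    C2 = [[C11, C12], [C12*, C22]],

with C11 = <|S_vv|^2>, C22 = <|S_vh|^2> and C12 the inter-channel covariance.
From C2 this module derives the ten parameters used by the lodging analysis:
calibrated backscatter in dB (VV, VH), their dB-domain combinations
(VV + VH, VV − VH, VH/VV), and the eigenvalue-decomposition family (mean
alpha angle, entropy, anisotropy, span, Shannon entropy).  A local-statistics
Lee filter provides speckle suppression.

Eigen quantities use the closed-form 2x2 Hermitian decomposition; the alpha
angle of each eigenvector is ``arccos`` of the magnitude of its first (VV)
component — the standard dual-pol convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .geo import GridTransform, RasterStack
from .reference import SAR_PARAMS

log = logging.getLogger(__name__)

DB_FLOOR = -50.0
PSD_TOL = 1e-8


@dataclass
class C2Raster:
    """Grid of per-pixel dual-pol covariance matrices."""

    c11: np.ndarray
    c22: np.ndarray
    c12: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        if not (self.c11.shape == self.c22.shape == self.c12.shape):
            raise ValueError("C2 component grids must share one shape")
        self.c11 = np.asarray(self.c11, dtype=float)
        self.c22 = np.asarray(self.c22, dtype=float)
        self.c12 = np.asarray(self.c12, dtype=complex)
        self.validate()

    def validate(self, tol: float = PSD_TOL) -> None:
        """Check positive semidefiniteness within tolerance."""
        scale = max(float(np.nanmax(self.c11, initial=0.0)), float(np.nanmax(self.c22, initial=0.0)), 1.0)
        if np.nanmin(self.c11) < -tol * scale or np.nanmin(self.c22) < -tol * scale:
            raise ValueError("C2 diagonal has negative power")
        excess = np.abs(self.c12) ** 2 - self.c11 * self.c22
        if np.nanmax(excess, initial=0.0) > tol * scale**2:
            raise ValueError("C2 is not positive semidefinite: |C12|^2 > C11*C22")

    @property
    def shape(self) -> tuple[int, int]:
        return self.c11.shape

    @property
    def trace(self) -> np.ndarray:
        return self.c11 + self.c22

    @property
    def det(self) -> np.ndarray:
        return self.c11 * self.c22 - np.abs(self.c12) ** 2


@dataclass
class DecompositionResult:
    """Eigen-based parameters of a C2 grid (all arrays share the grid shape)."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha_mean: np.ndarray
    entropy: np.ndarray
    anisotropy: np.ndarray


@dataclass
class SigmaFeatures:
    """Backscatter combinations computed in the dB domain."""

    vv_db: np.ndarray
    vh_db: np.ndarray
    vv_plus_vh: np.ndarray
    vv_minus_vh: np.ndarray
    vh_over_vv: np.ndarray


def to_db(linear_power: np.ndarray, floor_db: float = DB_FLOOR) -> np.ndarray:
    """Convert linear power to dB; non-positive pixels are set to ``floor_db``."""
    power = np.asarray(linear_power, dtype=float)
    bad = ~(power > 0)
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        log.warning("to_db: %d non-positive pixels floored at %.1f dB", n_bad, floor_db)
    out = np.full(power.shape, floor_db, dtype=float)
    np.log10(power, out=out, where=~bad)
    out[~bad] *= 10.0
    return out


def eigen_c2(c2: C2Raster) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form eigendecomposition of every 2x2 Hermitian matrix in the grid.

    Returns ``(lambda1, lambda2, alpha1, alpha2)`` with lambda1 >= lambda2 >= 0
    and alpha_i = arccos |<e_vv, v_i>| in [0, pi/2].  Eigenvalues follow from
    the trace/determinant quadratic; eigenvectors from (C2 - lambda I) v = 0.
    """
    t = c2.trace
    half_gap = np.sqrt(np.maximum((c2.c11 - c2.c22) ** 2 + 4.0 * np.abs(c2.c12) ** 2, 0.0)) / 2.0
    mid = t / 2.0
    lam1 = mid + half_gap
    lam2 = np.maximum(mid - half_gap, 0.0)

    abs_c12 = np.abs(c2.c12)
    alphas = []
    for lam in (lam1, lam2):
        # eigenvector (up to phase): [c12, lam - c11]; alpha = arccos of the
        # normalised magnitude of the first component
        d = lam - c2.c11
        norm = np.sqrt(abs_c12**2 + d**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_a = np.where(norm > 0, abs_c12 / np.where(norm > 0, norm, 1.0), np.nan)
        alphas.append(cos_a)
    cos_a1, cos_a2 = alphas

    # Degenerate direction (norm == 0) happens when c12 == 0 and the eigenvalue
    # equals c11: the eigenvector is e_vv (alpha = 0).  The paired eigenvector
    # is then e_vh (alpha = pi/2).
    deg1 = ~np.isfinite(cos_a1)
    deg2 = ~np.isfinite(cos_a2)
    alpha1 = np.arccos(np.clip(np.where(deg1, 1.0, cos_a1), 0.0, 1.0))
    alpha2 = np.arccos(np.clip(np.where(deg2, 1.0, cos_a2), 0.0, 1.0))
    return lam1, lam2, alpha1, alpha2


def entropy_anisotropy_alpha(
    lam1: np.ndarray, lam2: np.ndarray, alpha1: np.ndarray, alpha2: np.ndarray
) -> DecompositionResult:
    """Pseudo-probabilities, entropy (base 2), anisotropy and mean alpha.

    H = -sum_i P_i log2 P_i with 0·log0 := 0; A = (l1-l2)/(l1+l2);
    alpha_mean = sum_i P_i alpha_i.  Pixels with zero total power are NaN.
    """
    total = lam1 + lam2
    valid = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(valid, lam1 / np.where(valid, total, 1.0), np.nan)
    p2 = 1.0 - p1

    def plogp(p):
        out = np.zeros_like(p)
        pos = p > 0
        out[pos] = p[pos] * np.log2(p[pos])
        out[~np.isfinite(p)] = np.nan
        return out

    entropy = -(plogp(p1) + plogp(p2))
    with np.errstate(invalid="ignore", divide="ignore"):
        anisotropy = np.where(valid, (lam1 - lam2) / np.where(valid, total, 1.0), np.nan)
    alpha_mean = p1 * alpha1 + p2 * alpha2
    return DecompositionResult(lam1, lam2, p1, p2, alpha1, alpha2, alpha_mean, entropy, anisotropy)


def span(c2: C2Raster, mode: str = "trace", in_db: bool = True) -> np.ndarray:
    """Total power of C2.

    ``mode="trace"`` (default) is C11 + C22, the physical total-power
    convention consistent with reported dB span values; ``mode="squared"``
    evaluates C11^2 + 2|C12|^2 + C22^2 for comparison.  The mode should be
    recorded in output metadata by callers.
    """
    if mode == "trace":
        s = c2.trace
    elif mode == "squared":
        s = c2.c11**2 + 2.0 * np.abs(c2.c12) ** 2 + c2.c22**2
    else:
        raise ValueError(f"unknown span mode: {mode!r}")
    return to_db(s) if in_db else s


def shannon_entropy(c2: C2Raster, det_floor: float = 1e-12) -> np.ndarray:
    """Shannon entropy of the covariance matrix (nats).

    Two-term form: SE = 2 ln(pi e Tr(C2)/2) + ln(4 det(C2)/Tr(C2)^2), the sum
    of an intensity contribution and a polarimetric contribution.  The
    determinant is floored at ``det_floor`` (relative to Tr^2/4) before the
    log so rank-1 pixels give a large negative, finite polarimetry term.
    Pixels with non-positive trace are NaN.
    """
    t = c2.trace
    valid = t > 0
    d = np.maximum(c2.det, det_floor * np.maximum(t, 0.0) ** 2 / 4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = 2.0 * np.log(np.pi * np.e * t / 2.0)
        polarimetry = np.log(4.0 * d / t**2)
    se = np.where(valid, intensity + polarimetry, np.nan)
    return se


def sigma_combinations(vv_db: np.ndarray, vh_db: np.ndarray) -> SigmaFeatures:
    """dB-domain sum, difference and ratio of the two channels.

    The ratio is taken between dB values (not linear powers); pixels where
    VV is exactly 0 dB are undefined (NaN).
    """
    vv_db = np.asarray(vv_db, dtype=float)
    vh_db = np.asarray(vh_db, dtype=float)
    if vv_db.shape != vh_db.shape:
        raise ValueError("vv_db and vh_db grids are not aligned")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(vv_db != 0, vh_db / np.where(vv_db != 0, vv_db, 1.0), np.nan)
    return SigmaFeatures(
        vv_db=vv_db,
        vh_db=vh_db,
        vv_plus_vh=vv_db + vh_db,
        vv_minus_vh=vv_db - vh_db,
        vh_over_vv=ratio,
    )


def lee_filter(intensity: np.ndarray, window: int = 3, enl: float = 4.0) -> np.ndarray:
    """Local-statistics Lee speckle filter on a linear-intensity grid.

    Minimum-MSE weighting of the local mean against the centre pixel,
    x_hat = mean + W (x - mean) with W = var_x / var_y, where var_y is the
    observed local variance and var_x = (var_y - mean^2 / enl) / (1 + 1/enl)
    is the estimated underlying signal variance under multiplicative speckle
    with the given equivalent number of looks.  Edges use reflection padding.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if enl <= 0:
        raise ValueError("enl must be positive")
    x = np.asarray(intensity, dtype=float)
    cu2 = 1.0 / enl
    mean = uniform_filter(x, size=window, mode="reflect")
    mean_sq = uniform_filter(x * x, size=window, mode="reflect")
    var_y = np.maximum(mean_sq - mean**2, 0.0)
    var_x = np.maximum((var_y - mean**2 * cu2) / (1.0 + cu2), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(var_y > 0, var_x / np.where(var_y > 0, var_y, 1.0), 0.0)
    return mean + w * (x - mean)


def filter_c2(c2: C2Raster, window: int = 3, enl: float = 4.0) -> C2Raster:
    """Speckle-filter a C2 grid: Lee on the intensity channels, boxcar on C12.

    The off-diagonal term is smoothed with the same window (separately on its
    real and imaginary parts) and its magnitude clipped to keep the matrix
    positive semidefinite.
    """
    c11 = lee_filter(c2.c11, window=window, enl=enl)
    c22 = lee_filter(c2.c22, window=window, enl=enl)
    re = uniform_filter(c2.c12.real, size=window, mode="reflect")
    im = uniform_filter(c2.c12.imag, size=window, mode="reflect")
    c12 = re + 1j * im
    mag = np.abs(c12)
    cap = np.sqrt(np.maximum(c11 * c22, 0.0))
    scale = np.where(mag > cap, np.where(mag > 0, cap / np.where(mag > 0, mag, 1.0), 0.0), 1.0)
    return C2Raster(c11=c11, c22=c22, c12=c12 * scale, transform=c2.transform)


def feature_stack(
    c2: C2Raster,
    enl: float = 4.0,
    window: int = 3,
    speckle_filter: bool = True,
    span_mode: str = "trace",
) -> RasterStack:
    """Compute the full ten-parameter SAR feature stack from a C2 grid.

    Band order and names follow the canonical parameter list: VV, VH,
    VV + VH, VV − VH, VH/VV, Alpha, Anisotropy, Entropy, Shannon Entropy,
    Span.  When ``speckle_filter`` is set the C2 grid is Lee-filtered first.
    """
    if speckle_filter:
        c2 = filter_c2(c2, window=window, enl=enl)
    vv_db = to_db(c2.c11)
    vh_db = to_db(c2.c22)
    sig = sigma_combinations(vv_db, vh_db)
    lam1, lam2, a1, a2 = eigen_c2(c2)
    dec = entropy_anisotropy_alpha(lam1, lam2, a1, a2)
    bands = {
        "VV": sig.vv_db,
        "VH": sig.vh_db,
        "VV + VH": sig.vv_plus_vh,
        "VV − VH": sig.vv_minus_vh,
        "VH/VV": sig.vh_over_vv,
        "Alpha": dec.alpha_mean,
        "Anisotropy": dec.anisotropy,
        "Entropy": dec.entropy,
        "Shannon Entropy": shannon_entropy(c2),
        "Span": span(c2, mode=span_mode, in_db=True),
    }
    assert list(bands) == list(SAR_PARAMS)
    meta = {"span_mode": span_mode, "speckle_filter": speckle_filter, "enl": enl, "window": window}
    return RasterStack(bands, c2.transform, meta)
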