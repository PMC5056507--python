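"""Filter-scale texture features: LoG filtering, histogram and GLCM statistics.

The feature dictionary is the cross product of five Laplacian-of-Gaussian
(LoG) filter scales sigma in {0, 1.0, 1.5, 2.0, 2.5} (sigma = 0 meaning no
filtering) with

* ten first-order histogram statistics of the in-ROI filtered intensities:
  mean, SD, the mean and SD of the top beta fraction of the histogram for
  beta in {50%, 25%, 10%}, kurtosis and skewness; and
* five gray-level co-occurrence matrix (GLCM) statistics — contrast,
  correlation, entropy, energy, homogeneity — at offset delta = 1 in each
  of four directions alpha in {0, 45, 90, 135} degrees,

for 5 * (10 + 5 * 4) = 150 named features per (image, ROI) pair.

Conventions (each is a deliberate reading of an underspecified point and is
documented in docs/methods.md): SD uses divisor N; kurtosis is non-excess
(Gaussian -> 3); the top-beta subset holds the M = round(beta*N) largest
intensities; gray levels are Ng = 64 equal-width bins over the in-mask
min-max of the *filtered* values; the GLCM is accumulated symmetrically and
normalised to a probability distribution; entropy uses log base 2;
homogeneity weights are 1/(1 + (i-j)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ImageSlice, ROIMask

__all__ = [
    "SIGMAS",
    "BETAS",
    "THETAS",
    "NG_DEFAULT",
    "log_kernel",
    "log_filter",
    "histogram_features",
    "quantize",
    "glcm",
    "GLCMMatrix",
    "glcm_features",
    "extract_all",
    "feature_names",
]

SIGMAS: tuple[float, ...] = (0.0, 1.0, 1.5, 2.0, 2.5)
BETAS: tuple[float, ...] = (0.50, 0.25, 0.10)
THETAS: tuple[int, ...] = (0, 45, 90, 135)
NG_DEFAULT = 64

# (row, col) step for a delta=1 neighbour in each direction; rows grow
# downwards, so 45 deg points to the upper-right neighbour.
_THETA_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _sigma_tag(sigma: float) -> str:
    return "0" if sigma == 0 else f"{sigma:.1f}"


def log_kernel(sigma: float) -> np.ndarray:
    """Discretely sampled LoG kernel at scale ``sigma`` (pixels).

    LoG(x, y) = -(1/(pi sigma^4)) [1 - (x^2+y^2)/(2 sigma^2)]
                exp(-(x^2+y^2)/(2 sigma^2)),

    sampled on a square grid truncated at radius ceil(4*sigma) and
    mean-subtracted so the weights sum exactly to zero (a constant image
    filters to zero).
    """
    if sigma <= 0:
        raise ValueError("log_kernel requires sigma > 0; sigma = 0 is identity")
    r = math.ceil(4 * sigma)
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    q = (x * x + y * y) / (2.0 * sigma**2)
    k = -(1.0 / (math.pi * sigma**4)) * (1.0 - q) * np.exp(-q)
    return k - k.mean()


def log_filter(image: ImageSlice | np.ndarray, sigma: float) -> np.ndarray:
    """Filter a whole image at scale ``sigma``; ``sigma = 0`` is identity.

    Boundaries are handled by reflection.  Only the supported scales are
    accepted so feature names always map to a known filter.
    """
    if sigma not in SIGMAS:
        raise ValueError(f"unsupported filter scale {sigma!r}; choose from {SIGMAS}")
    pixels = image.pixels if isinstance(image, ImageSlice) else np.asarray(image, float)
    if sigma == 0:
        return pixels.copy()
    return ndimage.convolve(pixels, log_kernel(sigma), mode="reflect")


def _top_beta(sorted_desc: np.ndarray, beta: float) -> np.ndarray:
    m = max(1, int(np.floor(beta * sorted_desc.size + 0.5)))
    return sorted_desc[:m]


def histogram_features(values: np.ndarray, betas: tuple[float, ...] = BETAS) -> dict[str, float]:
    """Ten first-order statistics of the in-ROI intensity sample.

    Returns keys ``mean``, ``SD``, ``{b}_mean`` and ``SD_{b}`` for each
    beta (b = 100*beta as an integer), ``kurtosis`` and ``skewness``.
    Constant input is degenerate: SD = 0 and kurtosis/skewness are
    reported as 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("histogram features require at least 2 pixels")
    mean = float(x.mean())
    centred = x - mean
    var = float(np.mean(centred**2))
    sd = math.sqrt(var)
    out = {"mean": mean, "SD": sd}
    desc = np.sort(x)[::-1]
    for beta in betas:
        tag = str(int(round(beta * 100)))
        top = _top_beta(desc, beta)
        out[f"{tag}_mean"] = float(top.mean())
        out[f"SD_{tag}"] = float(np.sqrt(np.mean((top - top.mean()) ** 2)))
    if sd == 0.0:
        out["kurtosis"] = 0.0
        out["skewness"] = 0.0
    else:
        out["kurtosis"] = float(np.mean(centred**4) / var**2)
        out["skewness"] = float(np.mean(centred**3) / sd**3)
    return out


def quantize(values: np.ndarray, ng: int = NG_DEFAULT) -> np.ndarray:
    """Map intensities to integer gray levels 1..ng by equal-width binning.

    Bins span the min-max of ``values``; the maximum maps to level ng.
    Constant input maps everything to level 1.
    """
    if ng < 2:
        raise ValueError("need at least 2 gray levels")
    x = np.asarray(values, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones_like(x, dtype=np.int64)
    levels = np.floor((x - lo) / (hi - lo) * ng).astype(np.int64) + 1
    return np.minimum(levels, ng)


@dataclass
class GLCMMatrix:
    """Normalised symmetric co-occurrence matrix with its geometry."""

    P: np.ndarray
    ng: int
    theta: int
    delta: int = 1

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.ng, self.ng):
            raise ValueError("GLCM must be ng x ng")
        if np.any(self.P < 0) or not math.isclose(self.P.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("GLCM must be a probability distribution")


def glcm(
    level_image: np.ndarray,
    mask: ROIMask | np.ndarray,
    theta: int,
    delta: int = 1,
    ng: int | None = None,
) -> GLCMMatrix:
    """Co-occurrence matrix of gray-level pairs at the given offset.

    Only pairs whose *both* endpoints lie inside the mask are counted;
    each pair is accumulated in both orders (symmetric matrix) and the
    matrix is normalised to sum 1.
    """
    if theta not in _THETA_OFFSETS:
        raise ValueError(f"direction must be one of {tuple(_THETA_OFFSETS)} degrees")
    levels = np.asarray(level_image)
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask) > 0
    if m.shape != levels.shape:
        raise ValueError("mask shape does not match level image")
    if ng is None:
        ng = int(levels[m].max()) if m.any() else 1
    dr, dc = _THETA_OFFSETS[theta]
    dr, dc = dr * delta, dc * delta
    nrow, ncol = levels.shape
    r0 = slice(max(0, -dr), min(nrow, nrow - dr))
    c0 = slice(max(0, -dc), min(ncol, ncol - dc))
    r1 = slice(max(0, dr), min(nrow, nrow + dr))
    c1 = slice(max(0, dc), min(ncol, ncol + dc))
    both = m[r0, c0] & m[r1, c1]
    if not both.any():
        raise ValueError(
            f"no valid gray-level pairs at delta={delta}, theta={theta}: "
            "ROI too small or fragmented for this direction"
        )
    a = levels[r0, c0][both].astype(np.int64)
    b = levels[r1, c1][both].astype(np.int64)
    counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    P = counts / counts.sum()
    return GLCMMatrix(P=P, ng=ng, theta=theta, delta=delta)


def glcm_features(matrix: GLCMMatrix) -> dict[str, float]:
    """Contrast, correlation, entropy, energy and homogeneity of a GLCM.

    contrast    = sum_ij (i-j)^2 P(i,j)
    correlation = sum_ij (i - mu_x)(j - mu_y) P(i,j) / (sigma_x sigma_y)
    entropy     = -sum_ij P log2 P         (0 log 0 := 0)
    energy      = sum_ij P^2
    homogeneity = sum_ij P / (1 + (i-j)^2)

    where mu/sigma are the mean/SD of the marginals P_x, P_y.  A matrix
    with a degenerate marginal (sigma_x sigma_y = 0) reports correlation 0.
    """
    P = matrix.P
    ng = matrix.ng
    i = np.arange(1, ng + 1, dtype=float)
    diff2 = (i[:, None] - i[None, :]) ** 2
    px, py = P.sum(axis=1), P.sum(axis=0)
    mux, muy = float(i @ px), float(i @ py)
    sx = math.sqrt(float(((i - mux) ** 2) @ px))
    sy = math.sqrt(float(((i - muy) ** 2) @ py))
    contrast = float((diff2 * P).sum())
    if sx * sy == 0.0:
        correlation = 0.0
    else:
        cov = float(((i[:, None] - mux) * (i[None, :] - muy) * P).sum())
        correlation = cov / (sx * sy)
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((P * P).sum())
    homogeneity = float((P / (1.0 + diff2)).sum())
    return {
        "contrast": contrast,
        "correlation": correlation,
        "entropy": entropy,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def feature_names(
    sigmas: tuple[float, ...] = SIGMAS,
    betas: tuple[float, ...] = BETAS,
    thetas: tuple[int, ...] = THETAS,
) -> list[str]:
    """The full ordered feature dictionary (150 names by default)."""
    names: list[str] = []
    for sigma in sigmas:
        s = _sigma_tag(sigma)
        names += [f"his_mean_{s}", f"his_SD_{s}"]
        for beta in betas:
            names.append(f"his_{int(round(beta * 100))}_mean_{s}")
        for beta in betas:
            names.append(f"his_SD_{int(round(beta * 100))}_{s}")
        names += [f"kurtosis_{s}", f"skewness_{s}"]
        for stat in ("contrast", "correlation", "entropy", "energy", "homogeneity"):
            for theta in thetas:
                names.append(f"{stat}_{theta}_{s}")
    return names


def extract_all(
    image: ImageSlice,
    refined_mask: ROIMask,
    ng: int = NG_DEFAULT,
    sigmas: tuple[float, ...] = SIGMAS,
    betas: tuple[float, ...] = BETAS,
    thetas: tuple[int, ...] = THETAS,
) -> dict[str, float]:
    """Compute the full named feature vector for one (image, refined ROI).

    For each scale the whole image is filtered first and the in-mask
    filtered values feed both the histogram statistics and, after
    quantization to ``ng`` levels, the four-direction GLCM statistics.
    """
    if not refined_mask.refined:
        raise ValueError("mask must be refined by the HU window before extraction")
    m = refined_mask.mask
    if not m.any():
        raise ValueError("refined mask is empty")
    out: dict[str, float] = {}
    for sigma in sigmas:
        s = _sigma_tag(sigma)
        filtered = log_filter(image, sigma)
        vals = filtered[m]
        hist = histogram_features(vals, betas=betas)
        out[f"his_mean_{s}"] = hist["mean"]
        out[f"his_SD_{s}"] = hist["SD"]
        for beta in betas:
            b = str(int(round(beta * 100)))
            out[f"his_{b}_mean_{s}"] = hist[f"{b}_mean"]
        for beta in betas:
            b = str(int(round(beta * 100)))
            out[f"his_SD_{b}_{s}"] = hist[f"SD_{b}"]
        out[f"kurtosis_{s}"] = hist["kurtosis"]
        out[f"skewness_{s}"] = hist["skewness"]
        level_image = np.zeros(image.shape, dtype=np.int64)
        level_image[m] = quantize(vals, ng=ng)
        per_theta = {
            theta: glcm_features(glcm(level_image, m, theta=theta, ng=ng))
            for theta in thetas
        }
        for stat in ("contrast", "correlation", "entropy", "energy", "homogeneity"):
            for theta in thetas:
                out[f"{stat}_{theta}_{s}"] = per_theta[theta][stat]
    expected = feature_names(sigmas, betas, thetas)
    assert list(out) == expected and len(out) == len(expected)
    return out
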