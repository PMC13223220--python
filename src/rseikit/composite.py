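"""Per-year PCA compositing of the four normalized indices into RSEI.

The first principal component of the covariance matrix (computed over
valid pixels only; data are centred but not re-standardised) is
oriented so greenness loads positively, linearly rescaled to [0, 1] and
classified into five equal-interval quality levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from rseikit.indices import DegenerateLayerError, NormalizedIndices

INDEX_ORDER = ("ndvi", "wet", "lst", "ndbsi")
EXPECTED_SIGNS = (1, 1, -1, -1)

CLASS_NAMES = ("poor", "fair", "moderate", "good", "excellent")
#: Left-closed, right-open boundaries; the top class includes 1.0.
CLASS_EDGES = (0.2, 0.4, 0.6, 0.8)

#: Typical PC1 variance-ratio range; outside it a warning is emitted.
VARIANCE_RATIO_RANGE = (0.70, 0.85)


class SignPatternWarning(UserWarning):
    """PC1 loading signs deviate from the expected (+, +, -, -) pattern."""


class VarianceRatioWarning(UserWarning):
    """PC1 explains an unusual share of variance."""


@dataclass
class PcaResult:
    loadings: np.ndarray  # unit 4-vector, order NDVI, WET, LST, NDBSI
    eigenvalues: np.ndarray  # descending, nonnegative
    variance_ratio: float
    pc1_layer: np.ndarray
    oriented: bool
    year: int


@dataclass
class RseiResult:
    rsei_layer: np.ndarray
    class_layer: np.ndarray  # int codes 0..4 into CLASS_NAMES, -1 nodata
    pc1_min: float
    pc1_max: float
    pca: PcaResult

    @property
    def year(self) -> int:
        return self.pca.year


def pca_pc1(norm: NormalizedIndices, mask: np.ndarray | None = None) -> PcaResult:
    """Covariance-matrix PCA of the four indices; PC1 scores per pixel.

    Pixels with nodata in any index are excluded from both covariance
    estimation and scoring.
    """
    stack = norm.stack()  # (4, rows, cols)
    valid = np.isfinite(stack).all(axis=0)
    if mask is not None:
        valid &= mask
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise DegenerateLayerError(f"PCA needs >= 4 valid pixels, got {n_valid}")
    data = stack[:, valid]  # (4, n)
    cov = np.cov(data, ddof=1)
    scale = max(1.0, float(np.abs(data).max()) ** 2)
    if float(np.trace(cov)) <= 1e-20 * scale:  # numerically zero variance
        raise DegenerateLayerError("zero total variance across indices")
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order[0]]
    scores = loadings @ (data - data.mean(axis=1, keepdims=True))
    pc1 = np.full(valid.shape, np.nan)
    pc1[valid] = scores
    return PcaResult(
        loadings=loadings,
        eigenvalues=eigvals,
        variance_ratio=float(eigvals[0] / eigvals.sum()),
        pc1_layer=pc1,
        oriented=False,
        year=norm.year,
    )


def orient_loadings(pca: PcaResult) -> PcaResult:
    """Flip PC1 so the greenness loading is nonnegative.

    NDVI is the primary sign reference; WET breaks the tie if the NDVI
    loading is exactly zero.  After orientation, a sign pattern other
    than (+, +, -, -) triggers a warning but does not abort.
    """
    ref = pca.loadings[0] if pca.loadings[0] != 0 else pca.loadings[1]
    flip = ref < 0
    loadings = -pca.loadings if flip else pca.loadings.copy()
    pc1 = -pca.pc1_layer if flip else pca.pc1_layer.copy()
    signs = np.sign(loadings)
    if any(s != 0 and s != e for s, e in zip(signs, EXPECTED_SIGNS)):
        warnings.warn(
            f"year {pca.year}: oriented loading signs {signs.astype(int).tolist()} "
            f"deviate from expected {list(EXPECTED_SIGNS)}",
            SignPatternWarning,
            stacklevel=2,
        )
    return PcaResult(
        loadings=loadings,
        eigenvalues=pca.eigenvalues,
        variance_ratio=pca.variance_ratio,
        pc1_layer=pc1,
        oriented=True,
        year=pca.year,
    )


def rescale_rsei(pc1_layer: np.ndarray, robust_clip: bool = False):
    """Rescale PC1 linearly to [0, 1]: (PC1 - min) / (max - min).

    Min/max are the observed extremes over valid pixels; with
    ``robust_clip`` the 1st/99th percentiles are used instead and scores
    are clipped into [0, 1].  Returns ``(rsei, (lo, hi))``.
    """
    valid = np.isfinite(pc1_layer)
    if valid.sum() < 2:
        raise DegenerateLayerError("too few valid PC1 scores")
    vals = pc1_layer[valid]
    if robust_clip:
        lo, hi = np.percentile(vals, [1.0, 99.0])
    else:
        lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateLayerError("constant PC1 layer cannot be rescaled")
    out = np.full(pc1_layer.shape, np.nan)
    out[valid] = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    return out, (float(lo), float(hi))


def classify_rsei(rsei_layer: np.ndarray) -> np.ndarray:
    """Five-level classification of an RSEI layer.

    Intervals are left-closed, right-open ([0, 0.2), ..., [0.6, 0.8))
    except the top class [0.8, 1.0], which is closed.  Returns int codes
    0..4 indexing :data:`CLASS_NAMES`; nodata pixels get -1.
    """
    valid = np.isfinite(rsei_layer)
    codes = np.digitize(np.where(valid, rsei_layer, 0.0), CLASS_EDGES, right=False)
    codes = np.where(valid, codes, -1).astype(np.int32)
    return codes


def compose_rsei(norm: NormalizedIndices, mask: np.ndarray | None = None, robust_clip: bool = False) -> RseiResult:
    """Full per-year composite: PCA, orientation, rescale, classify."""
    pca = orient_loadings(pca_pc1(norm, mask))
    lo_hi = rescale_rsei(pca.pc1_layer, robust_clip=robust_clip)
    rsei_layer, (lo, hi) = lo_hi
    if not (VARIANCE_RATIO_RANGE[0] <= pca.variance_ratio <= VARIANCE_RATIO_RANGE[1]):
        warnings.warn(
            f"year {pca.year}: PC1 variance ratio {pca.variance_ratio:.3f} outside "
            f"typical range {VARIANCE_RATIO_RANGE}",
            VarianceRatioWarning,
            stacklevel=2,
        )
    return RseiResult(
        rsei_layer=rsei_layer,
        class_layer=classify_rsei(rsei_layer),
        pc1_min=lo,
        pc1_max=hi,
        pca=pca,
    )


def rsei_per_year(normalized_by_year: list[NormalizedIndices], mask: np.ndarray | None = None, robust_clip: bool = False) -> list[RseiResult]:
    """Independent RSEI composites for a sequence of years."""
    return [compose_rsei(norm, mask, robust_clip) for norm in normalized_by_year]
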