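"""Edge-candidate extraction for a single B-scan.

The pipeline turns a raw B-scan into a sparse map of *weighted edge
candidates* for one target layer:

1. :func:`smooth` — 3x3 boxcar averaging to knock down speckle.
2. :func:`log_zero_crossings` — zero crossings of a Laplacian-of-Gaussian
   response mark loci of locally maximal axial intensity gradient.
3. :func:`weight_zero_crossings` — each crossing is scored by the rectified
   signed vertical gradient, so crossings of the wrong polarity for the
   target layer (e.g. bright-to-dark when hunting the ILM) are suppressed.
4. :func:`link_candidates` — Canny-style hysteresis keeps weak crossings only
   when 8-connected to strong ones, and groups survivors into candidate
   segments.

The weighting scheme is deliberately simple — a rectified central-difference
gradient of the smoothed image — and is documented as an interpretation in
docs/methods.md; layer-specific behaviour enters through the
:class:`LayerProfile` polarity and thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import ParameterError, ValidationError

Polarity = Literal["dark_to_bright", "bright_to_dark"]
Band = Literal["vitreal", "posterior"]
AnchorEdge = Literal["top", "bottom"]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

#: Relative significance floor for the LoG response: magnitudes below this
#: fraction of the frame peak are treated as zero when marking crossings.
ZC_EPS = 1e-4


@dataclass(frozen=True)
class LayerProfile:
    """Layer-specific tuning of the edge pipeline and endpoint anchoring.

    polarity
        Direction of the axial reflectivity transition at the target surface
        (positive row direction points away from the vitreous).
    band
        Which high-reflectivity structure anchors source/destination
        selection: ``vitreal`` = the whole retinal bright complex seen from
        the vitreous side, ``posterior`` = the hyperreflective outer band.
    anchor_edge
        Whether the layer sits at the top or bottom edge of that band.
    log_sigma
        Scale (pixels) of the Laplacian-of-Gaussian filter.
    high_thresh, low_thresh
        Hysteresis thresholds as fractions of the per-frame maximum weight.
    """

    layer: str
    polarity: Polarity
    band: Band
    anchor_edge: AnchorEdge
    log_sigma: float = 2.0
    high_thresh: float = 0.2
    low_thresh: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.low_thresh <= self.high_thresh <= 1:
            raise ValidationError(
                "thresholds must satisfy 0 < low <= high <= 1; got "
                f"low={self.low_thresh}, high={self.high_thresh}"
            )
        if self.log_sigma <= 0:
            raise ValidationError(f"log_sigma must be > 0, got {self.log_sigma}")
        if self.polarity not in ("dark_to_bright", "bright_to_dark"):
            raise ValidationError(f"unknown polarity {self.polarity!r}")


def default_profiles() -> dict[str, LayerProfile]:
    """Per-layer defaults following standard OCT reflectivity anatomy.

    Only the ILM polarity (dark vitreous above, reflective retina below) is
    anatomically unambiguous; the outer-layer polarities and anchors are
    configurable defaults.
    """
    path = Path(__file__).parent / "data" / "default_profiles.json"
    return load_profiles(path)


def load_profiles(path: str | Path) -> dict[str, LayerProfile]:
    """Load layer profiles from a JSON config (one entry per layer)."""
    raw = json.loads(Path(path).read_text())
    profiles = {}
    for layer, entry in raw.items():
        profiles[layer] = LayerProfile(layer=layer, **entry)
    return profiles


@dataclass
class EdgeCandidateMap:
    """Weighted edge evidence plus linked candidate segments for one B-scan.

    ``weights`` is dense (0 = non-edge); ``candidates`` lists 8-connected
    segments as ``(rows, cols)`` index arrays, disjoint by construction,
    ordered by connected-component label. ``segment_ids`` maps each surviving
    pixel to its 1-based segment label (0 elsewhere).
    """

    weights: np.ndarray
    candidates: list[tuple[np.ndarray, np.ndarray]]
    segment_ids: np.ndarray
    source_image_shape: tuple[int, int]

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def candidate_mean_weight(self, index: int) -> float:
        rows, cols = self.candidates[index]
        return float(self.weights[rows, cols].mean())

    def is_candidate(self, row: int, col: int) -> bool:
        return bool(self.segment_ids[row, col] > 0)


def smooth(image: np.ndarray) -> np.ndarray:
    """3x3 boxcar average with edge replication at the borders."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ParameterError(
            f"image must be 2-D and at least 3x3, got shape {image.shape}"
        )
    return ndimage.uniform_filter(image, size=3, mode="nearest")


def log_zero_crossings(image: np.ndarray, sigma: float) -> np.ndarray:
    """Mark zero crossings of the Laplacian-of-Gaussian response.

    For every 4-neighbour pair whose responses have strictly opposite signs,
    the pixel with the smaller absolute response is marked (ties, within a
    1e-9 relative tolerance, go to the upper/left pixel). Pixels with a (numerically) zero response flanked by
    opposite signs are marked directly. Responses below ZC_EPS of the peak
    magnitude count as zero: far tails of the filter response carry no edge
    evidence, so sign flips there (including float dust) produce no
    crossings. One pixel per crossing per direction.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    return _mark_zero_crossings(log_response(image, sigma))


def _log_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """1-D Gaussian and zero-sum second-derivative-of-Gaussian kernels."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    g2 = ((x**2 - sigma**2) / sigma**4) * g
    # a Laplacian must annihilate constants exactly; the truncated kernel
    # does not quite sum to zero, which would leak the local intensity
    # level into the response and fabricate crossings in flat regions
    g2 -= g2.mean()
    return g, g2


def log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Laplacian-of-Gaussian response (separable, zero-sum kernels,
    replicated borders)."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    image = np.asarray(image, dtype=np.float64)
    g, g2 = _log_kernels(sigma)
    ryy = ndimage.correlate1d(
        ndimage.correlate1d(image, g2, axis=0, mode="nearest"),
        g, axis=1, mode="nearest",
    )
    rxx = ndimage.correlate1d(
        ndimage.correlate1d(image, g, axis=0, mode="nearest"),
        g2, axis=1, mode="nearest",
    )
    return ryy + rxx


def _mark_zero_crossings(log: np.ndarray) -> np.ndarray:
    out = np.zeros(log.shape, dtype=bool)
    absl = np.abs(log)
    tiny = ZC_EPS * absl.max()
    signed = np.where(absl <= tiny, 0.0, log)

    for axis in (0, 1):
        a = signed.take(np.arange(log.shape[axis] - 1), axis=axis)
        b = signed.take(np.arange(1, log.shape[axis]), axis=axis)
        opposite = (a * b) < 0
        abs_a = absl.take(np.arange(log.shape[axis] - 1), axis=axis)
        abs_b = absl.take(np.arange(1, log.shape[axis]), axis=axis)
        # tolerance-aware comparison: a crossing centred between two pixels
        # has |a| == |b| up to rounding; the upper/left pixel wins the tie
        first_smaller = abs_a <= abs_b + 1e-9 * np.maximum(abs_a, abs_b)
        mark_a = opposite & first_smaller
        mark_b = opposite & ~first_smaller
        if axis == 0:
            out[:-1][mark_a] = True
            out[1:][mark_b] = True
        else:
            out[:, :-1][mark_a] = True
            out[:, 1:][mark_b] = True

    # numerically-zero pixels sitting exactly between opposite signs
    zero = signed == 0
    if zero.any() and tiny > 0:
        for axis in (0, 1):
            before = np.zeros(log.shape)
            after = np.zeros(log.shape)
            if axis == 0:
                before[1:] = signed[:-1]
                after[:-1] = signed[1:]
            else:
                before[:, 1:] = signed[:, :-1]
                after[:, :-1] = signed[:, 1:]
            out |= zero & (before * after < 0)
    return out


def vertical_gradient(image: np.ndarray) -> np.ndarray:
    """Central-difference gradient along depth, positive pointing downward."""
    return np.gradient(np.asarray(image, dtype=np.float64), axis=0)


def weight_zero_crossings(
    image: np.ndarray, zc_map: np.ndarray, profile: LayerProfile
) -> np.ndarray:
    """Score zero crossings by the polarity-rectified vertical gradient.

    ``image`` should be the smoothed B-scan. Weight is ``max(0, s * g)``
    where ``g`` is the central-difference vertical gradient and ``s`` is +1
    for ``dark_to_bright``, -1 for ``bright_to_dark``; crossings whose
    gradient has the wrong sign for the target layer get weight 0.
    """
    image = np.asarray(image, dtype=np.float64)
    zc_map = np.asarray(zc_map, dtype=bool)
    if zc_map.shape != image.shape:
        raise ValidationError(
            f"zc_map shape {zc_map.shape} != image shape {image.shape}"
        )
    sign = 1.0 if profile.polarity == "dark_to_bright" else -1.0
    weights = np.maximum(0.0, sign * vertical_gradient(image))
    weights[~zc_map] = 0.0
    return weights


def link_candidates(weight_map: np.ndarray, profile: LayerProfile) -> EdgeCandidateMap:
    """Hysteresis linking of weighted crossings into candidate segments.

    A pixel survives iff its weight is at least ``low_thresh * W`` and it is
    8-connected, through pixels at or above that level, to a pixel at or
    above ``high_thresh * W``, with ``W`` the maximum weight in the map.
    Survivors are grouped into 8-connected segments. An all-zero map yields
    an empty candidate list.
    """
    weight_map = np.asarray(weight_map, dtype=np.float64)
    if weight_map.ndim != 2 or np.any(weight_map < 0):
        raise ValidationError("weight map must be 2-D and non-negative")
    w_max = weight_map.max()
    if w_max == 0:
        return EdgeCandidateMap(
            weights=np.zeros_like(weight_map),
            candidates=[],
            segment_ids=np.zeros(weight_map.shape, dtype=np.int32),
            source_image_shape=weight_map.shape,
        )
    weak = weight_map >= profile.low_thresh * w_max
    strong = weight_map >= profile.high_thresh * w_max
    labels, n = ndimage.label(weak, structure=_EIGHT)
    keep_labels = np.unique(labels[strong])
    keep_labels = keep_labels[keep_labels > 0]
    keep = np.isin(labels, keep_labels)

    weights = np.where(keep, weight_map, 0.0)
    seg_labels, n_seg = ndimage.label(keep, structure=_EIGHT)
    candidates = [
        tuple(np.nonzero(seg_labels == k)) for k in range(1, n_seg + 1)
    ]
    return EdgeCandidateMap(
        weights=weights,
        candidates=candidates,
        segment_ids=seg_labels.astype(np.int32),
        source_image_shape=weight_map.shape,
    )


def compute_candidates(image: np.ndarray, profile: LayerProfile) -> EdgeCandidateMap:
    """Full edge pipeline: smooth, LoG crossings, weighting, hysteresis."""
    smoothed = smooth(image)
    zc = log_zero_crossings(smoothed, profile.log_sigma)
    weights = weight_zero_crossings(smoothed, zc, profile)
    return link_candidates(weights, profile)
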