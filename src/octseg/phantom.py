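"""Synthetic OCT B-scan phantoms with known ground-truth boundaries.

A phantom is a stack of piecewise-constant reflectivity bands separated by
four smooth boundary curves (ILM, ISe, RPE, BM), optionally carved with
elliptical hyporeflective cystoid lesions and degraded by multiplicative
speckle (unit-mean gamma noise, the standard surrogate for averaged OCT
speckle). Rendering is 4x axially supersampled so fractional boundary
positions produce partial-volume intensities, as in real scans.

The module also simulates graders: a *manual* grader places jittered seed
points along the truth and fits the spline baseline; an *edge-select* grader
runs the interactive segmentation, inspects where the unconstrained path
errs against the truth, and adds jittered must-pass picks there — an
in-silico analogue of a three-grader reading-center study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .edges import LayerProfile, default_profiles
from .errors import ValidationError
from .io import LAYERS, GraderAnnotationSet, LayerBoundary, OCTVolume
from .pathing import ConstraintSet, CostParams, InteractiveSession
from .spline import SeedPointSet, fit_spline

#: Default band reflectivities (arbitrary units). The inner retina and the
#: sub-RPE band are chosen so that neighbouring transitions of equal polarity
#: have comparable gradient magnitude — on real scans no single boundary
#: dominates its neighbours either.
DEFAULT_REFLECTIVITY = {
    "vitreous": 15.0,
    "inner_retina": 115.0,
    "outer_band": 210.0,
    "sub_rpe": 127.0,
    "choroid": 44.0,
}


@dataclass(frozen=True)
class CystSpec:
    """Hyporeflective cystoid lesion, clipped to the ILM..BM interior.

    The outline is a superellipse: ``(|dc|/rx)**edge_exponent +
    (|dr|/ry)**2 <= 1``. The default exponent of 4 gives the steep lateral
    walls typical of cystoid spaces; 2 is a plain ellipse.
    """

    center_col: float
    center_row: float
    radius_cols: float
    radius_rows: float
    intensity: float = 45.0
    edge_exponent: float = 4.0
    #: fluid begins this many pixels below the ILM, leaving a thin
    #: reflective roof of retinal tissue over the lesion
    roof_px: float = 0.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic B-scan (or volume) with truth.

    ``truth`` maps each layer to a per-column row position (strictly ordered
    ILM < ISe < RPE < BM, inside the image). Spacings default to a
    Spectralis-like scale (3.87 um axial); everything is clearly synthetic.
    """

    shape: tuple[int, int] = (496, 512)
    truth: dict[str, np.ndarray] = field(default_factory=dict)
    reflectivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITY)
    )
    speckle_variance: float = 1.0 / 9.0
    cysts: tuple[CystSpec, ...] = ()
    seed: int = 0
    axial_spacing_um: float = 3.87
    lateral_spacing_um: float = 11.72
    frame_spacing_um: float = 91.8

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if not self.truth:
            self.truth = flat_truth_curves(self.shape)
        for layer in LAYERS:
            if layer not in self.truth:
                raise ValidationError(f"truth curve missing for layer {layer}")
            curve = np.asarray(self.truth[layer], dtype=np.float64)
            if curve.shape != (cols,):
                raise ValidationError(
                    f"truth curve for {layer} must have one value per column"
                )
            if curve.min() < 1 or curve.max() > rows - 2:
                raise ValidationError(f"truth curve for {layer} leaves the image")
            self.truth[layer] = curve
        stacked = np.stack([self.truth[l] for l in LAYERS])
        if not np.all(np.diff(stacked, axis=0) > 0):
            raise ValidationError("truth curves must satisfy ILM < ISe < RPE < BM")
        if self.speckle_variance < 0:
            raise ValidationError("speckle_variance must be >= 0")
        for cyst in self.cysts:
            # rendered interiors are clipped to [ILM, BM]; the ellipse itself
            # may overreach (a cyst opening right at the retinal surface)
            # but must intersect the retina
            c = int(np.clip(round(cyst.center_col), 0, cols - 1))
            top = cyst.center_row - cyst.radius_rows
            bottom = cyst.center_row + cyst.radius_rows
            if bottom < self.truth["ILM"][c] or top > self.truth["BM"][c]:
                raise ValidationError(
                    "cyst interior must intersect the ILM..BM band"
                )


def flat_truth_curves(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Gently curved default geometry scaled to the image height."""
    rows, cols = shape
    x = np.linspace(0, np.pi, cols)
    ilm = rows * 0.30 + 0.01 * rows * np.sin(x)
    d_ise = max(0.302 * rows, 40.0)
    d_rpe = max(0.0363 * rows, 12.0)
    d_bm = max(0.0302 * rows, 11.0)
    return {
        "ILM": ilm,
        "ISe": ilm + d_ise,
        "RPE": ilm + d_ise + d_rpe,
        "BM": ilm + d_ise + d_rpe + d_bm,
    }


def random_phantom_spec(
    seed: int,
    shape: tuple[int, int] = (496, 512),
    speckle_variance: float = 1.0 / 9.0,
    cysts: tuple[CystSpec, ...] = (),
) -> PhantomSpec:
    """Randomly perturbed smooth truth curves (slope + low-frequency waves)."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    x = np.linspace(0.0, 1.0, cols)
    base = flat_truth_curves(shape)
    tilt = rng.uniform(-0.01, 0.01) * rows * (x - 0.5)
    wave = (
        rng.uniform(0.005, 0.02)
        * rows
        * np.sin(2 * np.pi * (rng.uniform(0.5, 1.5) * x + rng.uniform(0, 1)))
    )
    offset = rng.uniform(-0.03, 0.03) * rows
    truth = {layer: base[layer] + tilt + wave + offset for layer in LAYERS}
    return PhantomSpec(
        shape=shape,
        truth=truth,
        speckle_variance=speckle_variance,
        cysts=cysts,
        seed=seed,
    )


def surface_cyst_phantom(
    shape: tuple[int, int] = (496, 512),
    seed: int = 0,
    speckle_variance: float = 0.0,
    dome_height_px: float = 120.0,
    dome_halfwidth_cols: int = 70,
    center_col: int | None = None,
) -> tuple[PhantomSpec, int]:
    """Large cystoid lesion elevating the inner retinal surface.

    The canonical failure case for unguided boundary tracing: the true ILM
    follows a domed, thin-roofed elevation over a large fluid space, while a
    strong spurious edge runs along the fluid/retina interface at the base.
    A shortest path that weighs axial excursion will shortcut across the
    base; one must-pass pick at the dome apex re-routes it over the roof.

    Returns the spec and the apex column.
    """
    rows, cols = shape
    cc = cols // 2 if center_col is None else center_col
    truth = flat_truth_curves(shape)
    x = np.arange(cols, dtype=np.float64) - cc
    dome = np.where(
        np.abs(x) <= dome_halfwidth_cols,
        0.5 * dome_height_px * (1.0 + np.cos(np.pi * x / dome_halfwidth_cols)),
        0.0,
    )
    truth["ILM"] = truth["ILM"] - dome
    base_ilm = float(flat_truth_curves(shape)["ILM"][cc])
    cyst = CystSpec(
        center_col=cc,
        center_row=base_ilm - 0.5 * dome_height_px,
        radius_cols=dome_halfwidth_cols - 4.0,
        radius_rows=0.5 * dome_height_px + 20.0,
        intensity=45.0,
        edge_exponent=4.0,
        roof_px=10.0,
    )
    spec = PhantomSpec(
        shape=shape,
        truth=truth,
        speckle_variance=speckle_variance,
        cysts=(cyst,),
        seed=seed,
    )
    return spec, cc


def _render_noiseless(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.shape
    ss = 4  # axial supersampling for partial-volume boundary pixels
    k = np.arange(rows * ss)
    r_pos = (k + 0.5) / ss - 0.5  # row coordinate of each supersample
    r_grid = r_pos[:, None]

    t = {layer: spec.truth[layer][None, :] for layer in LAYERS}
    refl = spec.reflectivity
    image = np.full((rows * ss, cols), refl["vitreous"])
    image = np.where(r_grid >= t["ILM"], refl["inner_retina"], image)
    image = np.where(r_grid >= t["ISe"], refl["outer_band"], image)
    image = np.where(r_grid >= t["RPE"], refl["sub_rpe"], image)
    image = np.where(r_grid >= t["BM"], refl["choroid"], image)

    c_grid = np.arange(cols)[None, :]
    for cyst in spec.cysts:
        ellipse = (
            (np.abs(c_grid - cyst.center_col) / cyst.radius_cols) ** cyst.edge_exponent
            + ((r_grid - cyst.center_row) / cyst.radius_rows) ** 2
        ) <= 1.0
        interior = (
            ellipse & (r_grid >= t["ILM"] + cyst.roof_px) & (r_grid <= t["BM"])
        )
        image = np.where(interior, cyst.intensity, image)

    return image.reshape(rows, ss, cols).mean(axis=1)


def generate_bscan(
    spec: PhantomSpec, frame_index: int = 0, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[LayerBoundary]]:
    """Render one B-scan and its exact ground-truth boundaries.

    Deterministic per spec seed; pass an explicit ``rng`` to draw successive
    frames of one volume from a single stream.
    """
    image = _render_noiseless(spec)
    if spec.speckle_variance > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        shape_k = 1.0 / spec.speckle_variance
        image = image * rng.gamma(shape_k, 1.0 / shape_k, size=image.shape)
    truth = [
        LayerBoundary(layer=layer, frame_index=frame_index, positions=spec.truth[layer])
        for layer in LAYERS
    ]
    return image, truth


def generate_volume(
    spec: PhantomSpec,
    n_frames: int,
    drift_px: float = 0.0,
    foveal_dip_px: float = 0.0,
) -> tuple[OCTVolume, GraderAnnotationSet]:
    """Stack B-scans with smoothly drifting truth curves.

    ``drift_px`` tilts all curves linearly across frames; ``foveal_dip_px``
    lowers the ILM toward the outer retina in a Gaussian bump centred on the
    central frame and column (minimum retinal thickness at the centre), as
    at the fovea. Truth is returned as an annotation set labelled
    ``method="truth"``.
    """
    if n_frames < 1:
        raise ValidationError(f"n_frames must be >= 1, got {n_frames}")
    rows, cols = spec.shape
    rng = np.random.default_rng(spec.seed)
    frames = []
    boundaries = []
    x = np.linspace(-1.0, 1.0, cols)
    for f in range(n_frames):
        u = 0.0 if n_frames == 1 else 2.0 * f / (n_frames - 1) - 1.0
        shift = drift_px * u
        truth_f = {layer: spec.truth[layer] + shift for layer in LAYERS}
        if foveal_dip_px > 0:
            bump = foveal_dip_px * np.exp(-(x**2) / (2 * 0.18**2)) * np.exp(
                -(u**2) / (2 * 0.35**2)
            )
            gap = truth_f["ISe"] - truth_f["ILM"]
            truth_f["ILM"] = truth_f["ILM"] + np.minimum(bump, gap - 2.0)
        frame_spec = replace(spec, truth=truth_f, speckle_variance=0.0)
        image, _ = generate_bscan(frame_spec, frame_index=f)
        if spec.speckle_variance > 0:
            shape_k = 1.0 / spec.speckle_variance
            image = image * rng.gamma(shape_k, 1.0 / shape_k, size=image.shape)
        frames.append(image)
        boundaries.extend(
            LayerBoundary(layer=layer, frame_index=f, positions=truth_f[layer])
            for layer in LAYERS
        )
    volume = OCTVolume(
        frames=np.stack(frames),
        axial_spacing_um=spec.axial_spacing_um,
        lateral_spacing_um=spec.lateral_spacing_um,
        frame_spacing_um=spec.frame_spacing_um,
        volume_id=f"phantom-{spec.seed}",
    )
    truth_set = GraderAnnotationSet(
        method="truth",
        grader_id="truth",
        boundaries=boundaries,
        volume_id=volume.volume_id,
    )
    return volume, truth_set


# ---------------------------------------------------------------------------
# grader simulation


@dataclass(frozen=True)
class GraderModel:
    """Minimal behavioural model of one grader.

    kind ``manual``: seed points every ``seed_spacing`` columns with vertical
    Gaussian jitter of ``seed_jitter_sd`` pixels, splined into a boundary.
    kind ``edgeselect``: run the unconstrained path, then add one must-pass
    pick (vertical jitter ``pick_jitter_sd``, snapped to the nearest edge
    candidate) at the centre of every span where the path errs by more than
    ``error_threshold_px``, each with probability ``pick_probability``, and
    re-route. The models exist to exercise the statistics pipeline, not to
    model human behaviour.
    """

    kind: str = "manual"
    seed_jitter_sd: float = 2.0
    seed_spacing: int = 32
    pick_jitter_sd: float = 1.0
    pick_probability: float = 1.0
    error_threshold_px: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("manual", "edgeselect"):
            raise ValidationError(f"unknown grader model kind {self.kind!r}")
        if not 0 <= self.pick_probability <= 1:
            raise ValidationError("pick_probability must be in [0, 1]")


def _erring_spans(err: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Contiguous column spans (start, stop) where |err| > threshold."""
    bad = np.isfinite(err) & (np.abs(err) > threshold)
    spans = []
    start = None
    for c, flag in enumerate(bad):
        if flag and start is None:
            start = c
        elif not flag and start is not None:
            spans.append((start, c))
            start = None
    if start is not None:
        spans.append((start, len(bad)))
    return [(a, b) for a, b in spans if b - a >= 2]


def simulate_grader(
    volume: OCTVolume,
    truth: GraderAnnotationSet,
    model: GraderModel,
    seed: int,
    grader_id: str = "g1",
    profiles: Mapping[str, LayerProfile] | None = None,
    params: CostParams = CostParams(),
) -> GraderAnnotationSet:
    """Produce one simulated grader's annotations for a whole volume."""
    rng = np.random.default_rng(seed)
    profiles = dict(profiles or default_profiles())
    rows, cols = volume.shape
    boundaries: list[LayerBoundary] = []
    for f in range(volume.n_frames):
        image = volume.frame(f)
        sessions: dict[str, InteractiveSession] = {}
        for layer in truth.layers:
            truth_pos = truth.get(layer, f).positions
            if model.kind == "manual":
                seed_cols = list(range(1, cols - 2, model.seed_spacing))
                if seed_cols[-1] != cols - 2:
                    seed_cols.append(cols - 2)
                pts = []
                for c in seed_cols:
                    row = truth_pos[c] + rng.normal(0.0, model.seed_jitter_sd)
                    pts.append((float(c), float(np.clip(row, 0.0, rows - 1.0))))
                seeds = SeedPointSet(layer=layer, frame_index=f, points=tuple(pts))
                boundaries.append(fit_spline(seeds, cols))
            else:
                session = sessions.get(layer)
                if session is None:
                    session = InteractiveSession(
                        image, profiles[layer], params=params, frame_index=f
                    )
                    sessions[layer] = session
                result = session.segment()
                err = result.boundary.positions - truth_pos
                valid = np.nonzero(np.isfinite(result.boundary.positions))[0]
                picks: list[tuple[int, int, int]] = []
                for a, b in _erring_spans(err, model.error_threshold_px):
                    if rng.random() > model.pick_probability:
                        continue
                    # keep picks strictly inside the source-destination span
                    c = int(np.clip((a + b) // 2, valid[0] + 1, valid[-1] - 1))
                    if picks and c <= picks[-1][2]:
                        continue
                    target = truth_pos[c] + rng.normal(0.0, model.pick_jitter_sd)
                    cand_rows = np.nonzero(session.candidates.segment_ids[:, c] > 0)[0]
                    if cand_rows.size == 0:
                        continue
                    row = int(cand_rows[np.argmin(np.abs(cand_rows - target))])
                    picks.append((f, row, c))
                if picks:
                    picks.sort(key=lambda p: p[2])
                    result = session.segment(ConstraintSet(must_pass=picks))
                boundaries.append(result.boundary)
    return GraderAnnotationSet(
        method=model.kind,
        grader_id=grader_id,
        boundaries=boundaries,
        volume_id=volume.volume_id,
    )
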