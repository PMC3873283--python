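"""Volume and annotation I/O for OCT raster scans.

This module owns the coordinate and unit conventions used everywhere else in
the package:

* A B-scan is a 2-D array with **rows = axial depth** (row 0 on the vitreous
  side, matching the usual OCT display with the vitreous at the top) and
  **columns = lateral position** (one A-scan per column).
* Boundary positions are 0-based fractional row indices, stored in pixels.
  Conversion to micrometres happens only at reporting time via the per-volume
  axial spacing — no device constant is hard-coded.
* Intensities are handled as floating point regardless of the stored bit
  depth, because downstream filtering needs signed arithmetic.

Supported containers: DICOM ophthalmic tomography (OPT) for real volumes,
a multi-page TIFF stack with a JSON sidecar for fixtures, and a plain JSON
format for very small volumes. Pixel-spacing metadata is *required*: a file
without it raises :class:`~octseg.errors.MetadataError` rather than assuming
a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import (
    BoundsError,
    FormatError,
    MetadataError,
    ValidationError,
)

#: Retinal surfaces this package segments, in anatomical (inner-to-outer) order:
#: inner limiting membrane, inner segment/ellipsoid interface, retina/RPE
#: interface, Bruch's membrane.
LAYERS: tuple[str, ...] = ("ILM", "ISe", "RPE", "BM")

VolumeFormat = Literal["dicom_opt", "tiff_stack", "raw_json"]

_ANNOTATION_SCHEMA = "octseg-annotations-v1"


@dataclass
class OCTVolume:
    """A stack of B-scans with physical pixel spacing.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; rows are axial depth,
        columns lateral position. Stored as float64.
    axial_spacing_um, lateral_spacing_um, frame_spacing_um
        Micrometres per pixel along depth, along a B-scan, and between
        adjacent B-scans. All must be strictly positive.
    volume_id
        Opaque identifier used to pair annotations with volumes.
    """

    frames: np.ndarray
    axial_spacing_um: float
    lateral_spacing_um: float
    frame_spacing_um: float
    volume_id: str = "volume"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValidationError(
                f"frames must be (n_frames, rows, cols); got ndim={frames.ndim}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValidationError("intensities must be finite")
        if frames.min() < 0:
            raise ValidationError("intensities must be non-negative")
        for name in ("axial_spacing_um", "lateral_spacing_um", "frame_spacing_um"):
            value = float(getattr(self, name))
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")
            setattr(self, name, value)
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of each B-scan."""
        return self.frames.shape[1], self.frames.shape[2]

    def frame(self, index: int) -> np.ndarray:
        if not 0 <= index < self.n_frames:
            raise BoundsError(f"frame index {index} out of range [0, {self.n_frames})")
        return self.frames[index]

    def __eq__(self, other: object) -> bool:  # value semantics for round trips
        if not isinstance(other, OCTVolume):
            return NotImplemented
        return (
            self.frames.shape == other.frames.shape
            and np.array_equal(self.frames, other.frames)
            and self.axial_spacing_um == other.axial_spacing_um
            and self.lateral_spacing_um == other.lateral_spacing_um
            and self.frame_spacing_um == other.frame_spacing_um
            and self.volume_id == other.volume_id
        )


@dataclass
class LayerBoundary:
    """One axial position (fractional pixels) per image column for one layer.

    ``positions[c]`` is meaningful only where ``valid_mask[c]`` is True;
    invalid columns carry NaN.
    """

    layer: str
    frame_index: int
    positions: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        positions = np.asarray(self.positions, dtype=np.float64)
        if positions.ndim != 1:
            raise ValidationError("positions must be 1-D (one value per column)")
        if self.valid_mask is None:
            mask = np.isfinite(positions)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
        if mask.shape != positions.shape:
            raise ValidationError("valid_mask must match positions in length")
        if not np.all(np.isfinite(positions[mask])):
            raise ValidationError("valid positions must be finite")
        if np.any(positions[mask] < 0):
            raise ValidationError("valid positions must be >= 0")
        positions = positions.copy()
        positions[~mask] = np.nan
        self.positions = positions
        self.valid_mask = mask
        self.frame_index = int(self.frame_index)

    @property
    def width(self) -> int:
        return self.positions.shape[0]

    def check_against_image(self, rows: int, cols: int) -> None:
        """Validate the boundary against an image geometry."""
        if self.width != cols:
            raise ValidationError(
                f"boundary width {self.width} != image width {cols}"
            )
        valid = self.positions[self.valid_mask]
        if valid.size and (valid.max() > rows - 1):
            raise ValidationError("boundary positions exceed image height")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayerBoundary):
            return NotImplemented
        if self.layer != other.layer or self.frame_index != other.frame_index:
            return False
        if not np.array_equal(self.valid_mask, other.valid_mask):
            return False
        return bool(
            np.array_equal(
                self.positions[self.valid_mask], other.positions[other.valid_mask]
            )
        )


@dataclass
class GraderAnnotationSet:
    """All boundaries one grader produced on one volume with one method."""

    method: str
    grader_id: str
    boundaries: list[LayerBoundary] = field(default_factory=list)
    volume_id: str = "volume"

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for b in self.boundaries:
            key = (b.layer, b.frame_index)
            if key in seen:
                raise ValidationError(f"duplicate boundary for layer/frame {key}")
            seen.add(key)

    def get(self, layer: str, frame_index: int) -> LayerBoundary:
        for b in self.boundaries:
            if b.layer == layer and b.frame_index == frame_index:
                return b
        raise KeyError((layer, frame_index))

    def has(self, layer: str, frame_index: int) -> bool:
        return any(
            b.layer == layer and b.frame_index == frame_index for b in self.boundaries
        )

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(sorted({b.layer for b in self.boundaries}, key=LAYERS.index))

    @property
    def frame_indices(self) -> tuple[int, ...]:
        return tuple(sorted({b.frame_index for b in self.boundaries}))


# ---------------------------------------------------------------------------
# volume I/O


def boundary_to_physical(boundary: LayerBoundary, volume: OCTVolume) -> np.ndarray:
    """Convert boundary positions from pixels to micrometres of depth.

    Invalid columns propagate as NaN. Linear in the axial spacing.
    """
    if not 0 <= boundary.frame_index < volume.n_frames:
        raise BoundsError(
            f"boundary frame {boundary.frame_index} outside volume with "
            f"{volume.n_frames} frames"
        )
    out = boundary.positions * volume.axial_spacing_um
    out[~boundary.valid_mask] = np.nan
    return out


def read_volume(path: str | Path, format: VolumeFormat) -> OCTVolume:
    """Read an :class:`OCTVolume`, validating geometry and required metadata."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "dicom_opt":
        return _read_dicom_opt(path)
    if format == "tiff_stack":
        return _read_tiff_stack(path)
    if format == "raw_json":
        return _read_raw_json(path)
    raise FormatError(f"unknown volume format {format!r}")


def write_volume(volume: OCTVolume, path: str | Path, format: VolumeFormat) -> None:
    """Write ``volume`` so that :func:`read_volume` round-trips it exactly.

    DICOM OPT output requires integer-valued intensities in [0, 65535]
    (the container stores 16-bit pixels); TIFF and JSON are lossless for any
    float volume.
    """
    path = Path(path)
    if format == "dicom_opt":
        _write_dicom_opt(volume, path)
    elif format == "tiff_stack":
        _write_tiff_stack(volume, path)
    elif format == "raw_json":
        _write_raw_json(volume, path)
    else:
        raise FormatError(f"unknown volume format {format!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_tiff_stack(volume: OCTVolume, path: Path) -> None:
    import tifffile

    try:
        tifffile.imwrite(path, volume.frames.astype(np.float64))
    except OSError as exc:
        raise OSError(f"cannot write TIFF stack to {path}: {exc}") from exc
    meta = {
        "volume_id": volume.volume_id,
        "axial_spacing_um": volume.axial_spacing_um,
        "lateral_spacing_um": volume.lateral_spacing_um,
        "frame_spacing_um": volume.frame_spacing_um,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_tiff_stack(path: Path) -> OCTVolume:
    import tifffile

    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"missing spacing sidecar {sidecar.name}; pixel spacing is required"
        )
    meta = json.loads(sidecar.read_text())
    try:
        return OCTVolume(
            frames=np.asarray(frames, dtype=np.float64),
            axial_spacing_um=meta["axial_spacing_um"],
            lateral_spacing_um=meta["lateral_spacing_um"],
            frame_spacing_um=meta["frame_spacing_um"],
            volume_id=meta.get("volume_id", path.stem),
        )
    except KeyError as exc:
        raise MetadataError(f"sidecar missing required key: {exc}") from exc


def _write_raw_json(volume: OCTVolume, path: Path) -> None:
    payload = {
        "schema": "octseg-volume-v1",
        "volume_id": volume.volume_id,
        "axial_spacing_um": volume.axial_spacing_um,
        "lateral_spacing_um": volume.lateral_spacing_um,
        "frame_spacing_um": volume.frame_spacing_um,
        "frames": volume.frames.tolist(),
    }
    path.write_text(json.dumps(payload))


def _read_raw_json(path: Path) -> OCTVolume:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {path}: {exc}") from exc
    for key in ("axial_spacing_um", "lateral_spacing_um", "frame_spacing_um"):
        if key not in payload:
            raise MetadataError(f"volume JSON missing required {key}")
    frames = payload.get("frames")
    if frames is None:
        raise FormatError("volume JSON missing 'frames'")
    arr = [np.asarray(f, dtype=np.float64) for f in frames]
    if len({a.shape for a in arr}) > 1:
        raise ValidationError("frames have inconsistent dimensions")
    return OCTVolume(
        frames=np.stack(arr),
        axial_spacing_um=payload["axial_spacing_um"],
        lateral_spacing_um=payload["lateral_spacing_um"],
        frame_spacing_um=payload["frame_spacing_um"],
        volume_id=payload.get("volume_id", path.stem),
    )


# DICOM ophthalmic tomography (OPT). Read support targets the minimal
# attribute set: Rows, Columns, NumberOfFrames, PixelData and pixel spacing
# (either in the shared functional groups' Pixel Measures sequence, the
# standard location for enhanced multi-frame objects, or at top level).
# Only uncompressed little-endian transfer syntaxes are accepted.

_OPT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.77.1.5.4"
_ACCEPTED_TRANSFER_SYNTAXES = {
    "1.2.840.10008.1.2",  # implicit VR little endian
    "1.2.840.10008.1.2.1",  # explicit VR little endian
}


def _read_dicom_opt(path: Path) -> OCTVolume:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    tsuid = str(getattr(ds.file_meta, "TransferSyntaxUID", ""))
    if tsuid and tsuid not in _ACCEPTED_TRANSFER_SYNTAXES:
        raise FormatError(
            f"unsupported DICOM transfer syntax {tsuid}; only uncompressed "
            "little-endian OPT objects are supported"
        )
    try:
        pixels = ds.pixel_array.astype(np.float64)
    except Exception as exc:
        raise FormatError(f"cannot decode pixel data in {path}: {exc}") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]

    axial_mm = lateral_mm = frame_mm = None
    sfg = getattr(ds, "SharedFunctionalGroupsSequence", None)
    if sfg:
        pms = getattr(sfg[0], "PixelMeasuresSequence", None)
        if pms:
            spacing = getattr(pms[0], "PixelSpacing", None)
            if spacing is not None:
                axial_mm, lateral_mm = float(spacing[0]), float(spacing[1])
            sbs = getattr(pms[0], "SpacingBetweenSlices", None)
            if sbs is not None:
                frame_mm = float(sbs)
    if axial_mm is None and getattr(ds, "PixelSpacing", None) is not None:
        axial_mm, lateral_mm = (float(v) for v in ds.PixelSpacing)
    if frame_mm is None and getattr(ds, "SpacingBetweenSlices", None) is not None:
        frame_mm = float(ds.SpacingBetweenSlices)
    if axial_mm is None or lateral_mm is None:
        raise MetadataError(f"DICOM file {path} carries no PixelSpacing")
    if frame_mm is None:
        raise MetadataError(f"DICOM file {path} carries no SpacingBetweenSlices")

    return OCTVolume(
        frames=pixels,
        axial_spacing_um=axial_mm * 1000.0,
        lateral_spacing_um=lateral_mm * 1000.0,
        frame_spacing_um=frame_mm * 1000.0,
        volume_id=str(getattr(ds, "SeriesInstanceUID", path.stem)),
    )


def _write_dicom_opt(volume: OCTVolume, path: Path) -> None:
    """Write a minimal OPT object (16-bit, explicit VR little endian).

    Intended for fixtures and interchange; intensities must be integral and
    fit in 16 bits, which is what OCT devices export.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    frames = volume.frames
    if not np.array_equal(frames, np.round(frames)) or frames.max() > 65535:
        raise ValidationError(
            "DICOM OPT output stores 16-bit integers; intensities must be "
            "integral and <= 65535 (use tiff_stack for float volumes)"
        )

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(_OPT_SOP_CLASS)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = volume.volume_id if volume.volume_id else generate_uid()
    ds.Modality = "OPT"
    ds.Rows, ds.Columns = volume.shape
    ds.NumberOfFrames = volume.n_frames
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0

    pms = Dataset()
    pms.PixelSpacing = [volume.axial_spacing_um / 1000.0, volume.lateral_spacing_um / 1000.0]
    pms.SpacingBetweenSlices = volume.frame_spacing_um / 1000.0
    sfg = Dataset()
    sfg.PixelMeasuresSequence = [pms]
    ds.SharedFunctionalGroupsSequence = [sfg]

    ds.PixelData = frames.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# annotation I/O (documented plain-JSON schema, see README)


def write_annotations(annotations: GraderAnnotationSet, path: str | Path) -> None:
    path = Path(path)
    records = []
    for b in sorted(annotations.boundaries, key=lambda b: (b.frame_index, LAYERS.index(b.layer))):
        positions = [
            float(p) if ok else None
            for p, ok in zip(b.positions, b.valid_mask)
        ]
        records.append(
            {
                "layer": b.layer,
                "frame_index": b.frame_index,
                "positions": positions,
                "valid_mask": [bool(v) for v in b.valid_mask],
            }
        )
    payload = {
        "schema": _ANNOTATION_SCHEMA,
        "method": annotations.method,
        "grader_id": annotations.grader_id,
        "volume_id": annotations.volume_id,
        "boundaries": records,
    }
    path.write_text(json.dumps(payload))


def read_annotations(
    path: str | Path, image_width: int | None = None
) -> GraderAnnotationSet:
    """Load an annotation set, optionally validating against a declared width."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {path}: {exc}") from exc
    for key in ("method", "grader_id", "boundaries"):
        if key not in payload:
            raise FormatError(f"annotation file missing required key {key!r}")
    boundaries = []
    for rec in payload["boundaries"]:
        for key in ("layer", "frame_index", "positions"):
            if key not in rec:
                raise FormatError(f"annotation record missing required key {key!r}")
        positions = np.array(
            [np.nan if p is None else float(p) for p in rec["positions"]],
            dtype=np.float64,
        )
        mask = rec.get("valid_mask")
        mask = None if mask is None else np.asarray(mask, dtype=bool)
        if image_width is not None and positions.shape[0] != image_width:
            raise ValidationError(
                f"positions length {positions.shape[0]} != declared image width "
                f"{image_width} for layer {rec['layer']}"
            )
        boundaries.append(
            LayerBoundary(
                layer=rec["layer"],
                frame_index=rec["frame_index"],
                positions=positions,
                valid_mask=mask,
            )
        )
    return GraderAnnotationSet(
        method=payload["method"],
        grader_id=payload["grader_id"],
        boundaries=boundaries,
        volume_id=payload.get("volume_id", "volume"),
    )
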