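"""Voxel volumes, anatomical orientation, and cubic VOI extraction.

Axis convention
---------------
Volumes are stored as 3-D arrays with a fixed anatomical mapping:

* axis 0 — slice order, proximal (low index) to distal (high index);
* axis 1 — image vertical;
* axis 2 — image horizontal, anterior at low index.

For right bones (or mirrored left bones) the medial side therefore sits at a
consistent end of axis 2, so that fabric eigenvector components are
comparable across specimens.  Left bones must be mirrored exactly once;
:func:`mirror_left_bone` enforces this through the ``side`` flag.

Cubic volumes of interest (VOIs) are centred in an articular structure and
grown symmetrically as large as possible while staying inside a trabecular
compartment mask, i.e. without touching cortical bone.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelVolume",
    "AnatomicalLandmarks",
    "VOISelection",
    "STRUCTURE_LANDMARKS",
    "read_volume",
    "write_volume",
    "mirror_left_bone",
    "locate_voi_centre",
    "extract_cubic_voi",
    "MIN_VOI_EDGE",
]

#: Smallest usable cube edge, in voxels.  Below this a VOI contains only a
#: few trabeculae and is rejected rather than measured.
MIN_VOI_EDGE = 16


@dataclass
class VoxelVolume:
    """A 3-D scalar or binary grid with isotropic spacing.

    Parameters
    ----------
    data:
        3-D array; integer intensities or boolean/binary.
    spacing:
        Isotropic voxel edge length in micrometres.
    side:
        ``"left"`` or ``"right"``; anatomical side of the scanned bone.
    """

    data: np.ndarray
    spacing: float
    side: str = "right"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 2, got {self.data.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_binary(self) -> bool:
        return self.data.dtype == bool or len(np.unique(self.data)) <= 2


@dataclass
class AnatomicalLandmarks:
    """Named landmark coordinates for one articular structure.

    Coordinates are 0-based ``[z, y, x]`` voxel indices in the parent
    volume's axis convention.
    """

    structure: str
    landmarks: dict[str, tuple[int, int, int]]
    side: str = "right"

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURE_LANDMARKS:
            raise ValueError(
                f"unknown structure {self.structure!r}; expected one of "
                f"{sorted(STRUCTURE_LANDMARKS)}"
            )
        required = STRUCTURE_LANDMARKS[self.structure]
        missing = sorted(set(required) - set(self.landmarks))
        if missing:
            raise ValueError(
                f"structure {self.structure!r} is missing required "
                f"landmark(s): {', '.join(missing)}"
            )
        self.landmarks = {k: tuple(int(c) for c in v) for k, v in self.landmarks.items()}

    @classmethod
    def from_json(cls, path: str | Path) -> "AnatomicalLandmarks":
        payload = json.loads(Path(path).read_text())
        return cls(
            structure=payload["structure"],
            landmarks={k: tuple(v) for k, v in payload["landmarks"].items()},
            side=payload.get("side", "right"),
        )

    def digest(self) -> str:
        blob = json.dumps(
            {"structure": self.structure, "landmarks": {k: list(v) for k, v in sorted(self.landmarks.items())}},
            sort_keys=True,
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# Required landmark sets per articular structure.  The first two define the
# proximodistal extent; the rest bound the articular surface in-slice and
# are reduced to a bounding-box midpoint.
STRUCTURE_LANDMARKS: dict[str, tuple[str, ...]] = {
    "humeral_head": (
        "proximal_most",
        "distal_most",
        "anterolateral_corner",
        "medial_most",
        "posterior_most",
    ),
    "humeral_trochlea": (
        "proximal_most",
        "distal_most",
        "anterolateral_corner",
        "anteromedial_corner",
        "posterior_most",
    ),
    "femoral_head": (
        "proximal_most",
        "distal_most",
        "anterior_border",
        "medial_border",
        "posterior_border",
        "lateral_concavity",
    ),
    "femoral_lateral_condyle": (
        "proximal_most",
        "distal_most",
        "patellar_surface",
        "posterior_articular",
        "intercondylar_notch",
        "lateral_most",
    ),
}


@dataclass
class VOISelection:
    """Provenance record for an extracted cubic VOI."""

    centre: tuple[int, int, int]
    edge: int
    structure: str = ""
    landmark_digest: str = ""

    def __post_init__(self) -> None:
        if self.edge % 2 != 1:
            raise ValueError(f"VOI edge must be odd, got {self.edge}")


# ---------------------------------------------------------------------------
# I/O


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return data


def _read_dicom_dir(path: Path) -> tuple[np.ndarray, float | None]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".dicom"))
    if not files:
        raise FileNotFoundError(f"no DICOM slices found in {path}")
    datasets = [pydicom.dcmread(str(p)) for p in files]
    datasets.sort(key=lambda d: int(d.InstanceNumber))
    indices = [int(d.InstanceNumber) for d in datasets]
    full = range(indices[0], indices[-1] + 1)
    gaps = sorted(set(full) - set(indices))
    if gaps:
        raise ValueError(f"DICOM series has missing slice index(es): {gaps}")
    spacing = None
    if hasattr(datasets[0], "PixelSpacing"):
        px = [float(v) for v in datasets[0].PixelSpacing]
        thickness = float(getattr(datasets[0], "SliceThickness", px[0]))
        vals = px + [thickness]
        if max(vals) - min(vals) > 1e-9 * max(vals):
            raise ValueError(
                f"anisotropic voxel spacing in DICOM metadata: {vals}; cubic voxels required"
            )
        spacing = px[0] * 1000.0  # PixelSpacing is in mm
    return np.stack([d.pixel_array for d in datasets]), spacing


def _read_raw(path: Path) -> tuple[np.ndarray, float, str]:
    header = json.loads(path.with_suffix(".json").read_text())
    dtype = np.dtype(header.get("dtype", "uint8"))
    shape = tuple(header["shape"])
    data = np.fromfile(path, dtype=dtype).reshape(shape)
    return data, float(header["spacing_um"]), header.get("side", "right")


def read_volume(
    path: str | Path,
    spacing_override: float | None = None,
    side: str = "right",
) -> VoxelVolume:
    """Read a TIFF stack, DICOM series directory, or raw+JSON-header pair.

    Slices are assembled in ascending proximodistal order.  Spacing (µm) is
    taken from file metadata when present, unless ``spacing_override`` is
    given.  A missing DICOM slice or anisotropic metadata spacing raises.
    """
    path = Path(path)
    spacing = spacing_override
    if path.is_dir():
        data, meta_spacing = _read_dicom_dir(path)
        spacing = spacing if spacing is not None else meta_spacing
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = _read_tiff(path)
    elif path.suffix.lower() == ".raw":
        data, meta_spacing, side = _read_raw(path)
        spacing = spacing if spacing is not None else meta_spacing
    else:
        raise ValueError(f"unsupported volume format: {path}")
    if spacing is None:
        raise ValueError(f"no spacing in metadata for {path}; pass spacing_override")
    return VoxelVolume(data=data, spacing=float(spacing), side=side)


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF or a raw+JSON pair."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = vol.data.astype(np.uint8) if vol.data.dtype == bool else vol.data
        tifffile.imwrite(str(path), data)
    elif path.suffix.lower() == ".raw":
        vol.data.tofile(path)
        header = {
            "shape": list(vol.data.shape),
            "dtype": str(vol.data.dtype),
            "spacing_um": vol.spacing,
            "side": vol.side,
        }
        path.with_suffix(".json").write_text(json.dumps(header))
    else:
        raise ValueError(f"unsupported output format: {path}")


# ---------------------------------------------------------------------------
# Orientation


def mirror_left_bone(vol: VoxelVolume) -> VoxelVolume:
    """Mirror a left bone to right-bone orientation.

    Reverses the medial-lateral (horizontal) axis and flips the side flag.
    Mirroring an already-right volume raises: double mirroring silently
    scrambles the eigenvector sign convention downstream.
    """
    if vol.side != "left":
        raise ValueError("refusing to mirror a right-side volume")
    return replace(vol, data=vol.data[:, :, ::-1].copy(), side="right")


# ---------------------------------------------------------------------------
# VOI placement


def _mid(a: float, b: float) -> int:
    # midpoint with halves rounded down, for determinism
    return int(np.floor((a + b) / 2.0))


def locate_voi_centre(landmarks: AnatomicalLandmarks) -> tuple[int, int, int]:
    """Locate the VOI centre from anatomical landmarks.

    The slice index is the midpoint of the proximal-most and distal-most
    landmark slices; the in-slice position is the midpoint of the bounding
    box of the structure's remaining (edge) landmarks.  Midpoints at ``.5``
    round down.
    """
    pts = landmarks.landmarks
    z0, z1 = pts["proximal_most"][0], pts["distal_most"][0]
    if z0 == z1:
        raise ValueError(
            "proximal-most and distal-most landmarks collapse to a single "
            "slice; the articular surface has no proximodistal extent"
        )
    edge_names = [n for n in STRUCTURE_LANDMARKS[landmarks.structure] if n not in ("proximal_most", "distal_most")]
    ys = [pts[n][1] for n in edge_names]
    xs = [pts[n][2] for n in edge_names]
    return (_mid(z0, z1), _mid(min(ys), max(ys)), _mid(min(xs), max(xs)))


def _cube_fits(mask: np.ndarray, centre: tuple[int, int, int], half: int) -> bool:
    lo = [c - half for c in centre]
    hi = [c + half + 1 for c in centre]
    if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, mask.shape)):
        return False
    return bool(mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].all())


def extract_cubic_voi(
    vol: VoxelVolume,
    centre: tuple[int, int, int],
    trabecular_mask: np.ndarray | None = None,
    edge: int | None = None,
    structure: str = "",
    landmark_digest: str = "",
    min_edge: int = MIN_VOI_EDGE,
) -> tuple[VoxelVolume, VOISelection]:
    """Extract the largest centred cube inside the trabecular compartment.

    With a mask, the cube is grown symmetrically from ``centre`` one voxel
    layer at a time; growth stops at the first face protruding outside the
    mask, so the result never contains a non-mask voxel.  With a fixed
    ``edge`` (odd) the cube is cropped directly.  Cubes smaller than
    :data:`MIN_VOI_EDGE` voxels are rejected as unusable — they would hold
    only a few trabeculae.
    """
    centre = tuple(int(c) for c in centre)
    if (trabecular_mask is None) == (edge is None):
        raise ValueError("provide exactly one of trabecular_mask or edge")
    if trabecular_mask is not None:
        mask = np.asarray(trabecular_mask, dtype=bool)
        if mask.shape != vol.data.shape:
            raise ValueError("mask shape must match volume shape")
        if not mask[centre]:
            raise ValueError(f"VOI centre {centre} lies outside the trabecular mask")
        half = 0
        while _cube_fits(mask, centre, half + 1):
            half += 1
        edge = 2 * half + 1
    else:
        if edge % 2 != 1:
            raise ValueError(f"fixed edge must be odd, got {edge}")
    if edge < min_edge:
        raise ValueError(
            f"VOI edge {edge} voxels is below the usable minimum "
            f"({min_edge}); the VOI would contain only a few trabeculae"
        )
    half = edge // 2
    lo = [c - half for c in centre]
    hi = [c + half + 1 for c in centre]
    if any(l < 0 for l in lo) or any(h > s for h, s in zip(hi, vol.data.shape)):
        raise ValueError(f"cube edge {edge} at centre {centre} exceeds the volume")
    sub = vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy()
    selection = VOISelection(centre=centre, edge=edge, structure=structure, landmark_digest=landmark_digest)
    return replace(vol, data=sub), selection
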