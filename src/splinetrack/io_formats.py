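"""Domain containers and file I/O for diffusion MRI data.

Volumes and masks are NIfTI-1 (read through nibabel), gradient tables are
FSL-style whitespace-delimited ``bval``/``bvec`` text files, and tractograms
are TrackVis ``.trk`` v2 files.

Coordinate conventions
----------------------
Fiber points are kept in *continuous voxel coordinates*: integer values sit
at voxel centers of the source DWI grid.  This is the natural frame for the
tracking math (nearest-voxel FA and ODF lookups).  Conversion to the .trk
world convention happens only at (de)serialization, through the volume
affine, so files interoperate with TrackVis regardless of RAS/LPS voxel
order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Field as TrkField
from nibabel.streamlines.trk import TrkFile

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: b-values closer to zero than this (s/mm^2) count as unweighted volumes;
#: scanners routinely report small nonzero values for b=0 acquisitions.
B0_THRESHOLD = 50.0


@dataclass
class GradientTable:
    """Diffusion-sensitizing scheme: one b-value and unit direction per volume.

    Zero vectors are permitted (and expected) for b=0 entries.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValidationError(f"bvecs must be (G, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} directions"
            )
        if not np.any(self.b0_mask):
            raise ValidationError("gradient table has no b=0 entry")
        norms = np.linalg.norm(self.bvecs, axis=1)
        weighted = ~self.b0_mask
        bad = weighted & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise ValidationError(
                f"non-unit bvec(s) at indices {np.flatnonzero(bad).tolist()} "
                f"(norms {norms[bad].round(4).tolist()})"
            )
        # snap to exact unit length so downstream dot products are clean
        self.bvecs = self.bvecs.copy()
        self.bvecs[weighted] /= norms[weighted, None]

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted acquisition with its gradient table."""

    signal: np.ndarray  # (X, Y, Z, G), arbitrary units, >= 0
    affine: np.ndarray  # 4x4 voxel -> world (mm)
    gradient_table: GradientTable
    voxel_size: np.ndarray | None = None  # (3,) mm; derived from affine if None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != len(self.gradient_table):
            raise FormatError(
                f"volume has {self.signal.shape[3]} gradients but gradient "
                f"table has {len(self.gradient_table)} entries"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValidationError("signal contains negative values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if self.voxel_size is None:
            self.voxel_size = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def s0(self) -> np.ndarray:
        """Mean unweighted (b=0) volume."""
        return self.signal[..., self.gradient_table.b0_mask].mean(axis=3)

    def voxel_to_world(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class Fiber:
    """An ordered 3-D polyline in continuous voxel coordinates, with
    optional per-point scalar channels (e.g. sampled FA)."""

    points: np.ndarray  # (n, 3)
    scalars: dict[str, np.ndarray] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(f"fiber points must be (n, 3), got {self.points.shape}")
        if len(self.points) < 2:
            raise ValidationError("fiber needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("fiber contains non-finite points")
        for name, vals in self.scalars.items():
            vals = np.asarray(vals, dtype=float)
            if len(vals) != len(self.points):
                raise ValidationError(
                    f"scalar channel {name!r} has {len(vals)} values for "
                    f"{len(self.points)} points"
                )
            self.scalars[name] = vals

    @classmethod
    def from_points(cls, points: np.ndarray, **kw) -> "Fiber":
        """Construct after collapsing consecutive duplicate points."""
        points = np.asarray(points, dtype=float)
        keep = np.ones(len(points), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-12
        return cls(points[keep], **kw)

    def __len__(self) -> int:
        return len(self.points)

    def length(self, voxel_size=1.0) -> float:
        """Polyline arc length; pass the voxel size to get millimetres."""
        steps = np.diff(self.points * np.asarray(voxel_size, dtype=float), axis=0)
        return float(np.linalg.norm(steps, axis=1).sum())

    def reversed(self) -> "Fiber":
        return Fiber(
            self.points[::-1].copy(),
            {k: v[::-1].copy() for k, v in self.scalars.items()},
            set(self.flags),
        )


@dataclass
class Tractogram:
    """A collection of fibers sharing one voxel grid."""

    fibers: list[Fiber]
    affine: np.ndarray
    voxel_size: np.ndarray
    space_tag: str = "voxel"

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)


# ---------------------------------------------------------------------------
# readers / writers


def _load_gradient_text(path, n_rows_expected: int | None = None) -> np.ndarray:
    try:
        arr = np.loadtxt(path, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - report as format problem
        raise FormatError(f"could not parse gradient file {path}: {exc}") from exc
    return arr


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4-D NIfTI volume with its FSL-style bval/bvec files.

    bvec files are accepted in both 3xG (FSL row-major) and Gx3 layouts,
    auto-detected from shape.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected 4-D volume, got shape {data.shape}")
    n_vols = data.shape[3]

    bvals = _load_gradient_text(bval_path).ravel()
    bvecs = _load_gradient_text(bvec_path)
    if bvecs.shape == (3, len(bvals)) and bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise FormatError(
            f"bvec shape {bvecs.shape} inconsistent with {len(bvals)} b-values"
        )
    if len(bvals) != n_vols:
        raise FormatError(
            f"gradient table has {len(bvals)} entries but volume has {n_vols} gradients"
        )
    gtab = GradientTable(bvals, bvecs)
    # negative values can appear from interpolation; clip tiny undershoot
    data = np.clip(data, 0.0, None)
    vol = DWIVolume(data, img.affine, gtab)
    logger.info(
        "read %s: shape %s, %d b0 volume(s), %d weighted direction(s)",
        nifti_path, data.shape, int(gtab.b0_mask.sum()), int(gtab.dwi_mask.sum()),
    )
    return vol


def write_dwi(vol: DWIVolume, nifti_path, bval_path=None, bvec_path=None) -> None:
    nib.save(nib.Nifti1Image(vol.signal.astype(np.float32), vol.affine), str(nifti_path))
    if bval_path is not None:
        np.savetxt(str(bval_path), vol.gradient_table.bvals[None, :], fmt="%.1f")
    if bvec_path is not None:
        np.savetxt(str(bvec_path), vol.gradient_table.bvecs.T, fmt="%.8f")


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.asarray(affine, float)), str(path))


def read_mask(nifti_path, reference: DWIVolume) -> np.ndarray:
    """Load a binary ROI/seed mask on the reference grid.

    Any nonzero voxel is foreground.  The mask grid must match the reference
    spatial shape exactly; no resampling is attempted.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    if data.shape != reference.spatial_shape:
        raise FormatError(
            f"mask shape {data.shape} does not match reference shape "
            f"{reference.spatial_shape}"
        )
    mask = data != 0
    logger.info("read mask %s: %d foreground voxel(s)", nifti_path, int(mask.sum()))
    return mask


def write_tractogram(tractogram: Tractogram, path) -> None:
    """Write a TrackVis .trk v2 file.

    Points are converted from voxel coordinates to world (RAS mm) through the
    tractogram affine; per-point scalar channels are preserved.
    """
    if len(tractogram) == 0:
        warnings.warn("writing an empty tractogram", stacklevel=2)
    for f in tractogram.fibers:
        if len(f) < 2:
            raise ValidationError("tractogram contains a fiber with < 2 points")

    A = tractogram.affine
    streamlines = [f.points @ A[:3, :3].T + A[:3, 3] for f in tractogram.fibers]
    scalar_names = sorted({n for f in tractogram.fibers for n in f.scalars})
    data_per_point = {}
    for name in scalar_names:
        chans = []
        for f in tractogram.fibers:
            if name not in f.scalars:
                raise ValidationError(
                    f"scalar channel {name!r} missing on some fibers"
                )
            chans.append(f.scalars[name][:, None].astype(np.float32))
        data_per_point[name] = chans

    nib_tract = nib.streamlines.Tractogram(
        streamlines, data_per_point=data_per_point, affine_to_rasmm=np.eye(4)
    )
    hdr = {
        TrkField.VOXEL_TO_RASMM: A.astype(np.float32),
        TrkField.VOXEL_SIZES: tractogram.voxel_size.astype(np.float32),
        TrkField.VOXEL_ORDER: "".join(nib.aff2axcodes(A)),
    }
    TrkFile(nib_tract, header=hdr).save(str(path))


def read_tractogram(path) -> Tractogram:
    """Read a TrackVis .trk file back into voxel coordinates."""
    try:
        trk = TrkFile.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not read trk file {path}: {exc}") from exc
    A = np.asarray(trk.header[TrkField.VOXEL_TO_RASMM], dtype=float)
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:  # legacy files with zero affine
        A = np.eye(4)
    inv = np.linalg.inv(A)
    voxel_size = np.asarray(trk.header[TrkField.VOXEL_SIZES], dtype=float)
    fibers = []
    for i, sl in enumerate(trk.tractogram.streamlines):
        pts = np.asarray(sl, dtype=float) @ inv[:3, :3].T + inv[:3, 3]
        scalars = {
            name: np.asarray(trk.tractogram.data_per_point[name][i], float).ravel()
            for name in trk.tractogram.data_per_point
        }
        fibers.append(Fiber(pts, scalars))
    return Tractogram(fibers, A, voxel_size)
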