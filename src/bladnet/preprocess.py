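"""Volume preprocessing: load, resample, normalize, trim, and group axial slices.

The pipeline turns a 3-D FDG-PET intensity volume into a fixed number of
equal-sized groups of 2-D axial slices. Grouping is interleaved by default
(slice ``i`` goes to group ``i mod n_groups``) so that every group samples the
full cranio-caudal extent of the brain at equal spacing; a contiguous-block
alternative is available via :class:`PreprocessConfig`.

Coordinates are 0-based, intervals half-open, and the third array axis (z) is
the axial slice axis throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "BrainVolume",
    "SliceStack",
    "SliceGroupSet",
    "PreprocessConfig",
    "load_volume",
    "save_volume",
    "resample_volume",
    "normalize_intensity",
    "trim_zero_slices",
    "group_slices",
    "preprocess_volume",
    "save_groups_hdf5",
    "load_groups_hdf5",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class BrainVolume:
    """A 3-D non-negative intensity volume with voxel spacing in mm.

    Axes are (x, y, z); z is the axial slice axis. PET activity is
    non-negative, so negative intensities are rejected at construction.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    study_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"expected a 3-D volume, got ndim={self.voxels.ndim}"
            )
        if any(n < 1 for n in self.voxels.shape):
            raise ValidationError(f"axis lengths must be >= 1, got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite intensities")
        if self.voxels.min() < 0:
            raise ValidationError(
                "volume contains negative intensities; PET activity is non-negative"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class SliceStack:
    """Ordered axial slices cut from a volume's z axis.

    ``slices`` has shape (n_slices, nx, ny); ``source_range`` is the half-open
    interval of original z indices the stack was cut from, walked at ``stride``
    (stride 1 for a trimmed stack, stride n_groups for an interleaved group).
    """

    slices: np.ndarray
    source_range: tuple[int, int]
    stride: int = 1

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        lo, hi = self.source_range
        if len(range(lo, hi, self.stride)) != self.slices.shape[0]:
            raise ValidationError(
                f"source_range {self.source_range} at stride {self.stride} "
                f"does not cover {self.slices.shape[0]} slices"
            )

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass
class SliceGroupSet:
    """Equal-sized groups of axial slices; stage-1 CNN input.

    ``assignment`` maps each retained slice index (position within the trimmed
    stack) to its group index. Groups partition the kept slices.
    """

    groups: list[SliceStack]
    assignment: dict[int, int]

    def __post_init__(self) -> None:
        sizes = {g.n_slices for g in self.groups}
        if len(sizes) > 1:
            raise ValidationError(f"groups must be equal-sized, got sizes {sorted(sizes)}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def slices_per_group(self) -> int:
        return self.groups[0].n_slices if self.groups else 0

    def as_array(self) -> np.ndarray:
        """Stack to shape (n_groups, slices_per_group, nx, ny)."""
        return np.stack([g.slices for g in self.groups], axis=0)


@dataclass
class PreprocessConfig:
    """Settings for :func:`preprocess_volume`.

    The default grid (160 x 160 x 96) is the protocol grid for ADNI FDG-PET;
    whole-pipeline runs typically resample in-plane to a smaller grid for
    speed (see :class:`bladnet.model.PipelineConfig`).
    """

    shape: tuple[int, int, int] = (160, 160, 96)
    normalize: str = "minmax"
    n_groups: int = 4
    grouping: str = "interleaved"


# ---------------------------------------------------------------------------
# I/O


def _read_raw_array(path: Path) -> BrainVolume:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise IOError(f"raw-array sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta.get("dtype", "float32"))
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise IOError(
            f"raw-array file {path} holds {data.size} values, expected {int(np.prod(shape))}"
        )
    return BrainVolume(
        voxels=data.reshape(shape),
        spacing=tuple(meta["spacing_mm"]),
        study_id=str(meta.get("study_id", path.stem)),
        label=meta.get("label"),
    )


def load_volume(path: str | Path, format: str | None = None) -> BrainVolume:
    """Load a volume from NIfTI (.nii/.nii.gz) or the raw-array fixture format.

    The raw-array format is a flat binary file with a JSON sidecar
    ``<file>.json`` holding ``{shape, spacing_mm, study_id}``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    if format is None:
        format = "nifti" if path.name.endswith((".nii", ".nii.gz")) else "raw_array"
    if format == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asarray(img.get_fdata(dtype=np.float32))
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        except Exception as exc:  # nibabel raises a zoo of error types
            raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
        study_id = path.name.removesuffix(".gz").removesuffix(".nii")
        return BrainVolume(voxels=data, spacing=spacing, study_id=study_id)
    if format == "raw_array":
        return _read_raw_array(path)
    raise ValidationError(f"unknown volume format {format!r}")


def save_volume(v: BrainVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume as NIfTI or raw-array (+ JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format is None:
        format = "nifti" if path.name.endswith((".nii", ".nii.gz")) else "raw_array"
    if format == "nifti":
        import nibabel as nib

        affine = np.diag(list(v.spacing) + [1.0])
        nib.save(nib.Nifti1Image(v.voxels.astype(np.float32), affine), str(path))
    elif format == "raw_array":
        v.voxels.astype(np.float32).tofile(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(v.shape),
                    "spacing_mm": list(v.spacing),
                    "study_id": v.study_id,
                    "dtype": "float32",
                    "label": v.label,
                }
            )
        )
    else:
        raise ValidationError(f"unknown volume format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Transforms


def resample_volume(v: BrainVolume, target_shape: tuple[int, int, int]) -> BrainVolume:
    """Trilinear resample onto ``target_shape``, preserving physical extent.

    Sample points are placed so the first and last samples coincide with the
    first and last input voxels along each axis (endpoint-aligned linear
    interpolation); spacing is rescaled by the axis-length ratio.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if any(n < 1 for n in target_shape):
        raise ValidationError(f"target lengths must be >= 1, got {target_shape}")
    if target_shape == v.shape:
        out = v.voxels.copy()
    else:
        axes = [
            np.linspace(0.0, n_in - 1.0, n_out) if n_out > 1 else np.array([(n_in - 1) / 2.0])
            for n_in, n_out in zip(v.shape, target_shape)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        coords = np.stack([g.ravel() for g in grid], axis=0)
        out = ndimage.map_coordinates(
            v.voxels.astype(np.float64), coords, order=1, mode="nearest"
        ).reshape(target_shape)
    spacing = tuple(
        s * n_in / n_out for s, n_in, n_out in zip(v.spacing, v.shape, target_shape)
    )
    return BrainVolume(
        voxels=np.maximum(out, 0.0), spacing=spacing, study_id=v.study_id, label=v.label
    )


def normalize_intensity(v: BrainVolume, mode: str = "minmax") -> BrainVolume:
    """Map intensities affinely to [0, 1] (``minmax``) or pass through (``none``).

    A constant volume maps to all-zeros under ``minmax`` so the operation is
    defined for every valid input.
    """
    if mode == "none":
        return v
    if mode != "minmax":
        raise ValidationError(f"unknown normalization mode {mode!r}")
    lo = float(v.voxels.min())
    hi = float(v.voxels.max())
    if hi - lo == 0.0:
        out = np.zeros_like(v.voxels)
    else:
        out = (v.voxels - lo) / (hi - lo)
    return BrainVolume(voxels=out, spacing=v.spacing, study_id=v.study_id, label=v.label)


def trim_zero_slices(v: BrainVolume) -> SliceStack:
    """Drop the maximal runs of all-zero axial slices at both z-ends only.

    Interior all-zero slices are retained; an entirely zero volume is invalid.
    """
    nonzero = np.any(v.voxels != 0, axis=(0, 1))
    if not nonzero.any():
        raise ValidationError(f"volume {v.study_id!r} is entirely zero; nothing to keep")
    idx = np.flatnonzero(nonzero)
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    kept = np.moveaxis(v.voxels[:, :, lo:hi], 2, 0)
    return SliceStack(slices=np.ascontiguousarray(kept), source_range=(lo, hi))


def group_slices(s: SliceStack, n_groups: int = 4, grouping: str = "interleaved") -> SliceGroupSet:
    """Partition retained slices into ``n_groups`` equal-sized groups.

    ``interleaved`` assigns slice ``i`` to group ``i mod n_groups`` so each
    group covers the whole brain extent at equal intervals; ``contiguous``
    takes quartile blocks. A retained count not divisible by ``n_groups`` is
    truncated to the largest multiple (trailing slices dropped, warning
    logged).
    """
    if n_groups < 1:
        raise ValidationError(f"n_groups must be >= 1, got {n_groups}")
    n = s.n_slices
    if n < n_groups:
        raise ValidationError(f"{n} slices cannot fill {n_groups} groups")
    per_group = n // n_groups
    kept = per_group * n_groups
    if kept < n:
        logger.warning(
            "dropping %d trailing slice(s): %d retained slices not divisible by %d groups",
            n - kept,
            n,
            n_groups,
        )
    lo = s.source_range[0]
    groups: list[SliceStack] = []
    assignment: dict[int, int] = {}
    if grouping == "interleaved":
        for g in range(n_groups):
            groups.append(
                SliceStack(
                    slices=s.slices[g:kept:n_groups],
                    source_range=(lo + g, lo + kept),
                    stride=n_groups,
                )
            )
            assignment.update({i: g for i in range(g, kept, n_groups)})
    elif grouping == "contiguous":
        for g in range(n_groups):
            a, b = g * per_group, (g + 1) * per_group
            groups.append(SliceStack(slices=s.slices[a:b], source_range=(lo + a, lo + b)))
            assignment.update({i: g for i in range(a, b)})
    else:
        raise ValidationError(f"unknown grouping {grouping!r}")
    return SliceGroupSet(groups=groups, assignment=assignment)


def preprocess_volume(v: BrainVolume, cfg: PreprocessConfig | None = None) -> SliceGroupSet:
    """Resample -> normalize -> trim zero end-slices -> group. Deterministic."""
    cfg = cfg or PreprocessConfig()
    out = resample_volume(v, cfg.shape)
    out = normalize_intensity(out, cfg.normalize)
    stack = trim_zero_slices(out)
    return group_slices(stack, cfg.n_groups, cfg.grouping)


# ---------------------------------------------------------------------------
# HDF5 persistence


def save_groups_hdf5(gs: SliceGroupSet, path: str | Path, study_id: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["n_groups"] = gs.n_groups
        f.attrs["study_id"] = study_id
        keys = sorted(gs.assignment)
        f.create_dataset("assignment_keys", data=np.array(keys, dtype=np.int64), track_times=False)
        f.create_dataset(
            "assignment_values",
            data=np.array([gs.assignment[k] for k in keys], dtype=np.int64),
            track_times=False,
        )
        for i, g in enumerate(gs.groups):
            d = f.create_dataset(f"group_{i}", data=g.slices, track_times=False)
            d.attrs["source_range"] = list(g.source_range)
            d.attrs["stride"] = g.stride
    return path


def load_groups_hdf5(path: str | Path) -> SliceGroupSet:
    with h5py.File(path, "r") as f:
        n_groups = int(f.attrs["n_groups"])
        keys = f["assignment_keys"][()]
        values = f["assignment_values"][()]
        groups = []
        for i in range(n_groups):
            d = f[f"group_{i}"]
            groups.append(
                SliceStack(
                    slices=d[()],
                    source_range=tuple(int(x) for x in d.attrs["source_range"]),
                    stride=int(d.attrs.get("stride", 1)),
                )
            )
    return SliceGroupSet(groups=groups, assignment={int(k): int(v) for k, v in zip(keys, values)})
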