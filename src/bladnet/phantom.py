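"""Synthetic FDG-PET phantoms with stage-graded regional hypometabolism.

Each phantom is an ellipsoidal "brain" of baseline uptake 1.0 on a zero
background. Disease stage is encoded as a multiplicative uptake reduction
(the severity) inside fixed ellipsoidal regions chosen to mimic the canonical
Alzheimer's hypometabolism pattern: bilateral parieto-temporal cortex, a
posterior-cingulate-like midline region, and a frontal region that is only
involved at the most advanced stage of each class set. The volume is then
smoothed to the PET-typical 8 mm FWHM, Gaussian noise is added (clipped at
zero to keep activity non-negative), and a fixed number of axial end slices
are forced to zero so the end-trimming step of the preprocessing pipeline has
something to trim.

Severities are declared tunables of the generator, not estimates of real
ADNI effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .preprocess import BrainVolume, ValidationError, save_volume

logger = logging.getLogger(__name__)

__all__ = [
    "RoiSpec",
    "PhantomSpec",
    "LabeledDataset",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
    "write_dataset",
    "virtual_manifest",
    "phantom_loader",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class RoiSpec:
    """Ellipsoidal region in fractional volume coordinates (center, radii)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        acc = np.zeros(shape, dtype=np.float64)
        for g, n, c, r in zip(grids, shape, self.center, self.radii):
            acc = acc + ((g - c * n) / (r * n)) ** 2
        return acc <= 1.0


def _default_rois() -> dict[str, RoiSpec]:
    # x: left-right, y: posterior(low)-anterior(high), z: inferior-superior.
    return {
        "parieto_temporal_left": RoiSpec(center=(0.28, 0.35, 0.55), radii=(0.10, 0.14, 0.16)),
        "parieto_temporal_right": RoiSpec(center=(0.72, 0.35, 0.55), radii=(0.10, 0.14, 0.16)),
        "posterior_cingulate": RoiSpec(center=(0.50, 0.32, 0.58), radii=(0.07, 0.09, 0.11)),
        "frontal": RoiSpec(center=(0.50, 0.72, 0.55), radii=(0.16, 0.12, 0.15)),
    }


def _default_severity() -> dict[str, dict[str, float]]:
    # Graded reductions; CN is unaffected, frontal involvement only at the
    # most advanced stage of each class set (AD, LMCI).
    pt = ("parieto_temporal_left", "parieto_temporal_right", "posterior_cingulate")
    return {
        "CN": {},
        "MCI": {r: 0.15 for r in pt},
        "AD": {**{r: 0.30 for r in pt}, "frontal": 0.30},
        "EMCI": {r: 0.10 for r in pt},
        "LMCI": {**{r: 0.20 for r in pt}, "frontal": 0.20},
    }


@dataclass
class PhantomSpec:
    """Generator settings; the defaults define the study conditions.

    ``smooth_fwhm_mm`` is converted to a per-axis Gaussian sigma via
    sigma = FWHM / (2 * sqrt(2 ln 2) * voxel_size).
    """

    shape: tuple[int, int, int] = (160, 160, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    n_zero_end_slices: int = 2
    brain: RoiSpec = field(
        default_factory=lambda: RoiSpec(center=(0.5, 0.5, 0.5), radii=(0.42, 0.45, 0.44))
    )
    rois: dict[str, RoiSpec] = field(default_factory=_default_rois)
    severity: dict[str, dict[str, float]] = field(default_factory=_default_severity)
    noise_sigma: float = 0.03
    smooth_fwhm_mm: float = 8.0

    def __post_init__(self) -> None:
        for label, sev in self.severity.items():
            for roi, s in sev.items():
                if not 0.0 <= s <= 1.0:
                    raise ValidationError(f"severity[{label}][{roi}] = {s} outside [0, 1]")
                if roi not in self.rois:
                    raise ValidationError(f"severity names unknown ROI {roi!r}")
        if "CN" in self.severity and any(self.severity["CN"].values()):
            raise ValidationError("CN severity must be zero in every region")

    @property
    def class_sets(self) -> dict[str, list[str]]:
        return {"three_class": ["AD", "MCI", "CN"], "two_class": ["EMCI", "LMCI"]}

    def smoothing_sigma_voxels(self) -> tuple[float, float, float]:
        k = 2.0 * np.sqrt(2.0 * np.log(2.0))
        return tuple(self.smooth_fwhm_mm / (k * s) for s in self.spacing)

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "n_zero_end_slices": self.n_zero_end_slices,
            "brain": {"center": list(self.brain.center), "radii": list(self.brain.radii)},
            "rois": {
                k: {"center": list(r.center), "radii": list(r.radii)}
                for k, r in self.rois.items()
            },
            "severity": {k: dict(v) for k, v in self.severity.items()},
            "noise_sigma": self.noise_sigma,
            "smooth_fwhm_mm": self.smooth_fwhm_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            shape=tuple(d["shape"]),
            spacing=tuple(d["spacing"]),
            n_zero_end_slices=int(d["n_zero_end_slices"]),
            brain=RoiSpec(tuple(d["brain"]["center"]), tuple(d["brain"]["radii"])),
            rois={
                k: RoiSpec(tuple(r["center"]), tuple(r["radii"]))
                for k, r in d["rois"].items()
            },
            severity={k: dict(v) for k, v in d["severity"].items()},
            noise_sigma=float(d["noise_sigma"]),
            smooth_fwhm_mm=float(d["smooth_fwhm_mm"]),
        )


@dataclass
class LabeledDataset:
    volumes: list[BrainVolume]
    labels: list[str]
    spec: PhantomSpec
    seed: int

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.labels):
            raise ValidationError("volumes and labels must have equal length")

    def __len__(self) -> int:
        return len(self.volumes)


def generate_phantom(
    label: str,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    *,
    smooth: bool = True,
    noise: bool = True,
) -> BrainVolume:
    """Generate one labeled phantom volume; deterministic for a given seed.

    ``smooth``/``noise`` switches exist so tests can inspect the construction
    stages (pre-smoothing ROI intensities, noise-free separability).
    """
    spec = spec or PhantomSpec()
    if label not in spec.severity:
        raise ValidationError(f"unknown label {label!r}; known: {sorted(spec.severity)}")
    rng = np.random.default_rng(seed)
    vol = np.zeros(spec.shape, dtype=np.float64)
    vol[spec.brain.mask(spec.shape)] = 1.0
    for roi_name, s in spec.severity[label].items():
        vol[spec.rois[roi_name].mask(spec.shape)] *= 1.0 - s
    if smooth and spec.smooth_fwhm_mm > 0:
        vol = gaussian_filter(vol, sigma=spec.smoothing_sigma_voxels())
    if noise and spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        vol = np.maximum(vol, 0.0)
    k = spec.n_zero_end_slices
    if k > 0:
        vol[:, :, :k] = 0.0
        vol[:, :, -k:] = 0.0
    return BrainVolume(
        voxels=vol.astype(np.float32),
        spacing=spec.spacing,
        study_id=f"{label}_{seed:08d}",
        label=label,
    )


def _phantom_seed(master_seed: int, index: int) -> int:
    # Stable per-phantom stream, independent of generation order.
    return int(np.random.default_rng([master_seed, index]).integers(0, _SEED_MOD))


def generate_dataset(
    n_per_class: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    classes: list[str] | None = None,
) -> LabeledDataset:
    """Balanced dataset of phantoms; per-phantom seeds derive from ``seed``."""
    spec = spec or PhantomSpec()
    classes = classes or spec.class_sets["three_class"]
    volumes: list[BrainVolume] = []
    labels: list[str] = []
    for i in range(n_per_class * len(classes)):
        label = classes[i % len(classes)]
        volumes.append(generate_phantom(label, spec, _phantom_seed(seed, i)))
        labels.append(label)
    return LabeledDataset(volumes=volumes, labels=labels, spec=spec, seed=seed)


def split_dataset(
    d: LabeledDataset, train_frac: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded shuffle, then an 80/20 (by default) train/test split."""
    if not 0.0 < train_frac < 1.0:
        raise ValidationError(f"train_frac must be in (0, 1), got {train_frac}")
    n = len(d)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * train_frac))
    tr, te = order[:n_train], order[n_train:]
    mk = lambda idx: LabeledDataset(
        volumes=[d.volumes[i] for i in idx],
        labels=[d.labels[i] for i in idx],
        spec=d.spec,
        seed=d.seed,
    )
    return mk(tr), mk(te)


def write_dataset(d: LabeledDataset, out_dir: str | Path, format: str = "nifti") -> Path:
    """Write volumes + manifest CSV (study_id, path, label) + spec YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if format == "nifti" else ".raw"
    rows = []
    for v, label in zip(d.volumes, d.labels):
        path = out_dir / f"{v.study_id}{ext}"
        save_volume(v, path, format=format)
        rows.append({"study_id": v.study_id, "path": str(path), "label": label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (out_dir / "phantom_spec.yaml").write_text(yaml.safe_dump(d.spec.to_dict()))
    return manifest


# ---------------------------------------------------------------------------
# Virtual manifests: phantoms addressed by "phantom:<label>:<seed>" paths, so
# whole-dataset runs need neither disk space nor all volumes in memory.


def virtual_manifest(
    n_per_class: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    spec = spec or PhantomSpec()
    classes = classes or spec.class_sets["three_class"]
    rows = []
    for i in range(n_per_class * len(classes)):
        label = classes[i % len(classes)]
        s = _phantom_seed(seed, i)
        rows.append(
            {"study_id": f"{label}_{s:08d}", "path": f"phantom:{label}:{s}", "label": label}
        )
    return pd.DataFrame(rows)


def phantom_loader(spec: PhantomSpec | None = None):
    """Volume loader resolving ``phantom:<label>:<seed>`` paths on demand."""
    spec = spec or PhantomSpec()

    def load(path: str) -> BrainVolume:
        _, label, s = str(path).split(":")
        return generate_phantom(label, spec, int(s))

    return load
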