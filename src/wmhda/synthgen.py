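"""Seeded generator of two-domain synthetic FLAIR/T1-like cohorts.

Each subject is an ellipsoidal "brain" with a darker ventricle cavity and a
set of bright, fuzzily-bounded lesions on the FLAIR channel. Domains differ
through their tissue intensities, bias-field amplitude, noise level,
per-axis smoothing (slice anisotropy) and lesion-load distribution, standing
in for scanner/population shift between cohorts.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "DomainSpec",
    "DomainShift",
    "Subject",
    "generate_subject",
    "generate_cohort",
    "make_domain_pair",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class DomainSpec:
    """Parameters describing one imaging domain."""

    name: str
    volume_shape: tuple[int, int, int] = (40, 48, 40)
    tissue_means: dict[str, float] = field(
        default_factory=lambda: {"background": 0.0, "brain": 100.0, "lesion": 170.0}
    )
    bias_amplitude: float = 0.1        # fraction of the brain mean
    noise_sigma: float = 5.0
    lesion_count_range: tuple[int, int] = (3, 8)
    lesion_radius_range: tuple[float, float] = (1.5, 4.0)
    periventricular_fraction: float = 0.6
    anisotropy: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: contrast of unlabelled bright flow-artifact sheets near the ventricle,
    #: as a multiple of this domain's lesion-brain contrast (0 disables them)
    artifact_level: float = 0.0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.volume_shape)
        object.__setattr__(self, "volume_shape", shape)
        if any(s <= 0 for s in shape):
            raise ValueError("volume_shape must be positive")
        if not 0.0 <= self.periventricular_fraction <= 1.0:
            raise ValueError("periventricular_fraction must be in [0, 1]")
        if not all(np.isfinite(v) for v in self.tissue_means.values()):
            raise ValueError("tissue means must be finite")
        if 2 * self.lesion_radius_range[1] > min(shape):
            raise ValueError("lesion_radius_range does not fit inside volume_shape")


@dataclass(frozen=True)
class DomainShift:
    """Source->target offsets applied by :func:`make_domain_pair`.

    Multiplicative fields default to 1 and additive fields to 0, so the
    default instance is the identity shift.
    """

    intensity_scale: float = 1.0        # multiplies all tissue means
    lesion_contrast_scale: float = 1.0  # scales (lesion - brain) contrast
    bias_delta: float = 0.0
    noise_delta: float = 0.0
    anisotropy_delta: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lesion_count_delta: int = 0
    artifact_delta: float = 0.0

    def __post_init__(self):
        vals = [self.intensity_scale, self.lesion_contrast_scale,
                self.bias_delta, self.noise_delta, self.artifact_delta,
                *self.anisotropy_delta]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("shift parameters must be finite")


@dataclass
class Subject:
    """One case: FLAIR + T1 volumes, lesion and brain masks, domain label."""

    flair: np.ndarray
    t1: np.ndarray
    lesion_mask: np.ndarray
    brain_mask: np.ndarray
    domain: str
    subject_id: str
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shapes = {self.flair.shape, self.t1.shape,
                  self.lesion_mask.shape, self.brain_mask.shape}
        if len(shapes) != 1:
            raise ValueError("all subject arrays must share one shape")
        self.lesion_mask = self.lesion_mask.astype(bool)
        self.brain_mask = self.brain_mask.astype(bool)
        if np.any(self.lesion_mask & ~self.brain_mask):
            raise ValueError("lesion mask must lie inside the brain mask")


def _ellipsoid(shape: tuple[int, int, int], centre, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi_axes))
    return r2 <= 1.0


def _anatomy(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Brain ellipsoid and a two-lobed ventricle cavity near its centre."""
    centre = [(s - 1) / 2 for s in shape]
    brain = _ellipsoid(shape, centre, [0.42 * s for s in shape])
    gap = max(1.5, 0.08 * shape[0])
    vent = np.zeros(shape, bool)
    for side in (-1, 1):
        c = [centre[0] + side * gap, centre[1], centre[2]]
        vent |= _ellipsoid(shape, c, [0.05 * shape[0] + 0.8,
                                      0.22 * shape[1],
                                      0.07 * shape[2] + 0.8])
    return brain, vent & brain


def generate_subject(spec: DomainSpec, seed: int) -> Subject:
    """Deterministically synthesise one subject from (spec, seed)."""
    if seed < 0:
        raise ValueError("seed must be >= 0")
    name_key = zlib.crc32(spec.name.encode())  # stable across processes
    rng = np.random.default_rng(np.random.SeedSequence([name_key, seed]))
    shape = spec.volume_shape
    brain, vent = _anatomy(shape)

    means = spec.tissue_means
    vent_mean = means["background"] + 0.35 * (means["brain"] - means["background"])

    # -- lesion placement ---------------------------------------------------
    n_lo, n_hi = spec.lesion_count_range
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    # lesions seed well inside the brain (clear of the rim, where the
    # artifact sheets of shifted domains live) and outside the ventricle
    erosion = max(2, int(round(0.12 * min(shape))))
    interior = ndimage.binary_erosion(brain, iterations=erosion) & ~ndimage.binary_dilation(vent, iterations=1)
    if n_lesions > 0 and not interior.any():
        raise ValueError("volume too small to place any lesion")
    pv_shell = (ndimage.binary_dilation(vent, iterations=3) & interior)
    interior_idx = np.argwhere(interior)
    shell_idx = np.argwhere(pv_shell) if pv_shell.any() else interior_idx

    soft = np.zeros(shape, dtype=np.float64)
    coords = np.indices(shape, dtype=np.float64)
    for _ in range(n_lesions):
        pool = shell_idx if rng.random() < spec.periventricular_fraction else interior_idx
        seed_vox = pool[rng.integers(len(pool))]
        radius = rng.uniform(*spec.lesion_radius_range)
        # sphere deformed by a smooth random radial perturbation, soft edge
        stretch = rng.uniform(0.75, 1.3, size=3)
        d = np.sqrt(sum(((coords[a] - seed_vox[a]) * stretch[a]) ** 2 for a in range(3)))
        bump = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
        bump *= 0.35 * radius / (np.abs(bump).max() + 1e-12)
        lesion = np.clip((radius + bump - d) / 1.0 + 0.5, 0.0, 1.0)
        soft = np.maximum(soft, lesion)
    soft *= interior
    lesion_mask = soft > 0.5

    # unlabelled artifact sheets: patchy shell along the brain rim, bright on
    # FLAIR like lesions but absent from the lesion mask
    art_soft = np.zeros(shape, dtype=np.float64)
    if spec.artifact_level > 0:
        shell = brain & ~ndimage.binary_erosion(brain, iterations=3)
        patchiness = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
        art = shell & (patchiness > 0.6 * patchiness[shell].std())
        art_soft = np.clip(ndimage.gaussian_filter(art.astype(float), 0.7) * 1.8, 0, 1)
        art_soft[soft > 0.25] = 0.0  # lesions take precedence

    # -- intensity composition ---------------------------------------------
    contrast = means["lesion"] - means["brain"]
    artifact_mean = means["brain"] + spec.artifact_level * contrast
    flair = np.full(shape, means["background"], dtype=np.float64)
    flair[brain] = means["brain"]
    flair[vent] = vent_mean
    flair = flair * (1 - art_soft) + artifact_mean * art_soft
    flair = flair * (1 - soft) + means["lesion"] * soft

    # smooth multiplicative bias field from upsampled low-frequency noise
    low = rng.standard_normal((4, 4, 4))
    bias = ndimage.zoom(low, [s / 4 for s in shape], order=3)
    bias = 1.0 + spec.bias_amplitude * bias / (np.abs(bias).max() + 1e-12)
    flair[brain] *= bias[brain]

    # T1 companion: inverted lesion/ventricle contrast, independent noise
    t1 = np.full(shape, means["background"], dtype=np.float64)
    t1[brain] = means["brain"]
    t1[vent] = means["background"] + 0.25 * (means["brain"] - means["background"])
    # T1 lesion contrast mirrors (inverted, attenuated) the FLAIR contrast so
    # that domain shifts in lesion conspicuity affect both channels
    t1_lesion = means["brain"] - 0.4 * (means["lesion"] - means["brain"])
    t1_artifact = means["brain"] - 0.4 * spec.artifact_level * contrast
    t1 = t1 * (1 - art_soft) + t1_artifact * art_soft
    t1 = t1 * (1 - soft) + t1_lesion * soft
    t1[brain] *= bias[brain]

    if any(a > 0 for a in spec.anisotropy):
        flair = ndimage.gaussian_filter(flair, spec.anisotropy)
        t1 = ndimage.gaussian_filter(t1, spec.anisotropy)

    flair += rng.normal(0.0, spec.noise_sigma, shape)
    t1 += rng.normal(0.0, spec.noise_sigma, shape)

    return Subject(
        flair=flair.astype(np.float32),
        t1=t1.astype(np.float32),
        lesion_mask=lesion_mask,
        brain_mask=brain,
        domain=spec.name,
        subject_id=f"{spec.name}_{seed:05d}",
    )


def _subject_seed(root_seed: int, index: int) -> int:
    """Stable per-subject seed stream split from a root seed."""
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: DomainSpec, n: int, seed: int) -> list[Subject]:
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    subjects = []
    for i in range(n):
        s = generate_subject(spec, _subject_seed(seed, i))
        s.subject_id = f"{spec.name}_{i:03d}"
        subjects.append(s)
    return subjects


def make_domain_pair(base: DomainSpec, shift: DomainShift) -> tuple[DomainSpec, DomainSpec]:
    """Source spec plus a target spec offset by the given shift."""
    means = dict(base.tissue_means)
    contrast = means["lesion"] - means["brain"]
    means["lesion"] = means["brain"] + shift.lesion_contrast_scale * contrast
    means = {k: shift.intensity_scale * v for k, v in means.items()}
    lo, hi = base.lesion_count_range
    target = replace(
        base,
        name=base.name + "_target" if base.name else "target",
        tissue_means=means,
        bias_amplitude=base.bias_amplitude + shift.bias_delta,
        noise_sigma=base.noise_sigma + shift.noise_delta,
        anisotropy=tuple(a + d for a, d in zip(base.anisotropy, shift.anisotropy_delta)),
        lesion_count_range=(max(0, lo + shift.lesion_count_delta),
                            max(0, hi + shift.lesion_count_delta)),
        artifact_level=base.artifact_level + shift.artifact_delta,
    )
    source = replace(base, name=base.name + "_source" if base.name else "source")
    return source, target


# -- NIfTI / manifest I/O ----------------------------------------------------

def _affine(voxel_dims) -> np.ndarray:
    return np.diag(list(voxel_dims) + [1.0])


def save_cohort(subjects: list[Subject], out_dir: str | Path) -> Path:
    """Write per-subject NIfTI files plus a manifest CSV; returns manifest path."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "domain", "flair", "t1", "mask", "brain"])
        for s in subjects:
            aff = _affine(s.voxel_dims)
            paths = {}
            for key, arr in [("flair", s.flair), ("t1", s.t1),
                             ("mask", s.lesion_mask.astype(np.uint8)),
                             ("brain", s.brain_mask.astype(np.uint8))]:
                p = out_dir / f"{s.subject_id}_{key}.nii.gz"
                nib.save(nib.Nifti1Image(np.asarray(arr), aff), p)
                paths[key] = p.name
            writer.writerow([s.subject_id, s.domain, paths["flair"],
                             paths["t1"], paths["mask"], paths["brain"]])
    return manifest


def load_cohort(manifest: str | Path) -> list[Subject]:
    import nibabel as nib

    manifest = Path(manifest)
    base = manifest.parent
    subjects = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            imgs = {k: nib.load(base / row[k]) for k in ("flair", "t1", "mask", "brain")}
            vox = tuple(float(z) for z in imgs["flair"].header.get_zooms()[:3])
            subjects.append(Subject(
                flair=np.asarray(imgs["flair"].dataobj, dtype=np.float32),
                t1=np.asarray(imgs["t1"].dataobj, dtype=np.float32),
                lesion_mask=np.asarray(imgs["mask"].dataobj) > 0.5,
                brain_mask=np.asarray(imgs["brain"].dataobj) > 0.5,
                domain=row["domain"],
                subject_id=row["subject_id"],
                voxel_dims=vox,
            ))
    return subjects
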