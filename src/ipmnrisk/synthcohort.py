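"""Seeded synthetic multi-center T2W-like cohort generation.

The generator emulates the structure of a seven-center pancreatic-cyst MRI
cohort: each subject is a 3D volume containing a bright ellipsoidal cyst
(fluid is hyperintense on T2W) embedded in a duller organ region on a dark
background.  High-risk cysts differ from low-risk ones only through
*internal heterogeneity* — hypointense mural blobs, one or two septation
planes, and extra within-cyst intensity variance — all scaled by a single
``effect_size`` knob.  Centers differ only in acquisition: slice thickness
(3–8 mm), a smooth multiplicative bias field, additive noise, and a global
intensity scale.  Center therefore confounds image quality but never the
class-conditional texture, which is what leave-center-out validation is
meant to probe.

Everything is bit-reproducible from an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import MaskVolume, VolumeGrid

__all__ = [
    "CenterProfile",
    "SynthConfig",
    "Subject",
    "Cohort",
    "generate_cyst_volume",
    "generate_cohort",
    "perturb_mask",
    "simulate_ratings",
    "DEFAULT_CENTER_PROFILES",
    "DEFAULT_CENTER_WEIGHTS",
]

RATING_LEVELS = ("no", "low", "high")

# Per-center mean slice thicknesses follow the cohort's reported acquisition
# spread (3-8 mm); bias/noise/scale are free acquisition nuisance choices.
DEFAULT_CENTER_PROFILES: dict[str, "CenterProfile"] = {}

# Per-center subject shares consistent with the four-trial test-set sizes
# (AHN+MCA=29, EMC=36, IU=35, NYU=71 of 359; the MCF/NMH remainder is split).
DEFAULT_CENTER_WEIGHTS = {
    "AHN": 14, "EMC": 36, "IU": 35, "MCA": 15, "MCF": 94, "NMH": 94, "NYU": 71,
}


@dataclass(frozen=True)
class CenterProfile:
    """Acquisition profile of one imaging center."""

    slice_thickness: float  # mm, within [3, 8] by default
    bias_amplitude: float = 0.15
    noise_sd: float = 0.03
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if self.noise_sd < 0 or self.bias_amplitude < 0 or self.intensity_scale <= 0:
            raise ValueError("invalid center profile parameters")


DEFAULT_CENTER_PROFILES.update(
    {
        "AHN": CenterProfile(7.0, 0.20, 0.035, 0.85),
        "EMC": CenterProfile(7.3, 0.25, 0.040, 1.30),
        "IU": CenterProfile(7.0, 0.18, 0.030, 0.75),
        "MCA": CenterProfile(7.0, 0.15, 0.030, 1.10),
        "MCF": CenterProfile(4.0, 0.12, 0.025, 1.00),
        "NMH": CenterProfile(5.5, 0.15, 0.030, 0.95),
        "NYU": CenterProfile(5.0, 0.18, 0.035, 1.15),
    }
)


@dataclass
class SynthConfig:
    """Cohort-level generator configuration.

    Defaults mirror the study design: 359 subjects over 7 centers with a
    142/359 high-risk fraction and per-center slice thicknesses in 3-8 mm.
    """

    n_subjects: int = 359
    n_centers: int = 7
    class_balance: float = 142 / 359
    effect_size: float = 1.0
    center_profiles: dict[str, CenterProfile] = field(
        default_factory=lambda: dict(DEFAULT_CENTER_PROFILES)
    )
    center_weights: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CENTER_WEIGHTS)
    )
    volume_shape: tuple[int, int, int] = (40, 40, 18)
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_centers <= self.n_subjects):
            raise ValueError("need n_subjects >= n_centers >= 1")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if len(self.center_profiles) < self.n_centers:
            raise ValueError("not enough center profiles for n_centers")
        for name, prof in self.center_profiles.items():
            if not (3.0 <= prof.slice_thickness <= 8.0):
                raise ValueError(
                    f"center {name}: slice thickness {prof.slice_thickness} mm "
                    "outside the default [3, 8] mm acquisition range"
                )

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_subjects": self.n_subjects,
            "n_centers": self.n_centers,
            "class_balance": self.class_balance,
            "effect_size": self.effect_size,
            "volume_shape": list(self.volume_shape),
            "exact_counts": self.exact_counts,
            "seed": self.seed,
            "center_profiles": {
                k: vars(v) for k, v in self.center_profiles.items()
            },
            "center_weights": self.center_weights,
        }
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass(frozen=True)
class Subject:
    subject_id: str
    center_id: str
    cyst_type: str  # BD, MD, or mixed
    label: int  # 0 = low risk, 1 = high risk

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (low) or 1 (high)")
        if self.cyst_type not in ("BD", "MD", "mixed"):
            raise ValueError(f"unknown cyst type {self.cyst_type!r}")


@dataclass
class Cohort:
    subjects: list[Subject]
    volumes: dict[str, VolumeGrid]
    cyst_masks: dict[str, MaskVolume]
    organ_masks: dict[str, MaskVolume]
    config: SynthConfig | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    @property
    def centers(self) -> list[str]:
        return sorted({s.center_id for s in self.subjects})

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "center_id": s.center_id,
                    "cyst_type": s.cyst_type,
                    "label": s.label,
                }
                for s in self.subjects
            ]
        )

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.manifest.to_csv(out / "manifest.csv", index=False)
        if self.config is not None:
            self.config.to_json(out / "config.json")
        for s in self.subjects:
            self.volumes[s.subject_id].to_nifti(out / f"{s.subject_id}_T2W.nii.gz")
            self.cyst_masks[s.subject_id].to_nifti(out / f"{s.subject_id}_cyst.nii.gz")
            self.organ_masks[s.subject_id].to_nifti(out / f"{s.subject_id}_organ.nii.gz")


# ---------------------------------------------------------------------------
# single-subject phantom


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """exp of a random order-3 polynomial in normalized coords; positive, mean ~1."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    terms = [gx, gy, gz, gx * gy, gx * gz, gy * gz,
             gx ** 2, gy ** 2, gz ** 2, gx ** 3, gy ** 3, gz ** 3, gx * gy * gz]
    coeffs = rng.normal(0.0, 1.0, size=len(terms))
    poly = sum(c * t for c, t in zip(coeffs, terms))
    sd = poly.std()
    if sd > 0:
        poly = poly / sd * amplitude
    else:  # amplitude 0 or degenerate draw
        poly = np.zeros(shape)
    field = np.exp(poly)
    return field / field.mean()


MIN_CYST_RADIUS_MM = 5.0


def generate_cyst_volume(
    class_label: int,
    center_profile: CenterProfile,
    effect_size: float,
    shape: tuple[int, int, int] = (40, 40, 18),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[VolumeGrid, MaskVolume, MaskVolume]:
    """Generate one subject: T2W-like volume, cyst mask, organ mask.

    The heterogeneity machinery (blob positions, septation orientation) is
    always sampled from the stream, and its amplitudes are multiplied by
    ``class_label * effect_size`` — so at ``effect_size == 0`` the two
    classes come from the *identical* generator, bit for bit.
    """

    if any(n < 16 for n in shape):
        raise ValueError(f"shape {shape} too small: need >= 16 voxels per axis")
    spacing = (1.0, 1.0, float(center_profile.slice_thickness))
    rng = np.random.default_rng(seed)

    # geometry in voxels; z radii converted through slice thickness
    ctr = [n / 2.0 + rng.uniform(-1.5, 1.5) for n in shape]
    organ_r = [0.44 * n for n in shape]
    r_mm = rng.uniform(7.0, 13.0, size=3)
    cyst_r = [
        max(3.0, r_mm[0]),
        max(3.0, r_mm[1]),
        max(1.5, r_mm[2] / spacing[2]),
    ]
    for ax in range(3):
        cyst_r[ax] = min(cyst_r[ax], 0.6 * organ_r[ax])
    if min(cyst_r[0], cyst_r[1]) * spacing[0] < MIN_CYST_RADIUS_MM * 0.5:
        raise ValueError("volume too small to contain a cyst of minimum radius")

    organ = _ellipsoid(shape, ctr, organ_r)
    cyst = _ellipsoid(shape, ctr, cyst_r)
    cyst &= organ  # guaranteed by construction, asserted by contract

    vol = np.full(shape, 0.05)
    vol[organ] = 0.35 + 0.03 * rng.standard_normal(int(organ.sum()))
    vol[cyst] = 1.0

    # --- class heterogeneity (amplitude gated by label * effect_size) ---
    amp = float(class_label) * float(effect_size)
    idx = np.argwhere(cyst)
    n_blobs = int(rng.integers(2, 5))
    gx, gy, gz = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    hetero = np.zeros(shape)
    for _ in range(n_blobs):
        p = idx[rng.integers(len(idx))]
        sig = [max(1.0, r / 3.0) for r in cyst_r]
        blob = np.exp(
            -(((gx - p[0]) / sig[0]) ** 2 + ((gy - p[1]) / sig[1]) ** 2
              + ((gz - p[2]) / sig[2]) ** 2)
        )
        hetero -= 0.30 * blob
    for _ in range(int(rng.integers(1, 3))):  # 1-2 septation planes
        normal = rng.standard_normal(3)
        normal /= np.linalg.norm(normal)
        dist = (gx - ctr[0]) * normal[0] + (gy - ctr[1]) * normal[1] \
            + (gz - ctr[2]) * normal[2] * spacing[2]
        hetero -= 0.25 * np.exp(-(dist / 1.2) ** 2)
    hetero += 0.06 * rng.standard_normal(shape)  # within-cyst speckle
    vol[cyst] += amp * hetero[cyst]

    # --- acquisition effects (center) ---
    vol *= _bias_field(shape, center_profile.bias_amplitude, rng)
    vol += rng.normal(0.0, center_profile.noise_sd, size=shape)
    vol *= center_profile.intensity_scale
    vol = np.clip(vol, 0.0, None)

    return (
        VolumeGrid(vol, spacing),
        MaskVolume(cyst.astype(np.uint8), spacing),
        MaskVolume(organ.astype(np.uint8), spacing),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def _allocate_counts(total: int, weights: dict[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment; every center gets >= 1."""
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    ideal = total * w / w.sum()
    counts = np.floor(ideal).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > total:
        i = int(np.argmax(counts))
        counts[i] -= 1
    rem = ideal - np.floor(ideal)
    order = np.argsort(-rem)
    j = 0
    while counts.sum() < total:
        counts[order[j % len(names)]] += 1
        j += 1
    return dict(zip(names, counts.tolist()))


# P(MD-or-mixed | risk class), matching the reported subtype breakdown
# (high risk: 99/142 MD/mixed; low risk: 62/217).
_P_MDMIX = {1: 99 / 142, 0: 62 / 217}


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a full seeded cohort per :class:`SynthConfig`."""

    n = config.n_subjects
    n_high = int(round(n * config.class_balance))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))

    if config.exact_counts:
        labels = np.zeros(n, dtype=int)
        labels[:n_high] = 1
        rng.shuffle(labels)
    else:
        labels = (rng.random(n) < config.class_balance).astype(int)
    if labels.min() == labels.max():
        raise ValueError(
            "class_balance would yield a single-class cohort at this n"
        )

    center_names = sorted(config.center_profiles)[: config.n_centers]
    weights = {c: config.center_weights.get(c, 1) for c in center_names}
    counts = _allocate_counts(n, weights)
    center_of = np.concatenate([[c] * counts[c] for c in center_names])
    rng.shuffle(center_of)

    subjects: list[Subject] = []
    volumes: dict[str, VolumeGrid] = {}
    cysts: dict[str, MaskVolume] = {}
    organs: dict[str, MaskVolume] = {}
    child_seeds = np.random.SeedSequence([config.seed, 0xC1]).spawn(n)
    for i in range(n):
        sid = f"S{i:04d}"
        lab = int(labels[i])
        ctype = "BD"
        if rng.random() < _P_MDMIX[lab]:
            ctype = "MD" if rng.random() < 0.5 else "mixed"
        cname = str(center_of[i])
        vol, cmask, omask = generate_cyst_volume(
            lab,
            config.center_profiles[cname],
            config.effect_size,
            config.volume_shape,
            seed=child_seeds[i],
        )
        subjects.append(Subject(sid, cname, ctype, lab))
        volumes[sid] = vol
        cysts[sid] = cmask
        organs[sid] = omask
    return Cohort(subjects, volumes, cysts, organs, config)


# ---------------------------------------------------------------------------
# perturbed masks and simulated ratings


def perturb_mask(mask: MaskVolume, magnitude: float, seed: int = 0) -> MaskVolume:
    """Seeded boundary perturbation of a binary mask.

    The signed Euclidean distance of the mask is jittered by a smooth
    seeded noise field scaled by ``magnitude`` (voxels) and re-thresholded,
    so larger magnitudes push the expected Dice against the original
    monotonically down.  ``magnitude == 0`` returns the mask unchanged.
    """

    if mask.sum() == 0:
        raise ValueError("cannot perturb an empty mask")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return mask.copy()
    m = mask.as_bool()
    signed = ndimage.distance_transform_edt(m) - ndimage.distance_transform_edt(~m)
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(m.shape), sigma=2.0)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    out = (signed + magnitude * noise) > 0
    if not out.any():
        raise ValueError("perturbation emptied the mask")
    return MaskVolume(out.astype(np.uint8), mask.spacing)


def simulate_ratings(
    labels: np.ndarray,
    n_raters: int = 3,
    per_rater_sens: float | list[float] = 0.7,
    per_rater_spec: float | list[float] = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ordinal rater scores {no, low, high} against binary truth.

    A rater calls a true-high subject "high" with probability ``sens``
    (otherwise "no"/"low" at random) and a true-low subject "low" with
    probability ``spec`` (otherwise a false-positive "high"), so binarized
    scores (positive = "high") reproduce sens/spec in expectation.
    """

    if n_raters < 1:
        raise ValueError("need at least one rater")
    labels = np.asarray(labels, dtype=int)
    sens = np.broadcast_to(np.asarray(per_rater_sens, dtype=float), (n_raters,))
    spec = np.broadcast_to(np.asarray(per_rater_spec, dtype=float), (n_raters,))
    if np.any((sens < 0) | (sens > 1) | (spec < 0) | (spec > 1)):
        raise ValueError("sens and spec must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cols = {}
    for r in range(n_raters):
        scores = np.empty(len(labels), dtype=object)
        u = rng.random(len(labels))
        miss_cat = rng.random(len(labels))  # no/low split for missed highs
        for i, lab in enumerate(labels):
            if lab == 1:
                if u[i] < sens[r]:
                    scores[i] = "high"
                else:
                    scores[i] = "low" if miss_cat[i] < 0.5 else "no"
            else:
                scores[i] = "low" if u[i] < spec[r] else "high"
        cols[f"rater{r + 1}"] = scores
    df = pd.DataFrame(cols)
    df.insert(0, "label", labels)
    return df
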