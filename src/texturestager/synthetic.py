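"""Synthetic two-class cohorts of textured ROI images.

Each subject carries one image per sequence ("sagittal" and "axial") and
one ROI mask per (sequence, reader) pair.  Image texture is a Gaussian
random field: white noise smoothed with a class-specific correlation
length, so the two classes differ in spatial heterogeneity — a longer
correlation length yields smoother texture (higher GLCM energy, lower
entropy).  The two sequences share a latent field mixed with
``sequence_coupling``; the tumor mask is an irregular blob carved from a
separately smoothed field; a second simulated reader perturbs the mask
boundary within ``reader_perturb_radius`` pixels.

Randomness is keyed hierarchically: every draw uses a seed sequence built
from ``(master seed, subject index, purpose tag)``, so enlarging the
cohort never reshuffles earlier subjects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from texturestager.image_io import SEQUENCES

#: 4-connectivity structuring element for component labelling.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: Minimum ROI size in pixels.
MIN_MASK_PIXELS = 64

#: Class-separation presets: (correlation_length_neg, correlation_length_pos).
EFFECT_PRESETS: dict[str, tuple[float, float]] = {
    "none": (3.0, 3.0),
    "small": (3.0, 2.2),
    "large": (6.0, 1.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_per_class : int
        Subjects per class (class balance is exact).
    image_size : int
        Square image side in pixels.
    correlation_length_neg, correlation_length_pos : float
        Gaussian smoothing scale (pixels) of the intensity random field
        for the negative (label 0) and positive (label 1) class.  The
        positive class of the motivating application (node-positive
        tumors) is the more heterogeneous one, so its correlation length
        is typically the smaller.
    noise_sd_neg, noise_sd_pos : float
        Per-class white-noise standard deviation, in intensity units
        (the textured field has SD ~ 512 around a mean of 2048).
    sequence_coupling : float
        Weight in [0, 1] of the latent field shared by the two sequences.
    reader_perturb_radius : float
        Maximum boundary displacement (pixels) of the second reader's mask.
    seed : int
        Master seed; identical specs produce bit-identical cohorts.
    """

    n_per_class: int = 50
    image_size: int = 64
    correlation_length_neg: float = 3.0
    correlation_length_pos: float = 2.0
    noise_sd_neg: float = 25.0
    noise_sd_pos: float = 25.0
    sequence_coupling: float = 0.6
    reader_perturb_radius: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.correlation_length_neg <= 0 or self.correlation_length_pos <= 0:
            raise ValueError("correlation lengths must be > 0")
        if not 0.0 <= self.sequence_coupling <= 1.0:
            raise ValueError("sequence_coupling must be in [0, 1]")
        if self.noise_sd_neg < 0 or self.noise_sd_pos < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.reader_perturb_radius < 0:
            raise ValueError("reader_perturb_radius must be >= 0")

    @classmethod
    def with_effect(cls, effect: str = "large", **kwargs) -> "CohortSpec":
        """Spec with a named class-separation preset (none/small/large)."""
        if effect not in EFFECT_PRESETS:
            raise ValueError(f"unknown effect {effect!r}; choose from {list(EFFECT_PRESETS)}")
        neg, pos = EFFECT_PRESETS[effect]
        if effect == "none":
            kwargs.setdefault("noise_sd_pos", kwargs.get("noise_sd_neg", 25.0))
        return cls(correlation_length_neg=neg, correlation_length_pos=pos, **kwargs)


@dataclass
class SyntheticSubject:
    """One synthetic subject: images per sequence, masks per (sequence, reader)."""

    subject_id: str
    class_label: int
    images: dict[str, np.ndarray] = field(repr=False)
    masks: dict[tuple[str, int], np.ndarray] = field(repr=False)


def _rng(seed: int, *keys) -> np.random.Generator:
    """Generator keyed by (master seed, *purpose keys); order-stable."""
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _smooth_unit_field(rng: np.random.Generator, size: int, length: float) -> np.ndarray:
    """Gaussian random field with unit variance and zero mean."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), length, mode="reflect")
    f -= f.mean()
    sd = f.std()
    if sd == 0.0:  # pathological over-smoothing; keep the flat field
        return f
    return f / sd


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT4)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _blob_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Irregular single-component blob covering roughly 15-20% of the frame."""
    bumps = _smooth_unit_field(rng, size, size / 8.0)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    radial = ((yy - c) ** 2 + (xx - c) ** 2) / (size / 2.0) ** 2
    score = bumps - 2.5 * radial
    mask = score > np.quantile(score, 0.82)
    return _largest_component(mask)


def _perturb_mask(
    rng: np.random.Generator, mask: np.ndarray, radius: float
) -> np.ndarray:
    """Reader-2 mask: boundary locally shifted by at most ``radius`` px.

    The signed distance to the boundary is offset by a smooth random
    field bounded to (-radius, radius), so flipped pixels always lie
    within ``radius`` of the reader-1 boundary.
    """
    if radius == 0:
        return mask.copy()
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    signed = d_in - d_out  # >= 1 inside, <= -1 outside
    delta = radius * np.tanh(_smooth_unit_field(rng, mask.shape[0], 3.0))
    return _largest_component(signed + delta > 0)


def _make_subject(spec: CohortSpec, class_label: int, index: int) -> SyntheticSubject:
    length = spec.correlation_length_pos if class_label else spec.correlation_length_neg
    noise_sd = spec.noise_sd_pos if class_label else spec.noise_sd_neg
    subject_id = f"{'pos' if class_label else 'neg'}{index:03d}"
    size = spec.image_size
    w = spec.sequence_coupling

    shared = _smooth_unit_field(_rng(spec.seed, subject_id, "shared"), size, length)
    images: dict[str, np.ndarray] = {}
    masks: dict[tuple[str, int], np.ndarray] = {}
    for seq in SEQUENCES:
        own = _smooth_unit_field(_rng(spec.seed, subject_id, "field", seq), size, length)
        fld = np.sqrt(w) * shared + np.sqrt(1.0 - w) * own
        noise = _rng(spec.seed, subject_id, "noise", seq).normal(0.0, 1.0, (size, size))
        img = 2048.0 + 512.0 * fld + noise_sd * noise
        images[seq] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

        for attempt in range(100):
            mask_rng = _rng(spec.seed, subject_id, "mask", seq, attempt)
            m1 = _blob_mask(mask_rng, size)
            if m1.sum() < MIN_MASK_PIXELS:
                continue
            m2 = _perturb_mask(
                _rng(spec.seed, subject_id, "reader2", seq, attempt),
                m1,
                spec.reader_perturb_radius,
            )
            if m2.sum() < MIN_MASK_PIXELS:
                continue
            # perturbation must stay within the boundary band
            band = ndimage.distance_transform_edt(m1) <= spec.reader_perturb_radius
            band |= ndimage.distance_transform_edt(~m1) <= spec.reader_perturb_radius
            if np.any((m1 != m2) & ~band):
                continue
            break
        else:
            raise RuntimeError(
                f"could not generate a valid ROI mask for subject {subject_id}, "
                f"sequence {seq} after 100 attempts (image_size too small?)"
            )
        masks[(seq, 1)] = m1
        masks[(seq, 2)] = m2
    return SyntheticSubject(subject_id=subject_id, class_label=class_label, images=images, masks=masks)


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate a balanced two-class cohort; deterministic given the spec."""
    cohort = [_make_subject(spec, 0, i) for i in range(spec.n_per_class)]
    cohort += [_make_subject(spec, 1, i) for i in range(spec.n_per_class)]
    return cohort


def write_cohort(cohort: list[SyntheticSubject], out_dir: str | Path) -> Path:
    """Write a cohort to disk as 16-bit PNG images and 8-bit PNG masks.

    Produces ``images/`` and ``masks/`` subdirectories, a ``labels.csv``
    (subject_id, class_label) and a ``manifest.csv`` (subject_id,
    sequence, reader, image_path, mask_path) with paths relative to
    ``out_dir``.  Returns the manifest path.  The written files
    round-trip losslessly through :func:`texturestager.image_io.load_manifest`.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    labels_rows = []
    for subj in cohort:
        labels_rows.append({"subject_id": subj.subject_id, "class_label": subj.class_label})
        for seq, img in subj.images.items():
            img_rel = f"images/{subj.subject_id}_{seq}.png"
            Image.fromarray(img.astype(np.uint16)).save(out_dir / img_rel)
            for reader in (1, 2):
                mask = subj.masks[(seq, reader)]
                mask_rel = f"masks/{subj.subject_id}_{seq}_r{reader}.png"
                Image.fromarray((mask.astype(np.uint8)) * 255).save(out_dir / mask_rel)
                manifest_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "sequence": seq,
                        "reader": reader,
                        "image_path": img_rel,
                        "mask_path": mask_rel,
                    }
                )
    pd.DataFrame(labels_rows).to_csv(out_dir / "labels.csv", index=False)
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return manifest_path


def cohort_to_samples(cohort: list[SyntheticSubject]) -> list:
    """View a cohort as in-memory :class:`~texturestager.image_io.ROISample`s.

    Equivalent to ``write_cohort`` followed by ``load_manifest`` but
    without touching disk; useful for simulation studies.
    """
    from texturestager.image_io import ROISample

    samples = []
    for subj in cohort:
        for seq, img in subj.images.items():
            for reader in (1, 2):
                samples.append(
                    ROISample(
                        subject_id=subj.subject_id,
                        sequence=seq,
                        reader=reader,
                        image=img.astype(np.float64),
                        mask=subj.masks[(seq, reader)],
                        class_label=subj.class_label,
                    )
                )
    return samples


def null_spec(**kwargs) -> CohortSpec:
    """Cohort spec with no class difference (both classes share parameters)."""
    kwargs.setdefault("correlation_length_pos", kwargs.get("correlation_length_neg", 3.0))
    kwargs.setdefault("noise_sd_pos", kwargs.get("noise_sd_neg", 25.0))
    return CohortSpec(**kwargs)


__all__ = [
    "CohortSpec",
    "cohort_to_samples",
    "SyntheticSubject",
    "EFFECT_PRESETS",
    "generate_cohort",
    "write_cohort",
    "null_spec",
]
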