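"""Synthetic inputs: stimulus sets, neural populations and fixation datasets.

The recordings this pipeline analyses — multi-area population responses to a
64-image natural-object stimulus set, and natural images paired with human
fixation points — are not publicly deposited.  This module generates
statistically structured stand-ins for every one of them so the whole
analysis chain can be exercised and validated end to end:

* texture-like stimulus images organised into categories (default 8
  categories of 8, i.e. the 64-stimulus design);
* per-area population rate tables whose representational geometry is driven
  either by low-level oriented-energy image features (V1-like) or by
  category identity (IT-like), with a mixing knob in between (V4-like);
* populations sampled from an explicit *planted* representational
  dissimilarity matrix, the ground truth for parameter-recovery tests;
* images plus fixation points sampled from a planted saliency density, with
  mirror augmentation as used to double the training corpus.

Every generator is a pure function of its parameters and an explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .neural import RateTable

__all__ = [
    "StimulusSet",
    "PlantedStructure",
    "FixationRecord",
    "StructureError",
    "AREA_PROFILES",
    "generate_stimulus_set",
    "oriented_energy_features",
    "generate_neural_population",
    "generate_from_planted_rdm",
    "planted_block_rdm",
    "random_latent_rdm",
    "gaussian_mixture_density",
    "generate_fixation_dataset",
    "mirror_augment",
    "save_stimulus_set",
    "save_fixation_records",
    "load_fixation_records",
]


class StructureError(ValueError):
    """A planted structure is internally inconsistent (e.g. non-PSD)."""


@dataclass
class StimulusSet:
    """Category-structured stimulus images (values in [0, 1])."""

    images: list  # (size, size, 3) float arrays
    category_labels: list
    stimulus_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.stimulus_ids:
            self.stimulus_ids = list(range(1, len(self.images) + 1))
        if len(self.images) != len(self.category_labels):
            raise ValueError("one category label per image required")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("all stimulus images must share dimensions")
        for im in self.images:
            if im.min() < 0 or im.max() > 1:
                raise ValueError("stimulus intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class PlantedStructure:
    """Generative target for a population with a known latent RDM."""

    latent_rdm: np.ndarray
    signal_to_noise: float
    n_neurons: int
    seed: int

    def __post_init__(self):
        r = np.asarray(self.latent_rdm, dtype=np.float64)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise StructureError("latent_rdm must be square")
        if not np.allclose(r, r.T):
            raise StructureError("latent_rdm must be symmetric")
        if not np.allclose(np.diag(r), 0):
            raise StructureError("latent_rdm must have a zero diagonal")
        if r.min() < 0 or r.max() > 2:
            raise StructureError("latent_rdm entries must lie in [0, 2]")
        if self.signal_to_noise < 0:
            raise StructureError("signal_to_noise must be nonnegative")
        if self.n_neurons < 2:
            raise StructureError("n_neurons must be >= 2")
        self.latent_rdm = r


@dataclass
class FixationRecord:
    """Fixation coordinates on the canvas, (x, y) pixel pairs."""

    image_id: int
    fixation_points: list
    canvas_wh: tuple = (320, 240)

    def __post_init__(self):
        cw, ch = self.canvas_wh
        for x, y in self.fixation_points:
            if not (0 <= x < cw and 0 <= y < ch):
                raise ValueError(
                    f"fixation ({x}, {y}) outside canvas {cw}x{ch}")


# ---------------------------------------------------------------------------
# stimulus images

def _bandpass_spectrum(size: int, orientation: float, frequency: float,
                       ori_bw: float, freq_bw: float) -> np.ndarray:
    """Amplitude spectrum concentrated around one orientation/frequency band."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.hypot(fx, fy)
    angle = np.arctan2(fy, fx)
    dori = np.angle(np.exp(2j * (angle - orientation))) / 2  # pi-periodic
    amp = (np.exp(-0.5 * (dori / ori_bw) ** 2)
           * np.exp(-0.5 * ((radius - frequency) / freq_bw) ** 2))
    amp[0, 0] = 0.0
    return amp


def generate_stimulus_set(n_categories: int = 8, per_category: int = 8,
                          seed: int = 0, size: int = 256) -> StimulusSet:
    """Texture-like stimulus images with a shared spectral component per category.

    Each category draws a base amplitude spectrum (a random orientation and
    spatial-frequency band); each image combines that base with random phase
    and a small per-image spectral perturbation, so images within a category
    share pixel statistics while differing individually.  The default
    8 x 8 design mirrors the 64-image natural-object stimulus set.
    """
    if n_categories < 1 or per_category < 1:
        raise ValueError("n_categories and per_category must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for ci in range(n_categories):
        ori = rng.uniform(0, np.pi)
        freq = rng.uniform(0.04, 0.25)
        base = _bandpass_spectrum(size, ori, freq, ori_bw=0.3, freq_bw=0.04)
        for _ in range(per_category):
            jitter = _bandpass_spectrum(
                size, rng.uniform(0, np.pi), rng.uniform(0.04, 0.25),
                ori_bw=0.5, freq_bw=0.08)
            amp = base + 0.35 * jitter
            img = np.empty((size, size, 3))
            for ch in range(3):
                phase = rng.uniform(0, 2 * np.pi, size=(size, size))
                f = amp * np.exp(1j * phase)
                tex = np.real(np.fft.ifft2(f))
                tex = (tex - tex.mean()) / (tex.std() + 1e-12)
                img[:, :, ch] = np.clip(0.5 + 0.18 * tex, 0.0, 1.0)
            images.append(img)
            labels.append(f"cat{ci + 1}")
    return StimulusSet(images=images, category_labels=labels)


# ---------------------------------------------------------------------------
# neural populations

def oriented_energy_features(stimuli: StimulusSet, n_orientations: int = 4,
                             n_scales: int = 2) -> np.ndarray:
    """Local oriented-energy descriptors, one row per stimulus.

    Grayscale images are band-pass filtered in the Fourier domain at
    ``n_orientations x n_scales`` orientation/frequency bands; the feature
    is the mean energy per band over a coarse 4x4 spatial grid.  This is
    the low-level feature basis used for V1-like tuning.
    """
    feats = []
    for im in stimuli.images:
        gray = im.mean(axis=2)
        size = gray.shape[0]
        f = np.fft.fft2(gray - gray.mean())
        rows = []
        for si in range(n_scales):
            freq = 0.06 * (2 ** si)
            for oi in range(n_orientations):
                ori = np.pi * oi / n_orientations
                amp = _bandpass_spectrum(size, ori, freq,
                                         ori_bw=0.35, freq_bw=0.03)
                energy = np.abs(np.fft.ifft2(f * amp)) ** 2
                g = energy.reshape(4, size // 4, 4, size // 4).mean(axis=(1, 3))
                rows.append(g.ravel())
        feats.append(np.concatenate(rows))
    X = np.asarray(feats)
    X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)
    return X


def _category_features(stimuli: StimulusSet) -> np.ndarray:
    cats = sorted(set(stimuli.category_labels))
    onehot = np.zeros((len(stimuli), len(cats)))
    for i, lab in enumerate(stimuli.category_labels):
        onehot[i, cats.index(lab)] = 1.0
    return onehot - onehot.mean(axis=0)


#: mixing weight of category-identity features (vs. oriented energy) per area
AREA_PROFILES = {"V1": 0.0, "V4": 0.5, "IT": 0.9}


def generate_neural_population(stimuli: StimulusSet, area_profile, n_neurons: int,
                               noise_sd: float = 1.0, seed: int = 0,
                               baseline: float = 10.0, gain: float = 4.0,
                               area_label: str | None = None) -> RateTable:
    """Simulated population rates (stimuli x neurons) with area-specific tuning.

    Each neuron's rate is ``baseline + gain * tuning . features(i)`` plus
    Gaussian noise of sd ``noise_sd`` (spikes/s), rectified at zero.
    ``area_profile`` is either a profile name ("V1", "V4", "IT") or a float
    in [0, 1] giving the weight of category-identity features relative to
    oriented-energy features: 0 is purely feature-driven (V1-like), 1 purely
    category-driven (IT-like).
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2 (an RDM needs >= 2 units)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if isinstance(area_profile, str):
        label = area_profile
        if area_profile not in AREA_PROFILES:
            raise ValueError(f"unknown area profile {area_profile!r}")
        mix = AREA_PROFILES[area_profile]
    else:
        mix = float(area_profile)
        label = area_label or f"synthetic(mix={mix:g})"
        if not 0 <= mix <= 1:
            raise ValueError("area_profile mix must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    low = oriented_energy_features(stimuli)
    cat = _category_features(stimuli)
    # centre each stimulus's feature vector so the population's pattern
    # correlations reproduce the *correlation* geometry of the feature rows
    # (random linear tuning otherwise transmits their cosine geometry)
    low = low - low.mean(axis=1, keepdims=True)
    cat = cat - cat.mean(axis=1, keepdims=True)
    # unit-norm blocks so `mix` is an interpretable proportion
    low = low / np.linalg.norm(low, axis=1, keepdims=True).mean()
    cat = cat / (np.linalg.norm(cat, axis=1, keepdims=True).mean() + 1e-12)
    # feature rows are ~unit norm, so with N(0,1) tuning weights each
    # neuron's stimulus-driven sd is ~`gain` spikes/s
    feats = np.hstack([(1 - mix) * low, mix * cat])
    tuning = rng.standard_normal((feats.shape[1], n_neurons))
    rates = baseline + gain * feats @ tuning
    rates += rng.normal(0.0, noise_sd, size=rates.shape)
    rates = np.maximum(rates, 0.0)
    df = pd.DataFrame(rates, index=list(stimuli.stimulus_ids),
                      columns=[f"n{j + 1}" for j in range(n_neurons)])
    df.index.name = "stimulus_id"
    return RateTable(rates=df, area=area_label or label)


def random_latent_rdm(n_stimuli: int, rank: int = 20, seed: int = 0) -> np.ndarray:
    """Continuous-valued latent RDM realisable by a population.

    Drawn as the correlation-distance RDM of ``n_stimuli`` random prototype
    patterns of dimension ``rank``, so the implied correlation matrix is
    positive semidefinite by construction and the dissimilarities are
    spread continuously (no ties) — the preferred ground truth for
    rank-based recovery tests, where a two-valued block RDM would be
    degraded by tied ranks.
    """
    g = np.random.default_rng(seed).standard_normal((n_stimuli, rank))
    rdm = 1.0 - np.corrcoef(g)
    np.fill_diagonal(rdm, 0.0)
    return np.clip(rdm, 0.0, 2.0)


def planted_block_rdm(n_stimuli: int, labels=None, within: float = 0.7,
                      between: float = 0.0) -> np.ndarray:
    """Latent RDM with block (category) structure.

    Same-category stimulus pairs get dissimilarity ``1 - within``,
    different-category pairs ``1 - between``.  The implied correlation
    matrix is positive semidefinite for ``0 <= between <= within <= 1``.
    """
    if labels is None:
        labels = np.arange(n_stimuli) // max(1, n_stimuli // 8)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, within, between)
    np.fill_diagonal(corr, 1.0)
    rdm = 1.0 - corr
    np.fill_diagonal(rdm, 0.0)
    return rdm


def generate_from_planted_rdm(plan: PlantedStructure) -> RateTable:
    """Population whose inter-stimulus pattern correlations follow a latent RDM.

    Stimulus patterns are drawn from a multivariate Gaussian across stimuli
    with correlation matrix ``1 - latent_rdm`` (one independent draw per
    neuron), then independent unit-variance noise scaled by
    ``1 / signal_to_noise`` is added.  With finite noise the empirical
    correlations are the latent ones attenuated by snr^2 / (1 + snr^2), a
    monotone affine map, so the empirical RDM's *correspondence* with the
    latent converges to 1 as n_neurons grows; the matrix itself converges
    to the latent only in the noiseless limit.  ``signal_to_noise = 0``
    yields pure noise (no planted structure).
    """
    corr = 1.0 - plan.latent_rdm
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-8 * max(1.0, vals.max()):
        raise StructureError(
            "implied correlation matrix (1 - latent_rdm) is not positive "
            f"semidefinite (min eigenvalue {vals.min():.3g}); the latent RDM "
            "cannot be realised by any population")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(plan.seed)
    n = plan.latent_rdm.shape[0]
    z = rng.standard_normal((n, plan.n_neurons))
    signal = root @ z
    noise = rng.standard_normal((n, plan.n_neurons))
    snr = plan.signal_to_noise
    patterns = snr * signal + noise if snr > 0 else noise
    df = pd.DataFrame(patterns, index=np.arange(1, n + 1),
                      columns=[f"n{j + 1}" for j in range(plan.n_neurons)])
    df.index.name = "stimulus_id"
    return RateTable(rates=df, area="synthetic")


# ---------------------------------------------------------------------------
# fixation datasets

def gaussian_mixture_density(canvas_wh: tuple[int, int], n_components: int = 3,
                             seed: int = 0, sigma_frac=(0.05, 0.15)) -> np.ndarray:
    """Normalised saliency density: a random mixture of 2D Gaussians.

    Emulates the sparse multi-peak structure of empirical fixation maps.
    Returns a (height, width) grid summing to 1.
    """
    cw, ch = canvas_wh
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ch, 0:cw]
    density = np.zeros((ch, cw))
    for _ in range(n_components):
        cx = rng.uniform(0.15 * cw, 0.85 * cw)
        cy = rng.uniform(0.15 * ch, 0.85 * ch)
        sig = rng.uniform(*sigma_frac) * min(cw, ch)
        weight = rng.uniform(0.5, 1.0)
        density += weight * np.exp(-0.5 * (((xx - cx) / sig) ** 2
                                           + ((yy - cy) / sig) ** 2))
    return density / density.sum()


def _texture_image(rng: np.random.Generator, canvas_wh) -> np.ndarray:
    cw, ch = canvas_wh
    img = np.empty((ch, cw, 3))
    for c in range(3):
        noise = rng.standard_normal((ch, cw))
        f = np.fft.fft2(noise)
        fy = np.fft.fftfreq(ch)[:, None]
        fx = np.fft.fftfreq(cw)[None, :]
        radius = np.hypot(fx, fy)
        radius[0, 0] = 1.0
        tex = np.real(np.fft.ifft2(f / radius))  # 1/f spectrum
        tex = (tex - tex.mean()) / (tex.std() + 1e-12)
        img[:, :, c] = np.clip(0.5 + 0.2 * tex, 0, 1)
    return img


def generate_fixation_dataset(n_images: int, points_per_image: int,
                              density: np.ndarray | None = None, seed: int = 0,
                              canvas_wh: tuple[int, int] = (320, 240)):
    """Images paired with fixation points sampled i.i.d. from a saliency density.

    ``density`` is a (height, width) grid summing to 1; by default each
    image gets its own random 3-component Gaussian-mixture density.
    Returns a list of ``(image, FixationRecord)`` pairs; images are RGB
    naturalistic (1/f) textures at canvas resolution.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    cw, ch = canvas_wh
    if density is not None:
        density = np.asarray(density, dtype=np.float64)
        if density.shape != (ch, cw):
            raise ValueError(f"density must be (height={ch}, width={cw})")
        if abs(density.sum() - 1.0) > 1e-8 or density.min() < 0:
            raise ValueError("density must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        if density is None:
            d = gaussian_mixture_density(
                canvas_wh, seed=int(rng.integers(2 ** 31)))
        else:
            d = density
        img = _texture_image(rng, canvas_wh)
        flat = rng.choice(d.size, size=points_per_image, p=d.ravel())
        ys, xs = np.unravel_index(flat, d.shape)
        points = [(int(x), int(y)) for x, y in zip(xs, ys)]
        out.append((img, FixationRecord(image_id=i + 1, fixation_points=points,
                                        canvas_wh=canvas_wh)))
    return out


def mirror_augment(pairs):
    """Append left-right mirrored copies of each (image, map) pair.

    Doubles the training corpus (e.g. 5,790 originals -> 11,580 pairs).
    Mirroring is about the vertical midline: column x maps to width-1-x in
    both the image and its ground-truth map.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("mirror_augment requires a nonempty list")
    mirrored = [(np.asarray(im)[:, ::-1].copy(), np.asarray(mp)[:, ::-1].copy())
                for im, mp in pairs]
    return pairs + mirrored


# ---------------------------------------------------------------------------
# I/O

def save_stimulus_set(stimuli: StimulusSet, out_dir) -> Path:
    """Write PNGs plus a TSV manifest (stimulus_id, category, filename)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, lab, im in zip(stimuli.stimulus_ids, stimuli.category_labels,
                            stimuli.images):
        fname = f"stim{sid:03d}.png"
        arr = np.clip(np.round(im * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out_dir / fname)
        rows.append({"stimulus_id": sid, "category": lab, "filename": fname})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def save_fixation_records(records, path, canvas_wh=(320, 240)) -> None:
    """Write fixation records as TSV (image_id, x, y), one row per fixation."""
    rows = [{"image_id": r.image_id, "x": x, "y": y}
            for r in records for x, y in r.fixation_points]
    pd.DataFrame(rows, columns=["image_id", "x", "y"]).to_csv(
        path, sep="\t", index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({"canvas": list(canvas_wh)}))


def load_fixation_records(path):
    df = pd.read_csv(path, sep="\t")
    sidecar = Path(path).with_suffix(".json")
    canvas = (320, 240)
    if sidecar.exists():
        canvas = tuple(json.loads(sidecar.read_text())["canvas"])
    out = []
    for image_id, grp in df.groupby("image_id", sort=True):
        pts = [(int(x), int(y)) for x, y in zip(grp["x"], grp["y"])]
        out.append(FixationRecord(image_id=int(image_id), fixation_points=pts,
                                  canvas_wh=canvas))
    return out
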