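"""Synthetic labelled mass spectra with realistic acquisition variability.

The generator emulates the failure modes that make real profile spectra
hard to classify: per-spectrum jitter of every peak position (instrument
calibration drift), multiplicative log-normal intensity fluctuation,
an exponentially decaying additive baseline, additive detector noise and
occasional peak dropout.  Classes are defined by peak templates; a
configurable fraction of peak positions is shared across classes
("housekeeping" ions) so that class identity rests on the remainder.

Multi-task families emulate the transfer/cumulative-learning setting: one
large two-class source task plus several small target tasks on the same
bin grid, whose templates share a chosen fraction of generic peak
structure with the source.

Spectra are synthesised on a dense m/z axis at one fifth of the bin width
before binning, so sub-bin jitter produces genuine bin-level
misalignment — the artefact pooling layers are expected to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binning import BinGrid, RawSpectrum, SpectraDataset, bin_spectrum, scale_unit_interval

__all__ = [
    "ClassTemplate",
    "NoiseModel",
    "TaskSpec",
    "make_templates",
    "synthesize_spectrum",
    "generate_task",
    "generate_task_family",
    "family_specs",
]

DENSE_OVERSAMPLING = 5  # dense synthesis axis at bin_width / 5


@dataclass(frozen=True)
class ClassTemplate:
    """Ground-truth peak list of one class: positions (Da), amplitudes, width."""

    peak_mz: np.ndarray
    peak_amp: np.ndarray
    peak_width: float
    class_name: str

    def __post_init__(self):
        object.__setattr__(self, "peak_mz", np.asarray(self.peak_mz, dtype=float))
        object.__setattr__(self, "peak_amp", np.asarray(self.peak_amp, dtype=float))
        if self.peak_mz.shape != self.peak_amp.shape:
            raise ValueError("peak_mz and peak_amp must have equal length")
        if np.any(self.peak_amp <= 0) or self.peak_width <= 0:
            raise ValueError("amplitudes and width must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum variability model.

    shift_sd        Gaussian sd (Da) of the additive jitter applied to every
                    peak position in a spectrum (peak misalignment).
    intensity_cv    coefficient of variation of the per-peak multiplicative
                    log-normal amplitude fluctuation.
    baseline_amp    amplitude of the additive exponential baseline
                    ``a * exp(-decay * (mz - mass_min))``.
    baseline_decay  baseline decay constant (1/Da).
    noise_sd        sd of additive Gaussian noise, clipped at zero.
    dropout_p       probability that any given peak is absent from a spectrum.
    contaminant_rate
                    Poisson mean count of spurious chemical-background peaks
                    per spectrum, placed uniformly at random positions with
                    amplitudes comparable to the weaker template peaks.
    """

    shift_sd: float = 0.5
    intensity_cv: float = 0.6
    baseline_amp: float = 0.5
    baseline_decay: float = 0.01
    noise_sd: float = 0.1
    dropout_p: float = 0.15
    contaminant_rate: float = 10.0

    def __post_init__(self):
        if min(self.shift_sd, self.intensity_cv, self.baseline_amp, self.baseline_decay,
               self.noise_sd, self.contaminant_rate) < 0 or not 0 <= self.dropout_p < 1:
            raise ValueError("noise parameters must be >= 0 and dropout_p in [0, 1)")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TaskSpec:
    """Recipe for one labelled classification task."""

    grid: BinGrid
    templates: tuple[ClassTemplate, ...]
    n_per_class: tuple[int, ...]
    noise: NoiseModel = field(default_factory=NoiseModel)
    shared_fraction: float = 0.3
    seed: int = 0
    name: str = "task"

    def __post_init__(self):
        if len(self.n_per_class) != len(self.templates):
            raise ValueError("n_per_class must match number of templates")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")


def _draw_positions(rng, lo, hi, n, existing, min_sep):
    """Sample n positions in (lo, hi), each >= min_sep away from all others.

    Positions come from a randomly offset lattice with pitch ``2 * min_sep``
    plus sub-pitch jitter, which guarantees mutual separation and gives a
    hard capacity bound instead of open-ended rejection sampling.
    """
    pitch = 1.25 * min_sep
    offset = rng.uniform(0, pitch)
    slots = np.arange(lo + offset, hi, pitch)
    jitter = rng.uniform(-min_sep / 8, min_sep / 8, size=len(slots))
    slots = slots + jitter
    existing = np.asarray(list(existing), dtype=float)
    if existing.size:
        keep = np.min(np.abs(slots[:, None] - existing[None, :]), axis=1) >= min_sep
        slots = slots[keep]
    if len(slots) < n:
        raise ValueError(
            f"cannot place {n} peaks with separation {min_sep} in [{lo:.1f}, {hi:.1f}] "
            f"({len(slots)} free slots)"
        )
    return slots[rng.permutation(len(slots))[:n]].tolist()


def make_templates(
    n_classes: int,
    n_peaks: int,
    shared_fraction: float,
    grid: BinGrid,
    seed: int = 0,
    peak_width: float | None = None,
    position_pool: Sequence[float] | None = None,
    pool_fraction: float = 0.0,
    class_names: Sequence[str] | None = None,
    shared_amp_range: tuple[float, float] = (0.5, 2.0),
    specific_amp_range: tuple[float, float] = (0.5, 2.0),
    class_amp_variation: float = 0.0,
) -> list[ClassTemplate]:
    """Build one peak template per class.

    ``floor(shared_fraction * n_peaks)`` positions are common to all classes
    (housekeeping signal); the remainder is class-specific.  When a
    ``position_pool`` is given (the peak dictionary of another task family),
    ``floor(pool_fraction * n_peaks)`` of the shared positions are drawn from
    it, producing controlled cross-task overlap.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if n_peaks > grid.n_bins:
        raise ValueError(f"n_peaks={n_peaks} exceeds the {grid.n_bins}-bin grid")
    rng = np.random.default_rng(seed)
    sigma = peak_width if peak_width is not None else 1.5 * grid.bin_width
    margin = 10 * sigma + 3 * grid.bin_width
    lo, hi = grid.mass_min + margin, grid.mass_max - margin
    min_sep = 6 * sigma

    n_shared = int(np.floor(shared_fraction * n_peaks))
    n_from_pool = min(int(np.floor(pool_fraction * n_peaks)), n_shared)
    shared = []
    if position_pool is not None and n_from_pool > 0:
        pool = [p for p in position_pool if lo < p < hi]
        take = min(n_from_pool, len(pool))
        shared.extend(rng.choice(pool, size=take, replace=False).tolist())
    n_specific = n_peaks - n_shared
    n_new_shared = n_shared - len(shared)
    # one lattice draw for the whole template set guarantees capacity
    fresh = _draw_positions(
        rng, lo, hi, n_new_shared + n_classes * n_specific, shared, min_sep
    )
    shared.extend(fresh[:n_new_shared])
    specific = fresh[n_new_shared:]
    shared_amp = rng.uniform(*shared_amp_range, size=n_shared)

    names = list(class_names) if class_names else [f"class{c}" for c in range(n_classes)]
    templates = []
    for c in range(n_classes):
        own = specific[c * n_specific : (c + 1) * n_specific]
        own_amp = rng.uniform(*specific_amp_range, size=len(own))
        pos = np.array(shared + list(own))
        if class_amp_variation > 0:
            # classes express the common scaffold at class-specific levels
            sh_amp = shared_amp * np.exp(
                rng.normal(0.0, class_amp_variation, size=n_shared)
            )
        else:
            sh_amp = shared_amp
        amp = np.concatenate([sh_amp, own_amp])
        order = np.argsort(pos)
        templates.append(ClassTemplate(pos[order], amp[order], sigma, names[c]))
    return templates


def synthesize_spectrum(
    template: ClassTemplate, noise: NoiseModel, rng: np.random.Generator, grid: BinGrid
) -> RawSpectrum:
    """Draw one noisy profile spectrum from a class template.

    The profile is the sum of surviving Gaussian peaks at jittered
    positions with log-normally perturbed amplitudes, plus an exponential
    baseline and additive Gaussian noise clipped at zero.
    """
    step = grid.bin_width / DENSE_OVERSAMPLING
    mz = grid.mass_min + step * np.arange(int(round((grid.mass_max - grid.mass_min) / step)))
    signal = np.zeros_like(mz)

    keep = rng.random(len(template.peak_mz)) >= noise.dropout_p
    shifts = rng.normal(0.0, noise.shift_sd, size=len(template.peak_mz))
    if noise.intensity_cv > 0:
        # log-normal with unit median and the requested CV
        sd = np.sqrt(np.log1p(noise.intensity_cv**2))
        factors = np.exp(rng.normal(0.0, sd, size=len(template.peak_mz)))
    else:
        factors = np.ones(len(template.peak_mz))

    sigma = template.peak_width
    half = 5 * sigma
    for pos, amp, sh, f, k in zip(
        template.peak_mz, template.peak_amp, shifts, factors, keep, strict=True
    ):
        if not k:
            continue
        center = pos + sh
        i0 = np.searchsorted(mz, center - half)
        i1 = np.searchsorted(mz, center + half)
        window = mz[i0:i1]
        signal[i0:i1] += amp * f * np.exp(-0.5 * ((window - center) / sigma) ** 2)

    if noise.contaminant_rate > 0:
        n_cont = rng.poisson(noise.contaminant_rate)
        pos = rng.uniform(grid.mass_min + half, grid.mass_max - half, size=n_cont)
        amp = rng.uniform(0.2, 0.8, size=n_cont)
        for center, a in zip(pos, amp):
            i0 = np.searchsorted(mz, center - half)
            i1 = np.searchsorted(mz, center + half)
            window = mz[i0:i1]
            signal[i0:i1] += a * np.exp(-0.5 * ((window - center) / sigma) ** 2)

    if noise.baseline_amp > 0:
        signal += noise.baseline_amp * np.exp(-noise.baseline_decay * (mz - grid.mass_min))
    if noise.noise_sd > 0:
        signal += rng.normal(0.0, noise.noise_sd, size=len(mz))
    np.clip(signal, 0.0, None, out=signal)
    return RawSpectrum(mz, signal)


def generate_task(spec: TaskSpec, scale: bool = True) -> SpectraDataset:
    """Generate the binned, labelled dataset a :class:`TaskSpec` describes.

    Each spectrum gets an independent RNG substream keyed by
    ``(seed, class, index)`` so generation order cannot change results.
    """
    rows, labels, ids = [], [], []
    for c, (template, n_c) in enumerate(zip(spec.templates, spec.n_per_class, strict=True)):
        for i in range(n_c):
            rng = np.random.default_rng([spec.seed % (2**31), c, i])
            raw = synthesize_spectrum(template, spec.noise, rng, spec.grid)
            rows.append(bin_spectrum(raw, spec.grid, "sum"))
            labels.append(c)
            ids.append(f"{spec.name}_c{c}_{i}")
    ds = SpectraDataset(
        matrix=np.stack(rows),
        labels=np.array(labels),
        class_names=[t.class_name for t in spec.templates],
        grid=spec.grid,
        sample_ids=ids,
    )
    return scale_unit_interval(ds) if scale else ds


def generate_task_family(
    source_spec: TaskSpec,
    target_specs: Sequence[TaskSpec],
    scale: bool = True,
) -> dict[str, SpectraDataset]:
    """Generate a source task plus its target tasks on a common grid."""
    dims = {s.grid.n_bins for s in (source_spec, *target_specs)}
    if len(dims) != 1:
        raise ValueError(f"all tasks must share one feature dimension, got {sorted(dims)}")
    widths = {s.grid.bin_width for s in (source_spec, *target_specs)}
    if len(widths) != 1:
        raise ValueError("all tasks must share one bin width")
    out = {source_spec.name: generate_task(source_spec, scale)}
    for spec in target_specs:
        out[spec.name] = generate_task(spec, scale)
    return out


def family_specs(
    seed: int = 0,
    overlap: float = 0.5,
    preset: str = "default",
    noise: NoiseModel | None = None,
) -> tuple[TaskSpec, list[TaskSpec]]:
    """Task specs for the standard multi-task family.

    One large binary source task (tissue-typing shape) and three targets on
    the same grid: a 12-class histology-like task with ~20 spectra per
    class, a 5-class microorganism-like task with ~24 per class, and a
    binary intermediate task — mirroring the shape of a large imaging
    dataset feeding several small clinical ones.  ``preset='acceptance'``
    keeps the task structure but reduces the source to 2 x 1000 spectra on
    a 2000-bin grid so the whole family trains quickly on one CPU.
    """
    if preset == "default":
        grid = BinGrid(100.0, 1600.0, 0.1)  # 15000 features
        n_source = 5000
        n_intermediate = 1300
    elif preset == "acceptance":
        grid = BinGrid(100.0, 300.0, 0.1)  # 2000 features
        n_source = 1000
        n_intermediate = 260  # ~26% of the source, the medium-task proportion
    else:
        raise ValueError(f"unknown preset {preset!r}")
    noise = noise if noise is not None else NoiseModel()
    n_peaks = 30 if preset == "default" else 15

    # one spectral physics for every task in the family: a mostly shared
    # scaffold with a few weaker class-specific peaks; tasks differ in class
    # count and sample size, the way a large source and small clinical
    # targets do
    src_templates = make_templates(
        2, n_peaks, 0.7, grid, seed=seed, class_names=["matter_a", "matter_b"],
        specific_amp_range=(0.3, 0.9),
    )
    pool = np.concatenate([t.peak_mz for t in src_templates])
    source = TaskSpec(grid, tuple(src_templates), (n_source, n_source),
                      noise, 0.7, seed, "source")

    def target(n_classes, n_per, name, sub, specific_amp=(0.3, 0.9)):
        # clinical-style targets: classes share most of the peak scaffold and
        # differ in a few weaker presence/absence peaks
        templates = make_templates(
            n_classes, n_peaks, 0.7, grid, seed=seed + sub,
            position_pool=pool, pool_fraction=overlap,
            specific_amp_range=specific_amp,
        )
        return TaskSpec(grid, tuple(templates), tuple(n_per), noise, 0.7, seed + sub, name)

    targets = [
        target(2, [n_intermediate, n_intermediate], "intermediate", 1),
        # species-level differences: strong class-specific peaks, the highly
        # separable regime typical of microbial biotyping
        target(5, [24, 26, 24, 18, 23], "micro5", 2, specific_amp=(0.8, 1.8)),
        target(12, [20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 20, 20], "histology12", 3),
    ]
    return source, targets
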