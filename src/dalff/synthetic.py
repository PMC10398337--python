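"""Synthetic 4D BOLD-like cohorts with known ground truth.

Two generation modes cover the downstream analyses:

* :func:`generate_cohort` plants group differences in windowed-ALFF
  variability: each voxel carries band-limited oscillations whose slow
  amplitude envelope is modulated with a region/group-specific depth, so the
  coefficient of variation of sliding-window ALFF differs between groups in
  the planted blocks and nowhere else.
* :func:`generate_state_cohort` makes the spatial amplitude pattern switch
  between k prototype maps following a first-order Markov chain, producing
  known state sequences, occupancies, dwell times and transition counts.

Both are fully reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .preprocess import FWHM_TO_SIGMA, BoldImage, save_bold, save_covariates, save_volume

__all__ = [
    "EffectRegion",
    "SyntheticConfig",
    "GroundTruth",
    "Subject",
    "generate_cohort",
    "generate_state_cohort",
    "generate_atlas",
    "make_block_prototypes",
    "sample_markov_chain",
    "write_cohort",
]


@dataclass
class EffectRegion:
    """A rectangular voxel block with per-group envelope modulation depth."""

    name: str
    corner: tuple[int, int, int]
    size: tuple[int, int, int]
    depth_patient: float = 0.0
    depth_control: float = 0.0

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic BOLD generator.

    Defaults follow a 240-volume, TR = 2 s acquisition on a scaled-down grid.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_volumes: int = 240
    tr: float = 2.0
    n_patients: int = 20
    n_controls: int = 20
    effect_regions: list[EffectRegion] = field(default_factory=list)
    carrier_band: tuple[float, float] = (0.01, 0.08)
    envelope_freq: float = 0.005
    ar1_coef: float = 0.3
    noise_sd: float = 1.0
    drift_order: int = 1
    drift_scale: float = 0.5
    smooth_fwhm: float = 6.0
    carrier_amplitude: float = 1.0
    # state-switching mode
    state_prototypes: np.ndarray | None = None  # (k, x, y, z) amplitude maps
    state_transition_matrix: np.ndarray | None = None  # (k, k) row-stochastic
    epoch_length: int = 30  # TR units; one state label per epoch
    window_lengths: tuple[int, ...] = (30, 50, 80)
    seed: int = 0

    def validate(self) -> None:
        if any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        nyquist = 1.0 / (2.0 * self.tr)
        f_lo, f_hi = self.carrier_band
        if not (0 < f_lo < f_hi < nyquist):
            raise ValueError(
                f"carrier band must satisfy 0 < f_lo < f_hi < Nyquist={nyquist}; got {self.carrier_band}"
            )
        if self.envelope_freq >= f_lo:
            raise ValueError(
                f"envelope_freq {self.envelope_freq} must lie below the carrier band "
                f"(f_lo={f_lo}) or the modulation leaks into the analysis band"
            )
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.window_lengths and self.n_volumes < max(self.window_lengths) + 10:
            raise ValueError(
                f"n_volumes={self.n_volumes} too short for the longest window "
                f"{max(self.window_lengths)} (+10 discard margin)"
            )
        for region in self.effect_regions:
            if min(region.depth_patient, region.depth_control) < 0:
                raise ValueError(f"region {region.name}: modulation depths must be >= 0")
            for c, s, g in zip(region.corner, region.size, self.grid_shape):
                if c < 0 or s < 1 or c + s > g:
                    raise ValueError(f"region {region.name} does not fit inside grid {self.grid_shape}")
        if self.state_transition_matrix is not None:
            tm = np.asarray(self.state_transition_matrix, dtype=np.float64)
            if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
                raise ValueError("state_transition_matrix must be square")
            if np.any(tm < 0) or np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError("state_transition_matrix rows must each sum to 1")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        # center the grid on the world origin, MNI-style
        aff[:3, 3] = -0.5 * (np.array(self.grid_shape) - 1) * np.array(self.voxel_size)
        return aff


@dataclass
class GroundTruth:
    """What was planted: effect voxels, covariates, and (optionally) states."""

    effect_mask: np.ndarray
    covariates: pd.DataFrame
    state_sequences: dict[str, np.ndarray] | None = None
    transition_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.state_sequences is not None:
            for sid, seq in self.state_sequences.items():
                if np.any(seq < 1):
                    raise ValueError(f"state sequence of {sid} must use labels 1..k")


@dataclass
class Subject:
    subject_id: str
    group: str
    bold: BoldImage


def _subject_covariates(rng: np.random.Generator) -> dict:
    """Age/sex/clinical-score draws, independent of the planted effect."""
    return {
        "age": float(np.round(rng.uniform(20.0, 80.0), 1)),
        "sex": int(rng.integers(0, 2)),
        "score": int(rng.poisson(4.0)),
    }


def _carrier_frequencies(
    band: tuple[float, float], tr: float, window_length: int = 30
) -> np.ndarray:
    """Up to three fixed tones aligned to the DFT bins of the default window.

    Bin alignment (f = j / (window_length * tr)) makes the tones mutually
    orthogonal within every window of that length, so with no envelope
    modulation and no noise the windowed ALFF is constant across windows.
    """
    f_lo, f_hi = band
    base = 1.0 / (window_length * tr)
    js = np.arange(1, int(np.floor(f_hi / base)) + 1)
    js = js[(js * base >= f_lo) & (js * base <= f_hi)]
    if js.size == 0:
        raise ValueError(f"no window-bin frequency inside {band} Hz at tr={tr}")
    if js.size > 3:
        js = js[np.linspace(0, js.size - 1, 3).round().astype(int)]
    return js * base


def _ar1_noise(
    rng: np.random.Generator,
    shape_spatial: tuple[int, ...],
    t: int,
    ar1: float,
    sd: float,
    sigma_vox: np.ndarray,
) -> np.ndarray:
    """AR(1) Gaussian noise, optionally spatially smoothed volume-by-volume."""
    if sd == 0:
        return np.zeros(shape_spatial + (t,))
    burn = 25
    white = rng.standard_normal(shape_spatial + (t + burn,))
    if ar1 > 0:
        innov_sd = np.sqrt(1.0 - ar1**2)  # unit marginal variance
        series = signal.lfilter([innov_sd], [1.0, -ar1], white, axis=-1)
    else:
        series = white
    series = series[..., burn:]
    if np.any(sigma_vox > 0):
        series = ndimage.gaussian_filter(series, sigma=tuple(sigma_vox) + (0.0,), mode="reflect")
        # restore unit marginal variance lost to smoothing
        series /= series.std()
    return sd * series


def _drift(rng: np.random.Generator, t: int, order: int, scale: float) -> np.ndarray:
    if order <= 0 or scale == 0:
        return np.zeros(t)
    x = np.linspace(-1.0, 1.0, t)
    coeffs = rng.normal(0.0, scale, size=order)
    return sum(c * x ** (d + 1) for d, c in enumerate(coeffs))


def generate_cohort(config: SyntheticConfig) -> tuple[list[Subject], GroundTruth]:
    """Generate a two-group cohort with planted windowed-ALFF-CV differences.

    Every voxel's series is drift + sum of carriers a(t) sin(2 pi f t + phi)
    with envelope a(t) = A (1 + m g(t)), where g is a zero-mean slow sinusoid
    with subject-random phase and m is the region/group modulation depth, plus
    AR(1) Gaussian noise.  Patients and controls differ only through m inside
    the effect regions.
    """
    config.validate()
    shape = tuple(config.grid_shape)
    t = config.n_volumes
    time = np.arange(t) * config.tr
    freqs = _carrier_frequencies(config.carrier_band, config.tr)
    sigma_vox = (
        config.smooth_fwhm * FWHM_TO_SIGMA / np.asarray(config.voxel_size)
        if config.smooth_fwhm > 0
        else np.zeros(3)
    )
    mask = np.ones(shape, dtype=bool)
    effect_mask = np.zeros(shape, dtype=bool)
    depth = {"patient": np.zeros(shape), "control": np.zeros(shape)}
    for region in config.effect_regions:
        sl = region.slices()
        depth["patient"][sl] = region.depth_patient
        depth["control"][sl] = region.depth_control
        if region.depth_patient != region.depth_control:
            effect_mask[sl] = True

    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    seeds = np.random.SeedSequence(config.seed).spawn(len(groups))
    subjects: list[Subject] = []
    cov_rows = []
    for i, (group, seed) in enumerate(zip(groups, seeds)):
        rng = np.random.default_rng(seed)
        sid = f"sub-{i + 1:03d}"
        phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
        env_phase = rng.uniform(0, 2 * np.pi)
        g_t = np.sin(2 * np.pi * config.envelope_freq * time + env_phase)
        carrier = sum(
            config.carrier_amplitude * np.sin(2 * np.pi * f * time + p)
            for f, p in zip(freqs, phases)
        )
        envelope = 1.0 + depth[group][..., None] * g_t  # (x, y, z, t)
        data = envelope * carrier
        data += _drift(rng, t, config.drift_order, config.drift_scale)
        data += _ar1_noise(rng, shape, t, config.ar1_coef, config.noise_sd, sigma_vox)
        subjects.append(
            Subject(sid, group, BoldImage(data=data, affine=config.affine, tr=config.tr, mask=mask))
        )
        cov_rows.append({"subject_id": sid, "group": group, **_subject_covariates(rng)})

    truth = GroundTruth(effect_mask=effect_mask, covariates=pd.DataFrame(cov_rows))
    return subjects, truth


def sample_markov_chain(
    transition_matrix: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> np.ndarray:
    """Sample a first-order chain; returns 1-based labels of length n_steps."""
    tm = np.asarray(transition_matrix, dtype=np.float64)
    k = tm.shape[0]
    labels = np.empty(n_steps, dtype=np.int64)
    state = (initial_state - 1) if initial_state is not None else int(rng.integers(0, k))
    for i in range(n_steps):
        labels[i] = state + 1
        state = int(rng.choice(k, p=tm[state]))
    return labels


def generate_state_cohort(config: SyntheticConfig) -> tuple[list[Subject], GroundTruth]:
    """Generate a cohort whose spatial amplitude pattern switches states.

    Time is split into epochs of ``config.epoch_length`` volumes.  Each epoch
    draws its state from a first-order Markov chain over the prototype maps;
    within the epoch every voxel oscillates at a mid-band frequency with the
    prototype amplitude.  Analyzing with window = step = epoch_length makes
    window i correspond exactly to epoch i.
    """
    config.validate()
    if config.state_prototypes is None or config.state_transition_matrix is None:
        raise ValueError("state_prototypes and state_transition_matrix are required")
    protos = np.asarray(config.state_prototypes, dtype=np.float64)
    k = protos.shape[0]
    if k < 2:
        raise ValueError("state analysis is degenerate with a single state; need k >= 2")
    if protos.shape[1:] != tuple(config.grid_shape):
        raise ValueError(f"prototype maps must have shape {config.grid_shape}")
    tm = np.asarray(config.state_transition_matrix, dtype=np.float64)
    if tm.shape != (k, k):
        raise ValueError(f"transition matrix shape {tm.shape} does not match k={k} prototypes")

    shape = tuple(config.grid_shape)
    t = config.n_volumes
    epoch = int(config.epoch_length)
    n_epochs = t // epoch
    if n_epochs < 1:
        raise ValueError("epoch_length exceeds n_volumes")
    time = np.arange(t) * config.tr
    f0 = float(np.mean(config.carrier_band))
    sigma_vox = (
        config.smooth_fwhm * FWHM_TO_SIGMA / np.asarray(config.voxel_size)
        if config.smooth_fwhm > 0
        else np.zeros(3)
    )
    mask = np.ones(shape, dtype=bool)

    n_total = config.n_patients + config.n_controls
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    seeds = np.random.SeedSequence(config.seed).spawn(n_total)
    subjects: list[Subject] = []
    cov_rows = []
    sequences: dict[str, np.ndarray] = {}
    for i, (group, seed) in enumerate(zip(groups, seeds)):
        rng = np.random.default_rng(seed)
        sid = f"sub-{i + 1:03d}"
        labels = sample_markov_chain(tm, n_epochs, rng)
        sequences[sid] = labels
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * f0 * time + phase)
        amp = np.empty(shape + (t,))
        for e in range(n_epochs):
            amp[..., e * epoch : (e + 1) * epoch] = protos[labels[e] - 1][..., None]
        if n_epochs * epoch < t:  # tail beyond the last full epoch keeps the last state
            amp[..., n_epochs * epoch :] = protos[labels[-1] - 1][..., None]
        data = amp * carrier
        data += _ar1_noise(rng, shape, t, config.ar1_coef, config.noise_sd, sigma_vox)
        subjects.append(
            Subject(sid, group, BoldImage(data=data, affine=config.affine, tr=config.tr, mask=mask))
        )
        cov_rows.append({"subject_id": sid, "group": group, **_subject_covariates(rng)})

    truth = GroundTruth(
        effect_mask=np.zeros(shape, dtype=bool),
        covariates=pd.DataFrame(cov_rows),
        state_sequences=sequences,
        transition_matrix=tm,
    )
    return subjects, truth


def make_block_prototypes(
    grid_shape: tuple[int, int, int], k: int, base: float = 1.0, boost: float = 2.0
) -> np.ndarray:
    """k well-separated amplitude maps: slab i along x gets the boosted value."""
    protos = np.full((k,) + tuple(grid_shape), base)
    edges = np.linspace(0, grid_shape[0], k + 1).astype(int)
    for i in range(k):
        protos[i, edges[i] : edges[i + 1]] = boost
    return protos


def generate_atlas(
    regions: list[EffectRegion], grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Integer-labeled ROI volume from disjoint blocks; 0 = background."""
    atlas = np.zeros(tuple(grid_shape), dtype=np.int32)
    for label, region in enumerate(regions, start=1):
        sl = region.slices()
        for c, s, g in zip(region.corner, region.size, grid_shape):
            if c < 0 or c + s > g:
                raise ValueError(f"region {region.name} exceeds grid {grid_shape}")
        if np.any(atlas[sl] != 0):
            raise ValueError(f"region {region.name} overlaps a previously defined region")
        atlas[sl] = label
    return atlas


def write_cohort(
    subjects: list[Subject], truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write per-subject 4D NIfTI, the covariate CSV and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for subject in subjects:
        p = out / f"{subject.subject_id}_bold.nii"
        save_bold(subject.bold, p)
        paths[subject.subject_id] = p
    cov_path = out / "covariates.csv"
    save_covariates(truth.covariates, cov_path)
    paths["covariates"] = cov_path
    affine = subjects[0].bold.affine
    mask_path = out / "effect_mask.nii"
    save_volume(truth.effect_mask.astype(np.uint8), affine, mask_path)
    paths["effect_mask"] = mask_path
    if truth.state_sequences is not None:
        rows = [
            {"subject_id": sid, **{f"w{j}": int(s) for j, s in enumerate(seq)}}
            for sid, seq in truth.state_sequences.items()
        ]
        seq_path = out / "state_sequences.csv"
        pd.DataFrame(rows).to_csv(seq_path, index=False)
        paths["state_sequences"] = seq_path
    return paths
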