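"""Synthetic cohorts: up-chirp pretraining data and episodic two-class cohorts.

Two generators cover the two stages of the workflow with no external data:

* ``generate_chirp_cohort`` — every component of every subject is a
  concatenation of linear up-chirp segments (instantaneous frequency rising
  from a drawn ``f0`` to a drawn ``f1`` over the segment) plus Gaussian
  noise. The arrow of time is strongly identifiable: frequency content rises
  left to right, which a reversed copy cannot mimic.
* ``generate_episodic_cohort`` — a two-class cohort where controls are pure
  AR(1) noise per component and patients additionally carry a handful of
  short oscillatory bursts ("events") in a fixed subset of components at
  patient-specific random onsets. This emulates class-discriminative
  activity confined to short, focused time intervals.

All output is deterministic given the parameter seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import Cohort, SubjectTimeSeries

__all__ = [
    "ChirpParams",
    "EpisodicCohortParams",
    "generate_chirp_subject",
    "generate_chirp_cohort",
    "generate_episodic_cohort",
]


@dataclass
class ChirpParams:
    """Parameters of the up-chirp cohort generator.

    Frequencies are in cycles per segment. ``f1 > f0`` is enforced per draw,
    making every segment an up-chirp.
    """

    n_components: int = 53
    n_timepoints: int = 1200
    n_segments: int = 1
    f0_range: tuple[float, float] = (1.0, 5.0)
    f1_range: tuple[float, float] = (20.0, 60.0)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.f0_range[0] < 0:
            raise ValueError("f0_range low end must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _chirp_segment(length: int, f0: float, f1: float) -> np.ndarray:
    # linear chirp: phase(u) = f0*u + (f1-f0)*u^2/2 with u in [0, 1)
    u = np.arange(length, dtype=float) / length
    phase = f0 * u + (f1 - f0) * u * u / 2.0
    return np.sin(2.0 * np.pi * phase)


def generate_chirp_subject(params: ChirpParams, subject_seed: int) -> SubjectTimeSeries:
    """One subject: per component, ``n_segments`` concatenated up-chirps plus noise.

    Deterministic given ``(params.seed, subject_seed)``. Each segment draws
    ``f0 ~ U(f0_range)`` and ``f1 ~ U(f1_range)``, redrawing until ``f1 > f0``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, subject_seed]))
    T, N = params.n_timepoints, params.n_components
    bounds = np.linspace(0, T, params.n_segments + 1).astype(int)
    X = np.empty((T, N), dtype=float)
    for j in range(N):
        for k in range(params.n_segments):
            lo, hi = bounds[k], bounds[k + 1]
            f0 = rng.uniform(*params.f0_range)
            f1 = rng.uniform(*params.f1_range)
            while f1 <= f0:
                f1 = rng.uniform(*params.f1_range)
            X[lo:hi, j] = _chirp_segment(hi - lo, f0, f1)
    if params.noise_sd > 0:
        X += rng.normal(0.0, params.noise_sd, size=(T, N))
    return SubjectTimeSeries(subject_id=f"chirp{subject_seed:04d}", values=X)


def generate_chirp_cohort(n_subjects: int, params: ChirpParams) -> Cohort:
    """Unlabeled cohort of ``n_subjects`` chirp subjects; per-subject seeds derive from ``params.seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = [generate_chirp_subject(params, i) for i in range(n_subjects)]
    return Cohort(name=f"chirp-seed{params.seed}", subjects=subjects)


@dataclass
class EpisodicCohortParams:
    """Parameters of the two-class episodic cohort generator."""

    n_patients: int = 10
    n_controls: int = 10
    n_components: int = 8
    n_timepoints: int = 160
    ar_coefficient: float = 0.5
    base_noise_sd: float = 1.0
    n_events: int = 3
    event_length: int = 12
    event_amplitude: float = 3.0
    affected_components: int = 3
    event_cycles: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.base_noise_sd <= 0:
            raise ValueError("base_noise_sd must be positive")
        if self.event_length * self.n_events > self.n_timepoints:
            raise ValueError("event_length * n_events must not exceed n_timepoints")
        if self.affected_components > self.n_components:
            raise ValueError("affected_components must not exceed n_components")
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("class counts must be nonnegative")


def _ar1(rng: np.random.Generator, T: int, N: int, a: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=(T, N))
    X = np.empty((T, N))
    X[0] = eps[0]
    for t in range(1, T):
        X[t] = a * X[t - 1] + eps[t]
    return X


def _event_onsets(rng: np.random.Generator, T: int, n_events: int, length: int) -> np.ndarray:
    """Non-overlapping onsets drawn uniformly via the gaps construction."""
    slack = T - n_events * length
    cuts = np.sort(rng.integers(0, slack + 1, size=n_events))
    return cuts + length * np.arange(n_events)


def _burst(length: int, amplitude: float, cycles: float) -> np.ndarray:
    # oscillatory burst under a half-sine envelope: transient, high local variance
    u = np.arange(length, dtype=float) / length
    return amplitude * np.sin(np.pi * u) * np.sin(2.0 * np.pi * cycles * u)


def generate_episodic_cohort(params: EpisodicCohortParams) -> Cohort:
    """Two-class cohort: AR(1) controls, patients with added oscillatory events.

    Patients (label 1) receive ``n_events`` non-overlapping bursts of length
    ``event_length`` and peak amplitude ``event_amplitude`` added to a fixed
    random subset of ``affected_components`` components, at onsets drawn
    independently per patient. Controls (label 0) are baseline AR(1) only.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0]))
    affected = rng.choice(p.n_components, size=p.affected_components, replace=False)
    subjects: list[SubjectTimeSeries] = []
    for i in range(p.n_controls):
        srng = np.random.default_rng(np.random.SeedSequence([p.seed, 1, i]))
        X = _ar1(srng, p.n_timepoints, p.n_components, p.ar_coefficient, p.base_noise_sd)
        subjects.append(SubjectTimeSeries(f"ctrl{i:04d}", X, label=0))
    for i in range(p.n_patients):
        srng = np.random.default_rng(np.random.SeedSequence([p.seed, 2, i]))
        X = _ar1(srng, p.n_timepoints, p.n_components, p.ar_coefficient, p.base_noise_sd)
        if p.event_amplitude != 0 and p.n_events > 0:
            onsets = _event_onsets(srng, p.n_timepoints, p.n_events, p.event_length)
            for onset in onsets:
                burst = _burst(p.event_length, p.event_amplitude, p.event_cycles)
                for j in affected:
                    X[onset : onset + p.event_length, j] += burst
        subjects.append(SubjectTimeSeries(f"pat{i:04d}", X, label=1))
    return Cohort(name=f"episodic-seed{p.seed}", subjects=subjects)
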