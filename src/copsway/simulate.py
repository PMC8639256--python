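"""Seeded synthetic posturography cohorts with known ground truth.

Each simulated COP series is a sum of six narrowband oscillatory
components plus broadband white noise.  Band ``k`` (1-6) is centered at
``fs / 2**(k+1)`` — the dyadic scales an EMD filter bank resolves — so
a group difference injected into band ``k`` lands predictably in IMF
``k``.  A narrowband component is an amplitude-jittered sinusoid with
slow random frequency drift (control points every 2 s, linearly
interpolated), which keeps its spectral mass inside the band while
avoiding a strictly periodic signal.

Group structure mirrors a fall-risk cohort: 47 nonfall and 29 fall
subjects, four recording conditions (CR, OR, CF, OF) with
condition-dependent sway magnitude (standing on foam and closing the
eyes increase sway), three trials per condition, two COP axes (the
mediolateral axis scaled down relative to the anterior-posterior one).
The fall group differs from the nonfall group in two ways, both
configurable: the RMS amplitudes of the low-frequency bands are scaled
by ``fall_band_gain``, and an extra broadband-noise admixture
(``regularity_deficit``) lowers the regularity of the fall group's
signals, separating the entropy features.

Between-subject heterogeneity (a shared log-normal sway scale and
per-band log-normal gains) and within-subject trial jitter make the
classification problem non-trivial: with the defaults the raw-level
features separate the groups only weakly while the targeted IMF levels
separate them well.

Everything is deterministic under ``(spec, seed)``: subject-level
parameters derive from ``(seed, subject)`` and each trial's stream from
``(seed, subject, condition, trial, axis)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .io import CONDITIONS, CohortDataset, CopTrace, ForcePlateRecord

__all__ = ["CohortSpec", "GroundTruth", "generate_trace", "generate_cohort",
           "band_center", "band_edges", "to_force_plate"]

N_BANDS = 6


def band_center(sampling_rate: float, k: int) -> float:
    """Center frequency of band k (1-based): fs / 2**(k+1)."""
    if not 1 <= k <= N_BANDS:
        raise ValueError(f"band index must be 1..{N_BANDS}")
    return sampling_rate / 2.0 ** (k + 1)


def band_edges(sampling_rate: float, k: int) -> Tuple[float, float]:
    """Half-octave edges around the band center."""
    c = band_center(sampling_rate, k)
    return c / np.sqrt(2.0), c * np.sqrt(2.0)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Amplitudes are RMS displacements in meters.  ``band_rms`` gives the
    nonfall-group per-band amplitudes for the anterior-posterior axis
    under the OR (eyes open, rigid) reference condition; the other
    entries act multiplicatively on top of it.
    """

    n_nonfall: int = 47
    n_fall: int = 29
    trials_per_condition: int = 3
    sampling_rate: float = 100.0
    duration: float = 60.0
    #: nonfall per-band RMS amplitude (m), bands 1..6 (25 Hz .. 0.78 Hz)
    band_rms: Tuple[float, ...] = (1.5e-4, 3e-4, 6e-4, 12e-4, 5e-4, 3.5e-4)
    #: fall-group multiplier per band (the injected effect)
    fall_band_gain: Tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.5, 1.6)
    #: broadband white-noise RMS as a fraction of the deterministic RMS
    noise_rms_fraction: float = 0.10
    #: extra noise fraction added for the fall group (regularity effect)
    regularity_deficit: float = 0.03
    #: sway scale per recording condition
    condition_multipliers: Dict[str, float] = field(
        default_factory=lambda: {"CR": 1.15, "OR": 1.0, "CF": 1.35, "OF": 1.2}
    )
    #: mediolateral (y) amplitude relative to anterior-posterior (x)
    ml_ratio: float = 0.6
    #: between-subject log-SD of the shared sway scale
    subject_scale_sd: float = 0.15
    #: between-subject log-SD of per-band gains
    band_gain_sd: float = 0.18
    #: trial-to-trial log-SD of per-band amplitudes
    trial_jitter_sd: float = 0.10
    #: between-subject log-SD of the broadband-noise fraction
    noise_sd: float = 0.45
    #: slow amplitude-modulation depth (fraction)
    amp_jitter: float = 0.10
    #: slow frequency-drift depth (fraction of the band center)
    freq_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_nonfall < 2 or self.n_fall < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.duration * self.sampling_rate < 1000:
            raise ValueError("a trial must hold at least 1000 samples")
        if len(self.band_rms) != N_BANDS or len(self.fall_band_gain) != N_BANDS:
            raise ValueError(f"band parameter tuples must have length {N_BANDS}")
        if set(self.condition_multipliers) != set(CONDITIONS):
            raise ValueError(f"condition_multipliers must cover {CONDITIONS}")
        centers = [band_center(self.sampling_rate, k) for k in range(1, N_BANDS + 1)]
        assert all(a > b for a, b in zip(centers, centers[1:]))

    @property
    def n_subjects(self) -> int:
        return self.n_nonfall + self.n_fall

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def subject_group(self, subject_index: int) -> str:
        if not 0 <= subject_index < self.n_subjects:
            raise ValueError("subject_index out of range")
        return "nonfall" if subject_index < self.n_nonfall else "fall"

    def subject_id(self, subject_index: int) -> str:
        return f"S{subject_index:03d}"

    def null_effect(self) -> "CohortSpec":
        """Copy with zero injected group effect (for calibration runs)."""
        return dataclasses.replace(
            self, fall_band_gain=(1.0,) * N_BANDS, regularity_deficit=0.0
        )


@dataclass(frozen=True)
class GroundTruth:
    """What was actually injected, reproducible from (spec, seed) alone."""

    spec: CohortSpec
    group_labels: Dict[str, str]
    band_rms_by_group: Dict[str, Tuple[float, ...]]
    noise_fraction_by_group: Dict[str, float]

    @property
    def effect_bands(self) -> Tuple[int, ...]:
        return tuple(
            k + 1 for k, g in enumerate(self.spec.fall_band_gain) if g != 1.0
        )


def _subject_params(spec: CohortSpec, subject_index: int):
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, 1, subject_index))
    )
    scale = float(np.exp(rng.normal(0.0, spec.subject_scale_sd)))
    band_gains = np.exp(rng.normal(0.0, spec.band_gain_sd, N_BANDS))
    noise_factor = float(np.exp(rng.normal(0.0, spec.noise_sd)))
    return scale, band_gains, noise_factor


def _slow_modulation(rng, n, sampling_rate, depth):
    """Smooth random modulation in [-2, 2]*depth, control points every 2 s."""
    if depth == 0.0:
        return np.zeros(n)
    n_ctrl = max(int(np.ceil(n / (2.0 * sampling_rate))) + 1, 2)
    ctrl = np.clip(rng.standard_normal(n_ctrl), -2.0, 2.0)
    pos = np.linspace(0, n - 1, n_ctrl)
    return depth * np.interp(np.arange(n), pos, ctrl)


def generate_trace(
    spec: CohortSpec,
    subject_index: int,
    condition: str,
    trial: int,
    axis: str,
) -> np.ndarray:
    """One synthetic COP series (meters), deterministic under its key."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if not 1 <= trial <= spec.trials_per_condition:
        raise ValueError("trial index out of range")

    group = spec.subject_group(subject_index)
    scale, band_gains, noise_factor = _subject_params(spec, subject_index)
    cond_idx = CONDITIONS.index(condition)
    axis_idx = 0 if axis == "x" else 1
    rng = np.random.default_rng(
        np.random.SeedSequence(
            (spec.seed, 2, subject_index, cond_idx, trial, axis_idx)
        )
    )

    n = spec.n_samples
    fs = spec.sampling_rate
    cond_mult = spec.condition_multipliers[condition]
    axis_mult = 1.0 if axis == "x" else spec.ml_ratio

    series = np.zeros(n)
    sum_sq = 0.0
    for k in range(N_BANDS):
        a = spec.band_rms[k] * band_gains[k] * scale * cond_mult * axis_mult
        if group == "fall":
            a *= spec.fall_band_gain[k]
        a *= float(np.exp(rng.normal(0.0, spec.trial_jitter_sd)))
        sum_sq += a * a
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        f0 = band_center(fs, k + 1)
        f_inst = f0 * (1.0 + _slow_modulation(rng, n, fs, spec.freq_jitter))
        phase = phase0 + 2.0 * np.pi * np.cumsum(f_inst) / fs
        amp = a * np.sqrt(2.0) * (1.0 + _slow_modulation(rng, n, fs, spec.amp_jitter))
        series += amp * np.sin(phase)

    noise_frac = spec.noise_rms_fraction
    if group == "fall":
        noise_frac += spec.regularity_deficit
    noise_frac *= noise_factor
    if noise_frac > 0.0:
        series = series + rng.normal(0.0, noise_frac * np.sqrt(sum_sq), n)
    return series


def generate_cohort(spec: CohortSpec):
    """Build the full cohort: subjects x conditions x trials, both axes.

    Returns ``(dataset, ground_truth)``; with the defaults the dataset
    holds 76 x 4 x 3 = 912 traces.
    """
    traces = []
    for s in range(spec.n_subjects):
        sid = spec.subject_id(s)
        group = spec.subject_group(s)
        for condition in CONDITIONS:
            for trial in range(1, spec.trials_per_condition + 1):
                cop_x = generate_trace(spec, s, condition, trial, "x")
                cop_y = generate_trace(spec, s, condition, trial, "y")
                traces.append(
                    CopTrace(
                        subject_id=sid,
                        group_label=group,
                        condition=condition,
                        trial_index=trial,
                        sampling_rate=spec.sampling_rate,
                        cop_x=cop_x - cop_x.mean(),
                        cop_y=cop_y - cop_y.mean(),
                    )
                )
    labels = {
        spec.subject_id(s): spec.subject_group(s) for s in range(spec.n_subjects)
    }
    fall_rms = tuple(
        a * g for a, g in zip(spec.band_rms, spec.fall_band_gain)
    )
    truth = GroundTruth(
        spec=spec,
        group_labels=labels,
        band_rms_by_group={"nonfall": tuple(spec.band_rms), "fall": fall_rms},
        noise_fraction_by_group={
            "nonfall": spec.noise_rms_fraction,
            "fall": spec.noise_rms_fraction + spec.regularity_deficit,
        },
    )
    return CohortDataset(tuple(traces)), truth


def to_force_plate(trace: CopTrace, fz: float = 700.0) -> ForcePlateRecord:
    """Re-express a COP trace as force-plate channels (constant vertical
    load, zero shear), inverting the plate equations; exercises the raw
    force-plate reading path end to end."""
    n = trace.n_samples
    fz_arr = np.full(n, float(fz))
    zeros = np.zeros(n)
    return ForcePlateRecord(
        subject_id=trace.subject_id,
        group_label=trace.group_label,
        condition=trace.condition,
        trial_index=trace.trial_index,
        sampling_rate=trace.sampling_rate,
        fx=zeros,
        fy=zeros,
        fz=fz_arr,
        mx=trace.cop_y * fz_arr,
        my=-trace.cop_x * fz_arr,
        mz=zeros,
    )
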