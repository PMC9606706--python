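"""Synthetic auditory-evoked EEG cohort generator.

Emulates a passive-listening recording: 128-channel scalp EEG at 1 kHz,
epochs [-200, 1500] ms around stimulus onset, ~600 trials per subject and a
20-subject cohort. Each subject's primary-auditory-cortex (PAC) vertices
carry a stereotyped evoked waveform — a positive deflection peaking near
55 ms (P1) followed by a negative one near 100 ms (N1) — projected to the
sensors through the subject's TRUE head and electrode geometry, plus
spatially correlated AR(1) sensor noise. Trial-to-trial variability enters
as lognormal amplitude jitter and Gaussian latency jitter.

The generated truth is confined to the PAC patches, so any activity an
inverse solution places outside them is attributable to the estimator
(spatial leakage), not to the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from . import geometry
from .forward import Leadfield, compute_leadfield
from .geometry import (
    ElectrodeMontage,
    PerturbationProfile,
    SourceSpace,
    SphericalHeadModel,
)

__all__ = [
    "EvokedTemplate",
    "SensorEpochs",
    "CohortSpec",
    "SubjectRecord",
    "CohortBundle",
    "pac_waveform",
    "simulate_trials",
    "simulate_cohort",
    "subject_seed",
]

# purpose tags for the seed-splitting rule
_SEED_TAGS = {"anatomy": 1, "montage": 2, "trials": 3}


def subject_seed(master_seed: int, subject_index: int, purpose: str) -> np.random.SeedSequence:
    """Deterministic per-subject, per-purpose seed stream.

    Splitting is by entropy list (master, subject, purpose-tag), so partial
    re-runs (e.g. regenerating one subject's trials) are stable.
    """
    return np.random.SeedSequence([int(master_seed), int(subject_index), _SEED_TAGS[purpose]])


@dataclass(frozen=True)
class EvokedTemplate:
    """Two Gaussian-windowed deflections modelling the P1/N1 complex (A.m)."""

    p1_latency: float = 0.055
    p1_amplitude: float = 40e-9
    p1_width: float = 0.020
    n1_latency: float = 0.100
    n1_amplitude: float = -60e-9
    n1_width: float = 0.030
    hemi_scale: dict[str, float] = field(default_factory=lambda: {"L": 1.0, "R": 1.0})

    def __post_init__(self):
        if not (self.p1_amplitude > 0 > self.n1_amplitude) and not (
            self.p1_amplitude == 0 == self.n1_amplitude
        ):
            if self.p1_amplitude < 0 or self.n1_amplitude > 0:
                raise ValueError("P1 amplitude must be >= 0 and N1 amplitude <= 0")
        if self.p1_width <= 0 or self.n1_width <= 0:
            raise ValueError("component widths must be positive")
        if self.p1_latency >= self.n1_latency:
            raise ValueError("P1 must precede N1")


@dataclass
class SensorEpochs:
    """Trials x sensors x time sensor data (volts) with timing metadata."""

    data: np.ndarray
    fs: float
    epoch_window: tuple[float, float]
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x time")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel labels do not match the sensor axis")
        n_expected = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.fs)) + 1
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, expected {n_expected}"
            )

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.epoch_window[0] + np.arange(n) / self.fs

    @property
    def event_sample(self) -> int:
        return int(round(-self.epoch_window[0] * self.fs))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    n_subjects: int = 20
    n_trials: int = 600
    master_seed: int = 0
    fs: float = 1000.0
    epoch_window: tuple[float, float] = (-0.200, 1.500)
    target_snr: float = 0.3  # single-trial peak amplitude SNR
    spatial_bandwidth: float = 0.04  # m, Gaussian mixing kernel over sensors
    ar_coeff: float = 0.95  # AR(1) coefficient of the sensor noise
    amp_jitter_sd: float = 0.2  # lognormal sigma of trial amplitude
    latency_jitter_sd: float = 0.005  # s
    perturbation: PerturbationProfile = field(default_factory=PerturbationProfile)
    anatomy_scale_sd: float = 0.04
    anatomy_center_offset: float = 0.004  # m, radius of the centre-offset ball
    n_vertices: int = 2000
    template: EvokedTemplate = field(default_factory=EvokedTemplate)

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_trials <= 0:
            raise ValueError("cohort counts must be positive")


def pac_waveform(template: EvokedTemplate, times: np.ndarray) -> np.ndarray:
    """Evoked source time course (A.m): sum of two Gaussian deflections.

    Each component is exactly zero outside +/- 4 widths of its latency.
    """
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    for amp, lat, width in (
        (template.p1_amplitude, template.p1_latency, template.p1_width),
        (template.n1_amplitude, template.n1_latency, template.n1_width),
    ):
        z = (t - lat) / width
        mask = np.abs(z) <= 4.0
        out[mask] += amp * np.exp(-0.5 * z[mask] ** 2)
    return out


def _structured_noise(
    n_trials: int,
    n_sensors: int,
    n_times: int,
    sensor_pos: np.ndarray,
    bandwidth: float,
    ar: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-marginal-variance noise: AR(1) in time, Gaussian-kernel mixed in space."""
    burn = 200
    w = rng.standard_normal((n_trials, n_sensors, n_times + burn))
    if ar != 0.0:
        w *= np.sqrt(1.0 - ar**2)  # unit stationary variance
        w = lfilter([1.0], [1.0, -ar], w, axis=-1)
    w = w[..., burn:]
    if bandwidth > 0:
        d2 = np.sum((sensor_pos[:, None, :] - sensor_pos[None, :, :]) ** 2, axis=-1)
        K = np.exp(-0.5 * d2 / bandwidth**2)
        K /= np.linalg.norm(K, axis=1, keepdims=True)  # rows unit norm: variance kept
        w = np.einsum("ij,tjs->tis", K, w)
    return w


def _pac_gain_sum(leadfield: Leadfield, sourcespace: SourceSpace, h: str) -> np.ndarray:
    """Summed sensor projection of the PAC patch, for a UNIT total moment.

    The template amplitude is the total dipole moment of the hemisphere's
    PAC patch; it is spread uniformly over the patch vertices, which keeps
    sensor amplitudes independent of the grid resolution.
    """
    pac = sourcespace.rois[f"PAC_{h}"]
    return leadfield.gain[:, pac].sum(axis=1) / len(pac)


def evoked_sensor_signal(
    leadfield: Leadfield,
    sourcespace: SourceSpace,
    template: EvokedTemplate,
    times: np.ndarray,
) -> np.ndarray:
    """Noiseless, jitter-free sensor-level evoked response (sensors x time)."""
    sig = np.zeros((leadfield.gain.shape[0], len(times)))
    wave = pac_waveform(template, times)
    for h in ("L", "R"):
        cols = _pac_gain_sum(leadfield, sourcespace, h)
        sig += np.outer(cols, template.hemi_scale.get(h, 1.0) * wave)
    return sig


def simulate_trials(
    leadfield_true: Leadfield,
    sourcespace: SourceSpace,
    template: EvokedTemplate,
    spec: CohortSpec,
    n_trials: int,
    seed,
    sensor_positions: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> SensorEpochs:
    """Trial-level sensor data: forward-projected PAC activity plus noise.

    Every PAC vertex (both hemispheres) carries the evoked waveform, scaled
    per trial by lognormal amplitude jitter and shifted by Gaussian latency
    jitter; all other vertices are silent. The additive noise has unit
    marginal variance before being scaled so that the single-trial peak SNR
    (max |clean evoked| over channels and time, divided by the noise sd)
    equals ``spec.target_snr``.
    """
    rng = np.random.default_rng(seed)
    tmin, tmax = spec.epoch_window
    n_times = int(round((tmax - tmin) * spec.fs)) + 1
    times = tmin + np.arange(n_times) / spec.fs
    n_sensors = leadfield_true.gain.shape[0]

    clean = evoked_sensor_signal(leadfield_true, sourcespace, template, times)
    peak = np.abs(clean).max()
    if noise_sd is None:
        noise_sd = peak / spec.target_snr if (spec.target_snr > 0 and peak > 0) else 0.0

    amp = (
        rng.lognormal(mean=0.0, sigma=spec.amp_jitter_sd, size=n_trials)
        if spec.amp_jitter_sd > 0
        else np.ones(n_trials)
    )
    lat = (
        rng.normal(0.0, spec.latency_jitter_sd, size=n_trials)
        if spec.latency_jitter_sd > 0
        else np.zeros(n_trials)
    )

    # per-hemisphere PAC patch projection; waveform shared within the ROI
    gsum = {
        h: _pac_gain_sum(leadfield_true, sourcespace, h) * template.hemi_scale.get(h, 1.0)
        for h in ("L", "R")
    }
    data = np.zeros((n_trials, n_sensors, n_times))
    for k in range(n_trials):
        wave = pac_waveform(template, times - lat[k]) * amp[k]
        for h in ("L", "R"):
            data[k] += np.outer(gsum[h], wave)

    if noise_sd > 0:
        pos = sensor_positions
        if pos is None:
            pos = np.zeros((n_sensors, 3))  # no geometry -> no spatial mixing
            bw = 0.0
        else:
            bw = spec.spatial_bandwidth
        data += noise_sd * _structured_noise(
            n_trials, n_sensors, n_times, pos, bw, spec.ar_coeff, rng
        )
    return SensorEpochs(
        data=data,
        fs=spec.fs,
        epoch_window=spec.epoch_window,
        channel_labels=leadfield_true.channel_labels,
    )


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectRecord:
    """One synthetic subject: true geometry, condition leadfields, seeds.

    ``leadfields`` is keyed by (anatomy, electrodes) with levels
    'template'/'individual'; the ('individual','individual') entry is the
    true forward model used to generate the data. Trial data are generated
    on demand (``make_epochs``) to keep cohort memory bounded.
    """

    index: int
    head: SphericalHeadModel
    montage: ElectrodeMontage
    sourcespace: SourceSpace
    template_sourcespace: SourceSpace
    leadfields: dict[tuple[str, str], Leadfield]
    spec: CohortSpec

    @property
    def true_leadfield(self) -> Leadfield:
        return self.leadfields[("individual", "individual")]

    def make_epochs(self, n_trials: int | None = None) -> SensorEpochs:
        seed = subject_seed(self.spec.master_seed, self.index, "trials")
        return simulate_trials(
            self.true_leadfield,
            self.sourcespace,
            self.spec.template,
            self.spec,
            n_trials or self.spec.n_trials,
            seed,
            sensor_positions=self.montage.positions,
        )


@dataclass
class CohortBundle:
    spec: CohortSpec
    template_head: SphericalHeadModel
    template_montage: ElectrodeMontage
    template_sourcespace: SourceSpace
    subjects: list[SubjectRecord]

    def metadata(self) -> dict:
        """Deterministic cohort description (no bulky arrays)."""
        return {
            "n_subjects": self.spec.n_subjects,
            "n_trials": self.spec.n_trials,
            "master_seed": self.spec.master_seed,
            "subjects": [
                {
                    "index": s.index,
                    "head_radii_m": list(s.head.radii),
                    "head_center_m": s.head.center.tolist(),
                    "leadfield_refs": {
                        "|".join(k): lf.montage_ref for k, lf in s.leadfields.items()
                    },
                }
                for s in self.subjects
            ],
        }


def simulate_cohort(
    spec: CohortSpec,
    template_head: SphericalHeadModel | None = None,
    template_montage: ElectrodeMontage | None = None,
) -> CohortBundle:
    """Build the full cohort: per-subject true geometry plus the four
    condition leadfields (anatomy x electrodes, template/individual).

    Mismatched configurations mirror the co-registration workflow: the
    montage that does not belong to the chosen head is radially projected
    onto that head's scalp before the forward model is computed.
    """
    head_t = template_head or geometry.make_template_head()
    mont_t = template_montage or geometry.make_template_montage(head_t)
    ss_t = geometry.make_source_space(head_t, spec.n_vertices)

    subjects = []
    for i in range(spec.n_subjects):
        anat_seed = subject_seed(spec.master_seed, i, "anatomy")
        mont_seed = subject_seed(spec.master_seed, i, "montage")
        head_i = geometry.perturb_anatomy(
            head_t,
            anat_seed.generate_state(1)[0] % (2**31),
            spec.anatomy_scale_sd,
            spec.anatomy_center_offset,
        )
        ss_i = geometry.make_source_space(head_i, spec.n_vertices)
        mont_t_on_i = geometry.project_to_surface(mont_t, head_i)
        mont_i = geometry.perturb_montage(
            mont_t_on_i, head_i, spec.perturbation, mont_seed.generate_state(1)[0] % (2**31)
        )
        mont_i_on_t = geometry.project_to_surface(mont_i, head_t)

        lf_true = compute_leadfield(head_i, mont_i, ss_i)
        leadfields = {
            ("individual", "individual"): lf_true,
            ("individual", "template"): compute_leadfield(head_i, mont_t_on_i, ss_i),
            ("template", "individual"): compute_leadfield(head_t, mont_i_on_t, ss_t),
            ("template", "template"): compute_leadfield(head_t, mont_t, ss_t),
        }
        subjects.append(
            SubjectRecord(
                index=i,
                head=head_i,
                montage=mont_i,
                sourcespace=ss_i,
                template_sourcespace=ss_t,
                leadfields=leadfields,
                spec=spec,
            )
        )
    return CohortBundle(
        spec=spec,
        template_head=head_t,
        template_montage=mont_t,
        template_sourcespace=ss_t,
        subjects=subjects,
    )
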