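"""Synthetic vibrography data with known ground truth.

Emulates the acquisition chain end-to-end: the forward model supplies the
apex response at each drive frequency, from which sinusoidal displacement
traces are synthesised with (optionally) rigid reference motion of the
whole setup, second-harmonic contamination of the loudspeaker drive, and
additive Gaussian displacement noise.  Amplitudes are scaled to the level
seen in real acquisitions (hundreds of nm for flaps, up to ~10 um for
globes); every random draw is controlled by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import _build
from .oct import VibrationRecord
from .response import FrequencyResponse

__all__ = ["SynthSpec", "make_records", "make_noisy_frf"]


@dataclass
class SynthSpec:
    """Recipe for a synthetic vibrography run.

    ``amplitude_scale`` rescales the forward model's largest apex amplitude
    over the drive list to this physical level.  ``harmonic_fraction`` adds
    a second-harmonic component of that relative size (the loudspeaker does
    not emit a pure tone); ``reference_amplitude`` moves the whole setup
    rigidly (cancelled later by reference subtraction).
    """

    model_cfg: object
    drive_frequencies: tuple = (240.0, 280.0, 320.0, 360.0, 400.0, 440.0, 480.0, 520.0)
    amplitude_scale: float = 300e-9  # m
    noise_sd: float = 0.0  # m, additive on every sample
    reference_amplitude: float = 0.0  # m
    harmonic_fraction: float = 0.1
    frf_noise_frac: float = 0.0  # multiplicative log-normal sigma for FRFs
    seed: int = 0
    sampling_rate: float = 48000.0  # Hz
    duration: float = 0.05  # s
    positions: tuple = (0.0,)  # lateral probe positions, m
    valid_range: tuple = (20.0, 2000.0)  # Hz

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0.0 <= self.harmonic_fraction < 1.0:
            raise ValueError("harmonic contamination fraction must lie in [0, 1)")


def _forward_response(spec: SynthSpec):
    """Apex (and lateral) complex response of the forward model at every
    drive frequency, plus the scale factor to physical amplitude."""
    model = _build(spec.model_cfg)
    arc_r = model.mesh.nodes[model.arc_nodes, 0]
    cols = [int(np.argmin(np.abs(arc_r - p))) for p in spec.positions]
    probe_nodes = model.arc_nodes[cols]
    resp = np.empty((len(spec.drive_frequencies), len(probe_nodes)), dtype=complex)
    lo, hi = spec.valid_range
    for i, f in enumerate(spec.drive_frequencies):
        if not lo <= f <= hi:
            raise ValueError(
                f"drive frequency {f} Hz outside the forward-model range [{lo}, {hi}] Hz"
            )
        sol = model.solve(float(f))
        resp[i] = [sol.u_z(n) for n in probe_nodes]
    apex_amp = np.abs(resp[:, int(np.argmin(np.abs(spec.positions)))])
    scale = spec.amplitude_scale / apex_amp.max() if apex_amp.max() > 0 else 1.0
    return resp * scale


def make_records(spec: SynthSpec) -> list[VibrationRecord]:
    """Synthetic per-frequency displacement records.

    With zero noise and zero contamination, amplitude extraction recovers
    the forward FRF to floating-point accuracy (round-trip identity).  The
    ground-truth amplitude and phase are stored in each record's metadata.
    """
    rng = np.random.default_rng(spec.seed)
    resp = _forward_response(spec)
    t = np.arange(int(round(spec.duration * spec.sampling_rate))) / spec.sampling_rate
    records = []
    for i, f in enumerate(spec.drive_frequencies):
        ref_phase = rng.uniform(0, 2 * np.pi)
        ref = spec.reference_amplitude * np.cos(2 * np.pi * f * t + ref_phase)
        traces = np.empty((len(spec.positions), t.size))
        truth_amp, truth_phase = [], []
        for j in range(len(spec.positions)):
            A, ph = np.abs(resp[i, j]), np.angle(resp[i, j])
            x = A * np.cos(2 * np.pi * f * t + ph)
            x = x + spec.harmonic_fraction * A * np.cos(2 * np.pi * 2 * f * t + ph)
            x = x + ref
            if spec.noise_sd > 0:
                x = x + rng.normal(0.0, spec.noise_sd, size=t.size)
            traces[j] = x
            truth_amp.append(float(A))
            truth_phase.append(float(ph))
        ref_out = ref.copy()
        if spec.noise_sd > 0 and spec.reference_amplitude > 0:
            ref_out = ref_out + rng.normal(0.0, spec.noise_sd, size=t.size)
        records.append(
            VibrationRecord(
                drive_frequency=float(f),
                sampling_rate=spec.sampling_rate,
                displacement=traces,
                positions=np.asarray(spec.positions),
                reference=ref_out if spec.reference_amplitude > 0 else None,
                metadata={
                    "true_amplitude_m": truth_amp[int(np.argmin(np.abs(spec.positions)))],
                    "true_phase_rad": truth_phase[int(np.argmin(np.abs(spec.positions)))],
                    "seed": spec.seed,
                },
            )
        )
    return records


def make_noisy_frf(spec: SynthSpec) -> FrequencyResponse:
    """Forward FRF sampled on the drive grid with multiplicative log-normal
    amplitude noise (amplitude spectra are positive, so noise is applied on
    the log scale)."""
    rng = np.random.default_rng(spec.seed)
    resp = _forward_response(spec)
    apex = resp[:, int(np.argmin(np.abs(spec.positions)))]
    amps = np.abs(apex)
    if spec.frf_noise_frac > 0:
        amps = amps * rng.lognormal(0.0, spec.frf_noise_frac, size=amps.size)
    return FrequencyResponse(
        np.asarray(spec.drive_frequencies, dtype=float), amps, np.angle(apex)
    )
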