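"""Processing of vibrography displacement traces into a measured FRF.

A vibrography acquisition delivers, per drive frequency, a time series of
vertical tissue displacement at one or more lateral positions, optionally
together with the trace of a rigid glass reference mounted next to the
specimen (to cancel whole-setup motion).  The reference is subtracted
sample-wise, the trace is truncated to an integer number of drive periods
(leakage-free, since the drive frequency is known exactly), and the
discrete Fourier coefficient at the drive frequency yields the single-sided
oscillation amplitude and phase.  Assembling the per-frequency amplitudes
gives the measured frequency-response function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .response import FrequencyResponse

__all__ = [
    "VibrationRecord",
    "extract_amplitude",
    "assemble_frf",
    "write_records",
    "read_records",
    "read_record_csv",
]


@dataclass
class VibrationRecord:
    """One drive-frequency acquisition.

    ``displacement`` is (n_positions, n_samples) in metres; ``positions``
    are lateral (radial) coordinates in metres, with the corneal apex at 0.
    """

    drive_frequency: float  # Hz
    sampling_rate: float  # Hz
    displacement: np.ndarray
    positions: np.ndarray
    reference: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.displacement = np.atleast_2d(np.asarray(self.displacement, dtype=float))
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        if self.displacement.shape[0] != self.positions.size:
            raise ValueError("one displacement row per lateral position required")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.size != self.displacement.shape[1]:
                raise ValueError("reference trace length must match displacement traces")
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.displacement.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def validate(self) -> None:
        if self.sampling_rate <= 2.0 * self.drive_frequency:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz violates Nyquist for a "
                f"{self.drive_frequency} Hz drive"
            )
        if self.duration < 2.0 / self.drive_frequency:
            raise ValueError(
                f"trace of {self.duration * 1e3:.2f} ms holds fewer than 2 periods "
                f"of the {self.drive_frequency} Hz drive"
            )


def extract_amplitude(
    rec: VibrationRecord, position: float | None = None
) -> tuple[float, float]:
    """Single-sided oscillation amplitude (m) and phase (rad) at the drive
    frequency.

    The glass-reference trace (if present) is subtracted sample-wise, the
    signal is truncated to an integer number of drive periods, and the DFT
    coefficient at the drive frequency is evaluated directly.  The phase
    convention is ``x(t) = A cos(2 pi f t + phase)``; the result is invariant
    to start phase and to any DC offset.
    """
    rec.validate()
    if position is None:
        col = int(np.argmin(np.abs(rec.positions)))  # apex trace
    else:
        col = int(np.argmin(np.abs(rec.positions - position)))
    x = rec.displacement[col].astype(float)
    if rec.reference is not None:
        x = x - rec.reference
    f, fs = rec.drive_frequency, rec.sampling_rate
    n_periods = int(np.floor(x.size * f / fs))
    n_keep = min(x.size, int(round(n_periods * fs / f)))
    x = x[:n_keep]
    t = np.arange(n_keep) / fs
    # single-bin Fourier coefficient at the drive frequency.  On an exact
    # integer-period window this is the plain DFT; the least-squares
    # projection (with DC and second-harmonic nuisance columns) removes the
    # residual leakage of the fractional sample left by truncation.
    omega = 2.0 * np.pi * f
    cols = [np.cos(omega * t), np.sin(omega * t), np.ones_like(t)]
    if 2.0 * f < 0.5 * fs:
        cols += [np.cos(2 * omega * t), np.sin(2 * omega * t)]
    G = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(G, x, rcond=None)
    a, b = coef[0], coef[1]  # x ~ a cos(wt) + b sin(wt) = A cos(wt + phase)
    amp = float(np.hypot(a, b))
    phase = float(np.arctan2(-b, a))
    return amp, phase


def assemble_frf(records: list[VibrationRecord]) -> FrequencyResponse:
    """Apex amplitudes of many records as one FRF, sorted by frequency;
    duplicate drive frequencies are averaged."""
    if not records:
        raise ValueError("no vibration records given")
    rows: dict[float, list[tuple[float, float]]] = {}
    for rec in records:
        amp, ph = extract_amplitude(rec)
        rows.setdefault(round(rec.drive_frequency, 6), []).append((amp, ph))
    freqs = np.array(sorted(rows))
    amps = np.array([np.mean([a for a, _ in rows[f]]) for f in freqs])
    phases = np.array([np.angle(np.mean([np.exp(1j * p) for _, p in rows[f]])) for f in freqs])
    return FrequencyResponse(freqs, amps, phases)


# ------------------------------------------------------------------- I/O ----


def write_records(path, records: list[VibrationRecord]) -> None:
    """HDF5 container: one group per drive frequency with datasets
    ``trace[pos, t]`` and optional ``reference[t]``."""
    with h5py.File(path, "w") as h5:
        for k, rec in enumerate(records):
            grp = h5.create_group(f"record_{k:04d}")
            grp.attrs["drive_frequency_hz"] = rec.drive_frequency
            grp.attrs["sampling_rate_hz"] = rec.sampling_rate
            grp.create_dataset("trace", data=rec.displacement)
            grp.create_dataset("positions", data=rec.positions)
            if rec.reference is not None:
                grp.create_dataset("reference", data=rec.reference)
            for key, val in rec.metadata.items():
                if isinstance(val, (int, float, str)):
                    grp.attrs[f"meta_{key}"] = val


def read_records(path) -> list[VibrationRecord]:
    out = []
    with h5py.File(path, "r") as h5:
        for name in sorted(h5):
            grp = h5[name]
            meta = {
                key[5:]: grp.attrs[key] for key in grp.attrs if key.startswith("meta_")
            }
            out.append(
                VibrationRecord(
                    drive_frequency=float(grp.attrs["drive_frequency_hz"]),
                    sampling_rate=float(grp.attrs["sampling_rate_hz"]),
                    displacement=grp["trace"][()],
                    positions=grp["positions"][()],
                    reference=grp["reference"][()] if "reference" in grp else None,
                    metadata=meta,
                )
            )
    return out


def read_record_csv(
    path, drive_frequency: float, reference_position: float | None = None
) -> VibrationRecord:
    """Flat CSV dialect with columns (t, pos, displacement).

    The sampling rate is inferred from the time column; if
    ``reference_position`` is given, the trace at that lateral position is
    used as the rigid reference and removed from the displacement set.
    """
    df = pd.read_csv(path)
    need = {"t", "pos", "displacement"}
    if not need.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(need)}")
    wide = df.pivot_table(index="pos", columns="t", values="displacement", sort=True)
    t = wide.columns.to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    positions = wide.index.to_numpy(dtype=float)
    traces = wide.to_numpy(dtype=float)
    reference = None
    if reference_position is not None:
        i = int(np.argmin(np.abs(positions - reference_position)))
        reference = traces[i]
        traces = np.delete(traces, i, axis=0)
        positions = np.delete(positions, i)
    return VibrationRecord(
        drive_frequency=drive_frequency,
        sampling_rate=fs,
        displacement=traces,
        positions=positions,
        reference=reference,
    )
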