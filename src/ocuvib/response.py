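"""Frequency sweeps, apex frequency-response functions, resonance peaks and
mode-shape classification.

The frequency response function (FRF) is the vertical oscillation amplitude
of the corneal apex versus imposed frequency.  Resonance peaks are local
maxima of the FRF; each corresponds to a vibration mode, and successive
axisymmetric harmonics add nodal circles along the corneal surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .fem import HarmonicSolution
from .models import EyeModel

__all__ = [
    "FrequencyResponse",
    "ResonancePeak",
    "ModeShape",
    "sweep",
    "find_peaks",
    "classify_mode",
    "resonance_frequencies",
]


@dataclass
class FrequencyResponse:
    """Apex oscillation amplitude (and phase) versus imposed frequency."""

    frequencies: np.ndarray  # Hz, strictly increasing
    amplitude: np.ndarray  # m
    phase: np.ndarray  # rad
    probe: str = "apex"

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("FRF frequencies must be strictly increasing")
        if np.any(self.amplitude < 0):
            raise ValueError("FRF amplitudes must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f_hz": self.frequencies, "amplitude_m": self.amplitude, "phase_rad": self.phase}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrequencyResponse":
        df = pd.read_csv(path)
        return cls(df["f_hz"].values, df["amplitude_m"].values, df["phase_rad"].values)


@dataclass
class ResonancePeak:
    frequency: float  # Hz (quadratically refined)
    amplitude: float  # m
    width: float  # Hz, at half prominence
    index: int  # order of appearance in the sweep (ascending frequency)
    grid_frequency: float = 0.0  # raw grid point the peak was detected at


@dataclass
class ModeShape:
    frequency: float
    solution: HarmonicSolution
    nodal_circles: int
    scleral_participation: float
    cornea_dominated: bool


def sweep(model: EyeModel, f_min: float, f_max: float, step: float) -> FrequencyResponse:
    """One harmonic solve per grid point; deterministic."""
    if not f_min < f_max:
        raise ValueError("need f_min < f_max")
    if not 0 < step:
        raise ValueError("step must be positive")
    freqs = np.arange(f_min, f_max + 0.5 * step, step)
    amp = np.empty_like(freqs)
    ph = np.empty_like(freqs)
    system = model.system()
    from .fem import SolverError, solve_harmonic

    for k, f in enumerate(freqs):
        try:
            sol = solve_harmonic(system, float(f))
        except SolverError as exc:
            raise SolverError(f"sweep failed at {f:.6g} Hz: {exc}") from exc
        uz = sol.u_z(model.probe_node)
        amp[k] = abs(uz)
        ph[k] = np.angle(uz)
    return FrequencyResponse(freqs, amp, ph)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point quadratic interpolation of a local maximum at grid index i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[i]), float(y[i])
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -1.0, 1.0))
    h = x[i + 1] - x[i]
    return float(x[i] + d * h), float(y1 - 0.25 * (y0 - y2) * d)


def find_peaks(frf: FrequencyResponse, prominence_frac: float = 0.05) -> list[ResonancePeak]:
    """Local FRF maxima with prominence above ``prominence_frac`` of the
    global maximum, frequency-refined by 3-point quadratic interpolation."""
    if len(frf.frequencies) < 5:
        raise ValueError("need at least 5 grid points to detect peaks")
    amp = frf.amplitude
    top = amp.max()
    if top <= 0:
        return []
    idx, props = scipy.signal.find_peaks(amp, prominence=prominence_frac * top)
    if idx.size == 0:
        return []
    widths, _, _, _ = scipy.signal.peak_widths(amp, idx, rel_height=0.5)
    step = np.median(np.diff(frf.frequencies))
    peaks = []
    for k, i in enumerate(idx):
        f_ref, a_ref = _parabolic_refine(frf.frequencies, amp, int(i))
        peaks.append(
            ResonancePeak(
                frequency=f_ref,
                amplitude=a_ref,
                width=float(widths[k] * step),
                index=k,
                grid_frequency=float(frf.frequencies[i]),
            )
        )
    return peaks


def classify_mode(model: EyeModel, peak: ResonancePeak | float) -> ModeShape:
    """Solve at the (refined) peak frequency and classify the mode shape.

    Nodal circles are counted as sign changes of the real part of the
    vertical displacement along the anterior corneal arc (after rotating the
    field so the apex response is real).  Scleral participation is the
    scleral share of the elastic deformation energy (zero for flaps).
    """
    f = peak.frequency if isinstance(peak, ResonancePeak) else float(peak)
    sol = model.solve(f)
    uz_apex = sol.u_z(model.probe_node)
    rot = np.exp(-1j * np.angle(uz_apex)) if uz_apex != 0 else 1.0
    arc = model.arc_nodes
    w = np.real(rot * np.array([sol.u_z(n) for n in arc]))
    wmax = np.abs(w).max()
    circles = 0
    if wmax > 0:
        sgn = np.sign(w[np.abs(w) > 0.02 * wmax])
        circles = int(np.count_nonzero(np.diff(sgn) != 0))

    part = 0.0
    if model.kind == "globe":
        part = _scleral_participation(model, sol, f)
    return ModeShape(
        frequency=f,
        solution=sol,
        nodal_circles=circles,
        scleral_participation=part,
        cornea_dominated=part < 0.5,
    )


def _scleral_participation(model: EyeModel, sol: HarmonicSolution, f: float) -> float:
    """Scleral / total solid deformation-energy ratio at a solved frequency."""
    from . import elements as el
    from .materials import complex_modulus

    energies: dict[str, float] = {}
    mesh, dof = model.mesh, model.dof
    for e in np.flatnonzero(mesh.region != "fluid"):
        reg = str(mesh.region[e])
        mat = model.materials[reg]
        E_f = np.real(complex_modulus(mat, f)) * model.e_scale[e]
        lam, mu = mat.lame(E_f)
        xy = mesh.nodes[mesh.elements[e]]
        Ke, _ = el.solid_matrices(xy, lam, mu, mat.rho)
        u_e = sol.u[dof.sdofs(mesh.elements[e])]
        energies[reg] = energies.get(reg, 0.0) + 0.5 * float(np.real(np.conj(u_e) @ (Ke @ u_e)))
    total = sum(energies.values())
    if total <= 0:
        return 0.0
    return energies.get("sclera", 0.0) / total


def align_peak_frequencies(ref: np.ndarray, other: np.ndarray, gap: float = 80.0) -> np.ndarray:
    """Order-preserving assignment of ``other`` frequencies to ``ref`` modes.

    Classic sequence-alignment DP minimising the total |df| with a fixed gap
    penalty (Hz); returns, per reference mode, the matched frequency or NaN.
    Used to track modes across parameter levels and to pair simulated with
    observed peaks when a mode drifts out of the sweep window.
    """
    ref = np.asarray(ref, dtype=float)
    other = np.asarray(other, dtype=float)
    n, m = len(ref), len(other)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, :] = np.arange(m + 1) * gap
    D[:, 0] = np.arange(n + 1) * gap
    choice = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            opts = (
                D[i - 1, j - 1] + abs(ref[i - 1] - other[j - 1]),
                D[i - 1, j] + gap,
                D[i, j - 1] + gap,
            )
            k = int(np.argmin(opts))
            D[i, j], choice[i, j] = opts[k], k
    out = np.full(n, np.nan)
    i, j = n, m
    while i > 0 and j > 0:
        k = choice[i, j]
        if k == 0:
            out[i - 1] = other[j - 1]
            i, j = i - 1, j - 1
        elif k == 1:
            i -= 1
        else:
            j -= 1
    return out


def resonance_frequencies(
    model: EyeModel,
    f_min: float,
    f_max: float,
    step: float = 5.0,
    refine_step: float | None = 1.0,
    prominence_frac: float = 0.05,
) -> list[ResonancePeak]:
    """Detect resonance peaks with a coarse sweep plus local refinement.

    A coarse grid (``step``) locates the peaks; around each one a local
    sweep at ``refine_step`` plus quadratic interpolation pins the frequency
    down to sub-grid accuracy.  Pass ``refine_step=None`` to skip refinement.
    """
    frf = sweep(model, f_min, f_max, step)
    peaks = find_peaks(frf, prominence_frac)
    if refine_step is None or refine_step >= step:
        return peaks
    refined = []
    for pk in peaks:
        lo = max(f_min, pk.grid_frequency - step)
        hi = min(f_max, pk.grid_frequency + step)
        local = sweep(model, lo, hi, refine_step)
        i = int(np.argmax(local.amplitude))
        f_ref, a_ref = _parabolic_refine(local.frequencies, local.amplitude, i)
        refined.append(
            ResonancePeak(
                frequency=f_ref, amplitude=a_ref, width=pk.width,
                index=pk.index, grid_frequency=pk.grid_frequency,
            )
        )
    return refined
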