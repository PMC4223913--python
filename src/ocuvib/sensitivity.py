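"""One-at-a-time parameter sensitivity of the resonance frequencies.

Each recognised parameter is varied over a relative range (default +/-20%)
about its nominal value; the model is rebuilt and swept at every level, the
resonance peaks are tracked across levels by mode (order-preserving nearest
matching, since large parameter changes can move peaks in and out of the
window), and per-mode linear-regression slopes are reported in the natural
configuration units (Hz per kPa, per kg m^-3, per um, per mm, per mmHg).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import ConfigurationError
from .models import EyeModel, FlapConfig, GlobeConfig, WeakZone, apply_weak_zone, build_flap, build_globe
from .response import (
    FrequencyResponse,
    ResonancePeak,
    align_peak_frequencies as _align,
    find_peaks,
    resonance_frequencies,
    sweep,
)

__all__ = [
    "SweepSpec",
    "SensitivitySlope",
    "ParamSweepResult",
    "WeakeningReport",
    "apply_parameter",
    "run_sweep",
    "fit_slope",
    "sensitivity_table",
    "compare_weakened",
]

MMHG = 133.322  # Pa

# parameter name -> (config field(s), unit of the regression abscissa)
_FLAP_PARAMS = {
    "E": (("E_kpa",), "kPa"),
    "density": (("density",), "kg m^-3"),
    "thickness": (("thickness_um",), "um"),
    "diameter": (("diameter_mm",), "mm"),
    "radius": (("diameter_mm",), "mm"),  # jointly scaled, reported per mm of radius
    "prestress": (("prestress_kpa",), "kPa"),
}
_GLOBE_PARAMS = {
    "E": (("E_anterior_kpa", "E_posterior_kpa"), "kPa"),
    "density": (("density",), "kg m^-3"),
    "thickness": (("central_thickness_um",), "um"),
    "curvature": (("anterior_curvature_mm", "posterior_curvature_mm"), "mm"),
    "IOP": (("iop_kpa",), "mmHg"),
    "sclera_E": (("sclera_E_kpa",), "kPa"),
    "sclera_diameter": (("sclera_diameter_mm",), "mm"),
    "corneal_diameter": (("corneal_diameter_mm",), "mm"),
}


@dataclass(frozen=True)
class SweepSpec:
    """One-at-a-time sweep of a named parameter about its nominal value."""

    parameter: str
    rel_range: float = 0.2
    levels: int = 5

    def __post_init__(self):
        if self.rel_range <= 0:
            raise ConfigurationError("sweep range must be positive")
        if self.levels < 3:
            raise ConfigurationError("a sensitivity sweep needs at least 3 levels")


@dataclass
class SensitivitySlope:
    parameter: str
    mode: int
    slope: float  # Hz per unit
    unit: str
    r2: float
    nominal: float


@dataclass
class ParamSweepResult:
    parameter: str
    unit: str
    values: np.ndarray  # abscissa, natural units
    nominal: float
    peak_sets: list
    freq_table: np.ndarray  # (levels, n_modes), NaN = mode missing at level
    nominal_index: int


def _registry(cfg):
    if isinstance(cfg, FlapConfig):
        return _FLAP_PARAMS, build_flap
    if isinstance(cfg, GlobeConfig):
        return _GLOBE_PARAMS, build_globe
    raise ConfigurationError(f"unrecognised config type {type(cfg)!r}")


def apply_parameter(cfg, name: str, factor: float):
    """Scale the named parameter (jointly, for multi-field parameters)."""
    params, _ = _registry(cfg)
    if name not in params:
        raise ConfigurationError(
            f"unknown parameter {name!r}; recognised: {sorted(params)}"
        )
    fields, _ = params[name]
    return dataclasses.replace(
        cfg, **{fld: getattr(cfg, fld) * factor for fld in fields}
    )


def parameter_value(cfg, name: str) -> float:
    """Nominal abscissa value in the parameter's reporting unit."""
    params, _ = _registry(cfg)
    fields, unit = params[name]
    val = getattr(cfg, fields[0])
    if name == "radius":
        val = val / 2.0
    if name == "IOP":
        val = val * 1e3 / MMHG  # kPa -> mmHg
    return float(val)




def run_sweep(
    cfg,
    spec: SweepSpec,
    f_min: float,
    f_max: float,
    step: float = 5.0,
    refine_step: float | None = 1.0,
) -> ParamSweepResult:
    """Rebuild and sweep the model at each parameter level; peaks are matched
    across levels to the nominal level's modes (a peak that leaves the window
    is recorded as missing, never silently re-indexed)."""
    params, builder = _registry(cfg)
    factors = np.linspace(1.0 - spec.rel_range, 1.0 + spec.rel_range, spec.levels)
    nominal_index = int(np.argmin(np.abs(factors - 1.0)))
    peak_sets, values = [], []
    for fac in factors:
        c = apply_parameter(cfg, spec.parameter, float(fac))
        model = builder(c)
        peaks = resonance_frequencies(model, f_min, f_max, step, refine_step)
        peak_sets.append(peaks)
        values.append(parameter_value(c, spec.parameter))
    ref = np.array([p.frequency for p in peak_sets[nominal_index]])
    table = np.full((spec.levels, len(ref)), np.nan)
    for i, peaks in enumerate(peak_sets):
        table[i] = _align(ref, np.array([p.frequency for p in peaks]))
    _, unit = params[spec.parameter]
    return ParamSweepResult(
        parameter=spec.parameter,
        unit=unit,
        values=np.asarray(values),
        nominal=values[nominal_index],
        peak_sets=peak_sets,
        freq_table=table,
        nominal_index=nominal_index,
    )


def fit_slope(result: ParamSweepResult, mode: int) -> SensitivitySlope:
    """Ordinary least-squares slope of a tracked mode's frequency versus the
    parameter value."""
    f = result.freq_table[:, mode]
    ok = np.isfinite(f)
    if ok.sum() < 3:
        raise ValueError(
            f"mode {mode} of parameter {result.parameter!r} present at only "
            f"{int(ok.sum())} levels; need >= 3 for a regression"
        )
    x, y = result.values[ok], f[ok]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return SensitivitySlope(
        parameter=result.parameter,
        mode=mode,
        slope=float(slope),
        unit=f"Hz / {result.unit}",
        r2=float(np.clip(r2, 0.0, 1.0)),
        nominal=result.nominal,
    )


def sensitivity_table(
    cfg,
    parameters: list[str],
    f_min: float,
    f_max: float,
    step: float = 5.0,
    refine_step: float | None = 1.0,
    rel_range: float = 0.2,
    levels: int = 5,
) -> pd.DataFrame:
    """Slopes for several parameters in one table (one row per parameter,
    one column per tracked mode), mirroring a sensitivity-gradient summary."""
    rows = []
    for name in parameters:
        res = run_sweep(cfg, SweepSpec(name, rel_range, levels), f_min, f_max, step, refine_step)
        row = {"parameter": name, "nominal": res.nominal, "unit": res.unit}
        for mode in range(res.freq_table.shape[1]):
            try:
                sl = fit_slope(res, mode)
                row[f"mode{mode + 1}_slope"] = sl.slope
                row[f"mode{mode + 1}_r2"] = sl.r2
            except ValueError:
                row[f"mode{mode + 1}_slope"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def mode_signatures(
    model: EyeModel,
    f_min: float,
    f_max: float,
    step: float = 5.0,
    refine_step: float | None = 1.0,
    prominence_frac: float = 0.01,
):
    """Detected peaks with their classified mode shapes.

    Uses a low prominence threshold so weakly excited modes can still be
    paired by shape; spurious candidates are rejected downstream by the
    shape-matching step.  Returns a list of ``ModeShape`` (each knows its
    frequency, nodal-circle count and scleral participation).
    """
    from .response import classify_mode, resonance_frequencies

    peaks = resonance_frequencies(
        model, f_min, f_max, step, refine_step, prominence_frac=prominence_frac
    )
    return [classify_mode(model, pk) for pk in peaks]


def pair_modes_by_shape(modes_a, modes_b, max_df: float = 80.0):
    """Order-preserving pairing of two classified mode sets.

    Alignment DP where matching modes with different nodal-circle counts is
    heavily penalised, so a pair means "the same vibration mode was found
    in both models".  Returns a list of (mode_a, mode_b) pairs.
    """
    n, m = len(modes_a), len(modes_b)
    gap = max_df
    mismatch = 10.0 * max_df
    D = np.full((n + 1, m + 1), np.inf)
    D[0, :] = np.arange(m + 1) * gap
    D[:, 0] = np.arange(n + 1) * gap
    choice = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(modes_a[i - 1].frequency - modes_b[j - 1].frequency)
            if modes_a[i - 1].nodal_circles != modes_b[j - 1].nodal_circles:
                cost += mismatch
            # participation drifts continuously with the parameter, so only a
            # large jump marks a genuinely different mode
            if abs(
                modes_a[i - 1].scleral_participation
                - modes_b[j - 1].scleral_participation
            ) > 0.45:
                cost += mismatch
            opts = (D[i - 1, j - 1] + cost, D[i - 1, j] + gap, D[i, j - 1] + gap)
            k = int(np.argmin(opts))
            D[i, j], choice[i, j] = opts[k], k
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        k = choice[i, j]
        if k == 0:
            a, b = modes_a[i - 1], modes_b[j - 1]
            if (
                abs(a.frequency - b.frequency) <= max_df
                and a.nodal_circles == b.nodal_circles
                and abs(a.scleral_participation - b.scleral_participation) <= 0.45
            ):
                pairs.append((a, b))
            i, j = i - 1, j - 1
        elif k == 1:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def max_mode_shift(
    cfg: GlobeConfig,
    factor: float,
    parameter: str = "E",
    f_min: float = 50.0,
    f_max: float = 510.0,
    step: float = 1.0,
) -> float:
    """Largest per-mode natural-frequency shift produced by scaling a
    parameter (modes paired by shape between the nominal and scaled model)."""
    base = mode_signatures(build_globe(cfg), f_min, f_max, step, None)
    scaled_cfg = apply_parameter(cfg, parameter, factor)
    scaled = mode_signatures(build_globe(scaled_cfg), f_min, f_max, step, None)
    pairs = pair_modes_by_shape(base, scaled)
    if not pairs:
        raise RuntimeError("no modes could be paired between the two models")
    return float(max(abs(b.frequency - a.frequency) for a, b in pairs))


def cornea_dominated_mode_slopes(
    cfg: GlobeConfig,
    rel_range: float = 0.2,
    levels: int = 5,
    f_min: float = 50.0,
    f_max: float = 600.0,
    step: float = 5.0,
    refine_step: float | None = 1.0,
) -> list[SensitivitySlope]:
    """Per-mode elasticity slopes of the cornea-dominated globe modes.

    Modes whose scleral deformation-energy share exceeds one half (at the
    nominal level) are excluded before tracking: the cornea-dominated modes
    are the ones used to retrieve corneal properties.  The default window
    extends beyond the 510 Hz display range so the highest tracked mode
    stays in view over the whole +/-20% sweep (the simulations behind the
    reference gradients ran to 750 Hz); a mode that still leaves the window
    at some level is simply missing there.
    """
    factors = np.linspace(1.0 - rel_range, 1.0 + rel_range, levels)
    nominal_index = int(np.argmin(np.abs(factors - 1.0)))
    sigs, values = [], []
    for fac in factors:
        c = apply_parameter(cfg, "E", float(fac))
        modes = mode_signatures(build_globe(c), f_min, f_max, step, refine_step)
        sigs.append(modes)
        values.append(parameter_value(c, "E"))
    # dominance is judged at the nominal level only; a mode's scleral share
    # drifts with the parameter and must not re-label it mid-sweep
    ref = [m for m in sigs[nominal_index] if m.cornea_dominated]
    table = np.full((levels, len(ref)), np.nan)
    for i, modes in enumerate(sigs):
        for a, b in pair_modes_by_shape(ref, modes):
            k = ref.index(a)
            table[i, k] = b.frequency
    result = ParamSweepResult(
        parameter="E", unit="kPa", values=np.asarray(values),
        nominal=values[nominal_index], peak_sets=sigs, freq_table=table,
        nominal_index=nominal_index,
    )
    out = []
    for mode in range(table.shape[1]):
        try:
            out.append(fit_slope(result, mode))
        except ValueError:
            out.append(
                SensitivitySlope("E", mode, np.nan, "Hz / kPa", np.nan,
                                 result.nominal)
            )
    return out


@dataclass
class WeakeningReport:
    nominal_frf: FrequencyResponse
    weakened_frf: FrequencyResponse
    nominal_peaks: list
    weakened_peaks: list
    new_peaks: list  # peaks with no nominal counterpart within the tolerance
    shifted: list  # (nominal_f, weakened_f) pairs
    match_tol: float


def compare_weakened(
    cfg: GlobeConfig,
    zone: WeakZone,
    f_min: float,
    f_max: float,
    step: float = 1.0,
    match_tol: float = 15.0,
) -> WeakeningReport:
    """FRFs of the nominal and locally weakened globe on an identical grid;
    weakened-model peaks are classified as *new* (no nominal peak within
    ``match_tol``) or *shifted*."""
    nominal = build_globe(cfg)
    weakened = apply_weak_zone(nominal, zone)
    frf_n = sweep(nominal, f_min, f_max, step)
    frf_w = sweep(weakened, f_min, f_max, step)
    pk_n = find_peaks(frf_n)
    pk_w = find_peaks(frf_w)
    fn = np.array([p.frequency for p in pk_n])
    new, shifted = [], []
    used = set()
    for p in pk_w:
        if fn.size:
            order = np.argsort(np.abs(fn - p.frequency))
            j = next((int(j) for j in order if j not in used), None)
        else:
            j = None
        if j is not None and abs(fn[j] - p.frequency) <= match_tol:
            used.add(j)
            shifted.append((float(fn[j]), float(p.frequency)))
        else:
            new.append(p)
    return WeakeningReport(
        nominal_frf=frf_n,
        weakened_frf=frf_w,
        nominal_peaks=pk_n,
        weakened_peaks=pk_w,
        new_peaks=new,
        shifted=shifted,
        match_tol=match_tol,
    )
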