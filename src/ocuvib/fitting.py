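"""Model-based inversion of resonance frequencies to corneal elasticity.

The measured (or synthetic) resonance-peak frequencies are matched by
iteratively adjusting the corneal elastic modulus of the forward model until
the simulated peak set agrees with the observation in a least-squares sense.
For globe models the anterior modulus is fitted with the posterior modulus
co-scaled (one stiffness value per condition).  The frequency resolution of
the measurement propagates to a modulus uncertainty through the local
sensitivity slope of the most responsive matched mode.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .models import FlapConfig, GlobeConfig, build_flap, build_globe
from .response import align_peak_frequencies, resonance_frequencies

__all__ = [
    "FitResult",
    "PairingError",
    "fit_elasticity",
    "forward_peaks",
    "stiffness_factor",
    "with_corneal_E",
]

# Hz^2 per unmatched peak during iteration: large enough to prefer matching
# counts near the optimum, small enough not to mask the true basin when a
# marginal peak flickers across the detection threshold
_MISSING_PEAK_PENALTY = 20.0**2


class PairingError(RuntimeError):
    """Simulated and observed peak sets cannot be paired mode-by-mode."""


@dataclass
class FitResult:
    E_kpa: float  # fitted corneal elasticity (anterior, for globes)
    residual: float  # sum of squared matched peak-frequency differences, Hz^2
    uncertainty_kpa: float  # from the frequency resolution via the local slope
    f_resolution: float
    n_modes: int
    n_evaluations: int
    converged: bool
    history: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.E_kpa <= 0:
            raise ValueError("fitted modulus must be positive")


def with_corneal_E(cfg, E_kpa: float):
    """Config copy with corneal elasticity E (kPa).  Globe: anterior set to E,
    posterior co-scaled to preserve the anterior/posterior ratio."""
    if isinstance(cfg, FlapConfig):
        return dataclasses.replace(cfg, E_kpa=E_kpa)
    if isinstance(cfg, GlobeConfig):
        ratio = cfg.E_posterior_kpa / cfg.E_anterior_kpa
        return dataclasses.replace(
            cfg, E_anterior_kpa=E_kpa, E_posterior_kpa=E_kpa * ratio
        )
    raise TypeError(f"unrecognised config type {type(cfg)!r}")


def _build(cfg):
    return build_flap(cfg) if isinstance(cfg, FlapConfig) else build_globe(cfg)


def forward_peaks(
    cfg, f_min: float, f_max: float, step: float = 5.0, refine_step: float | None = 1.0
) -> list[float]:
    """Resonance-peak frequencies of the forward model (ascending)."""
    model = _build(cfg)
    return [p.frequency for p in resonance_frequencies(model, f_min, f_max, step, refine_step)]


def fit_elasticity(
    cfg,
    observed_peaks,
    f_resolution: float,
    bounds_kpa: tuple[float, float],
    f_min: float,
    f_max: float,
    step: float = 5.0,
    refine_step: float | None = 1.0,
    xatol_kpa: float = 0.02,
) -> FitResult:
    """Bounded scalar least-squares fit of corneal elasticity to peak
    frequencies.

    Peaks are paired by ascending frequency (a uniform corneal-modulus change
    preserves mode order, so frequency order equals mode order); during the
    line search an unequal peak count is penalised rather than raised so the
    optimiser can traverse regions where a mode leaves the sweep window.  A
    count mismatch *at the optimum* raises :class:`PairingError`.
    """
    obs = np.sort(np.asarray(list(observed_peaks), dtype=float))
    if obs.size == 0:
        raise ValueError("need at least one observed peak")
    lo, hi = bounds_kpa
    if not 0 < lo < hi:
        raise ValueError(f"invalid bounds {bounds_kpa}")
    history: list[tuple[float, float]] = []

    def peaks_at(E: float, refined: bool = False) -> np.ndarray:
        # during iteration the coarse grid plus quadratic interpolation is
        # accurate to a fraction of the grid step and several times cheaper
        return np.array(
            forward_peaks(
                with_corneal_E(cfg, float(E)), f_min, f_max, step,
                refine_step if refined else None,
            )
        )

    def objective(E: float, refined: bool = True) -> float:
        sim = peaks_at(E, refined)
        matched = align_peak_frequencies(obs, sim)
        ok = np.isfinite(matched)
        res = float(np.sum((matched[ok] - obs[ok]) ** 2))
        n_gaps = int((~ok).sum()) + max(0, sim.size - int(ok.sum()))
        res += _MISSING_PEAK_PENALTY * n_gaps
        history.append((float(E), res))
        return res

    # coarse scan first: the count-mismatch penalty makes the objective
    # piecewise, which can strand a pure Brent search in the wrong basin
    E_scan = np.linspace(lo, hi, 13)
    vals = np.array([objective(E, refined=False) for E in E_scan])
    k = int(np.argmin(vals))
    blo = E_scan[max(k - 1, 0)]
    bhi = E_scan[min(k + 1, len(E_scan) - 1)]
    opt = scipy.optimize.minimize_scalar(
        objective, bounds=(float(blo), float(bhi)), method="bounded",
        options={"xatol": xatol_kpa},
    )
    E_fit = float(opt.x)
    sim = peaks_at(E_fit, refined=True)
    if sim.size != obs.size:
        raise PairingError(
            f"peak-count mismatch at fitted E = {E_fit:.3f} kPa: "
            f"model {np.round(sim, 1).tolist()} Hz vs observed {np.round(obs, 1).tolist()} Hz"
        )
    residual = float(np.sum((sim - obs) ** 2))

    # uncertainty: frequency resolution / local slope of the most sensitive mode
    dE = max(0.03 * E_fit, 0.05)
    p_lo, p_hi = peaks_at(E_fit - dE, refined=True), peaks_at(E_fit + dE, refined=True)
    n = min(p_lo.size, p_hi.size, obs.size)
    if n > 0:
        slopes = np.abs(p_hi[:n] - p_lo[:n]) / (2 * dE)  # Hz / kPa
        s_max = float(slopes.max())
        uncertainty = f_resolution / s_max if s_max > 0 else np.inf
    else:
        uncertainty = np.inf

    return FitResult(
        E_kpa=E_fit,
        residual=residual,
        uncertainty_kpa=float(uncertainty),
        f_resolution=f_resolution,
        n_modes=int(obs.size),
        n_evaluations=len(history),
        converged=bool(opt.success),
        history=history,
    )


def stiffness_factor(fit_a: FitResult, fit_b: FitResult) -> tuple[float, float]:
    """Stiffness factor E_b / E_a with first-order uncertainty propagation."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    ratio = fit_b.E_kpa / fit_a.E_kpa
    rel = np.hypot(
        fit_a.uncertainty_kpa / fit_a.E_kpa, fit_b.uncertainty_kpa / fit_b.E_kpa
    )
    return float(ratio), float(ratio * rel)
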