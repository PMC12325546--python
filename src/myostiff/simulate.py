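"""Synthetic-data generators for the passive-stiffness pipeline.

Every downstream stage (contact-point detection, windowed Hertz estimation,
stretch-peak analysis, paired statistics) is exercised on data produced here,
with the ground truth returned alongside so recovery can be checked exactly.

Generators model:

* single AFM approach curves over a Hertzian spherical contact, including
  cantilever compliance (the implicit force balance ``k*d = F(z - z_c - d)``),
  a linear baseline tilt and additive Gaussian deflection noise;
* force maps — grids of pixels with log-normally distributed local stiffness
  measured repeatedly with independent technical noise;
* paired pre/post Young's-modulus cohorts with a known median reduction;
* step-stretch force traces with a quadratic peak–strain law and a
  single-exponential hold-phase relaxation.

All randomness flows from the explicit ``seed`` argument of each call; there
is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .contact import ProbeParams, hertz_force, hertz_prefactor

__all__ = [
    "ProbeParams",
    "ForceCurve",
    "GroundTruth",
    "ForceMapResult",
    "StretchProtocol",
    "StretchTrace",
    "DEFAULT_PROBE",
    "travel_for_force",
    "gen_hertz_curve",
    "gen_force_map",
    "gen_paired_dataset",
    "gen_stretch_trace",
]

#: Probe matching the study conditions: 4.9 um spherical tip, soft-tissue
#: cantilever stiffness within the calibrated 0.224-0.407 N/m range,
#: incompressible sample (nu = 0.5).
DEFAULT_PROBE = ProbeParams(spring_constant=0.3, tip_radius=4.9e-6, poisson_ratio=0.5)

#: Force the high analysis window tops out at (N); curves that cannot reach it
#: are useless to the windowed estimator, so the generator refuses to make them.
HIGH_WINDOW_TOP_N = 4.25e-9


@dataclass(frozen=True)
class ForceCurve:
    """A raw AFM force-height recording (approach segment).

    ``height`` is the piezo z position and ``deflection`` the cantilever
    deflection, both in metres; force is ``spring_constant * deflection``.
    """

    curve_id: str
    location_id: str
    height: np.ndarray
    deflection: np.ndarray
    probe: ProbeParams
    segment: str = "approach"
    condition: str = "baseline"
    phase: str = "pre"

    def __post_init__(self) -> None:
        h = np.asarray(self.height, dtype=float)
        d = np.asarray(self.deflection, dtype=float)
        if h.shape != d.shape or h.ndim != 1:
            raise ValueError("height and deflection must be 1-D arrays of equal length")
        if h.size < 10:
            raise ValueError(f"curve needs >= 10 samples, got {h.size}")
        if not (np.isfinite(h).all() and np.isfinite(d).all()):
            raise ValueError("height/deflection contain non-finite values")
        if self.segment == "approach" and not (np.diff(h) > 0).all():
            raise ValueError("approach segment must be strictly monotonic in height")
        object.__setattr__(self, "height", h)
        object.__setattr__(self, "deflection", d)
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Simulator bookkeeping for one generated curve."""

    E_true: float
    contact_point: float
    baseline_tilt: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _solve_deflection(dz: np.ndarray, E: float, probe: ProbeParams) -> np.ndarray:
    """Contact deflection d solving k*d = C*(dz - d)**1.5 for each dz > 0.

    Bracketed root-finder per sample (unconditionally convergent on
    [0, dz]); relative tolerance 1e-12.
    """
    C = hertz_prefactor(E, probe)
    k = probe.spring_constant
    out = np.zeros_like(dz)
    for i, z in enumerate(dz):
        if z <= 0:
            continue
        f = lambda d: C * (z - d) ** 1.5 - k * d
        out[i] = brentq(f, 0.0, z, xtol=1e-18, rtol=1e-12)
    return out


def peak_force(E: float, probe: ProbeParams, dz_max: float) -> float:
    """Force reached at piezo travel ``dz_max`` beyond contact."""
    if dz_max <= 0:
        return 0.0
    d = _solve_deflection(np.array([dz_max]), E, probe)[0]
    return probe.spring_constant * d


def travel_for_force(E: float, probe: ProbeParams, f_target: float = HIGH_WINDOW_TOP_N) -> float:
    """Piezo travel beyond contact needed to reach ``f_target``:
    indentation (f/C)**(2/3) plus cantilever deflection f/k."""
    C = hertz_prefactor(E, probe)
    return (f_target / C) ** (2.0 / 3.0) + f_target / probe.spring_constant


def gen_hertz_curve(
    E_true: float,
    contact_point: float,
    probe: ProbeParams = DEFAULT_PROBE,
    z_span: float = 3.0e-6,
    n_points: int = 600,
    noise_sd: float = 0.0,
    baseline_tilt: float = 0.0,
    seed: int = 0,
    *,
    z_start: float = 0.0,
    curve_id: str = "c0",
    location_id: str = "loc0",
    condition: str = "baseline",
    phase: str = "pre",
    min_peak_force: float | None = HIGH_WINDOW_TOP_N,
) -> tuple[ForceCurve, GroundTruth]:
    """Simulate one AFM approach curve over a Hertzian contact.

    The piezo ramps from ``z_start`` over ``z_span`` (m). Below the contact
    point the deflection is just the baseline (linear tilt plus noise); beyond
    it the deflection additionally carries the contact term obtained by
    solving the implicit force balance per sample.

    Returns the curve together with its :class:`GroundTruth`.

    Raises
    ------
    ValueError
        If parameters are invalid, or if the peak force reachable within
        ``z_span`` stays below ``min_peak_force`` ("window unreachable").
    """
    if E_true <= 0:
        raise ValueError("E_true must be > 0")
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if z_span <= 0:
        raise ValueError("z_span must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    z = np.linspace(z_start, z_start + z_span, n_points)
    dz = z - contact_point
    if min_peak_force is not None:
        fmax = peak_force(E_true, probe, float(dz[-1]))
        if fmax < min_peak_force:
            raise ValueError(
                "window unreachable: peak force "
                f"{fmax * 1e9:.3g} nN < {min_peak_force * 1e9:.3g} nN "
                "within z_span at this E_true"
            )

    d_contact = _solve_deflection(dz, E_true, probe)
    rng = np.random.default_rng(seed)
    baseline = baseline_tilt * (z - z[0])
    deflection = baseline + d_contact + rng.normal(0.0, noise_sd, size=n_points)

    curve = ForceCurve(
        curve_id=curve_id,
        location_id=location_id,
        height=z,
        deflection=deflection,
        probe=probe,
        condition=condition,
        phase=phase,
    )
    truth = GroundTruth(
        E_true=E_true,
        contact_point=contact_point,
        baseline_tilt=baseline_tilt,
        noise_sd=noise_sd,
        seed=seed,
    )
    return curve, truth


@dataclass
class ForceMapResult:
    """Curves of a repeated force-mapping grid plus their ground truth.

    ``truth`` has one row per pixel (row, col, x_m, y_m, E_true_Pa); each
    curve's ``location_id`` is ``"r{row}c{col}"`` and its ``curve_id`` appends
    ``"_rep{repeat}"``.
    """

    curves: list[ForceCurve] = field(default_factory=list)
    curve_truths: list[GroundTruth] = field(default_factory=list)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    repeats: int = 0


def gen_force_map(
    grid_rows: int = 6,
    grid_cols: int = 6,
    spacing: float = 5.0e-6,
    E_median: float = 963.3,
    E_dispersion: float = 0.5,
    repeats: int = 3,
    technical_noise_sd: float = 0.5e-9,
    probe: ProbeParams = DEFAULT_PROBE,
    seed: int = 0,
    *,
    contact_point: float = 1.0e-6,
    z_span: float = 4.0e-6,
    n_points: int = 400,
) -> ForceMapResult:
    """Simulate a repeated stiffness map (default 6 x 6 pixels, 5 um spacing,
    three repeats, matching the force-mapping control geometry).

    Each pixel draws one true modulus from a log-normal field (median
    ``E_median``, log-scale sd ``E_dispersion``) shared across repeats;
    technical deflection noise is drawn independently per repeat.
    """
    if grid_rows < 1 or grid_cols < 1 or repeats < 1:
        raise ValueError("grid_rows, grid_cols and repeats must all be >= 1")
    if E_median <= 0:
        raise ValueError("E_median must be > 0")
    if E_dispersion < 0 or technical_noise_sd < 0:
        raise ValueError("dispersions must be >= 0")

    rng = np.random.default_rng(seed)
    result = ForceMapResult(repeats=repeats)
    rows = []
    for r in range(grid_rows):
        for c in range(grid_cols):
            E_pix = E_median * np.exp(rng.normal(0.0, E_dispersion))
            rows.append(
                {"row": r, "col": c, "x_m": c * spacing, "y_m": r * spacing, "E_true_Pa": E_pix}
            )
            loc = f"r{r}c{c}"
            for rep in range(repeats):
                sub = int(rng.integers(0, 2**31 - 1))
                curve, truth = gen_hertz_curve(
                    E_pix,
                    contact_point,
                    probe=probe,
                    z_span=z_span,
                    n_points=n_points,
                    noise_sd=technical_noise_sd,
                    seed=sub,
                    curve_id=f"{loc}_rep{rep}",
                    location_id=loc,
                )
                result.curves.append(curve)
                result.curve_truths.append(truth)
    result.truth = pd.DataFrame(rows)
    return result


def gen_paired_dataset(
    n_locations: int = 90,
    baseline_median: float = 963.3,
    location_dispersion: float = 0.7,
    effect_pct: float = 20.0,
    residual_sd_pct: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a paired pre/post Young's-modulus cohort.

    Pre-treatment moduli are log-normal around ``baseline_median`` (the
    observed tissue median is used as the realistic scale, with a log-sd
    capturing the strong between-location heterogeneity). Post values are
    ``E_pre * (1 - effect_pct/100) * exp(eps)`` with ``eps`` zero-median
    Gaussian of sd ``residual_sd_pct/100`` on the log scale, so the *median*
    reduction equals ``effect_pct`` exactly by construction.

    Returns a DataFrame with columns ``location_id, E_pre_Pa, E_post_Pa``.
    """
    if not 0 <= effect_pct < 100:
        raise ValueError("effect_pct must be in [0, 100)")
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    if baseline_median <= 0:
        raise ValueError("baseline_median must be > 0")
    if location_dispersion < 0 or residual_sd_pct < 0:
        raise ValueError("dispersions must be >= 0")

    rng = np.random.default_rng(seed)
    E_pre = baseline_median * np.exp(rng.normal(0.0, location_dispersion, n_locations))
    eps = rng.normal(0.0, residual_sd_pct / 100.0, n_locations)
    E_post = E_pre * (1.0 - effect_pct / 100.0) * np.exp(eps)
    return pd.DataFrame(
        {
            "location_id": [f"loc{i}" for i in range(n_locations)],
            "E_pre_Pa": E_pre,
            "E_post_Pa": E_post,
        }
    )


@dataclass(frozen=True)
class StretchProtocol:
    """Step-stretch protocol: ordered strain levels (%), hold length and
    sampling rate, plus the normalization scheme its peaks will be reported
    under."""

    strain_levels: tuple = (4.0, 8.0, 12.0, 16.0, 20.0)
    hold_duration: float = 10.0
    sampling_rate: float = 1000.0
    normalization_mode: str = "max_pre"
    reference_strain: float = 25.0

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.strain_levels)
        if len(levels) == 0:
            raise ValueError("strain_levels must be non-empty")
        if any(x < 0 for x in levels):
            raise ValueError("strain levels must be >= 0")
        if not all(b > a for a, b in zip(levels, levels[1:])):
            raise ValueError("strain levels must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be > 0")
        if self.normalization_mode not in ("max_pre", "ref_strain_pre", "pre_mean"):
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")
        object.__setattr__(self, "strain_levels", levels)


@dataclass(frozen=True)
class StretchTrace:
    """A recorded step-stretch experiment: force and commanded strain vs time."""

    trace_id: str
    fiber_id: str
    time: np.ndarray
    force: np.ndarray
    strain_command: np.ndarray
    protocol: StretchProtocol
    phase: str = "pre"

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        s = np.asarray(self.strain_command, dtype=float)
        if not (t.shape == f.shape == s.shape) or t.ndim != 1:
            raise ValueError("time, force and strain_command must be equal-length 1-D arrays")
        if not (np.diff(t) > 0).all():
            raise ValueError("time must be strictly increasing")
        if not np.isfinite(f).all():
            raise ValueError("force contains non-finite values")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "strain_command", s)
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")


def gen_stretch_trace(
    protocol: StretchProtocol,
    peak_coeff_linear: float = 2.0e-5,
    peak_coeff_quad: float = 1.0e-6,
    relax_fraction: float = 0.25,
    relax_tau: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    force_scale: float = 1.0,
    trace_id: str = "t0",
    fiber_id: str = "f0",
    phase: str = "pre",
) -> tuple[StretchTrace, dict]:
    """Simulate a step-stretch force trace.

    At each strain level ``eps`` (in %) the instantaneous peak force is
    ``force_scale * (a*eps + b*eps**2)`` with ``a = peak_coeff_linear`` (N per
    % strain) and ``b = peak_coeff_quad`` (N per %^2). During each hold the
    force relaxes single-exponentially toward ``(1 - relax_fraction)`` of the
    peak with time constant ``relax_tau`` (s); the step to the next level is
    instantaneous and falls exactly on a sample, so the first sample of each
    hold carries the full peak. Gaussian force noise of sd ``noise_sd`` (N) is
    added throughout.

    Returns the trace and the ground-truth peaks ``{strain_pct: peak_N}``.
    """
    if not 0.0 <= relax_fraction < 1.0:
        raise ValueError("relax_fraction must be in [0, 1)")
    if relax_tau <= 0:
        raise ValueError("relax_tau must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    n_per = int(round(protocol.hold_duration * protocol.sampling_rate))
    if n_per < 2:
        raise ValueError("hold_duration * sampling_rate must give >= 2 samples per level")
    dt = 1.0 / protocol.sampling_rate
    rng = np.random.default_rng(seed)

    t_parts, f_parts, s_parts = [], [], []
    truth: dict = {}
    for j, eps in enumerate(protocol.strain_levels):
        peak = force_scale * (peak_coeff_linear * eps + peak_coeff_quad * eps**2)
        truth[eps] = peak
        t_local = np.arange(n_per) * dt
        decay = (1.0 - relax_fraction) + relax_fraction * np.exp(-t_local / relax_tau)
        t_parts.append(j * protocol.hold_duration + t_local)
        f_parts.append(peak * decay)
        s_parts.append(np.full(n_per, eps))

    time = np.concatenate(t_parts)
    force = np.concatenate(f_parts) + rng.normal(0.0, noise_sd, size=time.size)
    strain = np.concatenate(s_parts)
    trace = StretchTrace(
        trace_id=trace_id,
        fiber_id=fiber_id,
        time=time,
        force=force,
        strain_command=strain,
        protocol=protocol,
        phase=phase,
    )
    return trace, truth
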