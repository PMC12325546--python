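"""Windowed linearized-Hertz analysis of AFM force-height curves.

The reduction chain is

1. :func:`find_contact_point` — baseline tilt fit, threshold crossing, and a
   Hertz-extrapolation refinement of the contact height;
2. :func:`to_indentation` — force = k * corrected deflection, indentation =
   piezo travel beyond contact minus deflection;
3. :func:`estimate_modulus` — within a force window [f_lo, f_hi] the slope S
   of F**(2/3) versus indentation is fitted by least squares and converted to

       E = (3/4) * S**(3/2) * (1 - nu**2) / sqrt(r)

   For an exact spherical Hertz contact F**(2/3) is *linear* in indentation,
   so this windowed slope returns the true modulus regardless of where the
   window sits — the property the two-window design relies on.

Aggregation helpers average ~7 indentations per measurement location and
decompose force-map variance into between-pixel and between-repeat parts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


from .contact import ProbeParams
from .simulate import ForceCurve

__all__ = [
    "BaselineFit",
    "IndentationCurve",
    "ForceWindow",
    "ModulusEstimate",
    "LocationStiffness",
    "LOW_WINDOW",
    "HIGH_WINDOW",
    "find_contact_point",
    "to_indentation",
    "estimate_modulus",
    "analyze_curve",
    "analyze_location",
    "map_repeatability",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineFit:
    """Linear baseline (deflection vs height) fitted on the pre-contact region."""

    slope: float
    intercept: float
    rms: float  # residual RMS of the baseline region, noise-floor estimate

    def correct(self, height: np.ndarray, deflection: np.ndarray) -> np.ndarray:
        return deflection - (self.slope * height + self.intercept)


@dataclass(frozen=True)
class ForceWindow:
    """Closed force interval [f_lo, f_hi] (N) over which the slope is fitted."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    def label(self) -> str:
        return f"{self.f_lo * 1e9:.2f}-{self.f_hi * 1e9:.2f}nN"


#: The two compression-force windows used throughout (0.25 nN wide).
LOW_WINDOW = ForceWindow(2.00e-9, 2.25e-9)
HIGH_WINDOW = ForceWindow(4.00e-9, 4.25e-9)


@dataclass(frozen=True)
class IndentationCurve:
    """Force-indentation data for the retained in-contact samples."""

    force: np.ndarray
    indentation: np.ndarray
    contact_point: float
    source_curve_id: str
    probe: ProbeParams
    location_id: str = "loc0"
    ramp_fraction_at_contact: float = 0.0  # where in the ramp contact sits, for QC


@dataclass(frozen=True)
class ModulusEstimate:
    """Young's modulus from one curve and one force window, with QC."""

    E: float | None
    window: ForceWindow
    slope: float | None
    delta_d: float | None
    n_points: int
    curve_id: str
    location_id: str
    qc_flags: frozenset = frozenset()

    @property
    def ok(self) -> bool:
        return self.E is not None and not self.qc_flags


@dataclass(frozen=True)
class LocationStiffness:
    location_id: str
    window: ForceWindow
    E_mean: float
    n_curves: int
    phase: str = "pre"
    condition: str = "baseline"


def smooth_deflection(curve: ForceCurve, window: int) -> ForceCurve:
    """Return a copy of ``curve`` with a centred moving-average deflection.

    Intended as preprocessing for noisy recordings: F**(2/3) is linear in
    indentation over the whole Hertz contact, so local averaging does not
    bias the windowed slope while it suppresses deflection noise by about
    sqrt(window). Edges use the partial-window average.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return curve
    kernel = np.ones(window)
    num = np.convolve(curve.deflection, kernel, mode="same")
    den = np.convolve(np.ones_like(curve.deflection), kernel, mode="same")
    return ForceCurve(
        curve_id=curve.curve_id,
        location_id=curve.location_id,
        height=curve.height,
        deflection=num / den,
        probe=curve.probe,
        segment=curve.segment,
        condition=curve.condition,
        phase=curve.phase,
    )


def _threshold_crossing(corrected: np.ndarray, thr: float, min_run: int) -> int | None:
    above = corrected > thr
    for i in np.flatnonzero(above):
        stop = min(i + min_run, len(above))
        if above[i:stop].all():
            return int(i)
    return None


def find_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    threshold_mult: float = 3.0,
    *,
    min_run: int = 5,
    rms_floor: float = 1e-12,
    refine_force_cap_frac: float = 0.25,
    max_iter: int = 8,
) -> tuple[float, BaselineFit]:
    """Locate the contact height of an approach curve.

    The baseline line is fitted to a leading region of the ramp, initially
    the first ``baseline_fraction``. Because that region may already contain
    contact, the region is halved while a quadratic term fitted to it is
    statistically significant (a straight, noisy baseline has none; a Hertz
    onset is convex). The contact candidate is then the first height at which
    the tilt-corrected deflection exceeds ``threshold_mult`` times the
    baseline residual RMS and stays above it for ``min_run`` samples.
    Finally the candidate is refined by regressing F**(2/3) on
    (height - deflection) over the early-contact region (forces up to
    ``refine_force_cap_frac`` of the curve maximum) and extrapolating to zero
    force, which is exact for a Hertz contact.

    Returns ``(contact_point, baseline_fit)``.

    Raises
    ------
    ValueError
        "no contact detected" if the deflection never rises above baseline;
        or if the baseline region holds fewer than 10 samples.
    """
    z = curve.height
    d = curve.deflection
    n_base = int(len(z) * baseline_fraction)
    if n_base < 10:
        raise ValueError(
            f"baseline region too short: {n_base} samples (need >= 10); "
            "increase baseline_fraction or curve length"
        )

    for _ in range(max_iter):
        if n_base < 10:
            n_base = 10
        zb, db = z[:n_base], d[:n_base]
        if n_base >= 12:
            c2 = np.polyfit(zb, db, 2)
            resid2 = db - np.polyval(c2, zb)
            sigma2 = max(float(np.sqrt(np.mean(resid2**2))), rms_floor)
            # se of the quadratic coefficient for an even grid of n points of
            # spacing h: ~ sigma * sqrt(720/n^5) / h^2 (classical OLS result)
            h = (zb[-1] - zb[0]) / (n_base - 1)
            se_c2 = sigma2 * math.sqrt(720.0 / n_base**5) / h**2
            if abs(c2[0]) > 4.0 * se_c2 and n_base > 10:
                n_base //= 2  # contaminated: shrink and re-test
                continue
        break
    slope, intercept = np.polyfit(z[:n_base], d[:n_base], 1)
    resid = d[:n_base] - (slope * z[:n_base] + intercept)
    rms = max(float(np.sqrt(np.mean(resid**2))), rms_floor)
    baseline = BaselineFit(float(slope), float(intercept), rms)
    corrected = baseline.correct(z, d)
    idx = _threshold_crossing(corrected, threshold_mult * rms, min_run)
    if idx is None:
        raise ValueError("no contact detected")
    z_c = float(z[idx])

    # Hertz refinement: F^(2/3) = S * ((z - d) - z_c) exactly on a spherical
    # contact, so the zero-force intercept of this line is the contact height.
    force = curve.probe.spring_constant * corrected
    f_cap = refine_force_cap_frac * float(force.max())
    sel = (np.arange(len(z)) >= idx) & (force > 0) & (force <= f_cap)
    if sel.sum() >= 5:
        x = z[sel] - corrected[sel]
        y = force[sel] ** (2.0 / 3.0)
        s, b = np.polyfit(x, y, 1)
        if s > 0:
            z_ref = -b / s
            # keep the refinement only if it stays near the threshold crossing
            span = z[-1] - z[0]
            if abs(z_ref - z_c) < 0.1 * span:
                z_c = float(z_ref)
    return z_c, baseline


def to_indentation(
    curve: ForceCurve, contact_point: float, baseline: BaselineFit
) -> IndentationCurve:
    """Convert a force-height curve to force vs indentation.

    Force is ``spring_constant * (tilt-corrected deflection)``; indentation is
    ``(height - contact_point) - corrected deflection``. Only in-contact
    samples (indentation >= 0 and positive corrected force) are retained.

    Raises
    ------
    ValueError
        If the contact point lies outside the recorded height span, or fewer
        than 10 in-contact samples remain ("insufficient contact data").
    """
    z = curve.height
    if not (z[0] <= contact_point <= z[-1]):
        raise ValueError("contact_point lies outside the curve's height span")
    corrected = baseline.correct(z, curve.deflection)
    force = curve.probe.spring_constant * corrected
    indentation = (z - contact_point) - corrected
    mask = (indentation >= 0) & (force > 0)
    if mask.sum() < 10:
        raise ValueError(f"insufficient contact data: {int(mask.sum())} in-contact samples")
    frac = (contact_point - z[0]) / (z[-1] - z[0])
    return IndentationCurve(
        force=force[mask],
        indentation=indentation[mask],
        contact_point=contact_point,
        source_curve_id=curve.curve_id,
        probe=curve.probe,
        location_id=curve.location_id,
        ramp_fraction_at_contact=float(frac),
    )


def estimate_modulus(
    ic: IndentationCurve,
    window: ForceWindow,
    probe: ProbeParams | None = None,
    min_points: int = 5,
    *,
    slope_convention: str = "pointwise_f23",
) -> ModulusEstimate:
    """Estimate the Young's modulus from the samples inside a force window.

    ``slope_convention`` selects how the linearized-Hertz slope is read:

    * ``"pointwise_f23"`` (default): least-squares slope of F**(2/3) versus
      indentation over the window samples, i.e. Delta(F**(2/3)) / Delta(d).
      Exact on a Hertz curve for any window placement.
    * ``"endpoint_ratio"``: (Delta F)**(2/3) / Delta d using the window's
      force width and indentation span. Kept for comparison only; it is
      biased for windows that do not start at zero force.

    Raises
    ------
    ValueError
        "window not reached" when the curve's peak force is below ``f_hi``.
    """
    probe = probe or ic.probe
    if ic.force.max() < window.f_hi:
        raise ValueError(
            f"window not reached: peak force {ic.force.max() * 1e9:.3g} nN "
            f"< f_hi {window.f_hi * 1e9:.3g} nN"
        )
    sel = (ic.force >= window.f_lo) & (ic.force <= window.f_hi)
    n = int(sel.sum())
    flags = set()
    if n < min_points:
        flags.add("low_point_count")
    if ic.ramp_fraction_at_contact > 0.9:
        flags.add("late_contact")
    if n < 2:
        return ModulusEstimate(
            None, window, None, None, n, ic.source_curve_id, ic.location_id, frozenset(flags)
        )

    d_win = ic.indentation[sel]
    f_win = ic.force[sel]
    delta_d = float(d_win.max() - d_win.min())
    if slope_convention == "pointwise_f23":
        S = float(np.polyfit(d_win, f_win ** (2.0 / 3.0), 1)[0])
    elif slope_convention == "endpoint_ratio":
        if delta_d <= 0:
            S = -1.0
        else:
            S = float(window.width ** (2.0 / 3.0) / delta_d)
    else:
        raise ValueError(f"unknown slope_convention {slope_convention!r}")

    if S <= 0:
        flags.add("negative_slope")
        return ModulusEstimate(
            None, window, S, delta_d, n, ic.source_curve_id, ic.location_id, frozenset(flags)
        )
    E = 0.75 * S**1.5 * (1.0 - probe.poisson_ratio**2) / math.sqrt(probe.tip_radius)
    return ModulusEstimate(
        float(E), window, S, delta_d, n, ic.source_curve_id, ic.location_id, frozenset(flags)
    )


def analyze_curve(
    curve: ForceCurve,
    windows: list[ForceWindow] = (LOW_WINDOW, HIGH_WINDOW),
    min_points: int = 5,
    smooth_window: int = 1,
    **contact_kwargs,
) -> list[ModulusEstimate]:
    """Full per-curve pipeline: optional deflection smoothing -> contact
    point -> indentation -> one estimate per requested window.

    ``smooth_window`` (samples) engages :func:`smooth_deflection` for noisy
    recordings; the default leaves the curve untouched. The contact point and
    baseline are always fitted on the *raw* curve (smoothing correlates the
    noise, which defeats the threshold-crossing logic and the baseline RMS);
    only the windowed slope is taken from the smoothed channel.
    """
    z_c, baseline = find_contact_point(curve, **contact_kwargs)
    ic = to_indentation(smooth_deflection(curve, smooth_window), z_c, baseline)
    return [estimate_modulus(ic, w, min_points=min_points) for w in windows]


def analyze_location(
    curves: list[ForceCurve],
    windows: list[ForceWindow] = (LOW_WINDOW, HIGH_WINDOW),
    min_points: int = 5,
    agg: str = "mean",
    **contact_kwargs,
) -> list[LocationStiffness]:
    """Aggregate the per-curve moduli of one measurement location.

    QC-failed curves (no contact, unreached window, flagged estimates) are
    dropped with a log message; the remaining per-curve E values are averaged
    (arithmetic mean by default, ``agg="median"`` available) per window.

    Raises
    ------
    ValueError
        "location unanalyzable" when no curve survives QC in some window.
    """
    if not curves:
        raise ValueError("no curves supplied")
    loc_ids = {c.location_id for c in curves}
    if len(loc_ids) != 1:
        raise ValueError(f"curves span multiple locations: {sorted(loc_ids)}")
    per_window: dict[ForceWindow, list[float]] = {w: [] for w in windows}
    for c in curves:
        try:
            ests = analyze_curve(c, windows, min_points=min_points, **contact_kwargs)
        except ValueError as exc:
            logger.info("curve %s dropped: %s", c.curve_id, exc)
            continue
        for est in ests:
            if est.ok:
                per_window[est.window].append(est.E)
            else:
                logger.info("curve %s window %s flagged: %s",
                            c.curve_id, est.window.label(), sorted(est.qc_flags))
    out = []
    reducer = np.mean if agg == "mean" else np.median
    for w in windows:
        vals = per_window[w]
        if not vals:
            raise ValueError(f"location unanalyzable: no QC-passing curves in {w.label()}")
        out.append(
            LocationStiffness(
                location_id=curves[0].location_id,
                window=w,
                E_mean=float(reducer(vals)),
                n_curves=len(vals),
                phase=curves[0].phase,
                condition=curves[0].condition,
            )
        )
    return out


def map_repeatability(estimates: pd.DataFrame) -> dict:
    """One-way random-effects variance decomposition of a repeated force map.

    ``estimates`` must hold one row per (pixel, repeat) with columns
    ``pixel``, ``repeat`` and ``E_Pa``. The decomposition is done on log-E
    (the stiffness field is right-skewed): method-of-moments components
    sigma2_pixel = (MSB - MSW) / r (clipped at 0) and sigma2_repeat = MSW.

    Returns a dict with the two components, the between-pixel variance
    fraction, and the grid-mean E per repeat.

    Raises
    ------
    ValueError
        If fewer than 2 pixels or repeats, or the table is incomplete (the
        missing (pixel, repeat) cells are listed).
    """
    required = {"pixel", "repeat", "E_Pa"}
    if not required.issubset(estimates.columns):
        raise ValueError(f"estimates must have columns {sorted(required)}")
    pixels = sorted(estimates["pixel"].unique())
    repeats = sorted(estimates["repeat"].unique())
    if len(pixels) < 2 or len(repeats) < 2:
        raise ValueError("need >= 2 pixels and >= 2 repeats")
    have = set(zip(estimates["pixel"], estimates["repeat"]))
    missing = [(p, r) for p in pixels for r in repeats if (p, r) not in have]
    if missing:
        raise ValueError(f"incomplete grid; missing cells: {missing}")

    df = estimates.copy()
    df["logE"] = np.log(df["E_Pa"])
    grand = df["logE"].mean()
    r = len(repeats)
    groups = df.groupby("pixel")["logE"]
    msb = r * ((groups.mean() - grand) ** 2).sum() / (len(pixels) - 1)
    msw = groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum() / (len(pixels) * (r - 1))
    s2_pixel = max(0.0, (msb - msw) / r)
    s2_repeat = float(msw)
    total = s2_pixel + s2_repeat
    frac = s2_pixel / total if total > 0 else 0.0
    repeat_means = df.groupby("repeat")["E_Pa"].mean().to_dict()
    return {
        "var_between_pixels": float(s2_pixel),
        "var_between_repeats": s2_repeat,
        "between_pixel_fraction": float(frac),
        "repeat_mean_E_Pa": repeat_means,
        "n_pixels": len(pixels),
        "n_repeats": r,
    }
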