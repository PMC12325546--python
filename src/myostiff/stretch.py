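"""Peak passive-force analysis of step-stretch traces.

A stretch protocol steps a permeabilized fiber (or cardiomyocyte) through
increasing strain levels with a hold at each; only the *peak* force of each
hold carries the elastic information analyzed here (the hold itself relaxes
viscoelastically). This module extracts those peaks from the command signal,
applies the three normalization schemes used for the different preparations,
fits the second-order polynomial force-strain summary, and computes
per-strain relative force changes between matched pre/post recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import StretchTrace
from .stats import median_ci

__all__ = [
    "PeakForceTable",
    "QuadraticFit",
    "StrainEffect",
    "extract_peaks",
    "normalize_peaks",
    "fit_quadratic",
    "relative_force_change",
]


@dataclass(frozen=True)
class PeakForceTable:
    """Per-strain peak passive forces of one recording.

    ``data`` has one row per protocol strain level with columns
    ``strain_pct``, ``peak_force_N`` and (after normalization)
    ``normalized_pct``. ``normalization`` records the applied scheme.
    """

    fiber_id: str
    phase: str
    data: pd.DataFrame
    normalization: str | None = None

    def values(self) -> pd.Series:
        """Working values: normalized if normalization was applied, else raw
        peaks (indexed by strain)."""
        col = "normalized_pct" if self.normalization else "peak_force_N"
        return self.data.set_index("strain_pct")[col]


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares second-order polynomial y = c0 + c1*eps + c2*eps**2."""

    c0: float
    c1: float
    c2: float
    rss: float

    def __call__(self, strain_pct):
        eps = np.asarray(strain_pct, dtype=float)
        return self.c0 + self.c1 * eps + self.c2 * eps**2


@dataclass(frozen=True)
class StrainEffect:
    """Median relative force reduction (%) at one strain level, with 95% CI."""

    strain: float
    median_reduction: float
    ci_low: float
    ci_high: float
    n: int
    N: int | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median_reduction <= self.ci_high:
            raise ValueError("CI must bracket the median")


def extract_peaks(
    trace: StretchTrace,
    *,
    guard_start: float = 0.0,
    guard_end: float = 0.05,
) -> PeakForceTable:
    """Extract the peak force of every strain level's hold window.

    Hold windows are the plateaus of the commanded strain signal; a guard
    band (fraction of the plateau length) is trimmed from each end before
    taking the maximum. The default trims only the tail: the force decays
    during a hold, so the informative peak sits at the hold onset and a
    start guard would bias it low; ``guard_start`` is available for traces
    whose command ramps rather than steps.

    Raises
    ------
    ValueError
        If a protocol strain level never appears in the command signal (the
        missing level is named).
    """
    if not 0 <= guard_start < 0.5 or not 0 <= guard_end < 0.5:
        raise ValueError("guard fractions must lie in [0, 0.5)")
    cmd = trace.strain_command
    # contiguous plateaus of the command signal
    change = np.flatnonzero(np.diff(cmd) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(cmd)]))
    plateaus: dict[float, list[tuple[int, int]]] = {}
    for i0, i1 in zip(starts, ends):
        plateaus.setdefault(float(cmd[i0]), []).append((int(i0), int(i1)))

    rows = []
    for eps in trace.protocol.strain_levels:
        if eps not in plateaus:
            raise ValueError(f"strain level {eps}% missing from command signal")
        peak = -np.inf
        for i0, i1 in plateaus[eps]:
            n = i1 - i0
            a = i0 + int(np.floor(guard_start * n))
            b = i1 - int(np.floor(guard_end * n))
            if b <= a:
                continue
            peak = max(peak, float(trace.force[a:b].max()))
        if not np.isfinite(peak):
            raise ValueError(f"strain level {eps}% has no samples after guard bands")
        rows.append({"strain_pct": eps, "peak_force_N": peak})
    return PeakForceTable(
        fiber_id=trace.fiber_id, phase=trace.phase, data=pd.DataFrame(rows)
    )


def normalize_peaks(
    table: PeakForceTable,
    mode: str,
    reference: PeakForceTable,
    reference_strain: float | None = None,
) -> PeakForceTable:
    """Express peaks as % of a reference quantity taken from the pre table.

    Modes:

    * ``max_pre`` — the pre-phase peak at the longest stretch (the fresh
      fiber-bundle convention);
    * ``ref_strain_pre`` — the pre-phase peak at ``reference_strain``
      (glycerinated fibers: 25% strain);
    * ``pre_mean`` — per strain level, the pre-phase peak at the *same*
      strain (the cardiomyocyte convention, where the pre value is already
      the mean of repeated stretches).

    The reference table must come from the pre phase of the same fiber/cell.
    """
    if reference.phase != "pre":
        raise ValueError("reference table must be phase='pre'")
    if reference.fiber_id != table.fiber_id:
        raise ValueError(
            f"reference fiber {reference.fiber_id!r} != table fiber {table.fiber_id!r}"
        )
    ref_vals = reference.values()
    vals = table.values()

    if mode == "max_pre":
        denom = float(ref_vals.loc[ref_vals.index.max()])
        normalized = vals / denom * 100.0
    elif mode == "ref_strain_pre":
        if reference_strain is None:
            reference_strain = table.data.attrs.get(
                "reference_strain", getattr(reference, "reference_strain", None)
            )
        if reference_strain is None:
            raise ValueError("ref_strain_pre mode needs reference_strain")
        if reference_strain not in ref_vals.index:
            raise ValueError(
                f"reference strain {reference_strain}% absent from pre table"
            )
        normalized = vals / float(ref_vals.loc[reference_strain]) * 100.0
    elif mode == "pre_mean":
        missing = [s for s in vals.index if s not in ref_vals.index]
        if missing:
            raise ValueError(f"strains {missing} absent from pre table")
        normalized = vals / ref_vals.reindex(vals.index) * 100.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")

    df = table.data.copy()
    df["normalized_pct"] = normalized.to_numpy()
    return PeakForceTable(
        fiber_id=table.fiber_id, phase=table.phase, data=df, normalization=mode
    )


def fit_quadratic(table: PeakForceTable) -> QuadraticFit:
    """Second-order polynomial fit of the table's working values vs % strain."""
    vals = table.values()
    if vals.index.nunique() < 3:
        raise ValueError("need >= 3 distinct strain levels for a quadratic fit")
    eps = vals.index.to_numpy(dtype=float)
    y = vals.to_numpy(dtype=float)
    c2, c1, c0 = np.polyfit(eps, y, 2)
    rss = float(np.sum((y - (c0 + c1 * eps + c2 * eps**2)) ** 2))
    return QuadraticFit(float(c0), float(c1), float(c2), rss)


def relative_force_change(
    pre_tables: dict[str, PeakForceTable],
    post_tables: dict[str, PeakForceTable],
    *,
    ci_level: float = 0.95,
    n_animals: int | None = None,
) -> list[StrainEffect]:
    """Per-strain median force reduction across matched fibers.

    For every fiber and strain, reduction = (1 - post/pre) * 100 on raw
    peaks (the reduction is invariant to any shared normalization scheme,
    since the reference cancels in the ratio). Reductions are summarized per
    strain level by the median and a distribution-free 95% CI.

    Raises
    ------
    ValueError
        If the pre/post fiber id sets differ (the mismatch is listed).
    """
    unmatched = set(pre_tables) ^ set(post_tables)
    if unmatched:
        raise ValueError(f"unmatched fiber ids across phases: {sorted(unmatched)}")
    if not pre_tables:
        raise ValueError("no fibers supplied")

    per_strain: dict[float, list[float]] = {}
    for fid in pre_tables:
        pre = pre_tables[fid].data.set_index("strain_pct")["peak_force_N"]
        post = post_tables[fid].data.set_index("strain_pct")["peak_force_N"]
        for eps in pre.index.intersection(post.index):
            if pre.loc[eps] <= 0:
                continue  # slack level: reduction undefined at zero pre force
            red = (1.0 - post.loc[eps] / pre.loc[eps]) * 100.0
            per_strain.setdefault(float(eps), []).append(float(red))

    effects = []
    for eps in sorted(per_strain):
        vals = per_strain[eps]
        mci = median_ci(vals, level=ci_level)
        effects.append(
            StrainEffect(
                strain=eps,
                median_reduction=mci.median,
                ci_low=mci.ci_low,
                ci_high=mci.ci_high,
                n=len(vals),
                N=n_animals,
            )
        )
    return effects
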