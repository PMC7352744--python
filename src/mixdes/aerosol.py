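"""Aerosolization and inhalation-performance metrics.

Two measurement families feed these metrics:

* laser-diffraction volume percentiles DV10/DV50/DV90 of the nebulized
  droplet cloud, summarized by the span (DV90 - DV10) / DV50;
* cascade-impactor stage depositions, from which the emitted dose (ED),
  percent dispersed (PD = 100·ED/TD), percent inhaled (PI = 100·stage
  mass/TD), mass median aerodynamic diameter (MMAD), geometric standard
  deviation (GSD) and fine particle fraction (FPF) derive.

An impactor classifies aerosol mass by aerodynamic diameter: each stage
collects particles larger than its cutoff that escaped the stage above, so the
cumulative mass below a stage's cutoff is the sum of everything collected
further downstream.  MMAD is the 50th percentile of that cumulative-undersize
curve; interpolation between stage cutoffs is linear in log10(diameter)
(standard impactor practice, consistent with a lognormal aerodynamic
distribution), with a probit-scale alternative behind a flag.  GSD is
sqrt(d(84.13%) / d(15.87%)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PercentileDiameters:
    """Volume-undersize percentile diameters (µm); dv50 is the VMD."""

    dv10: float
    dv50: float
    dv90: float

    def __post_init__(self) -> None:
        if not (0 < self.dv10 <= self.dv50 <= self.dv90):
            raise ValueError(
                f"need 0 < dv10 <= dv50 <= dv90, got ({self.dv10}, {self.dv50}, {self.dv90})"
            )


def span(p: PercentileDiameters) -> float:
    """Distribution width normalized by the median: (DV90 - DV10) / DV50."""
    if p.dv50 == 0:
        raise ZeroDivisionError("dv50 is zero")
    return (p.dv90 - p.dv10) / p.dv50


@dataclass(frozen=True)
class ImpactorStage:
    """One collection stage: particles above ``cutoff_um`` deposit here."""

    label: str
    cutoff_um: float  # lower cutoff diameter; the backup filter has cutoff 0
    mass: float


@dataclass
class ImpactorRun:
    """A cascade-impactor experiment: stage deposits plus device-part deposits.

    ``stages`` must be ordered coarse to fine with strictly decreasing
    cutoffs, ending at the backup filter (cutoff 0).  ``device_parts`` are the
    non-classifying surfaces (adapter, mouthpiece, inlet cone, induction
    port); their mass counts toward the emitted dose but not the aerodynamic
    distribution.  ``chamber_mass`` is drug left in the nebulizer medication
    chamber — loaded but never emitted, so outside the emitted dose.
    """

    stages: list[ImpactorStage]
    device_parts: list[tuple[str, float]]
    total_dose: float
    chamber_mass: float = 0.0

    def __post_init__(self) -> None:
        cuts = [s.cutoff_um for s in self.stages]
        if any(b >= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("stage cutoffs must be strictly decreasing")
        if any(s.mass < 0 for s in self.stages) or any(m < 0 for _, m in self.device_parts):
            raise ValueError("deposited masses must be non-negative")
        if self.total_dose <= 0:
            raise ValueError("total dose must be positive")
        if self.deposited_total() > self.total_dose * (1 + 1e-9):
            raise ValueError("total deposits exceed the loaded dose")

    def stage_masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.stages], dtype=float)

    def device_mass(self) -> float:
        return float(sum(m for _, m in self.device_parts))

    def deposited_total(self) -> float:
        return float(self.stage_masses().sum()) + self.device_mass() + self.chamber_mass


@dataclass(frozen=True)
class ImpactorSummary:
    ed: float
    pd_percent: float
    pi_percent: float
    mmad_um: float
    gsd: float
    fpf_percent: float

    def __post_init__(self) -> None:
        if not (0 <= self.fpf_percent <= 100):
            raise ValueError("FPF must lie in [0, 100]%")
        if self.gsd < 1:
            raise ValueError("GSD must be >= 1")


def cumulative_undersize(run: ImpactorRun) -> tuple[np.ndarray, np.ndarray]:
    """(cutoffs, cumulative % of stage mass below each cutoff), fine to coarse.

    For stage k (coarse-to-fine index), the mass below its cutoff is the sum
    of deposits on all finer stages including the filter.  The curve is
    non-decreasing in diameter and reaches 100% above the coarsest cutoff.
    """
    masses = run.stage_masses()
    total = masses.sum()
    if total <= 0:
        raise ValueError("no mass on the stages")
    cuts = np.array([s.cutoff_um for s in run.stages])
    below = np.cumsum(masses[::-1])[::-1] - masses  # mass on stages finer than stage k
    frac = 100.0 * below / total
    order = np.argsort(cuts)
    # drop the filter's zero cutoff: log-diameter interpolation starts at the
    # finest real cutoff, below which the filter mass lives
    keep = cuts[order] > 0
    return cuts[order][keep], frac[order][keep]


def _percentile_diameter(
    cuts: np.ndarray, cum: np.ndarray, pct: float, scale: str
) -> float:
    logd = np.log10(cuts)
    y = stats.norm.ppf(np.clip(cum / 100.0, 1e-9, 1 - 1e-9)) if scale == "probit" else cum
    target = stats.norm.ppf(pct / 100.0) if scale == "probit" else pct
    if target <= y[0]:
        warnings.warn(
            f"{pct}th percentile below the finest cutoff {cuts[0]} µm: reporting the boundary",
            stacklevel=3,
        )
        return float(cuts[0])
    if target >= y[-1]:
        warnings.warn(
            f"{pct}th percentile above the coarsest cutoff {cuts[-1]} µm: reporting the boundary",
            stacklevel=3,
        )
        return float(cuts[-1])
    # strictly increasing sub-grid for interpolation
    return float(10 ** np.interp(target, y, logd))


def impactor_summary(
    run: ImpactorRun,
    include_filter_in_pi: bool = True,
    fpf_start_stage: str | None = None,
    interpolation: str = "loglinear",
) -> ImpactorSummary:
    """Summarize an impactor run into ED/PD/PI/MMAD/GSD/FPF.

    * ED: everything collected from the impactor assembly (device parts plus
      all stages and the filter).
    * PD = 100·ED/TD; PI = 100·(stage 0-7 mass, filter included by default —
      set ``include_filter_in_pi=False`` for the stricter reading)/TD.
    * FPF = 100·(mass on ``fpf_start_stage`` through the filter)/ED; by
      default the stage named "stage4", else the 5th stage from the top.
    * MMAD/GSD from the cumulative-undersize curve (see module docstring);
      ``interpolation`` is "loglinear" or "probit".
    """
    if interpolation not in ("loglinear", "probit"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    masses = run.stage_masses()
    if masses.sum() <= 0:
        raise ValueError("no mass on the stages")
    ed = float(masses.sum()) + run.device_mass()
    pd_pct = 100.0 * ed / run.total_dose
    stage_mass_for_pi = masses.sum()
    if not include_filter_in_pi and run.stages[-1].cutoff_um == 0:
        stage_mass_for_pi = masses[:-1].sum()
    pi_pct = 100.0 * float(stage_mass_for_pi) / run.total_dose

    labels = [s.label.replace(" ", "").lower() for s in run.stages]
    if fpf_start_stage is not None:
        key = fpf_start_stage.replace(" ", "").lower()
        if key not in labels:
            raise KeyError(f"no stage labelled {fpf_start_stage!r}")
        start = labels.index(key)
    elif "stage4" in labels:
        start = labels.index("stage4")
    else:
        start = min(4, len(run.stages) - 1)
    fpf_pct = 100.0 * float(masses[start:].sum()) / ed

    cuts, cum = cumulative_undersize(run)
    if len(cuts) == 1 or np.count_nonzero(masses) == 1:
        # all mass within one stage window: MMAD pinned inside it, GSD -> 1
        k = int(np.argmax(masses))
        lower = run.stages[k].cutoff_um
        upper = run.stages[k - 1].cutoff_um if k > 0 else lower * 2
        mmad = math.sqrt(max(lower, 1e-12) * upper) if lower > 0 else cuts[0]
        gsd = 1.0
        warnings.warn("degenerate distribution: single loaded stage", stacklevel=2)
    else:
        mmad = _percentile_diameter(cuts, cum, 50.0, interpolation)
        d84 = _percentile_diameter(cuts, cum, 84.13, interpolation)
        d16 = _percentile_diameter(cuts, cum, 15.87, interpolation)
        gsd = math.sqrt(d84 / d16) if d16 > 0 else 1.0
        gsd = max(gsd, 1.0)
    return ImpactorSummary(
        ed=ed,
        pd_percent=pd_pct,
        pi_percent=pi_pct,
        mmad_um=float(mmad),
        gsd=float(gsd),
        fpf_percent=fpf_pct,
    )
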