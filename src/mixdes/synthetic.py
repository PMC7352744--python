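"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* responses on a mixture design drawn as a known Scheffé surface plus i.i.d.
  homoscedastic Gaussian noise — the implicit error model of the ANOVA used
  on the real data;
* cascade-impactor runs whose aerodynamic diameters follow a lognormal
  distribution (median ``median_um``, geometric SD ``gsd``), binned into
  stage windows by the cutoff table, with a configurable fraction of the
  loaded dose retained upstream of the stages.

Both are bit-reproducible for a fixed seed (numpy Generator, PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aerosol import ImpactorRun, ImpactorStage
from .design import Design
from .scheffe import ScheffeModel

#: default response noise SD, the residual scale of a well-behaved particle
#: size fit on this design family (≈ sqrt(0.47) nm)
DEFAULT_NOISE_SD = 0.7


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth + noise level + seed for response simulation."""

    truth: ScheffeModel
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_design_responses(spec: SimulationSpec, design: Design) -> np.ndarray:
    """y_i = truth(x_i) + N(0, noise_sd²), seeded and reproducible."""
    mean = spec.truth.predict_many(design.as_array("real"))
    if spec.noise_sd == 0:
        return mean
    rng = np.random.default_rng(spec.seed)
    return mean + rng.normal(0.0, spec.noise_sd, size=len(mean))


def simulate_impactor_run(
    median_um: float,
    gsd: float,
    total_dose: float,
    cutoffs: list[tuple[str, float]],
    device_fraction: float = 0.3,
    n_quanta: int = 1_000_000,
    seed: int = 0,
    part_fraction: float = 0.01,
) -> ImpactorRun:
    """Simulate stage depositions from a lognormal aerodynamic distribution.

    ``cutoffs`` lists (label, lower cutoff µm) coarse to fine, ending with the
    backup filter at cutoff 0.  ``n_quanta`` equal mass quanta are sampled
    from lognormal(median_um, gsd) and assigned to the stage whose window
    contains them; the stages share ``(1 - device_fraction)`` of the loaded
    dose.  Of the withheld fraction, ``part_fraction`` of the total dose is
    spread over the four non-stage device parts (they belong to the emitted
    dose) and the rest is recorded as nebulizer chamber retention, so the
    percent dispersed is 100·(1 - device_fraction + part_fraction) by
    construction.
    """
    if gsd < 1:
        raise ValueError("gsd must be >= 1")
    if n_quanta <= 0:
        raise ValueError("n_quanta must be positive")
    if not 0 <= part_fraction <= device_fraction <= 1:
        raise ValueError("need 0 <= part_fraction <= device_fraction <= 1")
    cuts = [c for _, c in cutoffs]
    if any(b >= a for a, b in zip(cuts, cuts[1:])):
        raise ValueError("cutoffs must be strictly decreasing")
    rng = np.random.default_rng(seed)
    if gsd == 1.0:
        diam = np.full(n_quanta, float(median_um))
    else:
        diam = rng.lognormal(mean=math.log(median_um), sigma=math.log(gsd), size=n_quanta)
    # stage k collects diameters in [cut_k, cut_{k-1}); the top stage is open above
    edges = np.array(cuts[::-1])  # ascending, filter cutoff first
    idx = np.searchsorted(edges, diam, side="right") - 1  # ascending stage index
    counts = np.bincount(idx, minlength=len(cuts))[::-1]  # back to coarse-to-fine
    stage_budget = (1.0 - device_fraction) * total_dose
    stage_masses = stage_budget * counts / n_quanta
    stages = [
        ImpactorStage(label=lab, cutoff_um=cut, mass=float(m))
        for (lab, cut), m in zip(cutoffs, stage_masses)
    ]
    part_labels = ("adapter", "mouthpiece", "inlet cone", "induction port")
    per_part = part_fraction * total_dose / len(part_labels)
    device_parts = [(lab, per_part) for lab in part_labels]
    chamber = (device_fraction - part_fraction) * total_dose
    return ImpactorRun(
        stages=stages,
        device_parts=device_parts,
        total_dose=total_dose,
        chamber_mass=chamber,
    )
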