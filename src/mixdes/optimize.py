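"""Multi-response formulation optimization and external model validation.

Optimization uses Derringer-style desirability: each response goal and each
component directive is mapped to a desirability in [0, 1] (linear between the
response's min and max over a dense region grid, or between a component's
bounds), and the weighted geometric mean of all desirabilities is maximized
over the region by grid seeding followed by a deterministic pattern-search
refinement on the simplex slice.

Validation compares measured responses of hold-out formulations against model
predictions through the signed relative residual

    RSE% = 100 * (actual - predicted) / predicted,

reported by magnitude (the convention in formulation papers); records whose
|RSE| exceed a configurable bound (default 5%) are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import Blend, MixtureRegion
from .scheffe import ScheffeModel, predict


def rse_percent(actual: float, predicted: float) -> float:
    """Signed relative residual in percent: 100*(actual - predicted)/predicted."""
    if predicted == 0:
        raise ZeroDivisionError("predicted value is zero: RSE undefined")
    return 100.0 * (actual - predicted) / predicted


@dataclass
class ValidationRecord:
    name: str
    blend: Blend
    response: str
    actual: float
    predicted: float
    rse_percent: float
    flagged: bool

    @property
    def rse_magnitude(self) -> float:
        return abs(self.rse_percent)


def validate(
    models: dict[str, ScheffeModel],
    formulations,
    rse_limit: float = 5.0,
) -> list[ValidationRecord]:
    """Validate models against measured formulations.

    ``formulations`` is a DataFrame with one column per region component plus
    one measured-response column per key of ``models`` (missing/NaN responses
    are skipped with a warning); an optional "name" column labels the rows.
    Out-of-region blends are allowed but warn (extrapolation).
    """
    records: list[ValidationRecord] = []
    some_region = next(iter(models.values())).region
    comp_cols = list(some_region.names)
    for idx, row in formulations.iterrows():
        name = str(row["name"]) if "name" in formulations.columns else f"formulation_{idx}"
        amounts = np.array([float(row[c]) for c in comp_cols])
        blend = Blend(tuple(amounts), coding="real")
        for resp, model in models.items():
            if resp not in formulations.columns or not np.isfinite(row[resp]):
                warnings.warn(f"{name}: no measured value for {resp!r}; skipped", stacklevel=2)
                continue
            pred = predict(model, amounts)
            rse = rse_percent(float(row[resp]), pred)
            records.append(
                ValidationRecord(
                    name=name,
                    blend=blend,
                    response=resp,
                    actual=float(row[resp]),
                    predicted=pred,
                    rse_percent=rse,
                    flagged=abs(rse) > rse_limit,
                )
            )
    return records


# ---------------------------------------------------------------------------
# desirability optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseGoal:
    """Directive for one modelled response: minimize, maximize or in_range."""

    directive: str  # "minimize" | "maximize" | "in_range"
    weight: float = 1.0
    low: float | None = None   # in_range window
    high: float | None = None

    def __post_init__(self) -> None:
        if self.directive not in ("minimize", "maximize", "in_range"):
            raise ValueError(f"unknown response directive {self.directive!r}")
        if self.weight <= 0:
            raise ValueError("weights must be positive")
        if self.directive == "in_range" and (self.low is None or self.high is None):
            raise ValueError("in_range goals need low and high")


@dataclass(frozen=True)
class ComponentDirective:
    """Directive for one component: minimize, maximize, hold a target, or free."""

    directive: str  # "minimize" | "maximize" | "target" | "free"
    weight: float = 1.0
    target: float | None = None

    def __post_init__(self) -> None:
        if self.directive not in ("minimize", "maximize", "target", "free"):
            raise ValueError(f"unknown component directive {self.directive!r}")
        if self.weight <= 0:
            raise ValueError("weights must be positive")
        if self.directive == "target" and self.target is None:
            raise ValueError("target directives need a target value")


@dataclass
class OptimizationGoal:
    """Bundle of response goals (keyed like the models dict) and component directives."""

    responses: dict[str, ResponseGoal]
    components: dict[str, ComponentDirective] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("at least one response goal is required")


@dataclass
class OptimizationResult:
    blend: Blend
    desirability: float
    predictions: dict[str, float]
    per_goal: dict[str, float]
    grid_desirability: float


def _response_desirability(values: np.ndarray, goal: ResponseGoal, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.ones_like(values)
    if goal.directive == "minimize":
        d = (hi - values) / span
    elif goal.directive == "maximize":
        d = (values - lo) / span
    else:  # in_range
        d = ((values >= goal.low) & (values <= goal.high)).astype(float)
    return np.clip(d, 0.0, 1.0)


def _component_desirability(x: np.ndarray, directive: ComponentDirective, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.ones_like(x)
    if directive.directive == "minimize":
        d = (hi - x) / span
    elif directive.directive == "maximize":
        d = (x - lo) / span
    else:  # target: triangular peak at the target value
        t = float(directive.target)
        d = np.where(x <= t, 1.0 - (t - x) / max(t - lo, 1e-12), 1.0 - (x - t) / max(hi - t, 1e-12))
    return np.clip(d, 0.0, 1.0)


def _region_grid(region: MixtureRegion, resolution: int) -> np.ndarray:
    import itertools

    f = region.filler_index()
    free = [i for i in range(region.n_components) if i != f]
    axes = [
        np.linspace(region.components[i].lower, region.components[i].upper, resolution)
        if region.components[i].range > 0
        else np.array([region.components[i].lower])
        for i in free
    ]
    fl, fu = region.components[f].lower, region.components[f].upper
    pts = []
    for combo in itertools.product(*axes):
        rest = region.total - sum(combo)
        if fl - 1e-9 <= rest <= fu + 1e-9:
            row = np.empty(region.n_components)
            row[free] = combo
            row[f] = rest
            pts.append(row)
    if not pts:
        raise ValueError("empty feasible set: no grid point satisfies the bounds")
    return np.array(pts)


def optimize(
    models: dict[str, ScheffeModel],
    goal: OptimizationGoal,
    resolution: int = 21,
    seed: int = 0,
) -> OptimizationResult:
    """Maximize the geometric-mean desirability over the mixture region.

    Deterministic for a given resolution (the seed only shuffles tie-breaking
    among exactly-equal grid optima, which does not arise on generic
    surfaces).  The returned desirability is never below the best grid
    point's.
    """
    del seed  # grid + pattern search are fully deterministic
    missing = set(goal.responses) - set(models)
    if missing:
        raise KeyError(f"goals name responses without models: {sorted(missing)}")
    region = next(iter(models.values())).region
    for m in models.values():
        if m.region.names != region.names:
            raise ValueError("all models must share one mixture region")

    grid = _region_grid(region, resolution)
    preds = {k: models[k].predict_many(grid) for k in goal.responses}
    # anchor response desirability scales on the grid's prediction range
    scales = {k: (float(v.min()), float(v.max())) for k, v in preds.items()}
    name_to_idx = {n: i for i, n in enumerate(region.names)}

    def desirability_components(W: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        parts: dict[str, np.ndarray] = {}
        logd = np.zeros(W.shape[0])
        wsum = 0.0
        for k, g in goal.responses.items():
            vals = models[k].predict_many(W)
            d = _response_desirability(vals, g, *scales[k])
            parts[k] = d
            logd = logd + g.weight * np.log(np.maximum(d, 1e-300))
            wsum += g.weight
        for cname, directive in goal.components.items():
            if directive.directive == "free":
                continue
            i = name_to_idx[cname]
            c = region.components[i]
            d = _component_desirability(W[:, i], directive, c.lower, c.upper)
            parts[f"component:{cname}"] = d
            logd = logd + directive.weight * np.log(np.maximum(d, 1e-300))
            wsum += directive.weight
        return np.exp(logd / wsum), parts

    D, _ = desirability_components(grid)
    best_idx = int(np.argmax(D))
    grid_best = float(D[best_idx])
    if np.allclose(D, D[0]):
        warnings.warn("flat desirability surface: returning the first grid optimum", stacklevel=2)

    # deterministic pattern search from the best grid point
    f = region.filler_index()
    free = [i for i in range(region.n_components) if i != f]
    x = grid[best_idx].copy()
    cur = grid_best
    step = max((region.components[i].range for i in free), default=0.0) / max(resolution - 1, 1) / 2
    fl, fu = region.components[f].lower, region.components[f].upper
    while step > 1e-7:
        improved = False
        for i in free:
            for delta in (step, -step):
                trial = x.copy()
                trial[i] = np.clip(
                    trial[i] + delta, region.components[i].lower, region.components[i].upper
                )
                trial[f] = region.total - np.delete(trial, f).sum()
                if not (fl - 1e-9 <= trial[f] <= fu + 1e-9):
                    continue
                val = float(desirability_components(trial[None, :])[0][0])
                if val > cur + 1e-12:
                    x, cur = trial, val
                    improved = True
        if not improved:
            step /= 2.0
    x = np.round(x, 9)
    x[f] = region.total - np.delete(x, f).sum()

    Dx, parts = desirability_components(x[None, :])
    result_preds = {k: float(models[k].predict_many(x[None, :])[0]) for k in models}
    return OptimizationResult(
        blend=Blend(tuple(x), coding="real"),
        desirability=float(Dx[0]),
        predictions=result_preds,
        per_goal={k: float(v[0]) for k, v in parts.items()},
        grid_desirability=grid_best,
    )
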