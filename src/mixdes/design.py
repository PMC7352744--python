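"""Constrained mixture design spaces and D-optimal run selection.

A mixture experiment varies the proportions of q components that must sum to a
fixed total (here 100 wt%).  When each component additionally carries lower and
upper limits L_j <= x_j <= U_j the feasible set is a convex polytope inside the
simplex.  This module provides:

* :class:`MixtureRegion` / :class:`Blend` / :class:`Design` containers,
* the L-pseudo-component transform x' = (x - L) / (total - sum(L)) that maps a
  lower-bounded region onto the unit simplex (the coding in which Scheffé
  polynomials are fit and reported),
* a candidate-point constructor (3-level grid over the freely varying
  components: bounds, midpoints, centroid),
* a seeded point-exchange search for D-optimal designs, maximizing
  det(X'X) of the Scheffé model matrix, and the D-efficiency statistic
  det(X'X / n)^(1/p).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BoundViolationError,
    DegenerateRegionError,
    InfeasibleDesignError,
    RankDeficiencyError,
)

#: tolerance for composition equality / sum checks
COMPOSITION_TOL = 1e-9


@dataclass(frozen=True)
class ComponentBound:
    """Lower/upper limit of one mixture component, in the units of the total."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper):
            raise ValueError(
                f"component {self.name!r}: need 0 <= lower <= upper, "
                f"got [{self.lower}, {self.upper}]"
            )

    @property
    def range(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class MixtureRegion:
    """A bounded mixture design space: L_j <= x_j <= U_j with sum(x) = total."""

    components: tuple[ComponentBound, ...]
    total: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 2:
            raise ValueError("a mixture needs at least two components")
        if self.lowers.sum() > self.total + COMPOSITION_TOL:
            raise DegenerateRegionError(
                f"lower bounds sum to {self.lowers.sum()} > total {self.total}: empty region"
            )
        if self.uppers.sum() < self.total - COMPOSITION_TOL:
            raise DegenerateRegionError(
                f"upper bounds sum to {self.uppers.sum()} < total {self.total}: empty region"
            )
        for c in self.components:
            if c.upper > self.total + COMPOSITION_TOL:
                raise ValueError(f"component {c.name!r}: upper bound exceeds total")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def lowers(self) -> np.ndarray:
        return np.array([c.lower for c in self.components], dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.array([c.upper for c in self.components], dtype=float)

    @property
    def pseudo_denominator(self) -> float:
        """total - sum(L): the size of the L-pseudo simplex (0 => zero volume)."""
        return self.total - float(self.lowers.sum())

    def contains(self, amounts: np.ndarray, tol: float = COMPOSITION_TOL) -> bool:
        amounts = np.asarray(amounts, dtype=float)
        return bool(
            abs(amounts.sum() - self.total) <= max(tol, 1e-7 * self.total)
            and np.all(amounts >= self.lowers - tol)
            and np.all(amounts <= self.uppers + tol)
        )

    def centroid(self) -> "Blend":
        """Overall centroid: the mean of the region's extreme vertices.

        Vertices are enumerated as bound combinations of the free components
        with the filler taken by difference (the vertex family of the region
        classes this package targets).  On an unconstrained simplex this gives
        the usual (1/q, ..., 1/q) centroid; on a full box it gives the center
        of the ranges.
        """
        import itertools as _it

        f = self.filler_index()
        free = [i for i in range(self.n_components) if i != f]
        fl, fu = self.components[f].lower, self.components[f].upper
        vertices = []
        for combo in _it.product(*[(self.components[i].lower, self.components[i].upper)
                                   for i in free]):
            rest = self.total - sum(combo)
            if fl - 1e-9 <= rest <= fu + 1e-9:
                v = np.empty(self.n_components)
                v[free] = combo
                v[f] = rest
                vertices.append(v)
        if vertices:
            amounts = np.mean(vertices, axis=0)
        else:  # no bound-combination vertex: fall back to mid-ranges
            amounts = (self.lowers + self.uppers) / 2.0
        amounts[f] = self.total - np.delete(amounts, f).sum()
        return Blend(tuple(amounts), coding="real")

    def filler_index(self) -> int:
        """Index of the slack component: the one with the widest range (last on ties)."""
        ranges = self.uppers - self.lowers
        return int(len(ranges) - 1 - np.argmax(ranges[::-1]))


@dataclass(frozen=True)
class Blend:
    """One mixture composition, either in real wt% or in pseudo coordinates."""

    amounts: tuple[float, ...]
    coding: str = "real"  # "real" | "pseudo"

    def __post_init__(self) -> None:
        object.__setattr__(self, "amounts", tuple(float(a) for a in self.amounts))
        if self.coding not in ("real", "pseudo"):
            raise ValueError(f"unknown coding {self.coding!r}")

    def as_array(self) -> np.ndarray:
        return np.array(self.amounts, dtype=float)

    def __len__(self) -> int:
        return len(self.amounts)


@dataclass
class Design:
    """An ordered set of mixture runs plus the region they live in.

    ``replicate_groups`` partitions run indices by identical composition
    (within ``COMPOSITION_TOL``); it is recomputed from the runs on creation.
    """

    runs: list[Blend]
    region: MixtureRegion
    replicate_groups: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.runs = list(self.runs)
        if not self.replicate_groups:
            self.replicate_groups = _group_replicates(self.as_array())
        # sanity: the groups must partition the run indices
        flat = sorted(i for g in self.replicate_groups for i in g)
        if flat != list(range(len(self.runs))):
            raise ValueError("replicate_groups is not a partition of run indices")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def coding(self) -> str:
        return self.runs[0].coding if self.runs else "real"

    def as_array(self, coding: str | None = None) -> np.ndarray:
        """Run compositions as an (n, q) array, optionally re-coded."""
        arr = np.array([b.amounts for b in self.runs], dtype=float)
        if coding is None or not self.runs or coding == self.coding:
            return arr
        if coding == "pseudo":
            return real_to_pseudo(arr, self.region)
        return pseudo_to_real(arr, self.region)

    def replicated_groups(self) -> list[list[int]]:
        """Only the groups with at least two runs (those carrying pure error)."""
        return [g for g in self.replicate_groups if len(g) >= 2]


def _group_replicates(arr: np.ndarray, tol: float = COMPOSITION_TOL) -> list[list[int]]:
    groups: list[list[int]] = []
    reps: list[np.ndarray] = []
    for i, row in enumerate(arr):
        for g, rep in zip(groups, reps):
            if np.max(np.abs(row - rep)) <= tol:
                g.append(i)
                break
        else:
            groups.append([i])
            reps.append(row)
    return groups


# ---------------------------------------------------------------------------
# pseudo-component coding
# ---------------------------------------------------------------------------

def real_to_pseudo(amounts: np.ndarray, region: MixtureRegion) -> np.ndarray:
    """Vectorized L-pseudo transform x' = (x - L) / (total - sum L)."""
    denom = region.pseudo_denominator
    if denom <= COMPOSITION_TOL:
        raise DegenerateRegionError(
            "lower bounds exhaust the total: the pseudo simplex has zero volume"
        )
    return (np.asarray(amounts, dtype=float) - region.lowers) / denom


def pseudo_to_real(pseudo: np.ndarray, region: MixtureRegion) -> np.ndarray:
    denom = region.pseudo_denominator
    if denom <= COMPOSITION_TOL:
        raise DegenerateRegionError(
            "lower bounds exhaust the total: the pseudo simplex has zero volume"
        )
    return np.asarray(pseudo, dtype=float) * denom + region.lowers


def to_pseudo(blend: Blend, region: MixtureRegion) -> Blend:
    """Convert a real-wt% blend to L-pseudo coordinates.

    Raises :class:`BoundViolationError` if the blend is outside the region and
    :class:`DegenerateRegionError` if the region has zero volume.
    """
    if blend.coding == "pseudo":
        return blend
    arr = blend.as_array()
    if not region.contains(arr, tol=1e-7):
        raise BoundViolationError(
            f"blend {blend.amounts} violates the bounds of region {region.names}"
        )
    return Blend(tuple(real_to_pseudo(arr, region)), coding="pseudo")


def from_pseudo(blend: Blend, region: MixtureRegion) -> Blend:
    """Inverse of :func:`to_pseudo` (exact up to floating point)."""
    if blend.coding == "real":
        return blend
    return Blend(tuple(pseudo_to_real(blend.as_array(), region)), coding="real")


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------

def build_candidate_set(region: MixtureRegion, model_order: str = "quadratic") -> list[Blend]:
    """Candidate points for D-optimal selection on a bounded mixture region.

    The free components (all but the slack/filler component, which is computed
    by difference) are enumerated on the 3-level grid {L, (L+U)/2, U}; points
    whose implied filler amount falls outside its own bounds are discarded.
    The grid contains the region's extreme vertices, edge midpoints, face
    centroids of every dimension and the overall centroid, which together
    support Scheffé models up to the special cubic.  ``model_order`` is kept in
    the signature for symmetry with the selection step; the same grid serves
    all three orders.
    """
    del model_order  # the 3-level grid supports linear through special cubic
    f = region.filler_index()
    free = [i for i in range(region.n_components) if i != f]
    levels = []
    for i in free:
        c = region.components[i]
        if c.range <= COMPOSITION_TOL:
            levels.append((c.lower,))
        else:
            levels.append((c.lower, (c.lower + c.upper) / 2.0, c.upper))
    fl, fu = region.components[f].lower, region.components[f].upper
    seen: set[tuple[float, ...]] = set()
    out: list[Blend] = []
    for combo in itertools.product(*levels):
        rest = region.total - sum(combo)
        if rest < fl - 1e-9 or rest > fu + 1e-9:
            continue
        amounts = np.empty(region.n_components)
        amounts[free] = combo
        amounts[f] = rest
        key = tuple(np.round(amounts, 9))
        if key not in seen:
            seen.add(key)
            out.append(Blend(tuple(amounts), coding="real"))
    cen = region.centroid()
    key = tuple(np.round(cen.as_array(), 9))
    if key not in seen and region.contains(cen.as_array(), tol=1e-7):
        out.append(cen)
    if not out:
        raise DegenerateRegionError("candidate construction produced no feasible point")
    return out


# ---------------------------------------------------------------------------
# D-optimality
# ---------------------------------------------------------------------------

def _model_matrix_pseudo(arr_real: np.ndarray, region: MixtureRegion, order: str) -> np.ndarray:
    # local import: scheffe depends on the containers defined above
    from .scheffe import model_matrix_from_array

    return model_matrix_from_array(real_to_pseudo(arr_real, region), order)


def d_efficiency(design: Design, model_order: str = "quadratic") -> float:
    """D-efficiency det(X'X / n)^(1/p) of a design under a Scheffé model.

    X is the model matrix in pseudo coding; p its column count.  The value is
    invariant under run reordering.  A rank-deficient design returns 0.0 with
    a warning rather than raising, so that searches can simply avoid it.
    """
    X = _model_matrix_pseudo(design.as_array("real"), design.region, model_order)
    n, p = X.shape
    sign, logdet = np.linalg.slogdet(X.T @ X / n)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("rank-deficient design: D-efficiency reported as 0", stacklevel=2)
        return 0.0
    return float(np.exp(logdet / p))


def _logdet(X: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -np.inf


def d_optimal_select(
    candidates: list[Blend],
    model_order: str,
    n_total: int,
    n_replicates: int = 0,
    seed: int = 0,
    region: MixtureRegion | None = None,
    n_restarts: int = 10,
    replicate_point: Blend | None = None,
) -> Design:
    """Select an n_total-run D-optimal design from a candidate list.

    A point-exchange (Fedorov-style) search: starting from a random full-rank
    subset, repeatedly replace the design point whose swap with an unused
    candidate most increases det(X'X), until no swap improves it.  The search
    restarts ``n_restarts`` times from seeded random subsets and keeps the best
    final determinant (ties broken toward the earlier restart).  Replicate
    slots are filled with ``replicate_point`` (default: the region's overall
    centroid, the point of maximum prediction-variance interest) and are held
    fixed; the objective is evaluated on the full matrix including them.

    Deterministic for a given seed.  The per-iteration objective never
    decreases (asserted internally).
    """
    if region is None:
        raise ValueError("region is required (candidates are plain blends)")
    if n_replicates < 0 or n_total <= 0:
        raise ValueError("n_total and n_replicates must be non-negative")
    n_free = n_total - n_replicates
    cand_arr = np.array([b.amounts for b in candidates], dtype=float)
    from .scheffe import scheffe_terms

    p = len(scheffe_terms(region.n_components, model_order))
    if n_total < p:
        raise InfeasibleDesignError(
            f"n_total={n_total} is below the {p} terms of the {model_order} model"
        )
    if n_free > len(candidates):
        raise InfeasibleDesignError(
            f"need {n_free} distinct points but only {len(candidates)} candidates"
        )
    if replicate_point is None:
        replicate_point = region.centroid()
    rep_arr = np.tile(replicate_point.as_array(), (n_replicates, 1))
    Xc = _model_matrix_pseudo(cand_arr, region, model_order)
    Xr = _model_matrix_pseudo(rep_arr, region, model_order) if n_replicates else np.empty((0, p))

    def objective(idx: list[int]) -> float:
        return _logdet(np.vstack([Xc[idx], Xr]))

    if n_free == len(candidates):
        chosen = list(range(len(candidates)))
        best = (objective(chosen), chosen)
    else:
        rng = np.random.default_rng(seed)
        best: tuple[float, list[int]] | None = None
        for _ in range(n_restarts):
            # full-rank seeded start (a handful of attempts is plenty on these grids)
            idx = None
            for _attempt in range(50):
                trial = sorted(rng.choice(len(candidates), size=n_free, replace=False).tolist())
                if np.isfinite(objective(trial)):
                    idx = trial
                    break
            if idx is None:
                continue
            obj = objective(idx)
            improved = True
            while improved:
                improved = False
                best_swap: tuple[float, int, int] | None = None
                in_design = set(idx)
                for pos in range(n_free):
                    for j in range(len(candidates)):
                        if j in in_design:
                            continue
                        trial = list(idx)
                        trial[pos] = j
                        val = objective(trial)
                        if val > obj + 1e-12 and (best_swap is None or val > best_swap[0] + 1e-12):
                            best_swap = (val, pos, j)
                if best_swap is not None:
                    val, pos, j = best_swap
                    assert val >= obj  # exchange objective is monotone non-decreasing
                    idx[pos] = j
                    obj = val
                    improved = True
            idx = sorted(idx)
            if best is None or obj > best[0] + 1e-12:
                best = (obj, idx)
        if best is None or not np.isfinite(best[0]):
            raise RankDeficiencyError(
                "no full-rank design found: candidates do not span the model space"
            )
    runs = [candidates[i] for i in best[1]] + [replicate_point] * n_replicates
    return Design(runs=runs, region=region)
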