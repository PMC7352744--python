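"""Scheffé canonical polynomial models for mixture responses.

Because mixture proportions sum to a constant, the usual intercept/main-effect
parameterization is aliased; Scheffé's canonical forms drop the intercept:

* linear:         y = sum_i b_i x_i
* quadratic:      + sum_{i<j} b_ij x_i x_j
* special cubic:  + sum_{i<j<k} b_ijk x_i x_j x_k

Fits are performed in L-pseudo-component coding (see :mod:`mixdes.design`),
which is the coding in which coefficients are reported.  The least-squares
solve uses an orthogonal-decomposition routine rather than the normal
equations; the normal-equation solve is kept only as a test oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .design import Blend, Design, MixtureRegion, real_to_pseudo
from .errors import InfeasibleDesignError, RankDeficiencyError

ORDERS = ("linear", "quadratic", "special_cubic")

Term = tuple[int, ...]


def scheffe_terms(q: int, order: str) -> list[Term]:
    """Canonical term list: singles by index, then pairs, then triples (lexicographic)."""
    if order not in ORDERS:
        raise ValueError(f"unknown model order {order!r}; expected one of {ORDERS}")
    terms: list[Term] = [(i,) for i in range(q)]
    if order in ("quadratic", "special_cubic"):
        terms += [t for t in itertools.combinations(range(q), 2)]
    if order == "special_cubic":
        terms += [t for t in itertools.combinations(range(q), 3)]
    return terms


def term_label(term: Term, names: tuple[str, ...] | None = None) -> str:
    """Human-readable term label; single letters A, B, ... when no names given."""
    if names is None:
        return "".join(chr(ord("A") + i) for i in term)
    return "*".join(names[i] for i in term)


def model_matrix_from_array(pseudo: np.ndarray, order: str) -> np.ndarray:
    """Model matrix for pseudo-coded compositions: one column per Scheffé term."""
    pseudo = np.atleast_2d(np.asarray(pseudo, dtype=float))
    q = pseudo.shape[1]
    cols = [np.prod(pseudo[:, list(t)], axis=1) for t in scheffe_terms(q, order)]
    return np.column_stack(cols)


def model_matrix(design: Design, order: str) -> np.ndarray:
    """Model matrix of a design in pseudo coding (converted if stored as real)."""
    return model_matrix_from_array(design.as_array("pseudo"), order)


@dataclass(frozen=True)
class ScheffeModel:
    """A fitted or literature-specified Scheffé polynomial.

    ``coefficients`` maps canonical terms (tuples of 0-based component
    indices) to coefficients in response units; ``coding`` records the
    composition coding the coefficients refer to (always "pseudo" for models
    produced by :func:`fit`).
    """

    order: str
    coefficients: dict[Term, float]
    region: MixtureRegion
    coding: str = "pseudo"
    response_name: str = ""

    def __post_init__(self) -> None:
        expected = scheffe_terms(self.region.n_components, self.order)
        got = sorted(self.coefficients)
        if got != sorted(expected):
            raise ValueError(
                f"coefficient terms do not match a {self.order} model in "
                f"{self.region.n_components} components"
            )

    @property
    def terms(self) -> list[Term]:
        return scheffe_terms(self.region.n_components, self.order)

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.terms], dtype=float)

    def predict(self, blend: Blend | np.ndarray) -> float:
        return predict(self, blend)

    def predict_many(self, amounts_real: np.ndarray) -> np.ndarray:
        """Vectorized prediction on an (n, q) array of real-wt% compositions."""
        pseudo = (
            real_to_pseudo(amounts_real, self.region)
            if self.coding == "pseudo"
            else np.asarray(amounts_real, float) / self.region.total
        )
        return model_matrix_from_array(pseudo, self.order) @ self.coef_vector


@dataclass
class FitResult:
    """Least-squares fit of a Scheffé model with its decomposition of variance.

    ``ss_total_corrected`` is the mean-corrected total sum of squares: even
    though the model has no intercept, the mixture constraint makes the
    columns of the linear block sum to one, so the constant is in the column
    space and the mean-response null model is the correct baseline for R².
    """

    model: ScheffeModel
    design: Design
    responses: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    ss_total_corrected: float
    ss_model: float
    ss_residual: float
    dof_residual: int

    @property
    def n(self) -> int:
        return len(self.responses)

    @property
    def p(self) -> int:
        return len(self.model.terms)

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.dof_residual if self.dof_residual > 0 else float("nan")


def fit(design: Design, responses: np.ndarray, order: str, response_name: str = "") -> FitResult:
    """Fit a Scheffé polynomial of the given order by no-intercept least squares."""
    y = np.asarray(responses, dtype=float)
    X = model_matrix(design, order)
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"{len(y)} responses for {n} runs")
    if n < p:
        raise InfeasibleDesignError(
            f"{order} model has {p} terms but the design has only {n} runs"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear terms: those whose removal restores full column rank
        terms = scheffe_terms(design.region.n_components, order)
        bad = [
            term_label(terms[j])
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise RankDeficiencyError(
            f"model matrix rank {rank} < {p} terms; collinear terms: {', '.join(bad)}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    residuals = y - fitted
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    terms = scheffe_terms(design.region.n_components, order)
    model = ScheffeModel(
        order=order,
        coefficients={t: float(c) for t, c in zip(terms, coef)},
        region=design.region,
        coding="pseudo",
        response_name=response_name,
    )
    return FitResult(
        model=model,
        design=design,
        responses=y,
        fitted=fitted,
        residuals=residuals,
        ss_total_corrected=ss_tot,
        ss_model=ss_tot - ss_res,
        ss_residual=ss_res,
        dof_residual=n - p,
    )


def predict(model: ScheffeModel, blend: Blend | np.ndarray) -> float:
    """Evaluate a model at one blend (real wt% unless the blend says otherwise).

    Out-of-region blends trigger an extrapolation warning, not an error: the
    polynomial is defined everywhere, the data just never visited there.
    """
    if isinstance(blend, Blend):
        arr = blend.as_array()
        is_pseudo = blend.coding == "pseudo"
    else:
        arr = np.asarray(blend, dtype=float)
        is_pseudo = False
    if not is_pseudo and not model.region.contains(arr, tol=1e-7):
        warnings.warn(
            f"blend {tuple(arr)} is outside the model region: extrapolating",
            stacklevel=2,
        )
    if model.coding == "pseudo" and not is_pseudo:
        arr = real_to_pseudo(arr, model.region)
    elif model.coding == "real" and is_pseudo:
        from .design import pseudo_to_real

        arr = pseudo_to_real(arr, model.region) / model.region.total
    elif model.coding == "real":
        arr = arr / model.region.total
    row = model_matrix_from_array(arr, model.order)[0]
    return float(row @ model.coef_vector)


def to_real_coding(model: ScheffeModel) -> ScheffeModel:
    """Re-express a pseudo-coded model in real proportions (x / total).

    Provided for completeness; prediction is invariant because the two codings
    are related by an invertible affine map of the simplex.  The conversion is
    done numerically by refitting the model's own predictions on a candidate
    grid in real coding (exact for polynomials of matching order).
    """
    if model.coding == "real":
        return model
    from .design import build_candidate_set

    cands = build_candidate_set(model.region, model.order)
    arr = np.array([b.amounts for b in cands])
    y = model.predict_many(arr)
    Xr = model_matrix_from_array(arr / model.region.total, model.order)
    coef, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    terms = model.terms
    return ScheffeModel(
        order=model.order,
        coefficients={t: float(c) for t, c in zip(terms, coef)},
        region=model.region,
        coding="real",
        response_name=model.response_name,
    )


def surface_grid(
    model: ScheffeModel,
    free_components: tuple[int, ...],
    resolution: int = 21,
    fixed: dict[int, float] | None = None,
):
    """Lattice of predictions over 2-3 free components, for surface/contour plots.

    The free components sweep their bounds on a ``resolution``-point lattice;
    components listed in ``fixed`` are held at the stated wt%; the remaining
    (slack) component absorbs the difference.  Lattice points that leave the
    region are excluded (and counted in the returned frame's attrs).
    """
    import pandas as pd

    region = model.region
    q = region.n_components
    free = tuple(free_components)
    if not 2 <= len(free) <= 3:
        raise ValueError("free_components must name 2 or 3 components")
    fixed = dict(fixed or {})
    others = [i for i in range(q) if i not in free and i not in fixed]
    if not others:
        raise ValueError("no slack component left to absorb the mixture constraint")
    slack = others[-1]
    for i in others[:-1]:
        fixed[i] = float(region.centroid().amounts[i])
    axes = []
    for i in free:
        c = region.components[i]
        if c.range <= 0:
            raise ValueError(f"free component {c.name!r} has collapsed bounds")
        axes.append(np.linspace(c.lower, c.upper, resolution))
    rows = []
    n_clipped = 0
    for combo in itertools.product(*axes):
        amounts = np.empty(q)
        for i, v in zip(free, combo):
            amounts[i] = v
        for i, v in fixed.items():
            amounts[i] = v
        amounts[slack] = region.total - amounts[list(free) + list(fixed)].sum()
        if not region.contains(amounts, tol=1e-7):
            n_clipped += 1
            continue
        rows.append(list(amounts) + [predict(model, amounts)])
    frame = pd.DataFrame(rows, columns=list(region.names) + ["prediction"])
    frame.attrs["n_clipped"] = n_clipped
    return frame
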