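"""ANOVA and fit diagnostics for Scheffé mixture models.

Implements the Design-Expert-style decomposition used to judge mixture model
fits: overall model F-test, per-interaction-term partial F-tests, the
lack-of-fit / pure-error split of the residual (available when the design
carries replicate runs), R², adjusted R², and the "adequate precision"
signal-to-noise statistic.  Single-component terms receive no individual
F-test: under the mixture constraint they are not separately testable in the
Scheffé parameterization, so the per-term rows cover only the interaction
(pair/triple) terms, as practitioners report them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import Design
from .scheffe import FitResult, fit as scheffe_fit, scheffe_terms, term_label, model_matrix

ADEQUATE_PRECISION_THRESHOLD = 4.0


@dataclass
class AnovaRow:
    label: str
    dof: int
    ss: float
    ms: float | None = None
    f_value: float | None = None
    p_value: float | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]
    r2: float
    adj_r2: float
    adequate_precision: float
    response_name: str = ""
    order: str = ""
    warnings: list[str] = field(default_factory=list)

    def row(self, label: str) -> AnovaRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "source": r.label,
                    "df": r.dof,
                    "ss": r.ss,
                    "ms": r.ms,
                    "F": r.f_value,
                    "p": r.p_value,
                }
                for r in self.rows
            ]
        )


def r_squared(fitres: FitResult) -> float:
    """R² = 1 - SS_residual / SS_total(corrected)."""
    if fitres.ss_total_corrected <= 0:
        raise ValueError("constant responses: R² undefined")
    return 1.0 - fitres.ss_residual / fitres.ss_total_corrected


def adj_r_squared(fitres: FitResult) -> float:
    r2 = r_squared(fitres)
    n, p = fitres.n, fitres.p
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def adequate_precision(fitres: FitResult) -> float:
    """Signal-to-noise ratio: fitted-value range over average prediction SE.

    Computed as (max ŷ - min ŷ) / sqrt(p · MS_residual / n) over the design
    runs; values above 4 indicate the model discriminates adequately across
    the design space.  A zero residual MS (perfect interpolation) returns inf
    with a warning.
    """
    if fitres.dof_residual <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = fitres.ms_residual
    rng = float(fitres.fitted.max() - fitres.fitted.min())
    # numerical zero: a residual MS below float precision of the response scale
    if ms_res <= 1e-16 * max(rng * rng, 1.0):
        warnings.warn("zero residual mean square: adequate precision is infinite", stacklevel=2)
        return math.inf
    return rng / math.sqrt(fitres.p * ms_res / fitres.n)


def _pure_error(design: Design, y: np.ndarray) -> tuple[float, int]:
    ss = 0.0
    dof = 0
    for g in design.replicated_groups():
        grp = y[g]
        ss += float(((grp - grp.mean()) ** 2).sum())
        dof += len(g) - 1
    return ss, dof


def anova(fitres: FitResult, design: Design | None = None) -> AnovaTable:
    """Mixture-model ANOVA table.

    Rows: Model (df p-1 under the mixture constraint), one per interaction
    term (partial extra SS from deleting that term and refitting — a
    Type-III-like test), Residual, and, when the design has replicate runs,
    Lack of fit and Pure error.  F ratios use MS_residual (model and term
    rows) and MS_pure_error (lack-of-fit row); p-values come from the upper
    tail of the F distribution.
    """
    design = design or fitres.design
    y = fitres.responses
    n, p = fitres.n, fitres.p
    if fitres.dof_residual <= 0:
        raise ValueError("saturated model: no residual degrees of freedom for ANOVA")
    notes: list[str] = []

    dof_model = p - 1
    ms_model = fitres.ss_model / dof_model
    ms_res = fitres.ms_residual
    f_model = ms_model / ms_res
    rows = [
        AnovaRow(
            "Model",
            dof_model,
            fitres.ss_model,
            ms_model,
            f_model,
            float(stats.f.sf(f_model, dof_model, fitres.dof_residual)),
        )
    ]

    # partial SS for each interaction term: delete the single column, refit
    order = fitres.model.order
    terms = scheffe_terms(design.region.n_components, order)
    X = model_matrix(design, order)
    for j, t in enumerate(terms):
        if len(t) == 1:
            continue
        Xr = np.delete(X, j, axis=1)
        coef, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        ss_res_reduced = float(((y - Xr @ coef) ** 2).sum())
        ss_term = max(ss_res_reduced - fitres.ss_residual, 0.0)
        f_term = ss_term / ms_res
        rows.append(
            AnovaRow(
                term_label(t),
                1,
                ss_term,
                ss_term,
                f_term,
                float(stats.f.sf(f_term, 1, fitres.dof_residual)),
            )
        )

    rows.append(AnovaRow("Residual", fitres.dof_residual, fitres.ss_residual, ms_res))

    ss_pe, dof_pe = _pure_error(design, y)
    if dof_pe > 0 and fitres.dof_residual > dof_pe:
        ss_lof = max(fitres.ss_residual - ss_pe, 0.0)
        dof_lof = fitres.dof_residual - dof_pe
        ms_lof = ss_lof / dof_lof
        ms_pe = ss_pe / dof_pe
        if ms_pe > 0:
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, dof_lof, dof_pe))
        else:
            f_lof, p_lof = math.inf, 0.0
            notes.append("zero pure-error mean square: lack-of-fit F is infinite")
        rows.append(AnovaRow("Lack of fit", dof_lof, ss_lof, ms_lof, f_lof, p_lof))
        rows.append(AnovaRow("Pure error", dof_pe, ss_pe, ms_pe))
    else:
        notes.append("no replicate runs: lack-of-fit split omitted")
        warnings.warn(notes[-1], stacklevel=2)

    return AnovaTable(
        rows=rows,
        r2=r_squared(fitres),
        adj_r2=adj_r_squared(fitres),
        adequate_precision=adequate_precision(fitres),
        response_name=fitres.model.response_name,
        order=order,
        warnings=notes,
    )


def select_model(design: Design, responses: np.ndarray, alpha: float = 0.05):
    """Choose among linear/quadratic/special-cubic fits.

    Fits every estimable order (n > p) and selects the highest order that
    earns its extra terms: the base (lowest) order must have model p < alpha,
    and each higher order must pass the sequential F-test of its added term
    block (extra-SS / extra-df over the residual MS of the richer model) at
    alpha, keep a non-significant lack of fit (p > alpha when testable), and
    improve the adjusted R².  The overall model F of a richer model inherits
    the lower-order signal, so the block test — not the overall test — is
    what justifies an upgrade.  If no order reaches significance the linear
    fit is returned with a warning — the data then simply do not resolve
    composition effects.

    Returns ``(chosen_order, {order: (FitResult, AnovaTable)})``.
    """
    y = np.asarray(responses, dtype=float)
    n = design.n_runs
    candidates: dict[str, tuple[FitResult, AnovaTable]] = {}
    for order in ("linear", "quadratic", "special_cubic"):
        p = len(scheffe_terms(design.region.n_components, order))
        if n <= p:  # need residual df for any testing
            continue
        try:
            fr = scheffe_fit(design, y, order)
            candidates[order] = (fr, anova(fr, design))
        except Exception as exc:  # rank deficiency on exotic regions
            warnings.warn(f"{order} fit skipped: {exc}", stacklevel=2)
    if not candidates:
        raise ValueError("no model order is estimable for this design")

    chosen = None
    prev: tuple[FitResult, AnovaTable] | None = None
    for order in ("linear", "quadratic", "special_cubic"):
        if order not in candidates:
            continue
        fr, table = candidates[order]
        try:
            lof_p = table.row("Lack of fit").p_value
        except KeyError:
            lof_p = None
        lof_ok = lof_p is None or lof_p > alpha
        if prev is None:
            significant = table.row("Model").p_value < alpha
        else:
            prev_fr, prev_table = prev
            extra_df = fr.p - prev_fr.p
            block_f = (prev_fr.ss_residual - fr.ss_residual) / extra_df / fr.ms_residual
            block_p = float(stats.f.sf(block_f, extra_df, fr.dof_residual))
            significant = block_p < alpha and table.adj_r2 > prev_table.adj_r2
        if significant and lof_ok:
            chosen = order
        elif prev is not None:
            break  # higher orders build on a block that did not earn its terms
        prev = (fr, table)
    if chosen is None:
        warnings.warn("no model order is significant: returning linear", stacklevel=2)
        chosen = "linear" if "linear" in candidates else next(iter(candidates))
    return chosen, candidates


def predicted_vs_actual(fitres: FitResult):
    """Paired (actual, fitted) table plus the slope of fitted on actual.

    The slope is the ordinary regression slope of the fitted values on the
    observed responses (intercept included).  For a least-squares fit it
    equals R², so it is ~1 for a tight fit and visibly below 1 when the model
    explains little of the response variance.  (The reverse regression —
    actual on fitted — is identically 1 for any least-squares fit and carries
    no diagnostic information.)
    """
    import pandas as pd

    frame = pd.DataFrame({"actual": fitres.responses, "predicted": fitres.fitted})
    x = fitres.responses
    if float(np.ptp(x)) == 0.0:
        slope = float("nan")
    else:
        slope = float(np.polyfit(x, fitres.fitted, 1)[0])
    frame.attrs["slope"] = slope
    return frame, slope
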