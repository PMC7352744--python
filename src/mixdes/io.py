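"""File I/O and report formatting.

Interchange formats: CSV for regions and designs (no domain standard exists
for DOE tables), JSON for models and reports, YAML for optimization goals.
Design round-trips are lossless at 12 significant digits and replicate groups
are re-detected on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import Blend, ComponentBound, Design, MixtureRegion
from .diagnostics import AnovaTable
from .errors import SchemaError
from .optimize import ComponentDirective, OptimizationGoal, ResponseGoal, ValidationRecord
from .scheffe import ScheffeModel, scheffe_terms, term_label


def read_region_csv(path: str | Path, total: float = 100.0) -> MixtureRegion:
    """Region file: CSV with columns name, lower, upper (wt%)."""
    frame = pd.read_csv(path)
    missing = {"name", "lower", "upper"} - set(frame.columns)
    if missing:
        raise SchemaError(f"region file lacks columns: {sorted(missing)}")
    comps = tuple(
        ComponentBound(str(r["name"]), float(r["lower"]), float(r["upper"]))
        for _, r in frame.iterrows()
    )
    return MixtureRegion(components=comps, total=total)


def write_region_csv(region: MixtureRegion, path: str | Path) -> None:
    pd.DataFrame(
        {"name": region.names, "lower": region.lowers, "upper": region.uppers}
    ).to_csv(path, index=False)


def read_design_csv(path: str | Path, region: MixtureRegion) -> Design:
    """Design file: one row per run, one wt% column per component.

    Extra columns (run ids, responses) are ignored here; non-numeric cells in
    component columns raise a :class:`SchemaError` naming the cell.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise SchemaError(f"{path}: no runs")
    missing = set(region.names) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: design lacks component columns {sorted(missing)}")
    runs = []
    for i, row in frame.iterrows():
        amounts = []
        for c in region.names:
            try:
                amounts.append(float(row[c]))
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}: non-numeric cell at row {i}, column {c!r}") from exc
        runs.append(Blend(tuple(amounts), coding="real"))
    return Design(runs=runs, region=region)


def write_design_csv(design: Design, path: str | Path) -> None:
    arr = design.as_array("real")
    frame = pd.DataFrame(arr, columns=list(design.region.names))
    frame.insert(0, "run", np.arange(1, len(frame) + 1))
    frame.to_csv(path, index=False, float_format="%.12g")


def read_responses_csv(path: str | Path, column: str) -> np.ndarray:
    frame = pd.read_csv(path)
    if column not in frame.columns:
        raise SchemaError(f"{path}: no response column {column!r}")
    return frame[column].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def model_to_dict(model: ScheffeModel) -> dict:
    return {
        "order": model.order,
        "coding": model.coding,
        "response_name": model.response_name,
        "region": {
            "total": model.region.total,
            "components": [
                {"name": c.name, "lower": c.lower, "upper": c.upper}
                for c in model.region.components
            ],
        },
        "coefficients": {
            term_label(t): model.coefficients[t] for t in model.terms
        },
    }


def model_from_dict(payload: dict) -> ScheffeModel:
    reg = MixtureRegion(
        components=tuple(
            ComponentBound(c["name"], float(c["lower"]), float(c["upper"]))
            for c in payload["region"]["components"]
        ),
        total=float(payload["region"]["total"]),
    )
    terms = scheffe_terms(reg.n_components, payload["order"])
    labels = {term_label(t): t for t in terms}
    coefs = {}
    for label, value in payload["coefficients"].items():
        if label not in labels:
            raise SchemaError(f"unknown model term {label!r}")
        coefs[labels[label]] = float(value)
    return ScheffeModel(
        order=payload["order"],
        coefficients=coefs,
        region=reg,
        coding=payload.get("coding", "pseudo"),
        response_name=payload.get("response_name", ""),
    )


def write_model_json(model: ScheffeModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=True) + "\n")


def read_model_json(path: str | Path) -> ScheffeModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# goal YAML
# ---------------------------------------------------------------------------

def goal_from_dict(payload: dict) -> OptimizationGoal:
    responses = {
        name: ResponseGoal(
            directive=spec.get("goal", "minimize"),
            weight=float(spec.get("weight", 1.0)),
            low=spec.get("low"),
            high=spec.get("high"),
        )
        for name, spec in (payload.get("responses") or {}).items()
    }
    components = {
        name: ComponentDirective(
            directive=spec.get("goal", "free"),
            weight=float(spec.get("weight", 1.0)),
            target=spec.get("value"),
        )
        for name, spec in (payload.get("components") or {}).items()
    }
    return OptimizationGoal(responses=responses, components=components)


def read_goal_yaml(path: str | Path) -> OptimizationGoal:
    return goal_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def anova_report_dict(table: AnovaTable) -> dict:
    return {
        "response": table.response_name,
        "order": table.order,
        "rows": [
            {
                "source": r.label,
                "df": r.dof,
                "ss": r.ss,
                "ms": r.ms,
                "f_value": r.f_value,
                "p_value": r.p_value,
            }
            for r in table.rows
        ],
        "r_squared": table.r2,
        "adj_r_squared": table.adj_r2,
        "adequate_precision": table.adequate_precision,
        "warnings": list(table.warnings),
    }


def format_anova_text(table: AnovaTable) -> str:
    """Fixed-width text rendering at the precision formulation papers print."""
    lines = [
        f"ANOVA ({table.order} model{', ' + table.response_name if table.response_name else ''})",
        f"{'Source':<14}{'df':>4}{'SS':>12}{'MS':>12}{'F':>10}{'p':>10}",
    ]
    for r in table.rows:
        ms = f"{r.ms:.2f}" if r.ms is not None else "-"
        fv = f"{r.f_value:.2f}" if r.f_value is not None else "-"
        if r.p_value is None:
            pv = "-"
        elif r.p_value < 1e-4:
            pv = "<0.0001"
        else:
            pv = f"{r.p_value:.4f}"
        lines.append(f"{r.label:<14}{r.dof:>4}{r.ss:>12.2f}{ms:>12}{fv:>10}{pv:>10}")
    lines.append(
        f"R² = {table.r2:.4f}   adj R² = {table.adj_r2:.4f}   "
        f"adequate precision = {table.adequate_precision:.2f}"
    )
    return "\n".join(lines)


def validation_report_frame(records: list[ValidationRecord]) -> pd.DataFrame:
    """Validation records as a table; RSE shown by magnitude at 2 dp."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "response": r.response,
                "actual": r.actual,
                "predicted": round(r.predicted, 2),
                "rse_percent": round(abs(r.rse_percent), 2),
                "flagged": r.flagged,
            }
            for r in records
        ]
    )
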