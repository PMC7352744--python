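"""Embedded study tables for the docetaxel/curcumin nanoemulsion case.

The published study optimized aerosolized nanoemulsions of two anticancer
drugs (docetaxel, DTX; curcumin, CCM) over five mixture components:

    A  PKOE + safflower seed oil (1:1)
    B  lecithin
    C  Tween 85 + Span 85 (9:1)
    D  glycerol
    E  water

This module ships, digit for digit, the printed inputs that every analysis in
the package can be checked against: the component bounds, the 24-run
D-optimal design with its four responses, the published regression equations
(pseudo-component coding), the external-validation formulations, the
laser-diffraction percentiles, and the impactor stage-cutoff table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aerosol import PercentileDiameters
from .design import Blend, ComponentBound, Design, MixtureRegion
from .optimize import ComponentDirective, OptimizationGoal, ResponseGoal
from .scheffe import ScheffeModel, scheffe_terms

COMPONENT_NAMES = ("oil", "lecithin", "surfactant", "glycerol", "water")
COMPONENT_LETTERS = ("A", "B", "C", "D", "E")

RESPONSE_COLUMNS = ("ps_dtx", "ps_ccm", "vmd_dtx", "vmd_ccm")

_BOUNDS = ((4.0, 6.0), (2.0, 3.0), (1.0, 2.0), (1.5, 3.0), (86.0, 91.5))

# 24 runs: A B C D E | PS_DTX PS_CCM VMD_DTX VMD_CCM
_TABLE1 = np.array([
    [4.00, 2.00, 1.00, 1.50, 91.50, 114.41, 118.38, 5.19, 5.28],
    [4.00, 3.00, 1.00, 3.00, 89.00, 113.12, 113.80, 5.33, 5.22],
    [4.00, 3.00, 2.00, 3.00, 88.00, 101.88,  98.49, 5.13, 5.26],
    [5.00, 2.50, 1.50, 2.25, 88.75, 102.93, 106.76, 5.43, 5.31],
    [6.00, 2.00, 1.00, 3.00, 88.00, 103.16, 119.92, 5.24, 5.21],
    [6.00, 2.00, 1.50, 1.50, 89.00, 106.14, 103.90, 5.31, 5.45],
    [6.00, 2.50, 2.00, 1.50, 88.00,  96.92,  94.55, 5.34, 5.15],
    [4.00, 2.00, 2.00, 1.50, 90.50, 103.11, 109.21, 5.15, 5.11],
    [6.00, 3.00, 1.00, 1.50, 88.50, 104.55, 120.01, 5.47, 5.15],
    [6.00, 3.00, 1.50, 3.00, 86.50, 105.32, 105.42, 5.41, 5.32],
    [5.00, 3.00, 2.00, 1.50, 88.50,  94.59,  97.26, 5.32, 5.50],
    [6.00, 3.00, 2.00, 2.25, 86.75,  96.48,  97.19, 5.27, 5.10],
    [6.00, 2.00, 2.00, 3.00, 87.00,  99.31, 102.72, 5.22, 5.17],
    [4.00, 2.00, 1.50, 3.00, 89.50, 108.50, 113.11, 5.11, 5.37],
    [4.00, 3.00, 1.50, 1.50, 90.00, 109.07, 113.07, 5.29, 5.24],
    [5.00, 2.00, 1.00, 1.50, 90.50, 108.71, 112.76, 5.27, 5.20],
    [5.00, 3.00, 1.00, 3.00, 88.00, 107.16, 113.31, 5.55, 5.10],
    [5.00, 2.00, 2.00, 3.00, 88.00, 100.11, 102.43, 5.12, 5.31],
    [5.00, 3.00, 1.00, 1.50, 89.50, 106.08, 118.04, 5.34, 5.25],
    [5.00, 2.00, 2.00, 1.50, 89.50, 100.77,  98.72, 5.14, 5.23],
    [5.00, 2.50, 1.50, 2.25, 88.75, 102.89, 107.57, 5.22, 5.28],
    [5.00, 2.50, 1.50, 2.25, 88.75, 103.88, 106.32, 5.27, 5.11],
    [5.00, 2.50, 1.50, 2.25, 88.75, 103.76, 106.28, 5.29, 5.36],
    [4.00, 3.00, 2.00, 3.00, 88.00, 102.52,  97.51, 5.30, 5.39],
])

# published regression coefficients, pseudo-component coding
# quadratic: A B C D E AB AC AD AE BC BD BE CD CE DE
_EQ_PS_DTX = (128.29, 208.83, -219.77, 133.96, 114.30, -191.85, 350.39, -96.55,
              -54.91, 115.41, -79.11, -126.94, 349.42, 336.19, -49.55)
_EQ_PS_CCM = (168.39, 244.63, 149.55, 28.09, 118.53, -184.49, -327.76, 90.15,
              -99.98, -438.80, -168.24, -129.62, 29.91, -102.07, 123.59)
# linear: A B C D E
_EQ_VMD_DTX = (5.55, 5.99, 4.60, 5.17, 5.21)
_EQ_VMD_CCM = (5.48, 6.06, 5.29, 4.91, 5.10)

# validation formulations: name, A..E, actual PS (nm), actual VMD (µm)
_TABLE3_DTX = (
    ("DNE_1",   (5.50, 2.60, 1.60, 2.20, 88.10), 103.5, 5.45),
    ("DNE_2",   (4.50, 2.40, 1.40, 2.30, 89.40), 107.3, 5.39),
    ("DNE_3",   (5.20, 2.25, 1.60, 2.20, 88.75), 102.4, 5.41),
    ("DNE_opt", (6.00, 2.50, 2.00, 2.50, 87.00),  95.8, 5.48),
)
_TABLE3_CCM = (
    ("CNE_1",   (5.20, 2.70, 1.70, 2.00, 88.40), 103.1, 5.44),
    ("CNE_2",   (4.80, 2.70, 1.30, 2.10, 89.10), 113.2, 5.34),
    ("CNE_3",   (4.50, 2.30, 1.60, 2.40, 89.20), 108.8, 5.25),
    ("CNE_opt", (6.00, 2.50, 2.00, 2.50, 87.00),  96.9, 5.40),
)

# Table 3 printed predictions (from the published equations, 1 dp / 2 dp)
TABLE3_PRINTED_PREDICTIONS = {
    "DNE_opt": {"ps": 97.2, "vmd": 5.28},
    "CNE_opt": {"ps": 98.4, "vmd": 5.32},
}

# laser-diffraction percentiles (µm) of the optimized formulations
_TABLE5_PERCENTILES = {
    "dne": (2.50, 5.48, 11.48),
    "cne": (2.38, 5.40, 11.53),
}

# impactor summary values as printed, for context in reports
TABLE5_IMPACTION = {
    "dne": {"pd": 70.82, "pi": 70.13, "mmad": 3.19, "gsd": 1.71, "fpf": 76.85},
    "cne": {"pd": 73.89, "pi": 72.67, "mmad": 3.08, "gsd": 1.67, "fpf": 83.30},
}

#: the composition selected as the optimum for both drug loads (wt%)
OPTIMIZED_COMPOSITION = (6.00, 2.50, 2.00, 2.50, 87.00)

#: Andersen cascade-impactor lower cutoffs (µm), coarse to fine.  The study
#: prints the stage 3-6 windows (4.70-3.3, 3.3-2.10, 2.10-1.10, 1.10-0.65 µm
#: at 15 L/min); the remaining stages default to the classic Andersen table
#: and are meant to be overridden when a calibrated table is available.
DEFAULT_ACI_CUTOFFS: tuple[tuple[str, float], ...] = (
    ("stage0", 9.0),
    ("stage1", 5.8),
    ("stage2", 4.7),
    ("stage3", 3.3),
    ("stage4", 2.1),
    ("stage5", 1.1),
    ("stage6", 0.65),
    ("stage7", 0.43),
    ("filter", 0.0),
)


def region() -> MixtureRegion:
    """The bounded five-component design space (total 100 wt%)."""
    return MixtureRegion(
        components=tuple(
            ComponentBound(name, lo, hi) for name, (lo, hi) in zip(COMPONENT_NAMES, _BOUNDS)
        ),
        total=100.0,
    )


def design() -> Design:
    """The 24-run D-optimal design (four centroid replicates: runs 4/21/22/23)."""
    reg = region()
    runs = [Blend(tuple(row[:5]), coding="real") for row in _TABLE1]
    return Design(runs=runs, region=reg)


def responses() -> pd.DataFrame:
    """The four measured response columns of the 24-run design."""
    return pd.DataFrame(_TABLE1[:, 5:], columns=list(RESPONSE_COLUMNS))


def design_frame() -> pd.DataFrame:
    """Design and responses as one table (CSV-ready)."""
    comp = pd.DataFrame(_TABLE1[:, :5], columns=list(COMPONENT_NAMES))
    return pd.concat([comp, responses()], axis=1)


def published_model(response: str) -> ScheffeModel:
    """The printed regression equation for one response, as a ScheffeModel.

    ``response`` is one of "ps_dtx", "ps_ccm", "vmd_dtx", "vmd_ccm".
    """
    coefs = {
        "ps_dtx": (_EQ_PS_DTX, "quadratic"),
        "ps_ccm": (_EQ_PS_CCM, "quadratic"),
        "vmd_dtx": (_EQ_VMD_DTX, "linear"),
        "vmd_ccm": (_EQ_VMD_CCM, "linear"),
    }
    if response not in coefs:
        raise KeyError(f"unknown response {response!r}")
    values, order = coefs[response]
    terms = scheffe_terms(5, order)
    return ScheffeModel(
        order=order,
        coefficients=dict(zip(terms, map(float, values))),
        region=region(),
        coding="pseudo",
        response_name=response,
    )


def validation_table(drug: str) -> pd.DataFrame:
    """External-validation formulations with measured responses.

    ``drug`` is "dtx" or "ccm"; response columns are named ``ps_<drug>`` and
    ``vmd_<drug>`` so the frame plugs directly into :func:`mixdes.validate`.
    """
    rows = {"dtx": _TABLE3_DTX, "ccm": _TABLE3_CCM}[drug]
    return pd.DataFrame(
        [
            {"name": name, **dict(zip(COMPONENT_NAMES, comp)),
             f"ps_{drug}": ps, f"vmd_{drug}": vmd}
            for name, comp, ps, vmd in rows
        ]
    )


def percentiles(formulation: str) -> PercentileDiameters:
    """Laser-diffraction DV10/DV50/DV90 of "dne" or "cne" (µm)."""
    return PercentileDiameters(*_TABLE5_PERCENTILES[formulation])


def paper_goal() -> OptimizationGoal:
    """The desirability configuration that reproduces the reported optimum.

    The study's verbal criterion ("smallest response at minimal component
    amounts") does not pin a unique optimum, so this goal encodes the
    formulators' choices explicitly: both responses of both drug loads
    minimized, oil maximized with triple weight (drug payload dominates the
    size penalty of added oil), and the emulsifier (lecithin) and humectant
    (glycerol) held at their selected 2.5 wt% levels by target directives.
    The surfactant and water levels then follow from the
    response goals.  Other defensible configurations yield different optima;
    see the methods note.
    """
    return OptimizationGoal(
        responses={
            "ps_dtx": ResponseGoal("minimize"),
            "ps_ccm": ResponseGoal("minimize"),
            "vmd_dtx": ResponseGoal("minimize"),
            "vmd_ccm": ResponseGoal("minimize"),
        },
        components={
            "oil": ComponentDirective("maximize", weight=3.0),
            "lecithin": ComponentDirective("target", target=2.5),
            "glycerol": ComponentDirective("target", target=2.5),
        },
    )
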