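"""Closed-form brain-disposition quantities and logBB regression models.

logBB is the log10 brain:blood concentration ratio at steady state;
logPS derives from in-situ brain perfusion through the Renkin–Crone
relation. Four published multiple-linear-regression models predicting
logBB from 2D descriptors are implemented with their central coefficients
(standard-error terms are not propagated — the models are applied as point
predictors):

``kansy_eq4``    logBB = -0.021·PSA - 0.003·MolVol + 1.643
``clark_eq5``    logBB = -0.0148·PSA + 0.152·ClogP + 0.139
``vilar_eq6``    logBB = 0.5159·ClogP - 0.0277·TPSA - 0.3462
``vilar_eq7``    logBB = 0.2289·ClogP - 0.0326·TPSA
                          - 0.5671·(a_acid + a_base) + 2.3420

The two Vilar models carry classification semantics: a positive output of
model 6 predicts logBB ≥ 0.3 (CNS+), a positive output of model 7 predicts
logBB ≥ −1. The Kansy and Clark regressions return a value only.

The CNS access score is the composite log(PS·f_u,brain) + logBB with
penetrance bands at −3.50 and −3.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import ConfigurationError, DomainError, ScoringError
from .profiles import DescriptorProfile
from .rules import Classification

__all__ = [
    "BrainDisposition",
    "PerfusionExperiment",
    "LogBBPrediction",
    "CnsAccessInputs",
    "CnsAccessResult",
    "PenetranceCategory",
    "logbb_from_concentrations",
    "ps_renkin_crone",
    "kin_from_perfusion",
    "predict_logbb",
    "classify_logbb",
    "cns_access",
    "LOGBB_MODELS",
]


@dataclass(frozen=True)
class BrainDisposition:
    """Steady-state brain and blood concentrations (same units)."""

    c_brain: float
    c_blood: float


@dataclass(frozen=True)
class PerfusionExperiment:
    """In-situ brain perfusion quantities.

    ``flow`` (F) and ``kin``/``ps`` in mL/min/g brain; ``q_br`` is the
    vascular-corrected brain amount, ``c_pf`` the perfusion-fluid
    concentration and ``t_perfusion`` the perfusion time in minutes.
    """

    flow: Optional[float] = None
    kin: Optional[float] = None
    ps: Optional[float] = None
    q_br: Optional[float] = None
    c_pf: Optional[float] = None
    t_perfusion: Optional[float] = None


def logbb_from_concentrations(d: BrainDisposition) -> float:
    """logBB = log10(C_brain / C_blood); concentrations must be positive."""
    if d.c_brain <= 0 or d.c_blood <= 0:
        raise DomainError(
            f"concentrations must be positive, got {d.c_brain}, {d.c_blood}"
        )
    return math.log10(d.c_brain / d.c_blood)


def ps_renkin_crone(e: PerfusionExperiment) -> float:
    """Renkin–Crone permeability–surface-area product: PS = −F·ln(1 − Kin/F).

    Valid for 0 ≤ Kin < F; PS → 0 as Kin → 0 and diverges as uptake
    approaches flow limitation.
    """
    if e.flow is None or e.kin is None:
        raise DomainError("need flow and kin")
    if e.flow <= 0:
        raise DomainError(f"flow must be positive, got {e.flow}")
    if not 0 <= e.kin < e.flow:
        raise DomainError(f"need 0 <= kin < flow, got kin={e.kin}, flow={e.flow}")
    return -e.flow * math.log1p(-e.kin / e.flow)


def kin_from_perfusion(e: PerfusionExperiment) -> float:
    """Unidirectional transfer constant: Kin = (Q_br / C_pf) / T."""
    if e.q_br is None or e.c_pf is None or e.t_perfusion is None:
        raise DomainError("need q_br, c_pf and t_perfusion")
    if e.c_pf <= 0 or e.t_perfusion <= 0:
        raise DomainError("c_pf and t_perfusion must be positive")
    return (e.q_br / e.c_pf) / e.t_perfusion


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogBBPrediction:
    model_id: str
    value: float
    classification: Classification


#: model_id -> (descriptor requirements, coefficient mapping, intercept)
LOGBB_MODELS = {
    "kansy_eq4": ({"psa": -0.021, "molvol": -0.003}, 1.643),
    "clark_eq5": ({"psa": -0.0148, "clogp": 0.152}, 0.139),
    "vilar_eq6": ({"clogp": 0.5159, "tpsa": -0.0277}, -0.3462),
    "vilar_eq7": (
        {"clogp": 0.2289, "tpsa": -0.0326, "n_acid_base": -0.5671},
        2.3420,
    ),
}


def predict_logbb(model_id: str, profile: DescriptorProfile) -> LogBBPrediction:
    """Apply one of the linear logBB models to a descriptor profile.

    ``vilar_eq6`` output > 0 is read as logBB ≥ 0.3 (CNS+); ``vilar_eq7``
    output > 0 as logBB ≥ −1 (CNS+); both strict at zero. The Kansy and
    Clark models return ``Classification.NOT_APPLICABLE`` — their output is
    a logBB estimate to be thresholded explicitly via
    :func:`classify_logbb`.
    """
    try:
        coeffs, intercept = LOGBB_MODELS[model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown logBB model {model_id!r}; "
            f"available: {sorted(LOGBB_MODELS)}"
        ) from None
    value = intercept
    for descriptor, coef in coeffs.items():
        x = profile.get(descriptor)
        if x is None:
            raise ScoringError(
                f"model {model_id!r} requires descriptor {descriptor!r}"
            )
        value += coef * float(x)
    if model_id in ("vilar_eq6", "vilar_eq7"):
        classification = (
            Classification.CNS_PLUS if value > 0 else Classification.CNS_MINUS
        )
    else:
        classification = Classification.NOT_APPLICABLE
    return LogBBPrediction(model_id, value, classification)


def classify_logbb(logbb: float, threshold: float = 0.0) -> Classification:
    """CNS+ iff logBB > threshold; a tie at the threshold classifies CNS−."""
    if not math.isfinite(logbb):
        raise DomainError(f"logbb must be finite, got {logbb}")
    return Classification.CNS_PLUS if logbb > threshold else Classification.CNS_MINUS


# ---------------------------------------------------------------------------
# CNS access score
# ---------------------------------------------------------------------------

class PenetranceCategory(str, Enum):
    NON_PENETRANT = "non_penetrant"
    WEAK_PENETRANT = "weak_penetrant"
    PENETRANT = "penetrant"


@dataclass(frozen=True)
class CnsAccessInputs:
    """Composite-score inputs: log(PS·f_u,brain) and a predicted logBB."""

    log_ps_fu_brain: float
    logbb: float


@dataclass(frozen=True)
class CnsAccessResult:
    score: float
    category: PenetranceCategory
    classification: Classification


#: band edges: score < -3.50 non-penetrant; -3.50 to -3.0 weak; > -3.0 penetrant
NON_PENETRANT_BELOW = -3.50
PENETRANT_ABOVE = -3.0


def cns_access(inputs: CnsAccessInputs) -> CnsAccessResult:
    """CNS access score = log(PS·f_u,brain) + logBB, with penetrance bands.

    Ternary: score < −3.50 non-penetrant (the boundary itself falls in this
    band — both comparators are strict as printed), −3.50 < score ≤ −3.0
    weak penetrant, score > −3.0 penetrant. Binary: weak penetrants count
    as penetrant, so CNS+ iff score > −3.50.
    """
    score = inputs.log_ps_fu_brain + inputs.logbb
    if not math.isfinite(score):
        raise DomainError("CNS access inputs must be finite")
    if score > PENETRANT_ABOVE:
        category = PenetranceCategory.PENETRANT
    elif score > NON_PENETRANT_BELOW:
        category = PenetranceCategory.WEAK_PENETRANT
    else:
        category = PenetranceCategory.NON_PENETRANT
    classification = (
        Classification.CNS_PLUS
        if score > NON_PENETRANT_BELOW
        else Classification.CNS_MINUS
    )
    return CnsAccessResult(score, category, classification)
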