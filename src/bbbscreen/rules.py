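"""Rule-of-thumb CNS permeability classifiers.

Each rule is a conjunction of per-descriptor threshold criteria over a
:class:`~bbbscreen.profiles.DescriptorProfile`. A compound is classified
CNS+ only when every evaluable criterion passes; if a required descriptor
is missing the verdict is withheld (indeterminate) and the gap is listed in
``missing_inputs``.

Built-in rules (registry ids):

``lipinski_cns``
    CNS adaptation of the rule of five: MW ≤ 400, ClogP ≤ 5, HBA ≤ 7,
    HBD ≤ 3.
``waterbeemd``
    MW ≤ 450, PSA < 90 Å², logD7.4 in 1–4.
``kelder``
    PSA ≤ 70 Å² (cutoff configurable down to 60, the narrowed range's
    other endpoint).
``hitchcock``
    ClogP 2–5, ClogD7.4 2–5, MW < 500, PSA < 90, HBD < 3.
``manallack_pka``
    Acidic pKa ≥ 6 when an acidic center exists; basic pKa ≤ 10.5 when a
    basic center exists. A missing center passes vacuously.
``ghose``
    2D guideline subset: TPSA < 76 Å², ≥ 1 nitrogen atom, < 3 polar
    hydrogens, and (when available) < 7 linear chains outside rings.
``norinder_rule1``
    N+O ≤ 5.
``norinder_rule2``
    ClogP − (N+O) > 0 predicts a positive logBB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, List, Optional

from .errors import ConfigurationError
from .profiles import DescriptorProfile

__all__ = [
    "Classification",
    "Criterion",
    "RuleVerdict",
    "evaluate_rule",
    "norinder_rule1",
    "norinder_rule2",
    "available_rules",
]


class Classification(str, Enum):
    CNS_PLUS = "CNS+"
    CNS_MINUS = "CNS-"
    NOT_APPLICABLE = "n/a"


@dataclass(frozen=True)
class Criterion:
    """One threshold check inside a rule."""

    name: str
    observed: Optional[float]
    bound: str
    passed: Optional[bool]  # None when the descriptor was unavailable


@dataclass(frozen=True)
class RuleVerdict:
    rule_id: str
    classification: Optional[Classification]
    criteria: List[Criterion]
    missing_inputs: List[str] = field(default_factory=list)

    @property
    def indeterminate(self) -> bool:
        return self.classification is None


# ---------------------------------------------------------------------------
# criterion helpers
# ---------------------------------------------------------------------------

def _check(
    name: str,
    value: Optional[float],
    bound: str,
    predicate: Callable[[float], bool],
    *,
    optional: bool = False,
    vacuous: bool = False,
) -> Criterion:
    """Evaluate one criterion.

    ``optional`` criteria are skipped (pass=True, not counted missing) when
    the descriptor is absent; ``vacuous`` criteria pass when the underlying
    center does not exist (Manallack semantics). Otherwise a missing value
    yields ``passed=None``.
    """
    if value is None:
        if optional or vacuous:
            return Criterion(name, None, bound, True)
        return Criterion(name, None, bound, None)
    return Criterion(name, float(value), bound, bool(predicate(float(value))))


def _verdict(rule_id: str, criteria: List[Criterion]) -> RuleVerdict:
    missing = [c.name for c in criteria if c.passed is None]
    if missing:
        classification = None
    elif all(c.passed for c in criteria):
        classification = Classification.CNS_PLUS
    else:
        classification = Classification.CNS_MINUS
    return RuleVerdict(rule_id, classification, criteria, missing)


# ---------------------------------------------------------------------------
# rule definitions
# ---------------------------------------------------------------------------

def _lipinski_cns(p: DescriptorProfile) -> List[Criterion]:
    return [
        _check("mw", p.mw, "MW <= 400", lambda v: v <= 400),
        _check("clogp", p.clogp, "ClogP <= 5", lambda v: v <= 5),
        _check("hba", p.hba, "HBA <= 7", lambda v: v <= 7),
        _check("hbd", p.hbd, "HBD <= 3", lambda v: v <= 3),
    ]


def _waterbeemd(p: DescriptorProfile) -> List[Criterion]:
    return [
        _check("mw", p.mw, "MW <= 450", lambda v: v <= 450),
        _check("psa", p.psa, "PSA < 90", lambda v: v < 90),
        _check("clogd74", p.clogd74, "1 <= logD7.4 <= 4", lambda v: 1 <= v <= 4),
    ]


def _kelder(p: DescriptorProfile, psa_cutoff: float = 70.0) -> List[Criterion]:
    return [
        _check("psa", p.psa, f"PSA <= {psa_cutoff:g}", lambda v: v <= psa_cutoff),
    ]


def _hitchcock(p: DescriptorProfile) -> List[Criterion]:
    return [
        _check("clogp", p.clogp, "2 <= ClogP <= 5", lambda v: 2 <= v <= 5),
        _check("clogd74", p.clogd74, "2 <= ClogD7.4 <= 5", lambda v: 2 <= v <= 5),
        _check("mw", p.mw, "MW < 500", lambda v: v < 500),
        _check("psa", p.psa, "PSA < 90", lambda v: v < 90),
        _check("hbd", p.hbd, "HBD < 3", lambda v: v < 3),
    ]


def _manallack(p: DescriptorProfile) -> List[Criterion]:
    return [
        _check(
            "pka_acidic", p.pka_acidic, "acidic pKa >= 6 (if acidic center)",
            lambda v: v >= 6, vacuous=True,
        ),
        _check(
            "pka_basic", p.pka_basic, "basic pKa <= 10.5 (if basic center)",
            lambda v: v <= 10.5, vacuous=True,
        ),
    ]


def _ghose(p: DescriptorProfile) -> List[Criterion]:
    return [
        _check("tpsa", p.tpsa, "TPSA < 76", lambda v: v < 76),
        _check("nitrogen_count", p.nitrogen_count, "N atoms >= 1", lambda v: v >= 1),
        _check("polar_h", p.polar_h, "polar H < 3", lambda v: v < 3),
        _check(
            "chains_outside_rings", p.chains_outside_rings,
            "linear chains outside rings < 7", lambda v: v < 7, optional=True,
        ),
    ]


def _norinder1(p: DescriptorProfile) -> List[Criterion]:
    return [_check("n_plus_o", p.n_plus_o, "N+O <= 5", lambda v: v <= 5)]


def _norinder2(p: DescriptorProfile) -> List[Criterion]:
    if p.clogp is None or p.n_plus_o is None:
        return [Criterion("clogp_minus_n_plus_o", None, "ClogP - (N+O) > 0", None)]
    d = p.clogp - p.n_plus_o
    return [Criterion("clogp_minus_n_plus_o", d, "ClogP - (N+O) > 0", d > 0)]


_RULES: dict = {
    "lipinski_cns": _lipinski_cns,
    "waterbeemd": _waterbeemd,
    "kelder": _kelder,
    "hitchcock": _hitchcock,
    "manallack_pka": _manallack,
    "ghose": _ghose,
    "norinder_rule1": _norinder1,
    "norinder_rule2": _norinder2,
}


def available_rules() -> List[str]:
    return sorted(_RULES)


def evaluate_rule(
    rule: str, profile: DescriptorProfile, **params
) -> RuleVerdict:
    """Evaluate a named rule of thumb against a descriptor profile.

    Extra keyword parameters are forwarded to rules that accept them
    (currently only ``kelder(psa_cutoff=...)``).
    """
    try:
        fn = _RULES[rule]
    except KeyError:
        raise ConfigurationError(
            f"unknown rule {rule!r}; available: {available_rules()}"
        ) from None
    criteria = fn(profile, **params) if params else fn(profile)
    return _verdict(rule, criteria)


def norinder_rule1(profile: DescriptorProfile) -> RuleVerdict:
    """First Norinder–Haeberlein rule: N+O ≤ 5 favors brain permeation."""
    return evaluate_rule("norinder_rule1", profile)


def norinder_rule2(profile: DescriptorProfile) -> RuleVerdict:
    """Second rule: positive ClogP − (N+O) predicts a positive logBB.

    The verdict's single criterion records the difference itself; zero is
    not positive, so a tie classifies CNS−.
    """
    return evaluate_rule("norinder_rule2", profile)
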