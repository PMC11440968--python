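"""Multiparameter-optimization (MPO) desirability scoring.

An MPO score maps each descriptor through a piecewise-linear desirability
function onto [0, 1] and sums the components into a composite in
[0, n_components]. Two six-component models are built in:

``cns_mpo``
    The CNS drug model (MW, ClogP, ClogD7.4, TPSA, HBD, most-basic pKa);
    a total > 4 classifies CNS+.
``cns_pet_mpo``
    The PET-tracer recalibration of the same six descriptors with tighter
    ranges; a total > 3 classifies CNS+.

Desirable/undesirable ranges per descriptor:

===========  ======================  =========================
descriptor   cns_mpo                 cns_pet_mpo
===========  ======================  =========================
MW           <=360 / >500            <=305.3 / >350.5
ClogP        <=3 / >5                <=2.8 / >4.0
ClogD7.4     <=2 / >4                <=1.7 / >2.8
TPSA (hump)  (20,40,90,120)          (32.3, 44.8, 63.3, 86.2)
HBD          <=0.5 / >3.5            <=1 / >2
pKa (basic)  <=8 / >10               <=7.2 / >9.5
===========  ======================  =========================

A separately configured five-descriptor "BBB score" (aromatic rings, heavy
atoms, MWHBN, TPSA, pKa combined through stepwise/polynomial piecewise
functions) is supported via :func:`score_bbb`; its coefficients are always
supplied by the caller's config, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .errors import ConfigurationError, ScoringError
from .profiles import DescriptorProfile
from .rules import Classification

__all__ = [
    "DesirabilityFunction",
    "MpoModel",
    "MpoScore",
    "transform_monotonic_decreasing",
    "transform_hump",
    "score_mpo",
    "get_model",
    "available_models",
    "model_from_dict",
    "model_from_yaml",
    "score_bbb",
    "BbbScore",
    "example_bbb_config",
    "CNS_MPO",
    "CNS_PET_MPO",
]


@dataclass(frozen=True)
class DesirabilityFunction:
    """Piecewise-linear map from a descriptor value to [0, 1].

    ``monotonic_decreasing`` scores 1 up to ``desirable_max``, ramps
    linearly to 0 at ``undesirable_min`` and stays 0 above it. ``hump``
    scores 1 inside the central window, 0 outside the outer window, with
    linear ramps in between.
    """

    kind: str
    desirable_max: Optional[float] = None
    undesirable_min: Optional[float] = None
    undesirable_lo: Optional[float] = None
    desirable_lo: Optional[float] = None
    desirable_hi: Optional[float] = None
    undesirable_hi: Optional[float] = None

    def __post_init__(self):
        if self.kind == "monotonic_decreasing":
            if self.desirable_max is None or self.undesirable_min is None:
                raise ConfigurationError(
                    "monotonic_decreasing needs desirable_max and undesirable_min"
                )
            if not self.desirable_max < self.undesirable_min:
                raise ConfigurationError(
                    f"need desirable_max < undesirable_min, got "
                    f"{self.desirable_max} >= {self.undesirable_min}"
                )
        elif self.kind == "hump":
            bounds = (
                self.undesirable_lo,
                self.desirable_lo,
                self.desirable_hi,
                self.undesirable_hi,
            )
            if any(b is None for b in bounds):
                raise ConfigurationError("hump needs all four bounds")
            if not (bounds[0] < bounds[1] < bounds[2] < bounds[3]):
                raise ConfigurationError(
                    f"hump bounds must be strictly increasing, got {bounds}"
                )
        else:
            raise ConfigurationError(f"unknown transform kind {self.kind!r}")

    def __call__(self, value: float) -> float:
        if self.kind == "monotonic_decreasing":
            return transform_monotonic_decreasing(value, self)
        return transform_hump(value, self)


def monotonic_decreasing(desirable_max: float, undesirable_min: float) -> DesirabilityFunction:
    return DesirabilityFunction(
        "monotonic_decreasing",
        desirable_max=desirable_max,
        undesirable_min=undesirable_min,
    )


def hump(ulo: float, dlo: float, dhi: float, uhi: float) -> DesirabilityFunction:
    return DesirabilityFunction(
        "hump",
        undesirable_lo=ulo,
        desirable_lo=dlo,
        desirable_hi=dhi,
        undesirable_hi=uhi,
    )


def transform_monotonic_decreasing(value: float, fn: DesirabilityFunction) -> float:
    """Score 1 for value ≤ desirable_max, 0 above undesirable_min, linear between."""
    if fn.kind != "monotonic_decreasing":
        raise ConfigurationError(f"expected monotonic_decreasing, got {fn.kind}")
    if value <= fn.desirable_max:
        return 1.0
    if value > fn.undesirable_min:
        return 0.0
    return (fn.undesirable_min - value) / (fn.undesirable_min - fn.desirable_max)


def transform_hump(value: float, fn: DesirabilityFunction) -> float:
    """Score 1 inside the central window, 0 outside the outer one, ramps between."""
    if fn.kind != "hump":
        raise ConfigurationError(f"expected hump, got {fn.kind}")
    if value <= fn.undesirable_lo or value > fn.undesirable_hi:
        return 0.0
    if fn.desirable_lo < value <= fn.desirable_hi:
        return 1.0
    if value <= fn.desirable_lo:
        return (value - fn.undesirable_lo) / (fn.desirable_lo - fn.undesirable_lo)
    return (fn.undesirable_hi - value) / (fn.undesirable_hi - fn.desirable_hi)


@dataclass(frozen=True)
class MpoModel:
    """An ordered set of (descriptor, desirability function) components."""

    name: str
    components: Tuple[Tuple[str, DesirabilityFunction], ...]
    cns_plus_threshold: float

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ConfigurationError("model needs at least one component")
        if not 0 < self.cns_plus_threshold < self.max_score:
            raise ConfigurationError(
                f"threshold {self.cns_plus_threshold} outside (0, {self.max_score})"
            )

    @property
    def max_score(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class MpoScore:
    total: float
    components: Dict[str, float]
    classification: Classification
    flags: Tuple[str, ...] = ()


CNS_MPO = MpoModel(
    name="cns_mpo",
    components=(
        ("mw", monotonic_decreasing(360.0, 500.0)),
        ("clogp", monotonic_decreasing(3.0, 5.0)),
        ("clogd74", monotonic_decreasing(2.0, 4.0)),
        ("tpsa", hump(20.0, 40.0, 90.0, 120.0)),
        ("hbd", monotonic_decreasing(0.5, 3.5)),
        ("pka_basic", monotonic_decreasing(8.0, 10.0)),
    ),
    cns_plus_threshold=4.0,
)

CNS_PET_MPO = MpoModel(
    name="cns_pet_mpo",
    components=(
        ("mw", monotonic_decreasing(305.3, 350.5)),
        ("clogp", monotonic_decreasing(2.8, 4.0)),
        ("clogd74", monotonic_decreasing(1.7, 2.8)),
        ("tpsa", hump(32.3, 44.8, 63.3, 86.2)),
        ("hbd", monotonic_decreasing(1.0, 2.0)),
        ("pka_basic", monotonic_decreasing(7.2, 9.5)),
    ),
    cns_plus_threshold=3.0,
)

_MODELS: Dict[str, MpoModel] = {m.name: m for m in (CNS_MPO, CNS_PET_MPO)}


def available_models() -> List[str]:
    return sorted(_MODELS)


def get_model(name: str) -> MpoModel:
    try:
        return _MODELS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown MPO model {name!r}; available: {available_models()}"
        ) from None


def model_from_dict(spec: dict) -> MpoModel:
    """Build a custom :class:`MpoModel` from a plain mapping.

    Schema::

        name: my_model
        cns_plus_threshold: 4
        components:
          - {descriptor: mw, kind: monotonic_decreasing,
             desirable_max: 360, undesirable_min: 500}
          - {descriptor: tpsa, kind: hump,
             undesirable_lo: 20, desirable_lo: 40,
             desirable_hi: 90, undesirable_hi: 120}
    """
    try:
        comps = []
        for c in spec["components"]:
            c = dict(c)
            descriptor = c.pop("descriptor")
            comps.append((descriptor, DesirabilityFunction(**c)))
        return MpoModel(
            name=spec["name"],
            components=tuple(comps),
            cns_plus_threshold=float(spec["cns_plus_threshold"]),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed MPO model spec: {exc}") from exc


def model_from_yaml(path) -> MpoModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def score_mpo(profile: DescriptorProfile, model: MpoModel) -> MpoScore:
    """Score a profile under an MPO model.

    Every non-pKa descriptor must be present (:class:`ScoringError`
    otherwise). A missing basic pKa — no basic center — contributes a full
    1.0 to the total, since the transform is decreasing in basicity; the
    imputation is recorded in ``flags``. Classification is strict:
    total > threshold for CNS+, ties classify CNS−.
    """
    components: Dict[str, float] = {}
    flags: List[str] = []
    for descriptor, fn in model.components:
        value = profile.get(descriptor)
        if value is None:
            if descriptor in ("pka_basic", "pka_acidic"):
                components[descriptor] = 1.0
                flags.append(f"{descriptor} absent: component imputed as 1.0")
                continue
            raise ScoringError(
                f"model {model.name!r} requires descriptor {descriptor!r}"
            )
        components[descriptor] = fn(float(value))
    total = sum(components.values())
    classification = (
        Classification.CNS_PLUS
        if total > model.cns_plus_threshold
        else Classification.CNS_MINUS
    )
    return MpoScore(total, components, classification, tuple(flags))


# ---------------------------------------------------------------------------
# config-driven BBB score
# ---------------------------------------------------------------------------

_BBB_DESCRIPTORS = ("aromatic_rings", "heavy_atoms", "mwhbn", "tpsa", "pka")


@dataclass(frozen=True)
class BbbScore:
    total: float
    components: Dict[str, float]
    config_id: str


def _eval_piecewise(value: float, spec: dict, name: str) -> float:
    """Evaluate one stepwise/polynomial piecewise function from config.

    Each piece is ``{lo, hi, coeffs}`` with the polynomial
    ``sum(c_k * value**k)`` applied on ``lo <= value < hi`` (the last piece
    is closed on the right); ``below``/``above`` give constant values
    outside the covered interval.
    """
    pieces = spec.get("pieces", [])
    for i, piece in enumerate(pieces):
        lo, hi = float(piece["lo"]), float(piece["hi"])
        last = i == len(pieces) - 1
        if lo <= value < hi or (last and value == hi):
            return float(
                sum(c * value**k for k, c in enumerate(piece["coeffs"]))
            )
    if pieces and value < float(pieces[0]["lo"]):
        return float(spec.get("below", 0.0))
    if pieces and value > float(pieces[-1]["hi"]):
        return float(spec.get("above", 0.0))
    raise ConfigurationError(f"piecewise config for {name!r} covers no interval")


def score_bbb(profile: DescriptorProfile, config: Optional[dict]) -> BbbScore:
    """Compute the five-descriptor BBB score from a caller-supplied config.

    ``config`` maps each of ``aromatic_rings``, ``heavy_atoms``, ``mwhbn``,
    ``tpsa`` and ``pka`` to a piecewise-function spec with a ``weight``,
    and may set ``mwhbn_exponent`` (default 0.5) used in
    ``MWHBN = HBN / MW**exponent``. The total is the weighted sum of the
    per-descriptor values; the config's ``id`` is recorded for provenance.
    """
    if config is None:
        raise ConfigurationError(
            "BBB score needs a piecewise-function config (per-descriptor "
            "pieces and weights); supply one via YAML or dict — coefficients "
            "are not built in"
        )
    missing = [d for d in _BBB_DESCRIPTORS if d not in config]
    if missing:
        raise ConfigurationError(f"BBB config missing descriptors: {missing}")
    exponent = float(config.get("mwhbn_exponent", 0.5))

    values: Dict[str, float] = {}
    if profile.aromatic_rings is None or profile.heavy_atoms is None:
        raise ScoringError("BBB score needs aromatic_rings and heavy_atoms")
    values["aromatic_rings"] = float(profile.aromatic_rings)
    values["heavy_atoms"] = float(profile.heavy_atoms)
    if profile.hbn is None or profile.mw is None:
        raise ScoringError("BBB score needs hbn and mw for MWHBN")
    values["mwhbn"] = profile.hbn / profile.mw**exponent
    if profile.tpsa is None:
        raise ScoringError("BBB score needs tpsa")
    values["tpsa"] = float(profile.tpsa)
    # pKa of the most basic center; absent center treated as fully neutral
    values["pka"] = float(profile.pka_basic) if profile.pka_basic is not None else 0.0

    components: Dict[str, float] = {}
    total = 0.0
    for name in _BBB_DESCRIPTORS:
        spec = config[name]
        weight = float(spec.get("weight", 1.0))
        comp = weight * _eval_piecewise(values[name], spec, name)
        components[name] = comp
        total += comp
    return BbbScore(total, components, str(config.get("id", "<unnamed config>")))


def example_bbb_config() -> dict:
    """A synthetic, clearly-illustrative BBB-score config for tests/demos.

    The shapes are plausible (unimodal preferences for ring count, size,
    MWHBN, TPSA and basicity, each worth up to one point) but the
    coefficients are NOT those of any published model.
    """
    def ramp_hump(ulo, dlo, dhi, uhi):
        up = 1.0 / (dlo - ulo)
        down = 1.0 / (uhi - dhi)
        return {
            "pieces": [
                {"lo": ulo, "hi": dlo, "coeffs": [-ulo * up, up]},
                {"lo": dlo, "hi": dhi, "coeffs": [1.0]},
                {"lo": dhi, "hi": uhi, "coeffs": [uhi * down, -down]},
            ],
            "below": 0.0,
            "above": 0.0,
            "weight": 1.0,
        }

    return {
        "id": "synthetic-example",
        "mwhbn_exponent": 0.5,
        "aromatic_rings": ramp_hump(-0.5, 0.5, 3.5, 5.5),
        "heavy_atoms": ramp_hump(4.0, 10.0, 35.0, 60.0),
        "mwhbn": ramp_hump(0.0, 0.05, 0.45, 0.9),
        "tpsa": ramp_hump(0.0, 20.0, 90.0, 150.0),
        "pka": ramp_hump(-1.0, 0.0, 8.0, 11.0),
    }


def load_bbb_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
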