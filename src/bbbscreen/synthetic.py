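"""Synthetic labeled tracer-profile generator.

Generates descriptor-level profiles (no chemical structures) with
controlled statistical structure, anchored to the desirable/undesirable
ranges of an MPO model, so every scoring and evaluation stage can be
exercised without external data. Three modes:

``clean``
    Positives drawn strictly inside every desirable range of the anchor
    model (total score = max by construction); negatives with exactly
    ``n_violations`` components strictly inside undesirable regions.
``boundary``
    Diagnostic records flanking (and, where representable, sitting exactly
    on) every printed comparator boundary of the anchor model.
``realistic``
    Per-class normal draws with configurable means/SDs truncated to
    physical ranges; the defaults straddle the anchor ranges and emulate a
    cohort of successful tracers against a smaller unsuccessful arm, the
    class imbalance matching the 109/20 structure of reported PET-tracer
    cohorts. The defaults are illustrative synthetic constants, not fitted
    to any measured dataset.

The default cohort size is 109 positives / 20 negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .mpo import DesirabilityFunction, MpoModel, get_model, score_mpo
from .profiles import DescriptorProfile, Label, TracerDataset, TracerRecord

__all__ = ["GeneratorConfig", "generate", "DEFAULT_CLASS_MEANS", "DEFAULT_CLASS_SDS"]

#: descriptors that must come out as integer counts
_INT_DESCRIPTORS = {"hbd"}

#: lower sampling bound for monotonic-decreasing components (physical floors)
_SAMPLING_FLOORS = {"mw": 150.0, "clogp": -1.0, "clogd74": -1.0, "pka_basic": 2.0}

#: physical truncation ranges applied in realistic mode
_PHYSICAL_RANGES = {
    "mw": (100.0, 1200.0),
    "clogp": (-5.0, 10.0),
    "clogd74": (-5.0, 10.0),
    "tpsa": (0.0, 300.0),
    "hbd": (0.0, 8.0),
    "pka_basic": (0.0, 14.0),
}

#: synthetic per-class normal parameters (illustrative, straddling the
#: cns_mpo cutoffs: e.g. positive MW 320±40 vs negative 520±60)
DEFAULT_CLASS_MEANS = {
    "pos": {"mw": 320.0, "clogp": 2.2, "clogd74": 1.4, "tpsa": 65.0,
            "hbd": 0.5, "pka_basic": 7.5},
    "neg": {"mw": 520.0, "clogp": 5.8, "clogd74": 4.8, "tpsa": 135.0,
            "hbd": 4.5, "pka_basic": 10.8},
}
DEFAULT_CLASS_SDS = {
    "pos": {"mw": 40.0, "clogp": 0.7, "clogd74": 0.6, "tpsa": 12.0,
            "hbd": 0.7, "pka_basic": 0.8},
    "neg": {"mw": 60.0, "clogp": 0.8, "clogd74": 0.8, "tpsa": 20.0,
            "hbd": 1.0, "pka_basic": 0.6},
}

_MODES = ("clean", "boundary", "realistic")


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 109
    n_neg: int = 20
    mode: str = "clean"
    model_id: str = "cns_mpo"
    # 3 violated components puts a six-component total at <= 3, below both
    # built-in CNS+ thresholds (> 4 and > 3), so clean-mode negatives are
    # separable by construction
    n_violations: int = 3
    seed: int = 0
    class_means: Optional[Dict[str, Dict[str, float]]] = None
    class_sds: Optional[Dict[str, Dict[str, float]]] = None

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; one of {_MODES}")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ConfigurationError("record counts must be non-negative")
        n_comp = len(get_model(self.model_id).components)
        if not 1 <= self.n_violations <= n_comp:
            raise ConfigurationError(
                f"n_violations must be in [1, {n_comp}], got {self.n_violations}"
            )


# ---------------------------------------------------------------------------
# per-component samplers
# ---------------------------------------------------------------------------

def _sample_desirable(rng, descriptor: str, fn: DesirabilityFunction) -> float:
    if fn.kind == "monotonic_decreasing":
        if descriptor in _INT_DESCRIPTORS:
            hi = int(math.floor(fn.desirable_max))
            return float(rng.integers(0, hi + 1))
        lo = _SAMPLING_FLOORS.get(
            descriptor, fn.desirable_max - 2 * (fn.undesirable_min - fn.desirable_max)
        )
        return float(rng.uniform(lo, fn.desirable_max))
    # hump: strictly inside the central window
    span = fn.desirable_hi - fn.desirable_lo
    return float(rng.uniform(fn.desirable_lo + 1e-6 * span, fn.desirable_hi))


def _sample_undesirable(rng, descriptor: str, fn: DesirabilityFunction) -> float:
    if fn.kind == "monotonic_decreasing":
        width = fn.undesirable_min - fn.desirable_max
        if descriptor in _INT_DESCRIPTORS:
            lo = int(math.floor(fn.undesirable_min)) + 1
            return float(rng.integers(lo, lo + 3))
        return float(rng.uniform(fn.undesirable_min + 0.01 * width,
                                 fn.undesirable_min + width))
    # hump: either tail, strictly inside the zero region
    if rng.random() < 0.5 and fn.undesirable_lo > 0:
        width = fn.desirable_lo - fn.undesirable_lo
        return float(rng.uniform(max(0.0, fn.undesirable_lo - width),
                                 fn.undesirable_lo - 1e-9 * width))
    width = fn.undesirable_hi - fn.desirable_hi
    return float(rng.uniform(fn.undesirable_hi + 0.01 * width,
                             fn.undesirable_hi + width))


def _desirable_mid(descriptor: str, fn: DesirabilityFunction) -> float:
    if fn.kind == "hump":
        return 0.5 * (fn.desirable_lo + fn.desirable_hi)
    if descriptor in _INT_DESCRIPTORS:
        return float(int(math.floor(fn.desirable_max)))
    lo = _SAMPLING_FLOORS.get(descriptor, fn.desirable_max - 1.0)
    return 0.5 * (lo + fn.desirable_max)


def _ancillary(rng, positive: bool) -> dict:
    """Counts not governed by the anchor model, kept invariant-consistent."""
    nitrogen = int(rng.integers(1, 3))
    oxygen = int(rng.integers(0, 4) if positive else rng.integers(2, 7))
    return {
        "nitrogen_count": nitrogen,
        "n_plus_o": nitrogen + oxygen,
        "hba": int(rng.integers(1, 7)),
        "aromatic_rings": int(rng.integers(1, 4)),
        "n_acid_base": int(rng.integers(0, 3)),
    }


def _build_profile(rng, descriptors: Dict[str, float], positive: bool) -> DescriptorProfile:
    extra = _ancillary(rng, positive)
    hbd = int(round(descriptors.get("hbd", 0)))
    extra["polar_h"] = hbd + int(rng.integers(0, 2))
    extra["heavy_atoms"] = max(5, int(round(descriptors.get("mw", 300.0) / 13.5)))
    return DescriptorProfile(**{**descriptors, "hbd": hbd, **extra})


# ---------------------------------------------------------------------------
# modes
# ---------------------------------------------------------------------------

def _generate_clean(rng, config: GeneratorConfig, model: MpoModel):
    records = []
    for i in range(config.n_pos):
        desc = {
            name: _sample_desirable(rng, name, fn) for name, fn in model.components
        }
        records.append(
            TracerRecord(
                identifier=f"pos_{i:04d}",
                profile=_build_profile(rng, desc, True),
                label=Label.SUCCESSFUL,
            )
        )
    n_comp = len(model.components)
    for i in range(config.n_neg):
        violated = set(
            rng.choice(n_comp, size=config.n_violations, replace=False).tolist()
        )
        desc = {}
        for j, (name, fn) in enumerate(model.components):
            sampler = _sample_undesirable if j in violated else _sample_desirable
            desc[name] = sampler(rng, name, fn)
        records.append(
            TracerRecord(
                identifier=f"neg_{i:04d}",
                profile=_build_profile(rng, desc, False),
                label=Label.UNSUCCESSFUL,
            )
        )
    return records


def _boundary_points(descriptor: str, fn: DesirabilityFunction):
    """(tag, value) probes per printed boundary: exact point plus both flanks."""
    if fn.kind == "monotonic_decreasing":
        bounds = [("desirable_max", fn.desirable_max),
                  ("undesirable_min", fn.undesirable_min)]
    else:
        bounds = [("undesirable_lo", fn.undesirable_lo),
                  ("desirable_lo", fn.desirable_lo),
                  ("desirable_hi", fn.desirable_hi),
                  ("undesirable_hi", fn.undesirable_hi)]
    probes = []
    for bname, b in bounds:
        if descriptor in _INT_DESCRIPTORS:
            below, above = math.floor(b), math.floor(b) + 1
            if float(b).is_integer():
                below, above = int(b) - 1, int(b) + 1
                probes.append((f"{bname}_at", float(int(b))))
            probes.append((f"{bname}_below", float(max(0, below))))
            probes.append((f"{bname}_above", float(above)))
        else:
            eps = 1e-6 * max(1.0, abs(b))
            probes.append((f"{bname}_at", b))
            probes.append((f"{bname}_below", b - eps))
            probes.append((f"{bname}_above", b + eps))
    return probes


def _generate_boundary(rng, config: GeneratorConfig, model: MpoModel):
    mids = {name: _desirable_mid(name, fn) for name, fn in model.components}
    records = []
    for name, fn in model.components:
        for tag, value in _boundary_points(name, fn):
            desc = dict(mids)
            desc[name] = value
            profile = _build_profile(rng, desc, True)
            label = (
                Label.SUCCESSFUL
                if score_mpo(profile, model).classification.value == "CNS+"
                else Label.UNSUCCESSFUL
            )
            records.append(
                TracerRecord(
                    identifier=f"bnd_{name}_{tag}",
                    profile=profile,
                    label=label,
                )
            )
    return records


def _generate_realistic(rng, config: GeneratorConfig, model: MpoModel):
    means = config.class_means or DEFAULT_CLASS_MEANS
    sds = config.class_sds or DEFAULT_CLASS_SDS
    records = []
    for cls, count, label, prefix in (
        ("pos", config.n_pos, Label.SUCCESSFUL, "pos"),
        ("neg", config.n_neg, Label.UNSUCCESSFUL, "neg"),
    ):
        for i in range(count):
            desc = {}
            for name, mu in means[cls].items():
                sd = sds[cls][name]
                value = float(rng.normal(mu, sd))
                lo, hi = _PHYSICAL_RANGES.get(name, (-math.inf, math.inf))
                value = min(max(value, lo), hi)
                if name in _INT_DESCRIPTORS:
                    value = float(int(round(value)))
                desc[name] = value
            records.append(
                TracerRecord(
                    identifier=f"{prefix}_{i:04d}",
                    profile=_build_profile(rng, desc, cls == "pos"),
                    label=label,
                )
            )
    return records


def generate(config: GeneratorConfig) -> TracerDataset:
    """Generate a labeled synthetic tracer dataset.

    Identical seeds reproduce identical datasets; see the module docstring
    for mode semantics.
    """
    rng = np.random.default_rng(config.seed)
    model = get_model(config.model_id)
    if config.mode == "clean":
        records = _generate_clean(rng, config, model)
    elif config.mode == "boundary":
        records = _generate_boundary(rng, config, model)
    else:
        records = _generate_realistic(rng, config, model)
    return TracerDataset(
        tuple(records),
        provenance=f"synthetic:{config.mode}:{config.model_id}:seed={config.seed}",
    )
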