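"""End-to-end screening: run rules and scores over a dataset, tally metrics.

:func:`screen` resolves each requested model id against the rule, MPO and
logBB registries (plus the precomputed-column models ``cns_access`` and
``vendor_logbb``), classifies every record, and — for labeled records with
determinate verdicts — computes the full statistics suite per model.
Indeterminate verdicts (missing descriptors) are tallied separately and
never folded into either class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import logbb as _logbb
from . import mpo as _mpo
from . import rules as _rules
from .errors import ConfigurationError, ValidationError
from .metrics import MetricsReport, confusion, metrics
from .profiles import Label, TracerDataset, TracerRecord
from .rules import Classification

__all__ = ["ScreeningReport", "screen", "available_model_ids"]

logger = logging.getLogger(__name__)

#: precomputed-column models: id -> (required score column, threshold doc)
_PRECOMPUTED_MODELS = {
    "cns_access": "cns_access",
    "vendor_logbb": "logbb",
}


@dataclass(frozen=True)
class ScreeningReport:
    """Per-record classifications plus per-model summary statistics."""

    per_record: pd.DataFrame
    per_model: Dict[str, Optional[MetricsReport]]
    fractions: Dict[str, Dict[str, Optional[float]]]
    run_config: Dict[str, object]
    provenance: Dict[str, str]  # model id -> "recomputed" | "precomputed"


def available_model_ids() -> List[str]:
    ids = list(_rules.available_rules())
    ids += _mpo.available_models() + ["bbb_score"]
    ids += sorted(_logbb.LOGBB_MODELS)
    ids += sorted(_PRECOMPUTED_MODELS)
    return sorted(set(ids))


def _classify_record(
    model_id: str,
    record: TracerRecord,
    bbb_config: Optional[dict],
) -> Tuple[Optional[float], Optional[Classification], str]:
    """Return (raw value, classification or None if indeterminate, provenance)."""
    profile = record.profile
    if model_id in _PRECOMPUTED_MODELS:
        column = _PRECOMPUTED_MODELS[model_id]
        if column not in record.precomputed_scores:
            raise ConfigurationError(
                f"model {model_id!r} needs precomputed column {column!r} "
                f"(absent on record {record.identifier!r}); map it via "
                "column_map['scores']"
            )
        value = record.precomputed_scores[column]
        if model_id == "cns_access":
            res = _logbb.cns_access(_logbb.CnsAccessInputs(value, 0.0))
            return value, res.classification, "precomputed"
        return value, _logbb.classify_logbb(value), "precomputed"

    if profile is None:
        return None, None, "recomputed"
    if model_id in _rules.available_rules():
        verdict = _rules.evaluate_rule(model_id, profile)
        value = (
            verdict.criteria[0].observed
            if model_id == "norinder_rule2"
            else None
        )
        return value, verdict.classification, "recomputed"
    if model_id in _mpo.available_models():
        score = _mpo.score_mpo(profile, _mpo.get_model(model_id))
        return score.total, score.classification, "recomputed"
    if model_id == "bbb_score":
        result = _mpo.score_bbb(profile, bbb_config)
        threshold = (bbb_config or {}).get("cns_plus_threshold")
        if threshold is None:
            return result.total, None, "recomputed"
        cls = (
            Classification.CNS_PLUS
            if result.total > float(threshold)
            else Classification.CNS_MINUS
        )
        return result.total, cls, "recomputed"
    if model_id in _logbb.LOGBB_MODELS:
        pred = _logbb.predict_logbb(model_id, profile)
        cls = (
            pred.classification
            if pred.classification is not Classification.NOT_APPLICABLE
            else None
        )
        return pred.value, cls, "recomputed"
    raise ConfigurationError(
        f"unknown model id {model_id!r}; available: {available_model_ids()}"
    )


def screen(
    dataset: TracerDataset,
    models: Sequence[str],
    bbb_config: Optional[dict] = None,
) -> ScreeningReport:
    """Screen a dataset with the requested models and summarize performance.

    Per model the report carries the raw value and CNS+/CNS− call per
    record, a :class:`MetricsReport` over the labeled, determinate records
    (``None`` when the dataset is unlabeled), and the headline fractions:
    share of positives called CNS+, share of negatives called CNS−, and the
    indeterminate tally. Deterministic for fixed inputs; models share no
    state, so screening singly or jointly gives identical columns.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot screen an empty dataset")
    if not models:
        raise ValidationError("no models requested")
    if len(set(models)) != len(models):
        raise ValidationError(f"duplicate model ids in {list(models)}")

    columns: Dict[str, list] = {"identifier": dataset.identifiers()}
    per_model: Dict[str, Optional[MetricsReport]] = {}
    fractions: Dict[str, Dict[str, Optional[float]]] = {}
    provenance: Dict[str, str] = {}

    for model_id in models:
        values, classes, prov = [], [], "recomputed"
        for record in dataset:
            value, cls, prov = _classify_record(model_id, record, bbb_config)
            values.append(value)
            classes.append(cls)
        provenance[model_id] = prov
        columns[f"{model_id}_value"] = values
        columns[f"{model_id}_class"] = [
            c.value if c is not None else "indeterminate" for c in classes
        ]

        labeled = [
            (cls, rec.label)
            for rec, cls in zip(dataset, classes)
            if rec.label is not Label.UNLABELED
        ]
        determinate = [
            (cls, lab)
            for cls, lab in labeled
            if cls in (Classification.CNS_PLUS, Classification.CNS_MINUS)
        ]
        n_indeterminate = len(labeled) - len(determinate)
        if determinate:
            counts = confusion(*zip(*determinate))
            report = metrics(counts)
            per_model[model_id] = report
            fractions[model_id] = {
                "positives_cns_plus": report.se,
                "negatives_cns_minus": report.sp,
                "indeterminate": n_indeterminate,
            }
            logger.info(
                "model=%s n=%d tp=%d fp=%d tn=%d fn=%d indeterminate=%d",
                model_id, counts.n, counts.tp, counts.fp, counts.tn,
                counts.fn, n_indeterminate,
            )
        else:
            per_model[model_id] = None
            fractions[model_id] = {
                "positives_cns_plus": None,
                "negatives_cns_minus": None,
                "indeterminate": n_indeterminate,
            }

    run_config = {
        "models": list(models),
        "n_records": len(dataset),
        "n_labeled": len(dataset.labeled()),
        "provenance_tag": dataset.provenance,
        "bbb_config_id": (bbb_config or {}).get("id"),
    }
    return ScreeningReport(
        per_record=pd.DataFrame(columns),
        per_model=per_model,
        fractions=fractions,
        run_config=run_config,
        provenance=provenance,
    )
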