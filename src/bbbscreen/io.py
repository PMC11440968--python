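"""Reading and writing tracer datasets and screening result tables.

CSV dialect: UTF-8, comma-separated, header row required, decimal point.
Column names are never hard-coded: the caller supplies a ``column_map``
from canonical descriptor field names (see
:class:`~bbbscreen.profiles.DescriptorProfile`) to the file's own headers,
plus the special keys ``identifier``, ``structure`` and ``label``, and an
optional ``scores`` sub-mapping for precomputed model-score columns.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import SchemaError, ValidationError
from .profiles import (
    DescriptorProfile,
    Label,
    TracerDataset,
    TracerRecord,
    compute_profile,
)

__all__ = [
    "load_dataset",
    "write_results",
    "dataset_to_frame",
    "identity_column_map",
    "DEFAULT_LABEL_MAP",
]

_SPECIAL_KEYS = {"identifier", "structure", "label", "scores"}

#: how label-column strings map onto the ternary label
DEFAULT_LABEL_MAP = {
    "successful": Label.SUCCESSFUL,
    "unsuccessful": Label.UNSUCCESSFUL,
    "cns+": Label.SUCCESSFUL,
    "cns-": Label.UNSUCCESSFUL,
    "1": Label.SUCCESSFUL,
    "0": Label.UNSUCCESSFUL,
}


def _clean(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def _parse_label(raw, label_map: Mapping[str, Label]) -> Label:
    raw = _clean(raw)
    if raw is None:
        return Label.UNLABELED
    key = str(raw).strip().lower()
    if key in label_map:
        return label_map[key]
    if key == Label.UNLABELED.value:
        return Label.UNLABELED
    raise ValidationError(f"unrecognized label value {raw!r}")


def _load_csv(
    path: Path,
    column_map: Mapping,
    backend: str,
    label_map: Mapping[str, Label],
) -> list:
    frame = pd.read_csv(path)
    score_map = dict(column_map.get("scores", {}))
    needed = [c for k, c in column_map.items() if k != "scores"]
    needed += list(score_map.values())
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")

    descriptor_keys = [k for k in column_map if k not in _SPECIAL_KEYS]
    records = []
    for idx, row in frame.iterrows():
        if "identifier" in column_map:
            ident = str(row[column_map["identifier"]])
        else:
            ident = f"row{idx}"
        structure = (
            _clean(row[column_map["structure"]])
            if "structure" in column_map
            else None
        )
        desc = {}
        for key in descriptor_keys:
            val = _clean(row[column_map[key]])
            if val is not None:
                desc[key] = float(val)
        profile = None
        if desc:
            profile = DescriptorProfile(**desc)
        elif structure is not None:
            profile = compute_profile(structure, backend=backend)
        label = (
            _parse_label(row[column_map["label"]], label_map)
            if "label" in column_map
            else Label.UNLABELED
        )
        scores = {}
        for name, col in score_map.items():
            val = _clean(row[col])
            if val is not None:
                scores[name] = float(val)
        records.append(
            TracerRecord(
                identifier=ident,
                structure=structure,
                profile=profile,
                label=label,
                precomputed_scores=scores,
            )
        )
    return records


def _load_sdf(
    path: Path,
    backend: str,
    label_prop: Optional[str],
    label_map: Mapping[str, Label],
) -> list:
    from rdkit import Chem

    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ValidationError(f"{path}: entry {idx} could not be parsed")
        ident = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        ident = ident.strip() or f"mol{idx}"
        smiles = Chem.MolToSmiles(mol)
        label = Label.UNLABELED
        if label_prop and mol.HasProp(label_prop):
            label = _parse_label(mol.GetProp(label_prop), label_map)
        records.append(
            TracerRecord(
                identifier=ident,
                structure=smiles,
                profile=compute_profile(smiles, backend=backend),
                label=label,
            )
        )
    return records


def load_dataset(
    path,
    format: str = "csv",
    column_map: Optional[Mapping] = None,
    backend: str = "rdkit",
    label_map: Optional[Mapping[str, Label]] = None,
    label_prop: Optional[str] = None,
    provenance: Optional[str] = None,
) -> TracerDataset:
    """Load a labeled tracer dataset from a CSV descriptor table or an SDF.

    For CSV input a ``column_map`` is required; every mapped column must be
    present in the header (:class:`SchemaError` otherwise). Rows carrying
    descriptor columns are ingested verbatim; rows with only a structure
    column get their profile computed with ``backend``. For SDF input the
    profile is always computed and ``label_prop`` optionally names the SDF
    property holding the success label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    if format == "csv":
        if column_map is None:
            raise SchemaError("CSV input requires a column_map")
        records = _load_csv(path, column_map, backend, label_map)
    elif format == "sdf":
        records = _load_sdf(path, backend, label_prop, label_map)
    else:
        raise SchemaError(f"unknown format {format!r}; expected 'csv' or 'sdf'")
    return TracerDataset(
        tuple(records), provenance=provenance or str(path)
    )


_PROFILE_FIELDS = [
    "mw", "clogp", "clogd74", "tpsa", "psa", "hbd", "hba", "n_plus_o",
    "pka_basic", "pka_acidic", "n_acid_base", "molvol", "aromatic_rings",
    "heavy_atoms", "hbn", "polar_h", "chains_outside_rings", "nitrogen_count",
]


def dataset_to_frame(dataset: TracerDataset) -> pd.DataFrame:
    """Flatten a dataset into the canonical CSV dialect (one row per record).

    Columns: ``identifier``, ``structure``, ``label``, every descriptor
    field present on at least one record, then any precomputed score
    columns. :func:`identity_column_map` on the resulting header feeds the
    frame straight back into :func:`load_dataset`.
    """
    rows = []
    for rec in dataset:
        row = {
            "identifier": rec.identifier,
            "structure": rec.structure,
            "label": rec.label.value,
        }
        if rec.profile is not None:
            for name in _PROFILE_FIELDS:
                row[name] = rec.profile.get(name)
        for score, value in rec.precomputed_scores.items():
            row[score] = value
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.dropna(axis=1, how="all")


def identity_column_map(columns, score_columns=()) -> dict:
    """Identity column map for the canonical header written by this package."""
    cmap = {c: c for c in columns if c in _PROFILE_FIELDS}
    for special in ("identifier", "structure", "label"):
        if special in columns:
            cmap[special] = special
    scores = {c: c for c in score_columns if c in columns}
    if scores:
        cmap["scores"] = scores
    return cmap


def write_results(dataset: TracerDataset, scores: pd.DataFrame, path) -> Path:
    """Write a per-record score/classification table next to the dataset.

    ``scores`` must carry one row per record in an ``identifier`` column (or
    index) matching the dataset exactly. Output is a deterministic CSV: one
    row per record in dataset order, byte-identical across re-runs on
    identical input.
    """
    if scores is None or len(scores.columns.difference(["identifier"])) == 0:
        raise ValidationError("score table is empty")
    table = scores.copy()
    if "identifier" not in table.columns:
        table = table.reset_index().rename(columns={"index": "identifier"})
    table["identifier"] = table["identifier"].astype(str)
    ids = dataset.identifiers()
    if sorted(table["identifier"]) != sorted(ids):
        raise ValidationError(
            "score table identifiers do not match dataset identifiers"
        )
    table = table.set_index("identifier").loc[ids].reset_index()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\n")
    return path
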