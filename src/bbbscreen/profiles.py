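"""Per-compound physicochemical descriptor profiles and labeled tracer records.

A :class:`DescriptorProfile` is the vector every downstream rule and score
consumes: molecular weight, lipophilicity (ClogP / ClogD at pH 7.4),
polar surface area, hydrogen-bonding counts, ionization constants and a few
structural counts. Profiles can be computed from a SMILES string with an
open descriptor backend (RDKit by default) or ingested from a descriptor
table; the two routes are deliberately separate because descriptor values
differ between calculation packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Callable, Optional, Sequence

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "DescriptorProfile",
    "Label",
    "TracerRecord",
    "TracerDataset",
    "compute_profile",
    "available_backends",
]

#: descriptor fields that must be non-negative integers when present
_COUNT_FIELDS = (
    "hbd",
    "hba",
    "n_plus_o",
    "hbn",
    "polar_h",
    "aromatic_rings",
    "heavy_atoms",
    "chains_outside_rings",
    "nitrogen_count",
    "n_acid_base",
)


def _as_count(name: str, value):
    """Coerce a numeric value to a non-negative int, or raise."""
    if value is None:
        return None
    iv = int(round(float(value)))
    if abs(float(value) - iv) > 1e-9:
        raise ValidationError(f"{name} must be an integer count, got {value!r}")
    if iv < 0:
        raise ValidationError(f"{name} must be non-negative, got {value!r}")
    return iv


@dataclass(frozen=True)
class DescriptorProfile:
    """Physicochemical descriptor vector for one compound.

    All fields are optional at the type level so that partially-populated
    tables (e.g. a CSV carrying only MW/ClogP/TPSA/HBD) can flow through the
    pipeline; consumers that need a missing descriptor raise an explicit
    error or flag the verdict as indeterminate.

    Units: ``mw`` in g/mol, ``tpsa``/``psa`` in Å², lipophilicity and pKa
    dimensionless; all ``*_count`` style fields are plain atom/group counts.
    """

    mw: Optional[float] = None
    clogp: Optional[float] = None
    clogd74: Optional[float] = None
    tpsa: Optional[float] = None
    psa: Optional[float] = None
    hbd: Optional[int] = None
    hba: Optional[int] = None
    n_plus_o: Optional[int] = None
    pka_basic: Optional[float] = None
    pka_acidic: Optional[float] = None
    n_acid_base: Optional[int] = None
    molvol: Optional[float] = None
    aromatic_rings: Optional[int] = None
    heavy_atoms: Optional[int] = None
    hbn: Optional[int] = None
    polar_h: Optional[int] = None
    chains_outside_rings: Optional[int] = None
    nitrogen_count: Optional[int] = None

    def __post_init__(self):
        for name in _COUNT_FIELDS:
            object.__setattr__(self, name, _as_count(name, getattr(self, name)))
        if self.mw is not None and self.mw <= 0:
            raise ValidationError(f"mw must be positive, got {self.mw}")
        if self.tpsa is not None and self.tpsa < 0:
            raise ValidationError(f"tpsa must be non-negative, got {self.tpsa}")
        # PSA defaults to TPSA when not supplied separately
        if self.psa is None and self.tpsa is not None:
            object.__setattr__(self, "psa", float(self.tpsa))
        # HBN = HBD + HBA: derive it, or check consistency if supplied
        if self.hbd is not None and self.hba is not None:
            total = self.hbd + self.hba
            if self.hbn is None:
                object.__setattr__(self, "hbn", total)
            elif self.hbn != total:
                raise ValidationError(
                    f"hbn={self.hbn} inconsistent with hbd+hba={total}"
                )
        if (
            self.n_plus_o is not None
            and self.nitrogen_count is not None
            and self.n_plus_o < self.nitrogen_count
        ):
            raise ValidationError(
                f"n_plus_o={self.n_plus_o} < nitrogen_count={self.nitrogen_count}"
            )

    def get(self, name: str):
        """Return a descriptor by field name (None when absent)."""
        if name not in {f.name for f in fields(self)}:
            raise KeyError(name)
        return getattr(self, name)


class Label(str, Enum):
    """Outcome label of a tracer record."""

    SUCCESSFUL = "successful"
    UNSUCCESSFUL = "unsuccessful"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class TracerRecord:
    """One labeled compound flowing through the screening pipeline."""

    identifier: str
    profile: Optional[DescriptorProfile] = None
    structure: Optional[str] = None  # SMILES
    label: Label = Label.UNLABELED
    precomputed_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.profile is None and self.structure is None:
            raise ValidationError(
                f"record {self.identifier!r} needs a structure or a profile"
            )
        if not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(self.label))


@dataclass(frozen=True)
class TracerDataset:
    """An ordered collection of tracer records with unique identifiers."""

    records: tuple
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.identifier for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate identifiers: {dupes}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def identifiers(self) -> list:
        return [r.identifier for r in self.records]

    def labeled(self) -> "TracerDataset":
        """Subset of records carrying a success/failure label."""
        return TracerDataset(
            tuple(r for r in self.records if r.label is not Label.UNLABELED),
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# descriptor backends
# ---------------------------------------------------------------------------

def _rdkit_profile(smiles: str) -> DescriptorProfile:
    """RDKit 2D descriptor backend.

    Definitions used here: HBD counts N/O atoms bearing at least one
    hydrogen (so water has one donor); HBA follows RDKit's CalcNumHBA;
    polar_h counts hydrogens attached to N or O; ClogD7.4 is approximated
    by ClogP (neutral-species assumption — no open logD model is bundled),
    which is exact for non-ionizable compounds and optimistic for bases.
    pKa, molar volume and chain counts are left unset.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES {smiles!r}")
    hetero_h = 0
    hbd = 0
    n_count = 0
    n_plus_o = 0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("N", "O"):
            n_plus_o += 1
            nh = atom.GetTotalNumHs()
            hetero_h += nh
            if nh > 0:
                hbd += 1
            if sym == "N":
                n_count += 1
    clogp = float(Crippen.MolLogP(mol))
    return DescriptorProfile(
        mw=float(Descriptors.MolWt(mol)),
        clogp=clogp,
        clogd74=clogp,
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        hbd=hbd,
        hba=int(rdMolDescriptors.CalcNumHBA(mol)),
        n_plus_o=n_plus_o,
        aromatic_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        heavy_atoms=int(mol.GetNumHeavyAtoms()),
        polar_h=hetero_h,
        nitrogen_count=n_count,
    )


_BACKENDS: dict = {"rdkit": _rdkit_profile}


def available_backends() -> Sequence[str]:
    return sorted(_BACKENDS)


def register_backend(name: str, fn: Callable[[str], DescriptorProfile]) -> None:
    """Register an alternative descriptor calculator under ``name``."""
    _BACKENDS[name] = fn


def compute_profile(structure: str, backend: str = "rdkit") -> DescriptorProfile:
    """Compute a :class:`DescriptorProfile` from a SMILES string.

    Deterministic: the same structure and backend always yield an identical
    profile. Raises :class:`ParseError` for unparseable structures and
    :class:`ConfigurationError` for unknown backends.
    """
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ConfigurationError(
            f"unknown descriptor backend {backend!r}; "
            f"available: {available_backends()}"
        ) from None
    return fn(structure)
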