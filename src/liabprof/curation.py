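"""Curation of raw structure-activity records into QSAR-ready datasets.

Raw bioactivity tables are heterogeneous: mixed concentration units, censored
measurements, non-human assays, salt forms, and replicate measurements of the
same parent compound. This module applies a sequential cleaning protocol:

1. record-level filters (species, censoring, activity type),
2. structure standardization (salt stripping, functional-group normalization,
   neutralization, canonicalization),
3. activity normalization to pACTIVITY = -log10(molar concentration),
4. de-duplication on exact standardized-SMILES match, taking the median
   pACTIVITY over replicates.

Every removal is attributed to the first rule a record fails, and the
per-reason counts are kept in a provenance log that reconciles exactly with
the raw and retained record counts.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ActivityRecord",
    "CuratedCompound",
    "CuratedDataset",
    "FilterRules",
    "CurationError",
    "UNIT_FACTORS",
    "standardize_structure",
    "normalize_activity",
    "apply_filters",
    "deduplicate",
    "curate",
    "read_records_csv",
    "write_curated_csv",
    "read_curated_csv",
]


class CurationError(ValueError):
    """A record could not be curated; the message carries the reason code."""


#: Conversion factors from supported concentration units to mol/L.
UNIT_FACTORS: dict[str, float] = {
    "nm": 1e-9,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,  # greek mu
    "mm": 1e-3,
    "m": 1.0,
}

#: Activity types admitted by default (functional + binding pooled).
DEFAULT_ACTIVITY_TYPES = frozenset({"IC50", "EC50", "Ki", "Kd"})
BINDING_TYPES = frozenset({"Ki", "Kd"})
FUNCTIONAL_TYPES = frozenset({"IC50", "EC50"})

#: Species labels accepted (case-insensitive exact match).
DEFAULT_SPECIES = frozenset({"homo sapiens", "human"})


@dataclass(frozen=True)
class ActivityRecord:
    """One raw structure-activity measurement."""

    structure: str
    value: float
    unit: str
    activity_type: str
    species: str = "human"
    censor: str = "none"  # "none" | ">" | "<"


@dataclass(frozen=True)
class CuratedCompound:
    standardized_smiles: str
    pactivity: float
    n_source_records: int = 1


@dataclass
class CuratedDataset:
    """QSAR-ready dataset: unique standardized compounds with pACTIVITY."""

    target_id: str
    compounds: list[CuratedCompound]
    provenance_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def smiles(self) -> list[str]:
        return [c.standardized_smiles for c in self.compounds]

    @property
    def pactivity(self) -> np.ndarray:
        return np.array([c.pactivity for c in self.compounds], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "standardized_smiles": self.smiles,
                "pACTIVITY": self.pactivity,
                "n_source_records": [c.n_source_records for c in self.compounds],
            }
        )


@dataclass(frozen=True)
class FilterRules:
    """Record-level admission rules.

    ``activity_types`` may be narrowed to binding-only ({"Ki","Kd"}) or
    functional-only ({"IC50","EC50"}) to reproduce single-assay-class models.
    """

    species: frozenset[str] = DEFAULT_SPECIES
    activity_types: frozenset[str] = DEFAULT_ACTIVITY_TYPES
    exclude_censored: bool = True


_uncharger = rdMolStandardize.Uncharger()


def standardize_structure(smiles: str) -> str:
    """Standardize a raw SMILES to a canonical, salt-free, neutral form.

    Steps: parse; keep the largest fragment by heavy-atom count among the
    fragments containing at least one carbon (lexicographically smallest
    canonical SMILES breaks ties); normalize charge-separated functional
    groups (nitro, N-oxide, azide, ...); neutralize; canonicalize.
    Deterministic and idempotent; no 3D coordinates are ever generated.

    Raises
    ------
    CurationError
        If the SMILES does not parse, contains no carbon fragment, or fails
        sanitization after standardization.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise CurationError("empty_smiles")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError("unparsable_smiles")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    candidates = []
    for frag in frags:
        has_carbon = any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())
        if has_carbon:
            candidates.append(frag)
    if not candidates:
        raise CurationError("no_organic_fragment")
    # largest by heavy atoms; ties broken by canonical SMILES order
    parent = min(
        candidates,
        key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )

    try:
        parent = rdMolStandardize.Normalize(parent)
        parent = _uncharger.uncharge(parent)
        Chem.SanitizeMol(parent)
    except Exception as exc:  # pragma: no cover - rdkit raises rarely here
        raise CurationError(f"standardization_failed: {exc}") from exc
    return Chem.MolToSmiles(parent)


def normalize_activity(value: float, unit: str) -> float:
    """Convert an activity value in a concentration unit to pACTIVITY.

    pACTIVITY = -log10(value in mol/L); e.g. 1 µM -> 6.0, 10 µM -> 5.0.
    """
    key = str(unit).strip().lower()
    if key not in UNIT_FACTORS:
        raise CurationError(f"unknown_unit: {unit!r}")
    if not math.isfinite(value) or value <= 0:
        raise CurationError(f"nonpositive_value: {value!r}")
    return float(-np.log10(value * UNIT_FACTORS[key]))


def apply_filters(
    records: Sequence[ActivityRecord], rules: FilterRules = FilterRules()
) -> tuple[list[ActivityRecord], Counter]:
    """Apply record-level admission rules, preserving input order.

    Returns the retained records and a Counter of removals keyed by the first
    rule each excluded record failed
    (``species`` -> ``censored`` -> ``activity_type``).
    """
    allowed_species = {s.lower() for s in rules.species}
    retained: list[ActivityRecord] = []
    removed: Counter = Counter()
    for rec in records:
        if rec.species.strip().lower() not in allowed_species:
            removed["species"] += 1
        elif rules.exclude_censored and rec.censor in (">", "<"):
            removed["censored"] += 1
        elif rec.activity_type not in rules.activity_types:
            removed["activity_type"] += 1
        else:
            retained.append(rec)
    return retained, removed


def deduplicate(
    entries: Iterable[tuple[str, float]], target_id: str = "", provenance: dict | None = None
) -> CuratedDataset:
    """Collapse (standardized_smiles, pACTIVITY) entries to one compound each.

    The representative pACTIVITY of a replicate group is the median; the
    result is invariant to input record order. Compounds are emitted in order
    of first appearance.
    """
    groups: dict[str, list[float]] = {}
    order: list[str] = []
    for smi, p in entries:
        if smi not in groups:
            groups[smi] = []
            order.append(smi)
        groups[smi].append(float(p))
    compounds = [
        CuratedCompound(smi, float(np.median(groups[smi])), len(groups[smi]))
        for smi in order
    ]
    return CuratedDataset(target_id, compounds, dict(provenance or {}))


def curate(
    records: Sequence[ActivityRecord],
    rules: FilterRules = FilterRules(),
    target_id: str = "",
) -> CuratedDataset:
    """Full curation pipeline: filters -> standardize -> normalize -> dedupe.

    The provenance log records the raw count, per-reason removals and the
    retained unique-compound count; ``raw == kept_records + sum(removals)``
    always holds (de-duplication merges, it does not remove).
    """
    kept, removed = apply_filters(records, rules)
    entries: list[tuple[str, float]] = []
    for rec in kept:
        try:
            smi = standardize_structure(rec.structure)
            p = normalize_activity(rec.value, rec.unit)
        except CurationError as exc:
            removed[str(exc).split(":")[0]] += 1
            continue
        entries.append((smi, p))
    provenance = {"raw": len(records), "records_after_filters": len(entries)}
    provenance.update({f"removed_{k}": v for k, v in sorted(removed.items())})
    ds = deduplicate(entries, target_id=target_id, provenance=provenance)
    ds.provenance_log["retained_compounds"] = len(ds)
    return ds


# ---------------------------------------------------------------------------
# I/O

DEFAULT_COLUMNS = {
    "structure": "structure",
    "value": "value",
    "unit": "unit",
    "activity_type": "activity_type",
    "species": "species",
    "censor": "censor",
    "target": "target",
}


def read_records_csv(path, column_map: dict[str, str] | None = None) -> dict[str, list[ActivityRecord]]:
    """Read a delimited raw activity table, grouped by target.

    ``column_map`` maps the canonical field names to the file's column names.
    A missing censor/species column defaults to uncensored human records; a
    missing target column yields a single unnamed group.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(column_map or {})
    df = pd.read_csv(path)
    out: dict[str, list[ActivityRecord]] = {}
    for _, row in df.iterrows():
        rec = ActivityRecord(
            structure=str(row[cols["structure"]]),
            value=float(row[cols["value"]]),
            unit=str(row[cols["unit"]]),
            activity_type=str(row[cols["activity_type"]]),
            species=str(row.get(cols["species"], "human")),
            censor=str(row.get(cols["censor"], "none")),
        )
        target = str(row[cols["target"]]) if cols["target"] in df.columns else ""
        out.setdefault(target, []).append(rec)
    return out


def write_curated_csv(dataset: CuratedDataset, path, log_path=None) -> None:
    dataset.to_frame().to_csv(path, index=False)
    if log_path is not None:
        with open(log_path, "w") as fh:
            json.dump(dataset.provenance_log, fh, indent=2)


def read_curated_csv(path, target_id: str = "") -> CuratedDataset:
    df = pd.read_csv(path)
    compounds = [
        CuratedCompound(str(r.standardized_smiles), float(r.pACTIVITY), int(r.n_source_records))
        for r in df.itertuples()
    ]
    return CuratedDataset(target_id, compounds)
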