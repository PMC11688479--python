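"""Compound-table ingestion, canonicalization, and the OB/DL admission filter.

Compound libraries arrive as CSV tables carrying a SMILES string plus two
precomputed ADME descriptors: oral bioavailability (OB, percent) and
drug-likeness (DL, unitless in [0, 1]).  Admission into the screening
cascade requires OB >= 20% and DL >= 0.18, the conventional TCMSP
thresholds.  Both descriptors are consumed as given columns; nothing here
predicts them from structure.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit logs every rejected SMILES at error level; invalid records are
# expected input here and are reported through DedupReport instead.
RDLogger.DisableLog("rdApp.error")

DEFAULT_OB_MIN = 20.0
DEFAULT_DL_MIN = 0.18

CSV_COLUMNS = ("id", "name", "smiles", "ob", "dl", "source")


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound: identity, structure, and ADME descriptors.

    ``ob`` and ``dl`` may be NaN when the source table lacks them; such
    records are rejected (with a warning) by :func:`adme_filter`.
    """

    id: str
    name: str
    smiles: str
    ob: float = math.nan
    dl: float = math.nan
    source: str = ""


@dataclass(frozen=True)
class CompoundSet:
    """An ordered compound collection, unique by canonical SMILES."""

    records: tuple[CompoundRecord, ...] = ()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CompoundRecord:
        return self.records[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def smiles(self) -> tuple[str, ...]:
        return tuple(r.smiles for r in self.records)


@dataclass(frozen=True)
class DedupReport:
    """Bookkeeping from canonicalization: what survived and what was dropped."""

    compounds: CompoundSet
    n_input: int
    n_invalid: int
    n_duplicate: int
    invalid_ids: tuple[str, ...] = ()
    duplicate_ids: tuple[str, ...] = ()


def canonical_smiles(smiles: str) -> str | None:
    """Canonicalize one SMILES string, or return None if it does not parse.

    Internal whitespace is stripped first: SMILES lifted from typeset
    tables frequently acquire spaces around ``=``.  Stereochemistry is
    kept as written (no stripping).
    """
    cleaned = "".join(smiles.split())
    if not cleaned:
        return None
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def canonicalize_and_dedup(raw: Iterable[CompoundRecord]) -> DedupReport:
    """Canonicalize SMILES, drop unparsable records, deduplicate by structure.

    First occurrence wins on duplicates, so output order is the input
    order of the surviving first occurrences.  An empty SMILES counts as
    invalid.  Empty input yields an empty set.
    """
    seen: dict[str, str] = {}
    kept: list[CompoundRecord] = []
    invalid: list[str] = []
    dupes: list[str] = []
    n_input = 0
    for rec in raw:
        n_input += 1
        canon = canonical_smiles(rec.smiles)
        if canon is None:
            invalid.append(rec.id)
            continue
        if canon in seen:
            dupes.append(rec.id)
            continue
        seen[canon] = rec.id
        kept.append(replace(rec, smiles=canon))
    return DedupReport(
        compounds=CompoundSet(tuple(kept)),
        n_input=n_input,
        n_invalid=len(invalid),
        n_duplicate=len(dupes),
        invalid_ids=tuple(invalid),
        duplicate_ids=tuple(dupes),
    )


def adme_filter(
    compounds: CompoundSet,
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
) -> CompoundSet:
    """Retain compounds with OB >= ob_min and DL >= dl_min (inclusive).

    Records missing either descriptor (NaN) are rejected with a logged
    warning.  Idempotent: filtering twice equals filtering once.
    """
    kept = []
    for rec in compounds:
        if math.isnan(rec.ob) or math.isnan(rec.dl):
            logger.warning(
                "compound %s rejected: missing OB/DL descriptor", rec.id
            )
            continue
        if rec.ob >= ob_min and rec.dl >= dl_min:
            kept.append(rec)
    return CompoundSet(tuple(kept))


def read_compound_csv(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table (columns id,name,smiles,ob,dl,source; UTF-8).

    ``ob``/``dl``/``source`` are optional columns; ``id`` and ``smiles``
    are required.  Raises ValueError on a missing header.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in reader.fieldnames:
            raise ValueError(f"{path}: header with a 'smiles' column is required")
        records = []
        for i, row in enumerate(reader):
            records.append(
                CompoundRecord(
                    id=str(row.get("id") or f"row{i + 1}"),
                    name=str(row.get("name") or ""),
                    smiles=str(row.get("smiles") or ""),
                    ob=_parse_float(row.get("ob")),
                    dl=_parse_float(row.get("dl")),
                    source=str(row.get("source") or ""),
                )
            )
    return records


def write_compound_csv(compounds: CompoundSet, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in compounds:
            writer.writerow([r.id, r.name, r.smiles, _fmt(r.ob), _fmt(r.dl), r.source])


def _parse_float(value: object) -> float:
    if value is None or str(value).strip() == "":
        return math.nan
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return math.nan


def _fmt(x: float) -> str:
    return "" if math.isnan(x) else repr(x)
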