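"""Per-read species assignment from tabular local-alignment hits.

Hits arrive in the standard 12-column tabular format (``-outfmt 6``).  After
an e-value cutoff, each read is assigned by a prescription-aware rule: if any
hit's subject is a prescribed species (PHS), the highest-scoring PHS hit
wins; otherwise the overall highest-scoring hit wins.  Ties break
deterministically by category (PHS > SHS > CHS), then lower e-value, then
lexicographic species name.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .prescription import Prescription, SpeciesCategory, TaxonName, classify_species

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "AssignmentRecord",
    "HitTableError",
    "load_hit_table",
    "load_species_map",
    "assign_read",
    "assign_sample",
    "DEFAULT_MAX_EVALUE",
]

DEFAULT_MAX_EVALUE = 1e-10

_CATEGORY_RANK = {
    SpeciesCategory.PHS: 0,
    SpeciesCategory.SHS: 1,
    SpeciesCategory.CHS: 2,
}


class HitTableError(ValueError):
    """Raised on malformed alignment-hit tables."""


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-species alignment candidate."""

    read_id: str
    subject_species: TaxonName
    identity: float
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.evalue < 0:
            raise HitTableError(
                f"{self.read_id}: negative bitscore/e-value ({self.bitscore}, {self.evalue})"
            )


@dataclass(frozen=True)
class AssignmentRecord:
    """The single species call for one read (species None = unassigned)."""

    read_id: str
    species: Optional[TaxonName]
    category_at_call: Optional[SpeciesCategory]
    winning_bitscore: Optional[float]

    @property
    def assigned(self) -> bool:
        return self.species is not None


def load_species_map(path: Union[str, Path]) -> dict[str, str]:
    """Sidecar TSV mapping subject ids to species names (2 columns)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise HitTableError(f"{path}:{lineno}: expected 2 columns")
        mapping[cols[0].strip()] = cols[1].strip()
    return mapping


def load_hit_table(
    path: Union[str, Path],
    species_map: Optional[Mapping[str, str]] = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> dict[str, list[AlignmentHit]]:
    """Parse a 12-column tabular hit file, grouped by read id.

    Hits with e-value above *max_evalue* are discarded at load.  Subject ids
    are resolved through *species_map* when given, else interpreted directly
    as species names (underscores read as spaces).
    """
    grouped: dict[str, list[AlignmentHit]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise HitTableError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
        read_id, subject = cols[0], cols[1]
        try:
            identity = float(cols[2])
            evalue = float(cols[10])
            bitscore = float(cols[11])
        except ValueError as exc:
            raise HitTableError(f"{path}:{lineno}: {exc}") from exc
        if evalue > max_evalue:
            continue
        if species_map is not None:
            if subject not in species_map:
                logger.warning("%s:%d: unresolvable subject id %r dropped", path, lineno, subject)
                continue
            subject = species_map[subject]
        hit = AlignmentHit(
            read_id=read_id,
            subject_species=TaxonName.parse(subject),
            identity=identity,
            bitscore=bitscore,
            evalue=evalue,
        )
        grouped.setdefault(read_id, []).append(hit)
    return grouped


def _hit_sort_key(hit: AlignmentHit, rx: Prescription):
    category = classify_species(hit.subject_species, rx)
    return (
        -hit.bitscore,
        _CATEGORY_RANK[category],
        hit.evalue,
        hit.subject_species.binomial,
    )


def assign_read(hits: Sequence[AlignmentHit], rx: Prescription) -> AssignmentRecord:
    """Assign one read: best PHS hit if any, else the overall best hit."""
    if not hits:
        read_id = ""
        return AssignmentRecord(read_id, None, None, None)
    read_id = hits[0].read_id
    phs_hits = [
        h for h in hits
        if classify_species(h.subject_species, rx) is SpeciesCategory.PHS
    ]
    pool = phs_hits if phs_hits else list(hits)
    best = min(pool, key=lambda h: _hit_sort_key(h, rx))
    return AssignmentRecord(
        read_id=read_id,
        species=best.subject_species,
        category_at_call=classify_species(best.subject_species, rx),
        winning_bitscore=best.bitscore,
    )


def assign_sample(
    grouped_hits: Mapping[str, Sequence[AlignmentHit]],
    rx: Prescription,
    all_read_ids: Optional[Iterable[str]] = None,
) -> tuple[list[AssignmentRecord], Counter, int]:
    """Assign every read of one sample/barcode.

    Returns (records, per-species read counts, number unassigned).  Reads in
    *all_read_ids* with no hits are recorded as unassigned.
    """
    records: list[AssignmentRecord] = []
    counts: Counter = Counter()
    n_unassigned = 0
    read_ids = list(all_read_ids) if all_read_ids is not None else sorted(grouped_hits)
    for read_id in read_ids:
        hits = grouped_hits.get(read_id, ())
        if not hits:
            records.append(AssignmentRecord(read_id, None, None, None))
            n_unassigned += 1
            continue
        rec = assign_read(list(hits), rx)
        records.append(rec)
        counts[rec.species.binomial] += 1
    assert sum(counts.values()) == len(records) - n_unassigned
    return records, counts, n_unassigned
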