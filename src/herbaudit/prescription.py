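"""Prescription model: herbal materials, their accepted source species, and
the PHS / SHS / CHS classification of any detected species.

A prescription maps each prescribed herbal material (PHM) to one or more
prescribed herbal species (PHS).  A detected species is a PHS if it is
prescribed, a substituted herbal species (SHS) if it merely shares a genus
with some PHS, and a contaminated herbal species (CHS) otherwise.  The three
categories partition the space of species names for a given prescription.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Union

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonName",
    "PHMEntry",
    "Prescription",
    "SpeciesCategory",
    "PrescriptionError",
    "load_prescription",
    "classify_species",
]


class PrescriptionError(ValueError):
    """Raised for malformed prescription files or entries."""


#: Tokens that start an authority / qualifier tail in a scientific name.
_QUALIFIER_TOKENS = {"var.", "var", "subsp.", "subsp", "ssp.", "ssp", "f.", "cv."}

# Authority fragments such as "L.", "Debx", "(Oliv.) Diels", "Sieb. et Zucc"
# are dropped by keeping only the first two name tokens.
_WS = re.compile(r"\s+")


def normalize_binomial(raw: str) -> str:
    """Normalize a species string to a case-folded two-token binomial.

    Case-folds, collapses whitespace, strips authority strings and trailing
    ``var./subsp.`` qualifiers by retaining the first two whitespace-delimited
    tokens.  Single-token names are returned as the bare (genus) token.
    """
    cleaned = _WS.sub(" ", raw.replace("_", " ").strip().strip("*"))
    if not cleaned:
        raise PrescriptionError(f"empty taxon name: {raw!r}")
    tokens = cleaned.split(" ")
    genus = tokens[0].strip(".,;").capitalize()
    if len(tokens) == 1:
        return genus
    epithet = tokens[1].strip(".,;").lower()
    if not epithet or epithet in _QUALIFIER_TOKENS:
        return genus
    # A hybrid sign or an abbreviated epithet is not a usable epithet.
    if epithet in {"x", "×", "sp", "sp.", "spp", "spp."}:
        return genus
    return f"{genus} {epithet}"


@dataclass(frozen=True, order=True)
class TaxonName:
    """A normalized binomial; matching is on the first two name tokens."""

    binomial: str

    def __post_init__(self) -> None:
        if not self.binomial or not self.binomial.split()[0]:
            raise PrescriptionError("TaxonName requires a non-empty genus")

    @classmethod
    def parse(cls, raw: str) -> "TaxonName":
        normalized = normalize_binomial(raw)
        if " " not in normalized:
            logger.warning(
                "taxon %r has a single token; genus-only matching applies", raw
            )
        return cls(normalized)

    @property
    def genus(self) -> str:
        return self.binomial.split(" ", 1)[0]

    @property
    def is_binomial(self) -> bool:
        return " " in self.binomial

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.binomial


class SpeciesCategory(str, Enum):
    """Audit category of a detected species relative to a prescription."""

    PHS = "PHS"
    SHS = "SHS"
    CHS = "CHS"


@dataclass(frozen=True)
class PHMEntry:
    """One prescribed herbal material and its accepted source species."""

    phm_name: str
    phs: frozenset[TaxonName]
    processed: bool = False

    def __post_init__(self) -> None:
        if not self.phm_name:
            raise PrescriptionError("PHM name must be non-empty")
        if not self.phs:
            raise PrescriptionError(f"PHM {self.phm_name!r} has an empty PHS list")


@dataclass(frozen=True)
class Prescription:
    """A preparation's many-to-many PHM -> PHS map."""

    preparation: str
    phms: tuple[PHMEntry, ...]
    _species_to_phms: Mapping[TaxonName, frozenset[str]] = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        if not self.phms:
            raise PrescriptionError("a prescription needs at least one PHM")
        names = [e.phm_name for e in self.phms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PrescriptionError(f"duplicate PHM names: {dupes}")
        mapping: dict[TaxonName, set[str]] = {}
        for entry in self.phms:
            for sp in entry.phs:
                mapping.setdefault(sp, set()).add(entry.phm_name)
        object.__setattr__(
            self,
            "_species_to_phms",
            {sp: frozenset(ms) for sp, ms in mapping.items()},
        )

    @property
    def phs_universe(self) -> frozenset[TaxonName]:
        return frozenset(self._species_to_phms)

    @property
    def phs_genera(self) -> frozenset[str]:
        return frozenset(sp.genus for sp in self.phs_universe)

    @property
    def phm_names(self) -> tuple[str, ...]:
        return tuple(e.phm_name for e in self.phms)

    def phms_for_species(self, species: TaxonName) -> frozenset[str]:
        """All PHM names that list *species* as a source (empty if none)."""
        return self._species_to_phms.get(species, frozenset())

    def classify(self, species: TaxonName) -> SpeciesCategory:
        return classify_species(species, self)


def classify_species(species: TaxonName, rx: Prescription) -> SpeciesCategory:
    """Classify a detected species as PHS, SHS, or CHS.

    PHS if the species is prescribed; SHS if only its genus is prescribed;
    CHS otherwise.  Genus-only names can never be PHS, only SHS/CHS.
    """
    if species.is_binomial and species in rx.phs_universe:
        return SpeciesCategory.PHS
    if species.genus in rx.phs_genera:
        if not species.is_binomial:
            logger.warning(
                "genus-only name %r classified by genus match", species.binomial
            )
        return SpeciesCategory.SHS
    return SpeciesCategory.CHS


def _entry_from_fields(phm: str, phs_raw: Iterable[str], processed) -> PHMEntry:
    species = frozenset(TaxonName.parse(s) for s in phs_raw if str(s).strip())
    if isinstance(processed, str):
        processed = processed.strip().lower() in {"1", "true", "yes", "y"}
    return PHMEntry(phm_name=phm.strip(), phs=species, processed=bool(processed))


def load_prescription(path: Union[str, Path]) -> Prescription:
    """Load a prescription from TSV or JSON.

    TSV columns: ``preparation, phm, phs_semicolon_list, processed``.
    JSON schema: ``{"preparation": ..., "phms": [{"phm": ..., "phs": [...],
    "processed": bool}, ...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise PrescriptionError(f"prescription file not found: {path}")
    if path.suffix.lower() == ".json":
        return _load_json(path)
    return _load_tsv(path)


def _load_json(path: Path) -> Prescription:
    data = json.loads(path.read_text())
    try:
        preparation = data["preparation"]
        entries = [
            _entry_from_fields(e["phm"], e["phs"], e.get("processed", False))
            for e in data["phms"]
        ]
    except (KeyError, TypeError) as exc:
        raise PrescriptionError(f"bad prescription schema in {path}: {exc}") from exc
    return Prescription(preparation=preparation, phms=tuple(entries))


def _load_tsv(path: Path) -> Prescription:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise PrescriptionError(f"empty prescription file: {path}")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    required = {"preparation", "phm", "phs", "processed"}
    if not required.issubset(header):
        raise PrescriptionError(
            f"{path}: header must contain {sorted(required)}, got {header}"
        )
    idx = {name: header.index(name) for name in required}
    preparation = None
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) < len(header):
            raise PrescriptionError(f"{path}:{lineno}: expected {len(header)} columns")
        prep = cols[idx["preparation"]].strip()
        preparation = preparation or prep
        if prep != preparation:
            raise PrescriptionError(
                f"{path}:{lineno}: mixed preparations {preparation!r}/{prep!r}"
            )
        entries.append(
            _entry_from_fields(
                cols[idx["phm"]],
                cols[idx["phs"]].split(";"),
                cols[idx["processed"]],
            )
        )
    return Prescription(preparation=preparation, phms=tuple(entries))
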