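"""Audit of detected species against a prescription.

Per sample: classify every post-threshold species as PHS / SHS / CHS.
Per preparation: pool the detected PHS over all samples, map them to the
materials (PHMs) they source, and report the sensitivity statistic

    sensitivity = 100 * detected PHMs / PHMs detectable in theory

rounded half-up to one decimal.  Detection reports from different barcodes
can be merged by set union, with sensitivity recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .abundance import AbundanceTable
from .prescription import Prescription, SpeciesCategory, TaxonName, classify_species

__all__ = [
    "AuditSummary",
    "DetectionReport",
    "audit_sample",
    "detect_phms",
    "sensitivity",
    "make_report",
    "union_barcodes",
    "presence_matrix",
]

UNION_LABEL = "UNION"


@dataclass(frozen=True)
class AuditSummary:
    """Detected species of one sample, split into the three audit categories."""

    sample_id: str
    barcode_label: str
    phs: frozenset[TaxonName]
    shs: frozenset[TaxonName]
    chs: frozenset[TaxonName]

    def __post_init__(self) -> None:
        if self.phs & self.shs or self.phs & self.chs or self.shs & self.chs:
            raise ValueError("audit categories must be disjoint")

    @property
    def n_phs(self) -> int:
        return len(self.phs)

    @property
    def n_shs(self) -> int:
        return len(self.shs)

    @property
    def n_chs(self) -> int:
        return len(self.chs)


@dataclass(frozen=True)
class DetectionReport:
    """Preparation-level detection outcome for one barcode (or the union)."""

    preparation: str
    barcode_label: str
    detected_phs: frozenset[TaxonName]
    detected_phms: frozenset[str]
    n_phms_total: int
    sensitivity_pct: float

    def to_dict(self) -> dict:
        return {
            "preparation": self.preparation,
            "barcode_label": self.barcode_label,
            "detected_phs": sorted(t.binomial for t in self.detected_phs),
            "detected_phms": sorted(self.detected_phms),
            "n_phms_total": self.n_phms_total,
            "sensitivity_pct": self.sensitivity_pct,
        }


def audit_sample(
    row_counts: Mapping[Union[str, TaxonName], int],
    rx: Prescription,
    sample_id: str = "",
    barcode_label: str = "",
) -> AuditSummary:
    """Classify every species with a positive count in one (filtered) row."""
    buckets: dict[SpeciesCategory, set[TaxonName]] = {c: set() for c in SpeciesCategory}
    for species, count in row_counts.items():
        if count <= 0:
            continue
        taxon = species if isinstance(species, TaxonName) else TaxonName.parse(species)
        buckets[classify_species(taxon, rx)].add(taxon)
    return AuditSummary(
        sample_id=sample_id,
        barcode_label=barcode_label,
        phs=frozenset(buckets[SpeciesCategory.PHS]),
        shs=frozenset(buckets[SpeciesCategory.SHS]),
        chs=frozenset(buckets[SpeciesCategory.CHS]),
    )


def audit_table(table: AbundanceTable, rx: Prescription) -> list[AuditSummary]:
    """Audit every sample row of a (filtered) abundance table."""
    return [
        audit_sample(table.row_counts(sid), rx, sample_id=sid,
                     barcode_label=table.barcode_label)
        for sid in table.samples
    ]


def detect_phms(
    summaries: Iterable[Union[AuditSummary, frozenset, set]],
    rx: Prescription,
) -> frozenset[str]:
    """PHMs detected for a preparation: union of detected PHS over samples.

    A PHM counts as detected as soon as one of its PHS appears in at least
    one sample; a PHS shared by several PHMs marks all of them detected.
    Accepts AuditSummary objects or bare PHS sets.
    """
    detected: set[str] = set()
    for item in summaries:
        phs_set = item.phs if isinstance(item, AuditSummary) else item
        for species in phs_set:
            detected |= rx.phms_for_species(species)
    return frozenset(detected)


def sensitivity(
    detected_phms: Union[Iterable[str], int], rx: Prescription
) -> float:
    """Detected PHMs over prescription PHMs, as a percent, half-up 1 decimal."""
    n_total = len(rx.phms)
    if n_total == 0:  # unreachable: Prescription enforces >= 1 PHM
        raise ValueError("empty prescription")
    if isinstance(detected_phms, int):
        n_detected = detected_phms
    else:
        detected = set(detected_phms)
        unknown = detected - set(rx.phm_names)
        if unknown:
            raise ValueError(f"detected PHMs not in prescription: {sorted(unknown)}")
        n_detected = len(detected)
    if not 0 <= n_detected <= n_total:
        raise ValueError(f"detected count {n_detected} outside [0, {n_total}]")
    pct = Decimal(100 * n_detected) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def make_report(
    detected_phs: Iterable[TaxonName],
    rx: Prescription,
    barcode_label: str,
) -> DetectionReport:
    """Build a preparation-level report from a pooled detected-PHS set."""
    phs = frozenset(detected_phs)
    stray = {t for t in phs if t not in rx.phs_universe}
    if stray:
        raise ValueError(
            f"species not prescribed for {rx.preparation}: "
            f"{sorted(t.binomial for t in stray)}"
        )
    phms = detect_phms([phs], rx)
    return DetectionReport(
        preparation=rx.preparation,
        barcode_label=barcode_label,
        detected_phs=phs,
        detected_phms=phms,
        n_phms_total=len(rx.phms),
        sensitivity_pct=sensitivity(phms, rx),
    )


def union_barcodes(
    reports: Sequence[DetectionReport], rx: Prescription
) -> DetectionReport:
    """Merge per-barcode reports of one preparation by set union."""
    if not reports:
        raise ValueError("no reports to merge")
    preparations = {r.preparation for r in reports}
    if len(preparations) != 1 or preparations != {rx.preparation}:
        raise ValueError(
            f"reports cover {sorted(preparations)}, prescription is {rx.preparation!r}"
        )
    phs = frozenset().union(*(r.detected_phs for r in reports))
    phms = frozenset().union(*(r.detected_phms for r in reports))
    return DetectionReport(
        preparation=rx.preparation,
        barcode_label=UNION_LABEL,
        detected_phs=phs,
        detected_phms=phms,
        n_phms_total=len(rx.phms),
        sensitivity_pct=sensitivity(phms, rx),
    )


def presence_matrix(
    table: AbundanceTable, rx: Prescription
) -> pd.DataFrame:
    """Binary samples x PHS matrix: 1 iff the PHS survives thresholding.

    Columns span the full prescription PHS universe (sorted); row order
    follows the table's sample order.
    """
    universe = sorted(t.binomial for t in rx.phs_universe)
    matrix = pd.DataFrame(0, index=table.samples, columns=universe, dtype=int)
    for sid in table.samples:
        summary = audit_sample(table.row_counts(sid), rx, sample_id=sid)
        for species in summary.phs:
            matrix.loc[sid, species.binomial] = 1
    return matrix
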