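"""Demultiplexing, primer trimming, and per-barcode quality/length filters.

Reads carry 7-bp sample tags (MIDs) at both ends, then the amplification
primers, then the insert.  Demultiplexing requires exact dual-MID matches;
primer excision is IUPAC-aware; the quality filter rejects a read if any
rolling 5-bp window has mean Phred below 20, if it contains an N, a
homopolymer run longer than 8, or falls outside the barcode's length bounds
(ITS2: 150-510 bp, trnL: >= 75 bp).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

__all__ = [
    "SequenceRead",
    "BarcodeSpec",
    "QCParams",
    "QCResult",
    "demultiplex",
    "trim_primers",
    "qc_filter",
    "qc_stats",
    "run_qc",
    "read_fastq",
    "write_fastq",
    "load_barcode_sheet",
    "reverse_complement",
    "iupac_match",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


_PLAIN = frozenset("ACGT")


def iupac_match(pattern: str, text: str, max_mismatches: int = 0) -> bool:
    """True if *text* matches the IUPAC *pattern* with <= max_mismatches."""
    if len(pattern) != len(text):
        return False
    pattern = pattern.upper()
    text = text.upper()
    if max_mismatches == 0 and set(pattern) <= _PLAIN:
        return pattern == text
    mism = 0
    for p, t in zip(pattern, text):
        if t not in IUPAC.get(p, frozenset()):
            mism += 1
            if mism > max_mismatches:
                return False
    return True


@dataclass(frozen=True)
class SequenceRead:
    """One (pre-merged) amplicon read with per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.read_id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "SequenceRead":
        return SequenceRead(self.read_id, self.bases[start:stop], self.quals[start:stop])


@dataclass(frozen=True)
class BarcodeSpec:
    """Per-sample MID tags plus the primer pair for one barcode region."""

    sample_id: str
    mid_fwd: str
    mid_rev: str
    primer_fwd: str
    primer_rev: str
    barcode_label: str  # "ITS2" or "trnL"

    def __post_init__(self) -> None:
        for mid in (self.mid_fwd, self.mid_rev):
            if len(mid) != 7:
                raise ValueError(f"{self.sample_id}: MID tags must be 7 bp, got {mid!r}")


#: Per-barcode length bounds (min, max); None = unbounded.
LENGTH_BOUNDS = {"ITS2": (150, 510), "trnL": (75, None)}

#: Per-barcode relative-abundance thresholds live in :mod:`herbaudit.abundance`.


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds; defaults follow the published protocol."""

    min_len: int = 150
    max_len: Optional[int] = 510
    window: int = 5
    min_window_q: float = 20.0
    max_homopolymer: int = 8
    max_barcode_errors: int = 0
    max_primer_mismatches: int = 0
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_len < 1:
            raise ValueError("window and min_len must be positive")
        if self.max_len is not None and self.max_len < self.min_len:
            raise ValueError("max_len < min_len")

    @classmethod
    def for_barcode(cls, label: str, **overrides) -> "QCParams":
        try:
            lo, hi = LENGTH_BOUNDS[label]
        except KeyError:
            raise ValueError(f"unknown barcode label {label!r}") from None
        return cls(min_len=lo, max_len=hi, **overrides)


@dataclass
class QCResult:
    """Kept reads per sample plus every rejected read with its reason."""

    kept: dict[str, list[SequenceRead]]
    rejected: list[tuple[SequenceRead, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return sum(len(v) for v in self.kept.values()) + len(self.rejected)


def demultiplex(
    reads: Iterable[SequenceRead],
    specs: Sequence[BarcodeSpec],
    both_orientations: bool = False,
) -> tuple[dict[str, list[SequenceRead]], list[tuple[SequenceRead, str]]]:
    """Assign reads to samples by exact dual 7-bp MID match; strip the MIDs.

    The read layout is ``mid_fwd + ... + revcomp(mid_rev)``.  With
    ``both_orientations`` the reverse-complemented read is also tried.
    Returns (sample_id -> reads, rejects with reason).
    """
    lookup: dict[tuple[str, str], str] = {}
    for spec in specs:
        key = (spec.mid_fwd.upper(), reverse_complement(spec.mid_rev))
        if key in lookup:
            raise ValueError(
                f"duplicate MID pair for samples {lookup[key]!r} and {spec.sample_id!r}"
            )
        lookup[key] = spec.sample_id

    assigned: dict[str, list[SequenceRead]] = {s.sample_id: [] for s in specs}
    rejects: list[tuple[SequenceRead, str]] = []
    for read in reads:
        target = _match_mids(read, lookup)
        if target is None and both_orientations:
            flipped = SequenceRead(
                read.read_id, reverse_complement(read.bases), read.quals[::-1]
            )
            target = _match_mids(flipped, lookup)
            read = flipped if target is not None else read
        if target is None:
            rejects.append((read, "barcode"))
        else:
            assigned[target].append(read.slice(7, len(read) - 7))
    return assigned, rejects


def _match_mids(read: SequenceRead, lookup) -> Optional[str]:
    if len(read) < 14:
        return None
    return lookup.get((read.bases[:7].upper(), read.bases[-7:].upper()))


def trim_primers(
    read: SequenceRead, spec: BarcodeSpec, params: QCParams
) -> Optional[SequenceRead]:
    """Excise both primers (MIDs already removed); None if either is missing.

    The forward primer must match at the 5' end and the reverse complement of
    the reverse primer at the 3' end, each with at most
    ``params.max_primer_mismatches`` mismatches under IUPAC semantics.
    """
    fwd = spec.primer_fwd.upper()
    rev = reverse_complement(spec.primer_rev)
    if len(fwd) + len(rev) > len(read):
        return None
    if not iupac_match(fwd, read.bases[: len(fwd)], params.max_primer_mismatches):
        return None
    if not iupac_match(rev, read.bases[len(read) - len(rev):], params.max_primer_mismatches):
        return None
    return read.slice(len(fwd), len(read) - len(rev))


def qc_filter(read: SequenceRead, label: str, params: Optional[QCParams] = None) -> Optional[str]:
    """Return a rejection reason, or None when the read passes all filters.

    Checks, in order: length bounds, ambiguous bases, homopolymer runs, and
    the rolling window mean-quality rule (reads shorter than the window are
    evaluated as a single window).
    """
    if params is None:
        params = QCParams.for_barcode(label)
    n = len(read)
    if n < params.min_len or (params.max_len is not None and n > params.max_len):
        return "length"
    bases = read.bases.upper()
    if "N" in bases:
        return "ambiguous"
    run = params.max_homopolymer + 1
    if run == 9:  # substring probes beat the regex on the default setting
        if "A" * 9 in bases or "C" * 9 in bases or "G" * 9 in bases \
                or "T" * 9 in bases:
            return "homopolymer"
    else:
        if re.search(r"(.)\1{%d,}" % params.max_homopolymer, bases):
            return "homopolymer"
    if _has_low_quality_window(read.quals, params.window, params.min_window_q):
        return "quality"
    return None


def _has_low_quality_window(quals: Sequence[int], window: int, min_q: float) -> bool:
    q = np.asarray(quals)
    if q.size == 0:
        return True
    if q.min() >= min_q:  # no window of all-good bases can dip below
        return False
    if q.size <= window:
        return float(q.mean()) < min_q
    csum = q.cumsum(dtype=np.float64)
    sums = csum[window - 1:].copy()
    sums[1:] -= csum[:-window]
    return bool((sums < min_q * window).any())


def run_qc(
    reads: Iterable[SequenceRead],
    specs: Sequence[BarcodeSpec],
    params: Optional[QCParams] = None,
    both_orientations: bool = False,
) -> QCResult:
    """Full per-read QC: demultiplex -> primer trim -> quality/length filter."""
    if params is None:
        params = QCParams.for_barcode(specs[0].barcode_label)
    by_sample = {s.sample_id: s for s in specs}
    assigned, rejects = demultiplex(reads, specs, both_orientations)
    kept: dict[str, list[SequenceRead]] = {s: [] for s in assigned}
    result = QCResult(kept=kept, rejected=list(rejects))
    for sample_id, sample_reads in assigned.items():
        spec = by_sample[sample_id]
        for read in sample_reads:
            trimmed = trim_primers(read, spec, params)
            if trimmed is None:
                result.rejected.append((read, "primer"))
                continue
            reason = qc_filter(trimmed, spec.barcode_label, params)
            if reason is None:
                kept[sample_id].append(trimmed)
            else:
                result.rejected.append((trimmed, reason))
    return result


def qc_stats(result: QCResult):
    """Tabulate kept/rejected counts by reason (rejects are not per-sample)."""
    import pandas as pd

    reasons = sorted({reason for _, reason in result.rejected})
    rows = {sid: {"kept": len(reads)} for sid, reads in result.kept.items()}
    totals = {"kept": sum(len(r) for r in result.kept.values())}
    for reason in reasons:
        totals[reason] = sum(1 for _, r in result.rejected if r == reason)
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    frame = frame.sort_index()
    frame.attrs["rejected_by_reason"] = {r: totals[r] for r in reasons}
    frame.attrs["n_input"] = result.n_input
    assert totals["kept"] + sum(totals[r] for r in reasons) == result.n_input
    return frame


# ---------------------------------------------------------------------------
# FASTQ / sheet I/O


def read_fastq(path: Union[str, Path], phred_offset: int = 33) -> Iterator[SequenceRead]:
    """Stream FASTQ records (gzip-transparent) as :class:`SequenceRead`."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield SequenceRead(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(
    reads: Iterable[SequenceRead], path: Union[str, Path], phred_offset: int = 33
) -> int:
    """Write reads as plain FASTQ; returns the record count."""
    n = 0
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            qline = "".join(chr(q + phred_offset) for q in read.quals)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qline}\n")
            n += 1
    return n


def load_barcode_sheet(path: Union[str, Path]) -> list[BarcodeSpec]:
    """Load a MID/primer sheet (TSV: sample_id, mid_fwd, mid_rev,
    primer_fwd, primer_rev, barcode_label)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "mid_fwd", "mid_rev", "primer_fwd", "primer_rev", "barcode_label"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"barcode sheet {path} missing columns {missing}")
    return [BarcodeSpec(**{k: row[k] for k in required}) for _, row in frame.iterrows()]
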