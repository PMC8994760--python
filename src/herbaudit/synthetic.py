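"""Synthetic reference databases, prescriptions, reads and hit tables.

Everything needed to exercise the pipeline hermetically: congener-structured
reference sequences per barcode, per-sample species mixtures with optional
congeneric substitution, contamination and processed-material dropout,
MID/primer-wrapped reads with configurable error and quality profiles, and
alignment-hit tables consistent with the reads — all with a ground-truth
manifest and a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .prescription import PHMEntry, Prescription, TaxonName
from .read_qc import BarcodeSpec, SequenceRead, reverse_complement
from .taxonomy import AlignmentHit

__all__ = [
    "ReferenceDB",
    "SimParams",
    "TruthManifest",
    "DEFAULT_PRIMERS",
    "make_reference",
    "make_barcode_specs",
    "make_demo_prescription",
    "simulate_reads",
    "simulate_hits",
    "write_hit_table",
    "simulate_two_group_table",
    "planted_marker_design",
]

#: Default amplification primer pairs (forward, reverse) per barcode.
DEFAULT_PRIMERS = {
    "ITS2": ("ATGCGATACTTGGTGTGAAT", "TCCTCCGCTTATTGATATGC"),
    "trnL": ("CGAAATCGGTAGACGCTACG", "CCATTGAGTCTCTGCACCTATC"),
}

#: Insert-length regimes per barcode (min, max), inside the QC length bounds.
LENGTH_REGIMES = {"ITS2": (160, 450), "trnL": (75, 250)}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ReferenceDB:
    """Per-barcode species -> reference sequence, with congener structure."""

    sequences: Mapping[str, Mapping[str, str]]  # barcode -> binomial -> seq
    seed: int

    def barcodes(self) -> list[str]:
        return list(self.sequences)

    def species(self, barcode: str) -> list[str]:
        return sorted(self.sequences[barcode])

    def congeners(self, barcode: str, species: str) -> list[str]:
        genus = species.split(" ", 1)[0]
        return sorted(
            s for s in self.sequences[barcode]
            if s != species and s.split(" ", 1)[0] == genus
        )

    def write_fasta(self, path: Union[str, Path], barcode: str) -> None:
        with open(path, "w") as out:
            for name in self.species(barcode):
                out.write(f">{name.replace(' ', '_')}\n{self.sequences[barcode][name]}\n")


def _random_seq(rng: np.random.Generator, length: int, max_run: int = 6) -> str:
    """Random sequence with homopolymer runs capped at *max_run*."""
    while True:
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        if not _has_long_run(seq, max_run):
            return seq


def _has_long_run(seq: str, max_run: int) -> bool:
    run, prev = 1, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        if run > max_run:
            return True
        prev = ch
    return False


def _mutate(rng: np.random.Generator, seq: str, rate: float, max_run: int = 6) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    while True:
        n_mut = max(int(round(rate * len(seq))), 1)
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        out = arr.copy()
        for p in pos:
            choices = _BASES[_BASES != out[p]]
            out[p] = rng.choice(choices)
        mutated = out.tobytes().decode()
        if not _has_long_run(mutated, max_run):
            return mutated


def make_reference(
    n_genera: int,
    species_per_genus: int,
    seed: int = 0,
    barcodes: Sequence[str] = ("ITS2", "trnL"),
) -> ReferenceDB:
    """Generate a congener-structured reference database.

    Species of a genus derive from a shared ancestor at 2-5% divergence, so
    within-genus identity is high while cross-genus sequences are unrelated
    random draws.  Byte-identical output for identical seeds.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    sequences: dict[str, dict[str, str]] = {}
    names = [
        (f"Simgenus{g:02d}", f"Simgenus{g:02d} sp{s:02d}")
        for g in range(n_genera)
        for s in range(species_per_genus)
    ]
    for barcode in barcodes:
        lo, hi = LENGTH_REGIMES[barcode]
        table: dict[str, str] = {}
        for g in range(n_genera):
            length = int(rng.integers(lo, hi + 1))
            ancestor = _random_seq(rng, length)
            for s in range(species_per_genus):
                divergence = float(rng.uniform(0.02, 0.05))
                table[f"Simgenus{g:02d} sp{s:02d}"] = _mutate(rng, ancestor, divergence)
        sequences[barcode] = table
    return ReferenceDB(sequences=sequences, seed=seed)


def make_barcode_specs(
    sample_ids: Sequence[str], barcode_label: str, seed: int = 0
) -> list[BarcodeSpec]:
    """Random distinct 7-bp dual MIDs plus the default primer pair."""
    primer_fwd, primer_rev = DEFAULT_PRIMERS[barcode_label]
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, str]] = set()
    specs = []
    for sid in sample_ids:
        while True:
            mid_f = _random_seq(rng, 7, max_run=4)
            mid_r = _random_seq(rng, 7, max_run=4)
            if (mid_f, mid_r) not in seen:
                seen.add((mid_f, mid_r))
                break
        specs.append(
            BarcodeSpec(
                sample_id=sid,
                mid_fwd=mid_f,
                mid_rev=mid_r,
                primer_fwd=primer_fwd,
                primer_rev=primer_rev,
                barcode_label=barcode_label,
            )
        )
    return specs


def make_demo_prescription(
    db: ReferenceDB,
    n_phms: int,
    phs_per_phm: int = 1,
    processed_phms: Sequence[str] = (),
    preparation: str = "DEMO",
    barcode: Optional[str] = None,
) -> Prescription:
    """Build a prescription over the reference species, one genus per PHM."""
    barcode = barcode or db.barcodes()[0]
    genera: dict[str, list[str]] = {}
    for sp in db.species(barcode):
        genera.setdefault(sp.split(" ", 1)[0], []).append(sp)
    if len(genera) < n_phms:
        raise ValueError(f"reference has only {len(genera)} genera, need {n_phms}")
    entries = []
    for i, genus in enumerate(sorted(genera)[:n_phms]):
        name = f"PHM{i:02d}"
        phs = frozenset(
            TaxonName.parse(s) for s in sorted(genera[genus])[:phs_per_phm]
        )
        entries.append(
            PHMEntry(phm_name=name, phs=phs, processed=name in processed_phms)
        )
    return Prescription(preparation=preparation, phms=tuple(entries))


@dataclass(frozen=True)
class SimParams:
    """Knobs for one read-simulation run (one barcode)."""

    barcode_label: str
    composition: Mapping[str, Mapping[str, float]]  # sample -> species -> rel
    depth: int = 10_000
    substitution_rate: float = 0.0
    contamination: tuple[tuple[str, float], ...] = ()
    degradation: Mapping[str, float] = field(default_factory=dict)
    error_rate: float = 0.001
    quality_mean: float = 34.0
    quality_sd: float = 3.0
    low_quality_fraction: float = 0.0
    homopolymer_fraction: float = 0.0
    count_mode: str = "multinomial"  # or "exact"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.error_rate,
                     self.low_quality_fraction, self.homopolymer_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for phm, dropout in self.degradation.items():
            if not 0.0 <= dropout <= 1.0:
                raise ValueError(f"dropout for {phm!r} outside [0, 1]")
        for sid, comp in self.composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"composition of {sid!r} sums to {total}, not 1")
        if self.count_mode not in {"multinomial", "exact"}:
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class TruthManifest:
    """Ground truth for one simulated barcode run."""

    barcode_label: str
    read_origin: dict[str, tuple[str, str]]  # read_id -> (sample, species)
    true_abundances: dict[str, dict[str, float]]  # realized origin fractions
    specs: list[BarcodeSpec]
    seed: int

    def reads_of_sample(self, sample_id: str) -> list[str]:
        return [rid for rid, (sid, _) in self.read_origin.items() if sid == sample_id]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministic integer apportionment of *total* by *weights*."""
    target = weights / weights.sum() * total
    counts = np.floor(target).astype(np.int64)
    remainder = total - int(counts.sum())
    if remainder > 0:
        order = np.argsort(-(target - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _effective_weights(
    comp: Mapping[str, float],
    rx: Optional[Prescription],
    params: SimParams,
    db: ReferenceDB,
    rng: np.random.Generator,
) -> dict[str, float]:
    weights = dict(comp)
    # congeneric substitution: move a fraction of each prescribed species'
    # mass to its first congener in the reference
    if params.substitution_rate > 0 and rx is not None:
        for species in list(weights):
            taxon = TaxonName.parse(species)
            if taxon not in rx.phs_universe:
                continue
            congeners = [
                c for c in db.congeners(params.barcode_label, species)
                if c not in weights
            ]
            if not congeners:
                continue
            moved = weights[species] * params.substitution_rate
            weights[species] -= moved
            weights[congeners[0]] = weights.get(congeners[0], 0.0) + moved
    # contamination on top: scale the base mixture into the remaining mass
    contam_total = sum(a for _, a in params.contamination)
    if contam_total >= 1.0:
        raise ValueError("contamination abundances must sum to < 1")
    if params.contamination:
        weights = {s: w * (1.0 - contam_total) for s, w in weights.items()}
        for species, abundance in params.contamination:
            weights[species] = weights.get(species, 0.0) + abundance
    # degradation: a species survives through its least-degraded material
    if params.degradation and rx is not None:
        for species in list(weights):
            phms = rx.phms_for_species(TaxonName.parse(species))
            if not phms:
                continue
            survival = max(1.0 - params.degradation.get(p, 0.0) for p in phms)
            weights[species] *= survival
    return {s: w for s, w in weights.items() if w > 0.0}


def simulate_reads(
    rx: Optional[Prescription],
    db: ReferenceDB,
    params: SimParams,
) -> tuple[dict[str, list[SequenceRead]], TruthManifest]:
    """Simulate MID/primer-wrapped reads for every sample of one barcode.

    Sequencing errors are confined to the insert so that tag and primer
    handling stays exact under the zero-mismatch policy.  Returns
    (sample -> reads, manifest); manifest read ids exactly match the reads.
    """
    barcode = params.barcode_label
    available = set(db.species(barcode))
    specs = make_barcode_specs(sorted(params.composition), barcode, seed=params.seed)
    spec_of = {s.sample_id: s for s in specs}
    rng = np.random.default_rng(params.seed)

    reads_by_sample: dict[str, list[SequenceRead]] = {}
    origin: dict[str, tuple[str, str]] = {}
    true_abund: dict[str, dict[str, float]] = {}

    for sample_id in sorted(params.composition):
        comp = params.composition[sample_id]
        missing = {s for s in comp} - available
        if missing:
            raise ValueError(
                f"{sample_id}: species absent from {barcode} reference: {sorted(missing)}"
            )
        weights = _effective_weights(comp, rx, params, db, rng)
        missing = set(weights) - available
        if missing:
            raise ValueError(
                f"{sample_id}: species absent from {barcode} reference: {sorted(missing)}"
            )
        species_list = sorted(weights)
        w = np.asarray([weights[s] for s in species_list], dtype=float)
        if params.count_mode == "exact":
            counts = _largest_remainder(w, int(round(params.depth * w.sum())))
        else:
            probs = np.append(w, max(1.0 - w.sum(), 0.0))
            counts = rng.multinomial(params.depth, probs / probs.sum())[:-1]

        spec = spec_of[sample_id]
        sample_reads: list[SequenceRead] = []
        idx = 0
        for species, count in zip(species_list, counts):
            if count == 0:
                continue
            insert = db.sequences[barcode][species]
            for read in _emit_reads(
                rng, spec, insert, int(count), params,
                id_prefix=f"{sample_id}|{barcode}|", id_start=idx,
            ):
                origin[read.read_id] = (sample_id, species)
                sample_reads.append(read)
            idx += int(count)
        total = len(sample_reads)
        true_abund[sample_id] = {
            s: int(c) / total if total else 0.0
            for s, c in zip(species_list, counts) if c > 0
        }
        reads_by_sample[sample_id] = sample_reads

    manifest = TruthManifest(
        barcode_label=barcode,
        read_origin=origin,
        true_abundances=true_abund,
        specs=specs,
        seed=params.seed,
    )
    return reads_by_sample, manifest


def _emit_reads(
    rng: np.random.Generator,
    spec: BarcodeSpec,
    insert: str,
    count: int,
    params: SimParams,
    id_prefix: str,
    id_start: int,
) -> Iterable[SequenceRead]:
    prefix = spec.mid_fwd + spec.primer_fwd
    suffix = reverse_complement(spec.primer_rev) + reverse_complement(spec.mid_rev)
    total_len = len(prefix) + len(insert) + len(suffix)
    insert_arr = np.frombuffer(insert.encode(), dtype="S1")

    n_err = rng.binomial(len(insert), params.error_rate, size=count)
    quals = np.clip(
        np.rint(rng.normal(params.quality_mean, params.quality_sd,
                           size=(count, total_len))),
        2, 41,
    ).astype(np.int16)
    n_lowq = int(math.floor(count * params.low_quality_fraction))
    n_homo = int(math.floor(count * params.homopolymer_fraction))
    tail = min(30, len(insert))

    for i in range(count):
        if n_err[i] > 0:
            arr = insert_arr.copy()
            for p in rng.choice(len(insert), size=n_err[i], replace=False):
                arr[p] = rng.choice(_BASES[_BASES != arr[p]])
            body = arr.tobytes().decode()
        else:
            body = insert
        if i < n_homo and len(insert) >= 12:
            mid = len(insert) // 2
            body = body[: mid - 5] + "A" * 10 + body[mid + 5:]
        q = quals[i]
        if n_homo <= i < n_homo + n_lowq:
            q = q.copy()
            q[-(tail + len(suffix)):] = 12
        yield SequenceRead(
            read_id=f"{id_prefix}r{id_start + i:06d}",
            bases=prefix + body + suffix,
            quals=q,
        )


def simulate_hits(
    manifest: TruthManifest,
    db: ReferenceDB,
    score_noise: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[AlignmentHit]]:
    """Alignment hits consistent with the manifest, bypassing an aligner.

    Each read receives a top hit to its true species, congener hits at
    strictly lower (noise-perturbed) bitscores, and with probability
    *fp_rate* an extra cross-genus hit at a lower score still.  E-values
    decrease monotonically with bitscore.
    """
    rng = np.random.default_rng(seed)
    barcode = manifest.barcode_label
    taxa = {s: TaxonName.parse(s) for s in db.species(barcode)}
    congener_cache = {s: db.congeners(barcode, s) for s in db.species(barcode)}
    all_species = db.species(barcode)

    grouped: dict[str, list[AlignmentHit]] = {}
    for read_id, (_, species) in manifest.read_origin.items():
        length = len(db.sequences[barcode][species])
        base = 1.8 * length + (rng.normal(0.0, score_noise) if score_noise else 0.0)
        hits = [_hit(read_id, taxa[species], 99.0, base)]
        for rank, congener in enumerate(congener_cache[species], start=1):
            score = base - 15.0 * rank
            if score_noise:
                score -= abs(rng.normal(0.0, score_noise))
            hits.append(_hit(read_id, taxa[congener], 99.0 - 3.0 * rank, score))
        if fp_rate and rng.random() < fp_rate:
            genus = species.split(" ", 1)[0]
            others = [s for s in all_species if not s.startswith(genus + " ")]
            if others:
                fp = others[int(rng.integers(len(others)))]
                hits.append(_hit(read_id, taxa[fp], 85.0, max(base - 50.0, 60.0)))
        grouped[read_id] = hits
    return grouped


def _hit(read_id: str, taxon: TaxonName, identity: float, bitscore: float) -> AlignmentHit:
    bitscore = max(bitscore, 60.0)
    evalue = 10.0 ** max(-bitscore / 10.0, -180.0)
    return AlignmentHit(
        read_id=read_id,
        subject_species=taxon,
        identity=identity,
        bitscore=round(bitscore, 1),
        evalue=evalue,
    )


def write_hit_table(
    grouped: Mapping[str, Sequence[AlignmentHit]], path: Union[str, Path]
) -> int:
    """Write hits in the 12-column tabular alignment format; returns rows."""
    n = 0
    with open(path, "w") as out:
        for read_id in grouped:
            for h in grouped[read_id]:
                subject = h.subject_species.binomial.replace(" ", "_")
                length = 100
                out.write(
                    f"{h.read_id}\t{subject}\t{h.identity:.1f}\t{length}\t0\t0\t"
                    f"1\t{length}\t1\t{length}\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
                )
                n += 1
    return n


# ---------------------------------------------------------------------------
# Two-group designs for the biomarker pipeline


def planted_marker_design(
    effect: float = 4.0,
    n_background: int = 30,
    base_level: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float], dict[str, list[str]]]:
    """Two compositions differing ONLY in three planted marker species.

    The marker mass shifts balance out (+2d vs -d/-d with d =
    ``10**effect / 1e6``), so every background species has identical
    expected relative abundance in both groups.  Returns
    (composition_a, composition_b, {"A": [...], "B": [...]}).
    """
    d = 10.0 ** effect / 1e6
    markers_a = {"Marker alpha": (base_level + 2 * d, base_level)}
    markers_b = {
        "Marker beta": (base_level, base_level + d),
        "Marker gamma": (base_level, base_level + d),
    }
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.5, 1.5, size=n_background)
    marker_mass = base_level * 3 + 2 * d  # identical in both groups
    background = raw / raw.sum() * (1.0 - marker_mass)
    comp_a: dict[str, float] = {}
    comp_b: dict[str, float] = {}
    for i, mass in enumerate(background):
        name = f"Background sp{i:02d}"
        comp_a[name] = comp_b[name] = float(mass)
    for name, (a, b) in {**markers_a, **markers_b}.items():
        comp_a[name] = a
        comp_b[name] = b
    truth = {"A": sorted(markers_a), "B": sorted(markers_b)}
    return comp_a, comp_b, truth


def simulate_two_group_table(
    comp_a: Mapping[str, float],
    comp_b: Mapping[str, float],
    n_per_group: int = 9,
    depth: int = 10_000,
    seed: int = 0,
):
    """Multinomial relative-abundance table for two groups of samples.

    Returns (samples x species DataFrame of relative abundances, labels).
    """
    import pandas as pd

    if set(comp_a) != set(comp_b):
        raise ValueError("both compositions must cover the same species")
    rng = np.random.default_rng(seed)
    species = sorted(comp_a)
    rows, index, labels = [], [], []
    for group, comp in (("A", comp_a), ("B", comp_b)):
        probs = np.asarray([comp[s] for s in species], dtype=float)
        probs = probs / probs.sum()
        for i in range(n_per_group):
            counts = rng.multinomial(depth, probs)
            rows.append(counts / depth)
            index.append(f"{group}{i + 1}")
            labels.append(group)
    table = pd.DataFrame(rows, index=index, columns=species)
    return table, labels
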