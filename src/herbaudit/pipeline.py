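"""End-to-end orchestration: qc -> assign -> abundance -> audit -> compare.

Driven by a structured config (YAML or dict).  Every stage writes plain-text
outputs under the run directory; the run report records the thresholds
actually applied and a checksum per output, so reruns with identical config
and seeds are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from . import abundance as ab
from . import audit as au
from . import compare as cp
from . import read_qc as rq
from . import taxonomy as tx
from .prescription import Prescription, load_prescription

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when the run configuration is invalid or a stage fails."""


@dataclass(frozen=True)
class BarcodeInput:
    """Input bundle for one barcode: reads + MID sheet + hit table."""

    label: str
    reads: Path
    barcode_sheet: Path
    hits: Path
    species_map: Optional[Path] = None


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration with the protocol's default thresholds."""

    prescription: Path
    barcodes: tuple[BarcodeInput, ...]
    out_dir: Path
    max_evalue: float = tx.DEFAULT_MAX_EVALUE
    rel_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(ab.REL_ABUNDANCE_THRESHOLDS)
    )
    network_cutoffs: Mapping[str, float] = field(
        default_factory=lambda: dict(cp.NETWORK_CUTOFFS)
    )
    linkage: str = "complete"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base: Path = Path(".")) -> "RunConfig":
        def resolve(p) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            barcodes = tuple(
                BarcodeInput(
                    label=b["label"],
                    reads=resolve(b["reads"]),
                    barcode_sheet=resolve(b["barcode_sheet"]),
                    hits=resolve(b["hits"]),
                    species_map=resolve(b["species_map"]) if b.get("species_map") else None,
                )
                for b in raw["barcodes"]
            )
            cfg = cls(
                prescription=resolve(raw["prescription"]),
                barcodes=barcodes,
                out_dir=resolve(raw["out_dir"]),
                max_evalue=float(raw.get("max_evalue", tx.DEFAULT_MAX_EVALUE)),
                rel_thresholds={**ab.REL_ABUNDANCE_THRESHOLDS,
                                **raw.get("rel_thresholds", {})},
                network_cutoffs={**cp.NETWORK_CUTOFFS,
                                 **raw.get("network_cutoffs", {})},
                linkage=raw.get("linkage", "complete"),
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise PipelineError(f"invalid run config: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.prescription.exists():
            raise PipelineError(f"prescription file missing: {self.prescription}")
        if not self.barcodes:
            raise PipelineError("at least one barcode input is required")
        for b in self.barcodes:
            for p in (b.reads, b.barcode_sheet, b.hits):
                if not Path(p).exists():
                    raise PipelineError(f"{b.label}: input missing: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured barcode; returns the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rx = load_prescription(config.prescription)
    outputs: dict[str, str] = {}
    reports: list[au.DetectionReport] = []
    report: dict = {
        "preparation": rx.preparation,
        "seed": config.seed,
        "thresholds": {
            "max_evalue": config.max_evalue,
            "rel_abundance": dict(config.rel_thresholds),
            "network_cutoffs": dict(config.network_cutoffs),
            "qc": {
                label: {"min_len": rq.LENGTH_BOUNDS[label][0],
                        "max_len": rq.LENGTH_BOUNDS[label][1],
                        "window": 5, "min_window_q": 20.0, "max_homopolymer": 8}
                for label in rq.LENGTH_BOUNDS
            },
        },
        "barcodes": {},
    }

    def emit(path: Path, text: str) -> None:
        path.write_text(text)
        outputs[str(path.relative_to(out))] = _sha256(path)

    for binput in config.barcodes:
        label = binput.label
        bdir = out / label
        bdir.mkdir(exist_ok=True)

        specs = rq.load_barcode_sheet(binput.barcode_sheet)
        qc = rq.run_qc(rq.read_fastq(binput.reads), specs)
        stats = rq.qc_stats(qc)
        emit(bdir / "qc_stats.tsv",
             stats.to_csv(sep="\t") + "\n#rejected\t"
             + json.dumps(stats.attrs["rejected_by_reason"]) + "\n")

        species_map = (
            tx.load_species_map(binput.species_map) if binput.species_map else None
        )
        grouped = tx.load_hit_table(binput.hits, species_map, config.max_evalue)
        sample_counts = {}
        for sample_id, reads in qc.kept.items():
            sample_hits = {r.read_id: grouped.get(r.read_id, []) for r in reads}
            _, counts, n_un = tx.assign_sample(sample_hits, rx,
                                               [r.read_id for r in reads])
            sample_counts[sample_id] = counts
        table = ab.build_table(sample_counts, label)
        emit(bdir / "counts.tsv", table.counts.to_csv(sep="\t"))

        filtered = ab.threshold_filter(
            table, threshold=config.rel_thresholds.get(label)
        )
        emit(bdir / "filtered_counts.tsv", filtered.counts.to_csv(sep="\t"))

        summaries = au.audit_table(filtered, rx)
        detected_phs = frozenset().union(*(s.phs for s in summaries)) \
            if summaries else frozenset()
        det = au.make_report(detected_phs, rx, label)
        reports.append(det)
        emit(bdir / "detection_report.json", json.dumps(det.to_dict(), indent=2))

        pm = au.presence_matrix(filtered, rx)
        emit(bdir / "presence.tsv", pm.to_csv(sep="\t"))
        if len(pm.index) >= 2:
            dm = cp.euclidean_distances(pm)
            emit(bdir / "distances.tsv", dm.to_csv(sep="\t"))
            cutoff = config.network_cutoffs.get(label)
            if cutoff:
                edges = cp.network_edges(dm, cutoff)
                emit(bdir / "edges.tsv", "".join(
                    f"{a}\t{b}\t{d:g}\n" for a, b, d in edges))
            Z, _ = cp.hierarchical_cluster(dm, config.linkage)
            emit(bdir / "dendrogram.nwk",
                 cp.linkage_to_newick(Z, list(dm.index)) + "\n")

        report["barcodes"][label] = det.to_dict()

    if len(reports) > 1:
        union = au.union_barcodes(reports, rx)
        emit(out / "union_report.json", json.dumps(union.to_dict(), indent=2))
        report["union"] = union.to_dict()

    report["outputs"] = dict(sorted(outputs.items()))
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
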