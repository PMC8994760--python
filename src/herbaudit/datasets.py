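"""Bundled validation fixtures.

Prescription definitions for four marketed multi-ingredient preparations
(BYW, DHW, NJW, YGW) and species-level detection matrices recorded for two
of them under each barcode.  Detection matrices are stored species-by-sample
with 0/1 flags; per-species detection tallies are faithful to the recorded
results, while the placement of detections across samples is only pinned
where the record names the sample (set-level quantities are what downstream
analyses consume).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .prescription import Prescription, TaxonName, load_prescription

__all__ = [
    "available_prescriptions",
    "available_detection_tables",
    "load_bundled_prescription",
    "load_detection_table",
    "detected_species",
]

_PRESCRIPTIONS = {"BYW", "DHW", "NJW", "YGW"}
_DETECTION_TABLES = {
    ("NJW", "ITS2"): "detection_njw_its2.tsv",
    ("DHW", "ITS2"): "detection_dhw_its2.tsv",
    ("NJW", "trnL"): "detection_njw_trnl.tsv",
    ("DHW", "trnL"): "detection_dhw_trnl.tsv",
}


def _data_path(name: str) -> Path:
    return Path(resources.files("herbaudit").joinpath("data", name))


def available_prescriptions() -> list[str]:
    return sorted(_PRESCRIPTIONS)


def available_detection_tables() -> list[tuple[str, str]]:
    return sorted(_DETECTION_TABLES)


def load_bundled_prescription(code: str) -> Prescription:
    """Load one of the bundled prescriptions by preparation code."""
    code = code.upper()
    if code not in _PRESCRIPTIONS:
        raise KeyError(f"no bundled prescription {code!r}; see available_prescriptions()")
    return load_prescription(_data_path(f"prescription_{code.lower()}.tsv"))


def load_detection_table(preparation: str, barcode: str) -> pd.DataFrame:
    """Load a detection matrix as a binary samples x species DataFrame."""
    key = (preparation.upper(), "trnL" if barcode.lower() == "trnl" else barcode)
    if key not in _DETECTION_TABLES:
        raise KeyError(
            f"no bundled detection table for {key}; see available_detection_tables()"
        )
    frame = pd.read_csv(_data_path(_DETECTION_TABLES[key]), sep="\t", index_col=0)
    return frame.T.astype(int)  # file is species x samples


def detected_species(presence: pd.DataFrame) -> frozenset[TaxonName]:
    """Species detected in at least one sample of a presence matrix."""
    hit = presence.columns[(presence > 0).any(axis=0)]
    return frozenset(TaxonName.parse(s) for s in hit)


# For YGW and BYW no species-by-sample matrix was recorded, only the
# per-barcode detected-material counts (YGW: 6 of 9 by ITS2, 4 of 9 by trnL,
# union 7 with the Aconitum and Dioscorea materials undetected; BYW: 8 of 8
# by ITS2, 5 of 8 by trnL).  The species memberships below are a minimal
# reconstruction consistent with those counts; every downstream statistic
# depends only on the set sizes.
YGW_BARCODE_PHS: dict[str, tuple[str, ...]] = {
    "ITS2": (
        "Angelica sinensis", "Cinnamomum cassia", "Cornus officinalis",
        "Cuscuta australis", "Eucommia ulmoides", "Lycium barbarum",
    ),
    "trnL": (
        "Rehmannia glutinosa", "Cinnamomum cassia", "Eucommia ulmoides",
        "Lycium barbarum",
    ),
}

BYW_BARCODE_PHS: dict[str, tuple[str, ...]] = {
    "ITS2": (
        "Leonurus japonicus", "Codonopsis pilosula", "Atractylodes macrocephala",
        "Glycyrrhiza uralensis", "Angelica sinensis", "Paeonia lactiflora",
        "Ligusticum chuanxiong", "Rehmannia glutinosa",
    ),
    "trnL": (
        "Leonurus japonicus", "Codonopsis pilosula", "Angelica sinensis",
        "Paeonia lactiflora", "Glycyrrhiza uralensis",
    ),
}
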