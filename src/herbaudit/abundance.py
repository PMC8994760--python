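"""Sample x species abundance tables, per-barcode relative-abundance
thresholds, and rarefaction curves.

Species whose within-sample relative abundance falls strictly below the
barcode threshold (ITS2: 0.002, trnL: 0.001) have their reads removed in
that sample, and relative abundances are recomputed over the retained reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "REL_ABUNDANCE_THRESHOLDS",
    "AbundanceTable",
    "RarefactionCurve",
    "build_table",
    "threshold_filter",
    "rarefy",
]

#: Default per-barcode relative-abundance cutoffs (strictly-below removed).
REL_ABUNDANCE_THRESHOLDS = {"ITS2": 0.002, "trnL": 0.001}


@dataclass
class AbundanceTable:
    """Read counts per sample (rows) and species (columns) for one barcode."""

    barcode_label: str
    counts: pd.DataFrame  # samples x species, non-negative integers

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def rel(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero rows stay NaN (flagged)."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0), axis=0)

    def row_counts(self, sample_id: str) -> dict[str, int]:
        row = self.counts.loc[sample_id]
        return {sp: int(c) for sp, c in row.items() if c > 0}

    def drop_empty_species(self) -> "AbundanceTable":
        keep = self.counts.columns[(self.counts > 0).any(axis=0)]
        return AbundanceTable(self.barcode_label, self.counts[keep].copy())


def build_table(
    sample_counts: Mapping[str, Mapping[str, int]],
    barcode_label: str,
) -> AbundanceTable:
    """Assemble an abundance table from per-sample species tallies.

    Samples with zero assigned reads are retained as all-zero rows (their
    relative abundances are NaN in :attr:`AbundanceTable.rel`).
    """
    frame = pd.DataFrame.from_dict(
        {s: dict(c) for s, c in sample_counts.items()}, orient="index"
    )
    frame = frame.reindex(index=list(sample_counts.keys()),
                          columns=sorted(frame.columns))
    frame = frame.fillna(0).astype(np.int64)
    return AbundanceTable(barcode_label=barcode_label, counts=frame)


def threshold_filter(
    table: AbundanceTable,
    threshold: Optional[float] = None,
    iterate: bool = False,
    pooled: bool = False,
) -> AbundanceTable:
    """Zero out species below the relative-abundance threshold, per sample.

    Strict inequality: a species at exactly the threshold is retained.
    Relative abundances are implicitly recomputed over retained reads (row
    totals shrink).  One pass by default; ``iterate`` repeats to a fixpoint.
    ``pooled`` applies the threshold to abundances pooled over all samples.
    """
    if threshold is None:
        try:
            threshold = REL_ABUNDANCE_THRESHOLDS[table.barcode_label]
        except KeyError:
            raise ValueError(
                f"no default threshold for barcode {table.barcode_label!r}"
            ) from None
    counts = table.counts.copy()
    while True:
        totals = counts.sum(axis=1)
        if pooled:
            grand = totals.sum()
            if grand > 0:
                pooled_rel = counts.sum(axis=0) / grand
                counts.loc[:, pooled_rel < threshold] = 0
            break
        rel = counts.div(totals.where(totals > 0), axis=0)
        # NaN rows compare False, so all-zero rows stay untouched; entries
        # already at zero are excluded or the fixpoint loop would never end
        mask = (rel < threshold) & (counts > 0)
        if not mask.values.any():
            break
        counts = counts.mask(mask, 0)
        if not iterate:
            break
    return AbundanceTable(table.barcode_label, counts)


@dataclass
class RarefactionCurve:
    """Mean (+/- sd) species richness at increasing subsampling depths."""

    depths: tuple[int, ...]
    mean_richness: tuple[float, ...]
    sd: tuple[float, ...]
    replicates: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "mean_richness": self.mean_richness, "sd": self.sd}
        )


def rarefy(
    row: Union[Mapping[str, int], pd.Series],
    depths: Optional[Sequence[int]] = None,
    replicates: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction by exact subsampling without replacement.

    Each replicate shuffles the row's reads once; the subsample at depth *d*
    is the first *d* reads of the shuffle, so draws are nested within a
    replicate (distributionally identical to independent multivariate-
    hypergeometric draws, and richness is monotone in depth by construction).
    Depths must not exceed the row total.
    """
    counts = np.asarray(
        [int(c) for c in (row.values if isinstance(row, pd.Series) else row.values())
         if c > 0],
        dtype=np.int64,
    )
    total = int(counts.sum())
    if total == 0:
        raise ValueError("cannot rarefy an all-zero row")
    if depths is None:
        step = max(total // 100, 1)
        depths = list(range(step, total + 1, step))
        if depths[-1] != total:
            depths.append(total)
    depths = [int(d) for d in depths]
    if any(d < 1 or d > total for d in depths):
        raise ValueError(f"depths must lie in [1, {total}]")

    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(counts.size), counts)
    depth_arr = np.asarray(depths)
    richness = np.empty((replicates, len(depths)), dtype=np.float64)
    for r in range(replicates):
        perm = rng.permutation(pool)
        _, first_idx = np.unique(perm, return_index=True)
        # richness at depth d = species first seen before position d
        richness[r] = (first_idx[None, :] < depth_arr[:, None]).sum(axis=1)
    means = richness.mean(axis=0).tolist()
    sds = richness.std(axis=0, ddof=0).tolist()
    return RarefactionCurve(
        depths=tuple(depths),
        mean_richness=tuple(means),
        sd=tuple(sds),
        replicates=replicates,
        seed=seed,
    )
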