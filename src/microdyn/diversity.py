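"""Alpha-diversity trajectories: Shannon index and Faith's PD.

Shannon's index, SD = -sum_i p_i log p_i, summarizes richness and
evenness of a day's composition; Faith's phylogenetic diversity,
PD = sum over tree nodes j of I_j * branchlen_j, is the total branch
length spanned by the taxa present that day (I_j = 1 iff any tip
descending from node j is present).

The log base for Shannon defaults to 2 (bits), the convention of the
QIIME ecosystem; natural log is available via ``log_base="e"``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import skbio

from .table import AbundanceSeriesTable


@dataclasses.dataclass
class DiversitySeries:
    subject_id: str
    metric: str  # "shannon" | "faith_pd"
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValueError("days and values must align")


def shannon_index(row, log_base="2") -> float:
    """Shannon diversity of one day's counts.

    Zero-count taxa contribute nothing; an all-zero row is an error.
    """
    counts = np.asarray(row, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero row has undefined diversity")
    p = counts[counts > 0] / total
    h = -np.sum(p * np.log(p))
    if str(log_base) == "2":
        h /= math.log(2)
    elif str(log_base) != "e":
        raise ValueError("log_base must be '2' or 'e'")
    return float(h)


def faith_pd(row, asv_ids, tree: skbio.TreeNode) -> float:
    """Faith's phylogenetic diversity of one day's counts.

    Sums the lengths of every branch lying on a root-to-tip path for at
    least one present taxon, each branch counted once.
    """
    counts = np.asarray(row, dtype=float)
    present = {a for a, c in zip(asv_ids, counts) if c > 0}
    if not present:
        return 0.0
    tips = {t.name for t in tree.tips()}
    missing = present - tips
    if missing:
        raise KeyError(
            f"taxa present but absent from tree: {sorted(missing)[:5]}"
        )
    spanned = set()
    for name in present:
        node = tree.find(name)
        while node.parent is not None:
            if id(node) in spanned:
                break
            spanned.add(id(node))
            node = node.parent
    total = 0.0
    for node in tree.traverse(include_self=False):
        if id(node) in spanned:
            total += node.length or 0.0
    return float(total)


def diversity_series(
    table: AbundanceSeriesTable,
    metric: str,
    tree: skbio.TreeNode | None = None,
    log_base="2",
) -> DiversitySeries:
    """Compute one alpha-diversity value per day of the table."""
    if not table.is_rarefied:
        warnings.warn(
            "computing diversity on a non-rarefied table; values will be "
            "confounded by sequencing depth",
            stacklevel=2,
        )
    if metric == "shannon":
        values = [shannon_index(r, log_base=log_base) for r in table.counts]
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a phylogenetic tree")
        ids = table.asv_ids
        values = [faith_pd(r, ids, tree) for r in table.counts]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DiversitySeries(
        subject_id=table.subject_id,
        metric=metric,
        days=table.days.copy(),
        values=np.asarray(values, dtype=float),
    )
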