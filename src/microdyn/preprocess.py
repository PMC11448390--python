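"""Missing-day interpolation, rarefaction and compositional transforms.

Interpolation uses shape-preserving piecewise cubic Hermite polynomials
(PCHIP), which keep interpolated abundances non-negative between
non-negative knots, preserve monotone runs, and avoid the overshoot of
natural cubic splines on spiky count data.  Rarefaction subsamples each
day's reads without replacement to a common depth so diversity is not
confounded by sequencing effort.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from skbio.stats.composition import clr

from .table import AbundanceSeriesTable, align_daily_index


def interpolate_pchip(table: AbundanceSeriesTable) -> AbundanceSeriesTable:
    """Fill missing days of every ASV column with PCHIP interpolation.

    Observed rows are left bit-identical; only the gap days are new,
    and they are flagged in ``interpolated_days``.  Idempotent on
    complete tables.
    """
    values = table.counts
    if not np.isfinite(values).all():
        raise ValueError("non-finite input counts")
    days = table.days.astype(int)
    if len(days) < 2:
        raise ValueError("need at least 2 observed days to interpolate")
    _, missing = align_daily_index(table)
    if not missing:
        return table
    full_days = np.arange(days[0], days[-1] + 1)
    out = np.empty((len(full_days), values.shape[1]))
    obs_pos = np.searchsorted(full_days, days)
    gap_mask = np.ones(len(full_days), bool)
    gap_mask[obs_pos] = False
    for j in range(values.shape[1]):
        col = values[:, j]
        out[obs_pos, j] = col
        out[gap_mask, j] = PchipInterpolator(days, col)(full_days[gap_mask])
    # PCHIP between non-negative knots cannot undershoot below the
    # smaller knot, but clip defensively against float round-off.
    np.clip(out, 0.0, None, out=out)
    df = pd.DataFrame(out, index=full_days, columns=table.data.columns)
    return AbundanceSeriesTable(
        df,
        subject_id=table.subject_id,
        interpolated_days=table.interpolated_days | frozenset(missing),
        is_rarefied=False,
    )


@dataclasses.dataclass
class RarefactionReport:
    depth: int
    dropped_days: list
    seed: int


def rarefy_counts(
    table: AbundanceSeriesTable, depth: int, seed: int
) -> tuple[AbundanceSeriesTable, RarefactionReport]:
    """Subsample each day's reads without replacement to exactly `depth`.

    Non-integer (interpolated) counts are rounded half-to-even first.
    Days whose total falls below the depth are dropped and reported;
    all-zero ASV columns are retained so the taxon set is stable.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = np.rint(table.counts).astype(np.int64)
    rng = np.random.default_rng(seed)
    keep_rows, dropped = [], []
    out = np.zeros_like(counts)
    for i, day in enumerate(table.days):
        total = int(counts[i].sum())
        if total < depth:
            dropped.append(int(day))
            continue
        if total == depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(
                counts[i], depth, method="marginals"
            )
        keep_rows.append(i)
    if not keep_rows:
        raise ValueError(f"every day has fewer than {depth} reads")
    df = pd.DataFrame(
        out[keep_rows],
        index=table.days[keep_rows],
        columns=table.data.columns,
    )
    rarefied = AbundanceSeriesTable(
        df,
        subject_id=table.subject_id,
        interpolated_days=table.interpolated_days,
        is_rarefied=True,
    )
    return rarefied, RarefactionReport(depth=depth, dropped_days=dropped, seed=seed)


def clr_transform(table_or_counts, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of each day's composition.

    value[i, j] = ln(c_ij + pc) - mean_j ln(c_ij + pc); every row sums
    to zero, which makes Euclidean distance between rows the Aitchison
    distance.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if isinstance(table_or_counts, AbundanceSeriesTable):
        df = table_or_counts.data
    else:
        df = pd.DataFrame(table_or_counts)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    transformed = clr(values + pseudocount)
    return pd.DataFrame(transformed, index=df.index, columns=df.columns)
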