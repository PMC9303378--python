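"""Sample-wise relative-read-abundance (RRA) thresholding and sweeps.

An RRA threshold treats a taxon as absent from a sample when its share of
that sample's reads does not *exceed* the cutoff (strict ``>`` retains, so
a 0% threshold keeps every taxon with at least one read — the complete
data).  Thresholds are always applied to the original table, never
sequentially, so retained sets are nested across the sweep.  The sweep
records, per sample and per threshold, the observed richness, the percent
loss of initial richness ``100 * (1 - S_t / S_0)``, and the retained taxon
sets; companion reductions detect the threshold at which samples converge
to similar richness, rank-order inversions among samples, and per-group
"dropout" ledgers of the taxa lost at each cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .table import ReadCountTable, ValidationError

__all__ = [
    "SweepResult",
    "default_threshold_grid",
    "to_rra",
    "apply_threshold",
    "threshold_sweep",
    "convergence_threshold",
    "rank_order_trajectory",
    "dropout_ledger",
]


def default_threshold_grid() -> np.ndarray:
    """0% to 5% in 0.2% steps (26 points), as fractions."""
    return np.round(np.arange(0, 26) * 0.002, 10)


def to_rra(table: ReadCountTable) -> np.ndarray:
    """Counts to relative read abundance: each column sums to 1.

    All-zero samples stay zero and trigger a warning.
    """
    totals = table.sample_sums().astype(float)
    empty = totals == 0
    if empty.any():
        bad = [s for s, e in zip(table.sample_ids, empty) if e]
        warnings.warn(f"samples with zero reads left as all-zero RRA: {bad}")
    safe = np.where(empty, 1.0, totals)
    return table.counts / safe


def _check_threshold(threshold: float) -> float:
    t = float(threshold)
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    return t


def apply_threshold(table: ReadCountTable, threshold: float) -> ReadCountTable:
    """Zero out, per sample, every taxon whose RRA does not exceed the cutoff.

    Retention is strict (``rra > threshold``); counts of retained taxa are
    unchanged (no renormalisation), and the RRA is computed on the input
    table, so applying thresholds is idempotent and nested.
    """
    t = _check_threshold(threshold)
    rra = to_rra(table)
    kept = rra > t
    return table.copy_with_counts(np.where(kept, table.counts, 0))


@dataclass
class SweepResult:
    """Per-sample, per-threshold outcome of an RRA threshold sweep.

    Attributes
    ----------
    thresholds : ndarray
        The ascending grid of cutoffs (fractions).
    richness : DataFrame (samples × thresholds)
        Observed richness after filtering at each cutoff.
    pct_loss : DataFrame (samples × thresholds)
        ``100 * (1 - S_t / S_0)`` relative to the threshold-0 richness
        ``S_0``; 0 for samples that start empty.
    retained : dict
        ``retained[sample_id][j]`` is the frozenset of taxa retained in
        that sample at ``thresholds[j]``.
    """

    thresholds: np.ndarray
    richness: pd.DataFrame
    pct_loss: pd.DataFrame
    retained: dict[str, list[frozenset]] = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.richness.index)


def threshold_sweep(
    table: ReadCountTable, thresholds: Sequence[float] | None = None
) -> SweepResult:
    """Sweep RRA cutoffs over the table (default grid 0–5% step 0.2%).

    Each threshold is applied to the *original* table; richness loss is
    measured against the threshold-0 richness of each sample.
    """
    grid = default_threshold_grid() if thresholds is None else np.asarray(
        [float(t) for t in thresholds], dtype=float
    )
    if grid.size == 0:
        raise ValidationError("threshold grid must not be empty")
    if (np.diff(grid) < 0).any():
        raise ValidationError("thresholds must be sorted ascending")
    for t in (grid[0], grid[-1]):
        _check_threshold(t)

    rra = to_rra(table)
    present = table.counts > 0
    # kept[i, j, k]: taxon i retained in sample j at grid[k]
    kept = rra[:, :, None] > grid[None, None, :]
    kept &= present[:, :, None]
    richness = kept.sum(axis=0)  # samples come out as axis 0 after sum over taxa
    richness = pd.DataFrame(richness, index=table.sample_ids, columns=grid)

    s0 = (present).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        loss = 100.0 * (1.0 - richness.to_numpy() / np.where(s0 == 0, 1.0, s0)[:, None])
    loss[s0 == 0] = 0.0
    pct_loss = pd.DataFrame(loss, index=table.sample_ids, columns=grid)

    taxa = np.asarray(table.taxon_ids, dtype=object)
    retained = {
        sid: [frozenset(taxa[kept[:, j, k]]) for k in range(grid.size)]
        for j, sid in enumerate(table.sample_ids)
    }
    return SweepResult(thresholds=grid, richness=richness, pct_loss=pct_loss,
                       retained=retained)


def convergence_threshold(
    sweep: SweepResult, tolerance: int | None = 0
) -> float | tuple[float, int] | None:
    """Smallest grid threshold where per-sample richness values converge.

    With an integer ``tolerance``, returns the smallest threshold at which
    ``max - min`` richness across samples is at most ``tolerance`` taxa, or
    ``None`` if the grid never converges.  With ``tolerance=None``, uses the
    smallest tolerance achievable anywhere on the grid and returns the pair
    ``(threshold, achieved_tolerance)``.
    """
    if len(sweep.sample_ids) < 2:
        raise ValidationError("convergence needs a sweep over at least 2 samples")
    spread = sweep.richness.max(axis=0) - sweep.richness.min(axis=0)
    if tolerance is None:
        achieved = int(spread.min())
        idx = int(np.argmax(spread.to_numpy() <= achieved))
        return float(sweep.thresholds[idx]), achieved
    ok = spread.to_numpy() <= int(tolerance)
    if not ok.any():
        return None
    return float(sweep.thresholds[int(np.argmax(ok))])


def rank_order_trajectory(sweep: SweepResult) -> tuple[pd.DataFrame, list[float]]:
    """Per-threshold sample rankings by richness, plus inversion thresholds.

    Samples are ranked 1 = richest at each threshold, ties sharing the
    average rank.  An inversion is recorded at threshold ``t`` when some
    pair of samples strictly ordered at threshold 0 is strictly ordered the
    opposite way at ``t``.
    """
    if len(sweep.sample_ids) < 2:
        return sweep.richness.rank(axis=0, ascending=False), []
    ranks = sweep.richness.rank(axis=0, ascending=False, method="average")
    r = sweep.richness.to_numpy()
    base = r[:, 0]
    sign0 = np.sign(base[:, None] - base[None, :])
    inversions = []
    for k, t in enumerate(sweep.thresholds):
        sign_t = np.sign(r[:, k][:, None] - r[:, k][None, :])
        if ((sign0 != 0) & (sign_t == -sign0)).any():
            inversions.append(float(t))
    return ranks, inversions


def _taxon_labels(table: ReadCountTable, taxon_level: str | None) -> np.ndarray:
    """Per-taxon aggregation labels at a taxonomy rank ('unknown' if absent)."""
    if taxon_level is None:
        return np.asarray(table.taxon_ids, dtype=object)
    if table.taxonomy is None or taxon_level not in table.taxonomy.columns:
        raise ValidationError(
            f"taxonomy rank {taxon_level!r} not available in table taxonomy"
        )
    labels = table.taxonomy[taxon_level].astype(object).to_numpy()
    labels = np.where(pd.isna(labels), "unknown", labels)
    return labels.astype(object)


def dropout_ledger(
    table: ReadCountTable,
    thresholds: Sequence[float] | None = None,
    group_by: Sequence[str] | str = ("species", "season"),
    taxon_level: str | None = "family",
) -> pd.DataFrame:
    """Per-group ledger of taxa lost at each threshold, by taxonomy rank.

    A taxon is "present in a group" at threshold ``t`` when it is retained
    in at least one of the group's samples after filtering at ``t``; the
    ledger lists the sequence taxa present at threshold 0 but absent at
    ``t``, aggregated under their label at ``taxon_level`` (sequences with
    no annotation at that rank are reported under ``"unknown"``).

    Returns a tidy frame with columns
    ``group, threshold, rank_label, n_taxa_lost, taxa``.
    """
    grid = default_threshold_grid() if thresholds is None else np.asarray(
        [float(t) for t in thresholds], dtype=float
    )
    groups = table.groups(group_by)
    labels = _taxon_labels(table, taxon_level)
    rra = to_rra(table)
    present = table.counts > 0
    taxa = np.asarray(table.taxon_ids, dtype=object)

    rows = []
    for gname, sids in groups.items():
        cols = [table.sample_index(s) for s in sids]
        base = present[:, cols].any(axis=1)
        for t in grid:
            if t == 0:
                continue
            kept = ((rra[:, cols] > t) & present[:, cols]).any(axis=1)
            lost = base & ~kept
            if not lost.any():
                continue
            frame = pd.DataFrame({"label": labels[lost], "taxon": taxa[lost]})
            for lab, sub in frame.groupby("label", sort=True):
                rows.append(
                    {
                        "group": gname,
                        "threshold": float(t),
                        "rank_label": lab,
                        "n_taxa_lost": len(sub),
                        "taxa": ";".join(sorted(sub["taxon"])),
                    }
                )
    return pd.DataFrame(rows, columns=["group", "threshold", "rank_label",
                                       "n_taxa_lost", "taxa"])
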