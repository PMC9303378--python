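"""Hill-number diversity profiles and DNA-vs-microhistology comparison.

Hill numbers are a unified family of diversity indices expressed in
"effective number of taxa" units,

    D(q) = (sum_i p_i ** q) ** (1 / (1 - q)),        q != 1
    D(1) = exp(-sum_i p_i * ln(p_i)),

where the order ``q`` tunes the weight given to abundant versus rare taxa:
``q = 0`` is observed richness, ``q = 1`` the exponential of Shannon
entropy ("typical" taxa), and ``q = 2`` the inverse Simpson concentration
("dominant" taxa).  Evaluating D over a grid of q yields a diversity
profile; unlike abundance thresholds, downweighting rare taxa this way
preserves the rank-order of samples.

Zero-probability taxa are excluded from the power sum at every order,
including q = 0 (the standard Hill convention: richness counts only taxa
that are present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import to_rra
from .table import ReadCountTable, ValidationError

__all__ = [
    "DiversityProfile",
    "hill_number",
    "diversity_profile",
    "group_summary",
    "compare_methods",
    "default_q_grid",
]


def default_q_grid() -> np.ndarray:
    """Orders q from 0 to 2 in steps of 0.05 (41 points)."""
    return np.round(np.arange(0, 41) * 0.05, 10)


@dataclass(frozen=True)
class DiversityProfile:
    """Hill number D(q) over a grid of orders for one sample or group."""

    unit_id: str
    q_grid: np.ndarray
    d_values: np.ndarray

    def at(self, q: float) -> float:
        idx = np.flatnonzero(np.isclose(self.q_grid, q))
        if idx.size == 0:
            raise KeyError(f"order q={q} not on the profile grid")
        return float(self.d_values[idx[0]])


# q values within this distance of 1 are evaluated by the entropy limit,
# which is exact at q=1 and numerically stable in its neighbourhood
_Q1_WINDOW = 1e-9


def hill_number(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Effective number of taxa of order ``q`` for a composition ``p``.

    ``p`` must be non-negative with a positive sum; it is renormalised
    internally, and zero entries are dropped before the power sum.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("composition must be a 1-D vector")
    if (p < 0).any():
        raise ValidationError("composition entries must be non-negative")
    if q < 0:
        raise ValidationError(f"order q must be >= 0, got {q}")
    total = p.sum()
    if total <= 0:
        raise ValidationError("all-zero composition has undefined diversity")
    p = p[p > 0] / total
    if abs(q - 1.0) <= _Q1_WINDOW:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 0:
        return float(p.size)
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def diversity_profile(
    table: ReadCountTable,
    q_grid: Sequence[float] | None = None,
    pool_by: Sequence[str] | str | None = None,
) -> list[DiversityProfile]:
    """Hill profiles per sample, or per pooled group of samples.

    With ``pool_by`` given, counts are summed within each metadata group
    before converting to proportions (composite profiles); empty groups or
    samples are skipped with a warning.
    """
    grid = default_q_grid() if q_grid is None else np.asarray(
        [float(q) for q in q_grid], dtype=float
    )
    if (grid < 0).any():
        raise ValidationError("orders q must be >= 0")

    units: list[tuple[str, np.ndarray]]
    if pool_by is None:
        units = [(sid, table.counts[:, j]) for j, sid in enumerate(table.sample_ids)]
    else:
        units = []
        for gname, sids in table.groups(pool_by).items():
            cols = [table.sample_index(s) for s in sids]
            units.append((gname, table.counts[:, cols].sum(axis=1)))

    profiles = []
    for uid, counts in units:
        if counts.sum() == 0:
            warnings.warn(f"unit {uid!r} has no reads; skipped")
            continue
        d = np.array([hill_number(counts, q) for q in grid])
        profiles.append(DiversityProfile(unit_id=uid, q_grid=grid, d_values=d))
    return profiles


def group_summary(
    profiles: Sequence[DiversityProfile],
    group_of: Mapping[str, str],
    q_values: Sequence[float] = (0.0, 1.0, 2.0),
    transform: str | None = None,
) -> pd.DataFrame:
    """Per-group mean ± SD of D(q) at selected orders.

    ``group_of`` maps each profile's ``unit_id`` to a group label.  With
    ``transform="log"`` the natural log is applied per profile before
    averaging (the usual scale for comparing richness-like quantities
    across methods).  Single-member groups report SD 0 and are flagged.

    Returns a tidy frame ``group, q, mean, sd, n, single_member``.
    """
    if transform not in (None, "log"):
        raise ValidationError("transform must be None or 'log'")
    missing = [p.unit_id for p in profiles if p.unit_id not in group_of]
    if missing:
        raise ValidationError(f"no group for units: {missing}")
    rows = []
    by_group: dict[str, list[DiversityProfile]] = {}
    for p in profiles:
        by_group.setdefault(group_of[p.unit_id], []).append(p)
    for gname in sorted(by_group):
        members = by_group[gname]
        for q in q_values:
            vals = np.array([m.at(q) for m in members], dtype=float)
            if transform == "log":
                vals = np.log(vals)
            single = len(vals) == 1
            rows.append(
                {
                    "group": gname,
                    "q": float(q),
                    "mean": float(vals.mean()),
                    "sd": 0.0 if single else float(vals.std(ddof=1)),
                    "n": len(vals),
                    "single_member": single,
                }
            )
    return pd.DataFrame(rows)


def compare_methods(
    dna_table: ReadCountTable,
    micro_table: pd.DataFrame,
    group_by: Sequence[str] | str = ("species", "season"),
    q_set: Sequence[float] = (0.0, 1.0, 2.0),
    transform: str | None = None,
) -> pd.DataFrame:
    """Paired Hill summaries: DNA metabarcoding vs microhistology composites.

    ``micro_table`` holds one percent-composition column per group-level
    composite (columns summing to ~100; tolerance 2%), with rows as
    microhistology categories.  Column names must match the group labels
    derived from the DNA table's metadata via ``group_by`` (e.g.
    ``bison_summer``); a mismatch raises an error listing both sides.

    Returns a tidy frame ``group, q, method, mean, sd, n`` where the DNA
    rows are across-sample means ± SD and the microhistology rows are the
    single composite value (sd NaN, n 1).
    """
    groups = dna_table.groups(group_by)
    micro_cols = [str(c) for c in micro_table.columns]
    if set(micro_cols) != set(groups):
        raise ValidationError(
            "microhistology composites do not match DNA groups; "
            f"micro columns: {sorted(micro_cols)}; dna groups: {sorted(groups)}"
        )
    sums = micro_table.sum(axis=0)
    bad = sums[(sums < 98.0) | (sums > 102.0)]
    if len(bad):
        raise ValidationError(
            f"microhistology columns must sum to ~100%: {dict(bad.round(2))}"
        )

    sample_group = {
        sid: gname for gname, sids in groups.items() for sid in sids
    }
    dna_profiles = diversity_profile(dna_table, q_grid=q_set)
    dna = group_summary(dna_profiles, sample_group, q_values=q_set,
                        transform=transform)
    dna = dna.assign(method="dna")[["group", "q", "method", "mean", "sd", "n"]]

    rows = []
    for gname in sorted(groups):
        comp = micro_table[gname].to_numpy(dtype=float)
        for q in q_set:
            val = hill_number(comp, q)  # renormalises percent -> proportions
            if transform == "log":
                val = float(np.log(val))
            rows.append({"group": gname, "q": float(q), "method": "microhistology",
                         "mean": val, "sd": np.nan, "n": 1})
    micro = pd.DataFrame(rows)
    return pd.concat([dna, micro], ignore_index=True).sort_values(
        ["group", "q", "method"], ignore_index=True
    )
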