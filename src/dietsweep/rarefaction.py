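"""Depth rarefaction: subsample every sample to a common number of reads.

Unequal sequencing depth inflates the apparent richness of deeply
sequenced samples.  Rarefaction draws, without replacement, a fixed number
of reads from each sample's observed reads (a multivariate hypergeometric
draw per sample), so every retained sample carries exactly the same
evidence.  Samples shallower than the target depth are dropped with a
warning, and taxa whose total count falls to zero table-wide are removed.
An optional multinomial (with-replacement) mode supports purely simulated
data where reads are draws from a known composition rather than a finite
sequencing pool.
"""

from __future__ import annotations

import warnings

import numpy as np

from .table import ReadCountTable, ValidationError

__all__ = ["rarefy_table"]


def rarefy_table(
    table: ReadCountTable,
    depth: int | None = None,
    seed: int | np.random.Generator = 0,
    mode: str = "hypergeometric",
) -> ReadCountTable:
    """Subsample each sample to ``depth`` reads.

    Parameters
    ----------
    table : ReadCountTable
    depth : int, optional
        Common depth; defaults to the minimum positive sample total
        ("equal sequencing depth" with no stated depth).
    seed : int or Generator
        Drives the per-sample draws; results are reproducible given the
        seed and the sample order.
    mode : str
        ``hypergeometric`` (default; without replacement, subsampled counts
        never exceed the originals) or ``multinomial`` (with replacement,
        proportions as weights).

    Returns
    -------
    ReadCountTable
        Every retained sample sums exactly to ``depth``; empty taxa are
        dropped.  Attrs record ``rarefaction_depth``, ``rarefaction_seed``
        and ``rarefaction_mode``.
    """
    if mode not in ("hypergeometric", "multinomial"):
        raise ValidationError(f"unknown rarefaction mode {mode!r}")
    totals = table.sample_sums()
    positive = totals[totals > 0]
    if positive.size == 0:
        raise ValidationError("cannot rarefy a table with no reads")
    if depth is None:
        depth = int(positive.min())
    if depth < 1 or int(depth) != depth:
        raise ValidationError(f"depth must be a positive integer, got {depth}")
    depth = int(depth)

    keep = [s for s, tot in zip(table.sample_ids, totals) if tot >= depth]
    dropped = [s for s in table.sample_ids if s not in keep]
    if not keep:
        raise ValidationError(
            f"rarefaction depth {depth} exceeds every sample's total reads"
        )
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) shallower than depth {depth}: "
            f"{dropped}"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = table.select(samples=keep)
    out = np.zeros_like(sub.counts)
    for j in range(sub.n_samples):
        col = sub.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        elif mode == "hypergeometric":
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
        else:
            out[:, j] = rng.multinomial(depth, col / col.sum())

    result = sub.copy_with_counts(out).drop_empty_taxa()
    result.attrs.update(
        rarefaction_depth=depth,
        rarefaction_seed=(-1 if isinstance(seed, np.random.Generator) else int(seed)),
        rarefaction_mode=mode,
    )
    return result
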