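"""Sliding-window (bootscan-style) recombination screen.

A query sequence is slid along a multiple alignment in windows; within each
window the alignment columns are bootstrap-resampled and the query's nearest
non-query sequence (by uncorrected p-distance with pairwise gap deletion) is
recorded per replicate.  The fraction of replicates in which a candidate
parent is nearest is its support in that window.  A recombination breakpoint
is called where the above-threshold nearest parent changes identity along
the alignment.

p-distance is deliberately model-free: in windows as small as 50 nt,
model-based distance corrections are unstable.  The screen covers the
window-size regime 50-500 nt used for flavivirus genome scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .screens import _as_records

__all__ = ["WindowRecord", "BootscanProfile", "bootscan", "distance_profile"]

_GAP = ord("-")


@dataclass(frozen=True)
class WindowRecord:
    start: int
    midpoint: float
    parent: str | None  # best-supported (or nearest) candidate; None on tie
    support: float  # fraction of replicates (1.0 in distance_profile)
    ties: tuple = ()


@dataclass
class BootscanProfile:
    query: str
    window: int
    step: int
    records: list[WindowRecord]
    breakpoints: list[tuple[float, float]]
    support_threshold: float | None = None


def _encode(alignment, query: str):
    records = _as_records(alignment)
    ids = [sid for sid, _ in records]
    if query not in ids:
        raise ValueError(f"query {query!r} not in alignment")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    (length,) = lengths
    mat = np.frombuffer(
        "".join(s for _, s in records).encode(), dtype=np.uint8
    ).reshape(len(ids), length)
    qi = ids.index(query)
    others = [i for i in range(len(ids)) if i != qi]
    return ids, mat, qi, others, length


def _pdist_to_query(mat, qi, others, cols):
    """p-distance of each non-query row to the query over ``cols``."""
    q = mat[qi, cols]
    out = np.empty(len(others))
    for k, i in enumerate(others):
        r = mat[i, cols]
        valid = (q != _GAP) & (r != _GAP)
        n = int(valid.sum())
        out[k] = np.nan if n == 0 else float((q[valid] != r[valid]).sum()) / n
    return out


def _windows(length: int, window: int, step: int):
    if window > length:
        raise ValueError("window larger than alignment")
    starts = list(range(0, length - window + 1, step))
    return starts


def distance_profile(alignment, query: str, window: int, step: int | None = None):
    """Deterministic nearest-neighbor table per window (no bootstrap).

    Ties (including the all-identical case) are reported as ties with
    ``parent=None``.  ``step`` defaults to window/4.
    """
    ids, mat, qi, others, length = _encode(alignment, query)
    step = step or max(1, window // 4)
    records = []
    for start in _windows(length, window, step):
        cols = np.arange(start, start + window)
        d = _pdist_to_query(mat, qi, others, cols)
        rec = _pick_nearest(ids, others, d, start, window)
        records.append(rec)
    return records


def _pick_nearest(ids, others, d, start, window) -> WindowRecord:
    mid = start + window / 2
    if np.all(np.isnan(d)):
        return WindowRecord(start, mid, None, 1.0, tuple(ids[i] for i in others))
    best = np.nanmin(d)
    winners = [ids[others[k]] for k in range(len(others)) if d[k] == best]
    if len(winners) > 1:
        return WindowRecord(start, mid, None, 1.0, tuple(winners))
    return WindowRecord(start, mid, winners[0], 1.0)


def bootscan(
    alignment,
    query: str,
    replicates: int = 100,
    window: int = 200,
    step: int | None = None,
    seed=0,
    support_threshold: float = 0.7,
) -> BootscanProfile:
    """Bootstrap sliding-window scan for recombination breakpoints.

    Requires at least 4 aligned sequences (query, two candidate parents and
    an outgroup).  Within a window, a replicate votes for the single nearest
    non-query sequence; ties cast no vote.  Breakpoints are called between
    consecutive above-threshold windows whose winning parent differs; the
    reported interval spans the two window midpoints.
    """
    ids, mat, qi, others, length = _encode(alignment, query)
    if len(ids) < 4:
        raise ValueError("bootscan needs at least 4 aligned sequences")
    step = step or max(1, window // 4)
    rng = np.random.default_rng(seed)
    records = []
    for start in _windows(length, window, step):
        votes = {ids[i]: 0 for i in others}
        for _ in range(replicates):
            cols = rng.integers(start, start + window, size=window)
            d = _pdist_to_query(mat, qi, others, cols)
            if np.all(np.isnan(d)):
                continue
            best = np.nanmin(d)
            winners = [others[k] for k in range(len(others)) if d[k] == best]
            if len(winners) == 1:
                votes[ids[winners[0]]] += 1
        mid = start + window / 2
        if replicates > 0 and max(votes.values(), default=0) > 0:
            top = max(votes, key=lambda s: (votes[s], s))
            support = votes[top] / replicates
            records.append(WindowRecord(start, mid, top, support))
        else:
            records.append(WindowRecord(start, mid, None, 0.0, tuple(ids[i] for i in others)))

    breakpoints = []
    prev = None
    for rec in records:
        if rec.parent is None or rec.support < support_threshold:
            continue
        if prev is not None and rec.parent != prev.parent:
            breakpoints.append((prev.midpoint, rec.midpoint))
        prev = rec
    return BootscanProfile(
        query=query,
        window=window,
        step=step,
        records=records,
        breakpoints=breakpoints,
        support_threshold=support_threshold,
    )
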