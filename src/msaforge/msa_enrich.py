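"""Merging, identity/diversity filtering and diversity statistics for MSAs.

The filtering step reproduces the logic of identity-window MSA filters used
upstream of structure prediction: drop unlikely homologs (query identity
below ``min_qid``), drop near-duplicates of the query (identity above
``max_qid``), collapse redundant sequences, and — when the alignment is
still larger than ``max_kept`` — keep a diversity-maximizing subset chosen
by greedy farthest-point selection on pairwise sequence distance.

Diversity is summarized by N_eff, the effective number of sequences:
the exponential of the mean per-column Shannon entropy of Henikoff
position-weighted residue frequencies. N_eff is 1 for an alignment of
identical sequences and at most 20 (the amino-acid alphabet size); higher
values mean more diverse alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .msa_io import AlignedSequence, Msa, sequence_identity

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@dataclass(frozen=True)
class FilterParams:
    """Identity window and diversity cap of the MSA filter.

    Members with query identity in [min_qid, max_qid] (boundaries
    inclusive) are kept; at most ``max_kept`` non-query members survive
    the diversity cap.
    """

    min_qid: float = 0.2
    max_qid: float = 0.95
    max_kept: int = 3000

    def __post_init__(self):
        if not (0.0 <= self.min_qid < self.max_qid <= 1.0):
            raise ValueError("require 0 <= min_qid < max_qid <= 1")
        if self.max_kept < 1:
            raise ValueError("max_kept must be >= 1")


@dataclass(frozen=True)
class FilterLog:
    """Per-call accounting of filter decisions (for run summaries)."""

    n_input: int
    removed_low_id: int
    removed_high_id: int
    removed_duplicate: int
    removed_diversity_cap: int
    n_kept: int


@dataclass(frozen=True)
class MsaStats:
    n_members: int
    n_hits: int
    neff: float


def merge_msas(a: Msa, b: Msa) -> Msa:
    """Merge two alignments over the same query.

    The query appears once (first), then a's members, then b's, in order;
    exact duplicates — equal (header, match-state string) — appear once.
    Raises ``ValueError`` if the queries' match-state strings differ.
    """
    if a.query.seq != b.query.seq:
        raise ValueError(
            f"query mismatch: {a.query_id!r} and {b.query_id!r} differ in sequence"
        )
    seen: set[tuple[str, str]] = set()
    members: list[AlignedSequence] = []
    for m in list(a.members) + list(b.members[1:]):
        key = (m.id, m.match_string)
        if key in seen:
            continue
        seen.add(key)
        members.append(m)
    return Msa(query_id=a.query_id, members=tuple(members), L=a.L)


def pairwise_identity(x: AlignedSequence, y: AlignedSequence, L: int) -> float:
    """Fraction of the L match columns where x and y carry the same residue.

    Gaps and unknown residues (``X``) match nothing, so two gapped columns
    count as a mismatch.
    """
    xs, ys = x.match_string, y.match_string
    if len(xs) != L or len(ys) != L:
        raise ValueError(f"match-state length mismatch: {len(xs)}, {len(ys)} vs L={L}")
    same = sum(1 for a, b in zip(xs, ys) if a == b and a != "-" and a != "X")
    return same / L


def _farthest_point_subset(
    msa: Msa, candidates: list[int], seqids: dict[int, float], k: int
) -> list[int]:
    # Greedy max-min selection seeded with the query: repeatedly add the
    # candidate farthest (1 - pairwise identity) from everything selected.
    # Ties: higher query identity first, then input order.
    L = msa.L
    strings = {i: msa.members[i].match_string for i in candidates}
    qstr = msa.query.seq

    def pid(s: str, t: str) -> float:
        same = sum(1 for a, b in zip(s, t) if a == b and a != "-" and a != "X")
        return same / L

    min_dist = {i: 1.0 - pid(strings[i], qstr) for i in candidates}
    order = {i: r for r, i in enumerate(candidates)}
    selected: list[int] = []
    remaining = set(candidates)
    while len(selected) < k and remaining:
        best = max(
            remaining,
            key=lambda i: (min_dist[i], seqids[i], -order[i]),
        )
        selected.append(best)
        remaining.discard(best)
        bs = strings[best]
        for i in remaining:
            d = 1.0 - pid(strings[i], bs)
            if d < min_dist[i]:
                min_dist[i] = d
    return selected


def filter_msa_report(msa: Msa, params: FilterParams) -> tuple[Msa, FilterLog]:
    """:func:`filter_msa` plus a :class:`FilterLog` of every decision count."""
    seqids = {i: sequence_identity(msa, i) for i in range(1, len(msa.members))}

    low = high = dup = 0
    seen_seqs: set[str] = set()
    windowed: list[int] = []
    for i in range(1, len(msa.members)):
        sid = seqids[i]
        if sid < params.min_qid:
            low += 1
            continue
        if sid > params.max_qid:
            high += 1
            continue
        ms = msa.members[i].match_string
        if ms in seen_seqs:
            dup += 1
            continue
        seen_seqs.add(ms)
        windowed.append(i)

    capped = 0
    if len(windowed) > params.max_kept:
        kept = _farthest_point_subset(msa, windowed, seqids, params.max_kept)
        capped = len(windowed) - len(kept)
        kept_set = set(kept)
        windowed = [i for i in windowed if i in kept_set]

    # Output order: query first, then by descending query identity,
    # ties broken by input order.
    windowed.sort(key=lambda i: (-seqids[i], i))
    members = (msa.query,) + tuple(msa.members[i] for i in windowed)
    out = Msa(query_id=msa.query_id, members=members, L=msa.L)
    log = FilterLog(
        n_input=msa.n_hits,
        removed_low_id=low,
        removed_high_id=high,
        removed_duplicate=dup,
        removed_diversity_cap=capped,
        n_kept=len(windowed),
    )
    return out, log


def filter_msa(msa: Msa, params: FilterParams | None = None) -> Msa:
    """Apply the identity window, duplicate collapse and diversity cap.

    The query is always retained; the result may be query-only. The
    operation is idempotent.
    """
    if params is None:
        params = FilterParams()
    return filter_msa_report(msa, params)[0]


def _henikoff_weights(cols: np.ndarray) -> np.ndarray:
    """Position-based sequence weights over match columns.

    ``cols`` is an (n_seq, L) integer matrix; values 0..19 are residues,
    -1 is gap/unknown. Each column distributes 1/(r * s) to every sequence,
    where r is the number of distinct residue types in the column and s the
    count of the sequence's own residue; gapped positions get nothing.
    Weights are normalized to sum to 1.
    """
    n, L = cols.shape
    w = np.zeros(n)
    for c in range(L):
        col = cols[:, c]
        mask = col >= 0
        if not mask.any():
            continue
        vals, inverse, counts = np.unique(col[mask], return_inverse=True, return_counts=True)
        r = len(vals)
        w[mask] += 1.0 / (r * counts[inverse])
    total = w.sum()
    if total <= 0:
        # all-gap alignment: fall back to uniform weights
        return np.full(n, 1.0 / n)
    return w / total


def _encode(msa: Msa) -> np.ndarray:
    cols = np.full((len(msa.members), msa.L), -1, dtype=np.int32)
    for i, m in enumerate(msa.members):
        for j, c in enumerate(m.match_string):
            cols[i, j] = _AA_INDEX.get(c, -1)
    return cols


def neff(msa: Msa) -> float:
    """Effective number of sequences of an alignment.

    exp of the mean over match columns of the Shannon entropy (natural
    log) of Henikoff-weighted residue frequencies; gaps and ``X`` are
    excluded from column counts and an all-gap column contributes zero
    entropy. Bounded by [1, 20].
    """
    cols = _encode(msa)
    w = _henikoff_weights(cols)
    n, L = cols.shape
    entropies = np.zeros(L)
    for c in range(L):
        col = cols[:, c]
        mask = col >= 0
        if not mask.any():
            continue
        freqs = np.bincount(col[mask], weights=w[mask], minlength=20)
        total = freqs.sum()
        if total <= 0:
            continue
        p = freqs[freqs > 0] / total
        entropies[c] = -(p * np.log(p)).sum()
    return float(math.exp(entropies.mean()))


def msa_stats(msa: Msa) -> MsaStats:
    """Member/hit counts and N_eff of an alignment."""
    return MsaStats(n_members=msa.n_members, n_hits=msa.n_hits, neff=neff(msa))
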