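"""Discordant read-pair classification, pooled clustering and SV candidates.

A pair is *discordant* when both mates map with mapping quality >= 29 but
the alignment geometry is abnormal: not in the expected inner-facing
(+,-) orientation, an insert span >= 1,000 bp, or mates on different
sequences.  Discordant pairs from all accessions are pooled, clustered by
requiring both anchors of two pairs to start within a window (225 bp by
default, single linkage), and clusters supported by at least three pairs
become SV candidates.

Signature table (paired-end SV signatures):

====================  ======================  ==============
strands (left,right)  extra condition         signature
====================  ======================  ==============
(+,-)                 insert_span >= min      deletion_signal
(+,+) or (-,-)        --                      inversion_signal
(-,+)                 --                      eversion_signal
different chroms      --                      interchrom_signal
====================  ======================  ==============

``eversion_signal`` and ``interchrom_signal`` candidates are reported as
transpositions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignio import ReadPairRecord

logger = logging.getLogger(__name__)

MIN_MAPQ = 29
MIN_INSERT = 1000
CLUSTER_WINDOW = 225
MIN_SUPPORT = 3

SIGNATURE_TO_SVTYPE = {
    "deletion_signal": "deletion",
    "inversion_signal": "inversion",
    "eversion_signal": "transposition",
    "interchrom_signal": "transposition",
}


@dataclass(frozen=True)
class DiscordantPair:
    record: ReadPairRecord
    signature: str


@dataclass(eq=False)
class SvCandidate:
    id: int
    sv_type: str  # deletion, inversion, transposition
    chrom: str
    start: int
    end: int
    size: int
    support: int
    accessions: frozenset
    chrom_right: str = ""
    left_anchor: tuple = ()
    right_anchor: tuple = ()
    pair_ids: tuple = ()

    def __post_init__(self):
        if not self.chrom_right:
            self.chrom_right = self.chrom

    @property
    def interval(self):
        return (self.start, self.end)

    def __eq__(self, other):
        if not isinstance(other, SvCandidate):
            return NotImplemented
        return (self.id, self.sv_type, self.chrom, self.start, self.end,
                self.size, self.support, self.accessions) == \
               (other.id, other.sv_type, other.chrom, other.start, other.end,
                other.size, other.support, other.accessions)


def classify_pair(record: ReadPairRecord, min_mapq: int = MIN_MAPQ,
                  min_insert: int = MIN_INSERT):
    """Classify one pair: ``"normal"``, ``"low_quality"`` or a
    :class:`DiscordantPair` carrying its SV signature."""
    if record.mapq_left < min_mapq or record.mapq_right < min_mapq:
        return "low_quality"
    if record.chrom_left != record.chrom_right:
        return DiscordantPair(record, "interchrom_signal")
    sl, sr = record.strand_left, record.strand_right
    if sl == sr:
        return DiscordantPair(record, "inversion_signal")
    if (sl, sr) == ("-", "+"):
        return DiscordantPair(record, "eversion_signal")
    # inner-facing (+,-): discordant only on a long insert
    if record.insert_span >= min_insert:
        return DiscordantPair(record, "deletion_signal")
    return "normal"


def pool_discordant(streams: dict, min_mapq: int = MIN_MAPQ,
                    min_insert: int = MIN_INSERT):
    """Classify and pool pairs from per-accession record streams.

    Returns ``(pooled discordant list, per-accession counts dict)`` where
    counts track normal / low_quality / discordant per accession.
    """
    pooled: list[DiscordantPair] = []
    counts: dict[str, dict] = {}
    for accession, stream in streams.items():
        c = {"normal": 0, "low_quality": 0, "discordant": 0}
        for rec in stream:
            verdict = classify_pair(rec, min_mapq, min_insert)
            if isinstance(verdict, DiscordantPair):
                c["discordant"] += 1
                pooled.append(verdict)
            else:
                c[verdict] += 1
        counts[accession] = c
        logger.info("%s: %s", accession, c)
    return pooled, counts


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_pairs(pool: Sequence[DiscordantPair], window: int = CLUSTER_WINDOW,
                  min_support: int = MIN_SUPPORT) -> list[list[DiscordantPair]]:
    """Single-linkage clustering of pooled discordant pairs.

    Two pairs link iff they share signature and chromosome(s) and both
    their left-anchor starts and their right-anchor starts lie within
    ``window`` bp.  Clusters with fewer than ``min_support`` members are
    discarded.  The result is independent of input order (the pool is
    canonically sorted before linking).
    """
    if window <= 0 or min_support < 1:
        raise ValueError("window must be > 0 and min_support >= 1")
    groups: dict[tuple, list[DiscordantPair]] = {}
    for dp in pool:
        key = (dp.signature, dp.record.chrom_left, dp.record.chrom_right)
        groups.setdefault(key, []).append(dp)
    clusters = []
    for key, members in sorted(groups.items()):
        members.sort(key=lambda dp: (dp.record.left_start, dp.record.right_start,
                                     dp.record.pair_id))
        lefts = np.array([dp.record.left_start for dp in members])
        rights = np.array([dp.record.right_start for dp in members])
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            # members are sorted by left start; only a bounded span ahead
            # can satisfy the left-anchor window
            j = i + 1
            while j < len(members) and lefts[j] - lefts[i] <= window:
                if abs(int(rights[j]) - int(rights[i])) <= window:
                    uf.union(i, j)
                j += 1
        by_root: dict[int, list] = {}
        for i in range(len(members)):
            by_root.setdefault(uf.find(i), []).append(members[i])
        for root in sorted(by_root):
            cl = by_root[root]
            if len(cl) >= min_support:
                clusters.append(cl)
    return clusters


def make_candidates(clusters: Iterable[Sequence[DiscordantPair]]) -> list[SvCandidate]:
    """Turn clusters into typed SV candidates.

    Deletions take the inner edges of the two anchor groups as the
    predicted interval [max left_end, min right_start); deletion clusters
    with a non-positive predicted size are rejected.  Inversions and
    transpositions span [min left_start, max right_end).
    """
    out = []
    cid = 0
    for cl in clusters:
        sigs = {dp.signature for dp in cl}
        if len(sigs) != 1:
            raise RuntimeError(f"cluster mixes signatures {sigs}: clustering bug")
        sig = sigs.pop()
        sv_type = SIGNATURE_TO_SVTYPE[sig]
        recs = [dp.record for dp in cl]
        chrom = recs[0].chrom_left
        chrom_r = recs[0].chrom_right
        left_anchor = (min(r.left_start for r in recs), max(r.left_end for r in recs))
        right_anchor = (min(r.right_start for r in recs), max(r.right_end for r in recs))
        if sig == "deletion_signal":
            start = max(r.left_end for r in recs)
            end = min(r.right_start for r in recs)
            if end <= start:
                logger.debug("rejecting deletion cluster with non-positive size")
                continue
        else:
            start = min(r.left_start for r in recs)
            end = max(r.right_end for r in recs)
        out.append(SvCandidate(
            id=cid, sv_type=sv_type, chrom=chrom, chrom_right=chrom_r,
            start=start, end=end, size=end - start, support=len(recs),
            accessions=frozenset(r.accession for r in recs),
            left_anchor=left_anchor, right_anchor=right_anchor,
            pair_ids=tuple(r.pair_id for r in recs),
        ))
        cid += 1
    return out


def call_svs(streams: dict, window: int = CLUSTER_WINDOW,
             min_support: int = MIN_SUPPORT, min_mapq: int = MIN_MAPQ,
             min_insert: int = MIN_INSERT):
    """Convenience: classify, pool, cluster and emit candidates.

    Returns ``(candidates, pooled_discordant, per-accession counts)``.
    """
    pooled, counts = pool_discordant(streams, min_mapq, min_insert)
    clusters = cluster_pairs(pooled, window, min_support)
    return make_candidates(clusters), pooled, counts
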