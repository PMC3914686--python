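"""The SV filter cascade.

Candidates surviving clustering are filtered in a fixed order:

1. *reference-accession* — any candidate whose supporting accessions
   include the line that built the reference genome is spurious (aligning
   a line to itself cannot reveal a real variant);
2. *minimum size* — only SVs >= 1,000 bp are retained;
3. *deletion depth* — a true homozygous deletion leaves (almost) no
   coverage, so every carrier's mean depth over the predicted interval
   must fall in that carrier's lowest 10th percentile of genome-wide
   (per-1 kb-tile) depths;
4. *coverage band* (inversions/transpositions) — interval depth must stay
   between the 10th and 90th percentile for every supporting accession;
5. *discordant density* — candidates whose endpoints sit in windows rich
   in unrelated discordant pairs (repeat-like regions) are dropped: the
   count of pooled discordant anchors in a 5,000 bp window centred on
   each endpoint, discounting the candidate's own pairs, must not exceed
   the genome-wide 90th percentile of 5 kb-tile counts.

If any supporting accession fails a test the candidate is rejected for
all accessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FILTER_ORDER = ["ref_accession", "min_size", "deletion_depth",
                "coverage_band", "discordant_density"]


@dataclass
class DepthProfile:
    """Genome-wide depth distribution for one accession, summarized over
    non-overlapping tiles (1 kb by default)."""

    accession: str
    tile_size: int
    tile_means: np.ndarray

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.tile_means, q))

    def interval_mean(self, start: int, end: int) -> float:
        """Mean tile depth over [start, end).

        Uses tiles fully contained in the interval so that flanking
        sequence in partially-overlapping boundary tiles does not leak
        in; short intervals without a fully-contained tile fall back to
        the overlapping tiles.
        """
        if start < 0 or end > len(self.tile_means) * self.tile_size or end <= start:
            raise ValueError(f"interval [{start},{end}) outside depth profile")
        t0 = (start + self.tile_size - 1) // self.tile_size
        t1 = end // self.tile_size
        if t1 <= t0:  # interval smaller than one tile
            t0 = start // self.tile_size
            t1 = (end - 1) // self.tile_size + 1
        return float(self.tile_means[t0:t1].mean())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#accession={self.accession}\ttile_size={self.tile_size}\n")
            for i, d in enumerate(self.tile_means):
                fh.write(f"{i * self.tile_size}\t{float(d)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "DepthProfile":
        with open(path) as fh:
            header = fh.readline().lstrip("#").split("\t")
            meta = dict(kv.split("=") for kv in header)
            vals = [float(line.split("\t")[1]) for line in fh if line.strip()]
        return cls(meta["accession"].strip(), int(meta["tile_size"]),
                   np.asarray(vals))


class DiscordantIndex:
    """Positional index of pooled discordant-pair anchors for the density
    filter; the background is the genome-wide distribution of anchor
    counts in non-overlapping 5 kb tiles."""

    def __init__(self, pooled, genome_length: int, window: int = 5000):
        self.window = window
        anchors = []
        self.anchors_by_pair = {}
        for dp in pooled:
            r = dp.record
            anchors.append(r.left_start)
            anchors.append(r.right_start)
            self.anchors_by_pair[r.pair_id] = (r.left_start, r.right_start)
        self.anchors = np.sort(np.asarray(anchors, dtype=np.int64))
        n_tiles = max(genome_length // window, 1)
        counts = np.bincount(
            np.minimum(self.anchors // window, n_tiles - 1), minlength=n_tiles) \
            if len(self.anchors) else np.zeros(n_tiles)
        self.background_p90 = float(np.percentile(counts, 90))

    def count_window(self, center: int, exclude_pair_ids=()) -> int:
        lo, hi = center - self.window // 2, center + self.window // 2
        total = int(np.searchsorted(self.anchors, hi, side="left")
                    - np.searchsorted(self.anchors, lo, side="left"))
        for pid in exclude_pair_ids:
            for a in self.anchors_by_pair.get(pid, ()):
                if lo <= a < hi:
                    total -= 1
        return total


def reference_accession_filter(candidate, reference_line: str) -> bool:
    """Fail when the reference line supports the candidate."""
    return reference_line not in candidate.accessions


def min_size_filter(candidate, min_size: int = 1000) -> bool:
    return candidate.size >= min_size


def deletion_depth_filter(candidate, profiles: dict,
                          low_pct: float = 10.0) -> bool:
    """Every carrier's mean depth over the interval must be at or below
    that carrier's ``low_pct`` percentile."""
    for acc in candidate.accessions:
        prof = profiles[acc]
        if prof.interval_mean(candidate.start, candidate.end) > \
                prof.percentile(low_pct):
            return False
    return True


def coverage_band_filter(candidate, profiles: dict, low_pct: float = 10.0,
                         high_pct: float = 90.0) -> bool:
    """Interval depth must stay within [low, high] percentiles for every
    supporting accession (inversions/transpositions)."""
    for acc in candidate.accessions:
        prof = profiles[acc]
        mean = prof.interval_mean(candidate.start, candidate.end)
        if not prof.percentile(low_pct) <= mean <= prof.percentile(high_pct):
            return False
    return True


def discordant_density_filter(candidate, index: DiscordantIndex) -> bool:
    """Both endpoint windows, discounting the candidate's own pairs, must
    not exceed the genome-wide 90th percentile of window counts."""
    for endpoint in (candidate.start, candidate.end):
        if index.count_window(endpoint, candidate.pair_ids) > index.background_p90:
            return False
    return True


def apply_cascade(candidates, profiles: dict, index: DiscordantIndex,
                  reference_line: str, min_size: int = 1000,
                  low_pct: float = 10.0, high_pct: float = 90.0):
    """Apply the full cascade; returns (retained, verdicts DataFrame).

    The verdict table holds one row per input candidate with a pass/fail
    flag per applicable filter (NA where not applicable) and the final
    fate.  Filters are evaluated in declared order but all applicable
    flags are recorded even after the first failure, so the table fully
    explains each drop.
    """
    rows = []
    retained = []
    for c in candidates:
        flags = {
            "ref_accession": reference_accession_filter(c, reference_line),
            "min_size": min_size_filter(c, min_size),
        }
        if c.sv_type == "deletion":
            flags["deletion_depth"] = deletion_depth_filter(c, profiles, low_pct)
            flags["coverage_band"] = pd.NA
        else:
            flags["deletion_depth"] = pd.NA
            flags["coverage_band"] = coverage_band_filter(c, profiles,
                                                          low_pct, high_pct)
        flags["discordant_density"] = discordant_density_filter(c, index)
        final = all(v for v in flags.values() if v is not pd.NA)
        if final:
            retained.append(c)
        rows.append({"candidate_id": c.id, "sv_type": c.sv_type, **flags,
                     "retained": final})
    verdicts = pd.DataFrame(rows)
    if len(verdicts):
        logger.info("cascade: %d in, %d retained", len(verdicts), len(retained))
    return retained, verdicts
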