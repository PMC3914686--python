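"""Pileup-style base calling and population SNP table construction.

Lines are inbred and effectively homozygous, so one base call per line
suffices.  A base is called at a site when depth is between 3x and a
per-line maximum (25x by default; high-coverage lines may allow 40x) and
strictly more than 75% of the reads agree; SNPs are sites callable in
*all* focal lines and polymorphic among them.  Coding SNPs are assigned
synonymous/nonsynonymous using the reading frame of the gene's longest
transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass
class SiteCall:
    accession: str
    chrom: str
    pos: int
    depth: int
    base: str | None
    reason: str | None = None  # low_depth / high_depth / no_majority


def call_base(base_counts, depth: int | None = None, max_depth: int = 25,
              min_depth: int = 3, majority: float = 0.75,
              accession: str = "", chrom: str = "", pos: int = 0) -> SiteCall:
    """Call one site from base counts; the majority must be strict
    (> ``majority``), so an exact 75% plurality stays uncalled."""
    counts = {b: int(base_counts.get(b, 0)) for b in BASES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative base counts")
    if depth is None:
        depth = sum(counts.values())
    if depth < min_depth:
        return SiteCall(accession, chrom, pos, depth, None, "low_depth")
    if depth > max_depth:
        return SiteCall(accession, chrom, pos, depth, None, "high_depth")
    best = max(BASES, key=lambda b: counts[b])
    if counts[best] > majority * depth:
        return SiteCall(accession, chrom, pos, depth, best)
    return SiteCall(accession, chrom, pos, depth, None, "no_majority")


def call_pileup(pileup: pd.DataFrame, accession: str, max_depth: int = 25,
                min_depth: int = 3, majority: float = 0.75) -> pd.DataFrame:
    """Vectorized base calling over a pileup table with columns
    ``chrom, pos, depth, A, C, G, T``; returns calls with a ``base``
    column (NaN where uncallable) and the missing ``reason``."""
    depth = pileup["depth"].to_numpy()
    counts = pileup[list(BASES)].to_numpy()
    best_idx = counts.argmax(axis=1)
    best_count = counts.max(axis=1)
    base = np.array(BASES)[best_idx].astype(object)
    called = ((depth >= min_depth) & (depth <= max_depth)
              & (best_count > majority * depth))
    reason = np.select(
        [depth < min_depth, depth > max_depth, ~called],
        ["low_depth", "high_depth", "no_majority"], default="")
    base[~called] = None
    return pd.DataFrame({"chrom": pileup["chrom"], "pos": pileup["pos"],
                         "depth": depth, "base": base,
                         "reason": np.where(called, None, reason)},
                        index=pileup.index)


def build_snp_table(calls: dict, focal_lines: list) -> pd.DataFrame:
    """Population SNP table from per-line call tables.

    Keeps sites callable in every focal line and polymorphic among them.
    Multi-allelic sites are retained and flagged; their minor-allele
    count pools all non-major alleles.  Returns a table indexed by
    (chrom, pos) with one allele column per line plus ``major``,
    ``minor_count`` and ``multiallelic``.
    """
    mats = []
    for line in focal_lines:
        df = calls[line].set_index(["chrom", "pos"])["base"].rename(line)
        mats.append(df)
    table = pd.concat(mats, axis=1, join="outer")
    table = table.dropna(how="any")
    alleles = table[focal_lines]
    n_alleles = alleles.nunique(axis=1)
    table = table[n_alleles > 1].copy()
    counts = table[focal_lines].apply(lambda r: r.value_counts(), axis=1).fillna(0)
    major = counts.idxmax(axis=1)
    n = len(focal_lines)
    table["major"] = major
    table["minor_count"] = (n - counts.max(axis=1)).astype(int)
    table["multiallelic"] = counts.gt(0).sum(axis=1) > 2
    return table


# ---------------------------------------------------------------------------
# Coding-effect annotation


def _cds_intervals(features, transcript_id: str):
    """CDS intervals for a transcript: explicit CDS rows when present,
    otherwise exons with UTR overlap trimmed out."""
    cds = sorted((f.start, f.end) for f in features
                 if f.transcript_id == transcript_id and f.kind == "CDS")
    if cds:
        return cds
    exons = sorted((f.start, f.end) for f in features
                   if f.transcript_id == transcript_id and f.kind == "exon")
    utrs = sorted((f.start, f.end) for f in features
                  if f.transcript_id == transcript_id
                  and f.kind in ("five_prime_UTR", "three_prime_UTR"))
    out = []
    for s, e in exons:
        segs = [(s, e)]
        for us, ue in utrs:
            segs = [seg for piece in segs
                    for seg in _subtract(piece, (us, ue))]
        out.extend(segs)
    return sorted(out)


def _subtract(seg, cut):
    s, e = seg
    cs, ce = cut
    if ce <= s or cs >= e:
        return [seg]
    pieces = []
    if cs > s:
        pieces.append((s, cs))
    if ce < e:
        pieces.append((ce, e))
    return pieces


def annotate_effect(chrom: str, pos: int, ref_base: str, alt_base: str,
                    features, reference: str) -> str:
    """Effect of a substitution: noncoding, synonymous or nonsynonymous.

    Uses the coding frame of the longest transcript of the overlapping
    gene; sites in genes whose CDS length is not a multiple of three are
    skipped with a warning (returned as ``noncoding``).
    """
    gene = next((f for f in features if f.kind == "gene" and f.chrom == chrom
                 and f.start <= pos < f.end), None)
    if gene is None:
        return "noncoding"
    tids = {f.transcript_id for f in features
            if f.gene_id == gene.gene_id and f.longest and f.transcript_id}
    if not tids:
        return "noncoding"
    tid = sorted(tids)[0]
    cds = _cds_intervals([f for f in features if f.gene_id == gene.gene_id], tid)
    total = sum(e - s for s, e in cds)
    if total % 3 != 0:
        logger.warning("CDS of %s has length %d (not divisible by 3); "
                       "site %s:%d skipped", tid, total, chrom, pos)
        return "noncoding"
    offset = None
    acc = 0
    for s, e in cds:
        if s <= pos < e:
            offset = acc + (pos - s)
            break
        acc += e - s
    if offset is None:
        return "noncoding"
    spliced = "".join(reference[s:e] for s, e in cds)
    if gene.strand == "-":
        offset = total - 1 - offset
        spliced = str(Seq(spliced).reverse_complement())
        ref_base = str(Seq(ref_base).complement())
        alt_base = str(Seq(alt_base).complement())
    if spliced[offset] != ref_base:
        logger.warning("reference mismatch at %s:%d (%s vs %s)",
                       chrom, pos, spliced[offset], ref_base)
    codon_i = offset // 3
    frame = offset % 3
    codon = spliced[codon_i * 3:codon_i * 3 + 3]
    mutant = codon[:frame] + alt_base + codon[frame + 1:]
    return ("synonymous" if Seq(codon).translate() == Seq(mutant).translate()
            else "nonsynonymous")
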