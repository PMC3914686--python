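"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to and from
the 1-based conventions of SAM, GFF3 and VCF happens only at the I/O
boundary.  ``insert_span`` is the outer distance between the two mapped
ends of a pair (|TLEN| in SAM terms).

The ``pair_tsv`` dialect is a plain 12-column table, one aligned pair per
row, with a ``#``-prefixed header::

    accession chrom_left chrom_right left_start left_end right_start
    right_end strand_left strand_right mapq_left mapq_right insert_span

Positions in the TSV are already 0-based half-open; the SAM bitwise flag
is reconstructed from the strand fields on load.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

logger = logging.getLogger(__name__)

PAIR_TSV_COLUMNS = [
    "accession",
    "chrom_left",
    "chrom_right",
    "left_start",
    "left_end",
    "right_start",
    "right_end",
    "strand_left",
    "strand_right",
    "mapq_left",
    "mapq_right",
    "insert_span",
]

_INT_COLS = {"left_start", "left_end", "right_start", "right_end",
             "mapq_left", "mapq_right", "insert_span"}


@dataclass(frozen=True)
class ReadPairRecord:
    """One aligned read pair; the left anchor has the smaller start when
    both mates map to the same sequence."""

    accession: str
    chrom_left: str
    chrom_right: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    strand_left: str
    strand_right: str
    mapq_left: int
    mapq_right: int
    insert_span: int
    flag: int = 0
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not (self.left_start < self.left_end and self.right_start < self.right_end):
            raise ValueError("anchor intervals must be non-empty")
        if self.chrom_left == self.chrom_right and self.left_start > self.right_start:
            raise ValueError("left anchor must have the smaller start")
        if self.insert_span < 0:
            raise ValueError("insert_span must be >= 0")


@dataclass
class FeatureRecord:
    """One annotated interval (gene component or transposable element)."""

    chrom: str
    start: int
    end: int
    kind: str  # gene, exon, five_prime_UTR, three_prime_UTR, intron, TE
    family: str = ""
    transcript_id: str = ""
    gene_id: str = ""
    strand: str = "+"
    longest: bool = False  # set on components of the longest transcript

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty feature interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _flag_from_strands(strand_left: str, strand_right: str) -> int:
    flag = 0x1 | 0x40
    if strand_left == "-":
        flag |= 0x10
    if strand_right == "-":
        flag |= 0x20
    return flag


def _order_anchors(a, b):
    """Order two (chrom, start, end, strand, mapq) anchors left/right."""
    if (a[0], a[1]) <= (b[0], b[1]):
        return a, b
    return b, a


def load_alignments(path, dialect: str, accession: str | None = None,
                    counters: dict | None = None) -> Iterator[ReadPairRecord]:
    """Stream read pairs from a SAM/BAM file or a 12-column pair TSV.

    Pairs with an unmapped mate (or an orphan record) are skipped and
    counted under ``counters['skipped']``.
    """
    if counters is None:
        counters = {}
    counters.setdefault("skipped", 0)
    counters.setdefault("loaded", 0)
    if dialect == "sam_bam":
        yield from _load_sam(path, accession, counters)
    elif dialect == "pair_tsv":
        yield from _load_pair_tsv(path, counters)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    logger.info("loaded %d pairs from %s (%d skipped)",
                counters["loaded"], path, counters["skipped"])


def _load_sam(path, accession, counters):
    mode = "rb" if str(path).endswith(".bam") else "r"
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), mode) as fh:
        acc = accession or Path(str(path)).stem
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_unmapped or read.mate_is_unmapped:
                counters["skipped"] += 1
                pending.pop(read.query_name, None)
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            left, right = _order_anchors(
                (mate.reference_name, mate.reference_start, mate.reference_end,
                 "-" if mate.is_reverse else "+", mate.mapping_quality),
                (read.reference_name, read.reference_start, read.reference_end,
                 "-" if read.is_reverse else "+", read.mapping_quality),
            )
            span = abs(read.template_length) if read.reference_name == mate.reference_name else 0
            counters["loaded"] += 1
            yield ReadPairRecord(
                accession=acc,
                chrom_left=left[0], chrom_right=right[0],
                left_start=left[1], left_end=left[2],
                right_start=right[1], right_end=right[2],
                strand_left=left[3], strand_right=right[3],
                mapq_left=left[4], mapq_right=right[4],
                insert_span=span, flag=read.flag,
                pair_id=f"{acc}:{read.query_name}",
            )
    counters["skipped"] += len(pending)  # orphans


def _load_pair_tsv(path, counters):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(PAIR_TSV_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(PAIR_TSV_COLUMNS)} columns, "
                    f"got {len(parts)}")
            row = dict(zip(PAIR_TSV_COLUMNS, parts))
            try:
                for col in _INT_COLS:
                    row[col] = int(row[col])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed integer field: {exc}")
            counters["loaded"] += 1
            yield ReadPairRecord(
                flag=_flag_from_strands(row["strand_left"], row["strand_right"]),
                pair_id=f"{row['accession']}:{lineno}",
                **row,
            )


def write_pair_tsv(records: Iterable[ReadPairRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIR_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(str(getattr(r, c)) for c in PAIR_TSV_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# GFF3 features


def load_features(path_gff3, te_types=("transposable_element", "repeat_region"),
                  utr_pad_kinds=None) -> list[FeatureRecord]:
    """Load genes, transcripts components and TEs from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Introns are synthesized per transcript (gene span minus exons), the
    longest transcript of each gene is flagged, and child features poking
    outside their parent span are clamped with a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path_gff3), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    out: list[FeatureRecord] = []

    for te in db.all_features():
        if te.featuretype in te_types or te.source == "TE":
            family = te.attributes.get("Family", te.attributes.get("family", [""]))[0]
            out.append(FeatureRecord(te.seqid, te.start - 1, te.end, "TE",
                                     family=family, strand=te.strand or "+"))

    for gene in db.features_of_type("gene"):
        gspan = (gene.start - 1, gene.end)
        family = gene.attributes.get("Family", gene.attributes.get("family", [""]))[0]
        out.append(FeatureRecord(gene.seqid, gspan[0], gspan[1], "gene",
                                 family=family, gene_id=gene.id,
                                 strand=gene.strand or "+"))
        transcripts = list(db.children(gene, featuretype="mRNA"))
        if not transcripts:
            continue
        longest_id = max(transcripts, key=lambda t: t.end - t.start + 1).id
        for tr in transcripts:
            is_longest = tr.id == longest_id
            exons = []
            for kind in ("exon", "five_prime_UTR", "three_prime_UTR", "CDS"):
                for child in db.children(tr, featuretype=kind):
                    s, e = child.start - 1, child.end
                    if s < gspan[0] or e > gspan[1]:
                        logger.warning("feature %s outside parent %s; clamping",
                                       child.id, gene.id)
                        s, e = max(s, gspan[0]), min(e, gspan[1])
                    rec = FeatureRecord(child.seqid, s, e, kind,
                                        family=family, transcript_id=tr.id,
                                        gene_id=gene.id, strand=tr.strand or "+",
                                        longest=is_longest)
                    out.append(rec)
                    if kind == "exon":
                        exons.append((s, e))
            # introns: transcript span minus exons
            exons.sort()
            for (s1, e1), (s2, _) in zip(exons, exons[1:]):
                if e1 < s2:
                    out.append(FeatureRecord(gene.seqid, e1, s2, "intron",
                                             family=family, transcript_id=tr.id,
                                             gene_id=gene.id,
                                             strand=tr.strand or "+",
                                             longest=is_longest))
    return out


# ---------------------------------------------------------------------------
# Call files

CALL_TSV_COLUMNS = [
    "id", "sv_type", "chrom", "start", "end", "size", "support", "accessions",
]


def write_calls(candidates, path, format: str = "tsv",
                accessions_order: list[str] | None = None) -> None:
    """Write SV candidates as BED (0-based), VCF-like (1-based) or TSV.

    The TSV round-trips exactly through :func:`read_calls`.
    """
    candidates = list(candidates)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(CALL_TSV_COLUMNS) + "\n")
            for c in candidates:
                fh.write("\t".join([
                    str(c.id), c.sv_type, c.chrom, str(c.start), str(c.end),
                    str(c.size), str(c.support), ",".join(sorted(c.accessions)),
                ]) + "\n")
    elif format == "bed":
        with open(path, "w") as fh:
            for c in candidates:
                name = f"{c.sv_type}:{c.support}"
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\n")
    elif format == "vcf_like":
        if accessions_order is None:
            accs = sorted({a for c in candidates for a in c.accessions})
        else:
            accs = list(accessions_order)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCF-like\n")
            fh.write('##INFO=<ID=SVTYPE>\n##INFO=<ID=SVLEN>\n##INFO=<ID=END>\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(accs) + "\n")
            for c in candidates:
                svlen = -c.size if c.sv_type == "deletion" else c.size
                info = f"SVTYPE={c.sv_type.upper()[:3]};END={c.end};SVLEN={svlen}"
                gts = ["1" if a in c.accessions else "0" for a in accs]
                fh.write(f"{c.chrom}\t{c.start + 1}\t{c.id}\tN\t<{c.sv_type.upper()[:3]}>"
                         f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")
    else:
        raise ValueError(f"unknown call format: {format!r}")


def read_calls(path):
    """Read a TSV call file written by :func:`write_calls` back into
    :class:`~indelpop.discordant_sv.SvCandidate` objects."""
    from .discordant_sv import SvCandidate

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cid, sv_type, chrom, start, end, size, support, accs = \
                line.rstrip("\n").split("\t")
            out.append(SvCandidate(
                id=int(cid), sv_type=sv_type, chrom=chrom,
                start=int(start), end=int(end), size=int(size),
                support=int(support),
                accessions=frozenset(accs.split(",")) if accs else frozenset(),
            ))
    return out
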