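"""Synthetic populations of inbred genomes with planted structural variants.

Generates the stand-in for a resequencing study of ten fully homozygous
focal lines plus two outgroup lines: a random reference sequence with
gene and transposable-element annotation, planted deletions (1-200 kb)
with a configurable minor-allele-count spectrum, SNPs with a neutral
frequency law, and per-line paired-end *alignment records* (reads are
never simulated at the base level; the pipeline consumes alignments, and
every detection signal — long-insert spanning pairs, zero read depth in
carried deletions, chimeric-pair noise concentrated in repeat-like
hotspots, low-mapping-quality noise — is reproduced directly on the
records).

Line ``L00`` is the reference accession: its genome *is* the reference,
so its abnormal pairs arise only from noise.  Deletion carriers are drawn
from the nine non-reference focal lines.  Outgroup lines carry the
ancestral state of every variant, so polarization against truth is exact;
for a configurable fraction of variants the *deletion* is ancestral
(outgroups deleted too), making the reference (insertion) allele the
derived one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignio import FeatureRecord, ReadPairRecord, write_pair_tsv
from .sv_filters import DepthProfile

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

TE_FAMILIES = ["MULE", "Gypsy", "Copia", "hAT", "CACTA", "Helitron", "LINE", "TRIM"]
TE_FAMILY_WEIGHTS = [0.14, 0.24, 0.17, 0.09, 0.10, 0.12, 0.08, 0.06]


def _default_frequency_law():
    # neutral-like: minor-allele count m carries weight 1/m
    w = np.array([1 / m for m in range(1, 6)])
    return dict(zip(range(1, 6), w / w.sum()))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Library geometry (insert mean 275.8 bp, SD 28.8 bp, 2x75 reads) and
    the 10 focal + 2 outgroup design mirror the emulated study; genome
    size and variant counts are desk-scale.
    """

    seed: int = 0
    n_focal_lines: int = 10
    n_outgroup_lines: int = 2
    genome_length: int = 4_000_000
    chrom: str = "chr1"
    n_genes: int = 300
    n_tes: int = 800
    deletion_count: int = 30
    deletion_size_range: tuple = (1000, 200_000)
    deletion_size_shape: float = 0.74  # Pareto tail index; median ~2.5 kb
    deletion_frequency_law: dict = field(default_factory=_default_frequency_law)
    derived_insertion_fraction: float = 0.25
    snp_density: float = 0.01
    coverage_mean: float = 8.0
    insert_mean: float = 275.8
    insert_sd: float = 28.8
    read_len: int = 75
    chimera_rate: float = 0.001
    repeat_hotspot_count: int = 5
    hotspot_length: int = 20_000
    hotspot_chimera_multiplier: float = 20.0
    mapq_low_fraction: float = 0.05
    reference_line_index: int = 0

    def __post_init__(self):
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be positive")
        for name in ("n_focal_lines", "n_outgroup_lines", "genome_length",
                     "n_genes", "n_tes", "deletion_count",
                     "repeat_hotspot_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.deletion_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid deletion_size_range")
        if not 0 <= self.chimera_rate <= 1 or not 0 <= self.mapq_low_fraction <= 1:
            raise ValueError("rates must be in [0,1]")

    @property
    def focal_lines(self):
        return [f"L{i:02d}" for i in range(self.n_focal_lines)]

    @property
    def outgroup_lines(self):
        return [f"OUT{i}" for i in range(self.n_outgroup_lines)]

    @property
    def reference_line(self):
        return self.focal_lines[self.reference_line_index]


@dataclass
class PopulationTruth:
    """Ground truth for one synthetic population."""

    config: SimConfig
    reference: str
    features: list
    variants: pd.DataFrame  # id, start, end, size, mac, carriers, deletion_is_derived
    snp_pos: np.ndarray
    snp_anc: np.ndarray
    snp_der: np.ndarray
    snp_carriers: np.ndarray  # (n_focal, n_snps) bool: carries derived allele
    hotspots: list
    alignable_mask: list

    @property
    def line_names(self):
        return self.config.focal_lines

    def deletions_of(self, line: str) -> list:
        """Sorted (start, end) intervals of deletions carried by a line."""
        if line in self.config.outgroup_lines:
            sel = self.variants[~self.variants.deletion_is_derived]
            return sorted(zip(sel.start, sel.end))
        return sorted(
            (row.start, row.end)
            for row in self.variants.itertuples()
            if line in row.carriers)

    def snp_allele_matrix(self, lines=None) -> pd.DataFrame:
        """Base carried by each line at each SNP; NaN where the site falls
        inside a deletion carried by that line (no sequence to call)."""
        lines = lines or (self.config.focal_lines + self.config.outgroup_lines)
        n_l = len(lines)
        out = np.empty((n_l, len(self.snp_pos)), dtype=object)
        focal = self.config.focal_lines
        for i, line in enumerate(lines):
            if line in focal:
                der = self.snp_carriers[focal.index(line)]
            else:
                der = np.zeros(len(self.snp_pos), dtype=bool)  # outgroups ancestral
            out[i] = np.where(der, self.snp_der, self.snp_anc)
            for s, e in self.deletions_of(line):
                inside = (self.snp_pos >= s) & (self.snp_pos < e)
                out[i, inside] = np.nan
        return pd.DataFrame(out, index=lines, columns=self.snp_pos)

    def indel_genotypes(self) -> pd.DataFrame:
        """0/1 deletion-carrier matrix over focal lines (rows: variants)."""
        mat = np.zeros((len(self.variants), len(self.line_names)), dtype=int)
        for r, row in enumerate(self.variants.itertuples()):
            for line in row.carriers:
                mat[r, self.line_names.index(line)] = 1
        return pd.DataFrame(mat, index=self.variants.id, columns=self.line_names)


def _place_intervals(rng, lengths, genome_length, occupied, max_tries=200):
    """Place intervals of the given lengths uniformly without overlapping
    ``occupied`` (a list of (start,end)); returns placed list, updates
    occupied.  Raises if the genome is too crowded."""
    placed = []
    for L in lengths:
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - L))
            e = s + L
            if all(e <= os or s >= oe for os, oe in occupied):
                occupied.append((s, e))
                placed.append((s, e))
                break
        else:
            raise ValueError(
                f"genome too small to place an interval of {L} bp "
                f"({len(occupied)} intervals already placed)")
    return placed


def _make_gene(rng, chrom, start, gene_id, family):
    """Build one gene model: 5'UTR, 3 exons / 2 introns, 3'UTR."""
    utr5 = int(rng.integers(100, 300))
    utr3 = int(rng.integers(100, 300))
    exons = [int(rng.integers(200, 600)) for _ in range(3)]
    introns = [int(rng.integers(100, 400)) for _ in range(2)]
    strand = "+" if rng.random() < 0.5 else "-"
    feats = []
    pos = start
    tid = f"{gene_id}.1"
    # assemble 5'->3' in genomic order; strand flips which end is 5'
    parts = [("five_prime_UTR", utr5)]
    for i, ex in enumerate(exons):
        parts.append(("exon", ex))
        if i < 2:
            parts.append(("intron", introns[i]))
    parts.append(("three_prime_UTR", utr3))
    if strand == "-":
        parts = [(k.replace("five", "X").replace("three", "five").replace("X", "three"), L)
                 for k, L in parts[::-1]]
    spans = []
    for kind, L in parts:
        spans.append((kind, pos, pos + L))
        pos += L
    end = pos
    feats.append(FeatureRecord(chrom, start, end, "gene", family=family,
                               gene_id=gene_id, strand=strand))
    for kind, s, e in spans:
        feats.append(FeatureRecord(chrom, s, e, kind, family=family,
                                   transcript_id=tid, gene_id=gene_id,
                                   strand=strand, longest=True))
    return feats, end


def generate_truth(config: SimConfig) -> PopulationTruth:
    """Generate the reference, annotation, planted variants and haplotypes.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0xA11E])
    L = config.genome_length
    reference = "".join(BASES[rng.integers(0, 4, size=L)])

    occupied_annot: list = []
    features: list = []
    # gene family sizes: mostly small families plus a few large ones
    fam_sizes = rng.geometric(0.25, size=max(config.n_genes // 4, 1))
    fam_of_gene = []
    for fi, fs in enumerate(fam_sizes):
        fam_of_gene += [f"GF{fi:04d}"] * int(fs)
    while len(fam_of_gene) < config.n_genes:
        fam_of_gene.append(f"GF{len(fam_of_gene):04d}")
    rng.shuffle(fam_of_gene)
    gene_total = 0
    for gi in range(config.n_genes):
        for _ in range(200):
            start = int(rng.integers(0, L - 4000))
            feats, end = _make_gene(rng, config.chrom, start, f"gene{gi:04d}",
                                    fam_of_gene[gi])
            if all(end <= os or start >= oe for os, oe in occupied_annot):
                occupied_annot.append((start, end))
                features.extend(feats)
                gene_total += 1
                break
        else:
            raise ValueError("genome too small for requested gene count")

    te_lengths = rng.integers(300, 3000, size=config.n_tes)
    te_fams = rng.choice(TE_FAMILIES, p=TE_FAMILY_WEIGHTS, size=config.n_tes)
    te_spans = _place_intervals(rng, te_lengths, L, occupied_annot)
    for (s, e), fam in zip(te_spans, te_fams):
        features.append(FeatureRecord(config.chrom, s, e, "TE", family=str(fam)))

    # repeat-like hotspots: excluded from the alignable mask and from
    # deletion placement; chimeric noise concentrates here
    hotspot_occupied: list = []
    hotspots = _place_intervals(
        rng, [config.hotspot_length] * config.repeat_hotspot_count, L,
        hotspot_occupied)
    hotspots.sort()

    # planted deletions: truncated-Pareto sizes (strongly right-skewed,
    # median ~2.5 kb with a tail to the range maximum), non-overlapping,
    # off-hotspot
    lo, hi = config.deletion_size_range
    a = config.deletion_size_shape
    u = rng.uniform(size=config.deletion_count)
    sizes = (lo * (1 - u * (1 - (lo / hi) ** a)) ** (-1 / a)).astype(int)
    sizes = np.clip(sizes, lo, hi)
    del_occupied = list(hotspot_occupied)
    del_spans = _place_intervals(rng, sorted(sizes, reverse=True), L, del_occupied)
    macs = list(config.deletion_frequency_law.keys())
    mac_p = np.array([config.deletion_frequency_law[m] for m in macs], dtype=float)
    mac_p /= mac_p.sum()
    non_ref = [l for i, l in enumerate(config.focal_lines)
               if i != config.reference_line_index]
    rows = []
    for vid, (s, e) in enumerate(sorted(del_spans)):
        mac = int(rng.choice(macs, p=mac_p))
        mac = min(mac, len(non_ref))
        carriers = tuple(sorted(rng.choice(non_ref, size=mac, replace=False)))
        deletion_is_derived = bool(rng.random() >= config.derived_insertion_fraction)
        rows.append((f"del{vid:04d}", s, e, e - s, mac, carriers,
                     deletion_is_derived))
    variants = pd.DataFrame(
        rows, columns=["id", "start", "end", "size", "mac", "carriers",
                       "deletion_is_derived"])

    # SNPs: uniform positions, neutral derived-count law over focal lines
    n_snps = rng.poisson(config.snp_density * L)
    snp_pos = np.sort(rng.choice(L, size=n_snps, replace=False))
    i_arr = np.arange(1, config.n_focal_lines)
    p_law = (1.0 / i_arr) / (1.0 / i_arr).sum()
    derived_counts = rng.choice(i_arr, p=p_law, size=n_snps)
    carriers = np.zeros((config.n_focal_lines, n_snps), dtype=bool)
    for j, dc in enumerate(derived_counts):
        idx = rng.choice(config.n_focal_lines, size=dc, replace=False)
        carriers[idx, j] = True
    ref_arr = np.frombuffer(reference.encode(), dtype="S1")
    ref_base = ref_arr[snp_pos].astype("U1")
    other = BASES[(np.searchsorted(BASES, ref_base) + rng.integers(1, 4, n_snps)) % 4]
    ref_is_derived = carriers[config.reference_line_index]
    snp_anc = np.where(ref_is_derived, other, ref_base)
    snp_der = np.where(ref_is_derived, ref_base, other)

    # alignable mask = genome minus hotspots
    mask = []
    prev = 0
    for s, e in hotspots:
        if s > prev:
            mask.append((prev, s))
        prev = e
    if prev < L:
        mask.append((prev, L))

    return PopulationTruth(
        config=config, reference=reference, features=features,
        variants=variants, snp_pos=snp_pos, snp_anc=snp_anc, snp_der=snp_der,
        snp_carriers=carriers, hotspots=hotspots, alignable_mask=mask)


# ---------------------------------------------------------------------------
# Read-pair simulation


def _line_pair_arrays(truth, config, line, rng):
    """Vectorized simulation of one line's aligned pairs; returns a dict of
    numpy arrays in reference coordinates plus the skip counter."""
    L = config.genome_length
    R = config.read_len
    dels = truth.deletions_of(line)
    del_len = np.array([e - s for s, e in dels], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(del_len)])
    # junctions in line coordinates; line position p maps to p + cum[idx]
    junctions = np.array([s - c for (s, _), c in zip(dels, cum[:-1])],
                         dtype=np.int64)
    L_line = L - int(del_len.sum())
    n_pairs = int(L_line * config.coverage_mean / (2 * R))
    F = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    F = np.maximum(F, 2 * R + 5).astype(np.int64)
    s = rng.integers(0, L_line - F.max(), size=n_pairs)

    def map_read(a, b):
        ia = np.searchsorted(junctions, a, side="right")
        ib = np.searchsorted(junctions, b - 1, side="right")
        ok = ia == ib
        return a + cum[ia], ok

    l_start, ok_l = map_read(s, s + R)
    r_start, ok_r = map_read(s + F - R, s + F)
    ok = ok_l & ok_r
    skipped = int((~ok).sum())
    l_start, r_start = l_start[ok], r_start[ok]
    n = len(l_start)
    strand_l = np.zeros(n, dtype=bool)   # False = '+'
    strand_r = np.ones(n, dtype=bool)    # True  = '-'

    # chimeric pairs: random distal right anchor; elevated rate in hotspots
    p_chim = np.full(n, config.chimera_rate)
    for hs, he in truth.hotspots:
        p_chim[(l_start >= hs) & (l_start < he)] *= config.hotspot_chimera_multiplier
    chim = rng.random(n) < np.minimum(p_chim, 1.0)
    n_c = int(chim.sum())
    if n_c:
        r_start[chim] = rng.integers(0, L - R, size=n_c)
        strand_r[chim] = rng.random(n_c) < 0.5
        strand_l[chim] ^= rng.random(n_c) < 0.5
    l_end = l_start + R
    r_end = r_start + R
    # enforce the left-anchor-first convention
    swap = r_start < l_start
    for a, b in ((l_start, r_start), (l_end, r_end), (strand_l, strand_r)):
        a[swap], b[swap] = b[swap], a[swap].copy()
    insert = r_end - l_start

    mapq_l = np.full(n, 60, dtype=np.int64)
    mapq_r = np.full(n, 60, dtype=np.int64)
    low = rng.random(n) < config.mapq_low_fraction
    which = rng.random(n) < 0.5
    mapq_l[low & which] = rng.integers(0, 29, size=int((low & which).sum()))
    mapq_r[low & ~which] = rng.integers(0, 29, size=int((low & ~which).sum()))
    return {
        "left_start": l_start, "left_end": l_end,
        "right_start": r_start, "right_end": r_end,
        "strand_left": strand_l, "strand_right": strand_r,
        "mapq_left": mapq_l, "mapq_right": mapq_r,
        "insert_span": insert,
    }, skipped


def _depth_from_arrays(arrays, genome_length, read_len, accession,
                       tile_size=1000):
    n_tiles = (genome_length + tile_size - 1) // tile_size
    bp = np.zeros(n_tiles)
    for key in ("left_start", "right_start"):
        np.add.at(bp, arrays[key] // tile_size, read_len)
    return DepthProfile(accession=accession, tile_size=tile_size,
                        tile_means=bp / tile_size)


def _iter_records(arrays, accession, chrom):
    strands = np.array(["+", "-"])
    sl = strands[arrays["strand_left"].astype(int)]
    sr = strands[arrays["strand_right"].astype(int)]
    for i in range(len(arrays["left_start"])):
        yield ReadPairRecord(
            accession=accession, chrom_left=chrom, chrom_right=chrom,
            left_start=int(arrays["left_start"][i]),
            left_end=int(arrays["left_end"][i]),
            right_start=int(arrays["right_start"][i]),
            right_end=int(arrays["right_end"][i]),
            strand_left=str(sl[i]), strand_right=str(sr[i]),
            mapq_left=int(arrays["mapq_left"][i]),
            mapq_right=int(arrays["mapq_right"][i]),
            insert_span=int(arrays["insert_span"][i]),
            flag=0x1 | (0x10 if sl[i] == "-" else 0) | (0x20 if sr[i] == "-" else 0),
            pair_id=f"{accession}:{i}",
        )


def simulate_read_pairs(truth: PopulationTruth, config: SimConfig | None = None):
    """Simulate per-line aligned read pairs and depth profiles.

    Returns ``(streams, depths, counters)``: ``streams`` maps accession to
    a generator of :class:`ReadPairRecord`, ``depths`` to a
    :class:`~indelpop.sv_filters.DepthProfile`, and ``counters`` records
    pairs skipped because a read straddled a deletion junction.

    A carrier's pairs spanning a deletion acquire an insert span of about
    insert + deletion size in the (+,-) orientation; depth inside carried
    deletions is ~0; the reference line is simulated against its own
    genome so its discordant pairs come only from chimera/mapq noise.
    """
    config = config or truth.config
    streams = {}
    depths = {}
    counters = {}
    all_lines = config.focal_lines + config.outgroup_lines
    for li, line in enumerate(all_lines):
        rng = np.random.default_rng([config.seed, 0x5EAD, li])
        arrays, skipped = _line_pair_arrays(truth, config, line, rng)
        counters[line] = {"junction_skipped": skipped,
                          "simulated": len(arrays["left_start"])}
        depths[line] = _depth_from_arrays(arrays, config.genome_length,
                                          config.read_len, line)
        streams[line] = _iter_records(arrays, line, config.chrom)
    return streams, depths, counters


# ---------------------------------------------------------------------------
# Pileups for the SNP caller


def make_pileups(truth: PopulationTruth, config: SimConfig | None = None):
    """Error-free pileup tables at every true SNP position.

    Per line and site, depth ~ Poisson(coverage_mean) (0 inside carried
    deletions) and all reads show the line's base.  Returns a dict
    accession -> DataFrame(chrom, pos, depth, A, C, G, T).
    """
    config = config or truth.config
    alleles = truth.snp_allele_matrix()
    out = {}
    for li, line in enumerate(alleles.index):
        rng = np.random.default_rng([config.seed, 0x717E, li])
        depth = rng.poisson(config.coverage_mean, size=len(truth.snp_pos))
        base = alleles.loc[line].to_numpy()
        missing = pd.isna(base)
        depth[missing] = 0
        df = pd.DataFrame({"chrom": config.chrom, "pos": truth.snp_pos,
                           "depth": depth})
        for b in "ACGT":
            df[b] = np.where(~missing & (base == b), depth, 0)
        out[line] = df
    return out


# ---------------------------------------------------------------------------
# Scoring calls against truth


def evaluate_calls(candidates, truth: PopulationTruth,
                   reciprocal_overlap_threshold: float = 0.5):
    """Precision/recall of deletion calls against the planted registry.

    A call matches a planted deletion when their reciprocal overlap is at
    least the threshold and the called accession set covers at least half
    of the true carriers.  Returns ``(precision, recall, match_table)``;
    precision is NaN when nothing was called.
    """
    if not 0 < reciprocal_overlap_threshold <= 1:
        raise ValueError("reciprocal overlap threshold must be in (0,1]")
    dels = [c for c in candidates if c.sv_type == "deletion"]
    rows = []
    matched_calls = set()
    n_matched = 0
    for row in truth.variants.itertuples():
        best = None
        for c in dels:
            ov = min(row.end, c.end) - max(row.start, c.start)
            if ov <= 0:
                continue
            recip = min(ov / (row.end - row.start), ov / (c.end - c.start))
            if recip >= reciprocal_overlap_threshold:
                carriers = set(row.carriers)
                agree = len(carriers & set(c.accessions)) / max(len(carriers), 1)
                if agree >= 0.5 and (best is None or recip > best[1]):
                    best = (c, recip, agree)
        if best is not None:
            c, recip, agree = best
            matched_calls.add(c.id)
            n_matched += 1
            rows.append((row.id, c.id, recip, agree))
        else:
            rows.append((row.id, None, 0.0, 0.0))
    match_table = pd.DataFrame(
        rows, columns=["variant_id", "call_id", "reciprocal_overlap",
                       "carrier_agreement"])
    recall = n_matched / len(truth.variants) if len(truth.variants) else float("nan")
    precision = len(matched_calls) / len(dels) if dels else float("nan")
    return precision, recall, match_table


# ---------------------------------------------------------------------------
# Writers


def write_dataset(truth: PopulationTruth, outdir, write_pairs: bool = False):
    """Write the synthetic dataset: reference FASTA, GFF3 annotation,
    alignable-mask BED, truth JSON and (optionally) per-line pair TSVs."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    SeqIO.write([SeqRecord(Seq(truth.reference), id=cfg.chrom, description="")],
                str(outdir / "reference.fa"), "fasta")
    with open(outdir / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        genes = [f for f in truth.features if f.kind == "gene"]
        comps = [f for f in truth.features
                 if f.kind in ("exon", "five_prime_UTR", "three_prime_UTR")]
        tes = [f for f in truth.features if f.kind == "TE"]
        for g in genes:
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Family={g.family}\n")
            fh.write(f"{g.chrom}\tsim\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n")
            for c in comps:
                if c.gene_id == g.gene_id:
                    fh.write(f"{c.chrom}\tsim\t{c.kind}\t{c.start + 1}\t{c.end}"
                             f"\t.\t{c.strand}\t.\tParent={g.gene_id}.1\n")
        for i, t in enumerate(tes):
            fh.write(f"{t.chrom}\tsim\ttransposable_element\t{t.start + 1}\t"
                     f"{t.end}\t.\t+\t.\tID=te{i:05d};Family={t.family}\n")
    with open(outdir / "alignable.bed", "w") as fh:
        for s, e in truth.alignable_mask:
            fh.write(f"{cfg.chrom}\t{s}\t{e}\talignable\n")
    reg = truth.variants.copy()
    reg["carriers"] = reg["carriers"].map(list)
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"config": asdict(cfg),
                   "variants": reg.to_dict(orient="records"),
                   "hotspots": truth.hotspots}, fh, indent=1, default=str)
    if write_pairs:
        streams, depths, _ = simulate_read_pairs(truth)
        for line, stream in streams.items():
            write_pair_tsv(stream, outdir / f"pairs_{line}.tsv")
            depths[line].to_tsv(outdir / f"depth_{line}.tsv")
    logger.info("wrote synthetic dataset to %s", outdir)
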