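"""Genomic-context assignment and enrichment analyses for indel calls.

Answers where large indels fall with respect to genes and transposable
elements: nucleotide-level composition against the alignable-genome null,
positional density along normalized transcripts, TE- and gene-family
enrichment, indel/SNP density correlation in large windows, and the
size-by-frequency comparison.

A base inside both a gene and a TE counts toward both contexts (context
flags are independent, matching annotation overlap in real genomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


def _merged_tree(intervals) -> IntervalTree:
    t = IntervalTree()
    for s, e in intervals:
        if e > s:
            t.addi(s, e)
    t.merge_overlaps()
    return t


def _overlap_bp(tree: IntervalTree, start: int, end: int) -> int:
    return sum(min(iv.end, end) - max(iv.begin, start)
               for iv in tree.overlap(start, end))


@dataclass
class ContextAssignment:
    variant_id: str
    genic: bool
    te: bool
    intergenic: bool
    gene_ids: tuple
    bp_genic: int
    bp_te: int
    bp_intergenic: int


def assign_context(indels, features, alignable_mask):
    """Assign each indel to genomic contexts and test the nucleotide-level
    composition against the alignable null.

    ``indels`` is an iterable with ``id``/``start``/``end`` attributes (SV
    candidates or truth rows).  Returns ``(assignments, composition,
    chi2_result)`` where ``composition`` compares observed indel-bp shares
    with the gene/TE share of alignable bases and ``chi2_result`` is a
    chi-square test of independence on the bp contingency.
    """
    if not alignable_mask:
        raise ValueError("empty alignable mask")
    gene_tree = _merged_tree((f.start, f.end) for f in features if f.kind == "gene")
    te_tree = _merged_tree((f.start, f.end) for f in features if f.kind == "TE")
    genes = [f for f in features if f.kind == "gene"]

    align_bp = sum(e - s for s, e in alignable_mask)
    align_gene = sum(_overlap_bp(gene_tree, s, e) for s, e in alignable_mask)
    align_te = sum(_overlap_bp(te_tree, s, e) for s, e in alignable_mask)

    assignments = []
    for c in indels:
        bp_g = _overlap_bp(gene_tree, c.start, c.end)
        bp_t = _overlap_bp(te_tree, c.start, c.end)
        gids = tuple(g.gene_id for g in genes if g.start < c.end and g.end > c.start)
        size = c.end - c.start
        assignments.append(ContextAssignment(
            variant_id=str(c.id), genic=bp_g > 0, te=bp_t > 0,
            intergenic=bp_g == 0 and bp_t == 0, gene_ids=gids,
            bp_genic=bp_g, bp_te=bp_t,
            bp_intergenic=max(size - bp_g - bp_t, 0)))

    obs = np.array([sum(a.bp_genic for a in assignments),
                    sum(a.bp_te for a in assignments),
                    sum(a.bp_intergenic for a in assignments)], dtype=float)
    exp_shares = np.array([align_gene, align_te,
                           max(align_bp - align_gene - align_te, 0)], dtype=float)
    composition = pd.DataFrame({
        "context": ["gene", "TE", "other"],
        "indel_bp": obs,
        "indel_share": obs / obs.sum() if obs.sum() else obs,
        "alignable_bp": exp_shares,
        "alignable_share": exp_shares / exp_shares.sum(),
    })
    contingency = np.vstack([obs, exp_shares])
    keep = contingency.sum(axis=0) > 0
    chi2, p, dof, _ = stats.chi2_contingency(contingency[:, keep])
    return assignments, composition, {"chi2": float(chi2), "p": float(p),
                                      "dof": int(dof)}


# ---------------------------------------------------------------------------
# Normalized transcript profile

REGIONS = ("five_prime_UTR", "gene_body", "three_prime_UTR")


@dataclass
class BinProfile:
    region: str
    n_bins: int
    counts: np.ndarray        # indel bp per bin
    density: np.ndarray       # counts / total (sums to 1 when nonzero)
    ci_low: float             # binomial 95% bounds on per-bin counts
    ci_high: float
    enriched: np.ndarray = field(default=None)
    depleted: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.enriched is None:
            self.enriched = self.counts > self.ci_high
        if self.depleted is None:
            self.depleted = self.counts < self.ci_low


def _region_intervals(features, gene_id: str):
    """Genomic intervals of each normalized region for a gene's longest
    transcript; gene_body = exons plus introns (the span between UTRs)."""
    feats = [f for f in features if f.gene_id == gene_id and f.longest]
    strand = feats[0].strand if feats else "+"
    utr5 = sorted((f.start, f.end) for f in feats if f.kind == "five_prime_UTR")
    utr3 = sorted((f.start, f.end) for f in feats if f.kind == "three_prime_UTR")
    body = sorted((f.start, f.end) for f in feats
                  if f.kind in ("exon", "intron", "CDS"))
    if body:
        body = [(body[0][0], body[-1][1])]
    return {"five_prime_UTR": utr5, "gene_body": body,
            "three_prime_UTR": utr3}, strand


def transcript_profile(indels, features, n_bins: int = 100):
    """Indel-bp density along normalized gene regions.

    Each indel-covered base in a region is mapped to its relative 5'->3'
    position (strand aware) and binned into ``n_bins`` equal bins; per-bin
    95% bounds come from Binomial(n = total indel bp in the region,
    p = 1/n_bins).  Genes lacking UTR annotation contribute to gene_body
    only.  Returns a dict region -> :class:`BinProfile` (regions with no
    indel bp are omitted).
    """
    gene_ids = sorted({f.gene_id for f in features if f.kind == "gene"})
    counts = {r: np.zeros(n_bins) for r in REGIONS}
    for gid in gene_ids:
        regions, strand = _region_intervals(features, gid)
        for region, ivs in regions.items():
            total = sum(e - s for s, e in ivs)
            if total == 0:
                continue
            for c in indels:
                acc = 0
                for s, e in ivs:
                    a, b = max(s, c.start), min(e, c.end)
                    if b > a:
                        for pos in range(a, b):
                            rel = (acc + pos - s + 0.5) / total
                            if strand == "-":
                                rel = 1.0 - rel
                            counts[region][min(int(rel * n_bins), n_bins - 1)] += 1
                    acc += e - s
    out = {}
    for region in REGIONS:
        total = counts[region].sum()
        if total == 0:
            continue
        lo, hi = stats.binom.ppf([0.025, 0.975], int(total), 1.0 / n_bins)
        out[region] = BinProfile(region, n_bins, counts[region],
                                 counts[region] / total, float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# TE and gene family enrichment


def te_family_assign(indel, te_features, purity: float = 0.90):
    """Family of the single TE class constituting >= ``purity`` of the
    indel, or None."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0,1]")
    size = indel.end - indel.start
    by_family: dict[str, IntervalTree] = {}
    for f in te_features:
        if f.kind == "TE" and f.start < indel.end and f.end > indel.start:
            by_family.setdefault(f.family, IntervalTree()).addi(f.start, f.end)
    best, best_bp = None, 0
    for fam, tree in by_family.items():
        tree.merge_overlaps()
        bp = _overlap_bp(tree, indel.start, indel.end)
        if bp > best_bp:
            best, best_bp = fam, bp
    if best is not None and best_bp >= purity * size:
        return best
    return None


def family_enrichment(assigned_families, reference_families) -> pd.DataFrame:
    """Per-family enrichment of indel-assigned TE families against the
    annotation composition (two-sided Fisher's exact, Bonferroni).

    ``assigned_families`` are family labels of family-pure indels;
    ``reference_families`` the family labels of all annotated TEs.
    """
    obs = pd.Series(list(assigned_families)).value_counts()
    ref = pd.Series(list(reference_families)).value_counts()
    families = sorted(ref.index)
    n_obs, n_ref = obs.sum(), ref.sum()
    rows = []
    for fam in families:
        o = int(obs.get(fam, 0))
        r = int(ref.get(fam, 0))
        expected = n_obs * r / n_ref
        table = [[o, n_obs - o], [r, n_ref - r]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"family": fam, "observed": o, "expected": expected,
                     "fold": o / expected if expected else np.nan,
                     "p": p, "p_bonferroni": min(1.0, p * len(families))})
    return pd.DataFrame(rows)


def gene_family_enrichment(indel_gene_ids, family_of_gene: dict):
    """Gene-family cluster-size comparison and per-family enrichment.

    Tests whether genes hit by an indel belong to larger paralog families
    (Mann-Whitney U on family sizes) and which families are over- or
    under-represented (Fisher's exact per family, Bonferroni).
    """
    fam_sizes = pd.Series(family_of_gene).value_counts()
    all_sizes = np.array([fam_sizes[family_of_gene[g]] for g in family_of_gene])
    indel_genes = [g for g in indel_gene_ids if g in family_of_gene]
    hit_sizes = np.array([fam_sizes[family_of_gene[g]] for g in indel_genes])
    if len(hit_sizes) and len(all_sizes):
        u, p = stats.mannwhitneyu(hit_sizes, all_sizes, alternative="two-sided")
    else:
        u, p = np.nan, np.nan
    hit_fams = pd.Series([family_of_gene[g] for g in indel_genes]).value_counts()
    n_hit, n_all = len(indel_genes), len(family_of_gene)
    rows = []
    for fam in fam_sizes.index:
        o = int(hit_fams.get(fam, 0))
        tot = int(fam_sizes[fam])
        table = [[o, n_hit - o], [tot, n_all - tot]]
        _, fp = stats.fisher_exact(table)
        rows.append({"family": fam, "observed": o, "family_size": tot,
                     "expected": n_hit * tot / n_all, "p": fp,
                     "p_bonferroni": min(1.0, fp * len(fam_sizes))})
    return {
        "median_cluster_all": float(np.median(all_sizes)) if len(all_sizes) else np.nan,
        "median_cluster_indel": float(np.median(hit_sizes)) if len(hit_sizes) else np.nan,
        "mannwhitney_u": float(u), "mannwhitney_p": float(p),
        "per_family": pd.DataFrame(rows),
    }


# ---------------------------------------------------------------------------
# Window correlation and size-by-frequency


def window_density_correlation(indel_positions, snp_positions, coverage,
                               genome_length: int, window: int = 500_000):
    """Correlation of coverage-normalized indel and SNP densities across
    non-overlapping windows.

    ``coverage`` is total read coverage per window (array of length
    n_windows) or a scalar applied to all windows.  Requires >= 3 windows.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = genome_length // window
    if n_win < 3:
        raise ValueError("need at least 3 windows")
    edges = np.arange(0, (n_win + 1) * window, window)
    ind = np.histogram(np.asarray(indel_positions), bins=edges)[0]
    snp = np.histogram(np.asarray(snp_positions), bins=edges)[0]
    cov = np.broadcast_to(np.asarray(coverage, dtype=float), (n_win,))
    if (cov <= 0).any():
        raise ValueError("coverage must be positive in every window")
    x, y = snp / cov, ind / cov
    fit = stats.linregress(x, y)
    return {"r": float(fit.rvalue), "slope": float(fit.slope),
            "p": float(fit.pvalue), "df": n_win - 2, "n_windows": n_win}


def welch_anova(groups):
    """Welch's one-way ANOVA (unequal variances) with Satterthwaite df.

    ``groups`` is a list of 1-D samples; returns (F, df1, df2, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    n = np.array([len(g) for g in groups])
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    f_num = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    f_den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = f_num / f_den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    p = stats.f.sf(F, df1, df2)
    return float(F), df1, float(df2), float(p)


def size_by_maf(sizes, mafs):
    """Mean indel size per MAF class (0.1 steps) plus Welch's ANOVA on
    size across classes; classes with < 2 members are skipped."""
    sizes = np.asarray(sizes, dtype=float)
    mafs = np.round(np.asarray(mafs, dtype=float), 6)
    classes = sorted(set(mafs))
    means = {}
    groups = []
    for cl in classes:
        g = sizes[mafs == cl]
        means[cl] = float(g.mean()) if len(g) else np.nan
        if len(g) >= 2:
            groups.append(g)
        else:
            logger.warning("MAF class %.1f has <2 members; skipped from ANOVA", cl)
    F, df1, df2, p = welch_anova(groups)
    return {"class_means": means, "F": F, "df1": df1, "df2": df2, "p": p}
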