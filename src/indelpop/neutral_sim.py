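"""Neutral null machinery: fixed-S coalescent simulation and the
Monte-Carlo allele-frequency sampling-error calculator.

The simulator draws standard Kingman genealogies (no recombination, no
demography) and places a fixed number of segregating sites S on branches
multinomially in proportion to branch length (infinite-sites).  Because S
is fixed rather than theta, every summary computed here is invariant to
rescaling branch lengths, so the time units (2*Ne* generations,
coalescence rate k(k-1)/2 for k lineages) never affect the output.

The null envelope reproduces the study design: n=10 haploid genomes (one
per inbred line), S=100, 10,000 replicates; Tajima's D is computed on all
n chromosomes, while normalized Fay & Wu's H is computed on the ingroup
that remains after randomly designating 1-5 chromosomes as outgroup and
polarizing by strict outgroup consensus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .popgen_stats import (fay_wu_h_from_parts, fay_wu_h_norm, tajimas_d,
                           _pi_from_unfolded)

logger = logging.getLogger(__name__)

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "place_mutations",
    "NeutralEnvelope",
    "neutral_envelope",
    "simulate_d_h",
    "MafErrorResult",
    "maf_sampling_error",
    "analytic_folded_sfs",
]


@dataclass
class Genealogy:
    """A Kingman genealogy over ``n`` leaves.

    Branches are the 2n-2 edges below the root; ``branch_lengths[i]`` is
    the length of branch i in 2*Ne*-generation units and
    ``branch_leaves[i]`` the bitmask of leaves descending through it.
    """

    n: int
    branch_lengths: np.ndarray
    branch_leaves: np.ndarray  # uint64 bitmasks
    coalescence_times: np.ndarray  # waiting times while k=n..2 lineages

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def tmrca(self) -> float:
        return float(self.coalescence_times.sum())

    def scaled(self, factor: float) -> "Genealogy":
        return Genealogy(self.n, self.branch_lengths * factor,
                         self.branch_leaves.copy(),
                         self.coalescence_times * factor)


def simulate_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Simulate one standard-coalescent genealogy for ``n`` haploid samples.

    While k lineages remain the waiting time to the next coalescence is
    Exp(k(k-1)/2) in 2*Ne*-generation units; the coalescing pair is chosen
    uniformly.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    lengths = []
    masks = []
    active_masks = [np.uint64(1) << np.uint64(i) for i in range(n)]
    active_open = [0.0] * n  # accumulated length of each active lineage's branch
    waits = np.empty(n - 1)
    for step, k in enumerate(range(n, 1, -1)):
        t = rng.exponential(2.0 / (k * (k - 1)))
        waits[step] = t
        active_open = [v + t for v in active_open]
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        for idx in (j, i):  # close the two coalescing branches
            lengths.append(active_open[idx])
            masks.append(active_masks[idx])
        merged = active_masks[i] | active_masks[j]
        for idx in (j, i):
            del active_masks[idx], active_open[idx]
        active_masks.append(merged)
        active_open.append(0.0)
    return Genealogy(n, np.asarray(lengths), np.asarray(masks, dtype=np.uint64),
                     waits)


def place_mutations(genealogy: Genealogy, S: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Place exactly S infinite-sites mutations on the genealogy.

    Each site lands on one branch with probability proportional to branch
    length; returns the (n x S) 0/1 haplotype matrix (1 = derived).
    """
    n = genealogy.n
    if S == 0:
        return np.zeros((n, 0), dtype=np.uint8)
    p = genealogy.branch_lengths / genealogy.total_length
    branch_of_site = rng.choice(len(p), size=S, p=p)
    site_masks = genealogy.branch_leaves[branch_of_site]
    leaf_bits = np.uint64(1) << np.arange(n, dtype=np.uint64)
    return ((site_masks[None, :] & leaf_bits[:, None]) != 0).astype(np.uint8)


def analytic_folded_sfs(n: int) -> np.ndarray:
    """Expected folded SFS proportions p_i (minor count i=1..n//2) under
    the standard neutral model: p_i proportional to 1/i + 1/(n-i), halved
    at i = n/2."""
    i = np.arange(1, n // 2 + 1)
    w = 1.0 / i + 1.0 / (n - i)
    if n % 2 == 0:
        w[-1] = 1.0 / i[-1]
    return w / w.sum()


@dataclass
class NeutralEnvelope:
    """Simulated null-distribution summaries for the fixed-S design."""

    n: int
    S: int
    replicates: int
    seed: int
    mean_folded_sfs: list
    mean_maf: float
    D_low: float
    D_high: float
    H_low: float
    H_high: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NeutralEnvelope":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_d_h(n: int = 10, S: int = 100, reps: int = 10_000,
                 outgroup_sizes=(1, 2, 3, 4, 5), seed: int = 0,
                 drop_unoriented: str = "theta_l") -> dict:
    """Per-replicate D and H draws under the fixed-S neutral null.

    Returns a dict with arrays ``D`` and ``H`` (NaN where H is undefined),
    the aggregate folded SFS counts, the mean MAF, and per-replicate total
    tree lengths (useful for length-weighted comparisons against the
    theta-conditioned analytic SFS).  See :func:`neutral_envelope` for the
    meaning of ``drop_unoriented``.
    """
    if reps < 100:
        logger.warning("reps=%d < 100: envelope percentiles will be unstable", reps)
    if drop_unoriented not in ("theta_l", "all"):
        raise ValueError("drop_unoriented must be 'theta_l' or 'all'")
    rng = np.random.default_rng(seed)
    D = np.empty(reps)
    H = np.full(reps, np.nan)
    sfs_acc = np.zeros(n // 2)
    sfs_weighted = np.zeros(n // 2)
    tree_lengths = np.empty(reps)
    maf_sum = 0.0
    maf_n = 0
    for r in range(reps):
        g = simulate_genealogy(n, rng)
        tree_lengths[r] = g.total_length
        hap = place_mutations(g, S, rng)
        derived = hap.sum(axis=0)
        xi = np.bincount(derived, minlength=n)[1:n]
        pi = _pi_from_unfolded(xi, n)
        D[r] = tajimas_d(S, pi, n)
        minor = np.minimum(derived, n - derived)
        rep_sfs = np.bincount(minor, minlength=n // 2 + 1)[1:]
        sfs_acc += rep_sfs
        sfs_weighted += rep_sfs * g.total_length
        maf_sum += minor.sum() / n
        maf_n += S
        # outgroup assignment for H
        k = int(rng.choice(outgroup_sizes))
        out_idx = rng.choice(n, size=k, replace=False)
        in_mask = np.ones(n, dtype=bool)
        in_mask[out_idx] = False
        m = n - k
        og = hap[~in_mask]
        ig = hap[in_mask]
        anc1 = og.all(axis=0)        # outgroup consensus says 1 is ancestral
        anc0 = (og == 0).all(axis=0)
        ig_ones = ig.sum(axis=0)
        seg = (ig_ones >= 1) & (ig_ones <= m - 1)
        derived_in = np.where(anc0, ig_ones, m - ig_ones)
        oriented = (anc0 | anc1) & seg
        if drop_unoriented == "all":
            if oriented.any():
                xi_in = np.bincount(derived_in[oriented], minlength=m)[1:m]
                H[r] = fay_wu_h_norm(xi_in, m)
        else:
            S_in = int(seg.sum())
            if S_in:
                xi_all = np.bincount(ig_ones[seg], minlength=m)[1:m]
                pi_in = _pi_from_unfolded(xi_all, m)
                theta_l = float(derived_in[oriented].sum()) / (m - 1)
                H[r] = fay_wu_h_from_parts(pi_in, S_in, theta_l, m)
    return {"D": D, "H": H, "folded_sfs": sfs_acc,
            "folded_sfs_length_weighted": sfs_weighted,
            "mean_maf": maf_sum / maf_n,
            "tree_lengths": tree_lengths}


def neutral_envelope(n: int = 10, S: int = 100, reps: int = 10_000,
                     outgroup_sizes=(1, 2, 3, 4, 5), seed: int = 0,
                     drop_unoriented: str = "theta_l") -> NeutralEnvelope:
    """Simulate the neutral envelope: 2.5/97.5 percentiles of Tajima's D
    and normalized Fay & Wu's H, the mean folded SFS and the mean MAF.

    D uses all n chromosomes.  For H, each replicate draws an outgroup
    size uniformly from ``outgroup_sizes``, assigns that many random
    chromosomes to the outgroup, polarizes ingroup sites by strict
    outgroup consensus, and computes normalized H on the remaining
    ingroup sample.  Sites whose ancestral state cannot be oriented (a
    mixed outgroup) are handled per ``drop_unoriented``:

    * ``"theta_l"`` (default) — unorientable sites are excluded from
      theta_L only, while pi, S and the variance use every
      ingroup-segregating site;
    * ``"all"`` — unorientable sites are excluded from H entirely.

    The default reproduces the published (-1.88, +5.70) H interval; the
    stricter variant gives a narrower one (about (-2.2, +1.6)).
    """
    draws = simulate_d_h(n, S, reps, outgroup_sizes, seed, drop_unoriented)
    d_low, d_high = np.percentile(draws["D"], [2.5, 97.5])
    h_low, h_high = np.nanpercentile(draws["H"], [2.5, 97.5])
    sfs = draws["folded_sfs"]
    return NeutralEnvelope(
        n=n, S=S, replicates=reps, seed=seed,
        mean_folded_sfs=list(sfs / sfs.sum()),
        mean_maf=float(draws["mean_maf"]),
        D_low=float(d_low), D_high=float(d_high),
        H_low=float(h_low), H_high=float(h_high),
    )


@dataclass
class MafErrorResult:
    sample_size: int
    replicates: int
    mean_abs_error: float


def maf_sampling_error(sample_size: int = 10, reps: int = 50_000,
                       rng: np.random.Generator | None = None,
                       censoring: str = "clamp") -> MafErrorResult:
    """Monte-Carlo expectation of |observed - true| allele frequency for a
    small sample of inbred lines.

    True frequency p ~ Uniform(0,1); observed count k ~ Binomial(size, p).
    Because a variant is only ascertained when the minor allele appears in
    at least one line, the observed frequency is censored into
    [1/size, 1 - 1/size].  ``censoring`` selects how:

    * ``"clamp"`` (default) — observed k/size is clamped into the band,
      so monomorphic draws contribute at the boundary;
    * ``"redraw"`` — monomorphic draws (k = 0 or size) are discarded and
      redrawn.

    Returns the mean of |observed - p| over ``reps`` replicates.
    """
    if sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    if censoring not in ("clamp", "redraw"):
        raise ValueError("censoring must be 'clamp' or 'redraw'")
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = 1.0 / sample_size, 1.0 - 1.0 / sample_size
    if censoring == "clamp":
        p = rng.uniform(size=reps)
        k = rng.binomial(sample_size, p)
        obs = np.clip(k / sample_size, lo, hi)
        return MafErrorResult(sample_size, reps, float(np.abs(obs - p).mean()))
    need = reps
    acc = 0.0
    got = 0
    while got < reps:
        p = rng.uniform(size=need)
        k = rng.binomial(sample_size, p)
        ok = (k > 0) & (k < sample_size)
        vals = np.abs(k[ok] / sample_size - p[ok])
        take = min(len(vals), reps - got)
        acc += float(vals[:take].sum())
        got += take
        need = max(reps - got, 1024)
    return MafErrorResult(sample_size, reps, acc / reps)
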