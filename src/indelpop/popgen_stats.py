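"""Site-frequency-spectrum statistics and allele-age selection inference.

Implements the population-genetic layer of the pipeline:

* folded/unfolded site frequency spectra and minor-allele frequencies,
* Tajima's D (Tajima 1989) and the normalized Fay & Wu's H (Zeng et
  al. 2006) with their full variance constants,
* outgroup polarization of biallelic variants,
* delete-one jackknife confidence intervals,
* intra-allelic diversity (pi_A) over a fixed haplotype window, its
  conversion to mean allele age in 2*Ne*-generation units, and the
  diffusion-based inversion of mean age into a population-scaled
  selection-coefficient magnitude |Ne*s| under additive selection.

The diffusion model used for allele age assumes a constant population
size, no dominance and no recombination within the focal window.  With
time measured in 2*Ne* generations the allele-frequency diffusion has
infinitesimal variance x(1-x) and drift gamma*x(1-x), where gamma =
Ne*s; the expected age of an allele observed at frequency x is symmetric
in the sign of gamma (Maruyama 1974), so only its magnitude is
estimable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "tajima_constants",
    "tajimas_d",
    "fay_wu_h_norm",
    "fay_wu_h_from_parts",
    "diversity_summary",
    "DiversitySummary",
    "sfs_and_maf",
    "polarize",
    "jackknife_ci",
    "pi_a",
    "allele_age",
    "mean_allele_age",
    "nes_from_age",
]


# ---------------------------------------------------------------------------
# Frequency-spectrum statistics

def tajima_constants(n: int) -> dict:
    """Normalization constants a1..e2 for Tajima's D at sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from the number of segregating sites and mean pairwise
    diversity; NaN when S == 0 (the statistic is undefined)."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S == 0:
        return math.nan
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi - S / k["a1"]) / math.sqrt(var)


def _pi_from_unfolded(xi: np.ndarray, n: int) -> float:
    i = np.arange(1, n)
    return float(np.sum(xi * 2.0 * i * (n - i)) / (n * (n - 1)))


def fay_wu_h_norm(xi, n: int) -> float:
    """Normalized Fay & Wu's H from an unfolded (polarized) SFS.

    ``xi`` holds counts of sites with derived-allele count i for
    i = 1..n-1.  Uses the Zeng et al. (2006) normalization:
    H = (pi - theta_L) / sqrt(Var), with theta^2 estimated by
    S(S-1)/(a1^2 + a2).  NaN when there are no segregating sites.
    """
    xi = np.asarray(xi, dtype=float)
    if len(xi) != n - 1:
        raise ValueError(f"unfolded SFS must have n-1={n - 1} classes")
    S = int(xi.sum())
    if S == 0:
        return math.nan
    pi = _pi_from_unfolded(xi, n)
    theta_l = float(np.sum(np.arange(1, n) * xi)) / (n - 1)
    return fay_wu_h_from_parts(pi, S, theta_l, n)


def fay_wu_h_from_parts(pi: float, S: int, theta_l: float, n: int) -> float:
    """Normalized H from precomputed parts.

    Lets pi, S (and hence the variance) be computed over all segregating
    sites while ``theta_l`` is accumulated only over sites whose ancestral
    state could be oriented by the outgroup — the treatment of
    unorientable sites used when building the null envelope.
    """
    if S == 0:
        return math.nan
    k = tajima_constants(n)
    a1, a2 = k["a1"], k["a2"]
    bn1 = float(np.sum(1.0 / np.arange(1, n + 1) ** 2))
    theta_w = S / a1
    theta_sq = S * (S - 1) / (a1**2 + a2)
    var = (theta_w * (n - 2) / (6.0 * (n - 1))
           + theta_sq * (18 * n**2 * (3 * n + 2) * bn1
                         - (88 * n**3 + 9 * n**2 - 13 * n + 6))
           / (9.0 * n * (n - 1) ** 2))
    return (pi - theta_l) / math.sqrt(var)


@dataclass
class DiversitySummary:
    n: int
    S: int
    pi: float
    theta_w: float
    theta_l: float
    D: float
    H: float


def diversity_summary(derived_counts, n: int) -> DiversitySummary:
    """Summary statistics from per-site derived-allele counts (polarized).

    Monomorphic entries (count 0 or n) are ignored.
    """
    c = np.asarray(derived_counts, dtype=int)
    c = c[(c > 0) & (c < n)]
    S = len(c)
    xi = np.bincount(c, minlength=n)[1:n]
    pi = _pi_from_unfolded(xi, n)
    if S == 0:
        return DiversitySummary(n, 0, 0.0, 0.0, 0.0, math.nan, math.nan)
    k = tajima_constants(n)
    theta_l = float(np.sum(np.arange(1, n) * xi)) / (n - 1)
    return DiversitySummary(
        n=n, S=S, pi=pi, theta_w=S / k["a1"], theta_l=theta_l,
        D=tajimas_d(S, pi, n), H=fay_wu_h_norm(xi, n),
    )


def sfs_and_maf(counts, n: int, warn_monomorphic: bool = True):
    """Folded SFS and minor-allele frequencies from per-site allele counts.

    ``counts`` are counts of one allele (derived or arbitrary) per site
    out of ``n`` haplotypes.  Monomorphic sites are excluded.  Returns
    ``(folded_sfs_counts, maf_per_site, mean_maf)`` where the folded SFS
    is indexed by minor-allele count 1..n//2.
    """
    c = np.asarray(counts, dtype=int)
    mono = (c == 0) | (c == n)
    if mono.any() and warn_monomorphic:
        logger.warning("excluding %d monomorphic sites", int(mono.sum()))
    c = c[~mono]
    minor = np.minimum(c, n - c)
    folded = np.bincount(minor, minlength=n // 2 + 1)[1:]
    maf = minor / n
    mean_maf = float(maf.mean()) if len(maf) else math.nan
    return folded, maf, mean_maf


def polarize(genotypes, outgroup_calls):
    """Assign derived vs ancestral state per variant from outgroup lines.

    Both arguments are DataFrames indexed by variant with one column per
    line; entries are allele codes (any hashable; NaN = uncallable in
    ``outgroup_calls``).  The ancestral allele is the one carried by all
    callable outgroups; if outgroups disagree or none is callable the
    variant is left unpolarized.

    Returns a DataFrame with columns ``ancestral``, ``derived`` (NaN when
    unknown) and ``derived_is_minor``, plus the fraction of polarizable
    minor alleles that are derived as ``.attrs['minor_derived_fraction']``.
    """
    import pandas as pd

    rows = []
    for idx in genotypes.index:
        og = outgroup_calls.loc[idx].dropna()
        focal = genotypes.loc[idx]
        alleles = focal.value_counts()
        anc = der = float("nan")
        derived_is_minor = float("nan")
        if len(og) > 0 and og.nunique() == 1:
            anc = og.iloc[0]
            others = [a for a in alleles.index if a != anc]
            if len(others) == 1:
                der = others[0]
                minor_allele = alleles.idxmin() if alleles.iloc[0] != alleles.iloc[-1] \
                    else alleles.index[-1]
                # with a tie either allele is "minor"; call derived minor then
                derived_is_minor = bool(
                    alleles[der] < alleles.max() or alleles.nunique() == 1)
            elif len(others) == 0:
                der = float("nan")  # focal population monomorphic ancestral
        rows.append((anc, der, derived_is_minor))
    out = pd.DataFrame(rows, index=genotypes.index,
                       columns=["ancestral", "derived", "derived_is_minor"])
    known = out["derived_is_minor"].dropna()
    out.attrs["minor_derived_fraction"] = \
        float(known.mean()) if len(known) else math.nan
    return out


def jackknife_ci(lines, statistic, z: float = 1.96):
    """Delete-one jackknife mean and normal-approximation CI.

    ``lines`` is a sequence of sample units; ``statistic`` maps a list of
    units to a float.  Subsets on which the statistic is NaN are skipped
    with a warning.  Returns ``(mean, lo, hi, se)``.
    """
    lines = list(lines)
    g = len(lines)
    if g < 3:
        raise ValueError("jackknife needs at least 3 units")
    loo = []
    for i in range(g):
        val = statistic(lines[:i] + lines[i + 1:])
        if math.isnan(val):
            logger.warning("statistic undefined with unit %d removed; skipped", i)
            continue
        loo.append(val)
    loo = np.asarray(loo)
    g_eff = len(loo)
    mean = float(loo.mean())
    se = math.sqrt((g_eff - 1) / g_eff * float(np.sum((loo - mean) ** 2)))
    return mean, mean - z * se, mean + z * se, se


# ---------------------------------------------------------------------------
# Intra-allelic diversity and allele age

def pi_a(carrier_haplotypes, window_length: int = 500) -> float:
    """Intra-allelic nucleotide diversity among carriers of a focal allele.

    ``carrier_haplotypes`` is an (n_carriers x n_sites) array of allele
    codes over the window's variable sites (NaN = missing); pairwise
    differences are counted only at sites callable in all carriers and
    normalized by ``window_length``.  Singleton alleles (one carrier)
    cannot be scored and raise ``ValueError``; callers should skip them.
    """
    h = np.asarray(carrier_haplotypes, dtype=float)
    if h.ndim != 2 or h.shape[0] < 2:
        raise ValueError("pi_a needs >= 2 carrier haplotypes")
    if h.shape[1]:
        callable_sites = ~np.isnan(h).any(axis=0)
        h = h[:, callable_sites]
    k = h.shape[0]
    diffs = 0
    for i in range(k):
        for j in range(i + 1, k):
            diffs += int(np.sum(h[i] != h[j]))
    n_pairs = k * (k - 1) // 2
    return diffs / n_pairs / window_length


def allele_age(pi_a_value: float, grand_mean_syn_pi_a: float) -> float:
    """Mean allele age in 2*Ne* generations: pi_A scaled by the neutral
    (grand-mean synonymous) pi_A, which accrues over 2*Ne* generations."""
    if grand_mean_syn_pi_a <= 0:
        raise ValueError("grand mean synonymous pi_A must be positive")
    return pi_a_value / grand_mean_syn_pi_a


def mean_allele_age(x: float, gamma: float) -> float:
    """Expected mean age (in 2*Ne* generations) of a derived allele observed
    at frequency ``x`` under additive selection of magnitude ``gamma`` = Ne*s.

    Computed from the sojourn-time densities of the Wright-Fisher
    diffusion: the age of an allele that entered at frequency 0 and is now
    at x is distributed as the loss time of the diffusion started at x and
    conditioned on loss.  In the neutral limit this reduces to the
    Kimura-Ohta closed form -2x*ln(x)/(1-x).  Symmetric in the sign of
    ``gamma``.
    """
    if not 0.0 < x < 1.0:
        raise ValueError("frequency x must be in (0,1)")
    a = abs(gamma)
    if a < 1e-6:
        return -2.0 * x * math.log(x) / (1.0 - x)

    # scale density psi(y)=exp(-2ay); all exponentials below have
    # non-positive arguments so the integrands are overflow-safe
    def E(z):
        return math.exp(-2.0 * a * z)

    denom = 1.0 - E(1.0)

    def below(xi):  # sojourn below x, conditioned on loss
        num = 1.0 - E(1.0 - xi) - E(xi) + E(1.0)
        return num / (a * denom * xi * (1.0 - xi))

    pref = (1.0 - E(x)) / (2.0 * a * (1.0 - E(1.0 - x)) * denom)

    def above(xi):  # sojourn above x, with the S(x)/u0(x) prefactor folded in
        return (pref * 2.0 * math.exp(-2.0 * a * (xi - x))
                * (1.0 - E(1.0 - xi)) ** 2 / (xi * (1.0 - xi)))

    i1, _ = quad(below, 0.0, x, limit=500)
    i2, _ = quad(above, x, 1.0, limit=500)
    return i1 + i2


def nes_from_age(T: float, x: float, gamma_max: float = 500.0,
                 rtol: float = 1e-6) -> float:
    """Invert the diffusion mean-age relation: the |Ne*s| at which the
    expected mean age of an allele at frequency ``x`` equals ``T``.

    Ages longer than the neutral expectation cannot be produced by
    selection of either sign; such ``T`` return 0 with a warning.
    """
    if T <= 0:
        raise ValueError("age T must be positive")
    neutral = mean_allele_age(x, 0.0)
    if T >= neutral:
        logger.warning("age %.4g exceeds neutral expectation %.4g; |NeS| -> 0",
                       T, neutral)
        return 0.0
    return float(brentq(lambda g: mean_allele_age(x, g) - T,
                        0.0, gamma_max, rtol=rtol))
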