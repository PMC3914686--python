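"""Joint Tajima's-D / normalized-H scan for positively selected indels.

For each polarized indel, SNP haplotypes of the focal lines over a 10 kb
segment centred on the indel are summarized with Tajima's D and
normalized Fay & Wu's H (polarized by the outgroup lines, with the same
treatment of unorientable sites as the null envelope).  An indel is an
outlier when both statistics fall below the lower bound of the neutral
envelope's 95% interval — the joint signature of a recent sweep.  The
derived-allele-frequency filter (>= 0.8 by default) selects the reported
candidate list, but every indel's scores are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neutral_sim import NeutralEnvelope
from .popgen_stats import (fay_wu_h_from_parts, tajimas_d, _pi_from_unfolded)

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    indel_id: str
    derived_freq: float
    n_snps: int
    D: float
    H: float
    outlier: bool
    passes_freq: bool


def _window_stats(allele_matrix: pd.DataFrame, focal_lines, outgroup_lines):
    """D and H from SNP columns of an allele matrix restricted to a window.

    Sites not callable in every focal line are dropped; H orients sites
    by strict outgroup consensus, excluding unorientable sites from
    theta_L only (matching the envelope's estimator).
    """
    n = len(focal_lines)
    foc = allele_matrix.loc[focal_lines]
    ok = foc.notna().all(axis=0)
    foc = foc.loc[:, ok]
    if foc.shape[1] == 0:
        return 0, math.nan, math.nan
    og = allele_matrix.loc[outgroup_lines, ok.index[ok]]
    counts = []
    derived = []
    oriented = []
    for col in foc.columns:
        vals = foc[col]
        uniq = vals.unique()
        if len(uniq) < 2:
            continue
        vc = vals.value_counts()
        ogc = og[col].dropna().unique()
        if len(ogc) == 1 and ogc[0] in vc.index:
            anc = ogc[0]
            der_count = int(n - vc[anc])
            if 1 <= der_count <= n - 1:
                derived.append(der_count)
                oriented.append(True)
                counts.append(int(vc.iloc[0]))
                continue
        counts.append(int(vc.iloc[0]))
        derived.append(-1)
        oriented.append(False)
    S = len(counts)
    if S == 0:
        return 0, math.nan, math.nan
    c = np.array(counts)
    xi_any = np.bincount(np.minimum(c, n - c), minlength=n)[1:n]  # by minor
    # pi is invariant to orientation; use minor-allele counts
    pi = _pi_from_unfolded(xi_any, n)
    D = tajimas_d(S, pi, n)
    theta_l = sum(d for d, o in zip(derived, oriented) if o) / (n - 1)
    H = fay_wu_h_from_parts(pi, S, theta_l, n)
    return S, D, H


def scan_indels(indels: pd.DataFrame, allele_matrix: pd.DataFrame,
                envelope: NeutralEnvelope, focal_lines, outgroup_lines,
                window: int = 10_000, freq_min: float = 0.8) -> pd.DataFrame:
    """Score each indel's surrounding window against the neutral envelope.

    ``indels`` needs columns ``id, start, end, derived_freq``;
    ``allele_matrix`` is lines x SNP-positions (as from
    ``PopulationTruth.snp_allele_matrix`` or the SNP caller).  SNPs inside
    the indel interval are excluded (missing in carriers by
    construction).  Windows with no SNPs score NA and are never outliers.
    """
    positions = np.asarray(allele_matrix.columns)
    rows = []
    for row in indels.itertuples():
        mid = (row.start + row.end) // 2
        lo, hi = mid - window // 2, mid + window // 2
        sel = (positions >= lo) & (positions < hi) & \
              ((positions < row.start) | (positions >= row.end))
        S, D, H = _window_stats(allele_matrix.loc[:, positions[sel]],
                                focal_lines, outgroup_lines) \
            if sel.any() else (0, math.nan, math.nan)
        outlier = (not math.isnan(D) and not math.isnan(H)
                   and D < envelope.D_low and H < envelope.H_low)
        rows.append(ScanResult(
            indel_id=str(row.id), derived_freq=float(row.derived_freq),
            n_snps=S, D=D, H=H, outlier=outlier,
            passes_freq=float(row.derived_freq) >= freq_min))
    return pd.DataFrame([r.__dict__ for r in rows])
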