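import numpy as np
import pandas as pd
import pytest

from indelpop.discordant_sv import DiscordantPair, SvCandidate
from indelpop.sv_filters import (DepthProfile, DiscordantIndex, apply_cascade,
                                 coverage_band_filter, deletion_depth_filter,
                                 discordant_density_filter, min_size_filter,
                                 reference_accession_filter)
from .test_discordant_sv import make_pair


def make_candidate(start=10_000, end=14_000, accessions=("L03", "L07"),
                   sv_type="deletion", pair_ids=(), cid=0):
    return SvCandidate(id=cid, sv_type=sv_type, chrom="chr1", start=start,
                       end=end, size=end - start, support=max(len(pair_ids), 3),
                       accessions=frozenset(accessions), pair_ids=tuple(pair_ids))


def profile_with(interval_depth, background=8.0, accession="L03",
                 n_tiles=100, lo_tiles=10, start_tile=10, end_tile=14):
    """100 x 1 kb tiles: background depth, a low tail so the 10th
    percentile is sensible, and a fixed depth over tiles [start,end)."""
    tiles = np.full(n_tiles, background)
    tiles[:lo_tiles] = np.linspace(0.5, 2.0, lo_tiles)
    tiles[start_tile:end_tile] = interval_depth
    return DepthProfile(accession, 1000, tiles)


def test_reference_accession_filter():
    assert reference_accession_filter(make_candidate(), "L00")
    assert not reference_accession_filter(
        make_candidate(accessions=("L00", "L03")), "L00")
    assert not reference_accession_filter(make_candidate(accessions=("L00",)),
                                          "L00")


@pytest.mark.parametrize("size,expected", [(999, False), (1000, True),
                                           (204_000, True)])
def test_min_size_boundary(size, expected):
    assert min_size_filter(make_candidate(end=10_000 + size)) is expected


def test_deletion_depth_filter_per_carrier():
    ok = {"L03": profile_with(0.2, accession="L03"),
          "L07": profile_with(0.2, accession="L07")}
    assert deletion_depth_filter(make_candidate(), ok)
    bad = {"L03": profile_with(0.2, accession="L03"),
           "L07": profile_with(6.0, accession="L07")}
    # one failing carrier rejects the candidate for all accessions
    assert not deletion_depth_filter(make_candidate(), bad)


def test_deletion_depth_interval_outside_profile_errors():
    prof = {"L03": profile_with(0.2)}
    with pytest.raises(ValueError):
        deletion_depth_filter(make_candidate(start=90_000, end=200_000,
                                             accessions=("L03",)), prof)


def test_coverage_band_filter():
    mid = {"L03": profile_with(8.0, accession="L03")}
    assert coverage_band_filter(make_candidate(sv_type="inversion",
                                               accessions=("L03",)), mid)
    zero = {"L03": profile_with(0.0)}
    assert not coverage_band_filter(make_candidate(sv_type="inversion",
                                                   accessions=("L03",)), zero)
    hot = {"L03": profile_with(50.0)}
    assert not coverage_band_filter(make_candidate(sv_type="inversion",
                                                   accessions=("L03",)), hot)


def _index_with_background(per_tile=12, n_tiles=20, extra=()):
    """Pooled pairs giving `per_tile` anchors in every 5 kb tile, plus
    extra (pair_id, left, right) anchors."""
    pairs = []
    k = 0
    for t in range(n_tiles):
        for j in range(per_tile // 2):  # each pair contributes 2 anchors
            l = t * 5000 + 100 + j * 7
            pairs.append(DiscordantPair(
                make_pair(l, l + 2000, insert=2075, pair_id=f"bg{k}"),
                "deletion_signal"))
            k += 1
    for pid, l, r in extra:
        pairs.append(DiscordantPair(
            make_pair(l, r, insert=r - l + 75, pair_id=pid),
            "deletion_signal"))
    return DiscordantIndex(pairs, genome_length=n_tiles * 5000)


def test_density_filter_discounts_focal_pairs():
    own = [(f"own{i}", 50_100 + i, 54_000 + i) for i in range(20)]
    idx = _index_with_background(extra=own)
    cand = make_candidate(start=50_175, end=54_000,
                          pair_ids=[p for p, _, _ in own])
    # own anchors are discounted, leaving only the uniform background
    assert discordant_density_filter(cand, idx)
    # an identical candidate that does not own those pairs fails
    stranger = make_candidate(start=50_175, end=54_000, pair_ids=())
    assert not discordant_density_filter(stranger, idx)


def test_density_filter_zero_background_passes():
    own = [(f"own{i}", 50_100, 54_000) for i in range(40)]
    pairs = [DiscordantPair(make_pair(l, r, insert=r - l + 75, pair_id=p),
                            "deletion_signal") for p, l, r in own]
    idx = DiscordantIndex(pairs, genome_length=100_000)
    cand = make_candidate(start=50_175, end=54_000,
                          pair_ids=[p for p, _, _ in own])
    assert discordant_density_filter(cand, idx)


def _cascade_inputs():
    profiles = {a: profile_with(0.2, accession=a)
                for a in ("L03", "L07", "L01")}
    profiles["L00"] = profile_with(0.2, accession="L00")
    idx = _index_with_background(per_tile=2)
    cands = [
        make_candidate(cid=0),
        make_candidate(cid=1, accessions=("L00", "L03")),   # ref line
        make_candidate(cid=2, end=10_800),                  # too small
    ]
    return cands, profiles, idx


def test_cascade_verdicts_and_accounting():
    cands, profiles, idx = _cascade_inputs()
    retained, verdicts = apply_cascade(cands, profiles, idx, "L00")
    assert len(verdicts) == len(cands)
    assert {c.id for c in retained} == {0}
    row = verdicts.set_index("candidate_id").loc[1]
    assert not row["ref_accession"] and not row["retained"]
    assert verdicts["retained"].sum() + (~verdicts["retained"]).sum() \
        == len(cands)


def test_cascade_idempotent():
    cands, profiles, idx = _cascade_inputs()
    retained, _ = apply_cascade(cands, profiles, idx, "L00")
    again, _ = apply_cascade(retained, profiles, idx, "L00")
    assert [c.id for c in again] == [c.id for c in retained]


def test_cascade_monotone_in_filters():
    """The full cascade never retains more than any prefix of it."""
    cands, profiles, idx = _cascade_inputs()
    full, _ = apply_cascade(cands, profiles, idx, "L00")
    prefix = [c for c in cands
              if reference_accession_filter(c, "L00") and min_size_filter(c)]
    assert {c.id for c in full} <= {c.id for c in prefix}


def test_depth_profile_round_trip(tmp_path):
    prof = profile_with(0.2)
    prof.to_tsv(tmp_path / "d.tsv")
    back = DepthProfile.from_tsv(tmp_path / "d.tsv")
    assert back.accession == prof.accession
    assert back.tile_size == prof.tile_size
    np.testing.assert_allclose(back.tile_means, prof.tile_means)


def test_interval_mean_trims_partial_boundary_tiles():
    tiles = np.full(10, 8.0)
    tiles[3:6] = 0.0
    prof = DepthProfile("x", 1000, tiles)
    # interval [2900, 6100): tiles 2 and 6 only partially overlap
    assert prof.interval_mean(2900, 6100) == 0.0
    # sub-tile interval falls back to the covering tile
    assert prof.interval_mean(3100, 3300) == 0.0
    assert prof.interval_mean(1100, 1300) == 8.0
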