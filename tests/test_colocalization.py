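import numpy as np
import pandas as pd
import pytest

from regulocate import (composite_effect, density_effect_correlation,
                        detect_de_regions, distance_density, filter_orf_hits,
                        motif_density, upstream_distance)
from regulocate.colocalization import de_flags
from regulocate.motifs import HIT_COLUMNS


def _hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# -- density tracks ---------------------------------------------------------

def test_single_hit_peak_location_and_height():
    hits = _hits([("r", 499_994, 500_007, "+", 1.0, 1e-6)])  # midpoint 500000.5
    track = motif_density(hits, 1_000_000, bandwidth=30000, grid_step=1000)
    assert track.argmax_position == pytest.approx(500_000, abs=1000)
    expected_peak = 1 / (30000 * np.sqrt(2 * np.pi))
    assert track.density.max() == pytest.approx(expected_peak, rel=1e-4)


def test_two_distant_hits_give_two_local_maxima():
    hits = _hits([("r", 100_000, 100_013, "+", 1.0, 1e-6),
                  ("r", 400_000, 400_013, "+", 1.0, 1e-6)])
    track = motif_density(hits, 500_000, bandwidth=30000, grid_step=1000)
    d = track.density
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
    peaks = track.positions[1:-1][interior]
    assert len(peaks) == 2
    assert peaks == pytest.approx([100_000, 400_000], abs=1500)


def test_density_is_linear_in_multiplicity():
    one = _hits([("r", 50_000, 50_013, "+", 1.0, 1e-6)])
    two = pd.concat([one, one], ignore_index=True)
    t1 = motif_density(one, 200_000)
    t2 = motif_density(two, 200_000)
    assert t2.density == pytest.approx(2 * t1.density)


def test_zero_hits_gives_zero_track():
    track = motif_density(_hits([]), 100_000, replicon="r")
    assert (track.density == 0).all()


def test_track_integrates_to_hit_count():
    hits = _hits([("r", 400_000, 400_013, "+", 1.0, 1e-6),
                  ("r", 600_000, 600_013, "+", 1.0, 1e-6)])
    track = motif_density(hits, 1_000_000, bandwidth=30000, grid_step=1000)
    integral = np.trapezoid(track.density, track.positions)
    assert integral == pytest.approx(2.0, rel=0.01)


# -- composite effect -------------------------------------------------------

def _de(lfc):
    return pd.DataFrame({"log2fc": lfc, "significant": [True] * len(lfc),
                         "tested": [True] * len(lfc)},
                        index=[f"g{i}" for i in range(len(lfc))])


def test_composite_single_strain_is_identity():
    de = {"m1.limited": _de([1.0, -2.0])}
    comp = composite_effect(de, ["m1"], "limited")
    assert list(comp) == [1.0, -2.0]


def test_composite_mean_and_na_skipping():
    de = {"m1.limited": _de([-2.0, np.nan]), "m2.limited": _de([-4.0, 3.0])}
    comp = composite_effect(de, ["m1", "m2"], "limited")
    assert comp["g0"] == pytest.approx(-3.0)
    assert comp["g1"] == pytest.approx(3.0)  # NA skipped


def test_composite_four_strain_toy_by_hand():
    de = {f"m{i}.limited": _de([v]) for i, v in enumerate([-1.0, -2.0, -3.0, -6.0])}
    comp = composite_effect(de, [f"m{i}" for i in range(4)], "limited")
    assert comp["g0"] == pytest.approx(-3.0)


def test_composite_empty_strain_set_raises():
    with pytest.raises(ValueError):
        composite_effect({}, [], "limited")


# -- DE regions -------------------------------------------------------------

def _flag_annotation(n):
    from regulocate import Gene, GenomeAnnotation
    genes = [Gene(f"g{i}", "chr", 1 + 1000 * i, 400 + 1000 * i, "+",
                  f"op{i}", 1) for i in range(n)]
    return GenomeAnnotation(genes, {"chr": 1000 * n + 1000})


def test_region_from_leading_run():
    ann = _flag_annotation(10)
    flags = pd.Series([True] * 5 + [False] * 5, index=[f"g{i}" for i in range(10)])
    regions = detect_de_regions(ann, flags)
    assert len(regions) == 1
    r = regions[0]
    assert r.gene_ids == [f"g{i}" for i in range(5)]
    assert r.fraction_de == pytest.approx(1.0)
    assert (r.start, r.end) == (1, 4400)


def test_region_bridges_single_gaps():
    ann = _flag_annotation(10)
    pattern = [True, True, False, True, True, False, True, True, False, True]
    flags = pd.Series(pattern, index=[f"g{i}" for i in range(10)])
    regions = detect_de_regions(ann, flags, max_gap=1)
    assert len(regions) == 1
    assert regions[0].n_genes == 10
    assert regions[0].fraction_de == pytest.approx(0.7)


def test_no_flags_no_regions():
    ann = _flag_annotation(10)
    flags = pd.Series(False, index=[f"g{i}" for i in range(10)])
    assert detect_de_regions(ann, flags) == []


def test_truth_region_recovered_on_synthetic_data(small_config):
    """Regions detected from the generator's truth flags overlap >=90% of the
    genuinely regulated hot-region genes."""
    from regulocate.simulate import simulate_dataset
    for seed in (1, 2, 3):
        ds = simulate_dataset(small_config, seed=seed)
        reg = set(ds.truth.regulated_genes["gene_id"])
        flags = pd.Series(ds.annotation.genes["gene_id"].isin(reg).to_numpy(),
                          index=ds.annotation.genes["gene_id"])
        regions = detect_de_regions(ds.annotation, flags)
        covered = set().union(*(r.gene_ids for r in regions)) if regions else set()
        assert len(covered & reg) / len(reg) >= 0.9


def test_de_flags_union():
    de = {"a": _de([1.0, 1.0]), "b": _de([1.0, 1.0])}
    de["a"].loc["g1", "significant"] = False
    de["b"].loc["g1", "significant"] = False
    f = de_flags(de)
    assert f["g0"] and not f["g1"]


# -- upstream distances -----------------------------------------------------

class _G:
    def __init__(self, replicon, start, end, strand):
        self.replicon, self.start, self.end, self.strand = (replicon, start,
                                                            end, strand)


def test_adjacent_hit_distance_one():
    hits = _hits([("chr", 987, 1000, "+", 1.0, 1e-6)])
    assert upstream_distance(_G("chr", 1001, 1400, "+"), hits) == 1


def test_orf_overlapping_hit_is_excluded(toy_annotation):
    hits = _hits([("chr", 1395, 1408, "+", 1.0, 1e-6)])  # inside g1
    kept = filter_orf_hits(hits, toy_annotation)
    assert kept.empty
    assert upstream_distance(_G("chr", 1700, 2100, "+"), kept) is None


def test_nearest_of_two_upstream_hits():
    hits = _hits([("chr", 958, 971, "+", 1.0, 1e-6),    # distance 30
                  ("chr", 838, 851, "+", 1.0, 1e-6)])   # distance 150
    assert upstream_distance(_G("chr", 1001, 1400, "+"), hits) == 30


def test_minus_strand_distance_convention():
    hits = _hits([("chr", 1501, 1514, "-", 1.0, 1e-6)])
    assert upstream_distance(_G("chr", 1001, 1400, "-"), hits) == 101


def test_beyond_window_is_none():
    hits = _hits([("chr", 500, 513, "+", 1.0, 1e-6)])
    assert upstream_distance(_G("chr", 1001, 1400, "+"), hits,
                             max_window=200) is None


# -- distance density -------------------------------------------------------

def test_equal_distances_mode_at_d():
    grid, dens = distance_density([40] * 10, bandwidth=10)
    assert grid[np.argmax(dens)] == pytest.approx(40)


def test_bimodal_toy_has_two_modes():
    grid, dens = distance_density([30] * 8 + [150] * 8, bandwidth=10)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    modes = grid[1:-1][interior]
    assert len(modes) == 2


def test_empty_distances_raise():
    with pytest.raises(ValueError):
        distance_density([])


# -- density/effect correlation ---------------------------------------------

def test_perfect_negative_relationship(small_config, rng):
    from regulocate.simulate import generate_genome
    _, ann = generate_genome(small_config, seed=0)
    hits = _hits([("hot", 100_000, 100_013, "+", 1.0, 1e-6)])
    track = motif_density(hits, 260_000, bandwidth=30000, replicon="hot")
    genes = ann.genes[ann.genes["replicon"] == "hot"]
    mids = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2
    comp = pd.Series(-5.0 * track.value_at(mids), index=genes["gene_id"])
    r, rho = density_effect_correlation(track, comp, ann)
    assert r == pytest.approx(-1.0, abs=1e-9)


def test_permuted_effect_has_small_correlation(small_config, rng):
    from regulocate.simulate import generate_genome
    _, ann = generate_genome(small_config, seed=0)
    hits = _hits([("hot", 100_000, 100_013, "+", 1.0, 1e-6)])
    track = motif_density(hits, 260_000, bandwidth=30000, replicon="hot")
    genes = ann.genes[ann.genes["replicon"] == "hot"]
    mids = (genes["start"].to_numpy() + genes["end"].to_numpy()) / 2
    base = -5.0 * track.value_at(mids)
    rs = []
    for _ in range(20):
        comp = pd.Series(rng.permutation(base), index=genes["gene_id"])
        r, _rho = density_effect_correlation(track, comp, ann)
        rs.append(abs(r))
    assert np.median(rs) < 0.15


def test_constant_effect_gives_nan_with_warning(small_config):
    from regulocate.simulate import generate_genome
    _, ann = generate_genome(small_config, seed=0)
    hits = _hits([("hot", 100_000, 100_013, "+", 1.0, 1e-6)])
    track = motif_density(hits, 260_000, bandwidth=30000, replicon="hot")
    genes = ann.genes[ann.genes["replicon"] == "hot"]
    comp = pd.Series(1.0, index=genes["gene_id"])
    with pytest.warns(UserWarning, match="constant"):
        r, rho = density_effect_correlation(track, comp, ann)
    assert np.isnan(r) and np.isnan(rho)


def test_too_few_genes_raise(toy_annotation):
    track = motif_density(_hits([]), 8000, replicon="chr")
    comp = pd.Series([1.0, 2.0], index=["g1", "g2"])
    with pytest.raises(ValueError):
        density_effect_correlation(track, comp, toy_annotation)
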