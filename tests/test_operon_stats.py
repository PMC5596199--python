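import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from regulocate import (classify_five_groups, classify_four_groups,
                        group_anova_tukey, operon_decay_profile,
                        region_enrichment)
from regulocate.motifs import HIT_COLUMNS


# -- classification ---------------------------------------------------------

def test_four_group_hand_labels(toy_annotation, toy_hits):
    labels = classify_four_groups(toy_annotation, toy_hits)
    assert labels.to_dict() == {"g1": "C", "g2": "C", "g3": "C", "g4": "A",
                                "g5": "B", "g6": "D", "g7": "D"}


def test_five_group_hand_labels(toy_annotation, toy_hits):
    five = classify_five_groups(toy_annotation, toy_hits)
    got = five["five_group"].to_dict()
    assert got == {"g1": "A", "g2": "B", "g3": "C", "g4": "A", "g5": "Z",
                   "g6": "E", "g7": "E"}
    assert five.loc["g2", "order"] == 2


def test_no_hits_only_bdz_e(toy_annotation):
    empty = pd.DataFrame(columns=HIT_COLUMNS)
    four = classify_four_groups(toy_annotation, empty)
    assert set(four.unique()) <= {"B", "D"}
    five = classify_five_groups(toy_annotation, empty)
    assert set(five["five_group"].unique()) <= {"Z", "E"}


def test_hit_beyond_window_treated_as_absent(toy_annotation):
    far = pd.DataFrame([("chr", 700, 713, "+", 9.0, 1e-6)],  # 288 bp before g1
                       columns=HIT_COLUMNS)
    labels = classify_four_groups(toy_annotation, far, window=200)
    assert labels["g1"] == "D"
    wide = classify_four_groups(toy_annotation, far, window=300)
    assert wide["g1"] == "C"


def test_multiple_hits_same_as_one(toy_annotation, toy_hits):
    doubled = pd.concat([toy_hits, toy_hits], ignore_index=True)
    a = classify_four_groups(toy_annotation, toy_hits)
    b = classify_four_groups(toy_annotation, doubled)
    assert a.equals(b)


def test_classification_is_partition(small_config):
    from regulocate.colocalization import filter_orf_hits
    from regulocate.simulate import simulate_dataset
    ds = simulate_dataset(small_config, seed=2)
    hits = filter_orf_hits(ds.truth.planted_hits.assign(score=0.0, p_value=0.0),
                           ds.annotation)
    four = classify_four_groups(ds.annotation, hits)
    five = classify_five_groups(ds.annotation, hits, max_order=3)
    assert len(four) == len(ds.annotation)
    assert four.isin(["A", "B", "C", "D"]).all()
    labelled = five["five_group"].dropna()
    excluded = five["five_group"].isna()
    assert labelled.isin(["A", "B", "C", "E", "Z"]).all()
    assert (five.loc[excluded, "order"] > 3).all()
    assert len(labelled) + excluded.sum() == len(ds.annotation)


def test_order_beyond_max_is_reported_unlabelled(toy_annotation, toy_hits):
    five = classify_five_groups(toy_annotation, toy_hits, max_order=2)
    assert pd.isna(five.loc["g3", "five_group"])
    assert five.loc["g3", "order"] == 3


# -- ANOVA + Tukey ----------------------------------------------------------

TOY_GROUPS = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]}


def _toy_series():
    y, g = [], []
    for name, vals in TOY_GROUPS.items():
        y.extend(vals)
        g.extend([name] * len(vals))
    idx = [f"g{i}" for i in range(len(y))]
    return pd.Series(y, index=idx, dtype=float), pd.Series(g, index=idx)


def test_anova_f_on_printed_toy():
    """Hand computation: SSB=42 (df 2), SSW=6 (df 6) -> F=21."""
    y, g = _toy_series()
    res = group_anova_tukey(y, g)
    assert res.f_statistic == pytest.approx(21.0)
    assert res.p_value == pytest.approx(sps.f.sf(21.0, 2, 6))


def test_identical_groups_f_zero_p_one():
    y = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
    g = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
    res = group_anova_tukey(y, g)
    assert res.f_statistic == pytest.approx(0.0)
    assert (res.tukey["p_adj"] > 0.9).all()


def test_tukey_matches_studentized_range_oracle():
    """Adjusted p equals an independent studentized-range CDF evaluation."""
    y, g = _toy_series()
    res = group_anova_tukey(y, g)
    msw, dfw, n = 1.0, 6, 3  # from the hand ANOVA above
    for _, row in res.tukey.iterrows():
        q = abs(row["meandiff"]) / np.sqrt(msw / n)
        expected = sps.studentized_range.sf(q, 3, dfw)
        assert row["p_adj"] == pytest.approx(expected, abs=1e-6)


def test_anova_matches_two_pass_oracle(rng):
    """F agrees with a brute-force two-pass sums-of-squares computation."""
    for _ in range(5):
        k = int(rng.integers(2, 5))
        sizes = rng.integers(3, 8, size=k)
        y, g = [], []
        for i, n in enumerate(sizes):
            y.extend(rng.normal(i * 0.5, 1.0, n))
            g.extend([f"grp{i}"] * n)
        idx = [f"g{j}" for j in range(len(y))]
        res = group_anova_tukey(pd.Series(y, index=idx),
                                pd.Series(g, index=idx))
        y = np.asarray(y)
        grand = y.mean()
        ssb = sum(len(vals) * (np.mean(vals) - grand) ** 2
                  for vals in (y[np.asarray(g) == grp]
                               for grp in np.unique(g)))
        ssw = sum(((y[np.asarray(g) == grp] - y[np.asarray(g) == grp].mean()) ** 2).sum()
                  for grp in np.unique(g))
        f_oracle = (ssb / (k - 1)) / (ssw / (len(y) - k))
        assert res.f_statistic == pytest.approx(f_oracle, abs=1e-9)


def test_small_groups_dropped_with_warning():
    y = pd.Series([1.0, 2, 3, 4, 5.0, 9.0], index=list("abcdef"))
    g = pd.Series(["x", "x", "x", "y", "y", "z"], index=list("abcdef"))
    with pytest.warns(UserWarning, match="dropping"):
        res = group_anova_tukey(y, g)
    assert res.dropped_groups == ["z"]
    assert set(res.group_sizes.index) == {"x", "y"}


# -- decay profile ----------------------------------------------------------

def test_decay_profile_recovers_geometric_attenuation(small_config):
    """With beta=3, delta=0.5 the order means sit near -3, -1.5, -0.75 and
    attenuate monotonically; motif-less operons stay near 0."""
    from regulocate.colocalization import filter_orf_hits
    from regulocate.simulate import simulate_dataset
    ds = simulate_dataset(small_config, seed=5)
    hits = filter_orf_hits(ds.truth.planted_hits.assign(score=0.0, p_value=0.0),
                           ds.annotation)
    five = classify_five_groups(ds.annotation, hits)
    truth = ds.truth.true_lfc
    lfc = (truth[truth["strain"] == "phbA"]
           .set_index("gene_id")["log2fc"]
           .reindex(ds.annotation.genes["gene_id"]).fillna(0.0))
    decay = operon_decay_profile(lfc, five, ds.annotation)
    motif = decay[decay["operon_class"] == "motif"].set_index("order")
    assert motif.loc[1, "mean_log2fc"] == pytest.approx(-3.0, abs=0.5)
    assert motif.loc[2, "mean_log2fc"] == pytest.approx(-1.5, abs=0.6)
    assert decay.attrs["monotone_attenuation"] is True
    nomotif = decay[decay["operon_class"] == "no_motif"]
    assert nomotif["mean_log2fc"].abs().max() < 0.5 or \
        nomotif["mean_log2fc"].isna().all()


def test_single_order_data_gives_na_flag(toy_annotation):
    hits = pd.DataFrame([("chr", 3550, 3563, "-", 10.0, 1e-6)],
                        columns=HIT_COLUMNS)  # only the singleton g4
    five = classify_five_groups(toy_annotation, hits)
    lfc = pd.Series(0.0, index=[f"g{i}" for i in range(1, 8)])
    decay = operon_decay_profile(lfc, five, toy_annotation)
    assert decay.attrs["monotone_attenuation"] is None


# -- enrichment -------------------------------------------------------------

def test_published_fold_arithmetic():
    res = region_enrichment(4, 14, 120_000, 6_691_694)
    assert res.fold == pytest.approx(15.9, abs=0.05)


def test_region_equal_genome_fold_one():
    assert region_enrichment(10, 10, 1000, 1000).fold == pytest.approx(1.0)


def test_ten_percent_region_fold_two():
    assert region_enrichment(2, 10, 100, 1000).fold == pytest.approx(2.0)


def test_enrichment_errors():
    with pytest.raises(ValueError):
        region_enrichment(1, 0, 100, 1000)
    with pytest.raises(ValueError):
        region_enrichment(5, 4, 100, 1000)
    with pytest.raises(ValueError):
        region_enrichment(1, 2, 2000, 1000)


def test_hypergeometric_tail_when_gene_counts_given():
    res = region_enrichment(4, 14, 120_000, 6_691_694,
                            region_genes=124, genome_genes=6200)
    expected = sps.hypergeom.sf(3, 6200, 14, 124)
    assert res.p_hypergeom == pytest.approx(expected)
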