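from itertools import product

import numpy as np
import pytest

from regulocate import (Gene, GenomeAnnotation, PWM, extract_upstream,
                        fixk_reference_pwm, read_meme, scan, write_meme)
from regulocate._util import revcomp
from regulocate.motifs import (bed_to_hits, consensus_match_count,
                               estimate_background, hits_to_bed)


# -- construction -----------------------------------------------------------

def test_from_sites_no_pseudocount():
    pwm = PWM.from_sites(["AC", "AC"], pseudocount=1e-12)
    assert pwm.probs[0, 0] == pytest.approx(1.0)
    assert pwm.probs[1, 1] == pytest.approx(1.0)


def test_from_sites_pseudocount_arithmetic():
    # two sites, pseudocount 1 per base: col1 A = (2+1)/(2+4) = 0.5
    pwm = PWM.from_sites(["AC", "AC"], pseudocount=1.0)
    assert pwm.probs[0, 0] == pytest.approx(0.5)
    assert pwm.probs[0, 1] == pytest.approx(1 / 6)


def test_from_sites_errors():
    with pytest.raises(ValueError):
        PWM.from_sites([])
    with pytest.raises(ValueError):
        PWM.from_sites(["AC", "ACG"])


def test_columns_sum_to_one_enforced():
    with pytest.raises(ValueError):
        PWM(np.array([[0.5, 0.2, 0.2, 0.2]]))


# -- consensus / reverse complement -----------------------------------------

def test_consensus_point_mass_and_uniform():
    pwm = PWM.from_consensus("ACGT", fixed=0.97)
    assert pwm.consensus() == "ACGT"
    uni = PWM(np.full((3, 4), 0.25))
    assert uni.consensus() == "NNN"


def test_fixk_reference_consensus():
    assert fixk_reference_pwm().consensus() == "TTGATNNNNATCAA"


def test_reverse_complement_involution(rng):
    probs = rng.dirichlet(np.ones(4), size=6)
    pwm = PWM(probs)
    back = pwm.reverse_complement().reverse_complement()
    assert back.probs == pytest.approx(pwm.probs)


def test_palindrome_consensus_is_revcomp_invariant():
    fix = fixk_reference_pwm()
    assert fix.reverse_complement().consensus() == "TTGATNNNNATCAA"


def test_uniform_pwm_is_revcomp_fixed_point():
    uni = PWM(np.full((4, 4), 0.25))
    assert uni.reverse_complement().probs == pytest.approx(uni.probs)


# -- scoring ----------------------------------------------------------------

def test_background_pwm_scores_zero():
    pwm = PWM(np.full((5, 4), 0.25))
    assert pwm.score("ACGTA") == pytest.approx(0.0)


def test_point_mass_score_is_width_times_two_bits():
    eps = 1e-12
    col = [1 - 3 * eps, eps, eps, eps]
    pwm = PWM(np.array([col, col]))
    assert pwm.score("AA") == pytest.approx(4.0, abs=1e-6)


def test_hand_scored_kmer():
    eps = 1e-12
    pwm = PWM(np.array([[0.5 - eps, 0.5 - eps, eps, eps],
                        [eps, eps, 1 - 3 * eps, eps]]))
    assert pwm.score("AG") == pytest.approx(3.0, abs=1e-6)


def test_non_acgt_scores_nan():
    pwm = PWM(np.full((3, 4), 0.25))
    assert np.isnan(pwm.score("ANG"))


# -- exact p-values ----------------------------------------------------------

def test_pvalue_of_minimum_score_is_one(rng):
    pwm = PWM(rng.dirichlet(np.ones(4), size=4))
    min_score = pwm.log_odds.min(axis=1).sum()
    assert pwm.score_pvalue(min_score) == 1.0


def test_width_one_enumeration():
    pwm = PWM(np.array([[0.5, 0.25, 0.125, 0.125]]))
    assert pwm.score_pvalue(1.0) == pytest.approx(0.25)


def _enumerated_scores(pwm):
    w = pwm.width
    lo = pwm.log_odds
    return np.sort([lo[np.arange(w), list(k)].sum()
                    for k in product(range(4), repeat=w)])


def test_dp_matches_enumeration_on_random_pwms(rng):
    """Spot check of the acceptance-scale oracle: DP tail equals brute-force
    enumeration at thresholds the lattice resolves unambiguously."""
    g = 1e-4
    for _ in range(8):
        w = int(rng.integers(2, 7))
        pwm = PWM(rng.dirichlet(np.ones(4) * rng.uniform(0.3, 3), size=w))
        scores = _enumerated_scores(pwm)
        uq = np.unique(scores)
        mids = (uq[:-1] + uq[1:]) / 2
        safe = np.diff(uq) > 4 * w * g
        for m in mids[safe][:: max(1, len(mids) // 40)]:
            p_dp = pwm.score_pvalue(m, granularity=g)
            p_bf = np.mean(scores >= m)
            assert abs(p_dp - p_bf) <= 1e-9


# -- scanning ---------------------------------------------------------------

def test_scan_reports_hand_checked_coordinates():
    fix = fixk_reference_pwm()
    hits = scan(fix, {"toy": "AAAAATTGATACGTATCAAAAAAA"}, p_threshold=1e-4)
    plus = hits[hits["strand"] == "+"]
    assert list(plus["start"]) == [6]
    assert list(plus["end"]) == [19]


def test_palindromic_hit_appears_on_both_strands():
    fix = fixk_reference_pwm()
    hits = scan(fix, {"toy": "AAAAATTGATACGTATCAAAAAAA"}, p_threshold=1e-4)
    assert set(hits["strand"]) == {"+", "-"}
    assert hits.groupby("strand")["start"].first().nunique() == 1


def test_threshold_below_min_achievable_gives_no_hits():
    fix = fixk_reference_pwm()
    hits = scan(fix, {"toy": "AAAAATTGATACGTATCAAAAAAA"}, p_threshold=1e-300)
    assert hits.empty


def test_short_sequence_gives_no_hits():
    fix = fixk_reference_pwm()
    assert scan(fix, {"s": "ACGT"}).empty


def test_scan_matches_naive_rescoring(rng):
    """Every reported hit, and no other window, passes the p threshold when
    each window is rescored independently."""
    pwm = PWM(rng.dirichlet(np.ones(4) * 0.4, size=8))
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    p_thr = 1e-3
    hits = scan(pwm, {"s": seq}, p_threshold=p_thr)
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        reported = set(hits.loc[hits["strand"] == strand, "start"])
        naive = set()
        for i in range(len(seq) - 7):
            sc = mat.score(seq[i:i + 8])
            if not np.isnan(sc) and mat.score_pvalue(sc) <= p_thr:
                naive.add(i + 1)
        assert reported == naive, strand


def test_scanning_revcomp_swaps_strands_preserves_hits(rng):
    pwm = PWM(rng.dirichlet(np.ones(4) * 0.3, size=7))
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    fwd = scan(pwm, {"s": seq}, p_threshold=1e-3)
    rev = scan(pwm.reverse_complement(), {"s": seq}, p_threshold=1e-3)
    swap = {"+": "-", "-": "+"}
    a = {(r.start, r.strand, round(r.score, 9)) for r in fwd.itertuples()}
    b = {(r.start, swap[r.strand], round(r.score, 9)) for r in rev.itertuples()}
    assert a == b


# -- upstream extraction ----------------------------------------------------

def test_upstream_window_exactly_fits():
    ann = GenomeAnnotation([Gene("g", "chr", 201, 400, "+", "op", 1)],
                           {"chr": 1000})
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), 1000))
    up, truncated = extract_upstream(ann, {"chr": seq}, window=200)
    assert up["g"] == seq[:200]
    assert truncated == set()


def test_minus_strand_upstream_is_reverse_complement():
    ann = GenomeAnnotation([Gene("g", "chr", 101, 300, "-", "op", 1)],
                           {"chr": 1000})
    seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 1000))
    up, _ = extract_upstream(ann, {"chr": seq}, window=200)
    assert up["g"] == revcomp(seq[300:500])


def test_edge_gene_is_truncated_and_flagged():
    ann = GenomeAnnotation([Gene("g", "chr", 51, 200, "+", "op", 1)],
                           {"chr": 300})
    seq = "A" * 300
    up, truncated = extract_upstream(ann, {"chr": seq}, window=200)
    assert len(up["g"]) == 50
    assert truncated == {"g"}


def test_two_gene_toy_extraction_base_by_base(toy_annotation):
    seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 8000))
    up, _ = extract_upstream(toy_annotation, {"chr": seq}, window=200)
    assert up["g1"] == seq[800:1000]
    assert up["g2"] == seq[1499:1699]


# -- I/O --------------------------------------------------------------------

def test_meme_round_trip(tmp_path, rng):
    motifs = {"m1": PWM(rng.dirichlet(np.ones(4), size=9)),
              "m2": fixk_reference_pwm()}
    path = tmp_path / "m.meme"
    write_meme(motifs, path, nsites={"m1": 12}, e_values={"m1": 1e-20})
    back = read_meme(path)
    assert set(back) == {"m1", "m2"}
    assert back["m2"].probs == pytest.approx(motifs["m2"].probs, abs=1e-5)


def test_bed_round_trip(tmp_path):
    fix = fixk_reference_pwm()
    hits = scan(fix, {"toy": "AAAAATTGATACGTATCAAAAAAA"}, p_threshold=1e-4)
    path = tmp_path / "h.bed"
    hits_to_bed(hits, path)
    assert "\t5\t19\t" in path.read_text()  # 0-based half-open on disk
    back = bed_to_hits(path)
    assert list(back["start"]) == list(hits["start"])
    assert list(back["end"]) == list(hits["end"])


def test_background_estimation_is_strand_symmetric():
    bg = estimate_background(["AAAAAAAATT"])
    assert bg[0] == pytest.approx(bg[3])  # A and T pooled across strands
    assert bg.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("query,expected", [
    ("TTGATNNNNATCAA", 14),
    ("NTTGATNNNNATCAANNNN", 14),   # wider with flanking Ns still aligns
    ("TTGAT", 9),                  # 5 fixed + 4 reference Ns
    ("AAAAA", 7),                  # A's over the ATCAA tail + 4 reference Ns
])
def test_consensus_match_count(query, expected):
    assert consensus_match_count(query, "TTGATNNNNATCAA") == expected


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 3), min_size=2, max_size=8),
       st.integers(0, 2**31 - 1))
def test_revcomp_involution_and_score_symmetry(codes, seed):
    """revcomp(revcomp(P)) == P, and a k-mer scores against P exactly as its
    reverse complement scores against revcomp(P)."""
    r = np.random.default_rng(seed)
    pwm = PWM(r.dirichlet(np.ones(4), size=len(codes)))
    back = pwm.reverse_complement().reverse_complement()
    assert back.probs == pytest.approx(pwm.probs)
    kmer = "".join("ACGT"[c] for c in codes)
    assert pwm.score(kmer) == pytest.approx(
        pwm.reverse_complement().score(revcomp(kmer)))
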