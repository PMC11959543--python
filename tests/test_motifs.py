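import numpy as np
import pytest

from dualbind.intervals import GenomicRegion, RegionSet
from dualbind.motifs import (
    PWM,
    MotifHit,
    build_consensus_pwm,
    calibrate_threshold,
    classify_configuration,
    cooccurrence,
    default_dr5_seed,
    derive_spacer_variant,
    map_motifs,
    merge_rare,
    motif_prevalence,
    random_control_sequences,
    read_pwm,
    region_configurations,
    sample_control_regions,
    score_sequence,
    threshold_from_scores,
    write_pwm,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def uniform_pwm(length=8):
    return PWM("uni", np.full((length, 4), 0.25), half_site_len=4, spacer_len=0)


# ---------------------------------------------------------------------------
# PWM type and derivation
# ---------------------------------------------------------------------------


def test_pwm_validation():
    with pytest.raises(ValueError):
        PWM("bad", np.full((5, 4), 0.25), half_site_len=4, spacer_len=0)  # length mismatch
    with pytest.raises(ValueError):
        PWM("bad", np.full((8, 3), 0.25), half_site_len=4, spacer_len=0)
    m = np.full((8, 4), 0.25)
    m[0] = [0.5, 0.5, 0.0, 0.0]
    with pytest.raises(ValueError):
        PWM("bad", m, half_site_len=4, spacer_len=0)  # zero probability


def test_dr5_seed_layout():
    seed = default_dr5_seed()
    assert len(seed) == 17  # 6 + 5 + 6
    assert seed.half_site_len == 6 and seed.spacer_len == 5
    # spacer columns are uniform
    assert np.allclose(seed.matrix[6:11], 0.25)


@pytest.mark.parametrize("k", range(10))
def test_derived_lengths(k):
    seed = default_dr5_seed()
    assert len(derive_spacer_variant(seed, k, "direct")) == 12 + k
    assert len(derive_spacer_variant(seed, k, "inverted")) == 12 + k


def test_dr3_spacer_uniform():
    dr3 = derive_spacer_variant(default_dr5_seed(), 3)
    assert len(dr3) == 15
    assert np.allclose(dr3.matrix[6:9], 0.25)
    assert dr3.id == "DR3"


def test_ir_downstream_half_site_is_reverse_complement():
    seed = default_dr5_seed()
    ir0 = derive_spacer_variant(seed, 0, "inverted")
    down = seed.matrix[11:]  # downstream half of the seed
    # A<->T and C<->G columns swapped, positions reversed
    expected = down[::-1][:, [3, 2, 1, 0]]
    assert np.allclose(ir0.matrix[6:], expected)


def test_derive_invalid_spacer():
    with pytest.raises(ValueError):
        derive_spacer_variant(default_dr5_seed(), 12)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_uniform_pwm_scores_zero():
    score, pos, strand = score_sequence(uniform_pwm(), "ACGTACGTACGT")
    assert score == pytest.approx(0.0)


def test_consensus_sequence_scores_maximum():
    pwm = build_consensus_pwm("toy", "AGGTCA", 0)
    consensus = "AGGTCAAGGTCA"
    score, pos, strand = score_sequence(pwm, consensus)
    expected = float(np.log2(pwm.matrix.max(axis=1) / 0.25).sum())
    assert score == pytest.approx(expected)
    assert expected > 0
    assert pos == 0 and strand == "+"


def test_n_bases_score_zero_contribution():
    pwm = build_consensus_pwm("toy", "AG", 0)
    s_all_n, _, _ = score_sequence(pwm, "NNNN")
    assert s_all_n == pytest.approx(0.0)


def test_short_sequence_errors():
    with pytest.raises(ValueError):
        score_sequence(uniform_pwm(8), "ACGT")


def test_strand_symmetry():
    rng = np.random.default_rng(0)
    pwm = default_dr5_seed()
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        fwd, _, _ = score_sequence(pwm, seq)
        rev, _, _ = score_sequence(pwm, revcomp(seq))
        assert fwd == pytest.approx(rev)


def test_scan_matches_bruteforce_oracle():
    """Exhaustive per-window log-odds oracle on a 2 kb sequence."""
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    pwm = derive_spacer_variant(default_dr5_seed(), 3)
    L = len(pwm)
    lo = np.log2(pwm.matrix / 0.25)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def window_score(w):
        return sum(lo[i, idx[b]] for i, b in enumerate(w))

    best_oracle = max(
        max(window_score(seq[i : i + L]) for i in range(len(seq) - L + 1)),
        max(
            window_score(revcomp(seq)[i : i + L])
            for i in range(len(seq) - L + 1)
        ),
    )
    got, _, _ = score_sequence(pwm, seq)
    assert got == pytest.approx(best_oracle)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_threshold_order_statistic():
    assert threshold_from_scores(np.arange(1, 101), 0.05) == 96.0


def test_threshold_fpr_one_is_min():
    scores = np.array([3.0, 1.0, 2.0])
    assert threshold_from_scores(scores, 1.0) == 1.0


def test_threshold_degenerate_errors():
    with pytest.raises(ValueError, match="degenerate"):
        threshold_from_scores(np.full(200, 5.0), 0.05)


def test_threshold_ties_resolve_to_fewer_positives():
    scores = np.array([1.0] * 90 + [5.0] * 10)
    # frac(>=5) = 0.10 > 0.05 -> threshold must exceed the max
    t = threshold_from_scores(scores, 0.05)
    assert (scores >= t).sum() == 0


def test_calibration_transfers_to_independent_controls():
    pwm = default_dr5_seed()
    c1 = random_control_sequences(1000, 200, 0.41, np.random.default_rng(3))
    c2 = random_control_sequences(1000, 200, 0.41, np.random.default_rng(4))
    thr = calibrate_threshold(pwm, c1, 0.05)
    from dualbind.motifs import best_scores

    # achieved rate on the calibration set never exceeds the target
    assert (best_scores(pwm, c1) >= thr).mean() <= 0.05
    rate = (best_scores(pwm, c2) >= thr).mean()
    se = np.sqrt(0.05 * 0.95 / 1000)
    assert abs(rate - 0.05) <= 3 * se


def test_calibration_needs_enough_controls():
    with pytest.raises(ValueError):
        calibrate_threshold(default_dr5_seed(), ["ACGT" * 50] * 10)


# ---------------------------------------------------------------------------
# control regions
# ---------------------------------------------------------------------------


def test_control_regions_size_matched_and_deterministic():
    rng = np.random.default_rng(3)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), size=50_000))}
    r1, s1 = sample_control_regions(genome, [200], 50, np.random.default_rng(7))
    r2, s2 = sample_control_regions(genome, [200], 50, np.random.default_rng(7))
    assert all(len(r) == 200 for r in r1)
    assert [r.key() for r in r1] == [r.key() for r in r2]
    assert s1 == s2


def test_control_regions_gc_matches_genome():
    rng = np.random.default_rng(4)
    p = [0.295, 0.205, 0.205, 0.295]
    genome = {"chr1": "".join(rng.choice(list("ACGT"), size=200_000, p=p))}
    _, seqs = sample_control_regions(genome, [200], 500, np.random.default_rng(8))
    gc = np.mean([(s.count("G") + s.count("C")) / len(s) for s in seqs])
    assert abs(gc - 0.41) < 0.02


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def planted_genome(rng, pwm, positions, length=10_000):
    seq = list(rng.choice(list("ACGT"), size=length))
    consensus = "".join("ACGT"[c] for c in pwm.matrix.argmax(axis=1))
    for pos in positions:
        seq[pos : pos + len(pwm)] = consensus
    return {"chrT": "".join(seq)}


def test_map_motifs_finds_planted_consensus():
    rng = np.random.default_rng(5)
    pwm = derive_spacer_variant(default_dr5_seed(), 3)
    genome = planted_genome(rng, pwm, [2000, 7000])
    controls = random_control_sequences(500, 200, 0.5, rng)
    thr = calibrate_threshold(pwm, controls, 0.05)
    hits = map_motifs(pwm, genome, thr)
    for pos in (2000, 7000):
        assert any(h.start <= pos < h.end or pos <= h.start < pos + len(pwm) for h in hits)


def test_map_motifs_threshold_above_max_empty():
    rng = np.random.default_rng(6)
    pwm = default_dr5_seed()
    genome = planted_genome(rng, pwm, [500])
    assert map_motifs(pwm, genome, pwm.max_score + 1) == []


def test_map_motifs_requires_threshold():
    with pytest.raises(ValueError):
        map_motifs(default_dr5_seed(), {"c": "ACGT" * 100})


def test_map_motifs_matches_window_oracle():
    """Raw above-threshold windows agree with a brute-force scan (5 kb)."""
    rng = np.random.default_rng(7)
    pwm = derive_spacer_variant(default_dr5_seed(), 3)
    seq = planted_genome(rng, pwm, [1000, 1005, 3000], length=5000)["chrT"]
    thr = 8.0
    L = len(pwm)
    lo = np.log2(pwm.matrix / 0.25)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score_plus(w):
        return sum(lo[i, idx[b]] for i, b in enumerate(w))

    plus_hits = {
        i for i in range(len(seq) - L + 1) if score_plus(seq[i : i + L]) >= thr
    }
    minus_hits = {
        i for i in range(len(seq) - L + 1)
        if score_plus(revcomp(seq[i : i + L])) >= thr
    }
    hits = map_motifs(pwm, {"chrT": seq}, thr)
    # every emitted hit is an oracle hit; every oracle hit overlaps an
    # emitted hit on its strand (collapsing keeps one best per chain)
    for h in hits:
        assert h.start in (plus_hits if h.strand == "+" else minus_hits)
    for strand, oracle in (("+", plus_hits), ("-", minus_hits)):
        emitted = [h.start for h in hits if h.strand == strand]
        for pos in oracle:
            assert any(abs(pos - e) < L for e in emitted)


def test_hit_collapsing_keeps_best():
    rng = np.random.default_rng(8)
    pwm = derive_spacer_variant(default_dr5_seed(), 3)
    genome = planted_genome(rng, pwm, [2000])
    hits = map_motifs(pwm, genome, 5.0)
    plus = sorted([h for h in hits if h.strand == "+"], key=lambda h: h.start)
    for h1, h2 in zip(plus, plus[1:]):
        assert h2.start >= h1.end  # no same-strand overlap survives


# ---------------------------------------------------------------------------
# merge_rare / prevalence / cooccurrence
# ---------------------------------------------------------------------------


def hit(start, pwm_id="DR5", chrom="chr1", score=10.0, length=17, strand="+"):
    return MotifHit(chrom, start, start + length, strand, score, pwm_id)


def test_merge_rare_counts_add_and_sorted():
    dr1 = [hit(500, "DR1", length=13)]
    dr2 = []
    dr5 = [hit(100, "DR5"), hit(300, "DR5")]
    rare = merge_rare(dr1, dr2, dr5)
    assert len(rare) == 3
    assert [h.start for h in rare] == [100, 300, 500]
    assert {h.pwm_id for h in rare} == {"DR1", "DR5"}


def test_prevalence_trivial_cases():
    regions = RegionSet(
        [GenomicRegion("chr1", 0, 200, name="r0"), GenomicRegion("chr1", 1000, 1200, name="r1")]
    )
    assert motif_prevalence(regions, [hit(50), hit(1100)]) == 1.0
    assert motif_prevalence(regions, [hit(50, chrom="chr9")]) == 0.0
    with pytest.raises(ValueError):
        motif_prevalence(RegionSet([]), [hit(0)])


def test_cooccurrence_partition():
    regions = RegionSet(
        [
            GenomicRegion("chr1", 0, 200, name="both"),
            GenomicRegion("chr1", 1000, 1200, name="rare"),
            GenomicRegion("chr1", 2000, 2200, name="dr3"),
            GenomicRegion("chr1", 3000, 3200, name="none"),
        ]
    )
    rare = [hit(50, "DR5"), hit(1050, "DR1", length=13)]
    dr3 = [hit(100, "DR3", length=15), hit(2050, "DR3", length=15)]
    cats, fracs = cooccurrence(regions, rare, dr3)
    assert cats == {
        "both": "both", "rare": "RARE-only", "dr3": "DR3-only", "none": "none"
    }
    assert sum(fracs.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# configuration classification
# ---------------------------------------------------------------------------

REGION = GenomicRegion("chr1", 0, 400, name="reg")


def test_config_partially_overlapping():
    dr3 = MotifHit("chr1", 100, 115, "+", 10.0, "DR3")
    dr1 = MotifHit("chr1", 110, 123, "+", 9.0, "DR1")
    cfg = classify_configuration(REGION, dr3, [dr1])
    assert cfg.overlap_bases == 5 and cfg.config_class == "partially"


def test_config_non_overlapping():
    dr3 = MotifHit("chr1", 100, 115, "+", 10.0, "DR3")
    dr5 = MotifHit("chr1", 300, 317, "+", 9.0, "DR5")
    cfg = classify_configuration(REGION, dr3, [dr5])
    assert cfg.overlap_bases == 0 and cfg.config_class == "non-overlapping"


def test_config_largely_overlapping():
    dr3 = MotifHit("chr1", 100, 115, "+", 10.0, "DR3")
    dr2 = MotifHit("chr1", 103, 117, "+", 9.0, "DR2")
    cfg = classify_configuration(REGION, dr3, [dr2])
    assert cfg.overlap_bases == 12 and cfg.config_class == "largely"


def test_config_nearest_by_middle_base_ties_by_score():
    dr3 = MotifHit("chr1", 100, 115, "+", 10.0, "DR3")  # middle 107
    near_lo = MotifHit("chr1", 80, 93, "+", 5.0, "DR1")   # middle 86, d=21
    near_hi = MotifHit("chr1", 121, 134, "+", 8.0, "DR1")  # middle 127, d=20
    cfg = classify_configuration(REGION, dr3, [near_lo, near_hi])
    assert cfg.nearest_rare_hit is near_hi


def test_config_requires_rare_in_region():
    dr3 = MotifHit("chr1", 100, 115, "+", 10.0, "DR3")
    with pytest.raises(ValueError):
        classify_configuration(REGION, dr3, [MotifHit("chr2", 0, 13, "+", 1.0, "DR1")])


def test_config_translation_invariance():
    dr3 = MotifHit("chr1", 100, 115, "+", 10.0, "DR3")
    dr1 = MotifHit("chr1", 110, 123, "+", 9.0, "DR1")
    base = classify_configuration(REGION, dr3, [dr1])
    shift = 10_000
    moved = classify_configuration(
        GenomicRegion("chr1", shift, 400 + shift, name="reg"),
        MotifHit("chr1", 100 + shift, 115 + shift, "+", 10.0, "DR3"),
        [MotifHit("chr1", 110 + shift, 123 + shift, "+", 9.0, "DR1")],
    )
    assert moved.config_class == base.config_class
    assert moved.overlap_bases == base.overlap_bases


def test_region_configurations_partition():
    regions = RegionSet(
        [
            GenomicRegion("chr1", 0, 400, name="r0"),
            GenomicRegion("chr1", 1000, 1400, name="r1"),
        ]
    )
    dr3 = [MotifHit("chr1", 100, 115, "+", 10.0, "DR3"),
           MotifHit("chr1", 1100, 1115, "+", 10.0, "DR3")]
    rare = [MotifHit("chr1", 110, 123, "+", 9.0, "DR1"),
            MotifHit("chr1", 1300, 1313, "+", 9.0, "DR1")]
    configs = region_configurations(regions, dr3, rare)
    assert len(configs) == 2
    assert {c.config_class for c in configs} == {"partially", "non-overlapping"}


def test_middle_base_lower_middle():
    assert MotifHit("c", 100, 115, "+", 0.0, "DR3").middle_base == 107  # odd
    assert MotifHit("c", 100, 114, "+", 0.0, "DR2").middle_base == 106  # even


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def test_pwm_round_trip(tmp_path):
    pwm = derive_spacer_variant(default_dr5_seed(), 3)
    pwm.threshold = 7.25
    p = tmp_path / "dr3.motif"
    write_pwm(pwm, str(p))
    back = read_pwm(str(p))
    assert back.id == "DR3" and back.threshold == pytest.approx(7.25)
    assert back.half_site_len == 6 and back.spacer_len == 3
    assert np.allclose(back.matrix, pwm.matrix, atol=1e-5)
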