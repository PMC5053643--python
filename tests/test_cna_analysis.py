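"""Segmentation, calling and cohort CNA statistics against brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from metaconcord.core import ConfigurationError, MetaconcordError, ProbeProfile, SamplePair
from metaconcord.cna_analysis import (
    GeneRegion,
    Segment,
    _max_arc_t,
    call_cna,
    fraction_altered,
    gene_amplification_status,
    gistic_like_scan,
    locus_frequency_comparison,
    pairwise_status_concordance,
    probe_states,
    segment_profile,
    smoothed_values,
)


def make_profile(values_by_chrom, spacing=1000):
    frames = []
    for chrom, vals in values_by_chrom.items():
        n = len(vals)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.arange(1, n + 1) * spacing,
                    "probe_id": [f"{chrom}_{i}" for i in range(n)],
                    "log2ratio": np.asarray(vals, dtype=float),
                }
            )
        )
    return ProbeProfile("s", pd.concat(frames, ignore_index=True))


# --- change-point statistic vs exhaustive oracle -------------------------


def brute_force_max_t(x):
    """Exhaustive arc search with the textbook pooled-variance t."""
    n = len(x)
    best = (-np.inf, None, None)
    for i in range(n):
        for j in range(i, n):
            k = j - i + 1
            if k >= n:
                continue
            inside = x[i : j + 1]
            outside = np.concatenate([x[:i], x[j + 1 :]])
            d = inside.mean() - outside.mean()
            sse = ((inside - inside.mean()) ** 2).sum() + (
                (outside - outside.mean()) ** 2
            ).sum()
            var = sse / max(n - 2, 1)
            denom = np.sqrt(var * (1 / k + 1 / (n - k)))
            t = np.inf if denom == 0 and abs(d) > 0 else (0.0 if denom == 0 else abs(d) / denom)
            if t > best[0]:
                best = (t, i, j)
    return best


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_arc_statistic_matches_exhaustive_search(seed, rng):
    x = np.random.default_rng(seed).normal(size=25)
    t_fast, i_fast, j_fast = _max_arc_t(x)
    t_slow, i_slow, j_slow = brute_force_max_t(x)
    assert t_fast == pytest.approx(t_slow, rel=1e-10)
    # an arc and its circular complement define the same partition
    same = (i_fast, j_fast) == (i_slow, j_slow)
    complementary = {i_fast, (j_fast + 1) % len(x)} == {i_slow, (j_slow + 1) % len(x)}
    assert same or complementary


def test_noiseless_step_breakpoint_is_exact():
    x = np.array([0.0] * 50 + [1.0] * 50)
    t, i, j = _max_arc_t(x)
    assert np.isinf(t)
    assert {i, j} <= {0, 49, 50, 99}  # the true breakpoint at 50/51
    prof = make_profile({"chr1": x})
    segs = segment_profile(prof, n_perm=200, random_state=0)
    assert [(s.start_index, s.end_index) for s in segs] == [(0, 49), (50, 99)]
    assert [s.mean_log2 for s in segs] == [0.0, 1.0]


def test_constant_profile_is_one_segment_per_chromosome():
    prof = make_profile({"chr1": np.zeros(60), "chr2": np.zeros(40)})
    segs = segment_profile(prof, n_perm=100, random_state=0)
    assert len(segs) == 2
    assert all(s.mean_log2 == 0.0 for s in segs)


def test_short_spike_absorbed_by_min_probe_rule():
    x = np.zeros(60)
    x[30:33] = 2.0  # 3-probe spike, below the 5-probe minimum
    prof = make_profile({"chr1": x})
    segs = segment_profile(prof, n_perm=200, random_state=0)
    assert all(s.n_probes >= 5 for s in segs)


def test_small_chromosome_rejected():
    prof = make_profile({"chr1": np.zeros(60)})
    with pytest.raises(MetaconcordError, match="chr1"):
        segment_profile(prof, min_probes=100)


def test_tiling_and_segment_means(small_cohort):
    sid = small_cohort.sample_ids[0]
    prof = small_cohort.profiles[sid]
    segs = segment_profile(prof, n_perm=100, random_state=0)
    per_chrom = prof.probes.groupby("chrom").size()
    for chrom, n in per_chrom.items():
        csegs = sorted(
            [s for s in segs if s.chrom == chrom], key=lambda s: s.start_index
        )
        assert sum(s.n_probes for s in csegs) == n  # conservation
        cursor = 0
        vals = prof.chrom_values(chrom)
        for s in csegs:
            assert s.start_index == cursor  # no gap, no overlap
            cursor = s.end_index + 1
            assert s.mean_log2 == pytest.approx(
                vals[s.start_index : s.end_index + 1].mean(), abs=1e-12
            )
    sm = smoothed_values(prof, segs)
    assert len(sm) == prof.n_probes


# --- calling --------------------------------------------------------------


def seg(mean, n=10):
    return Segment("chr1", 0, n - 1, 1, n * 1000, n, mean)


@pytest.mark.parametrize(
    "mean,state",
    [
        (0.7, "gain"),
        (1.2, "amplification"),
        (-1.2, "deletion"),
        (-0.6, "loss"),
        (0.4, "neutral"),
        (1.0, "gain"),  # strict at the outer boundary
        (-1.0, "loss"),
        (0.5, "neutral"),
        (-0.5, "neutral"),
    ],
)
def test_two_threshold_state_mapping(mean, state):
    assert call_cna([seg(mean)])[0].state == state


def test_threshold_order_validated():
    with pytest.raises(ConfigurationError):
        call_cna([seg(0.0)], low_thr=1.0, high_thr=0.5)


def test_fraction_altered_counts_probes():
    calls = call_cna([seg(0.0, 95), seg(0.8, 5)])
    assert fraction_altered(calls, 100) == pytest.approx(0.05)
    assert fraction_altered(call_cna([seg(0.0, 100)]), 100) == 0.0


def test_fraction_altered_monotone_in_low_threshold(rng):
    means = rng.normal(0, 0.8, size=40)
    segments = [seg(m) for m in means]
    fractions = [
        fraction_altered(call_cna(segments, low_thr=thr, high_thr=2.0), 400)
        for thr in (0.2, 0.4, 0.6, 0.8)
    ]
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))


# --- gene status ----------------------------------------------------------


ERBB2 = GeneRegion("ERBB2", "chr1", 10_000_000, 10_200_000)


def profile_with_level(level):
    x = np.zeros(150)
    x[5:40] = level  # probes at 6-40 Mb, overlapping the 10-10.2 Mb region
    return make_profile({"chr1": x}, spacing=1_000_000)


def calls_with_level(level):
    return call_cna(segment_profile(profile_with_level(level), n_perm=100, random_state=0))


def test_gene_amplification_status():
    assert gene_amplification_status(calls_with_level(1.5), ERBB2) == "amplified"
    assert gene_amplification_status(calls_with_level(0.0), ERBB2) == "non_amplified"
    assert gene_amplification_status(calls_with_level(0.7), ERBB2) == "non_amplified"
    with pytest.raises(MetaconcordError, match="chr9"):
        gene_amplification_status(calls_with_level(0.0), GeneRegion("X", "chr9", 1, 2))


def test_pairwise_status_concordance():
    pairs = [SamplePair(f"p{i}", f"p{i}-T", f"p{i}-M") for i in range(4)]
    amp, flat = calls_with_level(1.5), calls_with_level(0.0)
    calls = {}
    for i, p in enumerate(pairs):
        calls[p.primary_sample] = amp
        calls[p.metastasis_sample] = amp if i != 0 else flat  # one discordant pair
    rate, table = pairwise_status_concordance(calls, pairs, ERBB2)
    assert rate == pytest.approx(3 / 4)
    assert table["concordant"].tolist() == [False, True, True, True]
    with pytest.raises(MetaconcordError, match="p9"):
        pairwise_status_concordance(calls, pairs + [SamplePair("p9", "x", "y")], ERBB2)


# --- per-locus Fisher comparison ------------------------------------------


def enumeration_fisher(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    N, K, n = a + b + c + d, a + b, a + c
    rv = hypergeom(N, K, n)
    lo, hi = max(0, K + n - N), min(K, n)
    p_obs = rv.pmf(a)
    return float(
        sum(rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= p_obs * (1 + 1e-7))
    )


def test_identical_groups_give_p_one():
    states = np.zeros((5, 30), dtype=int)
    states[:, 10:15] = 1
    out = locus_frequency_comparison(states, states.copy())
    assert np.allclose(out["p_gain"], 1.0)
    assert np.allclose(out["p_loss"], 1.0)


def test_fully_separated_probe_matches_enumeration():
    a = np.zeros((10, 3), dtype=int)
    b = np.zeros((10, 3), dtype=int)
    a[:, 1] = 2  # amplified in 10/10 of A, 0/10 of B
    out = locus_frequency_comparison(a, b)
    assert out["p_gain"][1] == pytest.approx(enumeration_fisher(10, 0, 0, 10), rel=1e-9)
    assert out["p_gain"][1] == pytest.approx(1.082508822446903e-05, rel=1e-9)
    assert out["p_gain"][0] == 1.0


def test_locus_fisher_matches_enumeration_on_mixed_tables(rng):
    na, nb = 7, 9
    a = (rng.random((na, 40)) < 0.3).astype(int)
    b = -(rng.random((nb, 40)) < 0.4).astype(int)
    out = locus_frequency_comparison(a, b)
    for probe in range(40):
        ka = int((a[:, probe] > 0).sum())
        kb = int((b[:, probe] > 0).sum())
        assert out["p_gain"][probe] == pytest.approx(
            enumeration_fisher(ka, na - ka, kb, nb - kb), rel=1e-8
        )


# --- GISTIC-like scan -----------------------------------------------------


def test_no_alterations_no_regions(rng):
    smoothed = rng.normal(0, 0.05, size=(6, 200))
    chroms = np.repeat(["chr1", "chr2"], 100)
    pos = np.tile(np.arange(1, 101) * 1000, 2)
    regions, track = gistic_like_scan(smoothed, chroms, pos, n_resample=200, random_state=0)
    assert regions == []
    assert (track["q_value"] >= 0.25).all()


def test_planted_amplification_recovered():
    rng = np.random.default_rng(7)
    n_samples, n_probes = 10, 200
    smoothed = rng.normal(0, 0.1, size=(n_samples, n_probes))
    smoothed[:8, 50:60] += 1.5  # 80% of samples amplified at one locus
    chroms = np.array(["chr1"] * n_probes)
    pos = np.arange(1, n_probes + 1) * 1000
    regions, _ = gistic_like_scan(smoothed, chroms, pos, n_resample=500, random_state=1)
    assert any(r.start_pos <= 55_000 <= r.end_pos and r.q_value < 0.25 for r in regions)


def test_single_altered_sample_not_reported():
    rng = np.random.default_rng(8)
    smoothed = rng.normal(0, 0.1, size=(23, 200))
    smoothed[0, 50:60] += 0.9  # one sample, modest amplitude
    chroms = np.array(["chr1"] * 200)
    pos = np.arange(1, 201) * 1000
    regions, _ = gistic_like_scan(smoothed, chroms, pos, n_resample=500, random_state=2)
    assert not any(r.start_pos <= 55_000 <= r.end_pos for r in regions)


def test_scan_requires_two_samples():
    with pytest.raises(MetaconcordError):
        gistic_like_scan(np.zeros((1, 50)), np.array(["chr1"] * 50), np.arange(50))
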