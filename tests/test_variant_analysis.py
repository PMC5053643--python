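"""Filtering, recurrence classification and concordance accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from metaconcord.core import SamplePair, ValidationError, VariantKey, VARIANT_COLUMNS
from metaconcord.variant_analysis import (
    ConcordanceResult,
    RecurrenceCatalog,
    class_concordance_test,
    classify_recurrence,
    concordance_summary,
    filter_variants,
    pair_shared_flags,
    vaf_cutoff_sensitivity,
)


def table(rows):
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS + ["population_af"])


def row(gene="TP53", pos=100, vaf=0.2, depth=300, pop=np.nan, ref="A", alt="T"):
    return {
        "gene": gene, "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt,
        "vaf": vaf, "depth": depth, "kind": "snv", "population_af": pop,
    }


# --- filtering ------------------------------------------------------------


def test_filter_boundaries_inclusive():
    t = table(
        [
            row(pos=1, vaf=0.02, depth=10),     # boundary: kept
            row(pos=2, vaf=0.019),              # below vaf threshold
            row(pos=3, depth=9),                # below depth threshold
            row(pos=4, pop=0.02),               # known polymorphism
            row(pos=5, pop=0.01),               # boundary population AF: kept
            row(pos=6),                         # no population record: kept
        ]
    )
    kept = filter_variants(t)
    assert kept["pos"].tolist() == [1, 5, 6]


def test_filter_is_idempotent_and_order_preserving(rng):
    t = table(
        [row(pos=i, vaf=v, depth=d, pop=p)
         for i, (v, d, p) in enumerate(
            zip(rng.uniform(0, 0.6, 50), rng.integers(1, 400, 50),
                np.where(rng.random(50) < 0.3, rng.uniform(0, 0.05, 50), np.nan)))]
    )
    once = filter_variants(t)
    twice = filter_variants(once)
    pd.testing.assert_frame_equal(once, twice)
    assert once["pos"].is_monotonic_increasing


def test_malformed_vaf_reports_record_index():
    t = table([row(pos=1), row(pos=2, vaf=1.4)])
    with pytest.raises(ValidationError, match="index 1"):
        filter_variants(t)


# --- recurrence -----------------------------------------------------------


def test_recurrence_boundary_and_absent_key(catalog):
    h1047r = VariantKey("PIK3CA", "chr2", 70003140, "A", "G")
    assert classify_recurrence(h1047r, catalog) == "recurrent"
    small = RecurrenceCatalog({h1047r: 9})
    assert classify_recurrence(h1047r, small) == "non_recurrent"
    small[h1047r] = 10
    assert classify_recurrence(h1047r, small) == "recurrent"
    absent = VariantKey("NOPE", "chr1", 1, "A", "T")
    assert classify_recurrence(absent, catalog) == "non_recurrent"


# --- shared flags ---------------------------------------------------------


def test_identical_call_sets_fully_shared():
    t = table([row(pos=1), row(pos=2, gene="PIK3CA")])
    flags = pair_shared_flags(t, t.copy())
    assert len(flags) == 4
    assert flags["shared"].all()


def test_hand_enumerated_partial_overlap():
    prim = table([row(pos=1), row(pos=2, gene="B")])   # {A, B}
    met = table([row(pos=1)])                          # {A}
    flags = pair_shared_flags(prim, met)
    assert len(flags) == 3
    assert int(flags["shared"].sum()) == 2  # A counted once per member
    unshared = flags[~flags["shared"]]
    assert unshared["gene"].tolist() == ["B"]


def test_cutoff_changes_shared_status():
    prim = table([row(pos=1, vaf=0.20)])
    met = table([row(pos=1, vaf=0.03)])
    low = pair_shared_flags(prim, met, vaf_cutoff=0.02)
    assert low["shared"].all() and len(low) == 2
    high = pair_shared_flags(prim, met, vaf_cutoff=0.05)
    # the 0.03 occurrence drops out entirely; the partner no longer confers
    # shared status under the strict policy
    assert len(high) == 1 and not high["shared"].any()
    lenient = pair_shared_flags(prim, met, vaf_cutoff=0.05, partner_policy="lenient")
    assert len(lenient) == 1 and lenient["shared"].all()


def test_symmetry_under_role_swap(rng):
    prim = table([row(pos=int(p), vaf=v) for p, v in
                  zip(rng.choice(100, 12, replace=False), rng.uniform(0.02, 0.5, 12))])
    met = table([row(pos=int(p), vaf=v) for p, v in
                 zip(rng.choice(100, 9, replace=False), rng.uniform(0.02, 0.5, 9))])
    a = pair_shared_flags(prim, met, vaf_cutoff=0.05)
    b = pair_shared_flags(met, prim, vaf_cutoff=0.05)
    assert int(a["shared"].sum()) == int(b["shared"].sum())
    assert len(a) == len(b)


def test_duplicate_key_rejected():
    t = table([row(pos=1), row(pos=1)])
    with pytest.raises(ValidationError, match="duplicate"):
        pair_shared_flags(t, table([row(pos=2)]))


# --- cohort summaries -----------------------------------------------------


def small_pairs(tables):
    pairs = []
    by_sample = {}
    for i, (p, m) in enumerate(tables):
        pid = f"p{i}"
        pairs.append(SamplePair(pid, f"{pid}-T", f"{pid}-M"))
        by_sample[f"{pid}-T"] = p
        by_sample[f"{pid}-M"] = m
    return pairs, by_sample


def test_summary_counts_and_percent(catalog):
    shared = table([row(pos=1), row(pos=2)])
    prim = pd.concat([shared, table([row(pos=3)])], ignore_index=True)
    pairs, by_sample = small_pairs([(prim, shared.copy())])
    res = concordance_summary(by_sample, pairs, catalog)
    assert (res.total_occurrences, res.shared_occurrences, res.unshared_occurrences) == (5, 4, 1)
    assert res.percent == 80
    assert res.shared_occurrences % 2 == 0


def test_classes_sum_to_all(catalog):
    rec = table([row(gene="PIK3CA", pos=1)])
    rec.loc[0, ["gene", "chrom", "pos", "ref", "alt"]] = [
        "PIK3CA", "chr2", 70003140, "A", "G"]  # catalog hotspot
    prim = pd.concat([rec, table([row(pos=5), row(pos=6)])], ignore_index=True)
    met = pd.concat([rec.copy(), table([row(pos=5)])], ignore_index=True)
    pairs, by_sample = small_pairs([(prim, met)])
    res = {
        cls: concordance_summary(by_sample, pairs, catalog, variant_class=cls)
        for cls in ("all", "recurrent", "non_recurrent")
    }
    assert (
        res["recurrent"].total_occurrences + res["non_recurrent"].total_occurrences
        == res["all"].total_occurrences
    )
    assert (
        res["recurrent"].shared_occurrences + res["non_recurrent"].shared_occurrences
        == res["all"].shared_occurrences
    )


def test_empty_selection_flagged(catalog):
    pairs, by_sample = small_pairs([(table([]), table([]))])
    res = concordance_summary(by_sample, pairs, catalog)
    assert res.undefined
    assert np.isnan(res.rate)


def test_result_invariants_validated():
    with pytest.raises(ValidationError):
        ConcordanceResult("all", 0.02, 10, 4, 5)  # 4 + 5 != 10
    with pytest.raises(ValidationError):
        ConcordanceResult("all", 0.02, 10, 3, 7)  # odd shared count


# --- class comparison -----------------------------------------------------


def enumeration_fisher(a, b, c, d):
    N, K, n = a + b + c + d, a + b, a + c
    rv = hypergeom(N, K, n)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(k) for k in range(max(0, K + n - N), min(K, n) + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-7)))


def cres(cls, shared, unshared):
    return ConcordanceResult(cls, 0.02, shared + unshared, shared, unshared)


def test_balanced_table_is_null():
    # shared counts must be even; 2/2 vs 2/2 is the minimal balanced case
    out = class_concordance_test(cres("recurrent", 2, 2), cres("non_recurrent", 2, 2))
    assert out.p_value == pytest.approx(1.0)
    assert out.odds_ratio_cross_product == pytest.approx(1.0)


def test_small_table_enumeration():
    # [[4, 0], [0, 3]]: p = P(a=4) + P(a=0) under the hypergeometric null
    out = class_concordance_test(cres("recurrent", 4, 0), cres("non_recurrent", 0, 3))
    assert out.p_value == pytest.approx(enumeration_fisher(4, 0, 0, 3), rel=1e-9)


def test_degenerate_margin():
    out = class_concordance_test(cres("recurrent", 0, 0), cres("non_recurrent", 4, 2))
    assert out.degenerate and out.p_value == 1.0
    assert out.odds_ratio_conditional is None


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(40):
        a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
        a, c = 2 * a, 2 * c  # shared counts are even
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        out = class_concordance_test(cres("recurrent", a, b), cres("non_recurrent", c, d))
        assert out.p_value == pytest.approx(enumeration_fisher(a, b, c, d), rel=1e-8)


# --- cutoff sensitivity ---------------------------------------------------


def test_sensitivity_consistent_with_summary(catalog, small_cohort):
    filtered = {s: filter_variants(t) for s, t in small_cohort.variants.items()}
    sens = vaf_cutoff_sensitivity(filtered, small_cohort.pairs, catalog)
    for cutoff in (0.02, 0.05, 0.10):
        for cls in ("all", "recurrent", "non_recurrent"):
            res = concordance_summary(
                filtered, small_cohort.pairs, catalog, variant_class=cls, vaf_cutoff=cutoff
            )
            sel = sens[(sens["vaf_cutoff"] == cutoff) & (sens["variant_class"] == cls)]
            assert int(sel["total"].iloc[0]) == res.total_occurrences
            assert int(sel["shared"].iloc[0]) == res.shared_occurrences


def test_uniform_high_vaf_insensitive_to_cutoff(catalog):
    prim = table([row(pos=i, vaf=0.5) for i in range(6)])
    met = table([row(pos=i, vaf=0.5) for i in range(4)])
    pairs, by_sample = small_pairs([(prim, met)])
    sens = vaf_cutoff_sensitivity(by_sample, pairs, catalog)
    allc = sens[sens["variant_class"] == "all"]
    assert allc["rate"].nunique() == 1


def test_low_vaf_private_variants_reduce_rate_with_cutoff(catalog):
    # truncal variants at high VAF, private at low VAF: raising the cutoff
    # removes private occurrences from the tally, so with strict partner
    # policy the rate is verified against a direct recount
    trunk = [row(pos=i, vaf=0.40) for i in range(8)]
    prim = table(trunk + [row(pos=100 + i, vaf=0.04) for i in range(4)])
    met = table(trunk)
    pairs, by_sample = small_pairs([(prim, met)])
    sens = vaf_cutoff_sensitivity(by_sample, pairs, catalog, cutoffs=(0.02, 0.05))
    allc = sens[sens["variant_class"] == "all"].set_index("vaf_cutoff")
    # recount by hand: at 0.02 -> 16 shared + 4 unshared; at 0.05 -> 16 + 0
    assert allc.loc[0.02, "rate"] == pytest.approx(16 / 20)
    assert allc.loc[0.05, "rate"] == pytest.approx(1.0)


def test_unsorted_cutoffs_rejected(catalog):
    with pytest.raises(ValidationError):
        vaf_cutoff_sensitivity({}, [], catalog, cutoffs=(0.1, 0.02))
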