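"""Clinical descriptive statistics, paired tests, and report assembly.

``summarize_clinical`` reproduces the clinical-table style of summary:
median and range for numeric fields, integer percents (round-half-up) per
category computed over *informative* records only (missing values are
excluded from the denominator and the informative count is reported).

``paired_location_test`` is the paired comparison used for per-sample
burden statistics (probes altered per sample, mutations per sample). It is
implemented as the Wilcoxon signed-rank test — the canonical paired
analogue of the Mann-Whitney test — exact for n <= 25, two-sided, with
zero differences dropped; the unpaired Mann-Whitney U is exposed alongside
for comparison.

``build_report`` assembles the full analysis bundle for a cohort:
clinical summary, per-sample alteration fractions and mutation counts
with their paired tests, the concordance table across VAF cutoffs, the
recurrent-variant tally split by role, correlation heatmaps and the
bootstrap dendrogram, and therapy-selection concordance, all written
under one directory with a JSON metrics file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort, MetaconcordError, round_half_up_percent, VariantKey
from . import cna_analysis as cna
from . import similarity as sim
from . import therapy_rules as tr
from . import variant_analysis as va

logger = logging.getLogger(__name__)

__all__ = [
    "summarize_clinical",
    "paired_location_test",
    "unpaired_location_test",
    "recurrent_variant_tally",
    "build_report",
]

NUMERIC_FIELDS = ("age_at_diagnosis", "delay_months", "relapse_number")
CATEGORICAL_FIELDS = (
    "pathological_type",
    "grade",
    "er_status",
    "erbb2_status",
    "metastatic_site",
)


def summarize_clinical(records: pd.DataFrame) -> dict:
    """Median + range per numeric field; percent per category over
    informative records. Permutation-invariant in record order."""
    if len(records) == 0:
        raise MetaconcordError("summarize_clinical needs at least one record")
    out: dict = {"n_patients": int(len(records))}
    for fld in NUMERIC_FIELDS:
        if fld not in records.columns:
            continue
        vals = pd.to_numeric(records[fld], errors="coerce").dropna()
        if vals.empty:
            out[fld] = {"uninformative": True}
            continue
        out[fld] = {
            "median": float(np.median(vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_informative": int(len(vals)),
        }
    for fld in CATEGORICAL_FIELDS:
        if fld not in records.columns:
            continue
        col = records[fld]
        informative = col[col.notna() & (col.astype(str).str.strip() != "")]
        if informative.empty:
            out[fld] = {"uninformative": True}
            continue
        counts = informative.value_counts()
        out[fld] = {
            "n_informative": int(len(informative)),
            "percent": {
                str(k): round_half_up_percent(int(v), len(informative))
                for k, v in counts.items()
            },
            "count": {str(k): int(v) for k, v in counts.items()},
        }
    return out


def paired_location_test(values_a, values_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired differences (exact
    null distribution for n <= 25 after dropping zero differences)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise MetaconcordError("paired vectors must have equal length")
    diffs = a - b
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return {"p_value": 1.0, "degenerate": True, "n_nonzero": 0}
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return {
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "degenerate": False,
        "n_nonzero": int(len(nz)),
    }


def unpaired_location_test(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U, for comparison with the paired test."""
    res = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"p_value": float(res.pvalue), "statistic": float(res.statistic)}


def recurrent_variant_tally(
    variants_by_sample: dict[str, pd.DataFrame],
    pairs,
    catalog: va.RecurrenceCatalog,
    min_catalog_samples: int = 10,
) -> pd.DataFrame:
    """Per-variant occurrence counts of recurrent variants split by sample
    role, with a Total row (the recurrent-variant table shape)."""
    counts: dict[VariantKey, dict[str, int]] = {}
    for p in pairs:
        for role, sid in (("primary", p.primary_sample), ("metastasis", p.metastasis_sample)):
            for r in variants_by_sample[sid].itertuples(index=False):
                key = VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)
                if va.classify_recurrence(key, catalog, min_catalog_samples) != "recurrent":
                    continue
                counts.setdefault(key, {"primary": 0, "metastasis": 0})[role] += 1
    rows = [
        {
            "gene": k.gene,
            "chrom": k.chrom,
            "pos": k.pos,
            "ref": k.ref,
            "alt": k.alt,
            "primary_n": v["primary"],
            "metastasis_n": v["metastasis"],
        }
        for k, v in sorted(counts.items())
    ]
    df = pd.DataFrame(
        rows, columns=["gene", "chrom", "pos", "ref", "alt", "primary_n", "metastasis_n"]
    )
    total = pd.DataFrame(
        [
            {
                "gene": "Total",
                "chrom": "",
                "pos": "",
                "ref": "",
                "alt": "",
                "primary_n": int(df["primary_n"].sum()) if len(df) else 0,
                "metastasis_n": int(df["metastasis_n"].sum()) if len(df) else 0,
            }
        ]
    )
    return pd.concat([df, total], ignore_index=True)


def _altered_fraction_per_sample(cohort: Cohort, calls_by_sample) -> dict[str, float]:
    out = {}
    for sid, calls in calls_by_sample.items():
        out[sid] = cna.fraction_altered(calls, cohort.profiles[sid].n_probes)
    return out


def build_report(
    cohort: Cohort,
    out_dir: str | Path,
    catalog: va.RecurrenceCatalog,
    rulebook: tr.Rulebook | None = None,
    role_table: tr.RoleTable | None = None,
    gene_regions: dict | None = None,
    vaf_cutoffs: tuple[float, ...] = (0.02, 0.05, 0.10),
    segment_alpha: float = 0.01,
    segment_n_perm: int = 200,
    n_boot_per_scale: int = 100,
    seed: int = 0,
    make_figures: bool = True,
) -> dict:
    """Run every stage on one cohort and write the report bundle.

    Returns the metrics dictionary that is also written to metrics.json.
    Deterministic given the cohort and seed; rerunning on identical inputs
    reproduces the metrics file byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out_dir / "report.log", level=logging.INFO, force=False)
    metrics: dict = {"seed": seed, "n_pairs": len(cohort.pairs)}
    if not cohort.pairs:
        metrics["empty"] = True
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
        return metrics
    manifest_samples = set(cohort.sample_ids)
    extra = sorted(set(cohort.variants) - manifest_samples)
    missing = sorted(manifest_samples - set(cohort.variants))
    if extra or missing:
        raise MetaconcordError(
            f"manifest mismatch: extra samples {extra}, missing samples {missing}"
        )

    # clinical summary
    if cohort.clinical is not None:
        clin = summarize_clinical(cohort.clinical)
        metrics["clinical"] = clin
        pd.json_normalize(clin).to_csv(out_dir / "clinical_summary.csv", index=False)

    # copy-number stage
    rng = np.random.default_rng(seed)
    if cohort.profiles:
        calls_by_sample = {}
        smoothed = {}
        for sid in cohort.sample_ids:
            profile = cohort.profiles[sid]
            segs = cna.segment_profile(
                profile, alpha=segment_alpha, n_perm=segment_n_perm, random_state=rng
            )
            calls_by_sample[sid] = cna.call_cna(segs)
            smoothed[sid] = cna.smoothed_values(profile, segs)
        fractions = _altered_fraction_per_sample(cohort, calls_by_sample)
        fa_prim = [fractions[p.primary_sample] for p in cohort.pairs]
        fa_met = [fractions[p.metastasis_sample] for p in cohort.pairs]
        metrics["fraction_altered"] = {
            "primary_median_pct": float(100 * np.median(fa_prim)),
            "metastasis_median_pct": float(100 * np.median(fa_met)),
            "paired_test": paired_location_test(fa_prim, fa_met),
        }
        pd.DataFrame(
            {"sample": list(fractions), "fraction_altered": list(fractions.values())}
        ).to_csv(out_dir / "fraction_altered.csv", index=False)

        cna_mat = sim.cna_feature_matrix(cohort.profiles, cohort.sample_ids)
        prim_ids = [p.primary_sample for p in cohort.pairs]
        met_ids = [p.metastasis_sample for p in cohort.pairs]
        corr = sim.correlation_matrix(cna_mat.loc[prim_ids], cna_mat.loc[met_ids])
        corr.to_csv(out_dir / "cna_correlation_matrix.csv")
        expected = {p.metastasis_sample: p.primary_sample for p in cohort.pairs}
        _, frac_match = sim.best_match_assignment(corr, expected)
        metrics["cna_best_match_fraction"] = frac_match
        dend = sim.au_pvalues(
            cna_mat, n_boot_per_scale=n_boot_per_scale, random_state=np.random.default_rng(seed + 1)
        )
        (out_dir / "cna_dendrogram.nwk").write_text(sim.to_newick(dend))
        sib = sim.sibling_pair_count(
            dend, [(p.primary_sample, p.metastasis_sample) for p in cohort.pairs]
        )
        metrics["cna_sibling_pairs"] = {"n": sib, "of": len(cohort.pairs)}
        if make_figures:
            sim.plot_correlation_heatmap(corr, out_dir / "cna_correlation_heatmap.png")

    # variant stage
    if cohort.variants:
        filtered = {
            sid: va.filter_variants(t) for sid, t in cohort.variants.items()
        }
        n_prim = [len(filtered[p.primary_sample]) for p in cohort.pairs]
        n_met = [len(filtered[p.metastasis_sample]) for p in cohort.pairs]
        metrics["mutations_per_sample"] = {
            "primary_median": float(np.median(n_prim)),
            "metastasis_median": float(np.median(n_met)),
            "paired_test": paired_location_test(n_prim, n_met),
        }
        sens = va.vaf_cutoff_sensitivity(filtered, cohort.pairs, catalog, cutoffs=vaf_cutoffs)
        sens.to_csv(out_dir / "concordance_table.csv", index=False)
        base = sens[sens["vaf_cutoff"] == vaf_cutoffs[0]]
        metrics["concordance"] = {
            r.variant_class: {
                "total": int(r.total),
                "shared": int(r.shared),
                "unshared": int(r.unshared),
                "percent": None if pd.isna(r.rate) else int(r.percent),
            }
            for r in base.itertuples(index=False)
        }
        tally = recurrent_variant_tally(filtered, cohort.pairs, catalog)
        tally.to_csv(out_dir / "recurrent_variant_tally.csv", index=False)
        metrics["recurrent_tally_totals"] = {
            "primary": int(tally.iloc[-1]["primary_n"]),
            "metastasis": int(tally.iloc[-1]["metastasis_n"]),
        }
        vaf_mat = sim.vaf_feature_matrix(filtered, cohort.sample_ids)
        if vaf_mat.shape[1] >= 2:
            prim_ids = [p.primary_sample for p in cohort.pairs]
            met_ids = [p.metastasis_sample for p in cohort.pairs]
            vcorr = sim.correlation_matrix(vaf_mat.loc[prim_ids], vaf_mat.loc[met_ids])
            vcorr.to_csv(out_dir / "vaf_correlation_matrix.csv")
            if make_figures:
                sim.plot_correlation_heatmap(vcorr, out_dir / "vaf_correlation_heatmap.png")

    # therapy stage
    if rulebook is not None and cohort.variants:
        role_table = role_table or tr.packaged_role_table()
        gene_regions = gene_regions or {}
        decisions = []
        for p in cohort.pairs:
            for role, sid in (
                ("primary", p.primary_sample),
                ("metastasis", p.metastasis_sample),
            ):
                calls = calls_by_sample.get(sid, []) if cohort.profiles else []
                profile = tr.build_profile(
                    sid,
                    calls,
                    va.filter_variants(cohort.variants[sid]),
                    role_table,
                    gene_regions,
                    rulebook=rulebook,
                )
                decisions.append(
                    tr.select_therapies(profile, rulebook, patient_id=p.patient_id, role=role)
                )
        table, rate, fractions = tr.therapy_concordance(decisions, cohort.pairs, rulebook)
        table.to_csv(out_dir / "therapy_decisions.csv", index=False)
        metrics["therapy"] = {
            "trial": rulebook.trial,
            "concordance_percent": round_half_up_percent(
                int(table["concordant"].sum()), len(table)
            ),
            "candidate_fraction": fractions,
        }

    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    logger.info("report written to %s", out_dir)
    return metrics
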