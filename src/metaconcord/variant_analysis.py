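"""Variant filtering, recurrence classification and pair concordance.

Calls are kept when their allele fraction and depth reach the detection
thresholds (defaults 0.02 and 10) and they are not known population
polymorphisms (population allele frequency above 1%). A variant is
*recurrent* when its genomic key is present in at least
``min_catalog_samples`` (default 10) samples of the reference somatic
catalog; all other variants are non-recurrent (passengers).

Concordance bookkeeping counts *occurrences*: each call in one member of a
pair is one occurrence, and it is shared when the identical key is called
in the partner sample; a shared variant therefore contributes two shared
occurrences and a private one a single unshared occurrence. Rates are
reported both as fractions and as integer percents (round-half-up, so
374/499 prints as 75%).

Shared-status policy at a VAF cutoff: under the default ``strict`` policy
the partner call must itself pass the active cutoff to confer shared
status; under ``lenient`` a partner detection at any allele fraction
suffices. Occurrences below the cutoff are excluded from numerator and
denominator alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    MetaconcordError,
    SamplePair,
    ValidationError,
    VariantKey,
    round_half_up_percent,
    variant_keys,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecurrenceCatalog",
    "ConcordanceResult",
    "ClassComparison",
    "filter_variants",
    "classify_recurrence",
    "pair_shared_flags",
    "concordance_summary",
    "class_concordance_test",
    "vaf_cutoff_sensitivity",
]

VARIANT_CLASSES = ("all", "recurrent", "non_recurrent")


class RecurrenceCatalog(dict):
    """Map VariantKey -> number of catalog samples carrying the variant."""

    @classmethod
    def from_tsv(cls, path) -> "RecurrenceCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        cat = cls()
        for r in df.itertuples(index=False):
            cat[VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)] = int(
                r.catalog_count
            )
        return cat


@dataclass
class ConcordanceResult:
    """Shared/unshared occurrence counts for one variant class at one VAF
    cutoff (the shape of the study's concordance table)."""

    variant_class: str
    vaf_cutoff: float
    total_occurrences: int
    shared_occurrences: int
    unshared_occurrences: int
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.shared_occurrences + self.unshared_occurrences != self.total_occurrences:
            raise ValidationError("shared + unshared must equal total")
        if self.shared_occurrences % 2 != 0:
            raise ValidationError("shared occurrences come in pairs and must be even")

    @property
    def rate(self) -> float:
        if self.total_occurrences == 0:
            return float("nan")
        return self.shared_occurrences / self.total_occurrences

    @property
    def percent(self) -> int | None:
        if self.total_occurrences == 0:
            return None
        return round_half_up_percent(self.shared_occurrences, self.total_occurrences)


def filter_variants(
    calls: pd.DataFrame,
    vaf_min: float = 0.02,
    depth_min: int = 10,
    pop_af_max: float = 0.01,
) -> pd.DataFrame:
    """Detection and polymorphism filters; keeps row order, logs one reason
    per dropped call. Boundary values (vaf == vaf_min, depth == depth_min,
    population_af == pop_af_max) are kept."""
    if not 0 <= vaf_min <= 1:
        raise ValidationError(f"vaf_min must be in [0, 1], got {vaf_min}")
    if depth_min < 0:
        raise ValidationError("depth_min must be >= 0")
    vaf = calls["vaf"].to_numpy(dtype=float)
    bad = np.where((vaf < 0) | (vaf > 1) | ~np.isfinite(vaf))[0]
    if len(bad):
        raise ValidationError(f"vaf outside [0, 1] at record index {int(bad[0])}")
    keep = np.ones(len(calls), dtype=bool)
    reasons = {}
    keep &= vaf >= vaf_min
    for idx in np.where(vaf < vaf_min)[0]:
        reasons[idx] = f"vaf {vaf[idx]:.4g} < {vaf_min}"
    depth = calls["depth"].to_numpy()
    low_depth = depth < depth_min
    for idx in np.where(low_depth & keep)[0]:
        reasons[idx] = f"depth {depth[idx]} < {depth_min}"
    keep &= ~low_depth
    if "population_af" in calls.columns:
        pop = calls["population_af"].to_numpy(dtype=float)
        poly = np.isfinite(pop) & (pop > pop_af_max)
        for idx in np.where(poly & keep)[0]:
            reasons[idx] = f"population_af {pop[idx]:.4g} > {pop_af_max}"
        keep &= ~poly
    for idx, why in sorted(reasons.items()):
        logger.debug("dropped call %d: %s", idx, why)
    return calls.loc[keep].reset_index(drop=True)


def classify_recurrence(
    key: VariantKey, catalog: RecurrenceCatalog, min_catalog_samples: int = 10
) -> str:
    """'recurrent' iff the catalog carries the key in >= min_catalog_samples
    samples; absent keys count zero."""
    return (
        "recurrent" if catalog.get(key, 0) >= min_catalog_samples else "non_recurrent"
    )


def _check_unique(keys: list[VariantKey], sample: str) -> None:
    seen = set()
    for k in keys:
        if k in seen:
            raise ValidationError(f"duplicate variant key in sample {sample}: {k}")
        seen.add(k)


def pair_shared_flags(
    primary_calls: pd.DataFrame,
    metastasis_calls: pd.DataFrame,
    vaf_cutoff: float = 0.0,
    partner_policy: str = "strict",
) -> pd.DataFrame:
    """Per-occurrence shared flag for one pair.

    Occurrences with vaf below the cutoff are excluded. An occurrence is
    shared iff the identical key exists in the partner sample — under the
    'strict' policy at vaf >= cutoff, under 'lenient' at any detected vaf.
    Symmetric in the two members by construction.
    """
    if partner_policy not in ("strict", "lenient"):
        raise ValidationError(f"unknown partner_policy {partner_policy!r}")
    pk = variant_keys(primary_calls)
    mk = variant_keys(metastasis_calls)
    _check_unique(pk, "primary")
    _check_unique(mk, "metastasis")
    rows = []
    for role, own_calls, own_keys, partner_calls, partner_keys in (
        ("primary", primary_calls, pk, metastasis_calls, mk),
        ("metastasis", metastasis_calls, mk, primary_calls, pk),
    ):
        if partner_policy == "strict":
            partner_set = {
                k
                for k, v in zip(partner_keys, partner_calls["vaf"])
                if v >= vaf_cutoff
            }
        else:
            partner_set = set(partner_keys)
        for k, v in zip(own_keys, own_calls["vaf"]):
            if v < vaf_cutoff:
                continue
            rows.append(
                {
                    "role": role,
                    "gene": k.gene,
                    "chrom": k.chrom,
                    "pos": k.pos,
                    "ref": k.ref,
                    "alt": k.alt,
                    "vaf": float(v),
                    "shared": k in partner_set,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["role", "gene", "chrom", "pos", "ref", "alt", "vaf", "shared"],
    )


def concordance_summary(
    variants_by_sample: dict[str, pd.DataFrame],
    pairs: list[SamplePair],
    catalog: RecurrenceCatalog,
    variant_class: str = "all",
    vaf_cutoff: float = 0.0,
    min_catalog_samples: int = 10,
    partner_policy: str = "strict",
) -> ConcordanceResult:
    """Aggregate shared/unshared occurrences over all pairs for one variant
    class at one cutoff."""
    if variant_class not in VARIANT_CLASSES:
        raise ValidationError(f"unknown variant class {variant_class!r}")
    shared = unshared = 0
    for p in pairs:
        for sid in (p.primary_sample, p.metastasis_sample):
            if sid not in variants_by_sample:
                raise MetaconcordError(f"patient {p.patient_id}: missing sample {sid}")
        flags = pair_shared_flags(
            variants_by_sample[p.primary_sample],
            variants_by_sample[p.metastasis_sample],
            vaf_cutoff=vaf_cutoff,
            partner_policy=partner_policy,
        )
        for r in flags.itertuples(index=False):
            key = VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)
            cls = classify_recurrence(key, catalog, min_catalog_samples)
            if variant_class != "all" and cls != variant_class:
                continue
            if r.shared:
                shared += 1
            else:
                unshared += 1
    total = shared + unshared
    return ConcordanceResult(
        variant_class=variant_class,
        vaf_cutoff=vaf_cutoff,
        total_occurrences=total,
        shared_occurrences=shared,
        unshared_occurrences=unshared,
        undefined=(total == 0),
    )


@dataclass
class ClassComparison:
    """Two-sided Fisher comparison of shared/unshared counts between the
    recurrent and non-recurrent classes. Both odds-ratio estimators are
    reported: the sample cross-product and the conditional maximum
    likelihood estimate with its exact confidence interval."""

    p_value: float
    odds_ratio_cross_product: float | None
    odds_ratio_conditional: float | None
    ci_95: tuple[float, float] | None
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def class_concordance_test(
    recurrent: ConcordanceResult, non_recurrent: ConcordanceResult
) -> ClassComparison:
    a, b = recurrent.shared_occurrences, recurrent.unshared_occurrences
    c, d = non_recurrent.shared_occurrences, non_recurrent.unshared_occurrences
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return ClassComparison(
            p_value=1.0,
            odds_ratio_cross_product=None,
            odds_ratio_conditional=None,
            ci_95=None,
            table=table,
            degenerate=True,
        )
    res = stats.fisher_exact([[a, b], [c, d]])
    orr = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
    ci = orr.confidence_interval(0.95)
    cross = (a * d) / (b * c) if b * c else None
    return ClassComparison(
        p_value=float(res.pvalue),
        odds_ratio_cross_product=cross,
        odds_ratio_conditional=float(orr.statistic),
        ci_95=(float(ci.low), float(ci.high)),
        table=table,
    )


def vaf_cutoff_sensitivity(
    variants_by_sample: dict[str, pd.DataFrame],
    pairs: list[SamplePair],
    catalog: RecurrenceCatalog,
    cutoffs: tuple[float, ...] = (0.02, 0.05, 0.10),
    min_catalog_samples: int = 10,
    partner_policy: str = "strict",
) -> pd.DataFrame:
    """ConcordanceResult per (variant class, cutoff), as a tidy table."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValidationError("cutoffs must be sorted ascending")
    rows = []
    for cutoff in cutoffs:
        for cls in VARIANT_CLASSES:
            r = concordance_summary(
                variants_by_sample,
                pairs,
                catalog,
                variant_class=cls,
                vaf_cutoff=cutoff,
                min_catalog_samples=min_catalog_samples,
                partner_policy=partner_policy,
            )
            rows.append(
                {
                    "vaf_cutoff": cutoff,
                    "variant_class": cls,
                    "total": r.total_occurrences,
                    "shared": r.shared_occurrences,
                    "unshared": r.unshared_occurrences,
                    "rate": r.rate,
                    "percent": r.percent,
                }
            )
    return pd.DataFrame(rows)
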