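"""Packaged reference fixtures and fixture builders.

The package ships desk-scale, plain-text fixtures:

* the clinical table of the 23-patient cohort, transcribed exactly
  (including missing grades/statuses and the non-contiguous patient ids —
  there is no patient 3, 19 or 25);
* the catalog of 14 unique recurrent driver variants with their
  primary/metastasis occurrence counts (19 and 20) and reference-catalog
  sample counts. Genomic coordinates of these keys are synthetic (toy
  chromosome of the gene plus the cDNA offset) — identity only needs to be
  consistent within the package;
* a synthetic toy gene map placing the driver genes on the simulator's
  four-chromosome genome.

Builders assemble the per-pair call tables behind the published summary
counts: the recurrent-variant assignment distributes the 39 occurrences
over patients consistently with the reported per-gene patient counts and
places the three discordant occurrences with patients 5, 8 and 20; the
full concordance fixture adds synthetic passenger variants so the cohort
aggregates to 499 occurrences, 374 shared / 125 unshared.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .core import SamplePair, VariantKey, VARIANT_COLUMNS
from .cna_analysis import GeneRegion
from .therapy_rules import (
    MolecularProfile,
    Rulebook,
    TherapyDecision,
    packaged_role_table,
    select_therapies,
)
from .variant_analysis import RecurrenceCatalog

__all__ = [
    "load_clinical_table",
    "load_recurrent_variant_table",
    "load_recurrence_catalog",
    "load_gene_regions",
    "recurrent_fixture_cohort",
    "concordance_fixture_cohort",
    "therapy_fixture_decisions",
]

_DATA = importlib.resources.files("metaconcord.data")

#: Which patient carries which shared recurrent variant (gene, cDNA key).
#: The assignment reproduces the per-gene patient counts: PIK3CA variants in
#: 23 samples from 12 patients, TP53 in 11 samples from 6 patients, AKT1 in
#: 2 patients, plus the three discordant occurrences (patients 5, 8, 20).
_SHARED_ASSIGNMENT: dict[str, list[str]] = {
    "1": ["PIK3CA:A3140G", "TP53:G422T"],
    "2": ["PIK3CA:C1616G"],
    "4": ["PIK3CA:G1624A"],
    "5": ["PIK3CA:A3140G"],
    "6": ["PIK3CA:G1633A"],
    "9": ["PIK3CA:G1633A"],
    "10": ["PIK3CA:A3140G"],
    "11": ["PIK3CA:A3140G"],
    "12": ["PIK3CA:A3140T"],
    "13": ["PIK3CA:G353A"],
    "16": ["TP53:C152G"],
    "17": ["TP53:G128A"],
    "18": ["TP53:G317A"],
    "20": ["PIK3CA:A3140T"],
    "21": ["TP53:T304C"],
    "22": ["AKT1:G49A"],
    "23": ["AKT1:G49A"],
}
_PRIMARY_ONLY: dict[str, list[str]] = {"8": ["PIK3CA:G1633A"]}
_METASTASIS_ONLY: dict[str, list[str]] = {"5": ["TP53:C421T"], "20": ["ERBB2:T2264C"]}

#: Patients whose tumors are ERBB2-amplified in both members (drives the
#: lapatinib-arm selections in the therapy fixture).
_ERBB2_AMPLIFIED = ("16", "18")


def load_clinical_table() -> pd.DataFrame:
    """The 23-patient clinical table (missing values as NaN)."""
    return pd.read_csv(_DATA / "clinical_table1.csv")


def load_recurrent_variant_table() -> pd.DataFrame:
    """The 14 unique recurrent variants with per-role occurrence counts."""
    return pd.read_csv(
        _DATA / "recurrent_variants_table3.tsv",
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str},
    )


def load_recurrence_catalog() -> RecurrenceCatalog:
    """Toy recurrence catalog (all 14 driver keys at counts >= 10)."""
    return RecurrenceCatalog.from_tsv(_DATA / "driver_catalog.tsv")


def load_gene_regions() -> dict[str, GeneRegion]:
    """Synthetic toy map of driver genes on the simulator genome."""
    df = pd.read_csv(_DATA / "gene_regions.tsv", sep="\t", dtype={"chrom": str})
    return {
        r.gene: GeneRegion(r.gene, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    }


def _key_lookup() -> dict[str, VariantKey]:
    table = load_recurrent_variant_table()
    return {
        f"{r.gene}:{r.cdna}": VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)
        for r in table.itertuples(index=False)
    }


def _call_row(key: VariantKey, vaf: float, depth: int = 300) -> dict:
    kind = "snv" if len(key.ref) == len(key.alt) == 1 else "indel"
    return {
        "gene": key.gene,
        "chrom": key.chrom,
        "pos": key.pos,
        "ref": key.ref,
        "alt": key.alt,
        "vaf": vaf,
        "depth": depth,
        "kind": kind,
    }


def _cohort_pairs() -> list[SamplePair]:
    ids = load_clinical_table()["patient_id"].astype(str).tolist()
    return [SamplePair(pid, f"{pid}-T", f"{pid}-M") for pid in ids]


def recurrent_fixture_cohort() -> tuple[list[SamplePair], dict[str, pd.DataFrame]]:
    """Per-sample call tables containing only the 39 recurrent occurrences."""
    lookup = _key_lookup()
    pairs = _cohort_pairs()
    rows: dict[str, list[dict]] = {s: [] for p in pairs for s in (p.primary_sample, p.metastasis_sample)}
    for pid, names in _SHARED_ASSIGNMENT.items():
        for name in names:
            key = lookup[name]
            rows[f"{pid}-T"].append(_call_row(key, 0.30))
            rows[f"{pid}-M"].append(_call_row(key, 0.28))
    for pid, names in _PRIMARY_ONLY.items():
        for name in names:
            rows[f"{pid}-T"].append(_call_row(lookup[name], 0.25))
    for pid, names in _METASTASIS_ONLY.items():
        for name in names:
            rows[f"{pid}-M"].append(_call_row(lookup[name], 0.25))
    tables = {
        sid: pd.DataFrame(r, columns=VARIANT_COLUMNS) for sid, r in rows.items()
    }
    return pairs, tables


def concordance_fixture_cohort() -> tuple[list[SamplePair], dict[str, pd.DataFrame]]:
    """Recurrent occurrences plus synthetic passengers, aggregating to the
    published totals: 499 occurrences = 374 shared + 125 unshared, of which
    recurrent 39 = 36 + 3 and non-recurrent 460 = 338 + 122."""
    pairs, tables = recurrent_fixture_cohort()
    rows = {sid: t.to_dict("records") for sid, t in tables.items()}
    n_shared, n_unshared = 169, 122  # distinct non-recurrent variants
    shared_per_pair = [7 + (1 if i < n_shared - 7 * 23 else 0) for i in range(23)]
    unshared_per_pair = [5 + (1 if i < n_unshared - 5 * 23 else 0) for i in range(23)]
    for i, pair in enumerate(pairs):
        for j in range(shared_per_pair[i]):
            key = VariantKey(f"PSG{i:02d}S{j}", "chr4", 1_000_000 + i * 1000 + j, "A", "T")
            vaf = 0.05 + 0.02 * (j % 10)
            rows[pair.primary_sample].append(_call_row(key, vaf))
            rows[pair.metastasis_sample].append(_call_row(key, vaf + 0.01))
        for j in range(unshared_per_pair[i]):
            key = VariantKey(f"PSG{i:02d}U{j}", "chr4", 2_000_000 + i * 1000 + j, "G", "C")
            side = pair.primary_sample if (i + j) % 2 == 0 else pair.metastasis_sample
            rows[side].append(_call_row(key, 0.04 + 0.02 * (j % 8)))
    tables = {sid: pd.DataFrame(r, columns=VARIANT_COLUMNS) for sid, r in rows.items()}
    return pairs, tables


def therapy_fixture_decisions(
    rulebook: Rulebook,
) -> tuple[list[SamplePair], list[TherapyDecision]]:
    """Therapy decisions for the 23-patient fixture, derived by running the
    selection engine on profiles built from the recurrent-variant fixture.

    PIK3CA/AKT1 hotspot carriers select the mTOR arm; the two
    ERBB2-amplified patients select the ERBB2 arm. The only divergent pair
    is patient 8, whose activating PIK3CA mutation is present in the
    primary tumor but not the metastasis, so the primary-derived choice
    has one extra mTOR-arm candidate.
    """
    role_table = packaged_role_table()
    pairs, tables = recurrent_fixture_cohort()
    decisions = []
    for p in pairs:
        for role, sid in (("primary", p.primary_sample), ("metastasis", p.metastasis_sample)):
            profile = MolecularProfile(sample_id=sid)
            if p.patient_id in _ERBB2_AMPLIFIED:
                profile.amplified_genes.add("ERBB2")
            for r in tables[sid].itertuples(index=False):
                key = VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)
                if role_table.roles.get(key.gene) == "oncogene" and role_table.is_activating(key):
                    profile.activating_mutations.add((key.gene, key))
            decisions.append(
                select_therapies(profile, rulebook, patient_id=p.patient_id, role=role)
            )
    return pairs, decisions
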