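"""Actionability rule engine and therapy-choice concordance.

A rulebook encodes one trial's drug panel: each drug carries zero or more
triggers, a trigger being a (gene, alteration class) requirement with
class one of amplification, activating_mutation or biallelic_inactivation.
A drug is selected for a sample iff any of its triggers is satisfied by
the sample's molecular profile; drugs with no triggers are protocol
placeholders that never fire until populated.

Profiles follow the oncogene/tumor-suppressor semantics of
molecularly-guided trials: alterations must be *activating* for oncogenes
(amplification, or a mutation on the gene's hotspot allow-list) and
*biallelic inactivating* for tumor suppressors (a deleterious variant plus
loss of the locus, or a homozygous deletion). Two panels ship with the
package: a seven-drug panel (``shiva_like``) and a five-drug panel
(``most_like``); only the ERBB2 and PI3K/AKT/mTOR arms carry triggers, the
mapping the published selections imply.

Per-patient therapy concordance compares the primary-derived and
metastasis-derived drug sets as sets; the candidate fraction is the share
of patients with at least one selected drug.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import MetaconcordError, SamplePair, ValidationError, VariantKey
from .cna_analysis import CnaCall, GeneRegion, gene_amplification_status

__all__ = [
    "Trigger",
    "Drug",
    "Rulebook",
    "RoleTable",
    "MolecularProfile",
    "TherapyDecision",
    "load_rulebook",
    "packaged_rulebook",
    "save_rulebook",
    "load_role_table",
    "packaged_role_table",
    "build_profile",
    "select_therapies",
    "therapy_concordance",
]

ALTERATION_CLASSES = ("amplification", "activating_mutation", "biallelic_inactivation")


@dataclass(frozen=True)
class Trigger:
    gene: str
    alteration: str


@dataclass
class Drug:
    name: str
    pathway: str
    triggers: list[Trigger] = field(default_factory=list)


@dataclass
class Rulebook:
    trial: str
    drugs: list[Drug]

    @property
    def panel(self) -> set[str]:
        return {d.name for d in self.drugs}

    @property
    def trigger_genes(self) -> set[str]:
        return {t.gene for d in self.drugs for t in d.triggers}

    def to_dict(self) -> dict:
        return {
            "trial": self.trial,
            "drugs": [
                {
                    "name": d.name,
                    "pathway": d.pathway,
                    "triggers": [
                        {"gene": t.gene, "alteration": t.alteration} for t in d.triggers
                    ],
                }
                for d in self.drugs
            ],
        }


def _parse_rulebook(doc: dict) -> Rulebook:
    if not isinstance(doc, dict) or "trial" not in doc or "drugs" not in doc:
        raise ValidationError("rulebook must have 'trial' and 'drugs' fields")
    drugs = []
    for di, d in enumerate(doc["drugs"]):
        for fld in ("name", "pathway"):
            if fld not in d:
                raise ValidationError(f"drug #{di}: missing field '{fld}'")
        triggers = []
        for ti, t in enumerate(d.get("triggers", [])):
            if not t.get("gene"):
                raise ValidationError(
                    f"drug #{di} ({d['name']}), trigger #{ti}: empty gene"
                )
            alt = t.get("alteration")
            if alt not in ALTERATION_CLASSES:
                raise ValidationError(
                    f"drug #{di} ({d['name']}), trigger #{ti}: unknown alteration "
                    f"class {alt!r}"
                )
            triggers.append(Trigger(gene=t["gene"], alteration=alt))
        drugs.append(Drug(name=d["name"], pathway=d["pathway"], triggers=triggers))
    return Rulebook(trial=doc["trial"], drugs=drugs)


def load_rulebook(path: str | Path) -> Rulebook:
    """Load and validate a YAML or JSON rulebook."""
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _parse_rulebook(doc)


def save_rulebook(rulebook: Rulebook, path: str | Path) -> None:
    path = Path(path)
    doc = rulebook.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def packaged_rulebook(trial: str) -> Rulebook:
    """One of the shipped panels: 'shiva_like' (7 drugs) or 'most_like' (5)."""
    ref = importlib.resources.files("metaconcord.data") / f"rulebook_{trial}.yaml"
    return _parse_rulebook(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# role table


@dataclass
class RoleTable:
    """Gene roles (oncogene vs tumor suppressor) plus the hotspot
    allow-list of activating mutations per oncogene. The special hotspot
    entry 'any' marks every variant of the gene as qualifying (used for
    tumor suppressors where any deleterious variant counts)."""

    roles: dict[str, str]
    hotspots: dict[str, set[str] | str]  # gene -> {'chrom:pos:ref:alt', ...} or 'any'

    def covers(self, genes: set[str]) -> None:
        missing = sorted(g for g in genes if g not in self.roles)
        if missing:
            raise MetaconcordError(f"genes missing from role table: {missing}")

    def is_activating(self, key: VariantKey) -> bool:
        spots = self.hotspots.get(key.gene)
        if spots is None:
            return False
        if spots == "any":
            return True
        return f"{key.chrom}:{key.pos}:{key.ref}:{key.alt}" in spots

    def is_deleterious(self, key: VariantKey) -> bool:
        # without computational effect prediction, any listed variant of a
        # tumor suppressor counts as deleterious when its allow-list is 'any'
        return self.roles.get(key.gene) == "tsg" and self.is_activating(key)


def load_role_table(path) -> RoleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    roles, hotspots = {}, {}
    for r in df.itertuples(index=False):
        if r.role not in ("oncogene", "tsg"):
            raise ValidationError(f"gene {r.gene}: unknown role {r.role!r}")
        roles[r.gene] = r.role
        if r.hotspots == "any":
            hotspots[r.gene] = "any"
        elif r.hotspots:
            hotspots[r.gene] = set(r.hotspots.split(","))
    return RoleTable(roles=roles, hotspots=hotspots)


def packaged_role_table() -> RoleTable:
    ref = importlib.resources.files("metaconcord.data") / "role_table.tsv"
    return load_role_table(ref)


# ---------------------------------------------------------------------------
# profiles and selection


@dataclass
class MolecularProfile:
    sample_id: str
    amplified_genes: set[str] = field(default_factory=set)
    activating_mutations: set[tuple[str, VariantKey]] = field(default_factory=set)
    biallelic_inactivated_genes: set[str] = field(default_factory=set)


@dataclass
class TherapyDecision:
    patient_id: str
    role: str  # primary | metastasis
    drugs: set[str] = field(default_factory=set)


def build_profile(
    sample_id: str,
    cna_calls: list[CnaCall],
    variants: pd.DataFrame,
    role_table: RoleTable,
    gene_regions: dict[str, GeneRegion],
    rulebook: Rulebook | None = None,
) -> MolecularProfile:
    """Assemble a molecular profile from CNA calls and filtered variants.

    Amplified genes come from gene-level amplification status; activating
    mutations from the hotspot allow-list of oncogenes; biallelic
    inactivation of a tumor suppressor requires a deleterious variant plus
    loss/deletion of the locus, or a homozygous deletion alone.
    """
    if rulebook is not None:
        role_table.covers(rulebook.trigger_genes)
    profile = MolecularProfile(sample_id=sample_id)
    call_chroms = {c.segment.chrom for c in cna_calls}
    for gene, region in gene_regions.items():
        if gene not in role_table.roles:
            raise MetaconcordError(f"gene missing from role table: {gene}")
        if region.chrom not in call_chroms:
            continue
        if gene_amplification_status(cna_calls, region) == "amplified":
            profile.amplified_genes.add(gene)
    # per-gene locus loss for biallelic logic
    lost_genes, deleted_genes = set(), set()
    for gene, region in gene_regions.items():
        for c in cna_calls:
            if c.segment.chrom != region.chrom:
                continue
            if c.segment.start_pos <= region.end and c.segment.end_pos >= region.start:
                if c.state == "deletion":
                    deleted_genes.add(gene)
                if c.state in ("loss", "deletion"):
                    lost_genes.add(gene)
    deleterious_by_gene: set[str] = set()
    for r in variants.itertuples(index=False):
        key = VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)
        role = role_table.roles.get(key.gene)
        if role == "oncogene" and role_table.is_activating(key):
            profile.activating_mutations.add((key.gene, key))
        elif role == "tsg" and role_table.is_deleterious(key):
            deleterious_by_gene.add(key.gene)
    for gene, role in role_table.roles.items():
        if role != "tsg":
            continue
        if gene in deleted_genes or (gene in deleterious_by_gene and gene in lost_genes):
            profile.biallelic_inactivated_genes.add(gene)
    return profile


def _trigger_satisfied(trigger: Trigger, profile: MolecularProfile) -> bool:
    if trigger.alteration == "amplification":
        return trigger.gene in profile.amplified_genes
    if trigger.alteration == "activating_mutation":
        return any(g == trigger.gene for g, _ in profile.activating_mutations)
    return trigger.gene in profile.biallelic_inactivated_genes


def select_therapies(
    profile: MolecularProfile, rulebook: Rulebook, patient_id: str = "", role: str = ""
) -> TherapyDecision:
    """A drug is selected iff any of its triggers is satisfied; the
    selection is a deterministic function of profile and rulebook."""
    drugs = {
        d.name
        for d in rulebook.drugs
        if any(_trigger_satisfied(t, profile) for t in d.triggers)
    }
    return TherapyDecision(patient_id=patient_id, role=role, drugs=drugs)


def therapy_concordance(
    decisions: list[TherapyDecision],
    pairs: list[SamplePair],
    rulebook: Rulebook,
) -> tuple[pd.DataFrame, float, dict[str, float]]:
    """Per-patient agreement of primary- vs metastasis-derived drug sets.

    A patient is concordant iff the two sets are identical; the candidate
    fraction per role is the share of patients with a non-empty set.
    """
    by_key: dict[tuple[str, str], TherapyDecision] = {}
    for d in decisions:
        if not d.drugs <= rulebook.panel:
            raise ValidationError(
                f"decision for {d.patient_id}/{d.role} selects drugs outside the panel"
            )
        by_key[(d.patient_id, d.role)] = d
    rows = []
    for p in pairs:
        for role in ("primary", "metastasis"):
            if (p.patient_id, role) not in by_key:
                raise MetaconcordError(
                    f"patient {p.patient_id}: missing {role} therapy decision"
                )
        dp = by_key[(p.patient_id, "primary")]
        dm = by_key[(p.patient_id, "metastasis")]
        rows.append(
            {
                "patient_id": p.patient_id,
                "primary_drugs": ",".join(sorted(dp.drugs)),
                "metastasis_drugs": ",".join(sorted(dm.drugs)),
                "concordant": dp.drugs == dm.drugs,
            }
        )
    table = pd.DataFrame(rows)
    rate = float(table["concordant"].mean()) if len(table) else float("nan")
    fractions = {
        "primary": float(
            sum(1 for p in pairs if by_key[(p.patient_id, "primary")].drugs)
        )
        / max(len(pairs), 1),
        "metastasis": float(
            sum(1 for p in pairs if by_key[(p.patient_id, "metastasis")].drugs)
        )
        / max(len(pairs), 1),
    }
    return table, rate, fractions
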