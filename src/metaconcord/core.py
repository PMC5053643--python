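"""Core containers shared across the pipeline.

The analysis operates on four kinds of objects: probe-level copy-number
profiles (one log2-ratio value per array probe), per-sample somatic variant
tables, the pair manifest linking each patient's primary tumor to its
metastasis, and the clinical table. Variant tables are plain pandas
DataFrames with a fixed column dialect (``VARIANT_COLUMNS``); profiles keep
their probes sorted by (chromosome, position) and never contain sex
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple

import numpy as np
import pandas as pd

#: Column dialect of a variant table (flat TSV / in-memory DataFrame).
VARIANT_COLUMNS = ["gene", "chrom", "pos", "ref", "alt", "vaf", "depth", "kind"]

#: Chromosomes excluded from all copy-number analysis.
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


class MetaconcordError(Exception):
    """Base error for this package."""


class ConfigurationError(MetaconcordError):
    """An invalid configuration value, naming the offending field."""


class ValidationError(MetaconcordError):
    """Malformed input data."""


class VariantKey(NamedTuple):
    """Identity of a mutation: equality of this key defines the *same*
    variant across samples (genomic key, not protein annotation)."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # used in reports and newick-safe labels
        return f"{self.gene}:{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def variant_keys(table: pd.DataFrame) -> list[VariantKey]:
    """Extract the VariantKey of every row of a variant table."""
    return [
        VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt)
        for r in table.itertuples(index=False)
    ]


@dataclass
class ProbeProfile:
    """Ordered probe-level log2-ratio profile for one sample.

    ``probes`` has columns chrom, pos (1-based), probe_id, log2ratio and is
    sorted by (chrom, pos); positions are strictly increasing within a
    chromosome and sex chromosomes are rejected.
    """

    sample_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "probe_id", "log2ratio"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValidationError(f"probe table missing columns: {sorted(missing)}")
        bad = set(self.probes["chrom"].unique()) & SEX_CHROMOSOMES
        if bad:
            raise ValidationError(
                f"sample {self.sample_id}: sex-chromosome probes not allowed: {sorted(bad)}"
            )
        self.probes = self.probes.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        for chrom, sub in self.probes.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"sample {self.sample_id}: positions not strictly increasing on {chrom}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.probes.loc[self.probes["chrom"] == chrom, "log2ratio"].to_numpy()

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.probes.loc[self.probes["chrom"] == chrom, "pos"].to_numpy()


@dataclass
class SamplePair:
    """Primary/metastasis sample handles for one patient."""

    patient_id: str
    primary_sample: str
    metastasis_sample: str


@dataclass
class Cohort:
    """A paired cohort: manifest plus per-sample profiles and variant tables.

    ``truth`` (simulated cohorts only) maps patient id to the generator's
    event record; real cohorts carry ``truth=None``.
    """

    pairs: list[SamplePair]
    profiles: dict[str, ProbeProfile] = field(default_factory=dict)
    variants: dict[str, pd.DataFrame] = field(default_factory=dict)
    clinical: pd.DataFrame | None = None
    truth: dict | None = None
    genome: list[tuple[str, int, int]] | None = None  # (chrom, length, probe_count)

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for p in self.pairs:
            out.extend([p.primary_sample, p.metastasis_sample])
        return out

    def pair_for(self, patient_id: str) -> SamplePair:
        for p in self.pairs:
            if p.patient_id == patient_id:
                return p
        raise KeyError(f"no pair for patient {patient_id!r}")


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Integer percent with round-half-up (374/499 -> 75, 338/460 -> 73)."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
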