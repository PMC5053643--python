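"""Paired primary/metastasis cohort simulator with known clonal structure.

The generator emulates the branched-evolution picture of metastatic spread:
each patient's pair of samples shares a *truncal* set of alterations
(acquired before the metastatic lineage diverged) and carries *private*
alterations on each branch. Every downstream statistic in the pipeline can
therefore be checked against ground truth.

Generative model, per pair
--------------------------
* Distinct mutation events are drawn as three independent Poisson counts:
  truncal (rate ``trunk_mut_rate``), primary-private and metastasis-private
  (rates ``private_mut_rate_*``). When ``trunk_mut_rate`` is left ``None``
  it is derived from ``trunk_share_prob`` *q* as ``q/(1-q) * (rate_p +
  rate_m)``, which makes *q* exactly the probability that a distinct
  alteration is truncal; the expected occurrence-level concordance rate is
  then the closed form ``2q/(1+q)`` (a truncal event contributes two shared
  occurrences, a private event one unshared occurrence).
* Each mutation is a known driver (a key drawn from the recurrent-variant
  catalog, probability ``driver_event_prob``) or a random passenger key;
  truncal events are fully clonal, private events draw a clonal fraction
  from ``PRIVATE_CLONAL_FRACTION_RANGE`` so private variants sit at
  systematically lower allele fractions.
* Copy-number events are drawn the same way (truncal vs private) at a rate
  giving ``cna_event_rate`` expected events per sample; amplitudes come
  from the four configured log2 means.
* A sample's probe value is ``log2((1-c) + c * 2**a) + N(0, noise_sd)``
  where *a* is the summed amplitude of overlapping events scaled by their
  clonal fraction and *c* the sample's cellularity (linear mixture of tumor
  and normal DNA, the physics of a bulk log-ratio measurement).
* A variant's read depth is Poisson(``mean_depth``); the alternate count is
  Binomial(depth, clonal_fraction * cellularity / 2), the heterozygous
  expectation; calls with zero alternate reads are not emitted (undetected).

Random streams are split per (seed, pair, role) with ``SeedSequence`` so
adding a pair never perturbs earlier pairs' data, and identical config plus
seed gives byte-identical output files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core import (
    Cohort,
    ConfigurationError,
    ProbeProfile,
    SamplePair,
    VariantKey,
    VARIANT_COLUMNS,
)
from . import io as mio

__all__ = [
    "SimulationConfig",
    "ClonalEvent",
    "DEFAULT_GENOME",
    "default_driver_catalog",
    "simulate_cohort",
    "simulate_cna_profile",
    "simulate_variant_calls",
    "write_cohort",
    "expected_concordance",
    "truth_occurrence_counts",
]

#: Toy genome: 4 autosomes x 500 evenly spaced probes. The real array design
#: (~161k probes) is configuration, not code.
DEFAULT_GENOME: list[tuple[str, int, int]] = [
    ("chr1", 100_000_000, 500),
    ("chr2", 100_000_000, 500),
    ("chr3", 100_000_000, 500),
    ("chr4", 100_000_000, 500),
]

#: Private (branch) events are allowed to be subclonal.
PRIVATE_CLONAL_FRACTION_RANGE = (0.3, 1.0)

#: Mix of copy-number event kinds (gain, loss, amplification, deletion).
CNA_KIND_PROBS = {"gain": 0.35, "loss": 0.35, "amp": 0.15, "del": 0.15}

#: Copy-number event length in probes, drawn uniformly from this range.
CNA_LENGTH_PROBES = (20, 100)

_BASES = np.array(list("ACGT"))


def default_driver_catalog() -> list[tuple[VariantKey, float]]:
    """The packaged catalog of recurrent driver variants with sampling
    weights (weights follow the observed occurrence totals)."""
    ref = importlib.resources.files("metaconcord.data") / "driver_catalog.tsv"
    df = pd.read_csv(ref, sep="\t")
    return [
        (VariantKey(r.gene, r.chrom, int(r.pos), r.ref, r.alt), float(r.weight))
        for r in df.itertuples(index=False)
    ]


@dataclass
class ClonalEvent:
    """One alteration in a pair's truth set.

    ``compartment`` is trunk (both members), primary_private or
    metastasis_private. Mutations carry a VariantKey; copy-number events an
    interval plus log2 amplitude.
    """

    kind: str  # snv | indel | cna
    compartment: str  # trunk | primary_private | metastasis_private
    clonal_fraction: float
    key: VariantKey | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    amplitude: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.key is not None:
            d["key"] = list(self.key)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClonalEvent":
        d = dict(d)
        if d.get("key") is not None:
            d["key"] = VariantKey(*d["key"])
        return cls(**d)


@dataclass
class SimulationConfig:
    """Study conditions for the paired-cohort generator.

    Defaults emulate the profiled cohort: 23 pairs, ~300x depth, purity at
    least 50%, and event rates giving ~22 variant occurrences per pair with
    an expected occurrence-level concordance of 75% (``trunk_share_prob``
    0.6 => 2q/(1+q) = 0.75).
    """

    n_pairs: int = 23
    genome: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_GENOME)
    )
    trunk_share_prob: float = 0.6
    private_mut_rate_primary: float = 2.7
    private_mut_rate_metastasis: float = 2.7
    trunk_mut_rate: float | None = None  # derived from trunk_share_prob if None
    cna_event_rate: float = 4.0
    amp_log2_mean: float = 1.5
    gain_log2_mean: float = 0.7
    loss_log2_mean: float = -0.7
    del_log2_mean: float = -1.5
    probe_noise_sd: float = 0.15
    mean_depth: float = 300.0
    cellularity_range: tuple[float, float] = (0.5, 1.0)
    driver_catalog: list[tuple[VariantKey, float]] = field(
        default_factory=default_driver_catalog
    )
    driver_event_prob: float = 0.08
    indel_fraction: float = 0.17
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("trunk_share_prob", "driver_event_prob", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "private_mut_rate_primary",
            "private_mut_rate_metastasis",
            "cna_event_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_pairs < 0:
            raise ConfigurationError("n_pairs must be >= 0")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        lo, hi = self.cellularity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError(
                f"cellularity_range must satisfy 0 < lo <= hi <= 1, got {self.cellularity_range}"
            )
        for chrom, length, n in self.genome:
            if n < 5:
                raise ConfigurationError(
                    f"genome: probe_count must be >= 5 per chromosome, got {n} on {chrom}"
                )
            if length <= 0:
                raise ConfigurationError(f"genome: length must be > 0 on {chrom}")
        if self.trunk_mut_rate is None and self.trunk_share_prob >= 1.0:
            private = self.private_mut_rate_primary + self.private_mut_rate_metastasis
            if private > 0:
                raise ConfigurationError(
                    "trunk_share_prob=1 with positive private rates is inconsistent"
                )
            raise ConfigurationError(
                "trunk_mut_rate must be given explicitly when trunk_share_prob=1"
            )
        if self.trunk_mut_rate is not None and self.trunk_mut_rate < 0:
            raise ConfigurationError("trunk_mut_rate must be >= 0")

    @property
    def effective_trunk_rate(self) -> float:
        if self.trunk_mut_rate is not None:
            return self.trunk_mut_rate
        q = self.trunk_share_prob
        return q / (1.0 - q) * (
            self.private_mut_rate_primary + self.private_mut_rate_metastasis
        )


def expected_concordance(config: SimulationConfig) -> float:
    """Closed-form expected occurrence-level concordance 2t/(2t+p)."""
    t = config.effective_trunk_rate
    p = config.private_mut_rate_primary + config.private_mut_rate_metastasis
    if t == 0 and p == 0:
        return float("nan")
    return 2 * t / (2 * t + p)


def concordance_stderr(config: SimulationConfig, n_seeds: int = 1) -> float:
    """Delta-method standard error of the realized concordance estimator
    2T/(2T+P) with T, P independent Poisson over ``n_seeds`` cohorts."""
    t = config.effective_trunk_rate * config.n_pairs * n_seeds
    p = (
        config.private_mut_rate_primary + config.private_mut_rate_metastasis
    ) * config.n_pairs * n_seeds
    denom = (2 * t + p) ** 4
    return float(np.sqrt(4 * t * p * (t + p) / denom))


# ---------------------------------------------------------------------------
# event generation


def _random_passenger_key(rng: np.random.Generator, genome, indel: bool) -> VariantKey:
    chrom, length, _ = genome[rng.integers(len(genome))]
    pos = int(rng.integers(1, length + 1))
    i = rng.integers(4)
    j = (i + 1 + rng.integers(3)) % 4
    ref, alt = _BASES[i], _BASES[j]
    if indel:
        ins = rng.integers(2) == 0
        extra = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        if ins:
            ref, alt = ref, ref + extra
        else:
            ref, alt = ref + extra, ref
    gene = f"G{chrom[3:]}P{pos // 1_000_000:03d}"
    return VariantKey(gene, chrom, pos, str(ref), str(alt))


def _draw_mutation(
    rng: np.random.Generator, config: SimulationConfig, compartment: str, used: set
) -> ClonalEvent:
    indel = rng.random() < config.indel_fraction
    for _ in range(100):
        if config.driver_catalog and rng.random() < config.driver_event_prob:
            keys, weights = zip(*config.driver_catalog)
            w = np.asarray(weights, dtype=float)
            key = keys[rng.choice(len(keys), p=w / w.sum())]
            kind = "snv" if len(key.ref) == len(key.alt) == 1 else "indel"
        else:
            key = _random_passenger_key(rng, config.genome, indel)
            kind = "indel" if indel else "snv"
        if key not in used:
            break
    used.add(key)
    if compartment == "trunk":
        cf = 1.0
    else:
        lo, hi = PRIVATE_CLONAL_FRACTION_RANGE
        cf = float(rng.uniform(lo, hi))
    return ClonalEvent(kind=kind, compartment=compartment, clonal_fraction=cf, key=key)


def _draw_cna(
    rng: np.random.Generator, config: SimulationConfig, compartment: str
) -> ClonalEvent:
    chrom, length, n_probes = config.genome[rng.integers(len(config.genome))]
    kinds = list(CNA_KIND_PROBS)
    kind = kinds[rng.choice(len(kinds), p=list(CNA_KIND_PROBS.values()))]
    amplitude = {
        "amp": config.amp_log2_mean,
        "gain": config.gain_log2_mean,
        "loss": config.loss_log2_mean,
        "del": config.del_log2_mean,
    }[kind]
    spacing = length / n_probes
    n_span = int(rng.integers(CNA_LENGTH_PROBES[0], CNA_LENGTH_PROBES[1] + 1))
    span = int(n_span * spacing)
    start = int(rng.integers(1, max(2, length - span)))
    cf = 1.0
    if compartment != "trunk":
        lo, hi = PRIVATE_CLONAL_FRACTION_RANGE
        cf = float(rng.uniform(lo, hi))
    return ClonalEvent(
        kind="cna",
        compartment=compartment,
        clonal_fraction=cf,
        chrom=chrom,
        start=start,
        end=min(start + span, length),
        amplitude=amplitude,
    )


def generate_pair_events(
    config: SimulationConfig, pair_index: int
) -> list[ClonalEvent]:
    """Draw one pair's truth set (mutations and copy-number events)."""
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, pair_index, 2))
    )
    events: list[ClonalEvent] = []
    used: set = set()
    n_trunk = rng.poisson(config.effective_trunk_rate)
    n_p = rng.poisson(config.private_mut_rate_primary)
    n_m = rng.poisson(config.private_mut_rate_metastasis)
    for _ in range(n_trunk):
        events.append(_draw_mutation(rng, config, "trunk", used))
    for _ in range(n_p):
        events.append(_draw_mutation(rng, config, "primary_private", used))
    for _ in range(n_m):
        events.append(_draw_mutation(rng, config, "metastasis_private", used))
    # CNA events: per-pair rate chosen so each sample sees cna_event_rate
    # expected events: per-sample = N*(1+q)/2 for pair total N
    q = config.trunk_share_prob
    n_cna = rng.poisson(2 * config.cna_event_rate / (1 + q)) if config.cna_event_rate else 0
    for _ in range(n_cna):
        comp = (
            "trunk"
            if rng.random() < q
            else ("primary_private" if rng.random() < 0.5 else "metastasis_private")
        )
        events.append(_draw_cna(rng, config, comp))
    return events


# ---------------------------------------------------------------------------
# realization of one sample


def simulate_cna_profile(
    events: list[ClonalEvent],
    genome: list[tuple[str, int, int]],
    probe_noise_sd: float,
    cellularity: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> ProbeProfile:
    """Render copy-number events into a probe-level log2-ratio profile.

    Observed probe value = log2((1-c) + c * 2**a) + N(0, sd), with *a* the
    sum over overlapping events of amplitude * clonal_fraction and *c* the
    cellularity (linear tumor/normal mixture).
    """
    frames = []
    for chrom, length, n_probes in genome:
        pos = np.linspace(1, length, n_probes).astype(int)
        pos = np.unique(pos)  # keep strictly increasing
        a = np.zeros(len(pos))
        for ev in events:
            if ev.kind != "cna" or ev.chrom != chrom:
                continue
            if ev.start < 1 or ev.end > length:
                raise ConfigurationError(
                    f"cna event interval {ev.start}-{ev.end} outside {chrom} (length {length})"
                )
            mask = (pos >= ev.start) & (pos <= ev.end)
            a[mask] += ev.amplitude * ev.clonal_fraction
        signal = np.log2((1 - cellularity) + cellularity * np.exp2(a))
        noise = rng.normal(0.0, probe_noise_sd, size=len(pos)) if probe_noise_sd else 0.0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "probe_id": [f"{chrom}_p{i:05d}" for i in range(len(pos))],
                    "log2ratio": signal + noise,
                }
            )
        )
    return ProbeProfile(sample_id=sample_id, probes=pd.concat(frames, ignore_index=True))


def simulate_variant_calls(
    events: list[ClonalEvent],
    mean_depth: float,
    cellularity: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Render mutation events into an observed variant table.

    Expected VAF of a heterozygous event is clonal_fraction * cellularity /
    2; depth ~ Poisson(mean_depth), alternate count ~ Binomial(depth, VAF).
    Events with zero alternate reads are not emitted.
    """
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be > 0")
    rows = []
    for ev in events:
        if ev.kind == "cna":
            continue
        depth = int(rng.poisson(mean_depth))
        if depth == 0:
            continue
        evaf = ev.clonal_fraction * cellularity / 2.0
        alt = int(rng.binomial(depth, evaf))
        if alt == 0:
            continue
        k = ev.key
        rows.append(
            {
                "gene": k.gene,
                "chrom": k.chrom,
                "pos": k.pos,
                "ref": k.ref,
                "alt": k.alt,
                "vaf": alt / depth,
                "depth": depth,
                "kind": ev.kind,
            }
        )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return df.sort_values(["chrom", "pos", "ref", "alt"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# whole cohort


def _events_for_role(events: list[ClonalEvent], role: str) -> list[ClonalEvent]:
    private = f"{role}_private"
    return [e for e in events if e.compartment in ("trunk", private)]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full paired cohort with truth sets and a clinical stub."""
    config.validate()
    pairs, profiles, variants = [], {}, {}
    truth: dict = {"config_seed": config.seed, "patients": {}}
    clinical_rows = []
    for i in range(config.n_pairs):
        pid = f"P{i + 1:02d}"
        prim, met = f"{pid}-T", f"{pid}-M"
        pairs.append(SamplePair(pid, prim, met))
        events = generate_pair_events(config, i)
        truth["patients"][pid] = {
            "events": [e.to_dict() for e in events],
            "cellularity": {},
        }
        for role, sid, stream in (("primary", prim, 0), ("metastasis", met, 1)):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, i, stream)))
            lo, hi = config.cellularity_range
            cellularity = float(rng.uniform(lo, hi))
            truth["patients"][pid]["cellularity"][role] = cellularity
            role_events = _events_for_role(events, role)
            profiles[sid] = simulate_cna_profile(
                role_events,
                config.genome,
                config.probe_noise_sd,
                cellularity,
                rng,
                sample_id=sid,
            )
            variants[sid] = simulate_variant_calls(
                role_events, config.mean_depth, cellularity, rng, sample_id=sid
            )
        rng_c = np.random.default_rng(np.random.SeedSequence((config.seed, i, 3)))
        clinical_rows.append(
            {
                "patient_id": pid,
                "age_at_diagnosis": int(rng_c.integers(33, 73)),
                "pathological_type": "Ductal",
                "grade": int(rng_c.integers(1, 4)),
                "er_status": "positive" if rng_c.random() < 0.68 else "negative",
                "erbb2_status": "positive" if rng_c.random() < 0.33 else "negative",
                "prior_systemic_therapy": "chemoT",
                "metastatic_site": "Liver",
                "delay_months": int(rng_c.integers(0, 150)),
                "relapse_number": int(rng_c.integers(1, 7)),
            }
        )
    clinical = pd.DataFrame(
        clinical_rows,
        columns=[
            "patient_id",
            "age_at_diagnosis",
            "pathological_type",
            "grade",
            "er_status",
            "erbb2_status",
            "prior_systemic_therapy",
            "metastatic_site",
            "delay_months",
            "relapse_number",
        ],
    )
    return Cohort(
        pairs=pairs,
        profiles=profiles,
        variants=variants,
        clinical=clinical,
        truth=truth,
        genome=list(config.genome),
    )


def truth_occurrence_counts(truth: dict) -> dict[str, int]:
    """Compartment accounting over a cohort's truth sets (mutations only):
    trunk events contribute two occurrences, private events one."""
    n_trunk = n_private = 0
    for rec in truth["patients"].values():
        for d in rec["events"]:
            if d["kind"] == "cna":
                continue
            if d["compartment"] == "trunk":
                n_trunk += 1
            else:
                n_private += 1
    return {
        "trunk_events": n_trunk,
        "private_events": n_private,
        "total_occurrences": 2 * n_trunk + n_private,
    }


def write_cohort(cohort: Cohort, directory) -> dict[str, list[str]]:
    """Write the cohort bundle (probe TSVs, VCFs + TSVs, manifest, truth
    JSON, clinical CSV); see :mod:`metaconcord.io` for the round-trip
    guarantee."""
    return mio.write_cohort_files(cohort, directory)
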