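"""Readers and writers for the pipeline's on-disk formats.

Formats: probe-level log2-ratio TSV (chrom, pos, probe_id, log2ratio),
somatic variant tables as VCF 4.2 (via pysam) or an equivalent flat TSV
dialect, pair-manifest CSV, clinical CSV, truth JSON, SEG export of
segments and BED export of called regions.

Round-trip guarantee: cohorts written with :func:`write_cohort_files` and
read back with :func:`read_cohort_files` are value-identical. For VCF the
variant allele fraction is carried as the exact ratio of the AO (alternate
observation count) and DP format fields, so no float precision is lost.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import (
    Cohort,
    MetaconcordError,
    ProbeProfile,
    SamplePair,
    ValidationError,
    VARIANT_COLUMNS,
)

# ---------------------------------------------------------------------------
# probe profiles


def write_probe_tsv(profile: ProbeProfile, path: str | Path) -> None:
    profile.probes.to_csv(path, sep="\t", index=False)


def read_probe_tsv(path: str | Path, sample_id: str) -> ProbeProfile:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
    return ProbeProfile(sample_id=sample_id, probes=df)


# ---------------------------------------------------------------------------
# variant tables: flat TSV dialect


def write_variant_tsv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(VARIANT_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValidationError(f"variant TSV {path}: missing columns {sorted(missing)}")
    if "kind" not in df.columns:
        df["kind"] = np.where(
            (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1), "snv", "indel"
        )
    return df


# ---------------------------------------------------------------------------
# variant tables: VCF 4.2


def _vcf_header(
    sample_id: str, genome: list[tuple[str, int, int]] | None
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if genome:
        for chrom, length, _ in genome:
            header.contigs.add(chrom, length=length)
    else:
        # contig lines are still required for valid records; use a generous
        # default length when the genome is not known
        header.contigs.add("chr1", length=2**29)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("KIND", 1, "String", "Variant kind (snv or indel)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AO", 1, "Integer", "Alternate observation count")
    header.add_sample(sample_id)
    return header


def write_variant_vcf(
    table: pd.DataFrame,
    path: str | Path,
    sample_id: str,
    genome: list[tuple[str, int, int]] | None = None,
) -> None:
    """Write one sample's variant table as an uncompressed VCF 4.2 file.

    The alternate-allele count AO is the integer nearest vaf*depth, so for
    tables whose vaf is an exact read ratio (all simulated cohorts) the VCF
    round-trips exactly.
    """
    if genome is None:
        chroms = list(dict.fromkeys(table["chrom"])) or ["chr1"]
        genome = [(c, 2**29, 0) for c in chroms]
    header = _vcf_header(sample_id, genome)
    known = {c for c, _, _ in genome}
    extra = set(table["chrom"]) - known
    if extra:
        raise ValidationError(f"chromosomes absent from genome: {sorted(extra)}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in table.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = vcf.new_record(
                contig=r.chrom, start=int(r.pos) - 1, alleles=(r.ref, r.alt)
            )
            rec.info["GENE"] = r.gene
            rec.info["KIND"] = r.kind
            rec.samples[sample_id]["DP"] = int(r.depth)
            rec.samples[sample_id]["AO"] = int(round(r.vaf * r.depth))
            vcf.write(rec)


def read_variant_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            depth = rec.samples[sample]["DP"]
            ao = rec.samples[sample]["AO"]
            rows.append(
                {
                    "gene": rec.info["GENE"],
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "vaf": ao / depth if depth else 0.0,
                    "depth": depth,
                    "kind": rec.info["KIND"],
                }
            )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# ---------------------------------------------------------------------------
# manifest / clinical / truth


def write_manifest_csv(pairs: list[SamplePair], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "primary_sample": p.primary_sample,
                "metastasis_sample": p.metastasis_sample,
            }
            for p in pairs
        ],
        columns=["patient_id", "primary_sample", "metastasis_sample"],
    ).to_csv(path, index=False)


def read_manifest_csv(path: str | Path) -> list[SamplePair]:
    df = pd.read_csv(path, dtype=str)
    return [
        SamplePair(r.patient_id, r.primary_sample, r.metastasis_sample)
        for r in df.itertuples(index=False)
    ]


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# cohort bundle


def write_cohort_files(cohort: Cohort, directory: str | Path) -> dict[str, list[str]]:
    """Write a full cohort bundle; returns the file map, relative to dir."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise MetaconcordError(f"cannot create output directory {directory}: {exc}")
    files: dict[str, list[str]] = {"probes": [], "vcf": [], "tsv": [], "other": []}
    write_manifest_csv(cohort.pairs, directory / "manifest.csv")
    files["other"].append("manifest.csv")
    if cohort.truth is not None:
        write_truth_json(cohort.truth, directory / "truth.json")
        files["other"].append("truth.json")
    if cohort.clinical is not None:
        cohort.clinical.to_csv(directory / "clinical.csv", index=False)
        files["other"].append("clinical.csv")
    if cohort.genome is not None:
        write_truth_json(
            {"genome": [list(g) for g in cohort.genome]}, directory / "genome.json"
        )
        files["other"].append("genome.json")
    for sid, profile in cohort.profiles.items():
        name = f"{sid}.probes.tsv"
        write_probe_tsv(profile, directory / name)
        files["probes"].append(name)
    for sid, table in cohort.variants.items():
        vname, tname = f"{sid}.vcf", f"{sid}.variants.tsv"
        write_variant_vcf(table, directory / vname, sid, genome=cohort.genome)
        write_variant_tsv(table, directory / tname)
        files["vcf"].append(vname)
        files["tsv"].append(tname)
    return files


def read_cohort_files(directory: str | Path, variant_format: str = "vcf") -> Cohort:
    directory = Path(directory)
    pairs = read_manifest_csv(directory / "manifest.csv")
    truth = None
    if (directory / "truth.json").exists():
        truth = read_truth_json(directory / "truth.json")
    clinical = None
    if (directory / "clinical.csv").exists():
        clinical = pd.read_csv(directory / "clinical.csv")
    genome = None
    if (directory / "genome.json").exists():
        genome = [tuple(g) for g in read_truth_json(directory / "genome.json")["genome"]]
    profiles, variants = {}, {}
    sample_ids = []
    for p in pairs:
        sample_ids.extend([p.primary_sample, p.metastasis_sample])
    for sid in sample_ids:
        ppath = directory / f"{sid}.probes.tsv"
        if ppath.exists():
            profiles[sid] = read_probe_tsv(ppath, sid)
        if variant_format == "vcf" and (directory / f"{sid}.vcf").exists():
            variants[sid] = read_variant_vcf(directory / f"{sid}.vcf")
        elif (directory / f"{sid}.variants.tsv").exists():
            variants[sid] = read_variant_tsv(directory / f"{sid}.variants.tsv")
    return Cohort(
        pairs=pairs,
        profiles=profiles,
        variants=variants,
        clinical=clinical,
        truth=truth,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# SEG / BED export


def write_seg(segments_by_sample: dict[str, list], path: str | Path) -> None:
    """SEG-format export: sample, chrom, start, end, n_probes, mean_log2."""
    rows = []
    for sid, segs in segments_by_sample.items():
        for s in segs:
            rows.append(
                {
                    "sample": sid,
                    "chrom": s.chrom,
                    "start": s.start_pos,
                    "end": s.end_pos,
                    "n_probes": s.n_probes,
                    "mean_log2": s.mean_log2,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(regions: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """BED export; internal 1-based inclusive coordinates become 0-based
    half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in regions:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
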