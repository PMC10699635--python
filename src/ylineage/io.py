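"""File readers/writers: STR/SNP tables, VCF, BED, catalogs, rate configs.

All tabular outputs are TSV with '#'-prefixed provenance comments (tool
version, seed, parameters); every writer's output is readable by its
paired reader.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
import pysam
import yaml
from intervaltree import IntervalTree

from . import __version__
from .dating import RateConfig
from .discovery import VariantRecord
from .genotypes import SNPGenotypeTable, VALID_STATES
from .profiles import DEFAULT_EXCLUDED_LOCI, STRProfile, YFILER_LOCI


class ParseError(ValueError):
    pass


def provenance_lines(stage: str, seed=None, **params) -> list[str]:
    items = {"tool": f"ylineage {__version__}", "stage": stage}
    if seed is not None:
        items["seed"] = seed
    items.update(params)
    payload = ", ".join(f"{k}={v}" for k, v in items.items())
    return [f"# {payload}"]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".bed", ".txt")) else ","


def read_str_table(path) -> list[STRProfile]:
    """Read an STR profile table (CSV/TSV: sample_id[,population,group],loci...).

    Repeat counts must parse as integers; DYS385a/b load but stay excluded
    from downstream arithmetic. Locus columns outside the 17-locus panel
    are accepted with a warning.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    meta = [c for c in ("sample_id", "population", "group") if c in df.columns]
    loci = [c for c in df.columns if c not in meta]
    if not loci:
        raise ParseError(f"{path}: no locus columns found")
    unknown = [l for l in loci if l not in YFILER_LOCI]
    if unknown:
        warnings.warn(f"{path}: columns outside the 17-locus panel: {unknown}", stacklevel=2)
    profiles = []
    for i, row in df.iterrows():
        alleles = {}
        for l in loci:
            raw = row[l]
            try:
                value = int(raw)
                if value != float(raw):
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {i + 1}, column {l!r}: non-integer repeat {raw!r}"
                ) from None
            alleles[l] = value
        profiles.append(
            STRProfile(
                sample_id=str(row["sample_id"]),
                alleles=alleles,
                population=str(row.get("population", "pop1")),
                group=str(row.get("group", "group1")),
            )
        )
    return profiles


def write_str_table(profiles: Sequence[STRProfile], path, seed=None, **params) -> None:
    loci = list(profiles[0].alleles)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for line in provenance_lines("str_table", seed=seed, **params):
            fh.write(line + "\n")
        fh.write(sep.join(["sample_id", "population", "group", *loci]) + "\n")
        for p in profiles:
            row = [p.sample_id, p.population, p.group] + [str(p.alleles[l]) for l in loci]
            fh.write(sep.join(row) + "\n")


def read_snp_table(path) -> SNPGenotypeTable:
    """Read a wide SNP state table (states A/D/.), labels optional."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    populations = df.pop("population") if "population" in df.columns else None
    groups = df.pop("group") if "group" in df.columns else None
    bad = set(df.values.ravel()) - VALID_STATES
    if bad:
        raise ParseError(f"{path}: invalid SNP states {sorted(bad)}")
    return SNPGenotypeTable(df, populations=populations, groups=groups)


def write_snp_table(table: SNPGenotypeTable, path, seed=None, **params) -> None:
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for line in provenance_lines("snp_table", seed=seed, **params):
            fh.write(line + "\n")
        cols = ["sample_id"]
        if table.populations is not None:
            cols.append("population")
        if table.groups is not None:
            cols.append("group")
        cols += table.markers
        fh.write(sep.join(cols) + "\n")
        for s in table.samples:
            row = [s]
            if table.populations is not None:
                row.append(str(table.populations[s]))
            if table.groups is not None:
                row.append(str(table.groups[s]))
            row += [table.state(s, m) for m in table.markers]
            fh.write(sep.join(row) + "\n")


def read_vcf_variants(path) -> list[VariantRecord]:
    """Read variant records (one per ALT allele) from a VCF 4.x file."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt))
    return out


def write_vcf_variants(
    variants: Sequence[VariantRecord], path, contig_length: int = 59_373_566
) -> None:
    """Write a site-only VCF 4.2 for a variant list."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom, length=contig_length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            vcf.write(rec)


def read_bed_mask(path) -> dict[str, IntervalTree]:
    """Read a BED repeat mask (0-based half-open) into interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def write_bed_mask(mask: Mapping[str, Iterable], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask):
            intervals = mask[chrom]
            tuples = (
                sorted((iv.begin, iv.end) for iv in intervals)
                if isinstance(intervals, IntervalTree)
                else sorted(tuple(iv) for iv in intervals)
            )
            for start, end in tuples:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_known_catalog(path) -> set[tuple[str, int]]:
    """Known-variant positions from a 2-column TSV (chrom, pos) or a VCF."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return {(v.chrom, v.pos) for v in read_vcf_variants(path)}
    catalog = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos = line.split("\t")[:2]
            catalog.add((chrom, int(pos)))
    return catalog


def write_known_catalog(catalog: Iterable[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in sorted(catalog):
            fh.write(f"{chrom}\t{pos}\n")


def read_rates(path) -> list[RateConfig]:
    """Rate calibrations from YAML: a list of {name, mu_per_locus_per_gen, ...}."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    rates = []
    for rec in payload["rates"] if isinstance(payload, dict) else payload:
        rates.append(
            RateConfig(
                name=str(rec["name"]),
                mu_per_locus_per_gen=float(rec["mu_per_locus_per_gen"]),
                generation_years=float(rec.get("generation_years", 25.0)),
                n_loci=int(rec.get("n_loci", 15)),
            )
        )
    return rates


def write_tsv(df: pd.DataFrame, path, stage: str, seed=None, **params) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(stage, seed=seed, **params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(payload, path, stage: str, seed=None, **params) -> None:
    doc = {
        "provenance": {
            "tool": f"ylineage {__version__}",
            "stage": stage,
            "seed": seed,
            **params,
        },
        "data": payload,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
        fh.write("\n")
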