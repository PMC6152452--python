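"""Readers and writers for genotype tables and pop-gen exchange formats.

The native interchange format is a long CSV/TSV table with one row per
sample x replicate, two allele columns per locus and the usual metadata
columns; column names are remapped through :class:`TableSchema`.  Exports to
the Genepop 4 format and to the two-row-per-individual integer matrix used by
Bayesian clustering programs are provided for interoperability with the wider
tool ecosystem.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (
    Dataset,
    Locus,
    LocusGenotype,
    MultilocusGenotype,
    SampleRecord,
    Source,
)

PathLike = Union[str, Path]


class GenotypeTableError(ValueError):
    """Raised for structural problems in a genotype table."""


@dataclass
class TableSchema:
    """Column-name mapping for the long genotype table.

    Locus allele columns are ``f"{locus}{suffix}"`` for the two suffixes.
    ``missing`` lists sentinel values interpreted as a missing allele.
    """

    sample_id: str = "sample_id"
    replicate: str = "replicate"
    province: str = "province"
    source: str = "source"
    year: str = "year"
    lat: str = "lat"
    lon: str = "lon"
    sry: str = "sry"
    allele_suffixes: tuple[str, str] = ("_1", "_2")
    missing: tuple = (0, "0", "", "NA", "nan")


def _parse_allele(value, schema: TableSchema) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if value in schema.missing or str(value).strip() in map(str, schema.missing):
        return None
    try:
        return int(float(value))
    except (TypeError, ValueError):
        raise ValueError(f"non-integer allele {value!r}")


def _infer_repeat_unit(sizes: Sequence[int]) -> int:
    diffs = [b - a for a, b in zip(sorted(set(sizes)), sorted(set(sizes))[1:])]
    if not diffs:
        return 2
    return math.gcd(*diffs) or 2


def read_genotype_table(
    path: PathLike,
    schema: Optional[TableSchema] = None,
    loci: Optional[Sequence[Locus]] = None,
    sep: str = ",",
) -> Dataset:
    """Read a long genotype table into a :class:`Dataset`.

    Parameters
    ----------
    path
        Delimited text file, one row per sample x replicate.
    schema
        Column-name map; defaults to the native column names.
    loci
        Locus definitions.  If omitted, loci are inferred from the allele
        columns and each repeat unit is the gcd of observed allele spacings.

    Raises
    ------
    GenotypeTableError
        On duplicated sample x replicate rows, locus columns absent from the
        file, or (collected with line numbers) unparseable alleles.
    """
    schema = schema or TableSchema()
    df = pd.read_csv(path, sep=sep, dtype={schema.sample_id: str}, float_precision="round_trip")
    s1, s2 = schema.allele_suffixes

    if loci is None:
        names = [
            c[: -len(s1)]
            for c in df.columns
            if c.endswith(s1) and (c[: -len(s1)] + s2) in df.columns
        ]
        if not names:
            raise GenotypeTableError("no locus allele columns found")
        locus_defs: list[Locus] = []
        for name in names:
            observed = []
            for col in (name + s1, name + s2):
                for v in df[col]:
                    try:
                        a = _parse_allele(v, schema)
                    except ValueError:
                        continue
                    if a is not None:
                        observed.append(a)
            locus_defs.append(Locus(name, _infer_repeat_unit(observed)))
        loci = locus_defs
    else:
        for locus in loci:
            for col in (locus.name + s1, locus.name + s2):
                if col not in df.columns:
                    raise GenotypeTableError(f"unknown locus column {col!r}")

    key_cols = [schema.sample_id, schema.replicate]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        keys = df.loc[dup, key_cols].to_records(index=False).tolist()
        raise GenotypeTableError(f"duplicated sample x replicate rows: {keys}")

    locus_names = [l.name for l in loci]
    row_errors: list[str] = []
    samples: dict[str, SampleRecord] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        sid = str(row[schema.sample_id])
        calls: dict[str, LocusGenotype] = {}
        bad = False
        for name in locus_names:
            try:
                a = _parse_allele(row[name + s1], schema)
                b = _parse_allele(row[name + s2], schema)
            except ValueError as exc:
                row_errors.append(f"line {line_no}: locus {name}: {exc}")
                bad = True
                continue
            calls[name] = LocusGenotype(a, b)
        if bad:
            continue
        mlg = MultilocusGenotype.from_mapping(calls, locus_names)
        if sid not in samples:
            samples[sid] = SampleRecord(
                sample_id=sid,
                province=str(row[schema.province]),
                source=Source(str(row[schema.source])),
                year=int(row[schema.year]),
                lat=None if pd.isna(row.get(schema.lat)) else float(row[schema.lat]),
                lon=None if pd.isna(row.get(schema.lon)) else float(row[schema.lon]),
            )
        rec = samples[sid]
        rec.replicates.append(mlg)
        sry_val = row.get(schema.sry, False)
        rec.sry_positive.append(bool(sry_val) and str(sry_val).lower() not in ("0", "false", "nan"))

    if row_errors:
        raise GenotypeTableError("unparseable alleles:\n" + "\n".join(row_errors))
    return Dataset(samples=list(samples.values()), loci=list(loci))


def write_genotype_table(
    dataset: Dataset, path: PathLike, schema: Optional[TableSchema] = None, sep: str = ","
) -> None:
    """Write the long sample x replicate table (inverse of :func:`read_genotype_table`)."""
    schema = schema or TableSchema()
    s1, s2 = schema.allele_suffixes
    rows = []
    for rec in dataset.samples:
        for ridx, mlg in enumerate(rec.replicates):
            row = {
                schema.sample_id: rec.sample_id,
                schema.replicate: ridx + 1,
                schema.province: rec.province,
                schema.source: rec.source.value,
                schema.year: rec.year,
                schema.lat: None if rec.lat is None else float(rec.lat),
                schema.lon: None if rec.lon is None else float(rec.lon),
                schema.sry: int(rec.sry_positive[ridx]) if ridx < len(rec.sry_positive) else 0,
            }
            for name in dataset.locus_names:
                row[name + s1], row[name + s2] = _allele_cells(mlg[name])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _allele_cells(g: LocusGenotype) -> tuple:
    """CSV cells for one call; a provisional (single-allele) homozygote is
    written as its actual observation -- one allele and one blank -- so the
    low-confidence flag survives a round trip."""
    if g.is_missing:
        return "", ""
    if g.low_confidence and not g.is_heterozygote:
        return g.allele_a, ""
    return g.allele_a, g.allele_b


# ---------------------------------------------------------------------------
# Genepop 4 export
# ---------------------------------------------------------------------------

def genepop_code_maps(dataset: Dataset) -> dict[str, dict[int, int]]:
    """Per-locus map allele size -> sequential 3-digit code (sorted order)."""
    maps: dict[str, dict[int, int]] = {}
    for name in dataset.locus_names:
        sizes: set[int] = set()
        for rec in dataset.samples_with_consensus():
            g = rec.consensus[name]
            if not g.is_missing:
                sizes.update(g.alleles)
        if len(sizes) > 999:
            raise ValueError(f"locus {name}: >999 distinct alleles not representable")
        maps[name] = {size: i + 1 for i, size in enumerate(sorted(sizes))}
    return maps


def write_genepop(
    dataset: Dataset,
    path: PathLike,
    group_by: str = "province",
    title: str = "hairsnag export",
) -> None:
    """Write consensus genotypes as a Genepop 4 file, one ``Pop`` per group value."""
    samples = dataset.samples_with_consensus()
    if not samples:
        raise ValueError("no consensus genotypes to export")
    maps = genepop_code_maps(dataset)
    lines = [title]
    lines.extend(dataset.locus_names)
    groups: dict[str, list[SampleRecord]] = {}
    for rec in samples:
        groups.setdefault(str(getattr(rec, group_by)), []).append(rec)
    for value in sorted(groups):
        lines.append("Pop")
        for rec in groups[value]:
            fields = []
            for name in dataset.locus_names:
                g = rec.consensus[name]
                if g.is_missing:
                    fields.append("000000")
                else:
                    a, b = g.alleles
                    fields.append(f"{maps[name][a]:03d}{maps[name][b]:03d}")
            lines.append(f"{rec.sample_id} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Two-row integer matrix for Bayesian clustering programs
# ---------------------------------------------------------------------------

def write_cluster_input(
    items: Union[Dataset, Sequence[tuple[str, MultilocusGenotype]]],
    path: PathLike,
) -> None:
    """Write one pair of rows per individual; columns = id + loci; missing = -9.

    Accepts either a :class:`Dataset` (uses identified individuals if present,
    otherwise consensus samples) or explicit ``(label, genotype)`` pairs.
    """
    if isinstance(items, Dataset):
        if items.individuals:
            pairs = [(i.individual_id, i.consolidated_genotype) for i in items.individuals]
        else:
            pairs = [(s.sample_id, s.consensus) for s in items.samples_with_consensus()]
    else:
        pairs = list(items)
    if not pairs:
        raise ValueError("nothing to export")
    loci = list(pairs[0][1].loci)
    lines = []
    for label, mlg in pairs:
        for which in (0, 1):
            cells = [str(label)]
            for name in loci:
                g = mlg[name]
                cells.append("-9" if g.is_missing else str(g.alleles[which]))
            lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cluster_input(path: PathLike) -> list[tuple[str, MultilocusGenotype]]:
    """Parse the two-row matrix back into ``(label, genotype)`` pairs."""
    rows = [line.split("\t") for line in Path(path).read_text().splitlines() if line]
    if len(rows) % 2:
        raise ValueError("expected an even number of rows")
    n_loci = len(rows[0]) - 1
    loci = [f"L{i+1}" for i in range(n_loci)]
    out = []
    for r1, r2 in zip(rows[::2], rows[1::2]):
        if r1[0] != r2[0]:
            raise ValueError(f"row pair labels differ: {r1[0]} vs {r2[0]}")
        calls = {}
        for i, name in enumerate(loci):
            a, b = int(r1[i + 1]), int(r2[i + 1])
            calls[name] = LocusGenotype(None if a == -9 else a, None if b == -9 else b)
        out.append((r1[0], MultilocusGenotype(calls)))
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(dataset: Dataset) -> dict:
    """Report-only QC: replicate counts, allele-grid congruence, coordinate outliers.

    Returns a JSON-serializable dict; never mutates the dataset.
    """
    report: dict[str, list] = {
        "too_few_replicates": [],
        "off_grid_alleles": [],
        "coordinate_outliers": [],
    }
    for rec in dataset.samples:
        if not rec.is_tissue and len(rec.replicates) < 2:
            report["too_few_replicates"].append(rec.sample_id)

    for locus in dataset.loci:
        sizes: set[int] = set()
        for rec in dataset.samples:
            for mlg in rec.replicates:
                g = mlg[locus.name]
                if not g.is_missing:
                    sizes.update(g.alleles)
        if len(sizes) < 2:
            continue
        # modal residue class defines the grid
        residues = [s % locus.repeat_unit for s in sizes]
        modal = max(set(residues), key=residues.count)
        for s in sorted(sizes):
            if s % locus.repeat_unit != modal:
                report["off_grid_alleles"].append({"locus": locus.name, "allele": s})

    lats = [r.lat for r in dataset.samples if r.lat is not None]
    lons = [r.lon for r in dataset.samples if r.lon is not None]
    if len(lats) >= 3:
        import statistics

        lat_med, lon_med = statistics.median(lats), statistics.median(lons)
        for rec in dataset.samples:
            if rec.lat is None or rec.lon is None:
                continue
            if abs(rec.lat - lat_med) > 5 or abs(rec.lon - lon_med) > 5:
                report["coordinate_outliers"].append(rec.sample_id)
    return report


def write_validation_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Flat per-sample / per-individual tables used by the CLI between stages
# ---------------------------------------------------------------------------

def write_consensus_table(dataset: Dataset, path: PathLike) -> None:
    """One row per sample with its consensus genotype (post-consensus stage)."""
    rows = []
    for rec in dataset.samples:
        row = {
            "sample_id": rec.sample_id,
            "province": rec.province,
            "source": rec.source.value,
            "year": rec.year,
            "lat": rec.lat,
            "lon": rec.lon,
            "sry": int(rec.sry_any_positive),
            "status": rec.consensus_status or "",
        }
        for name in dataset.locus_names:
            if rec.consensus is None:
                row[name + "_1"] = row[name + "_2"] = ""
            else:
                row[name + "_1"], row[name + "_2"] = _allele_cells(rec.consensus[name])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_consensus_table(path: PathLike, loci: Optional[Sequence[Locus]] = None) -> Dataset:
    """Read a consensus table back into a Dataset (one 'replicate' = the consensus)."""
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    schema = TableSchema()
    s1, s2 = schema.allele_suffixes
    if loci is None:
        names = [c[:-2] for c in df.columns if c.endswith(s1) and c[:-2] + s2 in df.columns]
        loci = [Locus(n, 2) for n in names]
    locus_names = [l.name for l in loci]
    samples = []
    for _, row in df.iterrows():
        calls = {}
        for name in locus_names:
            a = _parse_allele(row[name + s1], schema)
            b = _parse_allele(row[name + s2], schema)
            calls[name] = LocusGenotype(a, b)
        mlg = MultilocusGenotype.from_mapping(calls, locus_names)
        status = str(row.get("status", "")) or None
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            province=str(row["province"]),
            source=Source(str(row["source"])),
            year=int(row["year"]),
            lat=None if pd.isna(row.get("lat")) else float(row["lat"]),
            lon=None if pd.isna(row.get("lon")) else float(row["lon"]),
            sry_positive=[bool(int(row.get("sry", 0)))],
            consensus=None if status in ("discarded", "mismatch_unresolved") else mlg,
            consensus_status=status,
        )
        samples.append(rec)
    return Dataset(samples=samples, loci=list(loci))
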