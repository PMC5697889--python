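"""Validated readers/writers for the tabular and sequence formats.

TSV dialect: UTF-8, tab-separated, ``#``-prefixed comment lines, header row
required.  Every reader fails with the offending row number; every
``write_*``/``read_*`` pair round-trips field-for-field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotatedCDS,
    CoverageTable,
    GenomeBin,
    TaxonProfile,
    ValidationError,
    validate_bins,
    validate_cds_list,
)


def _rows(path: str) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _header(path: str, required: Sequence[str]) -> tuple[list[str], Iterator]:
    it = _rows(path)
    try:
        lineno, header = next(it)
    except StopIteration:
        raise ValidationError(f"{path}: empty file, header required") from None
    missing = [c for c in required if c not in header]
    if missing:
        raise ValidationError(f"{path}:{lineno}: missing columns {missing}")
    return header, it


# ---------------------------------------------------------------------------
# CDS tables

CDS_COLUMNS = ["cds_id", "contig_id", "start", "end", "strand", "ko", "cazy_domains"]


def read_cds_table(path: str) -> list[AnnotatedCDS]:
    header, it = _header(path, CDS_COLUMNS)
    idx = {c: header.index(c) for c in CDS_COLUMNS}
    out: list[AnnotatedCDS] = []
    seen: set[str] = set()
    for lineno, fields in it:
        if len(fields) < len(header):
            fields = fields + [""] * (len(header) - len(fields))
        cid = fields[idx["cds_id"]]
        if cid in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate cds_id {cid!r}")
        seen.add(cid)
        try:
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
        except ValueError:
            raise ValidationError(
                f"{path}:{lineno}: malformed coordinates for {cid!r}"
            ) from None
        ko = fields[idx["ko"]] or None
        raw = fields[idx["cazy_domains"]]
        domains = tuple(d for d in raw.split(";") if d) if raw else ()
        try:
            out.append(
                AnnotatedCDS(
                    cds_id=cid,
                    contig_id=fields[idx["contig_id"]],
                    start=start,
                    end=end,
                    strand=fields[idx["strand"]],
                    ko=ko,
                    cazy_domains=domains,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return out


def write_cds_table(cds_list: Sequence[AnnotatedCDS], path: str) -> None:
    validate_cds_list(cds_list)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CDS_COLUMNS) + "\n")
        for c in cds_list:
            fh.write(
                "\t".join(
                    [
                        c.cds_id,
                        c.contig_id,
                        str(c.start),
                        str(c.end),
                        c.strand,
                        c.ko or "",
                        ";".join(c.cazy_domains),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Coverage tables


def read_coverage_table(path: str) -> CoverageTable:
    header, it = _header(path, ["contig_id", "length"])
    samples = [c for c in header if c not in ("contig_id", "length")]
    if not samples:
        raise ValidationError(f"{path}: no sample columns")
    ci, li = header.index("contig_id"), header.index("length")
    depth: dict[str, dict[str, float]] = {}
    lengths: dict[str, int] = {}
    for lineno, fields in it:
        if len(fields) != len(header):
            raise ValidationError(f"{path}:{lineno}: expected {len(header)} fields")
        contig = fields[ci]
        try:
            lengths[contig] = int(fields[li])
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: missing/invalid length") from None
        row: dict[str, float] = {}
        for s in samples:
            try:
                d = float(fields[header.index(s)])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: invalid depth in column {s}"
                ) from None
            if d < 0:
                raise ValidationError(f"{path}:{lineno}: negative depth {d}")
            row[s] = d
        depth[contig] = row
    return CoverageTable(samples=samples, depth=depth, contig_lengths=lengths)


def write_coverage_table(cov: CoverageTable, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["contig_id", "length"] + cov.samples) + "\n")
        for contig in cov.depth:
            vals = [repr(cov.depth[contig][s]) for s in cov.samples]
            fh.write(
                "\t".join([contig, str(cov.contig_lengths[contig])] + vals) + "\n"
            )


# ---------------------------------------------------------------------------
# Bins


def read_bins(
    membership_path: str, metadata_path: str, cov: CoverageTable | None = None
) -> list[GenomeBin]:
    """Load contig->bin membership plus per-bin metadata.

    Unbinned contigs are simply absent from the membership file.  A contig
    assigned to two bins is an error; bin sizes are derived from contig
    lengths when a coverage table is supplied.
    """
    header, it = _header(membership_path, ["contig_id", "bin_id"])
    ci, bi = header.index("contig_id"), header.index("bin_id")
    members: dict[str, set[str]] = {}
    owner: dict[str, str] = {}
    for lineno, fields in it:
        contig, bin_id = fields[ci], fields[bi]
        if contig in owner:
            raise ValidationError(
                f"{membership_path}:{lineno}: contig {contig} already in {owner[contig]}"
            )
        owner[contig] = bin_id
        members.setdefault(bin_id, set()).add(contig)

    mheader, mit = _header(
        metadata_path, ["bin_id", "completeness", "contamination", "taxonomy"]
    )
    midx = {c: mheader.index(c) for c in mheader}
    bins: list[GenomeBin] = []
    for lineno, fields in mit:
        bin_id = fields[midx["bin_id"]]
        if bin_id not in members:
            raise ValidationError(
                f"{metadata_path}:{lineno}: bin {bin_id} has no contigs"
            )
        contigs = frozenset(members[bin_id])
        size = (
            sum(cov.contig_lengths[c] for c in contigs) if cov is not None else 0
        )
        try:
            bins.append(
                GenomeBin(
                    bin_id=bin_id,
                    contig_ids=contigs,
                    completeness=float(fields[midx["completeness"]]),
                    contamination=float(fields[midx["contamination"]]),
                    size_bp=size,
                    taxonomy=fields[midx["taxonomy"]],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{metadata_path}:{lineno}: {exc}") from None
    validate_bins(bins, cov)
    return bins


def write_bins(
    bins: Sequence[GenomeBin], membership_path: str, metadata_path: str
) -> None:
    with open(membership_path, "w", encoding="utf-8") as fh:
        fh.write("contig_id\tbin_id\n")
        for b in bins:
            for contig in sorted(b.contig_ids):
                fh.write(f"{contig}\t{b.bin_id}\n")
    with open(metadata_path, "w", encoding="utf-8") as fh:
        fh.write("bin_id\tcompleteness\tcontamination\ttaxonomy\n")
        for b in bins:
            fh.write(
                f"{b.bin_id}\t{b.completeness!r}\t{b.contamination!r}\t{b.taxonomy}\n"
            )


# ---------------------------------------------------------------------------
# Taxon profiles


def read_taxon_profile(path: str, min_abundance: float = 0.0005) -> TaxonProfile:
    header, it = _header(path, ["lineage"])
    samples = [c for c in header if c != "lineage"]
    rows: dict[tuple[str, ...], list[float]] = {}
    for lineno, fields in it:
        lineage = tuple(fields[header.index("lineage")].split(";"))
        try:
            vals = [float(fields[header.index(s)]) for s in samples]
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: invalid abundance") from None
        rows[lineage] = vals
    return TaxonProfile(samples=samples, rows=rows, min_abundance=min_abundance)


def write_taxon_profile(profile: TaxonProfile, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["lineage"] + profile.samples) + "\n")
        for lineage, vals in profile.rows.items():
            fh.write("\t".join([";".join(lineage)] + [repr(v) for v in vals]) + "\n")


# ---------------------------------------------------------------------------
# Proteomes (FASTA)


def read_proteome(path: str) -> dict[str, str]:
    """Protein FASTA -> {cds_id: amino-acid sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate protein id {rec.id}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValidationError(f"{path}: no sequences")
    return out


def write_proteome(proteome: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Configuration

DEFAULT_CONFIG = {
    "completeness_min": 50.0,
    "contamination_max": 10.0,
    "q_threshold": 0.05,
    "p_threshold": 0.05,
    "min_kos_per_pathway": 3,
    "taxon_min_abundance": 0.0005,
    "aai_identity_min": 0.30,
    "aai_coverage_min": 0.70,
    "top_n_genomes": 15,
}


@dataclass(frozen=True)
class Thresholds:
    completeness_min: float = 50.0
    contamination_max: float = 10.0
    q_threshold: float = 0.05
    p_threshold: float = 0.05
    min_kos_per_pathway: int = 3
    taxon_min_abundance: float = 0.0005
    aai_identity_min: float = 0.30
    aai_coverage_min: float = 0.70
    top_n_genomes: int = 15


def load_config(path: str | None = None) -> Thresholds:
    values = dict(DEFAULT_CONFIG)
    if path is not None and os.path.exists(path):
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(values)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        values.update(user)
    return Thresholds(**values)
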