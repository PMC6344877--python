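"""ChIP peak filtering and assignment to genes and operons.

Peaks passing statistical filters (P < 0.05, fold enrichment >= 2 by
default) are assigned to a gene when the peak summit lies within a bounded
distance upstream of the gene's annotated start codon, strand-aware.  Genes
in operons then pull in their co-transcribed neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Peak",
    "GeneModel",
    "RegulonTable",
    "FEATURE_TYPES",
    "read_peaks",
    "read_genes_gff3",
    "read_operons",
    "filter_peaks",
    "assign_peaks_to_genes",
    "expand_operons",
    "summarize_regulon",
]

FEATURE_TYPES = ("CDS", "sRNA", "tRNA", "rRNA", "misc_RNA")


@dataclass(frozen=True)
class Peak:
    """A called ChIP peak; coordinates are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    summit: int
    p_value: float
    fold_enrichment: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.summit <= self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start},{self.end}]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene anchored by its start codon.

    ``start_codon_pos`` is the leftmost base of the start codon on the +
    strand and the rightmost base on the - strand (1-based).
    """

    gene_id: str
    chrom: str
    strand: str
    start_codon_pos: int
    feature_type: str = "CDS"
    operon_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")


@dataclass
class RegulonTable:
    """Gene -> assigned peak(s) with summit distance and provenance.

    ``assignments`` columns: gene_id, peak_name, chrom, summit, distance,
    source ('direct' or 'operon'), p_value, fold_enrichment.
    """

    assignments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "peak_name", "chrom", "summit", "distance",
                 "source", "p_value", "fold_enrichment"]))

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.assignments["gene_id"].unique().tolist())

    def write(self, path) -> None:
        self.assignments.to_csv(path, sep="\t", index=False)


def read_peaks(path, dialect: str = "xls") -> list[Peak]:
    """Read peaks from a MACS2-style table.

    ``dialect='xls'``: TSV with 1-based columns chrom, start, end, abs_summit
    (or summit), -log10(pvalue), fold_enrichment.
    ``dialect='narrowPeak'``: BED 6+4, 0-based half-open; the summit offset
    in column 10 is relative to start.  Both are converted to 1-based
    inclusive coordinates and linear P-values.
    """
    if dialect == "xls":
        df = pd.read_csv(path, sep="\t", comment="#")
        cols = {c.lower(): c for c in df.columns}
        summit_col = cols.get("abs_summit", cols.get("summit"))
        p_col = cols.get("-log10(pvalue)", cols.get("neg_log10_pvalue"))
        peaks = []
        for i, row in df.iterrows():
            name = str(row[cols["name"]]) if "name" in cols else f"peak_{i + 1}"
            peaks.append(Peak(
                chrom=str(row[cols["chr"]] if "chr" in cols else row[cols["chrom"]]),
                start=int(row[cols["start"]]),
                end=int(row[cols["end"]]),
                summit=int(row[summit_col]),
                p_value=float(10.0 ** -row[p_col]),
                fold_enrichment=float(row[cols["fold_enrichment"]]),
                name=name,
            ))
        return peaks
    if dialect == "narrowPeak":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "name", "score",
                                "strand", "signalValue", "pValue", "qValue",
                                "peak"])
        peaks = []
        for _, row in df.iterrows():
            start1 = int(row["start"]) + 1          # 0-based -> 1-based
            summit = int(row["start"]) + int(row["peak"]) + 1
            peaks.append(Peak(
                chrom=str(row["chrom"]), start=start1, end=int(row["end"]),
                summit=summit, p_value=float(10.0 ** -row["pValue"]),
                fold_enrichment=float(row["signalValue"]),
                name=str(row["name"]),
            ))
        return peaks
    raise ValueError(f"unknown peak dialect {dialect!r}")


def write_peaks_xls(peaks: list[Peak], path) -> None:
    import numpy as np
    rows = [{"chr": p.chrom, "start": p.start, "end": p.end,
             "abs_summit": p.summit,
             "-log10(pvalue)": -np.log10(p.p_value),
             "fold_enrichment": p.fold_enrichment, "name": p.name}
            for p in peaks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3; start codon = feature start (+) / end (-).

    The feature type column must be one of the known types; operon
    membership, if present, is taken from an ``operon_id`` attribute.
    """
    genes = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line[:80]}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in FEATURE_TYPES:
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gene_id = attr.get("ID") or attr.get("locus_tag")
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID: {line[:80]}")
            genes.append(GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand,
                start_codon_pos=int(start) if strand == "+" else int(end),
                feature_type=ftype, operon_id=attr.get("operon_id") or None,
            ))
    return genes


def read_operons(path) -> pd.DataFrame:
    """Read an operon membership TSV with columns operon_id, gene_id, rank."""
    df = pd.read_csv(path, sep="\t", dtype={"operon_id": str, "gene_id": str})
    required = {"operon_id", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"operon table must have columns {sorted(required)}")
    return df


def filter_peaks(peaks: list[Peak], p_max: float = 0.05,
                 fe_min: float = 2.0) -> list[Peak]:
    """Keep peaks with p_value < p_max and fold_enrichment >= fe_min."""
    return [p for p in peaks if p.p_value < p_max and p.fold_enrichment >= fe_min]


def assign_peaks_to_genes(peaks: list[Peak], genes: list[GeneModel],
                          max_upstream: int = 300) -> RegulonTable:
    """Assign each peak to every gene whose start codon it sits upstream of.

    The strand-aware upstream distance is d = start_codon - summit on the +
    strand and summit - start_codon on the - strand; a gene qualifies iff
    0 <= d <= max_upstream (both bounds inclusive; a summit exactly at the
    start codon counts).  One summit may serve several genes (divergent
    promoters).
    """
    known_chroms = {g.chrom for g in genes}
    rows = []
    for peak in peaks:
        if genes and peak.chrom not in known_chroms:
            raise ValueError(f"peak on unknown chromosome {peak.chrom!r}")
        for gene in genes:
            if gene.chrom != peak.chrom:
                continue
            if gene.strand == "+":
                d = gene.start_codon_pos - peak.summit
            else:
                d = peak.summit - gene.start_codon_pos
            if 0 <= d <= max_upstream:
                rows.append({
                    "gene_id": gene.gene_id, "peak_name": peak.name,
                    "chrom": peak.chrom, "summit": peak.summit, "distance": d,
                    "source": "direct", "p_value": peak.p_value,
                    "fold_enrichment": peak.fold_enrichment,
                })
    if not rows:
        return RegulonTable()
    return RegulonTable(pd.DataFrame(rows))


def expand_operons(direct: RegulonTable, operons: pd.DataFrame,
                   genes: list[GeneModel] | None = None) -> RegulonTable:
    """Pull whole operons into the table when any member is directly assigned.

    Added members are flagged ``source='operon'`` and inherit the peak of the
    directly assigned member; genes already present are not duplicated.
    Idempotent.
    """
    if genes is not None:
        known = {g.gene_id for g in genes}
        unknown = set(operons["gene_id"]) - known
        if unknown:
            raise ValueError(f"operon table references unknown genes: "
                             f"{sorted(unknown)[:5]}")
    table = direct.assignments
    if table.empty or operons.empty:
        return RegulonTable(table.copy())
    members = operons.groupby("operon_id")["gene_id"].apply(list).to_dict()
    gene_to_operon = dict(zip(operons["gene_id"], operons["operon_id"]))
    present = set(table["gene_id"])
    new_rows = []
    seen_new = set()
    for _, row in table.iterrows():
        op = gene_to_operon.get(row["gene_id"])
        if op is None:
            continue
        for member in members[op]:
            if member in present or member in seen_new:
                continue
            seen_new.add(member)
            new = row.to_dict()
            new.update(gene_id=member, source="operon")
            new_rows.append(new)
    if not new_rows:
        return RegulonTable(table.copy())
    out = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)
    return RegulonTable(out)


def summarize_regulon(table: RegulonTable,
                      genes: list[GeneModel]) -> dict[str, int]:
    """Counts of regulon members by feature type, plus distinct operons."""
    by_id = {g.gene_id: g for g in genes}
    counts = {ft: 0 for ft in FEATURE_TYPES}
    operons = set()
    for gid in table.gene_ids:
        gene = by_id.get(gid)
        if gene is None:
            continue
        counts[gene.feature_type] += 1
        if gene.operon_id:
            operons.add(gene.operon_id)
    counts["n_operons"] = len(operons)
    counts["n_genes"] = len(table.gene_ids)
    return counts
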