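"""Domain types and tabular I/O for APA isoform and miRNA target-site data.

Conventions used throughout the package
---------------------------------------
* Two cell states are compared: cell line ``A`` (normal-like) and cell line
  ``B`` (cancer-like).  Every "change" metric is B relative to A.
* A gene's short isoform ends at the 5'-most poly(A) site, the long isoform
  at the 3'-most site; the region between the two sites is the aUTR, the
  region upstream of the proximal site the cUTR.
* UTR offsets are 0-based, half-open, measured in nucleotides from the UTR
  start in transcript orientation.  A site whose start offset equals
  ``cutr_length`` lies on the aUTR side of the boundary: it requires sequence
  beyond the proximal cleavage site and so exists only on the long isoform.
* The site position used for compartment assignment is the site's 5' start.

All tables are plain TSV with fixed headers (schemas below); an optional
BED6 ingester is provided for poly(A) sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

APA_COLUMNS = ["gene_id", "cell_line", "short_reads", "long_reads",
               "cutr_length", "autr_length"]
MIRNA_COLUMNS = ["mirna_id", "reads_a", "reads_b"]
FAMILY_MAP_COLUMNS = ["mirna_id", "family_id"]
SITE_COLUMNS = ["family_id", "gene_id", "utr_offset"]
SHORTENED_COLUMNS = ["gene_id", "shortened"]

CUTR = "cUTR"
AUTR = "aUTR"


class ParseError(ValueError):
    """Malformed input table (bad header, bad value, wrong type)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


@dataclass(frozen=True)
class ApaGeneRecord:
    """Short/long isoform read counts and UTR segment lengths for one gene
    in one cell line."""

    gene_id: str
    cell_line: str
    short_reads: int
    long_reads: int
    cutr_length: int
    autr_length: int

    def __post_init__(self) -> None:
        if self.short_reads < 0 or self.long_reads < 0:
            raise ValidationError(
                f"{self.gene_id}/{self.cell_line}: negative read count")
        if self.cutr_length < 1 or self.autr_length < 1:
            raise ValidationError(
                f"{self.gene_id}/{self.cell_line}: UTR lengths must be >= 1 nt")


@dataclass
class PolyASiteTable:
    """All poly(A) cleavage sites of one gene, in genomic coordinates.

    ``site_positions`` are 1-based genomic coordinates in ascending order;
    ``site_reads`` maps cell line -> per-site read counts aligned with the
    positions; ``utr_start`` is the genomic coordinate of the 3'UTR start
    (the position transcript offsets are measured from).
    """

    gene_id: str
    strand: str
    utr_start: int
    site_positions: list[int]
    site_reads: dict[str, list[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class MirnaFamilyProfile:
    """A seed family's member miRNAs and aggregate read counts per cell line."""

    family_id: str
    members: frozenset[str]
    reads_a: int
    reads_b: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"family {self.family_id}: empty member set")
        if self.reads_a < 0 or self.reads_b < 0:
            raise ValidationError(f"family {self.family_id}: negative reads")


@dataclass(frozen=True)
class TargetSiteAssignment:
    """A predicted target site located to the cUTR or aUTR of a gene."""

    family_id: str
    gene_id: str
    compartment: str
    utr_offset: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df[columns]


def _to_int(df: pd.DataFrame, cols: list[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        try:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad.index[bad.isna()][0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-integer value in column '{col}' at line {line}")
    return out


def read_apa_table(path: str | Path) -> list[ApaGeneRecord]:
    """Read the per-gene isoform expression table.

    Schema: ``gene_id  cell_line  short_reads  long_reads  cutr_length
    autr_length``.  Duplicate (gene_id, cell_line) pairs are an error.
    """
    path = Path(path)
    df = _to_int(_read_tsv(path, APA_COLUMNS),
                 ["short_reads", "long_reads", "cutr_length", "autr_length"],
                 path)
    dup = df.duplicated(subset=["gene_id", "cell_line"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["gene_id", "cell_line"]].tolist()
        raise ValidationError(f"{path}: duplicate record for {tuple(pair)}")
    return [ApaGeneRecord(r.gene_id, r.cell_line, r.short_reads, r.long_reads,
                          r.cutr_length, r.autr_length)
            for r in df.itertuples(index=False)]


def apa_frame(records: list[ApaGeneRecord]) -> pd.DataFrame:
    """Records -> canonical DataFrame (one row per gene per cell line)."""
    return pd.DataFrame([r.__dict__ for r in records], columns=APA_COLUMNS)


def write_apa_table(records: list[ApaGeneRecord] | pd.DataFrame,
                    path: str | Path) -> None:
    df = records if isinstance(records, pd.DataFrame) else apa_frame(records)
    df[APA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mirna_profiles(path: str | Path) -> pd.DataFrame:
    """Mature-miRNA read counts: ``mirna_id  reads_a  reads_b``."""
    path = Path(path)
    df = _to_int(_read_tsv(path, MIRNA_COLUMNS), ["reads_a", "reads_b"], path)
    if (df[["reads_a", "reads_b"]] < 0).any().any():
        raise ValidationError(f"{path}: negative miRNA read count")
    if df["mirna_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate mirna_id")
    return df


def read_family_map(path: str | Path) -> pd.DataFrame:
    """Seed-family membership: ``mirna_id  family_id``."""
    df = _read_tsv(Path(path), FAMILY_MAP_COLUMNS)
    if df["mirna_id"].duplicated().any():
        raise ValidationError(f"{path}: a mature miRNA mapped to two families")
    return df


def group_families(profiles: pd.DataFrame,
                   family_map: pd.DataFrame) -> pd.DataFrame:
    """Aggregate mature-miRNA counts into seed-family profiles.

    Mature miRNAs sharing a seed target the same sites, so their read counts
    are summed per family.  Mature miRNAs absent from the family map are
    dropped with a log message.  Returns ``family_id  reads_a  reads_b
    n_members`` sorted by family_id.
    """
    merged = profiles.merge(family_map, on="mirna_id", how="left")
    unmapped = merged["family_id"].isna()
    if unmapped.any():
        logger.info("group_families: dropping %d mature miRNA(s) without a "
                    "family assignment", int(unmapped.sum()))
        merged = merged[~unmapped]
    out = (merged.groupby("family_id", as_index=False)
           .agg(reads_a=("reads_a", "sum"), reads_b=("reads_b", "sum"),
                n_members=("mirna_id", "nunique"))
           .sort_values("family_id", ignore_index=True))
    return out


def family_profiles(profiles: pd.DataFrame,
                    family_map: pd.DataFrame) -> list[MirnaFamilyProfile]:
    grouped = group_families(profiles, family_map)
    members = (profiles.merge(family_map, on="mirna_id")
               .groupby("family_id")["mirna_id"].agg(frozenset))
    return [MirnaFamilyProfile(r.family_id, members[r.family_id],
                               int(r.reads_a), int(r.reads_b))
            for r in grouped.itertuples(index=False)]


def read_sites(path: str | Path) -> pd.DataFrame:
    """Predicted target sites: ``family_id  gene_id  utr_offset`` (0-based
    nucleotides from the UTR start)."""
    path = Path(path)
    df = _to_int(_read_tsv(path, SITE_COLUMNS), ["utr_offset"], path)
    if (df["utr_offset"] < 0).any():
        raise ValidationError(f"{path}: negative utr_offset")
    return df


def write_sites(df: pd.DataFrame, path: str | Path) -> None:
    df[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_shortened_flags(path: str | Path) -> pd.Series:
    """Reported shortened-gene flags: ``gene_id  shortened`` (true/false)."""
    path = Path(path)
    df = _read_tsv(path, SHORTENED_COLUMNS)
    flags = df["shortened"].str.strip().str.lower()
    bad = ~flags.isin({"true", "false", "1", "0"})
    if bad.any():
        raise ParseError(f"{path}: 'shortened' must be true/false")
    return pd.Series(flags.isin({"true", "1"}).to_numpy(),
                     index=pd.Index(df["gene_id"], name="gene_id"),
                     name="shortened")


def write_shortened_flags(flags: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"gene_id": flags.index,
                  "shortened": flags.to_numpy()}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# poly(A)-site collapse and compartment assignment
# ---------------------------------------------------------------------------

def collapse_to_two_isoforms(sites: PolyASiteTable) -> list[ApaGeneRecord]:
    """Reduce a multi-site gene to the two-isoform representation.

    The short isoform takes the reads of the 5'-most site, the long isoform
    those of the 3'-most site; intermediate-site reads are discarded (not
    merged).  ``cutr_length`` is the distance from the UTR start to the
    proximal site and ``autr_length`` the proximal-to-distal distance.  On the
    minus strand the 5'-most site is the one with the largest genomic
    coordinate.  Returns one record per cell line.
    """
    if sites.strand not in {"+", "-"}:
        raise ValidationError(f"{sites.gene_id}: unknown strand {sites.strand!r}")
    n = len(sites.site_positions)
    if n < 2:
        raise ValidationError(f"{sites.gene_id}: need >= 2 poly(A) sites, got {n}")
    order = sorted(range(n), key=lambda i: sites.site_positions[i])
    if sites.strand == "-":
        order = order[::-1]
    proximal, distal = order[0], order[-1]
    cutr = abs(sites.site_positions[proximal] - sites.utr_start)
    autr = abs(sites.site_positions[distal] - sites.site_positions[proximal])
    records = []
    for cell_line in sorted(sites.site_reads):
        reads = sites.site_reads[cell_line]
        if len(reads) != n:
            raise ValidationError(
                f"{sites.gene_id}/{cell_line}: {len(reads)} read values for {n} sites")
        records.append(ApaGeneRecord(sites.gene_id, cell_line,
                                     int(reads[proximal]), int(reads[distal]),
                                     cutr, autr))
    return records


def assign_site_compartment(site_offset: int,
                            record: ApaGeneRecord) -> str | None:
    """Locate a site start offset to the cUTR or aUTR of a gene.

    Offsets below ``cutr_length`` are cUTR; the boundary offset itself and
    anything up to the distal site is aUTR.  Offsets at or beyond the distal
    cleavage site are dropped (returns None) with a warning.
    """
    if site_offset < 0:
        raise ValidationError("negative site offset")
    if site_offset < record.cutr_length:
        return CUTR
    if site_offset < record.cutr_length + record.autr_length:
        return AUTR
    logger.warning("site offset %d beyond UTR end (%d) for gene %s: dropped",
                   site_offset, record.cutr_length + record.autr_length,
                   record.gene_id)
    return None


def assign_compartments(sites: pd.DataFrame,
                        apa: pd.DataFrame) -> pd.DataFrame:
    """Vectorised compartment assignment for a whole site table.

    ``apa`` is the canonical per-gene table (lengths identical across cell
    lines).  Sites of genes absent from the APA table, and sites beyond the
    UTR end, are dropped and counted in the log.  Returns ``family_id
    gene_id  compartment  utr_offset``.
    """
    lengths = (apa.drop_duplicates("gene_id")
               [["gene_id", "cutr_length", "autr_length"]])
    merged = sites.merge(lengths, on="gene_id", how="left")
    unknown = merged["cutr_length"].isna()
    if unknown.any():
        logger.info("assign_compartments: %d site(s) on genes absent from the "
                    "APA table dropped", int(unknown.sum()))
        merged = merged[~unknown]
    total_len = merged["cutr_length"] + merged["autr_length"]
    beyond = merged["utr_offset"] >= total_len
    if beyond.any():
        logger.warning("assign_compartments: %d site(s) beyond the UTR end "
                       "dropped", int(beyond.sum()))
        merged = merged[~beyond]
    compartment = pd.Series(
        pd.Categorical.from_codes(
            (merged["utr_offset"] >= merged["cutr_length"]).astype(int),
            categories=[CUTR, AUTR]),
        index=merged.index, name="compartment").astype(str)
    out = merged[["family_id", "gene_id", "utr_offset"]].copy()
    out.insert(2, "compartment", compartment)
    return out.reset_index(drop=True)


def read_polya_bed(path: str | Path, cell_line: str,
                   utr_starts: dict[str, int]) -> list[PolyASiteTable]:
    """Optional BED6 ingester for poly(A) sites.

    Maps BED ``name`` -> gene_id and ``score`` -> read count; the interval
    start (converted to 1-based) is the cleavage position.  ``utr_starts``
    supplies the genomic 3'UTR start per gene, which BED6 cannot carry.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: BED6 needs 6 columns")
            chrom, start, _end, name, score, strand = parts[:6]
            try:
                rows.append((name, int(start) + 1, int(score), strand))
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer start/score")
    tables = []
    df = pd.DataFrame(rows, columns=["gene_id", "pos", "reads", "strand"])
    for gene_id, grp in df.groupby("gene_id", sort=True):
        if gene_id not in utr_starts:
            raise ValidationError(f"{path}: no UTR start given for {gene_id}")
        strands = set(grp["strand"])
        if len(strands) != 1:
            raise ValidationError(f"{path}: {gene_id}: inconsistent strand")
        grp = grp.sort_values("pos")
        tables.append(PolyASiteTable(
            gene_id=gene_id, strand=strands.pop(),
            utr_start=utr_starts[gene_id],
            site_positions=grp["pos"].tolist(),
            site_reads={cell_line: grp["reads"].tolist()}))
    return tables
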