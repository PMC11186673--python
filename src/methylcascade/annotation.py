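"""Genomic annotation container and readers/writers for the plain-text formats
used throughout the pipeline.

Coordinates are 0-based half-open internally.  BED input is native; GTF/GFF3
(1-based closed) is converted on read.  A gene's transcription start site is
``start`` on the + strand and ``end - 1`` on the - strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_CANONICAL_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}

PROBE_COLUMNS = ["probe_id", "chrom", "pos"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "name"]


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix: ``chr1`` and ``1`` are the same contig."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def is_canonical_chrom(chrom: str) -> bool:
    """True for autosomes 1-22 and the X/Y sex chromosomes (either spelling)."""
    return normalize_chrom(chrom) in _CANONICAL_CHROMS


@dataclass
class GenomicAnnotation:
    """Probe positions plus gene intervals.

    Attributes
    ----------
    probes : DataFrame with columns ``probe_id, chrom, pos`` (0-based position).
    genes : DataFrame with columns
        ``gene_id, chrom, start, end, strand, biotype, name``
        (0-based half-open, strand ``+``/``-``).
    """

    probes: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        for c in ("gene_id", "chrom", "start", "end", "strand"):
            if len(self.genes) and c not in self.genes.columns:
                raise ValueError(f"gene table missing column: {c}")
        if len(self.genes):
            if (self.genes["start"] >= self.genes["end"]).any():
                raise ValueError("gene intervals must satisfy start < end")
            bad = set(self.genes["strand"]) - {"+", "-"}
            if bad:
                raise ValueError(f"invalid strand values: {bad}")

    def probe_chromosomes(self) -> pd.Series:
        """Chromosome per probe_id (normalized spelling)."""
        s = self.probes.set_index("probe_id")["chrom"].map(normalize_chrom)
        return s

    def tss(self) -> pd.Series:
        """Strand-aware transcription start site per gene (0-based)."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"].to_numpy() == "+", g["start"], g["end"] - 1),
            index=g["gene_id"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_probe_bed(path) -> pd.DataFrame:
    """Read probe coordinates from BED (chrom, start, end, probe_id; 0-based
    half-open).  The probe position is the interval start (450K probes are
    single CpG sites)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "probe_id"], dtype={0: str})
    return pd.DataFrame({
        "probe_id": df["probe_id"].astype(str),
        "chrom": df["chrom"].astype(str),
        "pos": df["start"].astype(int),
    })


def write_probe_bed(probes: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "chrom": probes["chrom"],
        "start": probes["pos"].astype(int),
        "end": probes["pos"].astype(int) + 1,
        "probe_id": probes["probe_id"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_tsv(path) -> pd.DataFrame:
    """Read the simplified gene table: gene_id, chrom, start, end, strand,
    biotype[, name].  Coordinates are 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "name" not in df.columns:
        df["name"] = df["gene_id"]
    if "biotype" not in df.columns:
        df["biotype"] = "protein_coding"
    return df[GENE_COLUMNS]


def write_gene_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gtf_genes(path) -> pd.DataFrame:
    """Extract gene records from a GTF/GFF3 file into the simplified gene
    table, converting 1-based closed coordinates to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = _parse_attributes(f[8])
            gene_id = attrs.get("gene_id") or attrs.get("ID", "")
            rows.append({
                "gene_id": gene_id,
                "chrom": f[0],
                "start": int(f[3]) - 1,
                "end": int(f[4]),
                "strand": f[6],
                "biotype": attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding")),
                "name": attrs.get("gene_name", gene_id),
            })
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _parse_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and " " not in chunk.split("=", 1)[0]:
            key, val = chunk.split("=", 1)  # GFF3 style
        else:
            parts = chunk.split(None, 1)
            if len(parts) != 2:
                continue
            key, val = parts
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (set name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
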