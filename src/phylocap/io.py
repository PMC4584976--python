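"""Readers and writers for the file formats the pipeline consumes and emits.

Alignments travel as per-locus multi-FASTA (one record per accession);
supermatrices can additionally be written as NEXUS or relaxed PHYLIP with a
RAxML-style partition table.  Per-site base calls are accepted either as a
strict TSV dialect or as a minimal VCF subset (CHROM = locus, POS, QUAL,
simple SNP/indel records).  Coverage matrices are TSV with accessions as
rows and loci as columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_locus_fasta",
    "write_locus_fasta",
    "read_alignment_dir",
    "write_nexus",
    "write_phylip",
    "write_partitions",
    "read_calls_tsv",
    "write_calls_tsv",
    "read_calls_vcf",
    "write_calls_vcf",
    "read_coverage_tsv",
    "write_coverage_tsv",
]

CALL_COLUMNS = ["locus_id", "position", "call", "quality", "is_variant", "is_indel", "depth"]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_locus_fasta(path, locus_id: str | None = None, outgroup: str | None = None):
    """Read one per-locus multi-FASTA into a :class:`LocusAlignment`."""
    from .locus_screening import LocusAlignment

    path = Path(path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return LocusAlignment(
        locus_id=locus_id or path.stem, sequences=seqs, outgroup=outgroup
    )


def write_locus_fasta(aln, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_dir(directory, pattern: str = "*.fasta", outgroup: str | None = None) -> list:
    """Read every per-locus FASTA under ``directory`` (sorted by filename)."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern} in {directory}")
    return [read_locus_fasta(p, outgroup=outgroup) for p in paths]


def _to_msa(aln) -> MultipleSeqAlignment:
    records = []
    for acc, seq in aln.sequences.items():
        rec = SeqRecord(Seq(seq), id=acc, description="")
        rec.annotations["molecule_type"] = "DNA"
        records.append(rec)
    return MultipleSeqAlignment(records)


def write_nexus(aln, path) -> None:
    """Write an alignment (e.g. a concatenated supermatrix) as NEXUS."""
    AlignIO.write(_to_msa(aln), str(path), "nexus")


def write_phylip(aln, path) -> None:
    """Write an alignment as relaxed PHYLIP (full accession names)."""
    AlignIO.write(_to_msa(aln), str(path), "phylip-relaxed")


def write_partitions(partitions: pd.DataFrame, path, datatype: str = "DNA") -> None:
    """Write a RAxML-style partition file from a (locus_id, start, end) table."""
    with open(path, "w") as fh:
        for row in partitions.itertuples():
            fh.write(f"{datatype}, {row.locus_id} = {row.start}-{row.end}\n")


# ---------------------------------------------------------------------------
# base-call tables
# ---------------------------------------------------------------------------

def _validate_calls(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    if (df["quality"] < 0).any():
        raise ValueError("phred-scaled qualities must be non-negative")
    dup = df.duplicated(subset=["locus_id", "position"])
    if dup.any():
        raise ValueError("positions must be unique within a locus")
    return df.astype(
        {"position": int, "quality": float, "is_variant": bool, "is_indel": bool, "depth": int}
    )


def read_calls_tsv(path) -> pd.DataFrame:
    """Read the strict TSV call-table dialect (columns = CALL_COLUMNS)."""
    return _validate_calls(pd.read_csv(path, sep="\t"))


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    _validate_calls(calls)[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indel call">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_calls_vcf(calls: pd.DataFrame, path, reference_call: str = "A") -> None:
    """Write a call table as a minimal single-sample-free VCF.

    CHROM is the locus, POS the 1-based position; non-variant sites carry
    ALT='.'; indels are flagged in INFO.  The true reference base is not part
    of the table, so non-variant records write the call as REF and variant
    records write ``reference_call`` as a nominal REF differing from ALT.
    """
    calls = _validate_calls(calls)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for row in calls.itertuples():
            if row.is_variant:
                ref = reference_call if row.call != reference_call else "C"
                alt = row.call
            else:
                ref, alt = row.call, "."
            info = f"DP={row.depth}" + (";INDEL" if row.is_indel else "")
            fh.write(
                f"{row.locus_id}\t{row.position}\t.\t{ref}\t{alt}\t{row.quality:g}\t.\t{info}\n"
            )


def read_calls_vcf(path) -> pd.DataFrame:
    """Read the minimal VCF subset back into the standard call-table frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, qual, _filter, info = line.rstrip("\n").split("\t")[:8]
            is_variant = alt != "."
            is_indel = "INDEL" in info.split(";")
            depth = 0
            for field in info.split(";"):
                if field.startswith("DP="):
                    depth = int(field[3:])
            rows.append(
                {
                    "locus_id": chrom,
                    "position": int(pos),
                    "call": alt if is_variant else ref,
                    "quality": float(qual),
                    "is_variant": is_variant,
                    "is_indel": is_indel,
                    "depth": depth,
                }
            )
    if not rows:
        raise ValueError(f"no records in {path}")
    return _validate_calls(pd.DataFrame(rows, columns=CALL_COLUMNS))


# ---------------------------------------------------------------------------
# coverage matrices
# ---------------------------------------------------------------------------

def read_coverage_tsv(path) -> pd.DataFrame:
    """Accession x locus mean-depth matrix; blank cells are missing data."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("coverage depths must be non-negative")
    return df.astype(float)


def write_coverage_tsv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t")
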