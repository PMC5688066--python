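"""Readers and writers for the pipeline's on-disk formats.

FASTA through Bio.SeqIO (80-column wrapping, headers preserved, sequences
upper-cased with a logged count); alignment hits as BLAST tabular
(outfmt-6) TSV with two extension columns ``qlen`` and ``slen``; ORF
annotations as GFF3 with ``COG=``, ``function=`` and ``bin=`` attributes
(1-based inclusive on disk, converted to 0-based half-open here and only
here); read counts and sample metadata as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("marinibin")

HIT_COLUMNS_12 = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
HIT_COLUMNS = HIT_COLUMNS_12 + ["qlen", "slen"]

_HIT_DTYPES = {
    "qseqid": str, "sseqid": str, "pident": float, "length": int,
    "mismatch": int, "gapopen": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "evalue": float, "bitscore": float,
    "qlen": int, "slen": int,
}


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id -> sequence dict (description kept in the key's
    record id only; sequences upper-cased, count of lowercased records logged)."""
    records: dict[str, str] = {}
    n_lower = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            n_lower += 1
            seq = seq.upper()
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = seq
    if n_lower:
        logger.info("read_fasta(%s): upper-cased %d records", path, n_lower)
    return records


def write_fasta(records: Mapping[str, str], path) -> None:
    """Write an id (or 'id description') -> sequence mapping as 80-column FASTA."""
    seqrecs = []
    for header, seq in records.items():
        ident, _, desc = header.partition(" ")
        seqrecs.append(SeqRecord(Seq(seq), id=ident, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seqrecs)


def read_hits(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-style TSV (12 canonical columns, optionally
    + qlen, slen).  Values are typed and pident validated to [0, 100]."""
    path = Path(path)
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    ncol = first.shape[1]
    has_header = isinstance(first.iat[0, 0], str) and first.iat[0, 0] == "qseqid"
    if ncol == 12:
        names = HIT_COLUMNS_12
    elif ncol == 14:
        names = HIT_COLUMNS
    else:
        raise ValueError(
            f"{path}: expected 12 or 14 tab-separated columns, found {ncol}"
        )
    df = pd.read_csv(
        path, sep="\t", names=names, skiprows=1 if has_header else 0,
        dtype={k: v for k, v in _HIT_DTYPES.items() if k in names},
    )
    bad = df[(df["pident"] < 0) | (df["pident"] > 100)]
    if len(bad):
        raise ValueError(
            f"{path}: pident outside [0, 100] at row(s) {bad.index[:5].tolist()}"
        )
    return df


def write_hits(hits: pd.DataFrame, path) -> None:
    cols = HIT_COLUMNS if "qlen" in hits.columns else HIT_COLUMNS_12
    hits.to_csv(path, sep="\t", index=False, columns=cols)


def write_gff(orfs: pd.DataFrame, path) -> None:
    """Write ORF intervals as GFF3.

    ``orfs`` uses 0-based half-open ``start``/``end`` plus ``orf_id``,
    ``contig_id``, ``function`` and optional ``cog_id``/``bin_id`` columns;
    GFF3 on disk is 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs.itertuples(index=False):
            attrs = [f"ID={orf.orf_id}"]
            cog = getattr(orf, "cog_id", None)
            if cog:
                attrs.append(f"COG={cog}")
            func = getattr(orf, "function", None)
            if func:
                attrs.append(f"function={func}")
            bin_id = getattr(orf, "bin_id", getattr(orf, "clade_id", None))
            if bin_id:
                attrs.append(f"bin={bin_id}")
            fh.write(
                "\t".join([
                    str(orf.contig_id), "marinibin", "CDS",
                    str(int(orf.start) + 1), str(int(orf.end)), ".", "+", "0",
                    ";".join(attrs),
                ]) + "\n"
            )


def read_gff(path) -> pd.DataFrame:
    """Read GFF3 ORF annotations into a DataFrame with 0-based half-open
    coordinates and ``COG``/``function``/``bin`` attributes as columns."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.all_features():
        rows.append({
            "orf_id": feat.id,
            "contig_id": feat.seqid,
            "start": feat.start - 1,
            "end": feat.end,
            "gene_length": feat.end - feat.start + 1,
            "kind": "RNA" if "rna" in feat.featuretype.lower() else "protein",
            "cog_id": (feat.attributes.get("COG") or [None])[0],
            "function": (feat.attributes.get("function") or [None])[0],
            "bin_id": (feat.attributes.get("bin") or [None])[0],
        })
    return pd.DataFrame(
        rows, columns=["orf_id", "contig_id", "start", "end", "gene_length",
                       "kind", "cog_id", "function", "bin_id"],
    )


def read_counts(path) -> pd.DataFrame:
    """Read the per-ORF read-count table (orf_id, sample_id, count,
    total_mapped)."""
    df = pd.read_csv(path, sep="\t")
    required = {"orf_id", "sample_id", "count", "total_mapped"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_samples(path) -> pd.DataFrame:
    """Read sample metadata (sample_id plus o2_umol and/or redox flags)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df
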