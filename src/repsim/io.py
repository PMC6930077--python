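"""AIRR Rearrangement TSV and germline FASTA input/output.

The AIRR community Rearrangement schema is a plain TSV with standard
column names; round-trips through :func:`write_airr` / :func:`read_airr`
are bit-exact for every field.  Germline references travel as FASTA with
the CDR3 anchor offset carried in the description line.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FormatError,
    GermlineReference,
    JSegment,
    ParameterError,
    Rearrangement,
    VSegment,
)

MANDATORY_COLUMNS = (
    "sequence_id", "sequence", "v_call", "d_call", "j_call",
    "junction", "junction_aa", "productive", "duplicate_count", "locus",
)
OPTIONAL_COLUMNS = ("sample_id", "tissue")

_TRUE = {"T", "TRUE", "true", "True", "1"}
_FALSE = {"F", "FALSE", "false", "False", "0"}


def translate(nt: str) -> str:
    """Standard-genetic-code translation; stop codons rendered ``*``.

    Raises :class:`ParameterError` if the length is not a multiple of 3
    or the alphabet is not {A,C,G,T}.
    """
    if len(nt) % 3 != 0:
        raise ParameterError(f"sequence length {len(nt)} is not a multiple of 3")
    if not set(nt) <= set("ACGT"):
        bad = sorted(set(nt) - set("ACGT"))
        raise ParameterError(f"invalid nucleotide characters: {bad}")
    return str(Seq(nt).translate())


def read_airr(path: str | os.PathLike) -> list[Rearrangement]:
    """Read an AIRR Rearrangement TSV into a list of records.

    A missing ``duplicate_count`` column defaults every record to 1;
    missing optional ``sample_id``/``tissue`` default to "".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    for col in MANDATORY_COLUMNS:
        if col == "duplicate_count":
            continue  # optional with default below
        if col not in df.columns:
            raise FormatError(f"missing mandatory AIRR column: {col}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, "duplicate_count", "1") or "1"
        try:
            count = int(raw)
        except ValueError as exc:
            raise FormatError(
                f"row {i}: non-integer duplicate_count {raw!r}"
            ) from exc
        prod = row.productive
        if prod in _TRUE:
            productive = True
        elif prod in _FALSE:
            productive = False
        else:
            raise FormatError(f"row {i}: unparseable productive flag {prod!r}")
        records.append(Rearrangement(
            sequence_id=row.sequence_id,
            sequence=row.sequence,
            v_call=row.v_call,
            d_call=row.d_call,
            j_call=row.j_call,
            junction=row.junction,
            junction_aa=row.junction_aa,
            productive=productive,
            duplicate_count=count,
            locus=row.locus,
            sample_id=getattr(row, "sample_id", ""),
            tissue=getattr(row, "tissue", ""),
        ))
    return records


def airr_dataframe(records: list[Rearrangement]) -> pd.DataFrame:
    """Records as a DataFrame with AIRR column order (T/F productive flags)."""
    cols = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
    rows = [{
        "sequence_id": r.sequence_id, "sequence": r.sequence,
        "v_call": r.v_call, "d_call": r.d_call, "j_call": r.j_call,
        "junction": r.junction, "junction_aa": r.junction_aa,
        "productive": "T" if r.productive else "F",
        "duplicate_count": r.duplicate_count, "locus": r.locus,
        "sample_id": r.sample_id, "tissue": r.tissue,
    } for r in records]
    return pd.DataFrame(rows, columns=cols)


def write_airr(records: list[Rearrangement], path: str | os.PathLike) -> None:
    """Write records as AIRR TSV; read_airr(write_airr(x)) is lossless."""
    airr_dataframe(records).to_csv(path, sep="\t", index=False)


# -- germline FASTA ----------------------------------------------------------
#
# Description-line convention: ">NAME type=V locus=TRB anchor=45", where
# anchor is the 0-based offset of the conserved Cys (V) or Phe/Trp (J)
# codon.  Any FASTA following this convention is accepted; IMGT-derived
# references work once annotated with the two anchors.

def read_germline_fasta(path: str | os.PathLike) -> GermlineReference:
    v_segments: dict[str, VSegment] = {}
    j_segments: dict[str, JSegment] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            item.split("=", 1) for item in rec.description.split()[1:]
            if "=" in item
        )
        try:
            seg_type = fields["type"]
            locus = fields["locus"]
            anchor = int(fields["anchor"])
        except (KeyError, ValueError) as exc:
            raise FormatError(
                f"{rec.id}: germline header must carry type=, locus=, anchor="
            ) from exc
        seq = str(rec.seq).upper()
        if seg_type == "V":
            v_segments[rec.id] = VSegment(rec.id, seq, anchor, locus)
        elif seg_type == "J":
            j_segments[rec.id] = JSegment(rec.id, seq, anchor, locus)
        else:
            raise FormatError(f"{rec.id}: unknown segment type {seg_type!r}")
    return GermlineReference(v_segments, j_segments)


def write_germline_fasta(reference: GermlineReference,
                         path: str | os.PathLike) -> None:
    recs = []
    for seg in reference.v_segments.values():
        recs.append(SeqRecord(
            Seq(seg.sequence), id=seg.name,
            description=f"type=V locus={seg.locus} anchor={seg.cys_anchor}"))
    for seg in reference.j_segments.values():
        recs.append(SeqRecord(
            Seq(seg.sequence), id=seg.name,
            description=f"type=J locus={seg.locus} anchor={seg.phe_anchor}"))
    SeqIO.write(recs, str(path), "fasta")


def read_reads_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Plain (id, sequence) pairs from a FASTA of rearranged reads."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_reads_fasta(reads: list[tuple[str, str]],
                      path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in reads]
    SeqIO.write(recs, str(path), "fasta")
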