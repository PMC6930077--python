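"""CDR3 extraction and clonotype assembly.

A deliberately desk-scale re-implementation of the alignment stage that
read-level repertoire tools perform: V assignment by anchored prefix
matching up to and including the conserved Cys codon, J assignment by
sliding the anchor-containing germline suffix over the read, junction
extraction between the two anchors (both codons inclusive), productivity
classification (in frame and stop-free), and clonotype assembly keyed by
(V gene, CDR3 nucleotide sequence).

Gene assignment is exact/near-exact matching with a mismatch budget, not
Smith-Waterman: the contract is correctness on clean and lightly mutated
data; read rescue and D-segment calling are out of scope.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .model import (
    Clonotype,
    GermlineReference,
    ParameterError,
    Rearrangement,
)
from .io import translate

DEFAULT_MAX_MISMATCH = 2


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_v(seq: str, reference: GermlineReference,
             max_mismatch: int = DEFAULT_MAX_MISMATCH,
             ) -> tuple[str, int, int] | None:
    """Best V gene by prefix matching; returns (v_call, cys offset in read,
    mismatches) or None when no gene matches within the budget.

    The compared region is the germline prefix up to and including the Cys
    codon, anchored at read position 0.  Ties break by gene name.
    """
    if not reference.v_segments:
        raise ParameterError("empty V reference")
    best: tuple[int, str, int] | None = None
    for name in sorted(reference.v_segments):
        seg = reference.v_segments[name]
        prefix = seg.sequence[:seg.cys_anchor + 3]
        if len(seq) < len(prefix):
            continue
        mm = _hamming(seq[:len(prefix)], prefix)
        if best is None or mm < best[0]:
            best = (mm, name, seg.cys_anchor)
    if best is None or best[0] > max_mismatch:
        return None
    return best[1], best[2], best[0]


def assign_j(seq: str, reference: GermlineReference,
             max_mismatch: int = DEFAULT_MAX_MISMATCH,
             ) -> tuple[str, int, int] | None:
    """Best J gene by scanning its anchor-containing suffix over the read.

    Returns (j_call, phe anchor offset in read, mismatches) or None.  The
    query is the germline J from its Phe/Trp anchor through its 3' end, so
    the matched position is directly the anchor offset in the read.
    """
    if not reference.j_segments:
        raise ParameterError("empty J reference")
    best: tuple[int, str, int] | None = None
    for name in sorted(reference.j_segments):
        seg = reference.j_segments[name]
        query = seg.sequence[seg.phe_anchor:]
        # fast path: an exact occurrence beats any near-match
        hit = seq.find(query)
        if hit >= 0:
            if best is None or best[0] > 0:
                best = (0, name, hit)
            continue
        for pos in range(len(seq) - len(query) + 1):
            mm = _hamming(seq[pos:pos + len(query)], query)
            if best is None or mm < best[0]:
                best = (mm, name, pos)
    if best is None or best[0] > max_mismatch:
        return None
    return best[1], best[2], best[0]


def locate_j_anchor(seq: str, reference: GermlineReference, j_call: str,
                    max_mismatch: int = DEFAULT_MAX_MISMATCH) -> int | None:
    """Phe/Trp anchor offset of ``j_call`` in the read, or None."""
    seg = reference.j_segments[j_call]
    query = seg.sequence[seg.phe_anchor:]
    hit = seq.find(query)
    if hit >= 0:
        return hit
    best: tuple[int, int] | None = None
    for pos in range(len(seq) - len(query) + 1):
        mm = _hamming(seq[pos:pos + len(query)], query)
        if best is None or mm < best[0]:
            best = (mm, pos)
    if best is None or best[0] > max_mismatch:
        return None
    return best[1]


def extract_junction(seq: str, cys_offset: int, phe_offset: int) -> str:
    """Substring from the first base of the Cys codon through the last base
    of the Phe codon inclusive (length = phe - cys + 3)."""
    if phe_offset < cys_offset:
        raise ParameterError(
            f"anchors inverted: cys={cys_offset} > phe={phe_offset}")
    return seq[cys_offset:phe_offset + 3]


def classify_productive(junction: str) -> tuple[bool, str]:
    """Productive iff in frame (length % 3 == 0) and stop-free.

    Returns (flag, junction_aa); the aa string is empty when nonproductive.
    """
    if not junction:
        raise ParameterError("empty junction")
    if len(junction) % 3 != 0:
        return False, ""
    aa = translate(junction)
    if "*" in aa:
        return False, ""
    return True, aa


@dataclass
class ExtractionResult:
    """Extracted records plus per-read rejects with reason codes."""

    records: list[Rearrangement]
    rejects: pd.DataFrame  # columns: sequence_id, reason


def extract_rearrangements(reads: list[tuple[str, str]],
                           reference: GermlineReference,
                           max_mismatch: int = DEFAULT_MAX_MISMATCH,
                           locus_of_v: dict[str, str] | None = None,
                           read_counts: dict[str, int] | None = None,
                           read_labels: dict[str, tuple[str, str]] | None = None,
                           ) -> ExtractionResult:
    """Run the full extraction stage over (id, sequence) reads.

    Reads failing V or J assignment are returned in ``rejects`` with a
    reason code, never silently dropped.  ``read_counts`` and
    ``read_labels`` (sample_id, tissue) carry optional per-read metadata
    through to the output records.
    """
    records: list[Rearrangement] = []
    rejected: list[dict] = []
    for rid, seq in reads:
        v_hit = assign_v(seq, reference, max_mismatch)
        if v_hit is None:
            rejected.append({"sequence_id": rid, "reason": "no_v_assignment"})
            continue
        v_call, cys, _ = v_hit
        j_hit = assign_j(seq, reference, max_mismatch)
        if j_hit is None:
            rejected.append({"sequence_id": rid, "reason": "no_j_assignment"})
            continue
        j_call, phe, _ = j_hit
        if phe < cys:
            rejected.append({"sequence_id": rid, "reason": "anchors_inverted"})
            continue
        junction = extract_junction(seq, cys, phe)
        productive, aa = classify_productive(junction)
        sample_id, tissue = (read_labels or {}).get(rid, ("", ""))
        records.append(Rearrangement(
            sequence_id=rid, sequence=seq, v_call=v_call, d_call="",
            j_call=j_call, junction=junction, junction_aa=aa,
            productive=productive,
            duplicate_count=(read_counts or {}).get(rid, 1),
            locus=reference.v_segments[v_call].locus,
            sample_id=sample_id, tissue=tissue))
    rejects = pd.DataFrame(rejected, columns=["sequence_id", "reason"])
    return ExtractionResult(records, rejects)


def assemble_clonotypes(records: list[Rearrangement],
                        scope: str = "per-sample",
                        key: str = "nt",
                        include_j: bool = False,
                        productive_only: bool = True,
                        ) -> list[Clonotype]:
    """Collapse rearrangements into clonotypes.

    The default key is (v_call, CDR3 nucleotide); ``key='aa'`` keys on the
    amino-acid junction, ``include_j`` adds j_call to the key.  Scope
    ``'per-sample'`` keeps samples separate; ``'pooled'`` merges samples
    within a tissue before assembly.  Output is sorted by count descending,
    then key ascending.
    """
    if scope not in ("per-sample", "pooled"):
        raise ParameterError(f"unknown scope {scope!r}")
    if key not in ("nt", "aa"):
        raise ParameterError(f"unknown clonotype key {key!r}")
    groups: dict[tuple, list[Rearrangement]] = defaultdict(list)
    for r in records:
        if productive_only and not r.productive:
            continue
        cdr3 = r.junction if key == "nt" else r.junction_aa
        k = (r.locus, r.tissue, "" if scope == "pooled" else r.sample_id,
             r.v_call, r.j_call if include_j else "", cdr3)
        groups[k].append(r)
    clonotypes = []
    for (locus, tissue, sample, v_call, _, _), members in groups.items():
        first = members[0]
        clonotypes.append(Clonotype(
            v_call=v_call, j_call=first.j_call,
            cdr3_nt=first.junction, cdr3_aa=first.junction_aa,
            count=sum(m.duplicate_count for m in members),
            sample_id=sample, tissue=tissue, locus=locus))
    clonotypes.sort(key=lambda c: (-c.count, c.v_call, c.cdr3_nt,
                                   c.sample_id, c.tissue))
    return clonotypes
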