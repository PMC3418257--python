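"""In-silico PCR and poly-Q/poly-A repeat-length calling.

The RUNX2 exon-1 assay amplifies the glutamine/alanine repeat region with
a fixed primer pair; allele length differences show up as amplicon-length
shifts of 3 bp per codon (the common 16Q and 30Q variants are +/-21 bp
from the 23Q wild type).  This module extracts the amplicon from a
template by exact primer matching and calls the repeat as the maximal run
of glutamine codons (CAG/CAA) followed immediately by the maximal run of
alanine codons (GCN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_cohorts import (
    AMPLICON_FRAME_OFFSET,
    FWD_PRIMER,
    REV_PRIMER,
    revcomp,
    simulate_amplicon,
)

__all__ = [
    "AlleleCall",
    "NoProduct",
    "in_silico_pcr",
    "call_repeat",
    "write_amplicon_fasta",
    "call_fasta",
]

_Q_CODONS = frozenset({"CAG", "CAA"})
_A_CODONS = frozenset({"GCA", "GCC", "GCG", "GCT"})
_MIN_Q_RUN = 5


@dataclass
class AlleleCall:
    """Called repeat: glutamine and alanine codon counts plus geometry."""

    nQ: int
    nA: int
    fragment_length: int

    @property
    def label(self) -> str:
        return f"{self.nQ}Q/{self.nA}A"


class NoProduct:
    """Sentinel result when a primer site is absent from the template."""

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return False

    def __repr__(self) -> str:
        return "NoProduct()"


def _find_all(template: str, probe: str) -> list[int]:
    hits, start = [], 0
    while (i := template.find(probe, start)) != -1:
        hits.append(i)
        start = i + 1
    return hits


def in_silico_pcr(
    template: str, fwd: str = FWD_PRIMER, rev: str = REV_PRIMER
) -> str | NoProduct:
    """Extract the PCR product between exact primer matches.

    Returns the substring from the forward-primer match through the
    reverse complement of the reverse primer, inclusive.  Templates
    lacking either site give :class:`NoProduct`; multiple matches of
    either primer, or overlapping primer sites, raise.
    """
    template = template.upper()
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    rc = revcomp(rev)
    f_hits = _find_all(template, fwd)
    r_hits = _find_all(template, rc)
    if len(f_hits) > 1 or len(r_hits) > 1:
        raise ValueError(
            f"ambiguous product: {len(f_hits)} forward and {len(r_hits)} "
            "reverse primer sites"
        )
    if not f_hits or not r_hits:
        return NoProduct()
    f, r = f_hits[0], r_hits[0]
    end = r + len(rc)
    if r < f + len(fwd):
        raise ValueError("primer sites overlap or are inverted")
    return template[f:end]


def _longest_run(codons: list[str], members: frozenset[str]) -> tuple[int, int]:
    """(start index, length) of the longest run of member codons; first on
    ties; (-1, 0) when absent."""
    best_start, best_len = -1, 0
    run_start, run_len = -1, 0
    for i, c in enumerate(codons):
        if c in members:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    return best_start, best_len


def call_repeat(amplicon: str, frame_anchor: int | None = None) -> AlleleCall:
    """Call poly-Q/poly-A repeat lengths from an amplicon.

    ``frame_anchor`` is the codon-frame offset (0-2); when None all three
    frames are scanned and the frame with the longest glutamine run wins.
    nQ is the length of the maximal CAG/CAA run (a non-Q codon simply ends
    the run); nA is the length of the GCN run immediately following it.

    Raises
    ------
    ValueError
        If no glutamine run of at least 5 codons exists.
    """
    amplicon = amplicon.upper()
    frames = range(3) if frame_anchor is None else [frame_anchor % 3]
    best: tuple[int, int, list[str]] | None = None
    for off in frames:
        codons = [
            amplicon[i:i + 3]
            for i in range(off, len(amplicon) - 2, 3)
        ]
        start, length = _longest_run(codons, _Q_CODONS)
        if length and (best is None or length > best[1]):
            best = (start, length, codons)
    if best is None or best[1] < _MIN_Q_RUN:
        raise ValueError("repeat not found: no glutamine run of >= 5 codons")
    q_start, nQ, codons = best
    nA = 0
    for c in codons[q_start + nQ:]:
        if c in _A_CODONS:
            nA += 1
        else:
            break
    return AlleleCall(nQ=nQ, nA=nA, fragment_length=len(amplicon))


def write_amplicon_fasta(
    alleles: Iterable[tuple[int, int]], path: str | Path, seed: int = 0
) -> None:
    """Write synthetic amplicons for (nQ, nA) alleles to FASTA; the header
    records the repeat frame offset used for anchored calling."""
    records = []
    for i, (nq, na) in enumerate(alleles):
        seq = simulate_amplicon(nq, na, seed + i)
        records.append(SeqRecord(
            Seq(seq),
            id=f"{nq}Q_{na}A",
            description=f"synthetic amplicon frame={AMPLICON_FRAME_OFFSET}",
        ))
    SeqIO.write(records, str(path), "fasta")


def call_fasta(path: str | Path) -> list[tuple[str, AlleleCall]]:
    """Call repeats for every sequence in a FASTA file, honouring a
    ``frame=<k>`` tag in the description when present."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        frame = None
        for token in rec.description.split():
            if token.startswith("frame="):
                frame = int(token.split("=", 1)[1])
        out.append((rec.id, call_repeat(str(rec.seq), frame)))
    return out
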