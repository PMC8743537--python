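"""Open-reading-frame calling and translation on candidate genomes.

Leviviricete class membership is decided by genome architecture: the presence
of maturation protein (MP), coat protein (CP) and RNA-directed RNA polymerase
(RdRP) ORFs.  This module locates all maximal start→stop ORFs so those core
proteins can be picked out downstream by profile-HMM scanning.

Conventions: coordinates are 0-based half-open on the forward strand; ORFs on
the reverse strand are projected back onto forward coordinates.  ORFs that run
off the contig end without an in-frame stop are reported with ``runoff=True``
because metagenomic contigs frequently truncate the RdRP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seq_io import GenomeRecord, ProteinRecord

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class OpenReadingFrame:
    """A located, translated coding region on a genome."""

    genome_id: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str  # '+' | '-'
    frame: int  # 0|1|2 frame offset on the scanned strand
    protein: ProteinRecord
    runoff: bool = False  # no in-frame stop before the contig end
    role: str | None = None  # MP | CP | RdRP, filled in after HMM scan

    @property
    def orf_id(self) -> str:
        return f"{self.genome_id}|{self.start}-{self.end}|{self.strand}"

    @property
    def length_aa(self) -> int:
        return self.protein.length_aa


def translate(nt: str, table: int = 11) -> str:
    """Translate a nucleotide string under the given genetic code.

    Stops render as '*'; any codon containing N renders as 'X'.  The bacterial
    code (11) is the default.
    """
    nt = nt.upper().replace("U", "T")
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate(table=table)))
    return "".join(out)


def _scan_strand(seq: str, min_len_aa: int, starts: frozenset[str]):
    """Yield (start, end, frame, runoff) for maximal ORFs on one strand.

    Maximality: within a frame, an ORF opens at the first start codon after
    the previous stop, so no reported ORF is nested in a longer same-frame ORF.
    """
    n = len(seq)
    for frame in range(3):
        orf_start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if orf_start is None:
                if codon in starts:
                    orf_start = pos
            elif codon in STOP_CODONS:
                # include the stop codon in the span
                if (pos - orf_start) // 3 >= min_len_aa:
                    yield orf_start, pos + 3, frame, False
                orf_start = None
        if orf_start is not None:
            end = orf_start + ((n - orf_start) // 3) * 3
            if (end - orf_start) // 3 >= min_len_aa:
                yield orf_start, end, frame, True


def find_orfs(
    genome: GenomeRecord,
    min_len_aa: int = 30,
    starts: frozenset[str] = DEFAULT_START_CODONS,
    both_strands: bool = True,
    table: int = 11,
) -> list[OpenReadingFrame]:
    """All maximal start→stop ORFs with protein length ≥ ``min_len_aa``.

    Returned in ascending (start, end, strand) order with reverse-strand
    coordinates projected onto the forward strand.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    n = len(genome.sequence)
    found: list[OpenReadingFrame] = []

    def emit(start, end, frame, runoff, strand, nt):
        aa = translate(nt, table=table)
        if not runoff:
            aa = aa[:-1]  # drop the stop
        if "*" in aa:  # internal stop can only arise from N-free TGA in table diffs
            return
        prot = ProteinRecord(id=f"{genome.id}|{start}-{end}|{strand}", sequence=aa)
        found.append(
            OpenReadingFrame(genome.id, start, end, strand, frame, prot, runoff)
        )

    for s, e, frame, runoff in _scan_strand(genome.sequence, min_len_aa, starts):
        emit(s, e, frame, runoff, "+", genome.sequence[s:e])

    if both_strands:
        rc = str(Seq(genome.sequence).reverse_complement())
        for s, e, frame, runoff in _scan_strand(rc, min_len_aa, starts):
            # project reverse-strand coords onto the forward strand
            emit(n - e, n - s, frame, runoff, "-", rc[s:e])

    found.sort(key=lambda o: (o.start, o.end, o.strand))
    return found


def orf_proteins(orfs: list[OpenReadingFrame]) -> list[ProteinRecord]:
    return [o.protein for o in orfs]
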