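"""Sequence records, FASTA/GFF3/TSV input-output and the cluster→taxon map.

Internal coordinates are 0-based half-open; everything serialized to GFF3 is
1-based inclusive.  Nucleotide sequences are normalized to the DNA alphabet on
ingest (U→T) so RNA-virus deposits and DNA-alphabet records behave identically.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: roles of the three leviviricete core proteins
ROLES = ("MP", "CP", "RdRP")


@dataclass
class GenomeRecord:
    """A nucleotide genome or contig under classification."""

    id: str
    sequence: str
    description: str = ""
    source: str = "user"  # user | synthetic | external

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome record id must be non-empty")
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"genome {self.id!r}: illegal character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """An amino-acid sequence (20 standard residues plus X)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"protein {self.id!r}: illegal character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(
    path: str | Path, alphabet: Literal["nucleotide", "protein"]
) -> list[GenomeRecord] | list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-FASTA file.

    Nucleotide records get U→T normalization.  Duplicate ids, empty files and
    illegal characters are errors.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        if alphabet == "nucleotide":
            records.append(GenomeRecord(rec.id, str(rec.seq), description=desc))
        else:
            records.append(ProteinRecord(rec.id, str(rec.seq), description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Iterable[GenomeRecord | ProteinRecord], path: str | Path, width: int = 70
) -> None:
    """Write records as wrapped FASTA (atomic: temp file + rename)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with atomic_open(path) as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


def atomic_open(path: str | Path):
    """Open a temp file in the target directory; rename over `path` on close."""
    return _AtomicFile(Path(path))


class _AtomicFile:
    def __init__(self, path: Path):
        self._path = path
        self._tmp = None

    def __enter__(self):
        self._path.parent.mkdir(parents=True, exist_ok=True)
        fd, tmpname = tempfile.mkstemp(
            dir=str(self._path.parent), prefix=self._path.name + ".", suffix=".tmp"
        )
        self._tmp = tmpname
        self._handle = os.fdopen(fd, "w", encoding="utf-8")
        return self._handle

    def __exit__(self, exc_type, exc, tb):
        self._handle.close()
        if exc_type is None:
            os.replace(self._tmp, self._path)
        else:
            os.unlink(self._tmp)
        return False


def write_gff3(orfs, path: str | Path, genome_lengths: dict[str, int] | None = None) -> None:
    """Serialize ORFs as GFF3 CDS features (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for orf in orfs:
        if genome_lengths is not None:
            glen = genome_lengths.get(orf.genome_id)
            if glen is not None and orf.end > glen:
                raise ValueError(
                    f"ORF {orf.orf_id} ends at {orf.end} beyond genome "
                    f"{orf.genome_id} length {glen}"
                )
        attrs = f"ID={orf.orf_id}"
        if getattr(orf, "role", None):
            attrs += f";role={orf.role}"
        lines.append(
            "\t".join(
                [
                    orf.genome_id,
                    "levitax",
                    "CDS",
                    str(orf.start + 1),  # 0-based half-open → 1-based inclusive
                    str(orf.end),
                    ".",
                    orf.strand,
                    "0",
                    attrs,
                ]
            )
        )
    with atomic_open(path) as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cluster → taxon map
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["cluster_id", "role", "taxon_rank", "taxon_name", "parent_order"]

#: The published 2021 Leviviricetes scheme: nine coat-protein clusters mapped
#: onto six families in two orders, and the two RdRP clusters defining the
#: orders themselves.
DEFAULT_MAP_PATH = Path(__file__).parent / "data" / "cluster_taxon_map.tsv"


@dataclass
class ClusterTaxonMap:
    """Lookup from profile-HMM cluster labels to taxon names.

    CP clusters map to families (each family carrying its parent order);
    RdRP clusters map to orders.  MP clusters carry no rank and never appear
    here.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = set(_MAP_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"cluster map missing columns: {sorted(missing)}")
        cp = t[t.role == "CP"]
        dup = cp.cluster_id[cp.cluster_id.duplicated()]
        if len(dup):
            raise ValueError(
                f"CP cluster mapped to more than one family: {sorted(set(dup))}"
            )
        rd = t[t.role == "RdRP"]
        dup = rd.cluster_id[rd.cluster_id.duplicated()]
        if len(dup):
            raise ValueError(
                f"RdRP cluster mapped to more than one order: {sorted(set(dup))}"
            )
        orders = set(rd.taxon_name)
        bad_parents = set(cp.parent_order) - orders
        if bad_parents:
            raise ValueError(
                f"families reference unknown parent orders: {sorted(bad_parents)}"
            )

    @property
    def cp_clusters(self) -> list[str]:
        return list(self.table[self.table.role == "CP"].cluster_id)

    @property
    def rdrp_clusters(self) -> list[str]:
        return list(self.table[self.table.role == "RdRP"].cluster_id)

    @property
    def families(self) -> list[str]:
        return sorted(set(self.table[self.table.taxon_rank == "family"].taxon_name))

    @property
    def orders(self) -> list[str]:
        return sorted(set(self.table[self.table.taxon_rank == "order"].taxon_name))

    def family_of(self, cp_cluster: str) -> tuple[str, str] | None:
        """(family, parent_order) for a CP cluster, or None if unmapped."""
        rows = self.table[
            (self.table.role == "CP") & (self.table.cluster_id == cp_cluster)
        ]
        if rows.empty:
            return None
        row = rows.iloc[0]
        return row.taxon_name, row.parent_order

    def order_of(self, rdrp_cluster: str) -> str | None:
        rows = self.table[
            (self.table.role == "RdRP") & (self.table.cluster_id == rdrp_cluster)
        ]
        if rows.empty:
            return None
        return rows.iloc[0].taxon_name

    def write(self, path: str | Path) -> None:
        with atomic_open(path) as fh:
            self.table.to_csv(fh, sep="\t", index=False)


def read_cluster_taxon_map(path: str | Path | None = None) -> ClusterTaxonMap:
    """Read a cluster→taxon TSV; defaults to the packaged 2021 scheme."""
    if path is None:
        path = DEFAULT_MAP_PATH
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return ClusterTaxonMap(table)
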