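"""Genus and species demarcation by pairwise amino-acid identity (PAAI).

Genera are single-linkage clusters of RdRP proteins at ≥50 % PAAI; species
are clusters at ≥80 % within each genus, so species always nest inside
genera.  Single-linkage (connected components of the thresholded identity
graph) is the unique rule under which "PAAI ≥ cutoff" is itself the
demarcation criterion, and it guarantees threshold nesting.

Each cluster gets an exemplar by decreasing priority: an ICTV-archived
virus, then a GenBank-deposited sequence, then the longest contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .align import paai
from .seq_io import ProteinRecord, atomic_open

GENUS_PAAI = 50.0
SPECIES_PAAI = 80.0


@dataclass
class PairwiseIdentityMatrix:
    """Symmetric PAAI matrix (percent, diagonal 100) over protein ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in identity matrix")
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be 100")
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise ValueError("PAAI values must lie in [0, 100]")

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        with atomic_open(path) as fh:
            df.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "PairwiseIdentityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.index), values=df.to_numpy(dtype=float))


@dataclass
class ExemplarMetadata:
    """Per-sequence provenance used for exemplar selection."""

    id: str
    ictv_archived: bool = False
    genbank_deposited: bool = False
    contig_length: int = 0

    def __post_init__(self) -> None:
        if self.contig_length < 0:
            raise ValueError("contig_length must be >= 0")


@dataclass
class DemarcationResult:
    """Nested genus/species partitions with exemplars."""

    ids: list[str]
    genus_of: dict[str, str]
    species_of: dict[str, str]
    genus_clusters: dict[str, set[str]]
    species_clusters: dict[str, set[str]]
    exemplar_of_genus: dict[str, str] = field(default_factory=dict)
    exemplar_of_species: dict[str, str] = field(default_factory=dict)

    @property
    def n_genera(self) -> int:
        return len(self.genus_clusters)

    @property
    def n_species(self) -> int:
        return len(self.species_clusters)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i in self.ids:
            sp = self.species_of[i]
            rows.append(
                {
                    "id": i,
                    "genus_id": self.genus_of[i],
                    "species_id": sp,
                    "is_exemplar": self.exemplar_of_species.get(sp) == i,
                }
            )
        return pd.DataFrame(rows, columns=["id", "genus_id", "species_id", "is_exemplar"])

    def write_tsv(self, path) -> None:
        with atomic_open(path) as fh:
            self.as_frame().to_csv(fh, sep="\t", index=False)


def paai_matrix(
    proteins: list[ProteinRecord], **align_kwargs
) -> PairwiseIdentityMatrix:
    """Full symmetric PAAI matrix over a protein set."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    n = len(proteins)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = paai(proteins[i], proteins[j], **align_kwargs)
            m[i, j] = v
            m[j, i] = v
    return PairwiseIdentityMatrix(ids=ids, values=m)


def cluster_at_threshold(
    m: PairwiseIdentityMatrix, threshold: float
) -> list[set[str]]:
    """Single-linkage partition: components of the PAAI ≥ threshold graph.

    Clusters are ordered (and numbered downstream) by smallest member id.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    adj = csr_matrix(m.values >= threshold)
    _, comp = connected_components(adj, directed=False)
    clusters: dict[int, set[str]] = {}
    for node, c in zip(m.ids, comp):
        clusters.setdefault(c, set()).add(node)
    return sorted(clusters.values(), key=min)


def select_exemplar(
    members: set[str], metadata: dict[str, ExemplarMetadata] | None = None
) -> str:
    """Highest-priority member: ICTV-archived > GenBank-deposited > longest
    contig; ties by contig length descending, then lexicographic id."""
    if not members:
        raise ValueError("empty cluster")
    meta = metadata or {}

    def key(i: str):
        m = meta.get(i, ExemplarMetadata(id=i))
        tier = 0 if m.ictv_archived else (1 if m.genbank_deposited else 2)
        return (tier, -m.contig_length, i)

    return min(members, key=key)


def demarcate(
    m: PairwiseIdentityMatrix,
    genus_threshold: float = GENUS_PAAI,
    species_threshold: float = SPECIES_PAAI,
    metadata: dict[str, ExemplarMetadata] | None = None,
) -> DemarcationResult:
    """Nested genus (≥ genus_threshold) and species (≥ species_threshold)
    single-linkage demarcation with exemplar selection."""
    if species_threshold < genus_threshold:
        raise ValueError("species threshold must be >= genus threshold")
    genera = cluster_at_threshold(m, genus_threshold)
    genus_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    genus_clusters: dict[str, set[str]] = {}
    species_clusters: dict[str, set[str]] = {}
    exemplar_g: dict[str, str] = {}
    exemplar_s: dict[str, str] = {}

    idx = {i: k for k, i in enumerate(m.ids)}
    for gi, members in enumerate(genera, start=1):
        glabel = f"genus_{gi}"
        genus_clusters[glabel] = members
        for i in members:
            genus_of[i] = glabel
        exemplar_g[glabel] = select_exemplar(members, metadata)
        # species are clustered within the genus only
        sub_ids = sorted(members, key=lambda i: idx[i])
        rows = [idx[i] for i in sub_ids]
        sub = m.values[np.ix_(rows, rows)]
        adj = csr_matrix(sub >= species_threshold)
        _, comp = connected_components(adj, directed=False)
        sp_sets: dict[int, set[str]] = {}
        for node, c in zip(sub_ids, comp):
            sp_sets.setdefault(c, set()).add(node)
        for si, sp_members in enumerate(sorted(sp_sets.values(), key=min), start=1):
            slabel = f"{glabel}_species_{si}"
            species_clusters[slabel] = sp_members
            for i in sp_members:
                species_of[i] = slabel
            exemplar_s[slabel] = select_exemplar(sp_members, metadata)

    return DemarcationResult(
        ids=list(m.ids),
        genus_of=genus_of,
        species_of=species_of,
        genus_clusters=genus_clusters,
        species_clusters=species_clusters,
        exemplar_of_genus=exemplar_g,
        exemplar_of_species=exemplar_s,
    )
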