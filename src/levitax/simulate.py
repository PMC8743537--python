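"""Synthetic leviviricete-like genomes with planted taxonomy.

Every genome carries the three core ORFs (MP ≈ 400 aa, CP ≈ 130 aa,
RdRP ≈ 540 aa) arranged MP–CP–RdRP with short intergenic spacers, so the
completeness filter (MP ≥ 350, RdRP ≥ 500) passes by construction.  Protein
families evolve by star-wise substitution from shared ancestors with an
identity ladder — genus ancestors ≈ 40 % pairwise within a family, species
ancestors ≈ 70 % within a genus, members ≈ 90 % within a species — bracketing
the 50 %/80 % demarcation thresholds with ≥ 10-point margins so recovery is
not borderline.  Realized RdRP identities are asserted against those margins
at generation time (regenerated with a fresh derived seed up to 5 times).

Substitutions are BLOSUM62-weighted draws over replacement residues;
back-translation uses uniformly random synonymous codons of the bacterial
genetic code.  Each ORF is preceded by an in-frame stop so ORF calling
recovers exactly the planted coding regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .align import ALPHABET
from .classify import ReferenceMember
from .hmm import BACKGROUND, MultipleAlignment
from .seq_io import (
    ClusterTaxonMap,
    GenomeRecord,
    ProteinRecord,
    atomic_open,
    write_fasta,
)

AMINO = ALPHABET[:20]

MP_LEN = 400
CP_LEN = 130
RDRP_LEN = 540

#: pairwise identity targets of the planted ladder (percent)
GENUS_ANCESTOR_IDENTITY = 40.0
SPECIES_ANCESTOR_IDENTITY = 70.0
MEMBER_IDENTITY = 90.0

_ORDER_NAMES = ["Norzivirales", "Timlovirales"]
_FAMILY_NAMES = {
    "Norzivirales": ["Fiersviridae", "Atkinsviridae", "Solspiviridae", "Duinviridae"],
    "Timlovirales": ["Steitzviridae", "Blumeviridae"],
}

_CODON_TABLE = unambiguous_dna_by_id[11]
_CODONS_FOR = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


def _substitution_weights() -> np.ndarray:
    """P(b | a, b≠a) ∝ bg(b)·2^(S(a,b)/2) over the 20 standard residues."""
    from .align import substitution_matrix

    s = substitution_matrix("BLOSUM62")[:20, :20]
    w = BACKGROUND[None, :] * np.exp2(s / 2.0)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


_SUB_WEIGHTS = None


def mutate_protein(
    seq: ProteinRecord,
    target_identity: float,
    seed: int | np.random.Generator,
    indel_rate: float = 0.0,
    new_id: str | None = None,
) -> ProteinRecord:
    """Substitute a Bernoulli fraction 1 − target/100 of positions with
    BLOSUM62-weighted replacement residues; optional small indels."""
    if not (0 < target_identity <= 100):
        raise ValueError("target_identity must be in (0, 100]")
    if target_identity < 10:
        raise ValueError("target identity below 10 % is not a meaningful regime")
    if indel_rate > 0.02:
        raise ValueError("indel_rate capped at 2 % of length")
    global _SUB_WEIGHTS
    if _SUB_WEIGHTS is None:
        _SUB_WEIGHTS = _substitution_weights()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = 1.0 - target_identity / 100.0
    aa_index = {c: i for i, c in enumerate(AMINO)}
    chars = list(seq.sequence)
    for i, c in enumerate(chars):
        if c in aa_index and rng.random() < p:
            chars[i] = AMINO[rng.choice(20, p=_SUB_WEIGHTS[aa_index[c]])]
    if indel_rate > 0:
        n_indels = rng.binomial(len(chars), indel_rate)
        for _ in range(n_indels):
            pos = int(rng.integers(1, len(chars)))
            if rng.random() < 0.5 and len(chars) > 2:
                del chars[pos]
            else:
                chars.insert(pos, AMINO[rng.choice(20, p=BACKGROUND)])
    return ProteinRecord(
        id=new_id or f"{seq.id}_mut", sequence="".join(chars), description=""
    )


def _mutate_cds(
    seq: ProteinRecord, target: float, rng, new_id: str | None = None
) -> ProteinRecord:
    """Mutate a coding protein but keep the initiator methionine, so the ORF
    start codon (and hence the planted ORF span) is conserved."""
    out = mutate_protein(seq, target, rng, new_id=new_id)
    if not out.sequence.startswith("M"):
        out = ProteinRecord(out.id, "M" + out.sequence[1:], out.description)
    return out


def _random_protein(rng: np.random.Generator, length: int, pid: str) -> ProteinRecord:
    body = "".join(AMINO[i] for i in rng.choice(20, size=length - 1, p=BACKGROUND))
    return ProteinRecord(id=pid, sequence="M" + body)


def back_translate(protein: ProteinRecord, rng: np.random.Generator) -> str:
    """Nucleotide CDS with uniformly random synonymous codons plus a stop."""
    codons = [
        _CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))]
        if aa in _CODONS_FOR
        else "NNN"
        for aa in protein.sequence
    ]
    codons.append("TAA")
    return "".join(codons)


@dataclass
class PlantedTaxonomy:
    """Ground-truth labels and the generation parameters behind them."""

    table: pd.DataFrame  # id, order, family, cp_cluster, rdrp_cluster, genus_id, species_id
    seed: int
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    genomes: list[GenomeRecord]
    proteins: list[ProteinRecord]  # role-tagged: <genome_id>|MP / |CP / |RdRP
    truth: PlantedTaxonomy
    msas: dict[str, MultipleAlignment]
    taxon_map: ClusterTaxonMap

    def rdrp_reference(self) -> list[ReferenceMember]:
        """The planted RdRP proteins with their genus/species labels."""
        idx = {p.id: p for p in self.proteins}
        out = []
        for row in self.truth.table.itertuples():
            out.append(
                ReferenceMember(
                    protein=idx[f"{row.id}|RdRP"],
                    genus_id=row.genus_id,
                    species_id=row.species_id,
                )
            )
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genomes, outdir / "genomes.fasta")
        write_fasta(self.proteins, outdir / "proteins.faa")
        with atomic_open(outdir / "truth.tsv") as fh:
            self.truth.table.to_csv(fh, sep="\t", index=False)
        self.taxon_map.write(outdir / "cluster_taxon_map.tsv")
        msa_dir = outdir / "msa"
        msa_dir.mkdir(exist_ok=True)
        for name, msa in self.msas.items():
            with atomic_open(msa_dir / f"{name}.afa") as fh:
                for mid, row in zip(msa.ids, msa.rows):
                    fh.write(f">{mid}\n{row}\n")


def _identity_bands_ok(seqs: dict, truth: pd.DataFrame) -> bool:
    """Hamming-identity margins on the planted RdRPs (substitution-only, so
    hamming == gapless alignment identity)."""
    for family, fam_rows in truth.groupby("family"):
        ids = list(fam_rows.id)
        mat = np.array([[ord(c) for c in seqs[f"{i}|RdRP"]] for i in ids])
        genus = list(fam_rows.genus_id)
        species = list(fam_rows.species_id)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                ident = 100.0 * np.mean(mat[i] == mat[j])
                if species[i] == species[j]:
                    if ident <= 83.0:
                        return False
                elif genus[i] == genus[j]:
                    if not (53.0 <= ident <= 77.0):
                        return False
                else:
                    if ident >= 45.0:
                        return False
    return True


def simulate_reference_set(
    n_orders: int = 2,
    families_per_order: int = 3,
    genera_per_family: int = 4,
    species_per_genus: int = 3,
    members_per_species: int = 2,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate genomes, proteins, truth table, per-cluster MSAs and the
    matching cluster→taxon map."""
    for v in (n_orders, families_per_order, genera_per_family,
              species_per_genus, members_per_species):
        if v < 1:
            raise ValueError("all counts must be >= 1")

    for attempt in range(5):
        ds = _generate(
            n_orders, families_per_order, genera_per_family,
            species_per_genus, members_per_species,
            seed=(seed + 1_000_003 * attempt) % (2**31),
        )
        seqs = {p.id: p.sequence for p in ds.proteins}
        if _identity_bands_ok(seqs, ds.truth.table):
            ds.truth.seed = seed
            return ds
    raise RuntimeError("planted identity margins violated in 5 attempts")


def _generate(
    n_orders, families_per_order, genera_per_family,
    species_per_genus, members_per_species, seed,
) -> SimulatedDataset:
    rng = np.random.default_rng(seed)
    # star-wise per-branch identities so PAIRWISE identities hit the ladder
    g_branch = 100.0 * math.sqrt(GENUS_ANCESTOR_IDENTITY / 100.0)
    s_branch = 100.0 * math.sqrt(SPECIES_ANCESTOR_IDENTITY / 100.0)
    m_branch = 100.0 * math.sqrt(MEMBER_IDENTITY / 100.0)

    orders = [
        _ORDER_NAMES[i] if i < len(_ORDER_NAMES) else f"Order_{i + 1}"
        for i in range(n_orders)
    ]
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    genomes: list[GenomeRecord] = []
    proteins: list[ProteinRecord] = []
    truth_rows = []
    msas: dict[str, list[ProteinRecord]] = {}
    map_rows = []

    fam_counter = 0
    for oi, order in enumerate(orders):
        rdrp_cluster = f"RdRP_{letters[oi]}"
        mp_cluster = f"MP_{oi + 1}"
        map_rows.append((rdrp_cluster, "RdRP", "order", order, ""))
        # order-level ancestors: MP and RdRP families span the whole order
        mp_anc = _random_protein(rng, MP_LEN, f"{mp_cluster}_anc")
        rdrp_anc = _random_protein(rng, RDRP_LEN, f"{rdrp_cluster}_anc")
        stock = _FAMILY_NAMES.get(order, [])
        for fi in range(families_per_order):
            family = stock[fi] if fi < len(stock) else f"{order}_family_{fi + 1}"
            cp_cluster = f"CP_{letters[fam_counter]}"
            fam_counter += 1
            map_rows.append((cp_cluster, "CP", "family", family, order))
            cp_anc = _random_protein(rng, CP_LEN, f"{cp_cluster}_anc")
            # family-level RdRP/MP ancestors diverge inside the order-wide cluster
            fam_rdrp = _mutate_cds(rdrp_anc, 60.0, rng)
            fam_mp = _mutate_cds(mp_anc, 60.0, rng)
            for gi in range(genera_per_family):
                genus_id = f"{family}_genus_{gi + 1}"
                g_rdrp = _mutate_cds(fam_rdrp, g_branch, rng)
                g_mp = _mutate_cds(fam_mp, g_branch, rng)
                g_cp = _mutate_cds(cp_anc, g_branch, rng)
                for si in range(species_per_genus):
                    species_id = f"{genus_id}_species_{si + 1}"
                    s_rdrp = _mutate_cds(g_rdrp, s_branch, rng)
                    s_mp = _mutate_cds(g_mp, s_branch, rng)
                    s_cp = _mutate_cds(g_cp, s_branch, rng)
                    for mi in range(members_per_species):
                        gid = f"syn_o{oi + 1}_f{fi + 1}_g{gi + 1}_s{si + 1}_m{mi + 1}"
                        trio = {}
                        for role, anc, cluster in (
                            ("MP", s_mp, mp_cluster),
                            ("CP", s_cp, cp_cluster),
                            ("RdRP", s_rdrp, rdrp_cluster),
                        ):
                            prot = _mutate_cds(
                                anc, m_branch, rng, new_id=f"{gid}|{role}"
                            )
                            trio[role] = prot
                            proteins.append(prot)
                            msas.setdefault(cluster, []).append(prot)
                        genomes.append(_assemble_genome(gid, trio, rng))
                        truth_rows.append(
                            {
                                "id": gid,
                                "order": order,
                                "family": family,
                                "cp_cluster": cp_cluster,
                                "rdrp_cluster": rdrp_cluster,
                                "genus_id": genus_id,
                                "species_id": species_id,
                            }
                        )

    truth = PlantedTaxonomy(
        table=pd.DataFrame(truth_rows),
        seed=seed,
        counts={
            "orders": n_orders,
            "families_per_order": families_per_order,
            "genera_per_family": genera_per_family,
            "species_per_genus": species_per_genus,
            "members_per_species": members_per_species,
        },
    )
    map_table = pd.DataFrame(
        map_rows, columns=["cluster_id", "role", "taxon_rank", "taxon_name", "parent_order"]
    )
    msa_objs = {
        name: MultipleAlignment(
            ids=[p.id for p in members], rows=[p.sequence for p in members]
        )
        for name, members in msas.items()
    }
    return SimulatedDataset(
        genomes=genomes,
        proteins=proteins,
        truth=truth,
        msas=msa_objs,
        taxon_map=ClusterTaxonMap(map_table),
    )


def _random_spacer(rng: np.random.Generator, lo: int = 12, hi: int = 30) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _assemble_genome(gid: str, trio: dict[str, ProteinRecord], rng) -> GenomeRecord:
    """MP–CP–RdRP with spacers; each CDS is preceded by an in-frame TAA so the
    ORF caller recovers exactly the planted coding regions."""
    parts = [_random_spacer(rng)]
    for role in ("MP", "CP", "RdRP"):
        parts.append("TAA")  # in-frame stop immediately upstream of the start
        parts.append(back_translate(trio[role], rng))
        parts.append(_random_spacer(rng))
    return GenomeRecord(id=gid, sequence="".join(parts), source="synthetic")
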