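"""End-to-end taxonomic classification of candidate +ssRNA phage genomes.

Per genome: ORF calling → profile-HMM scan → role assignment (best passing
hit per role) → coding-completeness filter (MP ≥ 350 aa, RdRP ≥ 500 aa) →
order from the RdRP cluster → family from the CP cluster, with the
incongruence rule (a CP cluster whose family belongs to a different order
than the RdRP cluster leaves BOTH order and family unassigned) → genus and
species adoption by RdRP PAAI against a demarcated reference set (≥50 %
genus, ≥80 % species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import paai
from .demarcation import GENUS_PAAI, SPECIES_PAAI
from .hmm import ProfileHMM, best_hits, scan
from .orfs import OpenReadingFrame, find_orfs
from .seq_io import (
    ClusterTaxonMap,
    GenomeRecord,
    ProteinRecord,
    atomic_open,
    read_cluster_taxon_map,
)

UNASSIGNED = "Unassigned"

MIN_MP_LEN_AA = 350
MIN_RDRP_LEN_AA = 500


@dataclass
class DemarcationConfig:
    """Thresholds and lookup tables steering classification."""

    min_mp_len_aa: int = MIN_MP_LEN_AA
    min_rdrp_len_aa: int = MIN_RDRP_LEN_AA
    genus_paai: float = GENUS_PAAI
    species_paai: float = SPECIES_PAAI
    min_orf_len_aa: int = 30
    cluster_taxon_map: ClusterTaxonMap = field(default_factory=read_cluster_taxon_map)

    def __post_init__(self) -> None:
        if self.min_mp_len_aa <= 0 or self.min_rdrp_len_aa <= 0:
            raise ValueError("length thresholds must be positive")
        if self.species_paai < self.genus_paai:
            raise ValueError("species_paai must be >= genus_paai")


@dataclass
class ReferenceMember:
    protein: ProteinRecord
    genus_id: str
    species_id: str


@dataclass
class TaxonomyCall:
    """Per-genome classification with evidence flags."""

    genome_id: str
    complete: bool = False
    roles_found: dict[str, OpenReadingFrame] = field(default_factory=dict)
    rdrp_cluster: str | None = None
    cp_cluster: str | None = None
    order: str = UNASSIGNED
    family: str = UNASSIGNED
    genus_id: str | None = None
    species_id: str | None = None
    incongruent: bool = False
    notes: list[str] = field(default_factory=list)

    def role_len(self, role: str) -> int | None:
        orf = self.roles_found.get(role)
        return orf.length_aa if orf else None


def check_completeness(
    role_orfs: dict[str, OpenReadingFrame], cfg: DemarcationConfig
) -> tuple[bool, list[str]]:
    """Coding-completeness: MP, CP, RdRP present, MP and RdRP long enough."""
    reasons = []
    for role in ("MP", "CP", "RdRP"):
        if role not in role_orfs:
            reasons.append(f"{role} not found")
    mp = role_orfs.get("MP")
    if mp is not None and mp.length_aa < cfg.min_mp_len_aa:
        reasons.append(f"MP below {cfg.min_mp_len_aa}")
    rdrp = role_orfs.get("RdRP")
    if rdrp is not None and rdrp.length_aa < cfg.min_rdrp_len_aa:
        reasons.append(f"RdRP below {cfg.min_rdrp_len_aa}")
    return (not reasons), reasons


def assign_order(rdrp_cluster: str | None, taxon_map: ClusterTaxonMap) -> str:
    """Order from the RdRP cluster (RdRP_A → Norzivirales, RdRP_B → Timlovirales)."""
    if rdrp_cluster is None:
        return UNASSIGNED
    order = taxon_map.order_of(rdrp_cluster)
    if order is None:
        raise KeyError(f"RdRP cluster {rdrp_cluster!r} absent from the taxon map")
    return order


def assign_family(
    cp_cluster: str | None, order_from_rdrp: str, taxon_map: ClusterTaxonMap
) -> tuple[str, str, bool, str | None]:
    """(family, order, incongruent, note).

    An incongruent CP/RdRP combination (family's parent order differs from
    the RdRP-derived order) leaves both ranks unassigned.
    """
    if cp_cluster is None:
        return UNASSIGNED, order_from_rdrp, False, None
    hit = taxon_map.family_of(cp_cluster)
    if hit is None:
        return (
            UNASSIGNED,
            order_from_rdrp,
            False,
            f"CP cluster {cp_cluster} unmapped (novel family candidate)",
        )
    family, parent = hit
    if order_from_rdrp != UNASSIGNED and parent != order_from_rdrp:
        return (
            UNASSIGNED,
            UNASSIGNED,
            True,
            f"incongruent: CP {cp_cluster} implies {family} ({parent}) "
            f"but RdRP implies {order_from_rdrp}",
        )
    return family, order_from_rdrp, False, None


def assign_genus_species(
    query_rdrp: ProteinRecord,
    reference: list[ReferenceMember],
    cfg: DemarcationConfig,
    novel_counter: dict[str, int] | None = None,
) -> tuple[str, str, bool, bool]:
    """(genus_id, species_id, novel_genus, novel_species) by PAAI adoption.

    The query adopts the genus of its best reference match at ≥ genus_paai,
    then (within that genus) the species of its best match at ≥ species_paai;
    failing either step it founds a deterministic novel taxon.
    """
    counter = novel_counter if novel_counter is not None else {}
    best_val, best_member = -1.0, None
    per_member: list[tuple[float, ReferenceMember]] = []
    for member in reference:
        v = paai(query_rdrp, member.protein)
        per_member.append((v, member))
        if v > best_val:
            best_val, best_member = v, member
    if best_member is None or best_val < cfg.genus_paai:
        counter["genus"] = counter.get("genus", 0) + 1
        k = counter["genus"]
        return f"novel_genus_{k}", f"novel_genus_{k}_species_1", True, True
    genus = best_member.genus_id
    in_genus = [(v, m) for v, m in per_member if m.genus_id == genus]
    sp_val, sp_member = max(in_genus, key=lambda t: t[0])
    if sp_val >= cfg.species_paai:
        return genus, sp_member.species_id, False, False
    key = f"species:{genus}"
    counter[key] = counter.get(key, 0) + 1
    return genus, f"{genus}_novel_species_{counter[key]}", False, True


def _pick_role_orfs(
    orfs: list[OpenReadingFrame], hits_by_protein: dict
) -> dict[str, tuple[OpenReadingFrame, object]]:
    """Best ORF per role: highest bit score, ties by longer ORF then start."""
    chosen: dict[str, tuple[OpenReadingFrame, object]] = {}
    for orf in orfs:
        roles = hits_by_protein.get(orf.protein.id, {})
        for role, hit in roles.items():
            cur = chosen.get(role)
            key = (hit.bit_score, orf.length_aa, -orf.start)
            if cur is None or key > (cur[1].bit_score, cur[0].length_aa, -cur[0].start):
                chosen[role] = (orf, hit)
    return chosen


def classify_genomes(
    genomes: list[GenomeRecord],
    library: list[ProfileHMM],
    reference: list[ReferenceMember] | None = None,
    cfg: DemarcationConfig | None = None,
) -> list[TaxonomyCall]:
    """Classify genomes end to end; per-genome failures are recorded, not fatal."""
    cfg = cfg or DemarcationConfig()
    reference = reference or []
    calls: list[TaxonomyCall] = []
    novel_counter: dict[str, int] = {}
    for genome in genomes:
        call = TaxonomyCall(genome_id=genome.id)
        orfs = find_orfs(genome, min_len_aa=cfg.min_orf_len_aa)
        call.notes.append(f"orfs={len(orfs)}")
        if orfs:
            table = scan([o.protein for o in orfs], library)
            by_protein = best_hits(table)
            chosen = _pick_role_orfs(orfs, by_protein)
            for role, (orf, hit) in chosen.items():
                orf.role = role
                call.roles_found[role] = orf
                if role == "RdRP":
                    call.rdrp_cluster = hit.hmm_name
                elif role == "CP":
                    call.cp_cluster = hit.hmm_name
        call.complete, reasons = check_completeness(call.roles_found, cfg)
        call.notes.extend(reasons)
        order = assign_order(call.rdrp_cluster, cfg.cluster_taxon_map)
        family, order, incongruent, note = assign_family(
            call.cp_cluster, order, cfg.cluster_taxon_map
        )
        call.order, call.family, call.incongruent = order, family, incongruent
        if note:
            call.notes.append(note)
        # incongruent genomes keep their genus/species: the demarcation runs on
        # the RdRP whenever one was confidently found on a complete genome
        if call.complete and call.rdrp_cluster is not None:
            genus, species, novel_g, novel_s = assign_genus_species(
                call.roles_found["RdRP"].protein, reference, cfg, novel_counter
            )
            call.genus_id, call.species_id = genus, species
            if novel_g:
                call.notes.append("novel genus")
            elif novel_s:
                call.notes.append("novel species")
        calls.append(call)
    return calls


def calls_to_frame(calls: list[TaxonomyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "genome_id": c.genome_id,
                "complete": c.complete,
                "mp_len": c.role_len("MP") or 0,
                "cp_len": c.role_len("CP") or 0,
                "rdrp_len": c.role_len("RdRP") or 0,
                "rdrp_cluster": c.rdrp_cluster or "",
                "cp_cluster": c.cp_cluster or "",
                "order": c.order,
                "family": c.family,
                "genus_id": c.genus_id or "",
                "species_id": c.species_id or "",
                "incongruent": c.incongruent,
                "notes": ";".join(c.notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "complete", "mp_len", "cp_len", "rdrp_len",
            "rdrp_cluster", "cp_cluster", "order", "family",
            "genus_id", "species_id", "incongruent", "notes",
        ],
    )


def write_calls(calls: list[TaxonomyCall], path) -> None:
    with atomic_open(path) as fh:
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)
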