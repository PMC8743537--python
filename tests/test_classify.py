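"""Completeness filter, rank assignment, incongruence rule and the full classifier."""

import numpy as np
import pytest

from levitax.classify import (
    DemarcationConfig,
    ReferenceMember,
    assign_family,
    assign_genus_species,
    assign_order,
    calls_to_frame,
    check_completeness,
    classify_genomes,
)
from levitax.orfs import OpenReadingFrame
from levitax.seq_io import ProteinRecord, read_cluster_taxon_map
from levitax.simulate import mutate_protein

MAP = read_cluster_taxon_map()


def _orf(role, length):
    seq = ("M" + "KVLWAERTY" * 60)[:length]
    return OpenReadingFrame(
        genome_id="g", start=0, end=3 * (length + 1), strand="+", frame=0,
        protein=ProteinRecord(f"g|{role}", seq), role=role,
    )


class TestCompleteness:
    def test_threshold_lengths_are_inclusive(self):
        roles = {"MP": _orf("MP", 350), "CP": _orf("CP", 130), "RdRP": _orf("RdRP", 500)}
        ok, reasons = check_completeness(roles, DemarcationConfig())
        assert ok and reasons == []

    @pytest.mark.parametrize(
        "mp,rdrp,expect",
        [(349, 500, "MP below 350"), (350, 499, "RdRP below 500")],
    )
    def test_one_below_threshold_fails_with_reason(self, mp, rdrp, expect):
        roles = {"MP": _orf("MP", mp), "CP": _orf("CP", 130), "RdRP": _orf("RdRP", rdrp)}
        ok, reasons = check_completeness(roles, DemarcationConfig())
        assert not ok
        assert expect in reasons

    def test_missing_role_reported(self):
        roles = {"MP": _orf("MP", 400), "RdRP": _orf("RdRP", 540)}
        ok, reasons = check_completeness(roles, DemarcationConfig())
        assert not ok
        assert "CP not found" in reasons

    def test_relaxing_rdrp_threshold_is_monotone(self):
        """Every genome complete at a strict cutoff stays complete at a looser one."""
        rng = np.random.default_rng(0)
        lengths = rng.integers(420, 620, size=30)
        complete_at = {}
        for cutoff in (560, 520, 480):
            cfg = DemarcationConfig(min_rdrp_len_aa=cutoff)
            complete_at[cutoff] = {
                int(n)
                for n in lengths
                if check_completeness(
                    {"MP": _orf("MP", 400), "CP": _orf("CP", 130),
                     "RdRP": _orf("RdRP", int(n))},
                    cfg,
                )[0]
            }
        assert complete_at[560] <= complete_at[520] <= complete_at[480]


class TestRankAssignment:
    def test_rdrp_clusters_map_to_orders(self):
        assert assign_order("RdRP_A", MAP) == "Norzivirales"
        assert assign_order("RdRP_B", MAP) == "Timlovirales"
        assert assign_order(None, MAP) == "Unassigned"

    def test_unknown_rdrp_cluster_is_error(self):
        with pytest.raises(KeyError):
            assign_order("RdRP_Z", MAP)

    def test_congruent_cp_gives_family(self):
        family, order, incongruent, _ = assign_family("CP_A", "Norzivirales", MAP)
        assert (family, order, incongruent) == ("Fiersviridae", "Norzivirales", False)

    def test_incongruent_combination_unassigns_both(self):
        family, order, incongruent, note = assign_family("CP_E", "Norzivirales", MAP)
        assert (family, order) == ("Unassigned", "Unassigned")
        assert incongruent
        assert "incongruent" in note

    def test_missing_cp_keeps_order(self):
        family, order, incongruent, _ = assign_family(None, "Norzivirales", MAP)
        assert (family, order, incongruent) == ("Unassigned", "Norzivirales", False)

    def test_unmapped_cp_cluster_notes_novel_family(self):
        family, order, incongruent, note = assign_family("CP_Q", "Norzivirales", MAP)
        assert family == "Unassigned"
        assert not incongruent
        assert "novel family" in note

    def test_incongruence_fuzz_matches_parent_order_rule(self):
        """Every mismatched CP/RdRP pair double-unassigns; congruent never does."""
        rng = np.random.default_rng(99)
        cp_ids = MAP.cp_clusters
        rdrp_ids = MAP.rdrp_clusters
        for _ in range(500):
            cp = cp_ids[rng.integers(len(cp_ids))]
            rd = rdrp_ids[rng.integers(len(rdrp_ids))]
            order = assign_order(rd, MAP)
            family, order_out, incongruent, _ = assign_family(cp, order, MAP)
            expected_family, parent = MAP.family_of(cp)
            if parent != order:
                assert incongruent
                assert family == order_out == "Unassigned"
            else:
                assert not incongruent
                assert family == expected_family
                assert order_out == order


class TestGenusSpeciesAdoption:
    def _reference(self, rng):
        anc = ProteinRecord("ref_anc", "M" + "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=400)))
        members = []
        for s in range(2):
            sp = mutate_protein(anc, 84, rng, new_id=f"sp{s}")
            for m in range(2):
                members.append(
                    ReferenceMember(
                        protein=mutate_protein(sp, 96, rng, new_id=f"sp{s}_m{m}"),
                        genus_id="genus_ref",
                        species_id=f"species_{s}",
                    )
                )
        return members

    def test_identical_query_adopts_genus_and_species(self):
        rng = np.random.default_rng(21)
        ref = self._reference(rng)
        g, s, ng, ns = assign_genus_species(ref[0].protein, ref, DemarcationConfig())
        assert (g, s, ng, ns) == ("genus_ref", "species_0", False, False)

    def test_genus_level_query_founds_new_species(self):
        rng = np.random.default_rng(22)
        ref = self._reference(rng)
        query = mutate_protein(ref[0].protein, 62, rng, new_id="q")
        g, s, ng, ns = assign_genus_species(query, ref, DemarcationConfig())
        assert g == "genus_ref"
        assert ns and not ng
        assert s.startswith("genus_ref_novel_species")

    def test_empty_reference_founds_novel_genus(self):
        q = ProteinRecord("q", "MKVLW" * 30)
        g, s, ng, ns = assign_genus_species(q, [], DemarcationConfig())
        assert ng and ns
        assert g == "novel_genus_1"


class TestEndToEnd:
    def test_reference_set_classifies_to_itself(self, mini_dataset, mini_library, mini_config):
        """Idempotence: every member recovers its own planted taxonomy."""
        calls = classify_genomes(
            mini_dataset.genomes, mini_library,
            reference=mini_dataset.rdrp_reference(), cfg=mini_config,
        )
        truth = mini_dataset.truth.table.set_index("id")
        assert len(calls) == len(truth)
        for c in calls:
            row = truth.loc[c.genome_id]
            assert c.complete, c.notes
            assert not c.incongruent
            assert c.order == row.order
            assert c.family == row.family
            assert c.genus_id == row.genus_id
            assert c.species_id == row.species_id

    def test_runs_are_byte_identical(self, mini_dataset, mini_library, mini_config, tmp_path):
        from levitax.classify import write_calls

        args = dict(reference=mini_dataset.rdrp_reference(), cfg=mini_config)
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        write_calls(classify_genomes(mini_dataset.genomes[:6], mini_library, **args), a)
        write_calls(classify_genomes(mini_dataset.genomes[:6], mini_library, **args), b)
        assert a.read_bytes() == b.read_bytes()

    def test_incomplete_genome_keeps_upper_ranks_only(self, mini_dataset, mini_library, mini_config):
        """Truncating the genome before the RdRP drops completeness and
        genus/species but retains the evidence-backed upper ranks."""
        from levitax.seq_io import GenomeRecord

        g = mini_dataset.genomes[0]
        truncated = GenomeRecord(g.id, g.sequence[: len(g.sequence) // 2], source="synthetic")
        (call,) = classify_genomes(
            [truncated], mini_library,
            reference=mini_dataset.rdrp_reference(), cfg=mini_config,
        )
        assert not call.complete
        assert call.genus_id is None and call.species_id is None

    def test_empty_genome_list(self, mini_library, mini_config):
        assert classify_genomes([], mini_library, cfg=mini_config) == []

    def test_calls_frame_has_contracted_columns(self, mini_dataset, mini_library, mini_config):
        calls = classify_genomes(
            mini_dataset.genomes[:2], mini_library,
            reference=mini_dataset.rdrp_reference(), cfg=mini_config,
        )
        df = calls_to_frame(calls)
        assert list(df.columns) == [
            "genome_id", "complete", "mp_len", "cp_len", "rdrp_len",
            "rdrp_cluster", "cp_cluster", "order", "family",
            "genus_id", "species_id", "incongruent", "notes",
        ]
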