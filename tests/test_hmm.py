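"""Profile-HMM construction, scoring (vs exhaustive path enumeration) and HMMER3 I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from levitax.align import ALPHABET
from levitax.hmm import (
    BACKGROUND,
    MultipleAlignment,
    build_profile,
    forward_bits,
    read_hmmer3,
    role_of,
    scan,
    star_align,
    viterbi_bits,
    viterbi_score_bits,
    write_hmmer3,
)
from levitax.seq_io import ProteinRecord
from levitax.simulate import mutate_protein

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# independent oracle: enumerate every legal path and placement
# ---------------------------------------------------------------------------

def enumerate_path_scores(hmm, seq: str) -> list[float]:
    """Natural-log odds of every legal (prefix offset, core path) combination."""
    lm, li, tmm, tmi, tmd, tim, tii, tdm, tdd = hmm._log_params()
    idx = [ALPHABET.index(c) for c in seq]
    L, M = len(idx), hmm.M
    out: list[float] = []

    def rec(node, state, i, score):
        if node == M and state in ("M", "D"):
            out.append(score)  # free suffix
            return
        if state in ("B", "M"):
            if i < L:
                rec(node + 1, "M", i + 1, score + tmm[node] + lm[node + 1, idx[i]])
            if state == "M" and 1 <= node <= M - 1 and i < L:
                rec(node, "I", i + 1, score + tmi[node] + li[node, idx[i]])
            rec(node + 1, "D", i, score + tmd[node])
        elif state == "I":
            if i < L:
                rec(node, "I", i + 1, score + tii[node] + li[node, idx[i]])
                rec(node + 1, "M", i + 1, score + tim[node] + lm[node + 1, idx[i]])
        else:  # D
            if i < L:
                rec(node + 1, "M", i + 1, score + tdm[node] + lm[node + 1, idx[i]])
            rec(node + 1, "D", i, score + tdd[node])

    for s in range(L + 1):
        rec(0, "B", s, 0.0)
    return out


def _logsumexp(vals):
    m = max(vals)
    return m + math.log(sum(math.exp(v - m) for v in vals))


def _tiny_profiles():
    msas = [
        MultipleAlignment(ids=["s1"], rows=["A"]),
        MultipleAlignment(ids=["s1"], rows=["MKV"]),
        MultipleAlignment(ids=["s1", "s2"], rows=["MK", "M-"]),
        MultipleAlignment(ids=["s1", "s2", "s3"], rows=["MKV", "MRV", "M-V"]),
        MultipleAlignment(ids=["s1", "s2"], rows=["AC-W", "A-GW"]),
    ]
    return [build_profile(m, name=f"tiny{i}") for i, m in enumerate(msas)]


QUERIES = ["A", "M", "MK", "MKV", "KVW", "AXC", "W"]


@pytest.mark.parametrize("qi", range(len(QUERIES)))
def test_viterbi_and_forward_match_exhaustive_enumeration(qi):
    """All profiles with M <= 3 scored on queries with L <= 3."""
    q = QUERIES[qi]
    prot = ProteinRecord("q", q)
    for hmm in _tiny_profiles():
        assert hmm.M <= 4
        scores = enumerate_path_scores(hmm, q)
        v = viterbi_score_bits(hmm, prot)
        f = forward_bits(hmm, prot)
        assert v == pytest.approx(max(scores) / _LN2, abs=1e-9)
        assert f == pytest.approx(_logsumexp(scores) / _LN2, abs=1e-9)
        assert f >= v - 1e-12


_LEGAL = {
    "B": lambda n, k, s: (s == "M" and k == 1) or (s == "D" and k == 1),
}


def _path_is_legal(path, M):
    prev_state, prev_node = "B", 0
    for step in path:
        s, k = step[0], int(step[1:])
        if prev_state in ("B", "M"):
            ok = (
                (s == "M" and k == prev_node + 1)
                or (s == "D" and k == prev_node + 1)
                or (s == "I" and k == prev_node and 1 <= k <= M - 1 and prev_state == "M")
            )
        elif prev_state == "I":
            ok = (s == "M" and k == prev_node + 1) or (s == "I" and k == prev_node)
        else:  # D
            ok = (s == "M" and k == prev_node + 1) or (s == "D" and k == prev_node + 1)
        if not ok:
            return False
        prev_state, prev_node = s, k
    return prev_node == M and prev_state in ("M", "D")


def test_viterbi_path_is_legal_and_scores_match():
    for hmm in _tiny_profiles():
        for q in QUERIES:
            prot = ProteinRecord("q", q)
            score, path = viterbi_bits(hmm, prot)
            assert score == pytest.approx(viterbi_score_bits(hmm, prot), abs=1e-9)
            assert _path_is_legal(path, hmm.M), (path, hmm.name, q)


def test_forward_at_least_viterbi_on_larger_profiles(mini_dataset, mini_library):
    prots = mini_dataset.proteins[:4]
    for hmm in mini_library[:3]:
        for p in prots:
            assert forward_bits(hmm, p) >= viterbi_score_bits(hmm, p) - 1e-9


class TestBuildProfile:
    def test_single_sequence_emissions_peak_at_observed_residue(self):
        hmm = build_profile(MultipleAlignment(ids=["s"], rows=["MKV"]))
        assert hmm.M == 3
        amino = ALPHABET[:20]
        assert amino[int(np.argmax(hmm.match_emissions[0]))] == "M"
        assert amino[int(np.argmax(hmm.match_emissions[1]))] == "K"

    def test_duplicated_rows_converge_to_single_row_at_tiny_pseudocount(self):
        one = build_profile(
            MultipleAlignment(ids=["a"], rows=["MKV"]), pseudocount_weight=1e-9
        )
        two = build_profile(
            MultipleAlignment(ids=["a", "b"], rows=["MKV", "MKV"]),
            pseudocount_weight=1e-9,
        )
        np.testing.assert_allclose(one.match_emissions, two.match_emissions, atol=1e-8)

    def test_gap_majority_column_becomes_insert_state(self):
        # hand census: column 3 is non-gap in 1 of 3 rows -> insert; M = 3
        msa = MultipleAlignment(ids=["a", "b", "c"], rows=["MK-V", "MKA-", "MK-V"])
        hmm = build_profile(msa, match_fraction=0.5)
        assert hmm.M == 3

    def test_no_match_column_is_error(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError, match="match state"):
            build_profile(msa, match_fraction=1.0)

    def test_row_order_permutation_leaves_profile_unchanged(self):
        rows = ["MKVW", "MRVW", "M-VW"]
        a = build_profile(MultipleAlignment(ids=list("abc"), rows=rows))
        b = build_profile(MultipleAlignment(ids=list("cba"), rows=rows[::-1]))
        np.testing.assert_allclose(a.match_emissions, b.match_emissions)
        np.testing.assert_allclose(a.t_mm, b.t_mm)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_msas_yield_normalized_profiles(self, data):
        nrow = data.draw(st.integers(1, 5))
        ncol = data.draw(st.integers(1, 8))
        alphabet = ALPHABET[:20] + "-"
        rows = [
            "".join(data.draw(st.sampled_from(alphabet)) for _ in range(ncol))
            for _ in range(nrow)
        ]
        if all(set(r) == {"-"} for r in rows):
            rows[0] = "A" + rows[0][1:]
        msa = MultipleAlignment(ids=[f"s{i}" for i in range(nrow)], rows=rows)
        try:
            hmm = build_profile(msa)
        except ValueError:
            return  # no qualifying match column
        # ProfileHMM.__post_init__ enforces all normalization invariants
        assert hmm.M >= 1


class TestHmmer3:
    def test_round_trip_preserves_probabilities(self, tmp_path, mini_library):
        path = tmp_path / "lib.hmm"
        write_hmmer3(mini_library, path)
        back = read_hmmer3(path)
        assert [h.name for h in back] == [h.name for h in mini_library]
        for ours, rt in zip(mini_library, back):
            np.testing.assert_allclose(
                rt.match_emissions, ours.match_emissions, atol=1e-5
            )
            np.testing.assert_allclose(rt.t_mm, ours.t_mm, atol=1e-5)
            np.testing.assert_allclose(rt.t_dd, ours.t_dd, atol=1e-5)

    def test_round_trip_of_random_profiles(self, tmp_path):
        rng = np.random.default_rng(31)
        amino = ALPHABET[:20]
        hmms = []
        for i in range(10):
            n = int(rng.integers(2, 6))
            rows = [
                "".join(amino[j] for j in rng.choice(20, size=7))
                for _ in range(n)
            ]
            hmms.append(
                build_profile(
                    MultipleAlignment(ids=[f"s{k}" for k in range(n)], rows=rows),
                    name=f"rand_{i}",
                )
            )
        path = tmp_path / "rand.hmm"
        write_hmmer3(hmms, path)
        back = read_hmmer3(path)
        for ours, rt in zip(hmms, back):
            np.testing.assert_allclose(rt.match_emissions, ours.match_emissions, atol=1e-5)
            np.testing.assert_allclose(rt.insert_emissions, ours.insert_emissions, atol=1e-5)
            for attr in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
                np.testing.assert_allclose(
                    getattr(rt, attr), getattr(ours, attr), atol=1e-5, err_msg=attr
                )

    def test_dna_alphabet_is_rejected(self, tmp_path):
        path = tmp_path / "dna.hmm"
        path.write_text("HMMER3/f [x]\nNAME  d\nLENG  1\nALPH  DNA\nHMM\n//\n")
        with pytest.raises(ValueError, match="alphabet"):
            read_hmmer3(path)

    def test_minimal_hand_written_single_node_profile(self, tmp_path):
        """Fixture authored against the published HMMER3 ASCII layout."""
        flat = f"{math.log(20):.5f}"
        lines = [
            "HMMER3/f [hand]",
            "NAME  mini",
            "LENG  1",
            "ALPH  amino",
            "HMM  " + "  ".join(ALPHABET[:20]),
            "  m->m m->i m->d i->m i->i d->m d->d",
            "  " + " ".join([flat] * 20),  # node 0 insert emissions
            "  0.10536 * 2.30259 0.00000 * 0.00000 *",  # B->M1=0.9, B->D1=0.1
            "  1  " + " ".join([flat] * 20),
            "  " + " ".join([flat] * 20),
            "  0.00000 * * 0.00000 * 0.00000 *",
            "//",
        ]
        path = tmp_path / "mini.hmm"
        path.write_text("\n".join(lines) + "\n")
        (hmm,) = read_hmmer3(path)
        assert hmm.name == "mini"
        assert hmm.M == 1
        assert hmm.t_mm[0] == pytest.approx(0.9, abs=1e-5)
        np.testing.assert_allclose(hmm.match_emissions[0], 0.05, atol=1e-5)

    def test_truncated_node_table_reports_node(self, tmp_path, mini_library):
        path = tmp_path / "lib.hmm"
        write_hmmer3(mini_library[:1], path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:20] + ["//"]) + "\n")
        with pytest.raises(ValueError, match="node"):
            read_hmmer3(path)

    def test_pyhmmer_reads_our_library(self, tmp_path, mini_library):
        """Interoperability oracle: HMMER's own parser accepts our files."""
        pyhmmer = pytest.importorskip("pyhmmer")
        path = tmp_path / "lib.hmm"
        write_hmmer3(mini_library[:2], path)
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            theirs = list(fh)
        names = [h.name.decode() if isinstance(h.name, bytes) else h.name for h in theirs]
        assert names == [h.name for h in mini_library[:2]]
        assert [h.M for h in theirs] == [h.M for h in mini_library[:2]]


class TestScan:
    def test_training_family_member_best_hit_is_its_cluster(self, mini_dataset, mini_library):
        msa = mini_dataset.msas["CP_A"]
        seed_prot = ProteinRecord("probe_src", msa.rows[0])
        probe = mutate_protein(seed_prot, 95, 42, new_id="probe")
        table = scan([probe], mini_library)
        passing = table[table.passes]
        assert not passing.empty
        best = passing.sort_values("bit_score", ascending=False).iloc[0]
        assert best.hmm_name == "CP_A"

    def test_all_x_protein_passes_nothing(self, mini_library):
        table = scan([ProteinRecord("x", "X" * 80)], mini_library)
        assert not table.passes.any()
        assert (table.bit_score <= 0).all()

    def test_empty_protein_list_gives_empty_table(self, mini_library):
        table = scan([], mini_library)
        assert table.empty

    def test_score_ignores_id_and_description(self, mini_library):
        a = ProteinRecord("one", "MKVLLAWDE", description="x")
        b = ProteinRecord("two", "MKVLLAWDE", description="y")
        hmm = mini_library[0]
        assert viterbi_score_bits(hmm, a) == viterbi_score_bits(hmm, b)


def test_role_inference():
    assert role_of("CP_A") == "CP"
    assert role_of("RdRP_B") == "RdRP"
    assert role_of("MP_1") == "MP"
    assert role_of("AP205-like") == "CP"
    assert role_of("novel_CP_2") == "CP"
    assert role_of("whatever") is None


def test_star_alignment_covers_all_members(mini_dataset):
    msa = mini_dataset.msas["RdRP_A"]
    prots = [ProteinRecord(i, r.replace("-", "")) for i, r in zip(msa.ids[:5], msa.rows[:5])]
    aligned = star_align(prots)
    assert aligned.n_rows == 5
    for p, row in zip(prots, aligned.rows):
        assert row.replace("-", "") == p.sequence
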