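"""Profile hidden Markov models for the MP/CP/RdRP cluster library.

A Plan7-style architecture (match/insert/delete nodes) scored in log-odds
against a fixed amino-acid background, local in the sequence (unmatched
query prefix/suffix is free) and global in the model (every node is passed
through a match or delete state).  There is no bias correction and no
E-value calibration: acceptance is a per-profile bit-score threshold,
25 bits by default.

Generative model, per profile of M nodes:
  B → M1 | D1;  Mk → M(k+1) | Ik | D(k+1);  Ik → M(k+1) | Ik;
  Dk → M(k+1) | D(k+1);  MM → E, DM → E (probability 1).
The score of a path is Σ log2(e_state(x)/bg(x)) + Σ log2(t); flanking
residues outside the modelled region contribute nothing.  'X' always emits
the background frequency (zero log-odds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .align import ALPHABET, _encoded, encode
from .seq_io import ProteinRecord, atomic_open

AMINO = ALPHABET[:20]  # match-state emission alphabet (X handled separately)

#: Robinson–Robinson amino-acid frequencies, indexed like AMINO.
BACKGROUND = np.array(
    [
        0.0787945,  # A
        0.0151600,  # C
        0.0535222,  # D
        0.0668298,  # E
        0.0397062,  # F
        0.0695071,  # G
        0.0229198,  # H
        0.0590092,  # I
        0.0594422,  # K
        0.0963728,  # L
        0.0237718,  # M
        0.0414386,  # N
        0.0482904,  # P
        0.0395639,  # Q
        0.0540978,  # R
        0.0683364,  # S
        0.0540687,  # T
        0.0673417,  # V
        0.0114135,  # W
        0.0304133,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

DEFAULT_SCORE_THRESHOLD_BITS = 25.0
_LN2 = math.log(2.0)


@dataclass
class MultipleAlignment:
    """An aligned protein family (rows of equal length, gap '-')."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        self.rows = [r.upper() for r in self.rows]
        if all(set(col) == {"-"} for col in zip(*self.rows)):
            raise ValueError("alignment has no non-gap column")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class ProfileHMM:
    """A protein profile with M match nodes over the 20-letter alphabet.

    Transition arrays are indexed by source node 0..M-1, node 0 being the
    begin state (t_mm[0] = B→M1, t_md[0] = B→D1); transitions out of node M
    go to the end state with probability 1 and are implicit.
    """

    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M, 20)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    score_threshold_bits: float = DEFAULT_SCORE_THRESHOLD_BITS

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("profile needs at least one match state")
        if np.any(self.background <= 0):
            raise ValueError("background must be strictly positive")
        for arr, what in ((self.match_emissions, "match"), (self.insert_emissions, "insert")):
            if arr.shape != (self.M, 20):
                raise ValueError(f"{what} emissions must be (M, 20)")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{what} emission rows must sum to 1")
        groups = [
            self.t_mm[0] + self.t_md[0],
            *(self.t_mm[1:] + self.t_mi[1:] + self.t_md[1:]),
            *(self.t_im[1:] + self.t_ii[1:]),
            *(self.t_dm[1:] + self.t_dd[1:]),
        ]
        if not np.allclose(groups, 1.0, atol=1e-9):
            raise ValueError("outgoing transition groups must each sum to 1")

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def role(self) -> str | None:
        return role_of(self.name)

    # -- scoring parameterization (natural-log odds), cached lazily -------
    def _log_params(self):
        cached = getattr(self, "_cache", None)
        if cached is not None:
            return cached
        M = self.M
        lbg = np.log(self.background)
        lm = np.full((M + 1, 21), 0.0)
        li = np.full((M + 1, 21), 0.0)
        with np.errstate(divide="ignore"):
            lm[1:, :20] = np.log(self.match_emissions) - lbg
            li[1:, :20] = np.log(self.insert_emissions) - lbg
        # X (index 20) emits background: log-odds 0 (already)
        lm[np.isnan(lm)] = _kernels.NEG_INF
        li[np.isnan(li)] = _kernels.NEG_INF

        def safe_log(v):
            out = np.full(len(v), _kernels.NEG_INF)
            pos = v > 0
            out[pos] = np.log(v[pos])
            return out

        params = (
            lm,
            li,
            safe_log(self.t_mm),
            safe_log(self.t_mi),
            safe_log(self.t_md),
            safe_log(self.t_im),
            safe_log(self.t_ii),
            safe_log(self.t_dm),
            safe_log(self.t_dd),
        )
        self._cache = params
        return params


def role_of(name: str) -> str | None:
    """Infer the core-protein role from a cluster/profile name."""
    if name.startswith("AP205"):
        return "CP"
    for role in ("RdRP", "MP", "CP"):
        if name.startswith(role) or f"_{role}_" in name or name.endswith(f"_{role}"):
            return role
    return None


@dataclass
class HmmHit:
    protein_id: str
    hmm_name: str
    bit_score: float
    passes: bool

    @property
    def role(self) -> str | None:
        return role_of(self.hmm_name)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profile(
    msa: MultipleAlignment,
    match_fraction: float = 0.5,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
    score_threshold_bits: float = DEFAULT_SCORE_THRESHOLD_BITS,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile from an alignment.

    Columns with non-gap fraction ≥ match_fraction become match nodes.
    Match emissions are (counts + pseudocount_weight·background) normalized;
    insert emissions are the background itself.  Transitions are counted from
    the per-row state walks and Laplace-smoothed with pseudocount_weight.
    Insert residues before the first or after the last match column are
    treated as flanking sequence and ignored.
    """
    if not (0 < match_fraction <= 1):
        raise ValueError("match_fraction must be in (0, 1]")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = BACKGROUND if background is None else background
    nrow = msa.n_rows
    cols = list(zip(*msa.rows))
    is_match = [
        sum(c != "-" for c in col) / nrow >= match_fraction for col in cols
    ]
    M = sum(is_match)
    if M == 0:
        raise ValueError("no column qualifies as a match state")

    counts = np.zeros((M, 20))
    aa_index = {c: i for i, c in enumerate(AMINO)}
    node_of_col = np.cumsum(is_match)  # 1-based node for match columns

    # transition counts, indexed by source node 0..M-1
    c_mm = np.zeros(M)
    c_mi = np.zeros(M)
    c_md = np.zeros(M)
    c_im = np.zeros(M)
    c_ii = np.zeros(M)
    c_dm = np.zeros(M)
    c_dd = np.zeros(M)

    match_cols = [j for j, m in enumerate(is_match) if m]
    first_mc, last_mc = match_cols[0], match_cols[-1]

    for row in msa.rows:
        state, node = "M", 0  # begin behaves like a match state at node 0
        for j, ch in enumerate(row):
            if is_match[j]:
                k = node_of_col[j]  # target node
                new_state = "M" if ch != "-" else "D"
                src = node
                if state == "M":
                    (c_mm if new_state == "M" else c_md)[src] += 1
                elif state == "I":
                    # I→D is not a Plan7 move; count the legal I→M instead
                    c_im[src] += 1
                else:  # D
                    (c_dm if new_state == "M" else c_dd)[src] += 1
                if new_state == "M" and ch in aa_index:
                    counts[k - 1, aa_index[ch]] += 1
                state, node = new_state, k
            elif ch != "-" and first_mc < j < last_mc and 1 <= node <= M - 1:
                # insert residue between match columns
                if state == "M":
                    c_mi[node] += 1
                elif state == "I":
                    c_ii[node] += 1
                # D→I is not a Plan7 move; treated as flanking of the D run
                if state in ("M", "I"):
                    state = "I"
        # final transition into E is implicit

    w = pseudocount_weight
    match_emissions = counts + w * bg
    match_emissions /= match_emissions.sum(axis=1, keepdims=True)
    insert_emissions = np.tile(bg, (M, 1))

    def norm(parts):
        tot = sum(parts) + len(parts) * w
        return [(p + w) / tot for p in parts]

    t_mm = np.zeros(M)
    t_mi = np.zeros(M)
    t_md = np.zeros(M)
    t_im = np.zeros(M)
    t_ii = np.zeros(M)
    t_dm = np.zeros(M)
    t_dd = np.zeros(M)
    t_mm[0], t_md[0] = norm([c_mm[0], c_md[0]])
    for k in range(1, M):
        t_mm[k], t_mi[k], t_md[k] = norm([c_mm[k], c_mi[k], c_md[k]])
        t_im[k], t_ii[k] = norm([c_im[k], c_ii[k]])
        t_dm[k], t_dd[k] = norm([c_dm[k], c_dd[k]])

    return ProfileHMM(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        t_mm=t_mm,
        t_mi=t_mi,
        t_md=t_md,
        t_im=t_im,
        t_ii=t_ii,
        t_dm=t_dm,
        t_dd=t_dd,
        background=bg.copy(),
        score_threshold_bits=score_threshold_bits,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def viterbi_bits(hmm: ProfileHMM, protein: ProteinRecord) -> tuple[float, list[str]]:
    """Optimal path score in bits and the core state path (e.g. ['M1','I1','M2'])."""
    x = _encoded(protein)
    if len(x) == 0:
        raise ValueError("empty protein")
    score, end_i, end_state, PM, PI, PD = _kernels.hmm_viterbi_ptr(
        x, *hmm._log_params()
    )
    # reconstruct path
    path: list[str] = []
    i, k, state = end_i, hmm.M, end_state  # 0=M, 1=I, 2=D
    while True:
        if state == 0:
            path.append(f"M{k}")
            p = PM[i, k]
            if p == 3:
                break
            i, k, state = i - 1, k - 1, int(p)
        elif state == 1:
            path.append(f"I{k}")
            p = PI[i, k]
            i, state = i - 1, int(p)
        else:
            path.append(f"D{k}")
            p = PD[i, k]
            if p == 2:
                break
            if p == 0:
                k, state = k - 1, 0
            else:
                k, state = k - 1, 2
    path.reverse()
    return float(score) / _LN2, path


def viterbi_score_bits(hmm: ProfileHMM, protein: ProteinRecord) -> float:
    x = _encoded(protein)
    if len(x) == 0:
        raise ValueError("empty protein")
    return float(_kernels.hmm_viterbi(x, *hmm._log_params())) / _LN2


def forward_bits(hmm: ProfileHMM, protein: ProteinRecord) -> float:
    """Log2 of the summed odds over all paths and placements."""
    x = _encoded(protein)
    if len(x) == 0:
        raise ValueError("empty protein")
    return float(_kernels.hmm_forward(x, *hmm._log_params())) / _LN2


def scan(
    proteins: list[ProteinRecord], library: list[ProfileHMM]
) -> pd.DataFrame:
    """Score every protein against every profile.

    Returns a long-format table (protein_id, hmm_name, role, bit_score,
    passes) sorted by protein then descending score.  Use :func:`best_hits`
    to reduce to the best passing hit per protein per role.
    """
    if not library:
        raise ValueError("profile library is empty")
    rows = []
    for prot in proteins:
        for hmm in library:
            s = viterbi_score_bits(hmm, prot)
            rows.append(
                {
                    "protein_id": prot.id,
                    "hmm_name": hmm.name,
                    "role": role_of(hmm.name),
                    "bit_score": s,
                    "passes": s >= hmm.score_threshold_bits,
                }
            )
    table = pd.DataFrame(
        rows, columns=["protein_id", "hmm_name", "role", "bit_score", "passes"]
    )
    if len(table):
        table = table.sort_values(
            ["protein_id", "bit_score"], ascending=[True, False]
        ).reset_index(drop=True)
    return table


def best_hits(table: pd.DataFrame) -> dict[str, dict[str, HmmHit]]:
    """protein_id → role → best passing hit."""
    out: dict[str, dict[str, HmmHit]] = {}
    passing = table[table.passes]
    for (pid, role), grp in passing.groupby(["protein_id", "role"], dropna=True):
        row = grp.loc[grp.bit_score.idxmax()]
        out.setdefault(pid, {})[role] = HmmHit(
            protein_id=pid,
            hmm_name=row.hmm_name,
            bit_score=float(row.bit_score),
            passes=True,
        )
    return out


# ---------------------------------------------------------------------------
# HMMER3 ASCII interchange
# ---------------------------------------------------------------------------

def _fmt(p: float) -> str:
    return "*" if p <= 0 else f"{-math.log(p):.5f}"


def write_hmmer3(hmms: list[ProfileHMM], path) -> None:
    """Serialize profiles in HMMER3/f ASCII (values are −ln probability)."""
    with atomic_open(path) as fh:
        for h in hmms:
            fh.write(f"HMMER3/f [levitax]\n")
            fh.write(f"NAME  {h.name}\n")
            fh.write(f"LENG  {h.M}\n")
            fh.write("ALPH  amino\n")
            fh.write("HMM      " + "   ".join(f"{c:>7}" for c in AMINO) + "\n")
            fh.write(
                "        "
                + "  ".join(
                    f"{t:>8}"
                    for t in ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")
                )
                + "\n"
            )
            fh.write(
                "  COMPO  "
                + " ".join(f"{_fmt(p):>9}" for p in h.background)
                + "\n"
            )
            # node 0: I0 emissions (background) and begin transitions
            fh.write(
                "         " + " ".join(f"{_fmt(p):>9}" for p in h.background) + "\n"
            )
            fh.write(
                "         "
                + " ".join(
                    f"{v:>9}"
                    for v in (
                        _fmt(h.t_mm[0]),
                        "*",
                        _fmt(h.t_md[0]),
                        "0.00000",
                        "*",
                        "0.00000",
                        "*",
                    )
                )
                + "\n"
            )
            for k in range(1, h.M + 1):
                fh.write(
                    f"{k:>7}  "
                    + " ".join(f"{_fmt(p):>9}" for p in h.match_emissions[k - 1])
                    + "      - - - - -\n"
                )
                fh.write(
                    "         "
                    + " ".join(f"{_fmt(p):>9}" for p in h.insert_emissions[k - 1])
                    + "\n"
                )
                if k < h.M:
                    vals = (
                        _fmt(h.t_mm[k]),
                        _fmt(h.t_mi[k]),
                        _fmt(h.t_md[k]),
                        _fmt(h.t_im[k]),
                        _fmt(h.t_ii[k]),
                        _fmt(h.t_dm[k]),
                        _fmt(h.t_dd[k]),
                    )
                else:  # node M: M→E and D→E with probability 1
                    vals = ("0.00000", "*", "*", "0.00000", "*", "0.00000", "*")
                fh.write("         " + " ".join(f"{v:>9}" for v in vals) + "\n")
            fh.write("//\n")


def _parse_prob(tok: str) -> float:
    return 0.0 if tok == "*" else math.exp(-float(tok))


def read_hmmer3(
    path, score_threshold_bits: float = DEFAULT_SCORE_THRESHOLD_BITS
) -> list[ProfileHMM]:
    """Read profiles from a HMMER3 ASCII file (ours or hmmbuild's).

    Only the amino alphabet is supported.  Extra annotation columns on match
    lines (MAP/CONS/RF/MM/CS) and extra header lines (STATS, DATE, ...) are
    tolerated and ignored.
    """
    hmms: list[ProfileHMM] = []
    with open(path, encoding="utf-8") as fh:
        all_lines = fh.read().splitlines()
    blocks: list[list[str]] = []
    cur: list[str] | None = None
    for line in all_lines:
        if line.startswith("HMMER3"):
            cur = [line]
        elif cur is not None:
            if line.strip() == "//":
                blocks.append(cur)
                cur = None
            else:
                cur.append(line)
    if not blocks:
        raise ValueError(f"no HMMER3 profiles found in {path}")

    for block in blocks:
        name, leng, alph = None, None, None
        i = 0
        while i < len(block) and not block[i].lstrip().startswith("HMM "):
            tokens = block[i].split(None, 1)
            if len(tokens) == 2:
                key, val = tokens
                if key == "NAME":
                    name = val.strip()
                elif key == "LENG":
                    leng = int(val)
                elif key == "ALPH":
                    alph = val.strip().lower()
            i += 1
        if alph != "amino":
            raise ValueError(f"unsupported alphabet {alph!r} (only amino)")
        if leng is None or name is None:
            raise ValueError("missing NAME or LENG header")
        i += 2  # skip 'HMM ...' header and the transition-name line
        background = BACKGROUND.copy()
        if i < len(block) and block[i].split()[0] == "COMPO":
            background = np.array(
                [_parse_prob(t) for t in block[i].split()[1:21]]
            )
            i += 1
        i += 1  # node-0 insert emissions (ignored: inserts emit background)
        node0 = [_parse_prob(t) for t in block[i].split()[:7]]
        i += 1
        M = leng
        me = np.zeros((M, 20))
        ie = np.zeros((M, 20))
        t = {k: np.zeros(M) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
        z = node0[0] + node0[2]
        t["mm"][0], t["md"][0] = node0[0] / z, node0[2] / z
        for k in range(1, M + 1):
            if i + 2 >= len(block):
                raise ValueError(f"truncated node table at node {k}")
            mline = block[i].split()
            if not mline or mline[0] != str(k):
                raise ValueError(f"truncated or misnumbered node table at node {k}")
            me[k - 1] = [_parse_prob(tok) for tok in mline[1:21]]
            iline = block[i + 1].split()
            ie[k - 1] = [_parse_prob(tok) for tok in iline[:20]]
            tline = block[i + 2].split()
            if k < M:
                vals = [_parse_prob(tok) for tok in tline[:7]]
                s = sum(vals[:3])
                t["mm"][k], t["mi"][k], t["md"][k] = (v / s for v in vals[:3])
                s = vals[3] + vals[4]
                t["im"][k], t["ii"][k] = vals[3] / s, vals[4] / s
                s = vals[5] + vals[6]
                t["dm"][k], t["dd"][k] = vals[5] / s, vals[6] / s
            i += 3
        me /= me.sum(axis=1, keepdims=True)
        ie /= ie.sum(axis=1, keepdims=True)
        hmms.append(
            ProfileHMM(
                name=name,
                match_emissions=me,
                insert_emissions=ie,
                t_mm=t["mm"],
                t_mi=t["mi"],
                t_md=t["md"],
                t_im=t["im"],
                t_ii=t["ii"],
                t_dm=t["dm"],
                t_dd=t["dd"],
                background=background / background.sum(),
                score_threshold_bits=score_threshold_bits,
            )
        )
    return hmms


# ---------------------------------------------------------------------------
# library helpers
# ---------------------------------------------------------------------------

def build_library(
    msas: dict[str, "MultipleAlignment"], **build_kwargs
) -> list[ProfileHMM]:
    """One profile per named alignment, in sorted name order."""
    return [
        build_profile(msa, name=name, **build_kwargs)
        for name, msa in sorted(msas.items())
    ]


def star_align(proteins: list[ProteinRecord]) -> MultipleAlignment:
    """Star multiple alignment anchored on the longest member.

    Every member is pairwise-aligned to the anchor and projected onto shared
    columns; insertions relative to the anchor are padded across all rows.
    A deliberate simplification of progressive alignment, adequate for
    profile training on pre-clustered families.
    """
    from .align import global_align

    if not proteins:
        raise ValueError("no proteins to align")
    if len(proteins) == 1:
        return MultipleAlignment(ids=[proteins[0].id], rows=[proteins[0].sequence])
    anchor = max(proteins, key=lambda p: (p.length_aa, p.id))
    la = anchor.length_aa
    # per member: residue-or-gap for each anchor column, plus insertions
    # keyed by the anchor column they follow (0 = before the first column)
    projected = []
    ins_len = [0] * (la + 1)
    for p in proteins:
        if p.id == anchor.id:
            projected.append(([c for c in anchor.sequence], {}))
            continue
        aln = global_align(anchor, p)
        cols = [""] * la
        inserts: dict[int, str] = {}
        ai = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                cols[ai] = cb  # residue of p (or '-') under anchor column ai
                ai += 1
            else:
                inserts[ai] = inserts.get(ai, "") + cb
        projected.append((cols, inserts))
        for k, s in inserts.items():
            ins_len[k] = max(ins_len[k], len(s))

    ids, rows = [], []
    for p, (cols, inserts) in zip(proteins, projected):
        out = []
        for k in range(la + 1):
            if ins_len[k]:
                s = inserts.get(k, "")
                out.append(s + "-" * (ins_len[k] - len(s)))
            if k < la:
                out.append(cols[k])
        ids.append(p.id)
        rows.append("".join(out))
    return MultipleAlignment(ids=ids, rows=rows)
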