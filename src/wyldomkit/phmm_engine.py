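"""Self-contained profile hidden Markov model engine.

Implements the search semantics of the classic profile-HMM tool chain:
model construction from a multiple alignment, local multi-hit Viterbi and
Forward scoring in bits against an i.i.d. background null, segmentation of
the optimal path into per-domain envelopes, Gumbel E-value calibration on
random sequences, and threshold-driven database search / model-library scan.

The topology is Plan7-style: flanking N/C states, a J loop for multiple
domains per sequence, uniform local entry into any match state and free local
exit (the implicit-model convention), with match/insert/delete core states
estimated from the alignment. Scores are log2-odds against the background,
corrected by a geometric null length model. This is a semantic, not
bit-exact, reimplementation of the external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._tables import AA_INDEX, BACKGROUND, GAP
from .msa_core import Alignment, SequenceRecord

NEG = -np.inf

# transition Laplace pseudocount; emissions use the user-visible
# pseudocount_weight times the background instead
_TRANS_ALPHA = 0.1


@dataclass
class SearchThresholds:
    """E-value reporting/inclusion bounds mirroring -E/-domE/-incE/-incdomE."""

    report_E: float = 1.0
    report_domE: float = 1.0
    include_E: float = 0.01
    include_domE: float = 0.03
    min_domain_score: float | None = None

    def __post_init__(self) -> None:
        vals = (self.report_E, self.report_domE, self.include_E, self.include_domE)
        if any(v <= 0 for v in vals):
            raise ValueError("all E-value thresholds must be > 0")
        if self.include_E > self.report_E or self.include_domE > self.report_domE:
            raise ValueError("inclusion thresholds must not exceed reporting thresholds")

    @classmethod
    def search_defaults(cls) -> "SearchThresholds":
        return cls(1.0, 1.0, 0.01, 0.03)

    @classmethod
    def scan_defaults(cls) -> "SearchThresholds":
        return cls(0.1, 0.1, 0.01, 0.03)


@dataclass
class DomainHit:
    """One scored domain placement on a sequence (1-based inclusive coords)."""

    sequence_id: str
    model_name: str
    clan: str
    env_start: int
    env_end: int
    ali_start: int
    ali_end: int
    hmm_start: int
    hmm_end: int
    bit_score: float
    i_evalue: float
    included: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.ali_start <= self.ali_end <= self.env_end):
            raise ValueError(f"envelope nesting violated for {self.sequence_id!r}")
        if not (1 <= self.hmm_start <= self.hmm_end):
            raise ValueError("invalid hmm span")
        if not math.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass
class SequenceHits:
    """Per-sequence search result: full-sequence score plus domain hits."""

    sequence_id: str
    bit_score: float
    evalue: float
    hits: list[DomainHit]
    included: bool


@dataclass
class ProfileHMM:
    """Profile HMM core model (probabilities, not scores).

    Transition arrays are 0-based over nodes 1..M: ``tmm[k]`` is
    P(M_{k+1} -> M_{k+2}) with ``tmm[M-1]`` the core-end transition;
    ``tim``/``tii`` cover insert states I_1..I_{M-1}; ``tdm[M-1]`` is
    P(D_M -> end) = 1. Calibration is a Gumbel (mu in bits, lambda in 1/bits)
    fitted to multi-hit Viterbi scores of random background sequences.
    """

    name: str
    M: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    tmm: np.ndarray
    tmi: np.ndarray
    tmd: np.ndarray
    tim: np.ndarray
    tii: np.ndarray
    tdm: np.ndarray
    tdd: np.ndarray
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    clan: str = ""
    calibration: tuple[float, float] | None = None
    gathering_threshold: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.match_emissions.shape != (self.M, 20):
            raise ValueError("match emission table has wrong shape")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emission rows must sum to 1")
        if not np.isclose(self.insert_emissions.sum(), 1.0, atol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if not np.allclose(self.tmm + self.tmi + self.tmd, 1.0, atol=1e-9):
            raise ValueError("match-state transitions must sum to 1")
        if self.M > 1 and not np.allclose(self.tim + self.tii, 1.0, atol=1e-9):
            raise ValueError("insert-state transitions must sum to 1")
        if not np.allclose(self.tdm + self.tdd, 1.0, atol=1e-9):
            raise ValueError("delete-state transitions must sum to 1")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValueError("gumbel lambda must be > 0")

    def consensus(self) -> str:
        idx = np.argmax(self.match_emissions, axis=1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        return "".join(aas[i] for i in idx)

    def scores(self) -> dict:
        """Precomputed log2 score arrays shared by Viterbi/Forward."""
        if self._cache:
            return self._cache
        with np.errstate(divide="ignore"):
            msc = np.log2(self.match_emissions / self.background[None, :])
            msc = np.concatenate([msc, np.zeros((self.M, 1))], axis=1)  # 'X' -> 0
            lt = {k: np.log2(getattr(self, k)) for k in
                  ("tmm", "tmi", "tmd", "tim", "tii", "tdm", "tdd")}
        M = self.M
        cache = {
            "msc": msc,
            "entry": np.full(M, -np.log2(M)),
            "tmm_in": np.concatenate(([0.0], lt["tmm"][: M - 1])),
            "tim_in": np.concatenate(([0.0], lt["tim"][: M - 1])) if M > 1
                      else np.array([0.0]),
            "tdm_in": np.concatenate(([0.0], lt["tdm"][: M - 1])),
            "ltmi": np.where(np.arange(M) < M - 1, lt["tmi"], NEG),
            "ltii": np.concatenate((lt["tii"], [NEG])) if M > 1 else np.array([NEG]),
            "ltmd": lt["tmd"],
            "ltdd": lt["tdd"],
            # cumulative log2 of D->D chain over usable deletes (nodes 1..M-1)
            "dd_cum": np.concatenate(([0.0], np.cumsum(lt["tdd"][: M - 1]))),
        }
        self._cache.update(cache)
        return self._cache


def encode(residues: str) -> np.ndarray:
    return np.array([AA_INDEX.get(ch, 20) for ch in residues], dtype=np.int64)


def _special_costs(L: int, multihit: bool) -> tuple[float, float, float, float]:
    nj = 1.0 if multihit else 0.0
    loop = L / (L + 2.0 + nj)
    move = (2.0 + nj) / (L + 2.0 + nj)
    lloop, lmove = math.log2(loop), math.log2(move)
    if multihit:
        ltej = ltec = -1.0  # log2(0.5)
    else:
        ltej, ltec = NEG, 0.0
    return lloop, lmove, ltej, ltec


def _null_correction(L: int) -> float:
    return L * math.log2(L / (L + 1.0)) + math.log2(1.0 / (L + 1.0))


def _shift(arr: np.ndarray) -> np.ndarray:
    out = np.empty_like(arr)
    out[0] = NEG
    out[1:] = arr[:-1]
    return out


def _fill(
    model: ProfileHMM, enc: np.ndarray, multihit: bool, viterbi: bool,
    keep: bool = False, ctx_len: int | None = None,
):
    """Shared DP fill. Returns the bit score and, if keep, all matrices.

    `ctx_len` sets the length used for the flanking-state and null length
    models; rescoring a domain envelope with the costs of its full-length
    sequence context keeps per-domain scores on the calibration scale.
    """
    c = model.scores()
    M, L = model.M, len(enc)
    lloop, lmove, ltej, ltec = _special_costs(ctx_len or L, multihit)
    combine = np.maximum if viterbi else np.logaddexp2
    prevM = np.full(M, NEG)
    prevI = np.full(M, NEG)
    prevD = np.full(M, NEG)
    n_sc, b_sc, j_sc, c_sc = 0.0, lmove, NEG, NEG
    if keep:
        VM = np.full((L + 1, M), NEG)
        VI = np.full((L + 1, M), NEG)
        VD = np.full((L + 1, M), NEG)
        Ns = np.full(L + 1, NEG); Bs = np.full(L + 1, NEG)
        Js = np.full(L + 1, NEG); Cs = np.full(L + 1, NEG)
        Es = np.full(L + 1, NEG)
        Ns[0], Bs[0] = 0.0, b_sc
    dd_cum = c["dd_cum"]
    for i in range(1, L + 1):
        msc_col = c["msc"][:, enc[i - 1]]
        cand = combine(
            combine(b_sc + c["entry"], _shift(prevM) + c["tmm_in"]),
            combine(_shift(prevI) + c["tim_in"], _shift(prevD) + c["tdm_in"]),
        )
        curM = msc_col + cand
        curI = combine(prevM + c["ltmi"], prevI + c["ltii"])
        # delete chain within the row via cumulative combine
        curD = np.full(M, NEG)
        if M > 1:
            a = curM[: M - 1] + c["ltmd"][: M - 1] - dd_cum[1:M]
            if viterbi:
                run = np.maximum.accumulate(a)
            else:
                run = np.logaddexp2.accumulate(a)
            curD[1:] = run + dd_cum[1:M]
        e_sc = curM.max() if viterbi else _log2sum(curM)
        j_sc = combine(j_sc + lloop, e_sc + ltej)
        c_sc = combine(c_sc + lloop, e_sc + ltec)
        n_sc = n_sc + lloop
        b_sc = combine(n_sc + lmove, j_sc + lmove)
        if keep:
            VM[i], VI[i], VD[i] = curM, curI, curD
            Ns[i], Bs[i], Js[i], Cs[i], Es[i] = n_sc, b_sc, j_sc, c_sc, e_sc
        prevM, prevI, prevD = curM, curI, curD
    score = c_sc + lmove - _null_correction(ctx_len or L)
    if keep:
        return score, (VM, VI, VD, Ns, Bs, Js, Cs, Es)
    return score


def _log2sum(arr: np.ndarray) -> float:
    return float(np.logaddexp2.reduce(arr))


def viterbi(
    model: ProfileHMM, seq: SequenceRecord, multihit: bool = True
) -> tuple[float, list[tuple[str, int, int]]]:
    """Optimal local alignment score in bits and its state path.

    The path lists (state, sequence position, model node) with position/node 0
    for coordinates a state does not have. Metadata on the record never
    affects the score.
    """
    enc = encode(seq.residues)
    score, mats = _fill(model, enc, multihit, viterbi=True, keep=True)
    path = _traceback(model, enc, multihit, mats)
    return float(score), path


def viterbi_score(
    model: ProfileHMM, seq: SequenceRecord, multihit: bool = True,
    ctx_len: int | None = None,
) -> float:
    return float(_fill(model, encode(seq.residues), multihit, viterbi=True,
                       ctx_len=ctx_len))


def forward_score(model: ProfileHMM, seq: SequenceRecord, multihit: bool = True) -> float:
    """Log-sum-over-paths score in bits; always >= the Viterbi score."""
    return float(_fill(model, encode(seq.residues), multihit, viterbi=False))


def _argfirstmax(cands: list[float]) -> int:
    best = max(cands)
    for i, v in enumerate(cands):
        if v == best:
            return i
    return 0


def _traceback(model, enc, multihit, mats) -> list[tuple[str, int, int]]:
    """Walk the stored Viterbi matrices back from C[L].

    Ties prefer, in order: ending a domain over looping a flank state, the
    B/M/I/D predecessor order for match states, and M over I/D continuations,
    making the reported path deterministic.
    """
    c = model.scores()
    VM, VI, VD, Ns, Bs, Js, Cs, Es = mats
    M, L = model.M, len(enc)
    lloop, lmove, ltej, ltec = _special_costs(L, multihit)
    ltmd, ltdd = c["ltmd"], c["ltdd"]
    rev: list[tuple[str, int, int]] = []
    state, i, k = "C", L, -1  # k is a 0-based node index while in the core
    while not (state == "N" and i == 0):
        rev.append((state, i, k))
        if state == "C":
            if i >= 1 and Cs[i - 1] + lloop > Es[i] + ltec:
                i -= 1
            else:
                state = "E"
        elif state == "E":
            k = int(np.argmax(VM[i]))
            state = "M"
        elif state == "M":
            cands = [Bs[i - 1] + c["entry"][k], NEG, NEG, NEG]
            if k >= 1:
                cands[1] = VM[i - 1, k - 1] + c["tmm_in"][k]
                cands[2] = VI[i - 1, k - 1] + c["tim_in"][k]
                cands[3] = VD[i - 1, k - 1] + c["tdm_in"][k]
            choice = _argfirstmax(cands)
            i -= 1
            if choice == 0:
                state, k = "B", -1
            else:
                state = "MID"[choice - 1]
                k -= 1
        elif state == "I":
            if VM[i - 1, k] + c["ltmi"][k] < VI[i - 1, k] + c["ltii"][k]:
                state = "I"
            else:
                state = "M"
            i -= 1
        elif state == "D":
            if VM[i, k - 1] + ltmd[k - 1] >= VD[i, k - 1] + ltdd[k - 1]:
                state = "M"
            k -= 1
        elif state == "B":
            state = "N" if Ns[i] + lmove >= Js[i] + lmove else "J"
        elif state == "J":
            if i >= 1 and Js[i - 1] + lloop > Es[i] + ltej:
                i -= 1
            else:
                state = "E"
        elif state == "N":
            i -= 1
    rev.append(("N", 0, -1))
    return [
        (s, i, (k + 1) if s in ("M", "I", "D") else 0)
        for s, i, k in reversed(rev)
    ]


def find_domains(
    model: ProfileHMM, seq: SequenceRecord, db_size: int = 1
) -> list[DomainHit]:
    """Segment the optimal multi-hit path into per-domain hits.

    Each domain core (between local entry and exit) yields an envelope over
    its emitted residues; per-domain bit scores come from rescoring the
    envelope subsequence in single-hit mode, and independent E-values use the
    model's Gumbel calibration with the given database size.
    """
    _, path = viterbi(model, seq, multihit=True)
    domains: list[list[tuple[str, int, int]]] = []
    current: list[tuple[str, int, int]] | None = None
    for state, i, k in path:
        if state == "B":
            current = []
        elif state == "E":
            if current:
                domains.append(current)
            current = None
        elif current is not None and state in ("M", "I", "D"):
            current.append((state, i, k))
    segments = []
    for dom in domains:
        m_pos = [(i, k) for s, i, k in dom if s == "M"]
        if not m_pos:
            continue
        emit_pos = [i for s, i, _ in dom if s in ("M", "I")]
        segments.append({
            "ali": (m_pos[0][0], m_pos[-1][0]),
            "env": (min(emit_pos), max(emit_pos)),
            "hmm": (m_pos[0][1], m_pos[-1][1]),
        })
    # a noisy stretch can split one occurrence into two path segments whose
    # model spans progress monotonically; merge those back into one envelope
    # (genuine tandem copies restart at low model nodes and never merge).
    # A few nodes of overlap are tolerated: a split boundary often re-matches
    # the same conserved nodes on both sides. The sequence gap between the
    # segments must stay short — a split within one occurrence is bridged by
    # the unmatched stretch itself, while distant same-model matches are
    # separate occurrences however their node numbering happens to align.
    tol = min(8, max(1, model.M // 3))
    max_gap = max(10, model.M // 2)
    merged: list[dict] = []
    for seg in segments:
        if (
            merged
            and seg["hmm"][0] > merged[-1]["hmm"][1] - tol
            and seg["env"][0] - merged[-1]["env"][1] - 1 <= max_gap
        ):
            prev = merged[-1]
            prev["ali"] = (prev["ali"][0], seg["ali"][1])
            prev["env"] = (prev["env"][0], seg["env"][1])
            prev["hmm"] = (prev["hmm"][0], seg["hmm"][1])
        else:
            merged.append(seg)
    hits: list[DomainHit] = []
    L = len(seq)
    lloop = math.log2(L / (L + 3.0))
    for seg in merged:
        ali_start, ali_end = seg["ali"]
        env_start, env_end = seg["env"]
        sub = SequenceRecord("_env", seq.residues[env_start - 1 : env_end])
        # rescore the envelope with the full-sequence flank/null costs so the
        # per-domain score sits on the same scale the model was calibrated on:
        # residues outside the envelope contribute their flank loop costs
        dom_score = viterbi_score(model, sub, multihit=True, ctx_len=L)
        dom_score += (L - len(sub.residues)) * lloop
        ieval = (
            evalue(dom_score, model, db_size)
            if model.calibration is not None
            else float("nan")
        )
        hits.append(
            DomainHit(
                sequence_id=seq.id,
                model_name=model.name,
                clan=model.clan or model.name,
                env_start=env_start,
                env_end=env_end,
                ali_start=ali_start,
                ali_end=ali_end,
                hmm_start=seg["hmm"][0],
                hmm_end=seg["hmm"][1],
                bit_score=float(dom_score),
                i_evalue=float(ieval),
            )
        )
    hits.sort(key=lambda h: (h.env_start, h.env_end, h.model_name))
    return hits


# --- model construction ----------------------------------------------------

def assign_match_columns(aln: Alignment, gap_fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of match columns: gap fraction strictly below threshold."""
    if not (0.0 < gap_fraction < 1.0):
        raise ValueError("gap_fraction must be in (0, 1)")
    occ = aln.occupancy()
    mask = (1.0 - occ) < gap_fraction
    if not mask.any():
        raise ValueError(
            "no match columns at this gap fraction; curate the alignment "
            "or raise the threshold"
        )
    return mask


def build_profile(
    aln: Alignment,
    pseudocount_weight: float = 1.0,
    gap_fraction: float = 0.5,
    name: str = "model",
    clan: str = "",
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment.

    Match emissions are background-mixed counts; transitions are estimated
    from the observed match/insert/delete paths of each row with Laplace
    smoothing. Uses uniform sequence weights.
    """
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    mask = assign_match_columns(aln, gap_fraction)
    match_cols = np.flatnonzero(mask)
    M = len(match_cols)
    em = np.zeros((M, 20))
    # transition counts per node: rows [mm, mi, md], [im, ii], [dm, dd]
    cm = np.zeros((M, 3))
    ci = np.zeros((max(M - 1, 1), 2))
    cd = np.zeros((M, 2))
    col_to_node = {int(cj): n for n, cj in enumerate(match_cols)}
    for _, row in aln.rows:
        states: list[tuple[str, int]] = []  # (state, node index 0-based)
        for j, ch in enumerate(row):
            if j in col_to_node:
                node = col_to_node[j]
                if ch == GAP:
                    states.append(("D", node))
                else:
                    states.append(("M", node))
                    if ch in AA_INDEX:
                        em[node, AA_INDEX[ch]] += 1.0
            elif ch != GAP:
                if states:  # inserts before the first match column are local
                    states.append(("I", states[-1][1] if states[-1][0] != "I"
                                   else states[-1][1]))
        # walk transitions
        for (s1, n1), (s2, _n2) in zip(states, states[1:]):
            if s1 == "M":
                cm[n1, {"M": 0, "I": 1, "D": 2}[s2]] += 1.0
            elif s1 == "I":
                if n1 < M - 1:
                    ci[n1, 0 if s2 == "M" else 1] += 1.0
            elif s1 == "D":
                cd[n1, 0 if s2 == "M" else 1] += 1.0
        if states:  # closing transition of the last core state
            s_last, n_last = states[-1]
            if s_last == "M":
                cm[n_last, 0] += 1.0
            elif s_last == "D":
                cd[n_last, 0] += 1.0
    em = em + pseudocount_weight * BACKGROUND[None, :]
    row_sums = em.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError(
            "zero-count match column with zero pseudocount weight; "
            "increase pseudocount_weight"
        )
    em = em / row_sums
    tm = (cm + _TRANS_ALPHA) / (cm + _TRANS_ALPHA).sum(axis=1, keepdims=True)
    ti = (ci + _TRANS_ALPHA) / (ci + _TRANS_ALPHA).sum(axis=1, keepdims=True)
    td = (cd + _TRANS_ALPHA) / (cd + _TRANS_ALPHA).sum(axis=1, keepdims=True)
    # terminal node: no insert/delete continuation out of node M
    tmm, tmi, tmd = tm[:, 0].copy(), tm[:, 1].copy(), tm[:, 2].copy()
    tmm[M - 1] = 1.0
    tmi[M - 1] = 0.0
    tmd[M - 1] = 0.0
    tdm, tdd = td[:, 0].copy(), td[:, 1].copy()
    tdm[M - 1] = 1.0
    tdd[M - 1] = 0.0
    model = ProfileHMM(
        name=name,
        clan=clan,
        M=M,
        match_emissions=em,
        insert_emissions=BACKGROUND.copy(),
        tmm=tmm, tmi=tmi, tmd=tmd,
        tim=ti[:, 0][: max(M - 1, 1)] if M > 1 else np.array([1.0]),
        tii=ti[:, 1][: max(M - 1, 1)] if M > 1 else np.array([0.0]),
        tdm=tdm, tdd=tdd,
    )
    model.validate()
    return model


# --- calibration and E-values ----------------------------------------------

def random_background_sequence(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(aas[i] for i in idx)


def calibrate(
    model: ProfileHMM,
    n_random: int = 200,
    length: int = 350,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit a Gumbel law to multi-hit Viterbi scores of random sequences.

    Stores (mu, lambda) on the model and returns them. Deterministic for a
    fixed seed.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_random)
    for i in range(n_random):
        seq = SequenceRecord(f"_rnd{i}", random_background_sequence(rng, length))
        scores[i] = viterbi_score(model, seq)
    if np.std(scores) < 1e-9:
        raise ValueError("degenerate score distribution; cannot calibrate")
    loc, scale = stats.gumbel_r.fit(scores)
    model.calibration = (float(loc), float(1.0 / scale))
    return model.calibration


def evalue(score: float, model: ProfileHMM, db_size: int) -> float:
    """Expected number of hits at or above `score` in a null database."""
    if model.calibration is None:
        raise ValueError(f"model {model.name!r} is not calibrated")
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    mu, lam = model.calibration
    p = float(stats.gumbel_r.sf(score, loc=mu, scale=1.0 / lam))
    return db_size * p


# --- search and scan -------------------------------------------------------

def search(
    model: ProfileHMM,
    db: list[SequenceRecord],
    th: SearchThresholds | None = None,
) -> list[SequenceHits]:
    """Search a calibrated model against a sequence database.

    Sequences pass reporting at full-sequence E <= report_E; their domains are
    kept at i_evalue <= report_domE (and min_domain_score if set). A hit is
    marked included when both the sequence E and its i-E-value meet the
    inclusion bounds. Results are ordered by (E-value, id).
    """
    th = th or SearchThresholds.search_defaults()
    if model.calibration is None:
        raise ValueError("search requires a calibrated model")
    results: list[SequenceHits] = []
    n = len(db)
    for seq in db:
        score = viterbi_score(model, seq)
        ev = evalue(score, model, n)
        if ev > th.report_E:
            continue
        hits = []
        for h in find_domains(model, seq, db_size=n):
            if h.i_evalue > th.report_domE:
                continue
            if th.min_domain_score is not None and h.bit_score <= th.min_domain_score:
                continue
            h.included = ev <= th.include_E and h.i_evalue <= th.include_domE
            hits.append(h)
        seq_included = ev <= th.include_E and any(h.included for h in hits)
        results.append(SequenceHits(seq.id, float(score), float(ev), hits, seq_included))
    results.sort(key=lambda r: (r.evalue, r.sequence_id))
    return results


def scan(
    models: list[ProfileHMM],
    seq: SequenceRecord,
    th: SearchThresholds | None = None,
) -> list[DomainHit]:
    """Scan one sequence against a model library; E-values use len(models)."""
    th = th or SearchThresholds.scan_defaults()
    n = len(models)
    out: list[DomainHit] = []
    for model in models:
        if model.calibration is None:
            raise ValueError(f"scan requires calibrated models ({model.name!r})")
        score = viterbi_score(model, seq)
        ev = evalue(score, model, n)
        if ev > th.report_E:
            continue
        for h in find_domains(model, seq, db_size=n):
            if h.i_evalue > th.report_domE:
                continue
            if th.min_domain_score is not None and h.bit_score <= th.min_domain_score:
                continue
            h.included = ev <= th.include_E and h.i_evalue <= th.include_domE
            out.append(h)
    out.sort(key=lambda h: (h.env_start, h.env_end, h.model_name))
    return out


# --- file format (versioned text, full float precision) ---------------------

_FMT_VERSION = "WDKHMM1"


def _floats(arr) -> str:
    return " ".join(repr(float(v)) for v in np.asarray(arr).ravel())


def write_hmm(model: ProfileHMM, path) -> None:
    model.validate()
    with open(path, "w") as fh:
        fh.write(f"{_FMT_VERSION}\n")
        fh.write(f"NAME {model.name}\n")
        fh.write(f"CLAN {model.clan or '-'}\n")
        fh.write(f"LENG {model.M}\n")
        ga = "-" if model.gathering_threshold is None else repr(model.gathering_threshold)
        fh.write(f"GA {ga}\n")
        if model.calibration is not None:
            fh.write(f"CALIB {repr(model.calibration[0])} {repr(model.calibration[1])}\n")
        fh.write(f"BG {_floats(model.background)}\n")
        fh.write(f"INSEM {_floats(model.insert_emissions)}\n")
        for k in range(model.M):
            fh.write(f"NODE {k + 1}\n")
            fh.write(f"EM {_floats(model.match_emissions[k])}\n")
            im = model.tim[k] if k < model.M - 1 else 0.0
            ii = model.tii[k] if k < model.M - 1 else 0.0
            fh.write(
                "TR "
                + " ".join(
                    repr(float(v))
                    for v in (
                        model.tmm[k], model.tmi[k], model.tmd[k],
                        im, ii, model.tdm[k], model.tdd[k],
                    )
                )
                + "\n"
            )
        fh.write("END\n")


def read_hmm(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != _FMT_VERSION:
        raise ValueError(f"not a {_FMT_VERSION} file: {path}")
    meta: dict[str, str] = {}
    i = 1
    while not lines[i].startswith("NODE"):
        key, _, val = lines[i].partition(" ")
        meta[key] = val
        i += 1
    M = int(meta["LENG"])
    em = np.zeros((M, 20))
    tr = np.zeros((M, 7))
    while i < len(lines) and lines[i].startswith("NODE"):
        k = int(lines[i].split()[1]) - 1
        em[k] = [float(v) for v in lines[i + 1].split()[1:]]
        tr[k] = [float(v) for v in lines[i + 2].split()[1:]]
        i += 3
    calib = None
    if "CALIB" in meta:
        mu, lam = meta["CALIB"].split()
        calib = (float(mu), float(lam))
    model = ProfileHMM(
        name=meta["NAME"],
        clan="" if meta["CLAN"] == "-" else meta["CLAN"],
        M=M,
        match_emissions=em,
        insert_emissions=np.array([float(v) for v in meta["INSEM"].split()]),
        tmm=tr[:, 0], tmi=tr[:, 1], tmd=tr[:, 2],
        tim=tr[: M - 1, 3] if M > 1 else np.array([1.0]),
        tii=tr[: M - 1, 4] if M > 1 else np.array([0.0]),
        tdm=tr[:, 5], tdd=tr[:, 6],
        background=np.array([float(v) for v in meta["BG"].split()]),
        calibration=calib,
        gathering_threshold=None if meta.get("GA", "-") == "-" else float(meta["GA"]),
    )
    model.validate()
    return model


def write_hits_tsv(hits: list[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sequence_id\tmodel\tclan\tenv_from\tenv_to\tali_from\tali_to\t"
            "hmm_from\thmm_to\tscore_bits\ti_evalue\tincluded\n"
        )
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.model_name}\t{h.clan}\t{h.env_start}\t"
                f"{h.env_end}\t{h.ali_start}\t{h.ali_end}\t{h.hmm_start}\t"
                f"{h.hmm_end}\t{h.bit_score:.2f}\t{h.i_evalue:.3g}\t"
                f"{int(h.included)}\n"
            )
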