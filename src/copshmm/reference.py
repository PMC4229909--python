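"""Scalar reference decoders (oracles).

Three independent routes to the same unihit local Viterbi score:

* :func:`viterbi_score` — floating-point dynamic programming over the
  log-odds recurrences, with the special states N, B, E, C (J removed:
  unihit mode has no model re-entry).
* :func:`viterbi_score_quantized_scalar` — a scalar, one-sequence-at-a-time
  replica of the quantized saturated 16-bit pipeline.  The lock-step engine
  must match it bit-exactly on every channel; this function is the ground
  truth for that comparison and is deliberately written as plain Python
  loops over plain integers.
* :func:`enumerate_paths_score` — brute-force enumeration of every legal
  state path for tiny instances, scoring each path by summing its
  transition and emission log-odds and taking the maximum.

Recurrences (nats), for row ``i`` (sequence position) and column ``j``
(model node), with ``D`` updated within the current row::

    V_M[i][j] = em[j][x_i] + max(xB + entry[j],
                                 V_M[i-1][j-1] + t_MM[j-1],
                                 V_I[i-1][j-1] + t_IM[j-1],
                                 V_D[i-1][j-1] + t_DM[j-1])
    V_I[i][j] = ins[j][x_i] + max(V_M[i-1][j] + t_MI[j],
                                  V_I[i-1][j] + t_II[j])
    V_D[i][j] = max(V_M[i][j-1] + t_MD[j-1], V_D[i][j-1] + t_DD[j-1])
    xE[i] = max_j V_M[i][j]           (uniform local exit, score 0)
    xC[i] = max(xC[i-1], xE[i])       (cc = ec = 0)

The reported score is ``xC[L] + final_offset`` with the fixed -2.0 nat
flank approximation.  Delete states take no D→I or I→D moves (Plan 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .errors import SizeError, ValidationError
from .profile import (
    LogOddsProfile, QuantizedProfile,
    T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD,
)

NEG_INF = float("-inf")


@dataclass
class ViterbiResult:
    """Score of one sequence against one model.

    ``raw_score`` is the integer DP score on the quantized scale (``None``
    for float decoding); ``score_nats`` is the final nat-scale score
    including the -2.0 offset, ``-inf`` when no nonzero-probability path
    exists.
    """

    seq_id: str
    length: int
    score_nats: float
    raw_score: int | None = None

    @property
    def score_bits(self) -> float:
        return self.score_nats / np.log(2)


@dataclass
class DPMatrices:
    """Full float DP matrices, (L+1) x (M+1); for debugging and tests."""

    V_M: np.ndarray
    V_I: np.ndarray
    V_D: np.ndarray
    xN: np.ndarray
    xB: np.ndarray
    xE: np.ndarray
    xC: np.ndarray


def _check(lo: LogOddsProfile, seq: np.ndarray) -> np.ndarray:
    if lo.M < 1:
        raise ValidationError("empty model")
    seq = np.asarray(seq, dtype=np.int64)
    if seq.size and (seq.min() < 0 or seq.max() > lo.alphabet.K):
        raise ValidationError("residue code outside the model alphabet")
    return seq


def viterbi_matrices(lo: LogOddsProfile, seq: np.ndarray) -> DPMatrices:
    """Fill and return the complete float DP matrices."""
    seq = _check(lo, seq)
    M, L = lo.M, len(seq)
    sp = lo.special
    t = lo.transition_scores
    V_M = np.full((L + 1, M + 1), NEG_INF)
    V_I = np.full((L + 1, M + 1), NEG_INF)
    V_D = np.full((L + 1, M + 1), NEG_INF)
    xN = np.full(L + 1, NEG_INF)
    xB = np.full(L + 1, NEG_INF)
    xE = np.full(L + 1, NEG_INF)
    xC = np.full(L + 1, NEG_INF)
    xN[0] = 0.0
    xB[0] = xN[0] + sp.nb
    for i in range(1, L + 1):
        r = seq[i - 1]
        xN[i] = xN[i - 1] + sp.nn
        xB[i] = xN[i] + sp.nb
        for j in range(1, M + 1):
            best = xB[i - 1] + lo.entry_scores[j - 1]
            if j > 1:
                best = max(best,
                           V_M[i - 1][j - 1] + t[j - 2][T_MM],
                           V_I[i - 1][j - 1] + t[j - 2][T_IM],
                           V_D[i - 1][j - 1] + t[j - 2][T_DM])
            V_M[i][j] = best + lo.match_scores[j - 1][r]
            V_I[i][j] = lo.insert_scores[j - 1][r] + max(
                V_M[i - 1][j] + t[j - 1][T_MI],
                V_I[i - 1][j] + t[j - 1][T_II])
            if j > 1:
                V_D[i][j] = max(V_M[i][j - 1] + t[j - 2][T_MD],
                                V_D[i][j - 1] + t[j - 2][T_DD])
            xE[i] = max(xE[i], V_M[i][j] + sp.exit)
        xC[i] = max(xC[i - 1] + sp.cc, xE[i] + sp.ec)
    return DPMatrices(V_M, V_I, V_D, xN, xB, xE, xC)


def viterbi_score(lo: LogOddsProfile, seq: np.ndarray,
                  seq_id: str = "") -> ViterbiResult:
    """Float unihit local Viterbi score (row-vectorized over the model)."""
    seq = _check(lo, seq)
    M, L = lo.M, len(seq)
    sp = lo.special
    t = lo.transition_scores
    tMM, tIM, tDM = t[:, T_MM], t[:, T_IM], t[:, T_DM]
    tMI, tII = t[:, T_MI], t[:, T_II]
    tMD, tDD = t[:, T_MD], t[:, T_DD]
    entry = lo.entry_scores
    VM = np.full(M, NEG_INF)
    VI = np.full(M, NEG_INF)
    VD = np.full(M, NEG_INF)
    xB = sp.nb  # constant across rows: nn = 0 in unihit local mode
    xC = NEG_INF
    for i in range(L):
        r = seq[i]
        cand = xB + entry.copy()
        if M > 1:
            np.maximum(cand[1:], VM[:-1] + tMM[:-1], out=cand[1:])
            np.maximum(cand[1:], VI[:-1] + tIM[:-1], out=cand[1:])
            np.maximum(cand[1:], VD[:-1] + tDM[:-1], out=cand[1:])
        VM_new = cand + lo.match_scores[:, r]
        VI = lo.insert_scores[:, r] + np.maximum(VM + tMI, VI + tII)
        VD_new = np.full(M, NEG_INF)
        for j in range(1, M):  # within-row dependency: sequential in j
            VD_new[j] = max(VM_new[j - 1] + tMD[j - 1],
                            VD_new[j - 1] + tDD[j - 1])
        VM, VD = VM_new, VD_new
        xE = VM.max() + sp.exit
        xC = max(xC + sp.cc, xE + sp.ec)
    score = xC + sp.final_offset if xC != NEG_INF else NEG_INF
    return ViterbiResult(seq_id=seq_id, length=L, score_nats=score)


# ---------------------------------------------------------------------------
# scalar quantized twin
# ---------------------------------------------------------------------------

def sat_add(a: int, b: int, sent: int, max_value: int) -> int:
    """Saturated 16-bit addition with an absorbing -inf sentinel."""
    if a == sent or b == sent:
        return sent
    s = a + b
    if s > max_value:
        return max_value
    if s < sent:
        return sent
    return s


def viterbi_score_quantized_scalar(qp: QuantizedProfile, seq: np.ndarray,
                                   seq_id: str = "") -> ViterbiResult:
    """Scalar replica of the saturated 16-bit quantized pipeline.

    Runs over the original (unpadded) model columns; the engine runs over
    the padded columns.  Their raw scores must agree bit-exactly — dummy
    states carry the absorbing sentinel and cannot alter a score.
    """
    params = qp.params
    sent, maxv = params.sentinel_min, params.max_value
    bias = params.bias
    M = qp.original_length
    seq = np.asarray(seq, dtype=np.int64)
    L = len(seq)
    # plain-int copies: this oracle deliberately avoids numpy arithmetic
    match = [[int(x) for x in row] for row in qp.match_scores[:, :M]]
    insert = [[int(x) for x in row] for row in qp.insert_scores[:, :M]]
    t = [[int(x) for x in row] for row in qp.transition_scores[:, :M]]
    tMMr, tMIr, tMDr = t[T_MM], t[T_MI], t[T_MD]
    tIMr, tIIr = t[T_IM], t[T_II]
    tDMr, tDDr = t[T_DM], t[T_DD]
    base_entry = [sat_add(bias, int(e), sent, maxv)
                  for e in qp.entry_scores[:M]]

    Mmx = [sent] * M
    Imx = [sent] * M
    Dmx = [sent] * M
    xC = sent
    for i in range(L):
        em = match[seq[i]]
        ins = insert[seq[i]]
        Mnext = sent
        Dcv = sent
        xmxE = sent
        for j in range(M):
            Mpv, Ipv, Dpv = Mmx[j], Imx[j], Dmx[j]
            Mcv = sat_add(max(Mnext, base_entry[j]), em[j], sent, maxv)
            Icv = sat_add(max(sat_add(Mpv, tMIr[j], sent, maxv),
                              sat_add(Ipv, tIIr[j], sent, maxv)),
                          ins[j], sent, maxv)
            if Mcv > xmxE:
                xmxE = Mcv
            Mnext = max(sat_add(Mpv, tMMr[j], sent, maxv),
                        sat_add(Ipv, tIMr[j], sent, maxv),
                        sat_add(Dpv, tDMr[j], sent, maxv))
            Mmx[j] = Mcv
            Imx[j] = Icv
            Dmx[j] = Dcv
            Dcv = max(sat_add(Mcv, tMDr[j], sent, maxv),
                      sat_add(Dcv, tDDr[j], sent, maxv))
        if xmxE > xC:
            xC = xmxE
    return ViterbiResult(
        seq_id=seq_id, length=L, raw_score=xC,
        score_nats=params.dequantize(xC, qp.special.final_offset),
    )


# ---------------------------------------------------------------------------
# exhaustive path enumeration
# ---------------------------------------------------------------------------

MAX_ENUM_M = 6
MAX_ENUM_L = 8


def enumerate_paths_score(lo: LogOddsProfile, seq: np.ndarray,
                          *, max_m: int = MAX_ENUM_M,
                          max_l: int = MAX_ENUM_L) -> float:
    """Maximum path score by brute-force enumeration (tiny instances only).

    Walks every legal path N* → B → M_k → {M,I,D}* → E → C* → end that
    consumes exactly the sequence; N and C consume flanking residues at
    score 0.  Independent of the DP decoders by construction.
    """
    seq = _check(lo, seq)
    M, L = lo.M, len(seq)
    if M > max_m or L > max_l:
        raise SizeError(
            f"enumeration limited to M <= {max_m}, L <= {max_l} "
            f"(got M={M}, L={L})"
        )
    t = lo.transition_scores
    sp = lo.special
    best = NEG_INF

    def walk(state: str, j: int, pos: int, end: int, acc: float) -> None:
        # `state` at node j, having consumed seq[:pos] of the core window
        # ending at `end` (exclusive)
        nonlocal best
        if acc == NEG_INF:
            return
        if state == "M" and pos == end:
            # exit to E; C consumes the tail at cc = 0
            best = max(best, acc + sp.exit + sp.ec + sp.final_offset)
        if state in ("M", "I"):
            row = t[j - 1]
            if state == "M":
                moves = ((T_MM, "M"), (T_MI, "I"), (T_MD, "D"))
            else:
                moves = ((T_IM, "M"), (T_II, "I"))
        else:
            row = t[j - 1]
            moves = ((T_DM, "M"), (T_DD, "D"))
        for ti, nxt in moves:
            nj = j + 1 if nxt != "I" else j
            if nxt != "I" and j >= M:
                continue
            step = acc + row[ti]
            if nxt == "D":
                walk("D", nj, pos, end, step)
            elif pos < end:
                r = seq[pos]
                em = (lo.match_scores if nxt == "M"
                      else lo.insert_scores)[nj - 1][r]
                walk(nxt, nj, pos + 1, end, step + em)

    # choose the core window [s, e) aligned by the model; N eats seq[:s],
    # C eats seq[e:], both at score 0 per residue
    for s, e in product(range(L + 1), repeat=2):
        if e <= s:
            continue  # at least one match state must be visited
        for k in range(1, M + 1):
            entry = sp.nb + lo.entry_scores[k - 1]
            em = lo.match_scores[k - 1][seq[s]]
            walk("M", k, s + 1, e, entry + em)
    return best
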