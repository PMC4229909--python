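"""Inter-sequence lock-step Viterbi engine over quantized 16-bit scores.

Eight sequences are decoded simultaneously, one per *channel*, mirroring a
128-bit SIMD register of eight 16-bit lanes.  The dynamic program runs in
three nested loops:

* **Loop C** (outermost) over *partitions* — contiguous blocks of model
  columns of at most MP state-triplets, sized so one partition's working
  set fits the L1 data cache;
* **Loop B** over sequence rows ``1..L_max`` of the 8-sequence batch;
* **Loop A** over the partition's columns in unrolled blocks of 8, each
  block starting with an inline 8x8 transposition of the channels'
  emission scores from the per-sequence *continuous* layout into the
  per-column *striped* layout.

Adjacent partitions exchange exactly three values per channel per row —
the running row maximum ``xmxE``, the partial next-column match value
``Mnext`` (computed from the previous row at the boundary column), and the
boundary delete value ``Dcv`` — the *carrier line*.  A full-boundary-column
variant is provided to verify that those three values are sufficient.

All arithmetic is saturated 16-bit with the 16-bit minimum as an absorbing
-inf sentinel, so the dummy columns that pad the model to the multiple-of-8
barrier and the dummy rows that pad shorter sequences in a batch can never
alter an active channel's score.  Internally lanes are held in int32 and
clamped to the 16-bit range after every addition; results are bit-identical
to true int16 saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .profile import (
    QuantizedProfile,
    T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD,
)
from .reference import ViterbiResult


# ---------------------------------------------------------------------------
# batches and partition plans
# ---------------------------------------------------------------------------

@dataclass
class ChannelBatch:
    """Q digitized sequences packed for lock-step decoding.

    Dummy channels (``active[c] == False``) fill the batch remainder; they
    hold empty sequences, report ``-inf`` and are excluded from user-facing
    output by the scheduler.
    """

    ids: list
    sequences: list           # Q arrays of residue codes
    true_lengths: np.ndarray  # (Q,) int
    active: np.ndarray        # (Q,) bool
    orig_indices: list = field(default_factory=list)

    @property
    def Q(self) -> int:
        return len(self.sequences)

    @property
    def L_max(self) -> int:
        return int(self.true_lengths.max(initial=0))

    @classmethod
    def from_sequences(cls, seqs, ids=None, Q: int = 8, orig_indices=None):
        """Pack up to Q sequences, padding the remainder with dummies."""
        seqs = list(seqs)
        if len(seqs) > Q:
            raise ValidationError(f"batch holds at most {Q} sequences")
        n = len(seqs)
        ids = list(ids) if ids is not None else [f"seq{i}" for i in range(n)]
        orig = list(orig_indices) if orig_indices is not None else list(range(n))
        empty = np.zeros(0, dtype=np.int16)
        return cls(
            ids=ids + [""] * (Q - n),
            sequences=[np.asarray(s, dtype=np.int16) for s in seqs]
            + [empty] * (Q - n),
            true_lengths=np.array([len(s) for s in seqs] + [0] * (Q - n)),
            active=np.array([True] * n + [False] * (Q - n)),
            orig_indices=orig + [-1] * (Q - n),
        )


@dataclass(frozen=True)
class PartitionPlan:
    """Tiling of the padded model columns into cache-sized partitions."""

    MP: int
    ranges: tuple  # of (start, stop) half-open column intervals

    def validate(self, Mq: int, Q: int) -> None:
        if not self.ranges:
            raise ValidationError("empty partition plan")
        pos = 0
        for start, stop in self.ranges:
            if start != pos or stop <= start:
                raise ValidationError(
                    f"partition ranges must be contiguous; got {self.ranges}"
                )
            if (stop - start) % Q or stop - start > max(self.MP, Q):
                raise ValidationError(
                    f"partition [{start},{stop}) is not a multiple of {Q} "
                    f"or exceeds MP={self.MP}"
                )
            pos = stop
        if pos != Mq:
            raise ValidationError(
                f"plan covers [0,{pos}) but the padded model has {Mq} columns"
            )

    @classmethod
    def single(cls, Mq: int) -> "PartitionPlan":
        return cls(MP=Mq, ranges=((0, Mq),))


# ---------------------------------------------------------------------------
# saturated vector arithmetic
# ---------------------------------------------------------------------------

def _vsat_add(a: np.ndarray, b, sent: int, maxv: int) -> np.ndarray:
    """Lane-wise saturated add; `b` is a vector or a scalar score."""
    if np.isscalar(b) or getattr(b, "ndim", 1) == 0:
        if int(b) == sent:
            return np.full_like(a, sent)
        s = a + int(b)
        np.clip(s, sent, maxv, out=s)
        s[a == sent] = sent
        return s
    s = a + b
    np.clip(s, sent, maxv, out=s)
    s[(a == sent) | (b == sent)] = sent
    return s


# ---------------------------------------------------------------------------
# emission pre-processing
# ---------------------------------------------------------------------------

def transpose_emissions(rows: np.ndarray, j: int, Q: int = 8) -> np.ndarray:
    """Transpose a QxQ emission block from continuous to striped layout.

    ``rows`` holds one continuous score row per channel (shape (Q, Mq));
    the returned tile has ``tile[s][c] == rows[c][j + s]`` — one vector per
    model column, one lane per channel.
    """
    if rows.shape[0] != Q:
        raise ValidationError(f"expected {Q} channel rows, got {rows.shape[0]}")
    if j < 0 or j + Q > rows.shape[1]:
        raise ValidationError(
            f"state offset {j} out of range for {rows.shape[1]} columns"
        )
    return rows[:, j:j + Q].T


def load_emission_rows(qp: QuantizedProfile, batch: ChannelBatch,
                       i: int, *, table: str = "match") -> np.ndarray:
    """Continuous match-emission rows for sequence row ``i`` (1-based).

    Channel ``c`` gets the emission row of its residue at position ``i``;
    past its true length it gets the all-sentinel padding row, so padded
    cells cannot create matches.
    """
    scores = qp.match_scores if table == "match" else qp.insert_scores
    pad = qp.alphabet.padding_code
    codes = [
        int(batch.sequences[c][i - 1]) if 1 <= i <= batch.true_lengths[c]
        else pad
        for c in range(batch.Q)
    ]
    return scores[codes].astype(np.int32)


# ---------------------------------------------------------------------------
# the unrolled state-triplet kernel
# ---------------------------------------------------------------------------

def compute_state_triplet(Mpv, Ipv, Dpv, Mnext, Dcv, xmxE,
                          em, ins, base_entry, tcol, sent, maxv):
    """One column update for all Q channels.

    Inputs are Q-lane int32 vectors (previous-row M/I/D at this column, the
    carried ``Mnext`` and ``Dcv``, the running ``xmxE``, and the striped
    emission vectors) plus the scalar per-column transition scores ``tcol``
    and the precomputed ``xB + entry`` scalar.  Returns the stored triplet
    for this column and the carried values for the next column::

        (Mcv, Icv, Dstore, Mnext', Dcv', xmxE')

    The match value of the *next* column is only partially computable here
    (its emission is unknown); the partial maximum over the previous-row
    triplet plus transitions is carried as ``Mnext``.
    """
    Mcv = _vsat_add(np.maximum(Mnext, base_entry), em, sent, maxv)
    Icv = _vsat_add(
        np.maximum(_vsat_add(Mpv, tcol[T_MI], sent, maxv),
                   _vsat_add(Ipv, tcol[T_II], sent, maxv)),
        ins, sent, maxv)
    xmxE = np.maximum(xmxE, Mcv)
    Mnext_new = np.maximum(
        np.maximum(_vsat_add(Mpv, tcol[T_MM], sent, maxv),
                   _vsat_add(Ipv, tcol[T_IM], sent, maxv)),
        _vsat_add(Dpv, tcol[T_DM], sent, maxv))
    Dstore = Dcv
    Dcv_new = np.maximum(_vsat_add(Mcv, tcol[T_MD], sent, maxv),
                         _vsat_add(Dcv, tcol[T_DD], sent, maxv))
    return Mcv, Icv, Dstore, Mnext_new, Dcv_new, xmxE


# ---------------------------------------------------------------------------
# partitioned lock-step decode
# ---------------------------------------------------------------------------

def decode_batch(qp: QuantizedProfile, batch: ChannelBatch,
                 plan: PartitionPlan | None = None, *,
                 carrier: str = "minimal") -> list[ViterbiResult]:
    """Decode an 8-channel batch, returning one result per channel.

    ``carrier`` selects how inter-partition dependencies cross the
    boundary: ``"minimal"`` exchanges the 3-value carrier line
    (xmxE, Mnext, Dcv); ``"full-column"`` stores the complete boundary
    state triplet per row and recomputes the carried values on the
    consuming side.  Both are bit-exact against the scalar oracle.
    """
    params = qp.params
    Q = params.channels
    if batch.Q != Q:
        raise ValidationError(f"batch has {batch.Q} channels, engine wants {Q}")
    Mq = qp.padded_length
    if plan is None:
        plan = PartitionPlan.single(Mq)
    plan.validate(Mq, Q)
    if carrier not in ("minimal", "full-column"):
        raise ValidationError(f"unknown carrier mode {carrier!r}")
    sent, maxv = params.sentinel_min, params.max_value
    L_max = batch.L_max

    trans = qp.transition_scores.astype(np.int64)
    # xB is constant (unihit: N->N scores zero): bias + entry, saturated
    base_entry = np.array(
        [sent if e == sent else max(sent, min(maxv, params.bias + int(e)))
         for e in qp.entry_scores.astype(np.int64)], dtype=np.int32)

    Mmx = np.full((Mq, Q), sent, dtype=np.int32)
    Imx = np.full((Mq, Q), sent, dtype=np.int32)
    Dmx = np.full((Mq, Q), sent, dtype=np.int32)
    xC = np.full(Q, sent, dtype=np.int32)
    snapshots = np.full(Q, sent, dtype=np.int32)

    # carrier storage, one line per sequence row
    sent_line = np.full((L_max + 1, Q), sent, dtype=np.int32)
    c_xmxE = sent_line.copy()
    c_Mnext = sent_line.copy()
    c_Dcv = sent_line.copy()
    c_Mb = sent_line.copy()   # full-column variant: boundary M/I/D per row
    c_Ib = sent_line.copy()
    c_Db = sent_line.copy()

    n_parts = len(plan.ranges)
    for p, (j0, j1) in enumerate(plan.ranges):          # Loop C: partitions
        last = p == n_parts - 1
        # previous partition's boundary column (full-column carrier)
        bMprev = np.full(Q, sent, dtype=np.int32)
        bIprev = np.full(Q, sent, dtype=np.int32)
        bDprev = np.full(Q, sent, dtype=np.int32)
        bcol = j0 - 1
        for i in range(1, L_max + 1):                   # Loop B: rows
            if p == 0:
                xmxE = np.full(Q, sent, dtype=np.int32)
                Mnext = np.full(Q, sent, dtype=np.int32)
                Dcv = np.full(Q, sent, dtype=np.int32)
            elif carrier == "minimal":
                xmxE = c_xmxE[i].copy()
                Mnext = c_Mnext[i].copy()
                Dcv = c_Dcv[i].copy()
            else:
                # reconstruct Mnext from the previous row's boundary
                # triplet and Dcv from this row's, then stash this row's
                # triplet as next iteration's "previous row"
                xmxE = c_xmxE[i].copy()
                tb = trans[:, bcol]
                Mnext = np.maximum(
                    np.maximum(_vsat_add(bMprev, tb[T_MM], sent, maxv),
                               _vsat_add(bIprev, tb[T_IM], sent, maxv)),
                    _vsat_add(bDprev, tb[T_DM], sent, maxv))
                bM, bI, bD = c_Mb[i].copy(), c_Ib[i].copy(), c_Db[i].copy()
                Dcv = np.maximum(_vsat_add(bM, tb[T_MD], sent, maxv),
                                 _vsat_add(bD, tb[T_DD], sent, maxv))
                bMprev, bIprev, bDprev = bM, bI, bD

            mrows = load_emission_rows(qp, batch, i, table="match")
            irows = load_emission_rows(qp, batch, i, table="insert")
            for jb in range(j0, j1, Q):                 # Loop A: Q-blocks
                mtile = transpose_emissions(mrows, jb, Q)
                itile = transpose_emissions(irows, jb, Q)
                for s in range(Q):                      # unrolled triplets
                    j = jb + s
                    (Mcv, Icv, Dstore, Mnext, Dcv, xmxE) = \
                        compute_state_triplet(
                            Mmx[j], Imx[j], Dmx[j], Mnext, Dcv, xmxE,
                            mtile[s], itile[s], base_entry[j],
                            trans[:, j], sent, maxv)
                    Mmx[j] = Mcv
                    Imx[j] = Icv
                    Dmx[j] = Dstore

            if not last:
                # write the carrier line for partition p+1 (exactly 3
                # values per channel per row in minimal mode)
                c_xmxE[i] = xmxE
                if carrier == "minimal":
                    c_Mnext[i] = Mnext
                    c_Dcv[i] = Dcv
                else:
                    c_Mb[i] = Mmx[j1 - 1]
                    c_Ib[i] = Imx[j1 - 1]
                    c_Db[i] = Dmx[j1 - 1]
            else:
                # special states: E then C, finalized once per row here
                np.maximum(xC, xmxE, out=xC)
                ended = batch.true_lengths == i
                if ended.any():
                    snapshots[ended] = xC[ended]

    results = []
    for c in range(Q):
        raw = int(snapshots[c])
        results.append(ViterbiResult(
            seq_id=batch.ids[c], length=int(batch.true_lengths[c]),
            raw_score=raw,
            score_nats=params.dequantize(raw, qp.special.final_offset),
        ))
    return results
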