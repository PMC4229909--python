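"""FASTA input, batch scheduling and tabular result output."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .alphabets import Alphabet
from .engine import ChannelBatch
from .errors import CopsError
from .reference import ViterbiResult


@dataclass
class DigitizedSequence:
    """A sequence as integer residue codes into a model alphabet."""

    id: str
    residues: np.ndarray

    @property
    def L(self) -> int:
        return len(self.residues)


def read_fasta(path, alphabet: Alphabet, *,
               strict: bool = False) -> Iterator[DigitizedSequence]:
    """Stream digitized sequences from a FASTA file, in file order.

    Residues are case-insensitive.  Degenerate or unknown residues map to
    the alphabet's background-neutral degenerate code unless ``strict``.
    """
    for rec in SeqIO.parse(str(path), "fasta"):
        yield DigitizedSequence(
            id=rec.id,
            residues=alphabet.digitize(str(rec.seq), strict=strict,
                                       record_id=rec.id),
        )


def schedule_batches(seqs: Iterable[DigitizedSequence], Q: int = 8,
                     order_policy: str = "input") -> Iterator[ChannelBatch]:
    """Group sequences into Q-channel batches.

    ``order_policy="length"`` groups sequences of similar length together,
    reducing the empty padded cells of lock-step decoding; each batch
    remembers the original input indices so results can be re-emitted in
    input order.  The final partial batch is padded with inactive dummy
    channels.
    """
    seqs = list(seqs)
    order = list(range(len(seqs)))
    if order_policy == "length":
        # longest first: the sum of per-batch maxima is then minimal, and
        # the partial final batch (whose dummy channels each waste L_max
        # cells) holds the shortest sequences
        order.sort(key=lambda i: -seqs[i].L)  # stable: ties keep input order
    elif order_policy != "input":
        raise CopsError(f"unknown order policy {order_policy!r}")
    for start in range(0, len(order), Q):
        chunk = order[start:start + Q]
        yield ChannelBatch.from_sequences(
            [seqs[i].residues for i in chunk],
            ids=[seqs[i].id for i in chunk],
            Q=Q, orig_indices=chunk,
        )


def padded_cells(batches: Iterable[ChannelBatch]) -> int:
    """Total empty lock-step cells (dummy rows) across batches."""
    total = 0
    for b in batches:
        total += int(b.Q * b.L_max - b.true_lengths.sum())
    return total


RESULT_COLUMNS = ("seq_id", "length", "raw_score", "score_nats", "score_bits")


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "-inf" if x < 0 else "inf"
    return f"{x:.6f}"


def write_results(results: Iterable[ViterbiResult], path) -> None:
    """Write results as a TSV, one row per sequence, in the given order.

    ``raw_score`` is ``NA`` for float-decoded results; ``-inf`` scores are
    rendered literally.
    """
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for r in results:
                raw = "NA" if r.raw_score is None else str(r.raw_score)
                fh.write(f"{r.seq_id}\t{r.length}\t{raw}\t"
                         f"{_fmt(r.score_nats)}\t{_fmt(r.score_bits)}\n")
    except OSError as exc:
        raise CopsError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> list[ViterbiResult]:
    """Read back a results TSV (inverse of :func:`write_results`)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RESULT_COLUMNS:
            raise CopsError(f"unexpected results header in {path}")
        for ln in fh:
            sid, length, raw, nats, _bits = ln.rstrip("\n").split("\t")
            out.append(ViterbiResult(
                seq_id=sid, length=int(length),
                raw_score=None if raw == "NA" else int(raw),
                score_nats=float(nats),
            ))
    return out
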