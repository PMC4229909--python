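"""Residue alphabets and sequence digitization.

A digitized residue is an integer index into the model alphabet.  Two extra
codes exist beyond the ``K`` canonical residues:

* ``K`` — a *degenerate* residue (``N`` in DNA, ``X``/``B``/``Z`` etc. in
  protein).  Its emission log-odds is defined to be zero, i.e. the residue
  is scored exactly as the background, contributing nothing for or against
  the model at that position.
* ``K + 1`` — a *padding* code used internally by the lock-step engine for
  positions past a sequence's true end; its emission score is the -inf
  sentinel so padded cells can never create alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnsupportedAlphabetError, ValidationError

#: canonical residue orders (HMMER convention for amino acids)
DNA_SYMBOLS = "ACGT"
AMINO_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet of size ``K``."""

    name: str
    symbols: str
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def K(self) -> int:
        return len(self.symbols)

    @property
    def degenerate_code(self) -> int:
        return self.K

    @property
    def padding_code(self) -> int:
        return self.K + 1

    def digitize(self, seq: str, *, strict: bool = False,
                 record_id: str = "") -> np.ndarray:
        """Map a residue string to integer codes (case-insensitive).

        Unknown/degenerate residues map to :attr:`degenerate_code` by
        default; under ``strict`` they raise, naming the record and the
        1-based position.
        """
        out = np.empty(len(seq), dtype=np.int16)
        idx = self._index
        for i, ch in enumerate(seq.upper()):
            code = idx.get(ch)
            if code is None:
                if strict:
                    raise ValidationError(
                        f"record {record_id!r}: residue {ch!r} at position "
                        f"{i + 1} is not in the {self.name} alphabet"
                    )
                code = self.K
            out[i] = code
        return out


DNA = Alphabet("DNA", DNA_SYMBOLS)
AMINO = Alphabet("amino", AMINO_SYMBOLS)

_BY_NAME = {"dna": DNA, "amino": AMINO, "protein": AMINO}


def get_alphabet(name: str) -> Alphabet:
    """Look up an alphabet by (case-insensitive) name."""
    try:
        return _BY_NAME[name.strip().lower()]
    except KeyError:
        raise UnsupportedAlphabetError(
            f"unsupported alphabet {name!r}; supported: DNA, amino"
        ) from None
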