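"""Plan-7 profile HMM data types, ASCII model I/O, log-odds conversion and
16-bit score quantization.

The profile architecture is HMMER's *Plan 7*: per model node ``j`` a match
state ``M_j``, insert state ``I_j`` and delete state ``D_j`` with seven
transition types (M→M, M→I, M→D, I→M, I→I, D→M, D→D — no D↔I transitions),
plus flanking special states N, B, E, C configured here for *unihit local*
alignment: any match state can be entered from B and any match state can
exit to E, the N→N and C→C self loops score zero, and a fixed ``-2.0`` nat
offset is added to the final score to approximate the length-dependent
flank contribution ``log(L/(L+2))``.

Scoring pipeline::

    Plan7Profile  --to_log_odds-->  LogOddsProfile  --quantize-->  QuantizedProfile

Log-odds scores are in nats, ``ln(e/q)`` against the background ``q``.
Quantization multiplies by ``scale`` (units per nat, default 500), rounds,
and clamps into the signed 16-bit range; the 16-bit minimum is the -inf
sentinel, absorbing under saturated addition.  The additive ``bias``
(default 12000) is applied once to the dynamic-programming initialization,
not to the stored tables, so raw scores sit comfortably inside int16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabets import Alphabet, get_alphabet
from .errors import FormatError, QuantizationOverflowError, ValidationError

# transition column order, shared by every table in the package
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
TRANSITION_NAMES = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")

INT16_MAX = 32767
INT16_MIN = -32768  #: the -inf sentinel of the quantized pipeline


# ---------------------------------------------------------------------------
# probability-space profile
# ---------------------------------------------------------------------------

@dataclass
class Plan7Profile:
    """A profile HMM in probability space.

    Arrays are 0-indexed: row ``j - 1`` holds node ``j`` (``j = 1..M``).

    Parameters
    ----------
    name : str
        Free-text model name.
    alphabet : Alphabet
        Residue alphabet of size ``K``.
    match_emissions, insert_emissions : (M, K) float arrays
        Emission probabilities, each row summing to 1.
    transitions : (M, 7) float array
        Node transition probabilities in :data:`TRANSITION_NAMES` order.
        Rows satisfy ``MM+MI+MD = 1``, ``IM+II = 1``, ``DM+DD = 1``.
    background : (K,) float array
        Null-model residue distribution ``q``.
    """

    name: str
    alphabet: Alphabet
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def K(self) -> int:
        return self.alphabet.K

    def validate(self, tol: float = 1e-6) -> None:
        """Raise :class:`ValidationError` on any broken invariant."""
        M, K = self.M, self.K
        if M < 1:
            raise ValidationError("model must have at least one match state")
        for label, arr, shape in (
            ("match_emissions", self.match_emissions, (M, K)),
            ("insert_emissions", self.insert_emissions, (M, K)),
            ("transitions", self.transitions, (M, 7)),
            ("background", self.background, (K,)),
        ):
            if arr.shape != shape:
                raise ValidationError(f"{label}: shape {arr.shape} != {shape}")
            if np.any(arr < -tol) or np.any(arr > 1 + tol):
                raise ValidationError(f"{label}: probability outside [0, 1]")
        for label, sums in (
            ("match emissions", self.match_emissions.sum(axis=1)),
            ("insert emissions", self.insert_emissions.sum(axis=1)),
            ("M-state transitions",
             self.transitions[:, [T_MM, T_MI, T_MD]].sum(axis=1)),
            ("I-state transitions",
             self.transitions[:, [T_IM, T_II]].sum(axis=1)),
            ("D-state transitions",
             self.transitions[:, [T_DM, T_DD]].sum(axis=1)),
            ("background", np.array([self.background.sum()])),
        ):
            bad = np.nonzero(np.abs(sums - 1.0) > tol)[0]
            if bad.size:
                raise ValidationError(
                    f"{label} at node {bad[0] + 1} sum to {sums[bad[0]]:.8f}, "
                    f"not 1 ± {tol:g}"
                )


# ---------------------------------------------------------------------------
# HMMER3 ASCII subset I/O
# ---------------------------------------------------------------------------

_FORMAT_TAG = "HMMER3"


def _prob_to_field(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.5f}"


def _field_to_prob(tok: str, where: str) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise FormatError(f"{where}: bad score field {tok!r}") from None


def write_hmm(profile: Plan7Profile, path) -> None:
    """Write the HMMER3 ASCII subset this package reads.

    Probabilities are stored as ``-ln p`` with 5 decimals, ``*`` for zero.
    A ``BACKGR`` header line carries the background distribution (plain
    HMMER files omit it; see :func:`read_hmm`).
    """
    p = profile
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{_FORMAT_TAG}/f [copshmm]\n")
        fh.write(f"NAME  {p.name}\n")
        fh.write(f"LENG  {p.M}\n")
        fh.write(f"ALPH  {p.alphabet.name}\n")
        fh.write("BACKGR  "
                 + " ".join(_prob_to_field(q) for q in p.background) + "\n")
        fh.write("HMM  " + "  ".join(p.alphabet.symbols) + "\n")
        fh.write("     " + "  ".join(TRANSITION_NAMES) + "\n")
        # node 0: insert-0 emissions and begin transitions.  The decoder
        # derives local entry itself, so these carry no information here;
        # they are emitted for structural compatibility.
        fh.write("      "
                 + " ".join(_prob_to_field(q) for q in p.background) + "\n")
        fh.write("      " + " ".join(["*"] * 7) + "\n")
        for j in range(p.M):
            fh.write(f"{j + 1:7d} "
                     + " ".join(_prob_to_field(x)
                                for x in p.match_emissions[j]) + "\n")
            fh.write("        "
                     + " ".join(_prob_to_field(x)
                                for x in p.insert_emissions[j]) + "\n")
            fh.write("        "
                     + " ".join(_prob_to_field(x)
                                for x in p.transitions[j]) + "\n")
        fh.write("//\n")


def read_hmm(path) -> Plan7Profile:
    """Parse a HMMER3 ASCII model (the mandatory subset).

    Recognised header keys: ``NAME``, ``LENG``, ``ALPH``, and this
    package's optional ``BACKGR`` (background distribution as ``-ln q``
    fields).  When ``BACKGR`` is absent the background defaults to uniform.
    Optional annotation columns (MAP/CONS/RF/MM/CS) after the K match
    scores are ignored, as are ``COMPO`` and ``STATS`` lines.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    it = iter(enumerate(lines, start=1))

    def next_content():
        for no, ln in it:
            if ln.strip():
                return no, ln
        return None, None

    no, first = next_content()
    if first is None or not first.startswith(_FORMAT_TAG):
        raise FormatError(
            f"line {no or 1}: file does not start with a {_FORMAT_TAG} "
            "format tag"
        )

    name = "unnamed"
    M = None
    alphabet = None
    background = None
    while True:
        no, ln = next_content()
        if ln is None:
            raise FormatError("unexpected end of file before HMM line")
        key, _, rest = ln.strip().partition(" ")
        rest = rest.strip()
        if key == "NAME":
            name = rest
        elif key == "LENG":
            try:
                M = int(rest)
            except ValueError:
                raise FormatError(f"line {no}: bad LENG value {rest!r}") from None
        elif key == "ALPH":
            alphabet = get_alphabet(rest)
        elif key == "BACKGR":
            background = np.array(
                [_field_to_prob(t, f"line {no}") for t in rest.split()]
            )
        elif key == "HMM":
            break
        # other header keys (ACC, DESC, STATS, ...) are ignored

    if M is None or M < 1:
        raise FormatError("missing or invalid LENG header line")
    if alphabet is None:
        raise FormatError("missing ALPH header line")
    K = alphabet.K
    if background is None:
        background = np.full(K, 1.0 / K)
    elif background.shape != (K,):
        raise FormatError(
            f"BACKGR has {background.shape[0]} fields, expected {K}"
        )

    next_content()  # transition-name header line

    def score_line(n_expected: int, where: str, *, lead_index=None,
                   allow_extra=False):
        no, ln = next_content()
        if ln is None:
            raise FormatError(f"unexpected end of file at {where}")
        toks = ln.split()
        if lead_index is not None:
            if not toks or toks[0] != str(lead_index):
                raise FormatError(
                    f"line {no}: expected node {lead_index} match line, "
                    f"got {ln.strip()[:40]!r}"
                )
            toks = toks[1:]
        if len(toks) < n_expected or (
            not allow_extra and lead_index is None and len(toks) != n_expected
        ):
            raise FormatError(
                f"line {no}: {where}: expected {n_expected} fields, "
                f"got {len(toks)}"
            )
        return [_field_to_prob(t, f"line {no}") for t in toks[:n_expected]]

    # skip an optional COMPO line, then require the node-0 insert and
    # transition lines
    pos = None
    for no, ln in it:
        if ln.strip():
            pos = (no, ln)
            break
    if pos is None:
        raise FormatError("unexpected end of file after HMM header")
    if pos[1].split()[0] == "COMPO":
        score_line(K, "node 0 insert emissions")
    # else: pos was the node-0 insert line already — consume its values
    else:
        toks = pos[1].split()
        if len(toks) != K:
            raise FormatError(
                f"line {pos[0]}: node 0 insert emissions: expected {K} "
                f"fields, got {len(toks)}"
            )
    score_line(7, "node 0 transitions")

    match = np.empty((M, K))
    insert = np.empty((M, K))
    trans = np.empty((M, 7))
    for j in range(1, M + 1):
        match[j - 1] = score_line(K, f"node {j} match emissions",
                                  lead_index=j, allow_extra=True)
        insert[j - 1] = score_line(K, f"node {j} insert emissions")
        trans[j - 1] = score_line(7, f"node {j} transitions")

    no, ln = next_content()
    if ln is None or ln.strip() != "//":
        raise FormatError(f"line {no}: expected '//' terminator after node {M}")

    prof = Plan7Profile(name=name, alphabet=alphabet, match_emissions=match,
                        insert_emissions=insert, transitions=trans,
                        background=background)
    prof.validate(tol=1e-4)  # 5-decimal file encoding loosens normalization
    return prof


# ---------------------------------------------------------------------------
# log-odds conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecialConfig:
    """Scores (nats) of the unihit-local special transitions.

    ``nn``/``cc`` are the N→N and C→C self loops, ``nb`` is N→B, ``ec`` is
    E→C, ``exit`` is the uniform M_k→E local exit.  All default to zero;
    ``final_offset`` is the fixed -2.0 nat flank approximation added once
    to every final score.
    """

    nn: float = 0.0
    cc: float = 0.0
    nb: float = 0.0
    ec: float = 0.0
    exit: float = 0.0
    final_offset: float = -2.0


@dataclass
class LogOddsProfile:
    """Log-odds (nat) scores of a Plan-7 profile in unihit local mode.

    Emission score arrays have ``K + 1`` columns: column ``K`` is the
    degenerate residue, scored 0 (background-neutral).  ``entry_scores[k-1]``
    is the B→M_k local entry score.
    """

    name: str
    alphabet: Alphabet
    match_scores: np.ndarray       # (M, K+1)
    insert_scores: np.ndarray      # (M, K+1)
    transition_scores: np.ndarray  # (M, 7)
    entry_scores: np.ndarray       # (M,)
    special: SpecialConfig = field(default_factory=SpecialConfig)

    @property
    def M(self) -> int:
        return self.match_scores.shape[0]


def uniform_local_entry(M: int) -> np.ndarray:
    """The standard local-entry distribution B→M_k = 2(M-k+1)/(M(M+1))."""
    k = np.arange(1, M + 1)
    return 2.0 * (M - k + 1) / (M * (M + 1))


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def to_log_odds(profile: Plan7Profile, *,
                special: SpecialConfig | None = None,
                entry_probs: np.ndarray | None = None,
                score_insert_emissions: bool = True) -> LogOddsProfile:
    """Convert a probability-space profile to nat log-odds scores.

    Emissions become ``ln(e/q)``; transitions become ``ln t``; zero
    probabilities become ``-inf``.  ``entry_probs`` overrides the default
    uniform-local entry distribution.  With ``score_insert_emissions=False``
    insert emissions score 0 (the common HMMER filter convention) instead
    of ``ln(e_I/q)``.
    """
    # 1e-4 admits profiles round-tripped through the 5-decimal file encoding
    profile.validate(tol=1e-4)
    q = profile.background
    if np.any((q == 0) & (profile.match_emissions > 0).any(axis=0)):
        raise ValidationError(
            "background probability 0 for an emitted residue: log-odds "
            "undefined"
        )
    M, K = profile.M, profile.K

    def emis(e):
        s = np.empty((M, K + 1))
        with np.errstate(divide="ignore"):
            s[:, :K] = np.log(e / q)
        s[:, K] = 0.0  # degenerate residue: background-neutral
        return s

    match = emis(profile.match_emissions)
    if score_insert_emissions:
        insert = emis(profile.insert_emissions)
    else:
        insert = np.zeros((M, K + 1))
    trans = _safe_log(profile.transitions)
    if entry_probs is None:
        entry_probs = uniform_local_entry(M)
    entry = _safe_log(np.asarray(entry_probs, dtype=float))
    return LogOddsProfile(
        name=profile.name, alphabet=profile.alphabet, match_scores=match,
        insert_scores=insert, transition_scores=trans, entry_scores=entry,
        special=special if special is not None else SpecialConfig(),
    )


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantizationParams:
    """Fixed-point score representation.

    ``scale`` is quantized units per nat; ``bias`` is added once to the
    DP initialization so running scores stay inside int16.  The vector
    geometry (128-bit words of 16-bit lanes) fixes the channel count
    ``Q = vector_bits / word_bits = 8``.
    """

    scale: float = 500.0
    bias: int = 12000
    word_bits: int = 16
    vector_bits: int = 128

    @property
    def channels(self) -> int:
        return self.vector_bits // self.word_bits

    @property
    def sentinel_min(self) -> int:
        return -(1 << (self.word_bits - 1))

    @property
    def max_value(self) -> int:
        return (1 << (self.word_bits - 1)) - 1

    def __post_init__(self):
        if self.scale <= 0:
            raise ValidationError("quantization scale must be positive")
        if self.vector_bits % self.word_bits:
            raise ValidationError("vector_bits must be a multiple of word_bits")

    def dequantize(self, raw: int, final_offset: float = -2.0) -> float:
        """Map a raw DP score back to nats (including the final offset)."""
        if raw == self.sentinel_min:
            return float("-inf")
        return (raw - self.bias) / self.scale + final_offset


@dataclass
class QuantizedProfile:
    """Padded, integer-quantized score tables for the lock-step engine.

    Emission tables are laid out per residue as contiguous rows of length
    ``Mq`` (the padded model length): row ``r`` of ``match_scores`` is the
    match score of residue code ``r`` at every model column.  Two extra
    rows follow the K canonical residues: the degenerate residue (score 0
    inside the model, sentinel in the padding) and the all-sentinel
    padding row used for positions past a sequence's end.

    Transition tables are ``(7, Mq)`` plus the B→M entry row; padded
    columns ``j > M`` hold the sentinel everywhere ("dummy states").
    """

    name: str
    alphabet: Alphabet
    original_length: int
    padded_length: int
    match_scores: np.ndarray       # (K+2, Mq) int16
    insert_scores: np.ndarray      # (K+2, Mq) int16
    transition_scores: np.ndarray  # (7, Mq) int16
    entry_scores: np.ndarray       # (Mq,) int16
    params: QuantizationParams
    special: SpecialConfig = field(default_factory=SpecialConfig)

    @property
    def M(self) -> int:
        return self.original_length

    @property
    def Mq(self) -> int:
        return self.padded_length


def _quantize_array(arr: np.ndarray, params: QuantizationParams) -> np.ndarray:
    finite = np.isfinite(arr)
    q = np.rint(arr * params.scale)
    worst = q[finite].max(initial=0.0)
    if worst > params.max_value:
        raise QuantizationOverflowError(
            f"scale {params.scale} maps score {worst / params.scale:+.4f} "
            f"nats to {int(worst)}, outside the {params.word_bits}-bit range"
        )
    # deep negatives clamp to the smallest *finite* value; only true -inf
    # becomes the absorbing sentinel
    q = np.clip(q, params.sentinel_min + 1, params.max_value)
    out = q.astype(np.int16)
    out[~finite] = params.sentinel_min
    return out


def quantize(lo: LogOddsProfile,
             params: QuantizationParams | None = None) -> QuantizedProfile:
    """Quantize a log-odds profile and pad it to the channel barrier."""
    params = params or QuantizationParams()
    M, K = lo.M, lo.alphabet.K
    sent = params.sentinel_min

    def emis(scores):
        t = np.full((K + 2, M), sent, dtype=np.int16)
        t[:K + 1] = _quantize_array(scores.T, params)
        # row K+1 stays all-sentinel: the past-end padding residue
        return t

    qp = QuantizedProfile(
        name=lo.name, alphabet=lo.alphabet,
        original_length=M, padded_length=M,
        match_scores=emis(lo.match_scores),
        insert_scores=emis(lo.insert_scores),
        transition_scores=_quantize_array(lo.transition_scores.T, params),
        entry_scores=_quantize_array(lo.entry_scores, params),
        params=params, special=lo.special,
    )
    return pad_model(qp, params.channels)


def pad_model(qp: QuantizedProfile, Q: int) -> QuantizedProfile:
    """Pad the model with dummy states up to the next multiple-of-Q barrier.

    Dummy columns carry the -inf sentinel everywhere, so they can never
    contribute a path; scores at columns ``j <= M`` are untouched.
    Idempotent when already at the barrier.
    """
    if Q < 1:
        raise ValidationError("channel count must be >= 1")
    M = qp.original_length
    Mq = Q * ((M + Q - 1) // Q)
    if Mq <= qp.padded_length and qp.padded_length % Q == 0:
        return qp
    sent = qp.params.sentinel_min

    def pad2(a):
        out = np.full((a.shape[0], Mq), sent, dtype=np.int16)
        out[:, :M] = a[:, :M]
        return out

    entry = np.full(Mq, sent, dtype=np.int16)
    entry[:M] = qp.entry_scores[:M]
    return replace(
        qp, padded_length=Mq,
        match_scores=pad2(qp.match_scores),
        insert_scores=pad2(qp.insert_scores),
        transition_scores=pad2(qp.transition_scores),
        entry_scores=entry,
    )
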