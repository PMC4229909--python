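"""Deterministic generators of valid random profiles and sequences.

Every test and reproduction run in this package works from generated
inputs, so nothing need be downloaded.  Profiles draw emissions from
Dirichlet distributions (small concentration → peaked, profile-like
columns) and transitions from Dirichlet priors that favour the M→M
backbone, the dominant structure of real profile HMMs.  Sequences can be
sampled generatively from a profile (walking the unihit local state graph)
or from the background distribution, giving positive and negative decoys.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .alphabets import Alphabet, get_alphabet
from .errors import CopsError
from .profile import (
    Plan7Profile, QuantizationParams, quantize, to_log_odds,
    uniform_local_entry, write_hmm,
)
from .reference import viterbi_score_quantized_scalar
from .seqio import DigitizedSequence, write_results


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-profile generator.

    ``emission_concentration`` is the symmetric Dirichlet parameter for
    emission columns (0.3 by default: realistically peaked match columns;
    large values approach uniform).  ``transition_stickiness`` scales the
    Dirichlet weight on the M→M / I→I / D→D backbone.
    """

    seed: int = 0
    M: int = 50
    alphabet: str = "DNA"
    L_range: tuple = (10, 60)
    n_sequences: int = 16
    emission_concentration: float = 0.3
    transition_stickiness: float = 1.0


def sample_profile(cfg: GeneratorConfig) -> Plan7Profile:
    """Draw a random valid Plan-7 profile, deterministic under the seed."""
    if cfg.M < 1:
        raise CopsError("M must be >= 1")
    alphabet = get_alphabet(cfg.alphabet)
    K = alphabet.K
    if K < 2:
        raise CopsError("alphabet must have at least 2 symbols")
    rng = np.random.default_rng(cfg.seed)
    match = rng.dirichlet([cfg.emission_concentration] * K, size=cfg.M)
    insert = rng.dirichlet([cfg.emission_concentration * 4] * K, size=cfg.M)
    s = cfg.transition_stickiness
    m_trans = rng.dirichlet([20.0 * s, 1.0, 1.0], size=cfg.M)   # MM, MI, MD
    i_trans = rng.dirichlet([3.0, 1.0 * s], size=cfg.M)         # IM, II
    d_trans = rng.dirichlet([3.0, 1.0 * s], size=cfg.M)         # DM, DD
    transitions = np.hstack([m_trans, i_trans, d_trans])
    return Plan7Profile(
        name=f"synth-M{cfg.M}-{cfg.alphabet}-s{cfg.seed}",
        alphabet=alphabet,
        match_emissions=match,
        insert_emissions=insert,
        transitions=transitions,
        background=np.full(K, 1.0 / K),
    )


def sample_sequence_from(profile: Plan7Profile, seed: int, *,
                         exit_prob: float = 0.1,
                         flank_mean: float = 4.0,
                         seq_id: str = "") -> DigitizedSequence:
    """Emit a sequence by sampling a state path through the unihit graph.

    Entry node follows the uniform-local entry distribution; at each match
    state the path exits with probability ``exit_prob`` (always at node M);
    N/C flanks are geometric background residues of mean ``flank_mean``.
    """
    from .profile import T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD

    rng = np.random.default_rng(seed)
    M, K = profile.M, profile.K
    q = profile.background
    t = profile.transitions
    out = list(rng.choice(K, size=rng.geometric(1 / (1 + flank_mean)) - 1,
                          p=q))
    j = rng.choice(M, p=uniform_local_entry(M)) + 1
    state = "M"
    while True:
        if state == "M":
            out.append(int(rng.choice(K, p=profile.match_emissions[j - 1])))
            if j >= M or rng.random() < exit_prob:
                break
            move = rng.choice(3, p=t[j - 1][[T_MM, T_MI, T_MD]]
                              / t[j - 1][[T_MM, T_MI, T_MD]].sum())
            state = ("M", "I", "D")[move]
            j += move != 1
        elif state == "I":
            out.append(int(rng.choice(K, p=profile.insert_emissions[j - 1])))
            p = t[j - 1][[T_IM, T_II]]
            state = "M" if rng.random() < p[0] / p.sum() else "I"
            j += state == "M"
        else:  # D
            if j >= M:
                break  # delete path ran off the model end: no more matches
            p = t[j - 1][[T_DM, T_DD]]
            state = "M" if rng.random() < p[0] / p.sum() else "D"
            j += 1
    out.extend(rng.choice(K, size=rng.geometric(1 / (1 + flank_mean)) - 1,
                          p=q))
    return DigitizedSequence(id=seq_id or f"path{seed}",
                             residues=np.array(out, dtype=np.int16))


def sample_background_sequence(alphabet: Alphabet, L: int, seed: int,
                               background: np.ndarray | None = None,
                               seq_id: str = "") -> DigitizedSequence:
    """A length-L i.i.d. background sequence (negative decoy)."""
    rng = np.random.default_rng(seed)
    q = background if background is not None else np.full(alphabet.K,
                                                          1 / alphabet.K)
    return DigitizedSequence(
        id=seq_id or f"bg{seed}",
        residues=rng.choice(alphabet.K, size=L, p=q).astype(np.int16),
    )


def make_fixture_set(cfg: GeneratorConfig, outdir, *,
                     force: bool = False,
                     params: QuantizationParams | None = None) -> dict:
    """Write a self-contained fixture directory: model, FASTA, expected TSV.

    Expected scores come from the scalar quantized oracle — never from the
    lock-step engine — so the fixture can falsify the engine.  Byte
    deterministic under the config seed.
    """
    outdir = str(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise CopsError(f"refusing to write into non-empty {outdir!r} "
                        "(pass force=True)")
    os.makedirs(outdir, exist_ok=True)
    params = params or QuantizationParams()
    profile = sample_profile(cfg)
    alphabet = profile.alphabet
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.L_range
    seqs = []
    for i in range(cfg.n_sequences):
        sub = int(rng.integers(0, 2 ** 30))
        if i % 2 == 0:
            s = sample_sequence_from(profile, sub, seq_id=f"pos{i:03d}")
        else:
            s = sample_background_sequence(
                alphabet, int(rng.integers(lo, hi + 1)), sub,
                profile.background, seq_id=f"neg{i:03d}")
        seqs.append(s)

    hmm_path = os.path.join(outdir, "model.hmm")
    fasta_path = os.path.join(outdir, "sequences.fasta")
    tsv_path = os.path.join(outdir, "expected.tsv")
    write_hmm(profile, hmm_path)
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        for s in seqs:
            letters = "".join(alphabet.symbols[c] if c < alphabet.K else "N"
                              for c in s.residues)
            fh.write(f">{s.id}\n")
            for off in range(0, len(letters), 60):
                fh.write(letters[off:off + 60] + "\n")
    qp = quantize(to_log_odds(profile), params)
    expected = [viterbi_score_quantized_scalar(qp, s.residues, seq_id=s.id)
                for s in seqs]
    write_results(expected, tsv_path)
    return {"hmm": hmm_path, "fasta": fasta_path, "expected": tsv_path,
            "profile": profile, "sequences": seqs}
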