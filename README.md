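# copshmm

Cache-oblivious, inter-sequence lock-step Viterbi decoding of Plan-7
profile hidden Markov models in unihit local mode.

## The problem

Profile HMMs encode a sequence family position by position — match,
insert and delete states per model node — and homology search scores a
database sequence against the model with the Viterbi dynamic program,

```
V^M_j(i) = ln(e_Mj(x_i)/q_xi) + max{ V^M_{j-1}(i-1) + ln t_{M_{j-1}M_j},
                                     V^I_{j-1}(i-1) + ln t_{I_{j-1}M_j},
                                     V^D_{j-1}(i-1) + ln t_{D_{j-1}M_j},
                                     x_B + entry_j }
V^I_j(i) = ln(e_Ij(x_i)/q_xi) + max{ V^M_j(i-1) + ln t_{M_jI_j},
                                     V^I_j(i-1) + ln t_{I_jI_j} }
V^D_j(i) = max{ V^M_{j-1}(i) + ln t_{M_{j-1}D_j},
                V^D_{j-1}(i) + ln t_{D_{j-1}D_j} }
```

with flanking special states N, B, E, C configured for *unihit local*
alignment (any match state can start or end the aligned core; N→N and
C→C score 0 and a fixed −2.0 nat offset approximates their cumulative
contribution).  A fast 16-bit implementation quantizes the nat-scale
log-odds by a scale factor (500 units/nat) with an additive bias (12000)
on the DP initialization and *saturated* arithmetic, the 16-bit minimum
acting as an absorbing −∞.

This package implements an inter-sequence ("lock-step") decoder: eight
sequences occupy the eight 16-bit lanes of a notional 128-bit vector and
advance through the model together.  Two ideas make it cache-oblivious:

* **Inline striped emission loading** — each unrolled block of 8 model
  columns starts by transposing an 8×8 block of emission scores from the
  per-sequence continuous layout into per-column vectors, instead of
  pre-transposing whole rows through memory.
* **Model partitioning (loop tiling)** — the model's columns are split
  into partitions of at most MP state-triplets, sized from the L1 data
  cache (`MP = (size(L1D) − 900)/240`, shrunk by a safety fraction),
  iterated in an outermost loop.  Adjacent partitions exchange exactly
  **three values per sequence per row** — the running exit maximum
  `xmxE`, the partial next-column match `Mnext`, and the boundary delete
  `Dcv` — so the per-partition working set is constant regardless of
  model length.

The package's claim is *correctness*, verified three ways: exhaustive
path enumeration ≡ float Viterbi on small instances; the dequantized
16-bit scalar pipeline within the rounding bound `(2(L+M)+6)·0.5/scale`
nats of the float score; and the partitioned 8-channel engine **bit
exact** against the scalar pipeline for every partitioning and for a
full-boundary-column carrier variant.  This is a portable reference
implementation in NumPy/Python — it models the SIMD algorithm's
structure and semantics, not its machine-level speed.

## Worked example

Generate a self-contained fixture set (model + FASTA + oracle-scored
TSV), search it, and cross-check the engine:

```
$ cops synth --out-dir demo --seed 7 -m 24 --n-sequences 4
$ cops search --hmm demo/model.hmm --fasta demo/sequences.fasta --out demo/hits.tsv
$ cat demo/hits.tsv
seq_id  length  raw_score  score_nats  score_bits
pos000  13      13833       1.666000    2.403530
neg001  21      12304      -1.392000   -2.008231
pos002  11      11765      -2.470000   -3.563457
neg003  26      12265      -1.470000   -2.120762
```

`raw_score` is the integer DP result: `bias + scale·score` before the
offset, so `pos000`'s 13833 dequantizes to `(13833 − 12000)/500 − 2.0 =
1.666` nats (2.40 bits) — a sequence sampled *from* the model scoring
above background, while the background decoys (`neg*`) score below 0.

```
$ cops compare --hmm demo/model.hmm --fasta demo/sequences.fasta
sequences: 4
max |d_raw|: 0
max |d_nats| vs float: 0.003457
```

`d_raw = 0`: the lock-step engine matched the scalar quantized oracle
bit-for-bit; the dequantized scores sit 0.003 nats from the float
reference, inside the rounding bound.

```
$ cops plan --l1d-bytes 32768
{
  "l1d_bytes": 32768,
  "safety_fraction": 0.85,
  "MP": 112,
  "max_model_for_cache": {
    "cops": 167,
    "cops_partitioned": 132,
    "viterbi_filter": 1352
  }
}
```

A 32 KB L1D holds a non-partitioned 8-channel working set only up to
M = 167 states (192·167 + 700 = 32764 bytes); partitioning caps the
working set at MP = 112 state-triplets instead, independent of M.

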