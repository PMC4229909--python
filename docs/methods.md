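# Methods

## Model and scoring semantics

The decoder operates on Plan-7 profile HMMs: per node `j ∈ 1..M` a
match, insert and delete state with seven transition types (no D↔I
moves), plus flanking states N, B, E, C.  The alignment mode is fixed to
*unihit local*:

* **Local entry.**  B enters any match state `M_k`.  The entry
  distribution is the standard uniform-local convention
  `P(B→M_k) = 2(M−k+1)/(M(M+1))`, normalized over `k`, and overridable
  (`to_log_odds(entry_probs=...)`).  Delete states cannot be entered
  from B, so `D_1` is unreachable.
* **Local exit.**  Every match state exits to E at score 0.  E collects
  the row maximum over match values only.
* **Flanks.**  N→N and C→C self-loops score 0 and a fixed −2.0 nat
  offset is added once to the final score, approximating the cumulative
  flank contribution `ln(L/(L+2))` for large L.  With those choices the
  B value is a constant across rows, which is what lets the engine fold
  the entry contribution into a precomputed per-column constant.
* **No J state.**  Unihit mode removes the model re-entry loop; the
  score is read from `xC` at the row equal to the sequence's length.

All scores are natural-log odds against the background `q` (nats).
Insert emissions are scored as `ln(e_I/q)` by default; many production
filter implementations force them to 0, so `to_log_odds` exposes
`score_insert_emissions=False` for that convention.

A note on the delete recurrence: the log-odds recurrences are sometimes
written with an I→D term, but the Plan-7 topology has no I→D transition;
this implementation follows the topology (D receives from M and D only,
within the current row).

## Quantization

`QuantizationParams` fixes the 16-bit fixed-point representation:
`scale` = 500 quantized units per nat, `bias` = 12000 added once to the
DP initialization (so `raw = bias + scale·score` before the −2.0 offset
is applied at dequantization), int16 minimum (−32768) as the −∞
sentinel.  The scale/bias defaults are chosen so that with the −2 nat
offset, typical local-alignment scores of realistic models sit well
inside int16; they are configuration, not a claim of equality with any
particular production tool's constants.

Rules: finite scores map to `clamp(round(s·scale))`; a *positive* score
that would exceed +32767 raises (it would corrupt maxima silently),
while deep negatives clamp to −32767, the smallest *finite* value —
only a true zero probability becomes the sentinel.  Saturated addition
clamps into `[−32768, 32767]` and is absorbing at the sentinel: −∞ plus
anything is −∞.  Absorption is load-bearing — it is what makes the
dummy padding states and padded sequence rows provably inert — and it
is asserted directly in the tests, since native integers in this
implementation language neither wrap nor saturate.

The quantization error of a final score is bounded by the number of
quantized terms a path can sum: at most `L + M` emissions/transitions
pairs plus entry and bookkeeping, giving the bound
`(2(L+M)+6)·0.5/scale` nats used throughout the tests.  Randomized
measurement puts the observed error near 5 % of that bound.

## The lock-step engine

Eight sequences are decoded simultaneously (Q = 8 lanes of 16 bits in a
128-bit word; Q is a parameter, and Q = 16 models a 256-bit variant).
Loop structure: Loop C over model partitions, Loop B over sequence rows
1..L_max, Loop A over the partition's columns in unrolled blocks of Q.
Each block begins with an 8×8 transposition of emission scores from the
per-sequence *continuous* layout to the per-column *striped* layout
(`transpose_emissions`), done inline rather than via a pre-transposed
buffer in memory.  Lanes are held as int32 internally and clamped to the
16-bit range after every addition, which is bit-identical to true int16
saturation.

Per column the kernel (`compute_state_triplet`) computes M, I and the
next column's D, carrying two values across column iterations — the
partial next-column match `Mnext` (the max over the previous row's
triplet plus transitions; its emission is unknown until the next
column) and the current-row delete `Dcv` — plus the running exit
maximum `xmxE`.  Those three are exactly the values that must cross a
partition boundary, so the carrier line stores three values per channel
per row.  The entry contribution `bias + entry_j` is folded in at each
column rather than carried, keeping the carrier independent of it.

Partitioning correctness rests on two facts verified bit-exactly in the
tests: (1) any partitioning — including one partition per unrolled block
— produces the same raw scores as a single sweep, and (2) a variant
decoder that carries the *full* boundary state triplet per row (four
values: M, I, D and `xmxE`, with `Mnext`/`Dcv` recomputed on the
consuming side) agrees with the 3-value carrier, confirming the
minimization loses nothing.

Unequal lengths in a batch: the batch decodes to the longest member;
channels past their true length read the all-sentinel emission row, so
padded rows cannot start or extend an alignment, and each channel's
`xC` is snapshotted at its own true length.  A batch remainder is
filled with inactive dummy channels reporting −∞.  Model padding to the
multiple-of-Q barrier likewise uses sentinel scores in every table.

Special-state finalization (E → C, and the length snapshot) happens
only in the last partition of each row, where `xmxE` is complete.

## Cache planner

The inner loop's working set grows linearly in M: `192·M + 700` bytes
non-partitioned (three Q-lane state arrays, eight transition arrays,
match emissions, ~20 auxiliary vectors), `240·M + 900` with the
partition carrier arrays, against `24·M + 320` for a 16-bit striped
intra-sequence filter.  `max_model_for_cache` walks the footprint up to
the largest M that fits (167 for the 8-channel working set in 32 KB;
1352 for the striped filter — often quoted rounded to ≈1350).  The
partition length is `MP = (L1D − 900)/240` rounded down to a multiple
of Q, floored at Q, after multiplying by a safety fraction
(default 0.85) that leaves headroom for the cache lines the loop does
not own; 0.85 places MP at 112/48/224 for 32/16/64 KB caches,
matching the empirically optimal bands (112–120, ≈48, 216–224).  The
raw estimate (safety 1.0) gives 128 and 64 for 32/16 KB.

## Synthetic data

`synth` generates the inputs every test and reproduction run uses:

* **Profiles** — match emission columns from a symmetric Dirichlet with
  concentration 0.3 (peaked, conservation-like columns; 1e4 approaches
  uniform), insert emissions flatter (4× concentration), transitions
  Dirichlet-distributed with weight 20 on M→M (profiles are
  backbone-dominated), 3:1 on I→M and D→M.  Background is uniform.
* **Positive sequences** — sampled generatively: geometric N/C flanks of
  mean 4 background residues, entry node from the local-entry
  distribution, a walk over the transition probabilities with exit
  probability 0.1 per match visit (forced at node M).
* **Negatives** — i.i.d. background sequences of matched lengths.

What this emulates: score discrimination between family members and
background, realistic transition structure, degenerate residues (scored
background-neutral, i.e. log-odds 0).  What it does not: residue
composition bias, repeat structure, realistic family divergence or the
length distributions of curated databases — so passing tests establish
algorithmic correctness and score calibration of the pipeline, not
search sensitivity on real data.

Fixture sets (`make_fixture_set`) always score their expected TSV with
the *scalar* quantized oracle, never with the lock-step engine, so
fixtures can falsify the engine.

## Model file dialect

The reader parses the mandatory HMMER3 ASCII sections (format tag,
NAME/LENG/ALPH, the HMM header, node-0 lines, and per node the
match-emission, insert-emission and transition lines, probabilities
encoded as −ln p with `*` for zero); annotation columns and COMPO/STATS
lines are skipped.  Because the plain format does not carry a
background distribution (production tools hardwire it per alphabet),
the writer emits an optional `BACKGR` header line; on files without it
the background defaults to uniform.  The writer uses fixed 5-decimal
encoding, so write∘read is byte-stable and probabilities round-trip to
1e-5; validation after a file read therefore uses a 1e-4 normalization
tolerance (fresh in-memory profiles are held to 1e-6).

## Problem sizes and numerical choices

Randomized suites run at: enumeration cross-check M ≤ 4, L ≤ 5 (100
instances, exact to 1e-9); quantization bound M ≤ 120, L ≤ 200 (200
instances); engine bit-exactness M ≤ 64, L ≤ 48, all of MP ∈ {8, 48,
128, ≥Mq} (200 instances) — sizes chosen so the full suite completes in
about two minutes while covering multiple partitions, padded models,
empty and degenerate-residue sequences.  Ties in `max` resolve
identically in every implementation because all orderings use the same
operand order; `-inf` arithmetic in the float decoder never mixes signs,
so no NaNs can arise.

## Limitations

* Single-threaded, pure-Python/NumPy: the engine reproduces the SIMD
  algorithm's structure and bit-level semantics, not its throughput;
  no wall-clock or cache-miss measurement is attempted.
* Unihit local mode only — no multihit (J state), glocal or global
  configuration, no Forward/posterior decoding, no traceback/alignment
  output, and no E-value statistics.
* The `.hmm` dialect is the documented subset; binary model formats and
  model building from alignments are out of scope.
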