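"""Lock-step engine: transposition, triplet kernel, partitioned decoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copshmm import (
    ChannelBatch, PartitionPlan, ValidationError, choose_partition_plan,
    compute_state_triplet, decode_batch, load_emission_rows,
    transpose_emissions, viterbi_score_quantized_scalar,
)
from copshmm.reference import sat_add

from conftest import make_quantized, random_seq

SENT, MAXV = -32768, 32767


class TestTransposeEmissions:
    def test_constant_rows(self):
        rows = np.full((8, 16), 42)
        tile = transpose_emissions(rows, 8)
        assert tile.shape == (8, 8)
        assert np.all(tile == 42)

    def test_four_channel_striping(self):
        # channels a,b,c,d with per-sequence continuous layout
        # a0 a1 a2 a3 / b0 b1 ... become per-column vectors
        # (a0,b0,c0,d0), (a1,b1,c1,d1), ...
        rows = np.arange(16).reshape(4, 4)  # a=0..3, b=4..7, ...
        tile = transpose_emissions(rows, 0, Q=4)
        assert np.array_equal(tile[0], [0, 4, 8, 12])
        assert np.array_equal(tile[1], [1, 5, 9, 13])
        assert np.array_equal(tile[3], [3, 7, 11, 15])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_involution_on_8x8_blocks(self, seed):
        x = np.random.default_rng(seed).integers(SENT, MAXV, size=(8, 8))
        assert np.array_equal(
            transpose_emissions(transpose_emissions(x, 0), 0), x)

    def test_offset_out_of_range(self):
        with pytest.raises(ValidationError):
            transpose_emissions(np.zeros((8, 16), dtype=int), 9)

    def test_pure_transposition_against_source(self, rng):
        rows = rng.integers(SENT, MAXV, size=(8, 24))
        for j in (0, 8, 16):
            tile = transpose_emissions(rows, j)
            for s in range(8):
                for c in range(8):
                    assert tile[s][c] == rows[c][j + s]


class TestComputeStateTriplet:
    def _run(self, **kw):
        z = np.full(8, SENT, dtype=np.int32)
        args = dict(Mpv=z, Ipv=z, Dpv=z, Mnext=z, Dcv=z, xmxE=z,
                    em=z, ins=z, base_entry=SENT,
                    tcol=np.full(7, SENT), sent=SENT, maxv=MAXV)
        args.update(kw)
        return compute_state_triplet(**args)

    def test_all_sentinel_inputs_stay_sentinel(self):
        out = self._run()
        for v in out:
            assert np.all(np.asarray(v) == SENT)

    def test_sentinel_absorbing_against_finite_scores(self):
        # a sentinel lane plus any finite score stays sentinel
        out = self._run(em=np.full(8, 30000, dtype=np.int32),
                        tcol=np.zeros(7, dtype=np.int64))
        for v in out:
            assert np.all(np.asarray(v) == SENT)

    def test_single_finite_channel_matches_scalar_step(self):
        # channel 0 finite, others sentinel: channel isolation means the
        # finite lane reproduces the plain scalar recurrence step
        rngv = np.random.default_rng(5)
        def lane0(x):
            v = np.full(8, SENT, dtype=np.int32)
            v[0] = x
            return v
        Mpv, Ipv, Dpv = 120, -40, 15
        Mnext, Dcv = 33, -8
        em, ins = 250, -100
        base = 11000
        tcol = rngv.integers(-900, 0, size=7)
        Mcv, Icv, Dstore, Mnext2, Dcv2, xmxE = compute_state_triplet(
            lane0(Mpv), lane0(Ipv), lane0(Dpv), lane0(Mnext), lane0(Dcv),
            np.full(8, SENT, dtype=np.int32), lane0(em), lane0(ins),
            base, tcol, SENT, MAXV)
        s = lambda a, b: sat_add(a, int(b), SENT, MAXV)
        assert Mcv[0] == s(max(Mnext, base), em)
        assert Icv[0] == s(max(s(Mpv, tcol[1]), s(Ipv, tcol[4])), ins)
        assert Dstore[0] == Dcv
        assert Mnext2[0] == max(s(Mpv, tcol[0]), s(Ipv, tcol[3]),
                                s(Dpv, tcol[5]))
        assert Dcv2[0] == max(s(Mcv[0], tcol[2]), s(Dcv, tcol[6]))
        assert xmxE[0] == Mcv[0]
        # other lanes untouched by the finite channel
        assert np.all(Mcv[1:] == SENT) and np.all(Mnext2[1:] == SENT)


class TestLoadEmissionRows:
    def test_channel_past_end_gets_sentinel_row(self, quantized_pair):
        _, qp = quantized_pair
        batch = ChannelBatch.from_sequences(
            [np.zeros(3, dtype=np.int16), np.zeros(6, dtype=np.int16)])
        rows = load_emission_rows(qp, batch, 5)
        assert np.all(rows[0] == qp.params.sentinel_min)  # len 3 < row 5
        assert np.array_equal(rows[1], qp.match_scores[0])

    def test_identical_residues_identical_rows(self, quantized_pair):
        _, qp = quantized_pair
        batch = ChannelBatch.from_sequences(
            [np.full(4, 2, dtype=np.int16)] * 8)
        rows = load_emission_rows(qp, batch, 2)
        assert all(np.array_equal(rows[0], rows[c]) for c in range(8))

    def test_row_equals_direct_table_lookup(self, quantized_pair, rng):
        _, qp = quantized_pair
        seqs = [random_seq(rng, int(rng.integers(1, 12)), p_degenerate=0.2)
                for _ in range(8)]
        batch = ChannelBatch.from_sequences(seqs)
        for _ in range(100):
            c = int(rng.integers(0, 8))
            i = int(rng.integers(1, batch.L_max + 1))
            rows = load_emission_rows(qp, batch, i)
            if i <= len(seqs[c]):
                want = qp.match_scores[seqs[c][i - 1]]
            else:
                want = np.full(qp.padded_length, qp.params.sentinel_min)
            assert np.array_equal(rows[c], want)


def _random_batch(rng, n=None, L_hi=30, degenerate=True):
    n = n if n is not None else int(rng.integers(1, 9))
    seqs = [random_seq(rng, int(rng.integers(0, L_hi)),
                       p_degenerate=0.2 if degenerate else 0.0)
            for _ in range(n)]
    return seqs, ChannelBatch.from_sequences(seqs)


class TestDecodeBatch:
    def test_identical_sequences_identical_scores(self, quantized_pair,
                                                  rng):
        _, qp = quantized_pair
        seq = random_seq(rng, 12)
        batch = ChannelBatch.from_sequences([seq] * 8)
        raws = {r.raw_score for r in decode_batch(qp, batch)}
        assert len(raws) == 1

    def test_bit_exact_vs_scalar_oracle(self, rng):
        for t in range(25):
            _, qp = make_quantized(seed=700 + t, M=int(rng.integers(1, 40)))
            seqs, batch = _random_batch(rng)
            res = decode_batch(qp, batch)
            for c, s in enumerate(seqs):
                assert res[c].raw_score == \
                    viterbi_score_quantized_scalar(qp, s).raw_score

    def test_partition_invariance(self, rng):
        _, qp = make_quantized(seed=42, M=37)
        seqs, batch = _random_batch(rng)
        one = decode_batch(qp, batch, PartitionPlan.single(qp.padded_length))
        maxi = decode_batch(qp, batch, choose_partition_plan(qp.padded_length, 8))
        assert [r.raw_score for r in one] == [r.raw_score for r in maxi]

    def test_channel_permutation_permutes_results(self, rng):
        _, qp = make_quantized(seed=43, M=20)
        seqs, batch = _random_batch(rng, n=8)
        perm = rng.permutation(8)
        batch2 = ChannelBatch.from_sequences([seqs[i] for i in perm])
        raws = [r.raw_score for r in decode_batch(qp, batch)]
        raws2 = [r.raw_score for r in decode_batch(qp, batch2)]
        assert raws2 == [raws[i] for i in perm]

    def test_dummy_channels_report_neg_inf(self, rng):
        _, qp = make_quantized(seed=44, M=10)
        seqs, batch = _random_batch(rng, n=3)
        res = decode_batch(qp, batch)
        for c in range(3, 8):
            assert res[c].raw_score == qp.params.sentinel_min
            assert res[c].score_nats == -np.inf

    def test_batch_length_padding_invariance(self, rng):
        # a sequence's score does not depend on longer batch mates
        _, qp = make_quantized(seed=45, M=24)
        short = random_seq(rng, 6)
        long = random_seq(rng, 29)
        alone = decode_batch(qp, ChannelBatch.from_sequences([short]))
        mixed = decode_batch(qp, ChannelBatch.from_sequences([short, long]))
        assert alone[0].raw_score == mixed[0].raw_score

    def test_carrier_modes_agree(self, rng):
        for t in range(8):
            _, qp = make_quantized(seed=800 + t, M=int(rng.integers(9, 50)))
            seqs, batch = _random_batch(rng)
            plan = choose_partition_plan(qp.padded_length, 8)
            a = decode_batch(qp, batch, plan, carrier="minimal")
            b = decode_batch(qp, batch, plan, carrier="full-column")
            assert [r.raw_score for r in a] == [r.raw_score for r in b]

    def test_plan_mismatch_rejected(self, quantized_pair):
        _, qp = quantized_pair
        batch = ChannelBatch.from_sequences([np.zeros(2, dtype=np.int16)])
        bad = PartitionPlan(MP=8, ranges=((0, 8),))  # model has 24 columns
        with pytest.raises(ValidationError):
            decode_batch(qp, batch, bad)

    def test_empty_batch_all_neg_inf(self, quantized_pair):
        _, qp = quantized_pair
        batch = ChannelBatch.from_sequences([])
        res = decode_batch(qp, batch)
        assert all(r.score_nats == -np.inf for r in res)
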