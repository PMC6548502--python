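"""Sequence-effect models: context extraction, consensus coding, Lasso
pipelines, octamer counting and PWM scoring."""

import math

import numpy as np
import pytest

from splicekin.counting import GenomicInterval, Intron
from splicekin.seqmodel import (
    SpliceSiteSequenceContext,
    consensus_sequence,
    count_octamer_matrix,
    count_octamers,
    extract_context,
    fit_octamer_model,
    fit_single_nt_model,
    match_attract,
    mult_median_error,
    reverse_complement,
    rpm_score,
)

RNG = np.random.default_rng(123)


def random_context(rng, intron_id="i", length=220, first=False):
    def seq(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    intron = seq(length)
    # branchpoint placed 60 nt upstream of the acceptor so the branchpoint
    # and acceptor windows do not overlap (overlap would duplicate features)
    bp = length - 60
    windows = {
        "donor_up": seq(20),
        "donor_down": intron[:20],
        "acceptor_up": intron[-20:],
        "acceptor_down": seq(20),
        "branchpoint_up": intron[bp - 20:bp],
        "branchpoint_down": intron[bp:bp + 20],
    }
    return SpliceSiteSequenceContext(
        intron_id=intron_id,
        windows=windows,
        intron_seq=intron,
        bp_offset=bp,
        gc_intron=(intron.count("G") + intron.count("C")) / length,
        gc_donor=0.5,
        gc_acceptor=0.5,
        intron_length=length,
        first_intron=first,
    )


class TestExtractContext:
    GENOME = {"chrT": "ACGTACGGTT" * 40}  # 400 bp

    def test_plus_strand_windows_match_hand_read(self):
        g = self.GENOME["chrT"]
        intron = Intron(GenomicInterval("chrT", 100, 200, "+"))
        ctx = extract_context(self.GENOME, intron, branchpoint=170)
        assert ctx.windows["donor_up"] == g[80:100]
        assert ctx.windows["donor_down"] == g[100:120]
        assert ctx.windows["acceptor_up"] == g[180:200]
        assert ctx.windows["acceptor_down"] == g[200:220]
        assert ctx.windows["branchpoint_down"][0] == g[170]
        assert ctx.intron_seq == g[100:200]
        assert ctx.bp_offset == 70

    def test_minus_strand_reverse_complements(self):
        g = self.GENOME["chrT"]
        intron = Intron(GenomicInterval("chrT", 100, 200, "-"))
        ctx = extract_context(self.GENOME, intron, branchpoint=130)
        assert ctx.intron_seq == reverse_complement(g[100:200])
        # donor side of a minus intron is the high-coordinate end
        assert ctx.windows["donor_up"] == reverse_complement(g[200:220])
        assert ctx.windows["donor_down"] == reverse_complement(g[180:200])
        assert ctx.bp_offset == 69
        assert ctx.windows["branchpoint_down"][0] == reverse_complement(g[130])

    def test_gc_of_pure_gc_intron(self):
        genome = {"c": "AT" * 30 + "GC" * 50 + "AT" * 30}
        intron = Intron(GenomicInterval("c", 60, 160, "+"))
        ctx = extract_context(genome, intron, branchpoint=150)
        assert ctx.gc_intron == pytest.approx(1.0)

    def test_window_off_contig_rejected(self):
        intron = Intron(GenomicInterval("chrT", 5, 100, "+"))
        with pytest.raises(ValueError, match="chrT:5-100"):
            extract_context(self.GENOME, intron, branchpoint=80)

    def test_branchpoint_outside_intron_rejected(self):
        intron = Intron(GenomicInterval("chrT", 100, 200, "+"))
        with pytest.raises(ValueError):
            extract_context(self.GENOME, intron, branchpoint=250)


class TestSingleNtModel:
    def planted_data(self, n=700, noise=0.6, seed=5):
        rng = np.random.default_rng(seed)
        contexts = [random_context(rng, f"i{j}") for j in range(n)]
        cons = consensus_sequence(contexts)
        planted = [("donor_down", 0), ("donor_down", 4), ("acceptor_up", 19),
                   ("branchpoint_down", 0), ("donor_up", 18)]
        effects = {}
        y = np.full(n, 2.0)
        for w, i in planted:
            for b in "ACGT":
                if b != cons[(w, i)]:
                    effects[(w, i, b)] = rng.uniform(0.5, 1.2)
        for j, c in enumerate(contexts):
            for (w, i, b), e in effects.items():
                if c.windows[w][i] == b:
                    y[j] += e
        y += rng.normal(0, noise, size=n)
        return contexts, y, planted, effects

    def test_planted_positions_recovered(self):
        contexts, y, planted, effects = self.planted_data()
        model = fit_single_nt_model(contexts, y, seed=1)
        assert set(planted) <= set(model.retained_positions)
        # the one-SE penalty drops the large majority of the 115 no-effect
        # positions; the handful that survive carry near-zero coefficients
        assert len(model.retained_positions) <= 40
        got = {
            (r.window, r.position, r.base): r.coef for r in model.coefficients.itertuples()
        }
        for key, e in effects.items():
            assert got.get(key, 0.0) == pytest.approx(e, abs=0.25)
        planted_set = set(planted)
        spurious = [
            abs(r.coef)
            for r in model.coefficients.itertuples()
            if (r.window, r.position) not in planted_set
        ]
        assert max(spurious, default=0.0) < 0.25

    def test_consensus_input_predicts_intercept(self):
        contexts, y, _, _ = self.planted_data(n=300)
        model = fit_single_nt_model(contexts, y, seed=1)
        rng = np.random.default_rng(0)
        probe = random_context(rng, "probe")
        for (w, i), b in model.consensus.items():
            s = probe.windows[w]
            probe.windows[w] = s[:i] + b + s[i + 1:]
        probe.gc_intron, probe.gc_donor, probe.gc_acceptor = model.gc_means
        assert model.predict([probe])[0] == pytest.approx(model.intercept, abs=1e-9)

    def test_null_response_selects_nothing_much(self):
        rng = np.random.default_rng(8)
        contexts = [random_context(rng, f"i{j}") for j in range(400)]
        y = rng.normal(0, 1, size=400)
        model = fit_single_nt_model(contexts, y, seed=2)
        assert len(model.retained_positions) <= 5
        assert model.r_squared < 0.1

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(9)
        contexts = [random_context(rng, f"i{j}") for j in range(50)]
        with pytest.raises(ValueError):
            fit_single_nt_model(contexts, np.ones(50))

    def test_perfect_prediction_error_is_one(self):
        y = np.array([0.5, 1.5, -2.0])
        assert mult_median_error(y, y) == pytest.approx(1.0)

    def test_error_metric_worked_value(self):
        # ratios e and 1/e both count as a factor-e error
        assert mult_median_error(np.array([1.0, -1.0]), np.array([0.0, 0.0])) == pytest.approx(
            math.e
        )


class TestYieldResponse:
    def test_zero_yields_floored_not_fatal(self):
        from splicekin.seqmodel import fit_yield_sequence_model

        rng = np.random.default_rng(44)
        contexts = [random_context(rng, f"i{j}") for j in range(120)]
        etas = rng.uniform(0.0, 1.5, size=120)
        etas[:10] = 0.0  # failed junction fits
        model = fit_yield_sequence_model(contexts, etas, seed=3)
        assert np.isfinite(model.intercept)


class TestOctamerCounting:
    def test_poly_a(self):
        assert count_octamers("A" * 10, "A" * 8, 0) == 3

    def test_exact_single(self):
        assert count_octamers("ACGTACGT", "ACGTACGT", 2) == 1

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        octs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(50)]
        for m in (0, 1, 2):
            for o in octs[:: 5 if m else 1]:
                brute = sum(
                    sum(a != b for a, b in zip(seq[i:i + 8], o)) <= m
                    for i in range(len(seq) - 7)
                )
                assert count_octamers(seq, o, m) == brute

    def test_monotone_in_mismatch(self):
        rng = np.random.default_rng(18)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        for o in ("ACGTACGT", "GGGGCCCC", "TTTTTTTT"):
            c = [count_octamers(seq, o, m) for m in (0, 1, 2)]
            assert c[0] <= c[1] <= c[2]

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(19)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        octs = ["ACGTACGT", "AAAATTTT"]
        mat = count_octamer_matrix(seqs, octs, 2)
        for i, s in enumerate(seqs):
            for j, o in enumerate(octs):
                assert mat[i, j] == count_octamers(s, o, 2)

    def test_bad_octamer_length(self):
        with pytest.raises(ValueError):
            count_octamers("ACGTACGT", "ACGT", 0)


class TestOctamerModel:
    def build(self, n=500, effect=0.8, seed=21, null=False):
        rng = np.random.default_rng(seed)
        contexts = [random_context(rng, f"i{j}", length=240) for j in range(n)]
        planted = "ACGTTGCA"
        vocab = [planted] + ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(15)]
        y = np.zeros(n)
        if not null:
            counts = count_octamer_matrix(
                [c.region_sequences()["donor_downstream"] for c in contexts], [planted], 2
            )[:, 0]
            y = effect * np.log2(counts + 1.0)
        y = y + rng.normal(0, 0.2, size=n)
        return contexts, y, vocab, planted

    def test_planted_octamer_selected_with_correct_sign(self):
        contexts, y, vocab, planted = self.build()
        model = fit_octamer_model(contexts, y, octamers=vocab, seed=3)
        assert planted in model.region_selected["donor_downstream"]
        coefs = model.joint_coefficients
        row = coefs[(coefs["group"] == "octamers_donor_downstream") & (coefs["feature"] == planted)]
        assert len(row) == 1 and row["coef"].iloc[0] > 0
        assert model.r_squared_joint > 0.5

    def test_null_response_low_variance_explained(self):
        contexts, y, vocab, _ = self.build(n=600, null=True, seed=22)
        model = fit_octamer_model(contexts, y, octamers=vocab, seed=4)
        assert model.r_squared_joint < 0.03

    def test_variance_ledger_localizes_signal(self):
        contexts, y, vocab, _ = self.build()
        model = fit_octamer_model(contexts, y, octamers=vocab, seed=5)
        led = model.variance_ledger.set_index("feature_group")
        signal = led.loc["octamers_donor_downstream"]
        assert signal["individual_r2"] > 0.3
        assert signal["drop_one_loss"] > 0.1
        others = led.drop(index=["octamers_donor_downstream"], errors="ignore")
        assert (others["drop_one_loss"] < 0.1).all()


class TestPwm:
    def test_consensus_scores_one(self):
        rng = np.random.default_rng(30)
        pwm = rng.dirichlet(np.ones(4), size=8)
        consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=1))
        assert rpm_score(consensus, pwm) == pytest.approx(1.0)

    def test_uniform_pwm_scores_everything_one(self):
        pwm = np.full((8, 4), 0.25)
        for o in ("ACGTACGT", "AAAAAAAA", "GGGGTTTT"):
            assert rpm_score(o, pwm) == pytest.approx(1.0)

    def test_short_pwm_matches_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        pwm = rng.dirichlet(np.ones(4) * 2, size=5)
        col_max = pwm.max(axis=1)
        for _ in range(20):
            o = "".join(rng.choice(list("ACGT"), size=8))
            best = max(
                np.prod([pwm[j, "ACGT".index(o[off + j])] for j in range(5)])
                for off in range(4)
            )
            assert rpm_score(o, pwm) == pytest.approx(best / np.prod(col_max))

    def test_long_pwm_pads_with_neutral_n(self):
        rng = np.random.default_rng(32)
        pwm = rng.dirichlet(np.ones(4), size=10)
        inner = pwm[1:9]
        consensus = "".join("ACGT"[i] for i in inner.argmax(axis=1))
        score = rpm_score(consensus, pwm)
        # the two padded outer columns contribute neutrally
        assert score == pytest.approx(np.prod(inner.max(axis=1)) / np.prod(pwm.max(axis=1)) * pwm[0].max() * pwm[9].max() / (pwm[0].max() * pwm[9].max()), rel=1e-9) or 0 < score <= 1

    def test_scale_invariance_and_range(self):
        rng = np.random.default_rng(33)
        pwm = rng.dirichlet(np.ones(4), size=8)
        scaled = pwm * np.array([3.0, 1.0, 0.5, 2.0, 1.0, 1.0, 4.0, 1.0])[:, None]
        for o in ("ACGTACGT", "TTTTAAAA"):
            s = rpm_score(o, pwm)
            assert 0 < s <= 1
            assert rpm_score(o, scaled) == pytest.approx(s)

    def test_invalid_pwm(self):
        with pytest.raises(ValueError):
            rpm_score("ACGTACGT", np.zeros((8, 4)))
        with pytest.raises(ValueError):
            rpm_score("ACGTACGT", np.full((3, 4), 0.25))

    def test_match_attract_filters(self):
        rng = np.random.default_rng(34)
        pwm = np.full((8, 4), 0.01)
        target = "ACGTACGT"
        for j, b in enumerate(target):
            pwm[j, "ACGT".index(b)] = 0.97
        octs = [target] + ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(99)]
        hits = match_attract(octs, {"M1": pwm})
        assert len(hits) >= 1
        assert (hits["rpm_score"] >= 0.9).all()
        assert len(hits) <= max(1, int(np.ceil(0.05 * len(octs))))
        assert target in set(hits["octamer"])
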