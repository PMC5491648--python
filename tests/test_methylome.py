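import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from saltphen import simulate
from saltphen.methylome import (
    LowIdentityError,
    ReferenceRegion,
    align_clone,
    align_clones,
    call_dmrs,
    call_methylation,
    classify_context,
    reference_contexts,
    summarize_context,
)

REF = "ATCGGACGTTCATCGACCGTGCATTACGGA"


def _exhaustive_best_score(a, b, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Brute-force optimal affine-gap global alignment score for tiny inputs.

    Enumerates every monotone alignment path recursively; a gap run of
    length k costs gap_open + (k-1)*gap_extend.
    """

    best = -math.inf

    def recurse(i, j, score, state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            recurse(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open
            recurse(i + 1, j, score + cost, "X")
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open
            recurse(i, j + 1, score + cost, "Y")

    recurse(0, 0, 0.0, "M")
    return best


class TestAlignment:
    def test_fully_converted_clone_aligns_gaplessly(self):
        clone = REF.replace("C", "T")
        aln = align_clone(REF, clone)
        assert "-" not in aln.ref_aligned and "-" not in aln.clone_aligned
        assert aln.identity == 1.0
        assert aln.clone_aligned == clone

    def test_identical_clone_aligns_gaplessly(self):
        aln = align_clone(REF, REF)
        assert aln.ref_aligned == aln.clone_aligned == REF
        assert aln.identity == 1.0

    def test_internal_deletion_yields_single_gap_run(self):
        clone = REF[:10] + REF[13:]
        aln = align_clone(REF, clone)
        gaps = [len(g) for g in "".join(
            c if c == "-" else " " for c in aln.clone_aligned
        ).split()]
        assert gaps == [3]
        assert aln.ref_aligned.replace("-", "") == REF

    def test_conversion_never_penalized(self):
        """A partially converted clone scores the same as the reference itself."""
        rng = np.random.default_rng(1)
        clone = "".join(
            "T" if (b == "C" and rng.random() < 0.5) else b for b in REF
        )
        assert align_clone(REF, clone).score == align_clone(REF, REF).score

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_oracle_on_tiny_inputs(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        a = "".join(rng.choice(bases, size=int(rng.integers(4, 8))))
        b = "".join(rng.choice(bases, size=int(rng.integers(4, 8))))
        aln = align_clone(a.replace("C", "G"), b.replace("C", "G"), min_identity=0.0)
        assert aln.score == pytest.approx(
            _exhaustive_best_score(a.replace("C", "G"), b.replace("C", "G"))
        )

    def test_low_identity_clone_rejected_and_skipped(self):
        junk = "G" * len(REF)
        with pytest.raises(LowIdentityError):
            align_clone(REF, junk)
        kept = align_clones(REF, [REF, junk])
        assert len(kept) == 1


class TestContext:
    @pytest.mark.parametrize(
        "seq, pos, expected",
        [
            ("ACGT", 1, "CG"),
            ("ACAGT", 1, "CHG"),
            ("ACAAT", 1, "CHH"),
            ("ACCGT", 1, "CHG"),
            ("AACC", 3, "unknown"),  # fewer than two downstream bases
            ("AACG", 2, "CG"),
            ("ACNAT", 1, "unknown"),
            ("ACANT", 1, "unknown"),
        ],
    )
    def test_definition(self, seq, pos, expected):
        assert classify_context(seq, pos) == expected

    def test_non_cytosine_position_rejected(self):
        with pytest.raises(ValueError):
            classify_context("ACGT", 0)

    def test_contexts_are_a_pure_function_of_the_reference(self):
        ctx1 = reference_contexts(REF)
        ctx2 = reference_contexts(REF)
        assert ctx1 == ctx2
        assert set(ctx1) == {i for i, b in enumerate(REF) if b == "C"}


class TestCalls:
    def test_unconverted_clone_is_fully_methylated(self):
        calls = call_methylation(REF, [align_clone(REF, REF)])
        assert (calls["state"] == "methylated").all()

    def test_converted_clone_is_fully_unmethylated(self):
        clone = REF.replace("C", "T")
        calls = call_methylation(REF, [align_clone(REF, clone)])
        assert (calls["state"] == "unmethylated").all()

    def test_foreign_base_is_ambiguous_only_there(self):
        c_pos = REF.index("C")
        clone = REF[:c_pos] + "G" + REF[c_pos + 1 :]
        calls = call_methylation(REF, [align_clone(REF, clone)])
        assert (calls.loc[calls["pos"] == c_pos, "state"] == "ambiguous").all()
        others = calls[calls["pos"] != c_pos]
        assert (others["state"] == "methylated").all()

    def test_call_partition_is_complete(self):
        """methylated + unmethylated + ambiguous = n_reference_Cs × n_clones."""
        clones = [REF, REF.replace("C", "T"), REF[:10] + REF[13:]]
        alignments = align_clones(REF, clones)
        calls = call_methylation(REF, alignments)
        n_c = sum(1 for b in REF if b == "C")
        assert len(calls) == n_c * len(alignments)


class TestSummaries:
    def test_extreme_summaries(self):
        calls = call_methylation(REF, [align_clone(REF, REF)])
        summary = summarize_context(calls)
        for ctx in ("CG", "CHG", "CHH", "total"):
            if summary.counts.get(ctx, (0, 0)) != (0, 0):
                assert summary.percent(ctx) == 100.0

    def test_empty_context_is_missing_not_zero(self):
        calls = pd.DataFrame(
            {"pos": [0], "clone": [0], "context": ["CG"], "state": ["methylated"]}
        )
        summary = summarize_context(calls)
        assert summary.percent("CHH") is None
        assert summary.percent("CG") == 100.0

    def test_binomial_recovery_at_fixed_probability(self):
        """10 clones at p=0.78: estimate inside the exact binomial 99% CI."""
        p_true = 0.78
        ref = simulate.gen_reference(400, 0.45, seed=21)
        scenario = simulate.MethylomeScenario(p_true, p_true, p_true, n_clones=10)
        clones = simulate.gen_bisulfite_clones(ref, scenario, seed=21).clones
        calls = call_methylation(ref, align_clones(ref, clones))
        m, u = summarize_context(calls).total
        lo, hi = sps.binom.interval(0.99, m + u, p_true)
        assert lo <= m <= hi


class TestDmrs:
    def _calls(self, ref, p, n_clones, seed):
        scenario = simulate.MethylomeScenario(p, p, p, n_clones=n_clones)
        clones = simulate.gen_bisulfite_clones(ref, scenario, seed).clones
        return call_methylation(ref, align_clones(ref, clones))

    def test_identical_samples_have_no_dmrs(self):
        ref = simulate.gen_reference(200, 0.5, seed=3)
        calls = self._calls(ref, 0.6, 10, seed=3)
        tests = call_dmrs(calls, calls.copy(), len(ref))
        assert tests and not any(t.is_dmr for t in tests)
        assert all(t.p_value == pytest.approx(1.0, rel=1e-9) for t in tests)

    def test_extreme_window_matches_hypergeometric_enumeration(self):
        calls_a = pd.DataFrame(
            {"pos": list(range(20)), "clone": 0, "context": "CG", "state": "methylated"}
        )
        calls_b = calls_a.assign(state="unmethylated")
        (test,) = call_dmrs(calls_a, calls_b, region_length=20, window=100, step=50)
        assert test.p_value == pytest.approx(2 / math.comb(40, 20), rel=1e-9)
        assert test.is_dmr and test.direction == "hyper"

    def test_swapping_samples_flips_direction_and_keeps_p(self):
        ref = simulate.gen_reference(200, 0.5, seed=9)
        calls_a = self._calls(ref, 0.9, 10, seed=4)
        calls_b = self._calls(ref, 0.5, 10, seed=5)
        fwd = call_dmrs(calls_a, calls_b, len(ref))
        rev = call_dmrs(calls_b, calls_a, len(ref))
        flip = {"hyper": "hypo", "hypo": "hyper", None: None}
        for f, r in zip(fwd, rev):
            assert f.p_value == r.p_value
            assert r.direction == flip[f.direction]

    def test_window_without_calls_is_skipped(self):
        calls_a = pd.DataFrame(
            {"pos": [5], "clone": [0], "context": ["CG"], "state": ["methylated"]}
        )
        calls_b = calls_a.copy()
        tests = call_dmrs(calls_a, calls_b, region_length=200)
        assert all(t.end <= 105 for t in tests)  # windows past pos 5 skipped

    def test_flagging_rate_increases_with_effect_size(self):
        """Power is non-decreasing in |p_A − p_B| at fixed call counts."""
        ref = simulate.gen_reference(150, 0.5, seed=30)
        base = 0.5
        rates = []
        for delta_idx, p_b in enumerate((0.5, 0.7, 0.9)):
            flagged = total = 0
            for rep in range(20):
                seed_a = 1000 + 37 * delta_idx + rep
                seed_b = 5000 + 37 * delta_idx + rep
                calls_a = self._calls(ref, base, 10, seed_a)
                scenario_b = simulate.MethylomeScenario(p_b, p_b, p_b, n_clones=10)
                clones_b = simulate.gen_bisulfite_clones(ref, scenario_b, seed_b).clones
                calls_b = call_methylation(ref, align_clones(ref, clones_b))
                tests = call_dmrs(calls_a, calls_b, len(ref))
                flagged += sum(t.is_dmr for t in tests)
                total += len(tests)
            rates.append(flagged / total)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_context_restriction(self):
        ref = simulate.gen_reference(200, 0.5, seed=12)
        calls_a = self._calls(ref, 0.9, 10, seed=6)
        calls_b = self._calls(ref, 0.3, 10, seed=7)
        pooled = call_dmrs(calls_a, calls_b, len(ref))
        cg_only = call_dmrs(calls_a, calls_b, len(ref), contexts=["CG"])
        assert pooled and cg_only
        for t in cg_only:
            assert t.meth_a + t.unmeth_a <= max(x.meth_a + x.unmeth_a for x in pooled)


def test_reference_region_validation():
    with pytest.raises(ValueError):
        ReferenceRegion("r", "")
    with pytest.raises(ValueError):
        ReferenceRegion("r", "ACGU")
    region = ReferenceRegion("r", "acgt")
    assert region.sequence == "ACGT"
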