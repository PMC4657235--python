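import numpy as np
import pytest

import flankalign.vgp_align as V
from flankalign.gap_model import GapPenalties
from flankalign.seqio import AnnotatedSequence, ProteinSequence, SubstitutionMatrix
from tests.oracles import brute_force_score, gotoh_constant

ALPHA = "ARND"


def make_profile(rid, residues, gpo, gpe, S):
    ann = AnnotatedSequence(ProteinSequence(rid, residues), np.asarray(gpo, float), ())
    prof = V.profile_from_annotated(ann, S)
    object.__setattr__(prof, "penalties", GapPenalties(np.asarray(gpo, float),
                                                       np.asarray(gpe, float)))
    return prof


def random_case(rng, S, nmin=1, nmax=6, gpo_hi=6.0, gpe_hi=3.0):
    na, nb = rng.integers(nmin, nmax), rng.integers(nmin, nmax)
    a = "".join(rng.choice(list(ALPHA), na))
    b = "".join(rng.choice(list(ALPHA), nb))
    pa = make_profile("a", a, rng.uniform(0, gpo_hi, na), rng.uniform(0, gpe_hi, na), S)
    pb = make_profile("b", b, rng.uniform(0, gpo_hi, nb), rng.uniform(0, gpe_hi, nb), S)
    return a, b, pa, pb


class TestColumnScore:
    def test_single_residues_reduce_to_matrix(self, gonnet):
        ai = gonnet.index("A")
        wi = gonnet.index("W")
        ca = np.zeros(21)
        cb = np.zeros(21)
        ca[ai] = 1
        cb[wi] = 1
        assert V.column_score(ca, cb, gonnet, 1, 1) == gonnet.score("A", "W")
        cb2 = np.zeros(21)
        cb2[ai] = 1
        assert V.column_score(ca, cb2, gonnet, 1, 1) == gonnet.score("A", "A")

    def test_mixed_column_frequency_arithmetic(self):
        m = np.zeros((4, 4))
        m[0, 0] = 4.0  # S(A, A) = 4, S(V-stand-in, A) = 0
        S = SubstitutionMatrix("AVRN", m)
        ca = np.zeros(4)
        ca[0] = 1
        ca[1] = 1  # column {A:1, V:1} of a 2-row profile
        cb = np.zeros(4)
        cb[0] = 1  # column {A:1}
        assert V.column_score(ca, cb, S, 2, 1) == pytest.approx(2.0)

    def test_all_gap_column_rejected(self, gonnet):
        with pytest.raises(ValueError):
            V.column_score(np.zeros(21), np.zeros(21), gonnet, 1, 1)


class TestAlignPair:
    def test_self_alignment_gapless(self, gonnet, rng):
        from tests.conftest import random_protein

        s = random_protein(rng, 30)
        pa = make_profile("a", s, np.full(30, 5.0), np.full(30, 5.0), gonnet)
        pb = make_profile("b", s, np.full(30, 5.0), np.full(30, 5.0), gonnet)
        r = V.align_pair(pa, pb, gonnet)
        assert r.profile.alignment.rows == (s, s)
        assert r.score == pytest.approx(sum(gonnet.score(c, c) for c in s))

    def test_matches_brute_force_small_cases(self, toy_matrix, rng):
        for _ in range(120):
            a, b, pa, pb = random_case(rng, toy_matrix)
            got = V.align_pair(pa, pb, toy_matrix).score
            want = brute_force_score(
                a, b, toy_matrix.score,
                pa.penalties.gpo, pa.penalties.gpe,
                pb.penalties.gpo, pb.penalties.gpe,
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_matches_gotoh_with_constant_penalties(self, gonnet, rng):
        from tests.conftest import random_protein

        for _ in range(40):
            na, nb = rng.integers(5, 40), rng.integers(5, 40)
            a, b = random_protein(rng, na), random_protein(rng, nb)
            go, ge = rng.uniform(2, 12), rng.uniform(0.3, 4)
            pa = make_profile("a", a, np.full(na, go), np.full(na, ge), gonnet)
            pb = make_profile("b", b, np.full(nb, go), np.full(nb, ge), gonnet)
            got = V.align_pair(pa, pb, gonnet).score
            want = gotoh_constant(a, b, gonnet.score, go, ge)
            assert got == pytest.approx(want, abs=1e-6)

    def test_score_symmetry(self, toy_matrix, rng):
        for _ in range(30):
            _, _, pa, pb = random_case(rng, toy_matrix, nmax=12)
            assert V.align_pair(pa, pb, toy_matrix).score == pytest.approx(
                V.align_pair(pb, pa, toy_matrix).score, abs=1e-9
            )

    def test_raising_one_gpo_never_improves_score(self, toy_matrix, rng):
        for _ in range(20):
            a, b, pa, pb = random_case(rng, toy_matrix, nmin=3, nmax=10)
            base = V.align_pair(pa, pb, toy_matrix).score
            k = int(rng.integers(len(a)))
            bumped = pa.penalties.gpo.copy()
            bumped[k] += rng.uniform(0.5, 3)
            pa2 = make_profile("a", a, bumped, pa.penalties.gpe, toy_matrix)
            assert V.align_pair(pa2, pb, toy_matrix).score <= base + 1e-9

    def test_deterministic_traceback(self, toy_matrix, rng):
        _, _, pa, pb = random_case(rng, toy_matrix, nmax=10)
        r1 = V.align_pair(pa, pb, toy_matrix)
        r2 = V.align_pair(pa, pb, toy_matrix)
        assert r1.trace == r2.trace


class TestLinearSpace:
    def test_score_identity_with_forced_recursion(self, toy_matrix, rng, monkeypatch):
        monkeypatch.setattr(V, "_BASE_CELLS", 16)
        for _ in range(40):
            a, b, pa, pb = random_case(rng, toy_matrix, nmin=5, nmax=30)
            full = V.align_pair(pa, pb, toy_matrix)
            lin = V.align_pair(pa, pb, toy_matrix, linear_space=True)
            assert lin.score == pytest.approx(full.score, abs=1e-6)
            assert [s.residues for s in V.dealign(lin)] == [a, b]

    def test_merged_profiles_equivalent(self, gonnet, rng, monkeypatch):
        from tests.conftest import random_protein

        monkeypatch.setattr(V, "_BASE_CELLS", 32)
        a, b = random_protein(rng, 45), random_protein(rng, 38)
        pa = make_profile("a", a, np.full(45, 8.0), np.full(45, 2.0), gonnet)
        pb = make_profile("b", b, np.full(38, 8.0), np.full(38, 2.0), gonnet)
        lin = V.align_pair(pa, pb, gonnet, linear_space=True)
        assert lin.profile.n_columns == len(lin.trace)
        assert [s.residues for s in V.dealign(lin)] == [a, b]


class TestDealign:
    def test_degapping_recovers_inputs(self, toy_matrix, rng):
        for _ in range(20):
            a, b, pa, pb = random_case(rng, toy_matrix, nmax=12)
            r = V.align_pair(pa, pb, toy_matrix)
            assert [s.residues for s in V.dealign(r)] == [a, b]
            assert len(r.profile.alignment.rows) == 2

    def test_merged_penalties_match_trace(self, toy_matrix, rng):
        _, _, pa, pb = random_case(rng, toy_matrix, nmin=3, nmax=8)
        r = V.align_pair(pa, pb, toy_matrix)
        for col, (j, k) in enumerate(r.trace):
            expect = 0.0
            if j is not None:
                expect += pa.penalties.gpo[j]
            if k is not None:
                expect += pb.penalties.gpo[k]
            if j is not None and k is not None:
                assert r.profile.penalties.gpo[col] == pytest.approx(expect)
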