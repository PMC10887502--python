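"""Observation building, the read likelihood model, EM, and selection."""

import math

import numpy as np
import pytest

from oracles import grid_mixture_mle

from mtdemix.align import KmerAligner
from mtdemix.deconvolve import (
    DeconvolveConfig,
    build_observations,
    em_fit,
    expected_code_matrix,
    fragment_log_likelihoods,
    report_diagnostics,
    select_contributors,
)
from mtdemix.phylo import KnownHaplotype, parse_variant_token
from mtdemix.preprocess import Fragment


def frag_from_ref(ref, start0, length, frag_id="f", qual=30, edits=()):
    seq = list(ref.sequence[start0 : start0 + length])
    for pos1, base in edits:  # 1-based genome position -> base
        seq[pos1 - 1 - start0] = base
    return Fragment(frag_id, "".join(seq), np.full(length, qual, dtype=np.uint8))


@pytest.fixture(scope="module")
def aligner(ref):
    return KmerAligner(ref.sequence, circular=True)


class TestObservations:
    def test_uninformative_fragment_flagged(self, tree, ref, aligner):
        # region chosen free of diagnostic positions
        frag = frag_from_ref(ref, 7399, 150)
        obs = build_observations([frag], tree, ref, aligner)
        assert obs.n_fragments == 0 and obs.n_uninformative == 1

    def test_phred_epsilon_and_position(self, tree, ref, aligner):
        frag = frag_from_ref(ref, 2650, 150, qual=20, edits=[(2706, "G")])
        obs = build_observations([frag], tree, ref, aligner)
        assert obs.n_fragments == 1
        covered = obs.positions[obs.pos_index]
        assert 2706 in covered
        i = int(np.flatnonzero(covered == 2706)[0])
        assert obs.base_code[i] == 2  # G
        assert obs.eps[i] == pytest.approx(0.01)

    def test_single_diagnostic_position_in_window(self, tree, ref, aligner):
        # 2650-2800 covers exactly one bundled diagnostic position (2706)
        frag = frag_from_ref(ref, 2650, 150)
        obs = build_observations([frag], tree, ref, aligner)
        assert list(obs.positions[obs.pos_index]) == [2706]

    def test_unalignable_fragment_counted(self, tree, ref, aligner):
        rng = np.random.default_rng(3)
        junk = Fragment("j", "".join(rng.choice(list("ACGT"), 150)), np.full(150, 30, np.uint8))
        obs = build_observations([junk], tree, ref, aligner)
        assert obs.n_unaligned == 1 and obs.n_fragments == 0


class TestLikelihood:
    def test_closed_forms(self, tree, ref, aligner):
        # fragment matching H at 2706A and 7028C is far from 7028; use two
        # fragments covering one position each, eps = 0.01
        fA = frag_from_ref(ref, 2650, 150, "a", qual=20, edits=[(2706, "A")])
        obs = build_observations([fA], tree, ref, aligner)
        cand = ["mt-MRCA", "H"]
        codes = expected_code_matrix(tree, cand, obs.positions, ref)
        ll = fragment_log_likelihoods(obs, codes)
        assert ll[0, 1] == pytest.approx(math.log(0.99))  # matches H
        assert ll[0, 0] == pytest.approx(math.log(0.01 / 3))  # mismatches root

    def test_multi_position_window(self, tree, ref, aligner):
        # 12251-12400 covers three diagnostic positions: 12308 (U), 12361
        # (B2o) and 12372 (U); the fragment carries the U alleles and the
        # reference base at 12361
        fU = frag_from_ref(ref, 12250, 150, qual=20, edits=[(12308, "G"), (12372, "A")])
        obs = build_observations([fU], tree, ref, aligner)
        cand = ["U", "mt-MRCA"]
        codes = expected_code_matrix(tree, cand, obs.positions, ref)
        ll = fragment_log_likelihoods(obs, codes)
        assert ll[0, 0] == pytest.approx(3 * math.log(0.99))
        assert ll[0, 1] == pytest.approx(2 * math.log(0.01 / 3) + math.log(0.99))

    def test_reference_fragment_prefers_root(self, tree, ref, aligner):
        frag = frag_from_ref(ref, 2650, 150)  # reference bases at 2706
        obs = build_observations([frag], tree, ref, aligner)
        cand = sorted(tree.nodes)
        codes = expected_code_matrix(tree, cand, obs.positions, ref)
        ll = fragment_log_likelihoods(obs, codes)
        root = cand.index("mt-MRCA")
        h = cand.index("H")  # expects 2706A
        assert ll[0, root] > ll[0, h]


def synthetic_obs(tree, ref, aligner, spec):
    """Fragments covering given positions with given alleles: spec is a list of
    (start0, [(pos, base), ...]) entries."""
    frags = [
        frag_from_ref(ref, start0, 150, f"f{i}", edits=edits)
        for i, (start0, edits) in enumerate(spec)
    ]
    return build_observations(frags, tree, ref, aligner)


class TestEM:
    def test_single_candidate_normalizes(self, tree, ref, aligner):
        obs = synthetic_obs(tree, ref, aligner, [(2650, [(2706, "A")])] * 3)
        st = em_fit(obs, tree, candidates=["H"])
        assert st.pi == pytest.approx([1.0])

    def test_clean_two_way_mixture(self, tree, ref, aligner):
        # 30 fragments supporting H (2706A), 10 supporting root
        spec = [(2650, [(2706, "A")])] * 30 + [(2650, [])] * 10
        obs = synthetic_obs(tree, ref, aligner, spec)
        st = em_fit(obs, tree, candidates=["H", "mt-MRCA"])
        d = dict(zip(st.candidates, st.pi))
        assert d["H"] == pytest.approx(0.75, abs=0.01)
        assert d["mt-MRCA"] == pytest.approx(0.25, abs=0.01)

    def test_all_fragments_one_haplogroup(self, tree, ref, aligner):
        spec = [(2650, [(2706, "A")])] * 20
        obs = synthetic_obs(tree, ref, aligner, spec)
        st = em_fit(obs, tree, candidates=["H", "mt-MRCA"])
        assert dict(zip(st.candidates, st.pi))["H"] > 0.99

    def test_loglik_trace_non_decreasing(self, tree, ref, aligner):
        spec = [(2650, [(2706, "A")])] * 15 + [(2650, [])] * 5 + [(12250, [(12308, "G")])] * 9
        obs = synthetic_obs(tree, ref, aligner, spec)
        st = em_fit(obs, tree)
        assert all(b >= a - 1e-9 for a, b in zip(st.ll_trace, st.ll_trace[1:]))
        assert st.converged

    def test_simplex_invariant(self, tree, ref, aligner):
        spec = [(2650, [(2706, "A")])] * 12 + [(12250, [(12308, "G")])] * 8
        obs = synthetic_obs(tree, ref, aligner, spec)
        st = em_fit(obs, tree)
        assert st.pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert (st.pi >= 0).all()
        assert np.allclose(st.resp.sum(axis=1), 1.0)

    def test_fragment_order_invariance(self, tree, ref, aligner):
        spec = [(2650, [(2706, "A")])] * 12 + [(2650, [])] * 6 + [(12250, [(12308, "G")])] * 7
        obs_a = synthetic_obs(tree, ref, aligner, spec)
        obs_b = synthetic_obs(tree, ref, aligner, spec[::-1])
        sa = em_fit(obs_a, tree)
        sb = em_fit(obs_b, tree)
        assert sa.candidates == sb.candidates
        assert np.allclose(sa.pi, sb.pi, atol=1e-6)

    def test_matches_grid_oracle_three_candidates(self, tree, ref, aligner):
        rng = np.random.default_rng(7)
        spec = []
        for _ in range(24):
            r = rng.random()
            if r < 0.5:
                spec.append((2650, [(2706, "A")]))  # H
            elif r < 0.8:
                spec.append((12250, [(12308, "G"), (12372, "A")]))  # U
            else:
                spec.append((2650, []))  # root-like
        obs = synthetic_obs(tree, ref, aligner, spec)
        cand = ["H", "U", "mt-MRCA"]
        st = em_fit(obs, tree, candidates=cand, config=DeconvolveConfig(tol=1e-7, prune=False))
        codes = expected_code_matrix(tree, st.candidates, obs.positions, ref)
        ll = fragment_log_likelihoods(obs, codes)
        oracle = grid_mixture_mle(ll, step=0.001)
        assert np.abs(st.pi - oracle).max() <= 0.01

    def test_zero_informative_fragments_error(self, tree, ref, aligner):
        obs = build_observations([frag_from_ref(ref, 7399, 150)], tree, ref, aligner)
        with pytest.raises(ValueError, match="nothing to deconvolute"):
            em_fit(obs, tree)

    def test_duplicate_candidates_collapse(self, tree, ref, aligner):
        spec = [(2650, [(2706, "A")])] * 30 + [(2650, [])] * 10
        obs = synthetic_obs(tree, ref, aligner, spec)
        base = em_fit(obs, tree, candidates=["H", "mt-MRCA"])
        # graft a known identical to H over all diagnostic positions
        kh = KnownHaplotype("twin", tuple(tree.expected_variants("H")))
        t2 = tree.graft_known_haplotype(kh)
        dup = em_fit(obs, t2, candidates=["H", "twin", "mt-MRCA"], ref=ref)
        assert "twin" in dup.candidates and "H" not in dup.candidates  # known label wins
        assert dup.aliases["twin"] == ["H"]
        d0 = dict(zip(base.candidates, base.pi))
        d1 = dict(zip(dup.candidates, dup.pi))
        assert d1["twin"] == pytest.approx(d0["H"], abs=1e-3)


class TestSelectionAndReport:
    def test_single_source_single_contributor(self, tree, ref, aligner):
        # pure H3 signal; reference coverage of 1018 separates H3 from its
        # one-SNP child H3aq
        spec = (
            [(2650, [(2706, "A")])] * 40
            + [(6730, [(6776, "C")])] * 40
            + [(970, [])] * 20
        )
        obs = synthetic_obs(tree, ref, aligner, spec)
        st = em_fit(obs, tree)
        res = select_contributors(st, obs, tree, ref=ref)
        assert res.contributor_names() == ["H3"]
        res = report_diagnostics(res, obs, tree)
        for d in res.contributors[0].diagnostics:
            assert d.observed_fraction == pytest.approx(1.0)

    def test_low_support_fallback_warns(self, tree, ref, aligner):
        obs = synthetic_obs(tree, ref, aligner, [(2650, [(2706, "A")])] * 3)
        st = em_fit(obs, tree)
        cfg = DeconvolveConfig(min_unique_frags=10)
        res = select_contributors(st, obs, tree, cfg, ref=ref)
        assert len(res.contributors) == 1
        assert res.warnings

    def test_partial_haplotype_limited_to_covered_snps(self, tree, ref, aligner):
        obs = synthetic_obs(tree, ref, aligner, [(2650, [(2706, "A")])] * 20)
        st = em_fit(obs, tree, candidates=["H"])
        res = select_contributors(st, obs, tree, ref=ref)
        res = report_diagnostics(res, obs, tree)
        contrib = res.contributors[0]
        # only 2706 is covered; the partial haplotype contains just that SNP
        assert contrib.partial_haplotype == ["2706A"]

    def test_proportions_and_diagnostic_ownership(self, tree, ref, aligner):
        spec = [(2650, [(2706, "A")])] * 30 + [(12250, [(12308, "G"), (12372, "A")])] * 30
        obs = synthetic_obs(tree, ref, aligner, spec)
        st = em_fit(obs, tree)
        res = report_diagnostics(select_contributors(st, obs, tree, ref=ref), obs, tree)
        assert sum(c.proportion for c in res.contributors) <= 1.0 + 1e-9
        for c in res.contributors:
            own = {v.position for v in tree.expected_variants(c.haplogroup)}
            assert all(d.position in own for d in c.diagnostics)
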