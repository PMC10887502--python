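"""Synthetic read generation, subsetting, mixing, NUMT spiking, reduction."""

import numpy as np
import pytest

from mtdemix.align import KmerAligner
from mtdemix.phylo import parse_variant_token
from mtdemix.simdata import (
    ContributorSpec,
    bundled_reference,
    bundled_scheme,
    bundled_tree,
    default_numt_catalog,
    make_mixture,
    mix_fastqs,
    private_token,
    random_reduce,
    ratio_counts,
    simulate_sole_source,
    spike_numts,
    subset_fastq,
)


def read_ids(path):
    with open(path) as fh:
        return [line[1:].strip() for i, line in enumerate(fh) if i % 4 == 0]


def read_seqs(path):
    with open(path) as fh:
        return [line.strip() for i, line in enumerate(fh) if i % 4 == 1]


class TestBundled:
    def test_reference_shape(self, ref):
        assert len(ref) == 16569
        assert set(ref.sequence) <= set("ACGT")

    def test_tree_size_and_clades(self, tree):
        assert len(tree.nodes) == 23
        top_clades = tree.nodes[tree.root].children
        assert len(top_clades) >= 3
        # the H-like clade carries one-SNP branches for spurious fixtures
        assert len(tree.nodes["H3aq"].defining_variants) == 1
        assert len(tree.nodes["H27"].defining_variants) == 1

    def test_derived_alleles_differ_from_reference(self, tree, ref):
        for node in tree.nodes.values():
            for v in node.defining_variants:
                assert ref.base_at(v.position) != v.derived

    def test_scheme_covers_genome_interior(self, tree, ref):
        scheme = bundled_scheme()
        L = len(ref)
        for pos in tree.diagnostic_positions():
            interior = any(
                scheme.primer_len
                <= (pos - 1 - int(scheme.starts[j])) % L
                < int(scheme.lengths[j]) - scheme.primer_len
                for j in range(scheme.n_amplicons)
            )
            assert interior, pos

    def test_private_token_valid(self, ref):
        tok = private_token(8700, ref)
        v = parse_variant_token(tok)
        assert ref.base_at(8700) != v.derived


class TestSoleSource:
    def test_seeded_determinism(self, tmp_path):
        spec = ContributorSpec("U5a")
        a = simulate_sole_source(spec, 300, 9, tmp_path / "a")
        b = simulate_sole_source(spec, 300, 9, tmp_path / "b")
        c = simulate_sole_source(spec, 300, 10, tmp_path / "c")
        assert a.r1.read_bytes() == b.r1.read_bytes()
        assert a.r2.read_bytes() == b.r2.read_bytes()
        assert a.r1.read_bytes() != c.r1.read_bytes()

    def test_error_free_reads_match_reference_haplotype(self, tmp_path, ref):
        # the root contributor's genome equals the reference, so with the
        # error channels off every read substring-matches the (circular)
        # reference exactly
        out = simulate_sole_source(
            ContributorSpec("mt-MRCA"),
            120,
            3,
            tmp_path / "root",
            quality=90,
            primer_mismatch_prob=0.0,
        )
        doubled = ref.sequence + ref.sequence
        from mtdemix.preprocess import revcomp

        for seq in read_seqs(out.r1):
            assert seq in doubled
        for seq in read_seqs(out.r2):
            assert revcomp(seq) in doubled

    def test_haplotype_variants_present_in_reads(self, tmp_path, tree, ref):
        out = simulate_sole_source(
            ContributorSpec("L0a"), 2000, 4, tmp_path / "l0a", quality=90,
            primer_mismatch_prob=0.0,
        )
        aligner = KmerAligner(ref.sequence, circular=True)
        hits = ref_calls = 0
        expected = {v.position: v.derived for v in tree.expected_variants("L0a")}
        for seq in read_seqs(out.r1):
            pl = aligner.align(seq)
            assert pl.mapped
            for pos, derived in expected.items():
                off = (pos - 1 - pl.start0) % len(ref)
                if 20 <= off < len(seq) - 20:  # outside primer footprints
                    if seq[off] == derived:
                        hits += 1
                    else:
                        ref_calls += 1
        assert hits > 50 and ref_calls == 0

    def test_heteroplasmy_binomial_fraction(self, tmp_path, ref):
        # single-amplicon scheme so all 10,000 fragments cover the site
        from mtdemix.simdata import AmpliconScheme

        pos = 8700
        minor = parse_variant_token(private_token(pos, ref)).derived
        scheme = AmpliconScheme(
            starts=np.array([8600], dtype=np.int64),
            lengths=np.array([167], dtype=np.int64),
        )
        out = simulate_sole_source(
            ContributorSpec("mt-MRCA", heteroplasmies=((pos, minor, 0.25),)),
            10_000,
            11,
            tmp_path / "het",
            scheme=scheme,
            quality=90,
            primer_mismatch_prob=0.0,
        )
        off = pos - 1 - 8600  # interior offset inside every read 1
        calls = [seq[off] for seq in read_seqs(out.r1)]
        frac = sum(c == minor for c in calls) / len(calls)
        assert frac == pytest.approx(0.25, abs=0.02)

    @pytest.mark.parametrize("maf", [0.064, 0.47])
    def test_maf_range_endpoints_accepted(self, tmp_path, ref, maf):
        out = simulate_sole_source(
            ContributorSpec("mt-MRCA", heteroplasmies=((8700, "A" if ref.base_at(8700) != "A" else "C", maf),)),
            50,
            1,
            tmp_path / f"maf{maf}",
        )
        assert out.manifest.total_fragments == 50

    def test_invalid_specs_rejected(self, tmp_path, ref):
        with pytest.raises(ValueError, match="MAF"):
            simulate_sole_source(
                ContributorSpec("mt-MRCA", heteroplasmies=((8700, "A", 0.6),)),
                10, 1, tmp_path / "x",
            )
        tok = private_token(8700, ref)
        minor = parse_variant_token(tok).derived
        with pytest.raises(ValueError, match="contradictory"):
            simulate_sole_source(
                ContributorSpec("mt-MRCA", privates=(tok,), heteroplasmies=((8700, minor, 0.2),)),
                10, 1, tmp_path / "y",
            )


@pytest.fixture(scope="module")
def source(tmp_path_factory):
    td = tmp_path_factory.mktemp("src")
    return simulate_sole_source(ContributorSpec("J1"), 500, 21, td / "j1")


class TestSubsetAndMix:
    def test_subset_identity_when_n_equals_available(self, source, tmp_path):
        r1, r2 = subset_fastq(source.r1, source.r2, 500, 5, tmp_path / "all")
        assert sorted(read_ids(r1)) == sorted(read_ids(source.r1))

    def test_subset_zero(self, source, tmp_path):
        r1, r2 = subset_fastq(source.r1, source.r2, 0, 5, tmp_path / "none")
        assert read_ids(r1) == [] and read_ids(r2) == []

    def test_subset_seed_determinism(self, source, tmp_path):
        a1, _ = subset_fastq(source.r1, source.r2, 200, 5, tmp_path / "a")
        b1, _ = subset_fastq(source.r1, source.r2, 200, 5, tmp_path / "b")
        c1, _ = subset_fastq(source.r1, source.r2, 200, 6, tmp_path / "c")
        assert read_ids(a1) == read_ids(b1)
        assert read_ids(a1) != read_ids(c1)

    def test_subset_too_large_rejected(self, source, tmp_path):
        with pytest.raises(ValueError, match="available"):
            subset_fastq(source.r1, source.r2, 501, 5, tmp_path / "big")

    @pytest.mark.parametrize(
        "ratio,total,expect",
        [
            ((1, 3), 720_000, [180_000, 540_000]),
            ((3, 1), 720_000, [540_000, 180_000]),
            ((1, 1, 1), 840_000, [280_000, 280_000, 280_000]),
            ((1, 3, 3), 840_000, [120_000, 360_000, 360_000]),
            ((3, 3, 1), 7, [3, 3, 1]),
        ],
    )
    def test_ratio_arithmetic(self, ratio, total, expect):
        assert ratio_counts(ratio, total) == expect

    def test_mix_counts_pairing_and_uniqueness(self, tmp_path):
        a = simulate_sole_source(ContributorSpec("L0a"), 300, 1, tmp_path / "a")
        b = simulate_sole_source(ContributorSpec("T2"), 600, 2, tmp_path / "b")
        r1, r2, man = mix_fastqs([a, b], (1, 3), 800, 3, tmp_path / "mix")
        ids1, ids2 = read_ids(r1), read_ids(r2)
        assert ids1 == ids2  # mate pairing preserved through the shuffle
        assert len(ids1) == 800 and len(set(ids1)) == 800
        counts = {"L0a": 0, "T2": 0}
        for rid in ids1:
            counts[rid.split(":")[0]] += 1
        assert counts == {"L0a": 200, "T2": 600}
        assert man.proportions == {"L0a": 0.25, "T2": 0.75}

    def test_mix_source_too_small(self, tmp_path):
        a = simulate_sole_source(ContributorSpec("L0a"), 100, 1, tmp_path / "sa")
        b = simulate_sole_source(ContributorSpec("T2"), 100, 2, tmp_path / "sb")
        with pytest.raises(ValueError, match="needs"):
            mix_fastqs([a, b], (1, 3), 400, 3, tmp_path / "mx")


class TestNumtsAndReduction:
    def test_spike_zero_is_noop(self, tmp_path):
        a = simulate_sole_source(ContributorSpec("K"), 100, 1, tmp_path / "k")
        r1, r2, nuc, man = spike_numts(a.r1, a.r2, a.manifest, 0, 2, tmp_path / "sp")
        assert read_ids(r1) == read_ids(a.r1)
        assert man.numt_ids == []
        assert nuc.exists()

    def test_spike_records_ids_and_counts(self, tmp_path):
        a = simulate_sole_source(ContributorSpec("K"), 100, 1, tmp_path / "k2")
        r1, r2, nuc, man = spike_numts(a.r1, a.r2, a.manifest, 40, 2, tmp_path / "sp2")
        ids = read_ids(r1)
        assert len(ids) == 140
        assert man.total_fragments == 140
        assert len(man.numt_ids) == 40
        assert all(i.startswith("numt:") for i in man.numt_ids)

    def test_numt_catalog_distances(self, ref):
        nuclear, seg_off = default_numt_catalog(ref)
        # every read-length window of the nuclear copy is >= 3 edits from mito
        mito = KmerAligner(ref.sequence, circular=True)
        for start in (seg_off, seg_off + 100, seg_off + 233):
            window = nuclear[start : start + 150]
            pl = mito.align(window)
            assert (not pl.mapped) or pl.lev >= 3

    def test_random_reduce_preserves_ratio_in_expectation(self, tmp_path):
        a = simulate_sole_source(ContributorSpec("L0a"), 40_000, 1, tmp_path / "ra")
        b = simulate_sole_source(ContributorSpec("U5a"), 3_000, 2, tmp_path / "rb")
        r1, r2, man = mix_fastqs([a, b], (19, 1), 40_000, 3, tmp_path / "rmix")
        s1, s2, red = random_reduce(r1, r2, 20_000, 4, tmp_path / "red", man)
        assert red.total_fragments == 20_000
        minor = dict((s["source_id"], s["count"]) for s in red.sources)["U5a"]
        # hypergeometric around 1000 (sd ~22)
        assert abs(minor - 1000) < 150
        assert sum(s["count"] for s in red.sources) == 20_000


class TestScenario:
    def test_make_mixture_truth_and_files(self, tmp_path):
        sc = make_mixture(
            tmp_path,
            [ContributorSpec("L0a"), ContributorSpec("U5a")],
            (1, 3),
            400,
            seed=5,
        )
        assert sc.truth == {"L0a": 0.25, "U5a": 0.75}
        assert len(read_ids(sc.r1)) == 400
        khs = sc.known_haplotypes()
        assert {k.sample_id for k in khs} == {"known_L0a", "known_U5a"}

    def test_manifest_roundtrip(self, tmp_path):
        sc = make_mixture(
            tmp_path,
            [ContributorSpec("J1"), ContributorSpec("T2")],
            (1, 1),
            200,
            seed=6,
        )
        from mtdemix.simdata import TruthManifest

        again = TruthManifest.from_json(sc.manifest.to_json())
        assert again.proportions == sc.manifest.proportions
        assert again.ratio == (1, 1)
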