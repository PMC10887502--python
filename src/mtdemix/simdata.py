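"""Synthetic amplicon read sets, in-silico mixtures, and the bundled mini-phylogeny.

Everything the pipeline consumes can be generated here without downloads: a
16,569-base synthetic circular reference, a 23-haplogroup mini-tree spanning
deep African-like clades (L), Eurasian clades (U/K, J, T, B2) and a deliberately
shallow H-like clade whose one-SNP branches make spurious-haplogroup fixtures
constructible; a fixed overlapping-amplicon scheme (average amplicon 167 bp,
20-base primers) emulating whole-mitogenome multiplex kits; and generators for
sole-source paired reads with Phred-consistent sequencing error, point
heteroplasmy, private mutations, primer-directed error and implanted NUMT
fragments. Mixtures are built the way in-silico mixtures are built in
practice: without-replacement subsets of sole-source FASTQs combined at integer
ratios to an exact total, then optionally randomly reduced.

All generators are seeded and deterministic: identical configuration plus seed
yields byte-identical FASTQ output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import seq_to_codes
from .phylo import (
    SUBSTITUTION,
    KnownHaplotype,
    MitoReference,
    PhyloTree,
    Variant,
    parse_phylotree,
    parse_variant_token,
)
from .preprocess import PrimerSet, revcomp

__all__ = [
    "ContributorSpec",
    "TruthManifest",
    "MixtureScenario",
    "bundled_reference",
    "bundled_tree_text",
    "bundled_tree",
    "bundled_scheme",
    "bundled_primers_tsv",
    "bundled_primers",
    "simulate_sole_source",
    "subset_fastq",
    "mix_fastqs",
    "spike_numts",
    "random_reduce",
    "make_mixture",
    "default_numt_catalog",
]

MT_LENGTH = 16569
_REF_SEED = 16569  # fixed: the bundled reference is a constant of the package
_SCHEME_SEED = 167
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# name, parent (by indentation), variant tokens — rendered to the TSV dialect.
# The H clade is intentionally shallow (single-SNP branches) so that private
# mutations coinciding with its diagnostic SNPs can generate spurious calls.
_TREE_TABLE: list[tuple[int, str, str]] = [
    (0, "mt-MRCA", ""),
    (1, "L0", "263G 1048T 3516A 5442C 9042T 12007A"),
    (2, "L0a", "4586C 9347G 13276G"),
    (1, "L1", "825A 2395C 7055G 8468T 13789C"),
    (2, "L1c", "1738C 6071C 14178G"),
    (3, "L1c2", "4937G 11899C 15927A"),
    (1, "R", "73G 14766T"),
    (2, "H", "2706A 7028C"),
    (3, "H1", "3010A"),
    (3, "H3", "6776C"),
    (4, "H3aq", "1018A"),
    (3, "H27", "16093C"),
    (4, "H27e", "16129A"),
    (2, "U", "1811G 11467G 12308G 12372A"),
    (3, "U5", "3197C 9477A 13617C"),
    (4, "U5a", "5656G 14793G 16256T"),
    (3, "K", "1189C 10550G 14798C"),
    (2, "J", "295T 489C 10398G 12612G"),
    (3, "J1", "462T 3394C 14133G"),
    (2, "T", "709A 1888A 4917G 13368A"),
    (3, "T2", "11812G 14233G 15607G"),
    (2, "B2", "499A 4977C 6473T 11177T"),
    (3, "B2o", "5465C 5900G 12361G"),
]


def bundled_tree_text() -> str:
    """The bundled mini-phylotree in the package's TSV dialect."""
    lines = []
    for depth, name, tokens in _TREE_TABLE:
        lines.append("\t" * depth + (f"{name}\t{tokens}" if tokens else name))
    return "\n".join(lines) + "\n"


def _tree_variant_alleles() -> dict[int, str]:
    alleles: dict[int, str] = {}
    for _, _, tokens in _TREE_TABLE:
        for tok in tokens.split():
            v = parse_variant_token(tok)
            alleles[v.position] = v.derived
    return alleles


def bundled_reference() -> MitoReference:
    """Deterministic 16,569-base synthetic circular reference.

    At every bundled diagnostic position the reference base is forced to
    differ from the derived allele, as the tree contract requires.
    """
    rng = np.random.default_rng(_REF_SEED)
    codes = rng.integers(0, 4, MT_LENGTH, dtype=np.uint8)
    seq = bytearray(_BASES[codes].tobytes())
    order = b"ACGT"
    for pos, derived in _tree_variant_alleles().items():
        if chr(seq[pos - 1]) == derived:
            alt = next(b for b in order if chr(b) != derived)
            seq[pos - 1] = alt
    return MitoReference(name="mtSYN", sequence=bytes(seq).decode("ascii"))


def bundled_tree(reference: MitoReference | None = None) -> PhyloTree:
    return parse_phylotree(bundled_tree_text(), reference or bundled_reference())


@dataclass(frozen=True)
class AmpliconScheme:
    """Fixed overlapping-amplicon design: starts (0-based), lengths, primer length."""

    starts: np.ndarray
    lengths: np.ndarray
    primer_len: int = 20

    @property
    def n_amplicons(self) -> int:
        return len(self.starts)


def bundled_scheme(L: int = MT_LENGTH) -> AmpliconScheme:
    """166 overlapping amplicons, stride 100, lengths 157-177 (mean 167).

    Primer binding sites are placed to avoid the bundled tree's diagnostic
    positions (shifting an amplicon by a few bases where needed), mirroring
    how commercial panel primers are designed away from known polymorphic
    sites; a variant under a primer would otherwise be invisible in that
    amplicon's reads.
    """
    rng = np.random.default_rng(_SCHEME_SEED)
    starts = np.arange(0, L, 100, dtype=np.int64)
    lengths = rng.integers(157, 178, len(starts), dtype=np.int64)
    diag0 = np.array(sorted(_tree_variant_alleles()), dtype=np.int64) - 1
    p = 20

    def conflict(s: int, ln: int) -> bool:
        off = (diag0 - s) % L
        # keep diagnostic sites out of both primer footprints and out of the
        # few terminal bases a merged read pair can retain past trimming
        guard = 14
        return bool(
            np.any((off < p + guard) & (off < ln)) | np.any((off >= ln - p - guard) & (off < ln))
        )

    for j in range(len(starts)):
        s, ln = int(starts[j]), int(lengths[j])
        if not conflict(s, ln):
            continue
        placed = False
        for ds in sorted(range(-25, 26), key=abs):
            for dl in sorted(range(-7, 34), key=abs):
                s2, ln2 = (s + ds) % L, ln + dl
                if 150 <= ln2 <= 200 and not conflict(s2, ln2):
                    starts[j], lengths[j] = s2, ln2
                    placed = True
                    break
            if placed:
                break
    return AmpliconScheme(starts=starts, lengths=lengths)


def bundled_primers_tsv(ref: MitoReference | None = None, scheme: AmpliconScheme | None = None) -> str:
    """Primer TSV for the bundled scheme: reference 20-mers at amplicon termini."""
    ref = ref or bundled_reference()
    scheme = scheme or bundled_scheme(len(ref))
    doubled = ref.sequence + ref.sequence  # circular wrap
    rows = ["#primer_id\tsequence\tterminus"]
    for j in range(scheme.n_amplicons):
        s, ln, p = int(scheme.starts[j]), int(scheme.lengths[j]), scheme.primer_len
        fwd = doubled[s : s + p]
        rev = revcomp(doubled[s + ln - p : s + ln])
        rows.append(f"amp{j:03d}_F\t{fwd}\teither")
        rows.append(f"amp{j:03d}_R\t{rev}\teither")
    return "\n".join(rows) + "\n"


def bundled_primers(ref: MitoReference | None = None) -> PrimerSet:
    return PrimerSet.from_tsv(bundled_primers_tsv(ref))


def private_token(position: int, ref: MitoReference | None = None) -> str:
    """A valid private-mutation token at a position: first base differing from
    the reference, in A<C<G<T order. Convenient for building fixtures against
    the bundled synthetic reference."""
    ref = ref or bundled_reference()
    base = next(b for b in "ACGT" if b != ref.base_at(position))
    return f"{position}{base}"


# ---------------------------------------------------------------------------
# contributors and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContributorSpec:
    """One mixture contributor: a haplogroup plus individual-level features."""

    haplogroup: str
    sample_id: str = ""
    privates: tuple[str, ...] = ()  # variant tokens, e.g. ("8700G",)
    heteroplasmies: tuple[tuple[int, str, float], ...] = ()  # (pos, minor, MAF)

    @property
    def label(self) -> str:
        return self.sample_id or self.haplogroup

    def known_haplotype(self, tree: PhyloTree, sample_id: str | None = None) -> KnownHaplotype:
        """The contributor's full haplotype (tree path + privates) as a known."""
        variants = dict(tree.expected_variant_map(self.haplogroup))
        for tok in self.privates:
            v = parse_variant_token(tok)
            variants[v.position] = v
        return KnownHaplotype(
            sample_id=sample_id or f"known_{self.label}",
            variants=tuple(variants[p] for p in sorted(variants)),
            heteroplasmies=self.heteroplasmies,
        )


@dataclass
class TruthManifest:
    """Ground truth for a generated read set or mixture.

    Per-fragment origin is encoded in the read id prefix (``<source>:<i>`` or
    ``numt:<i>``), so the manifest only needs per-source metadata and counts.
    """

    total_fragments: int
    sources: list[dict] = field(default_factory=list)  # source_id, haplogroup, count, ...
    ratio: tuple[int, ...] | None = None
    numt_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def proportions(self) -> dict[str, float]:
        tot = sum(s["count"] for s in self.sources)
        return {s["source_id"]: s["count"] / tot for s in self.sources} if tot else {}

    def haplogroup_of(self, source_id: str) -> str:
        for s in self.sources:
            if s["source_id"] == source_id:
                return s["haplogroup"]
        raise KeyError(source_id)

    @staticmethod
    def origin_of(read_id: str) -> str:
        return read_id.split(":", 1)[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_fragments": self.total_fragments,
                "sources": self.sources,
                "ratio": list(self.ratio) if self.ratio else None,
                "numt_ids": self.numt_ids,
                "seed": self.seed,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            total_fragments=d["total_fragments"],
            sources=d["sources"],
            ratio=tuple(d["ratio"]) if d.get("ratio") else None,
            numt_ids=d.get("numt_ids", []),
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# sole-source simulation
# ---------------------------------------------------------------------------


def _contributor_genome(
    spec: ContributorSpec, tree: PhyloTree, ref: MitoReference
) -> np.ndarray:
    codes = seq_to_codes(ref.sequence).copy()
    variants = dict(tree.expected_variant_map(spec.haplogroup))
    for tok in spec.privates:
        v = parse_variant_token(tok)
        if v.position in variants:
            raise ValueError(f"private {tok} collides with a haplogroup-defining variant")
        variants[v.position] = v
    het_positions = {pos for pos, _, _ in spec.heteroplasmies}
    for pos, minor, maf in spec.heteroplasmies:
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"heteroplasmy MAF must be in (0, 0.5], got {maf}")
        if pos in variants:
            raise ValueError(
                f"contradictory contributor spec: variant and heteroplasmy both at {pos}"
            )
    del het_positions
    for pos, v in variants.items():
        if v.kind != SUBSTITUTION:
            raise ValueError(f"the read generator supports substitutions only, got {v.token()}")
        if ref.base_at(pos) == v.derived:
            raise ValueError(f"variant {v.token()} matches the reference base")
        codes[pos - 1] = seq_to_codes(v.derived)[0]
    return codes


def _amplicon_templates(
    genome: np.ndarray, ref_codes: np.ndarray, scheme: AmpliconScheme
) -> np.ndarray:
    """(n_amp, max_len) molecule templates; primer footprints carry reference
    alleles (primers are synthesized oligos, blind to the template's variants).
    Rows are padded with 255 beyond each amplicon's length."""
    L = len(genome)
    p = scheme.primer_len
    max_len = int(scheme.lengths.max())
    T = np.full((scheme.n_amplicons, max_len), 255, dtype=np.uint8)
    for j in range(scheme.n_amplicons):
        s, ln = int(scheme.starts[j]), int(scheme.lengths[j])
        idx = (s + np.arange(ln)) % L
        row = genome[idx].copy()
        row[:p] = ref_codes[idx[:p]]
        row[ln - p :] = ref_codes[idx[ln - p :]]
        T[j, :ln] = row
    return T


def _apply_errors(reads: np.ndarray, err: float, rng: np.random.Generator) -> None:
    mask = rng.random(reads.shape) < err
    n_err = int(mask.sum())
    if n_err:
        reads[mask] = (reads[mask] + rng.integers(1, 4, n_err, dtype=np.uint8)) % 4


def _write_fastq(path: Path, ids: list[str], reads: np.ndarray, qual_char: str) -> None:
    n, rl = reads.shape
    blob = _BASES[reads].tobytes()
    qual = qual_char * rl
    with open(path, "w") as fh:
        fh.write(
            "\n".join(
                f"@{ids[i]}\n{blob[i * rl:(i + 1) * rl].decode('ascii')}\n+\n{qual}"
                for i in range(n)
            )
        )
        fh.write("\n")


@dataclass
class SoleSourceSet:
    r1: Path
    r2: Path
    manifest: TruthManifest


def simulate_sole_source(
    contributor: ContributorSpec,
    n_fragments: int,
    seed: int,
    out_prefix: str | Path,
    tree: PhyloTree | None = None,
    ref: MitoReference | None = None,
    scheme: AmpliconScheme | None = None,
    read_len: int = 150,
    quality: int = 30,
    primer_mismatch_prob: float = 0.1,
) -> SoleSourceSet:
    """Simulate an amplicon-sequenced sole-source sample as paired FASTQ.

    Fragments are amplicon molecules drawn uniformly over the scheme; each
    molecule carries the contributor's haplotype, binomially sampled minor
    alleles at heteroplasmic positions (whole-molecule, so both mates agree),
    reference alleles across primer footprints, and with probability
    ``primer_mismatch_prob`` per end a one-base primer synthesis mismatch.
    Reads of length ``read_len`` are taken from both molecule ends with
    independent per-base errors at the Phred rate of ``quality``.
    """
    ref = ref or bundled_reference()
    tree = tree or bundled_tree(ref)
    scheme = scheme or bundled_scheme(len(ref))
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    ref_codes = seq_to_codes(ref.sequence)
    genome = _contributor_genome(contributor, tree, ref)
    T = _amplicon_templates(genome, ref_codes, scheme)
    L = len(ref)
    p = scheme.primer_len

    amp = rng.integers(0, scheme.n_amplicons, n_fragments)
    molecules = T[amp].copy()
    lens = scheme.lengths[amp]

    # whole-molecule heteroplasmy (template-level, interior of the amplicon)
    for pos, minor, maf in contributor.heteroplasmies:
        minor_code = int(seq_to_codes(minor)[0])
        for j in range(scheme.n_amplicons):
            off = int((pos - 1 - scheme.starts[j]) % L)
            if p <= off < scheme.lengths[j] - p:
                hit = (amp == j) & (rng.random(n_fragments) < maf)
                molecules[hit, off] = minor_code

    # primer-directed error: a mismatched degenerate-primer variant per end
    for end in ("fwd", "rev"):
        hit = rng.random(n_fragments) < primer_mismatch_prob
        offs = rng.integers(0, p, n_fragments)
        if end == "rev":
            offs = lens - 1 - offs
        rows = np.flatnonzero(hit)
        cur = molecules[rows, offs[rows]]
        molecules[rows, offs[rows]] = (cur + rng.integers(1, 4, len(rows), dtype=np.uint8)) % 4

    if int(lens.min()) < read_len:
        raise ValueError("amplicon shorter than the read length")
    r1 = molecules[:, :read_len].copy()
    cols = lens[:, None] - read_len + np.arange(read_len)[None, :]
    r2 = molecules[np.arange(n_fragments)[:, None], cols]
    r2 = (3 - r2)[:, ::-1].astype(np.uint8)  # reverse-complement

    err = 10.0 ** (-quality / 10.0)
    _apply_errors(r1, err, rng)
    _apply_errors(r2, err, rng)

    sid = contributor.label
    ids = [f"{sid}:{i}" for i in range(n_fragments)]
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    r1_path = Path(f"{out_prefix}_R1.fastq")
    r2_path = Path(f"{out_prefix}_R2.fastq")
    qc = chr(quality + 33)
    _write_fastq(r1_path, ids, r1, qc)
    _write_fastq(r2_path, ids, r2, qc)
    manifest = TruthManifest(
        total_fragments=n_fragments,
        sources=[
            {
                "source_id": sid,
                "haplogroup": contributor.haplogroup,
                "privates": list(contributor.privates),
                "heteroplasmies": [list(h) for h in contributor.heteroplasmies],
                "count": n_fragments,
            }
        ],
        seed=seed,
    )
    return SoleSourceSet(r1=r1_path, r2=r2_path, manifest=manifest)


# ---------------------------------------------------------------------------
# subsetting and mixing
# ---------------------------------------------------------------------------


def _iter_fastq_blocks(path: str | Path):
    with open(path) as fh:
        while True:
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                return
            if not lines[3]:
                raise ValueError(f"{path}: truncated FASTQ record")
            yield "".join(lines)


def _count_fastq(path: str | Path) -> int:
    n = 0
    with open(path) as fh:
        for _ in fh:
            n += 1
    if n % 4:
        raise ValueError(f"{path}: line count {n} not a multiple of 4")
    return n // 4


def subset_fastq(
    r1: str | Path,
    r2: str | Path,
    n: int,
    seed: int,
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Randomly select ``n`` fragments without replacement, preserving pairing.

    Selection is seeded-deterministic; output keeps the input record order.
    """
    total = _count_fastq(r1)
    if _count_fastq(r2) != total:
        raise ValueError("mate files carry different record counts")
    if n > total:
        raise ValueError(f"requested {n} fragments but only {total} available")
    rng = np.random.default_rng(seed)
    keep = np.zeros(total, dtype=bool)
    keep[rng.choice(total, n, replace=False)] = True
    out1 = Path(f"{out_prefix}_R1.fastq")
    out2 = Path(f"{out_prefix}_R2.fastq")
    for src, dst in ((r1, out1), (r2, out2)):
        with open(dst, "w") as fh:
            for i, block in enumerate(_iter_fastq_blocks(src)):
                if keep[i]:
                    fh.write(block)
    return out1, out2


def ratio_counts(ratio: tuple[int, ...], total: int) -> list[int]:
    """Per-source fragment counts at an integer ratio, largest-remainder rounding."""
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio parts must be positive")
    s = sum(ratio)
    quotas = [total * r / s for r in ratio]
    counts = [math.floor(q) for q in quotas]
    short = total - sum(counts)
    order = sorted(range(len(ratio)), key=lambda i: (counts[i] - quotas[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def mix_fastqs(
    sources: list[SoleSourceSet | tuple],
    ratio: tuple[int, ...],
    total: int,
    seed: int,
    out_prefix: str | Path,
) -> tuple[Path, Path, TruthManifest]:
    """Combine sole-source FASTQs into a mixture at an integer ratio.

    Per-source counts are ``total * ratio_k / sum(ratio)`` (largest-remainder
    rounding when not divisible); subsets are drawn without replacement and
    the mixture is written in a seeded-shuffled interleaving so downstream
    steps cannot exploit file order.
    """
    if len(sources) != len(ratio):
        raise ValueError("ratio length must match the number of sources")
    counts = ratio_counts(ratio, total)
    rng = np.random.default_rng(seed)
    blocks1: list[str] = []
    blocks2: list[str] = []
    src_meta: list[dict] = []
    for src, want in zip(sources, counts):
        if isinstance(src, SoleSourceSet):
            r1, r2, man = src.r1, src.r2, src.manifest
        else:
            r1, r2, man = src
        avail = man.total_fragments if man is not None else _count_fastq(r1)
        if want > avail:
            raise ValueError(f"source {r1} has {avail} fragments, needs {want}")
        keep = np.zeros(avail, dtype=bool)
        keep[rng.choice(avail, want, replace=False)] = True
        for path, sink in ((r1, blocks1), (r2, blocks2)):
            for i, block in enumerate(_iter_fastq_blocks(path)):
                if keep[i]:
                    sink.append(block)
        meta = dict(man.sources[0]) if man is not None and man.sources else {}
        meta["count"] = want
        meta.setdefault("source_id", Path(str(r1)).stem)
        meta.setdefault("haplogroup", "?")
        src_meta.append(meta)
    perm = rng.permutation(total)
    out1 = Path(f"{out_prefix}_R1.fastq")
    out2 = Path(f"{out_prefix}_R2.fastq")
    Path(out_prefix).parent.mkdir(parents=True, exist_ok=True)
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for i in perm:
            f1.write(blocks1[i])
            f2.write(blocks2[i])
    manifest = TruthManifest(
        total_fragments=total, sources=src_meta, ratio=tuple(ratio), seed=seed
    )
    return out1, out2, manifest


# ---------------------------------------------------------------------------
# NUMT implantation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NumtSpec:
    """A nuclear copy of a mitochondrial segment in the mini nuclear reference."""

    mito_start0: int = 5000
    length: int = 400
    edit_every: int = 25
    flank: int = 150


def default_numt_catalog(
    ref: MitoReference, spec: NumtSpec = NumtSpec(), seed: int = 5000
) -> tuple[str, int]:
    """Mini nuclear reference: random flanks around a mito segment with dense
    edits (every ``edit_every`` bases, so every read-sized window holds >= 3).
    Returns (nuclear sequence, segment offset in the nuclear sequence)."""
    rng = np.random.default_rng(seed)
    seg = seq_to_codes(ref.sequence[spec.mito_start0 : spec.mito_start0 + spec.length]).copy()
    for off in range(spec.edit_every // 2, spec.length, spec.edit_every):
        seg[off] = (seg[off] + rng.integers(1, 4)) % 4
    flank_l = rng.integers(0, 4, spec.flank, dtype=np.uint8)
    flank_r = rng.integers(0, 4, spec.flank, dtype=np.uint8)
    nuclear = np.concatenate([flank_l, seg, flank_r])
    return _BASES[nuclear].tobytes().decode("ascii"), spec.flank


def spike_numts(
    r1: str | Path,
    r2: str | Path,
    manifest: TruthManifest,
    count: int,
    seed: int,
    out_prefix: str | Path,
    ref: MitoReference | None = None,
    spec: NumtSpec = NumtSpec(),
    read_len: int = 150,
    frag_len: int = 167,
    quality: int = 30,
    read_edits: tuple[int, int] = (0, 2),
) -> tuple[Path, Path, Path, TruthManifest]:
    """Append ``count`` NUMT-origin fragments to a mixture and emit the mini
    nuclear FASTA they derive from. NUMT fragments are windows of the nuclear
    copy with 0-2 extra substitutions, so they sit at Levenshtein distance
    < 3 from the nuclear reference but >= 3 from the mitochondrial one. The
    substitutions are molecule-level (both mates agree) and are the *only*
    noise on NUMT fragments, so each fragment's nuclear edit distance is
    exactly its drawn edit count."""
    ref = ref or bundled_reference()
    nuclear, _ = default_numt_catalog(ref, spec)
    rng = np.random.default_rng(seed)
    nuc_codes = seq_to_codes(nuclear)
    ids: list[str] = []
    out1 = Path(f"{out_prefix}_R1.fastq")
    out2 = Path(f"{out_prefix}_R2.fastq")
    nuc_path = Path(f"{out_prefix}_nuclear.fasta")
    qc = chr(quality + 33)
    with open(r1) as s1, open(out1, "w") as d1:
        d1.write(s1.read())
    with open(r2) as s2, open(out2, "w") as d2:
        d2.write(s2.read())
    if count:
        starts = rng.integers(0, len(nuc_codes) - frag_len + 1, count)
        mol = nuc_codes[starts[:, None] + np.arange(frag_len)[None, :]].copy()
        lo, hi = read_edits
        n_ed = rng.integers(lo, hi + 1, count)
        for i in range(count):
            for off in rng.choice(frag_len, int(n_ed[i]), replace=False):
                mol[i, off] = (mol[i, off] + rng.integers(1, 4)) % 4
        fr1 = mol[:, :read_len].copy()
        fr2 = (3 - mol[:, frag_len - read_len :])[:, ::-1].astype(np.uint8)
        ids = [f"numt:{i}" for i in range(count)]
        blob1 = _BASES[fr1].tobytes()
        blob2 = _BASES[fr2].tobytes()
        qual = qc * read_len
        with open(out1, "a") as d1, open(out2, "a") as d2:
            for i in range(count):
                seq1 = blob1[i * read_len : (i + 1) * read_len].decode("ascii")
                seq2 = blob2[i * read_len : (i + 1) * read_len].decode("ascii")
                d1.write(f"@{ids[i]}\n{seq1}\n+\n{qual}\n")
                d2.write(f"@{ids[i]}\n{seq2}\n+\n{qual}\n")
    with open(nuc_path, "w") as fh:
        fh.write(">mini_nuclear synthetic NUMT catalogue\n")
        for i in range(0, len(nuclear), 70):
            fh.write(nuclear[i : i + 70] + "\n")
    new_manifest = TruthManifest(
        total_fragments=manifest.total_fragments + count,
        sources=manifest.sources,
        ratio=manifest.ratio,
        numt_ids=ids,
        seed=manifest.seed,
    )
    return out1, out2, nuc_path, new_manifest


def random_reduce(
    r1: str | Path,
    r2: str | Path,
    k: int,
    seed: int,
    out_prefix: str | Path,
    manifest: TruthManifest | None = None,
) -> tuple[Path, Path, TruthManifest | None]:
    """Randomly reduce a mixture to ``k`` fragments (without replacement) and
    recompute the manifest's achieved per-source counts from the read ids."""
    out1, out2 = subset_fastq(r1, r2, k, seed, out_prefix)
    new_manifest = None
    if manifest is not None:
        counts: dict[str, int] = {}
        numt_ids = []
        with open(out1) as fh:
            for i, line in enumerate(fh):
                if i % 4 == 0:
                    rid = line[1:].strip()
                    origin = TruthManifest.origin_of(rid)
                    counts[origin] = counts.get(origin, 0) + 1
                    if origin == "numt":
                        numt_ids.append(rid)
        sources = []
        for s in manifest.sources:
            s2 = dict(s)
            s2["count"] = counts.get(s["source_id"], 0)
            sources.append(s2)
        new_manifest = TruthManifest(
            total_fragments=k,
            sources=sources,
            ratio=manifest.ratio,
            numt_ids=numt_ids,
            seed=seed,
        )
    return out1, out2, new_manifest


# ---------------------------------------------------------------------------
# scenario helper
# ---------------------------------------------------------------------------


@dataclass
class MixtureScenario:
    """Everything needed to run the pipeline on one synthetic mixture."""

    r1: Path
    r2: Path
    manifest: TruthManifest
    tree: PhyloTree
    ref: MitoReference
    primers: PrimerSet
    contributors: list[ContributorSpec]
    nuclear_fasta: Path | None = None
    nuclear_seq: str | None = None

    @property
    def truth(self) -> dict[str, float]:
        """True haplogroup -> proportion."""
        props = self.manifest.proportions
        return {
            self.manifest.haplogroup_of(s["source_id"]): props[s["source_id"]]
            for s in self.manifest.sources
        }

    def known_haplotypes(self) -> list[KnownHaplotype]:
        return [c.known_haplotype(self.tree) for c in self.contributors]


def make_mixture(
    workdir: str | Path,
    contributors: list[ContributorSpec],
    ratio: tuple[int, ...],
    total: int,
    seed: int,
    numt_count: int = 0,
    quality: int = 30,
    primer_mismatch_prob: float = 0.1,
    source_margin: float = 0.1,
) -> MixtureScenario:
    """Simulate sole sources and combine them into one mixture scenario.

    Sole sources are generated with a ~10% fragment surplus so the mixture
    subsets are genuine without-replacement draws.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ref = bundled_reference()
    tree = bundled_tree(ref)
    primers = bundled_primers(ref)
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, len(contributors) + 2)
    counts = ratio_counts(ratio, total)
    sources: list[SoleSourceSet] = []
    for i, (spec, want) in enumerate(zip(contributors, counts)):
        n_src = want + max(50, int(want * source_margin))
        sources.append(
            simulate_sole_source(
                spec,
                n_src,
                int(sub_seeds[i]),
                workdir / f"src_{spec.label}",
                tree=tree,
                ref=ref,
                quality=quality,
                primer_mismatch_prob=primer_mismatch_prob,
            )
        )
    r1, r2, manifest = mix_fastqs(
        sources, ratio, total, int(sub_seeds[-2]), workdir / "mixture"
    )
    nuclear_fasta = nuclear_seq = None
    if numt_count:
        r1, r2, nuclear_fasta, manifest = spike_numts(
            r1, r2, manifest, numt_count, int(sub_seeds[-1]), workdir / "spiked", ref=ref
        )
        nuclear_seq, _ = default_numt_catalog(ref)
    return MixtureScenario(
        r1=r1,
        r2=r2,
        manifest=manifest,
        tree=tree,
        ref=ref,
        primers=primers,
        contributors=list(contributors),
        nuclear_fasta=nuclear_fasta,
        nuclear_seq=nuclear_seq,
    )
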