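"""Noise reduction ahead of deconvolution.

Three stages, applied in a fixed order to paired FASTQ input:

1. **Pair error correction** — mates sequenced from the same PCR amplicon
   overlap once the reverse read is reverse-complemented. If the mates differ
   at two or fewer positions inside the overlap, each disagreement is replaced
   in both mates by the base with the higher sequencer quality; pairs with
   more than two disagreements pass through unchanged.
2. **Primer trimming** — known primer sequences (or their reverse complements)
   are removed when they occur at a read terminus within a small mismatch
   allowance; interior occurrences are left alone. This targets
   primer-directed error from degenerate amplification primers.
3. **NUMT removal** — reads are aligned to a nuclear reference; unclipped
   reads with Levenshtein distance < 3 are NUMT candidates, and a candidate is
   removed when its nuclear distance is strictly smaller than its distance to
   the circularized mitochondrial reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import KmerAligner
from .phylo import MitoReference

__all__ = [
    "ReadPair",
    "Fragment",
    "PrimerSet",
    "AlignmentRecord",
    "PreprocessConfig",
    "levenshtein",
    "revcomp",
    "find_overlap",
    "correct_pair",
    "trim_primers",
    "circularize_reference",
    "numt_candidates",
    "classify_numts",
    "preprocess_pairs",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def levenshtein(a: str, b: str) -> int:
    """Minimal number of insertions, deletions and substitutions between two strings."""
    if a == b:
        return 0
    if not a or not b:
        return abs(len(a) - len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


@dataclass
class ReadPair:
    """One paired-end record; read 2 is reverse-strand by convention."""

    read_id: str
    seq1: str
    qual1: np.ndarray  # Phred scores, uint8
    seq2: str
    qual2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class Fragment:
    """A merged read pair (single amplicon molecule) ready for alignment."""

    frag_id: str
    seq: str
    qual: np.ndarray


@dataclass
class AlignmentRecord:
    """Alignment summary of one read against one reference (nuclear or mito)."""

    read_id: str
    target: str  # "nuclear" | "mito"
    mapped: bool
    soft_clipped: bool
    lev_distance: float  # +inf for unmapped records


class PrimerSet:
    """Amplification primers, degenerate bases expanded to explicit variants.

    Each entry is (primer_id, sequence, terminus) with terminus ``5'``, ``3'``
    or ``either``. A primer listed for one terminus is searched as-is there and
    as its reverse complement at the opposite terminus (the same oligo seen
    from the other strand).
    """

    def __init__(self, entries: list[tuple[str, str, str]]) -> None:
        self.entries: list[tuple[str, str, str]] = []
        for pid, seq, term in entries:
            if term not in ("5'", "3'", "either"):
                raise ValueError(f"primer {pid}: bad terminus {term!r}")
            for i, variant in enumerate(_expand_degenerate(seq.upper())):
                vid = pid if i == 0 else f"{pid}.{i}"
                self.entries.append((vid, variant, term))
        if not self.entries:
            raise ValueError("primer set is empty")
        # lookup tables: head = match at read 5' start, tail = at read 3' end
        self._head: dict[int, dict[str, list[tuple[str, str]]]] = {}
        self._tail: dict[int, dict[str, list[tuple[str, str]]]] = {}
        for pid, seq, term in self.entries:
            if term in ("5'", "either"):
                self._add(self._head, pid, seq)
                self._add(self._tail, pid, revcomp(seq))
            if term in ("3'", "either"):
                self._add(self._tail, pid, seq)
                self._add(self._head, pid, revcomp(seq))

    @staticmethod
    def _add(table: dict, pid: str, seq: str) -> None:
        by_len = table.setdefault(len(seq), {})
        h = len(seq) // 2
        # with <=1 mismatch allowed, one half of the primer matches exactly
        by_len.setdefault(seq[:h], []).append((pid, seq))
        by_len.setdefault(seq[h:], []).append((pid, seq))

    @classmethod
    def from_tsv(cls, text: str) -> "PrimerSet":
        entries = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                fields.append("either")
            entries.append((fields[0], fields[1], fields[2]))
        return cls(entries)

    def _lookup(self, table: dict, read: str, at_tail: bool, max_mismatch: int):
        best: tuple[int, str, str] | None = None  # (length, pid, primer_seq)
        for length, halves in table.items():
            if length > len(read):
                continue
            window = read[-length:] if at_tail else read[:length]
            h = length // 2
            seen: set[str] = set()
            for key in (window[:h], window[h:]):
                for pid, pseq in halves.get(key, ()):
                    if pid in seen:
                        continue
                    seen.add(pid)
                    mm = sum(1 for x, y in zip(window, pseq) if x != y)
                    if mm <= max_mismatch and (best is None or length > best[0]):
                        best = (length, pid, pseq)
        return best

    def match_head(self, read: str, max_mismatch: int = 1):
        return self._lookup(self._head, read, at_tail=False, max_mismatch=max_mismatch)

    def match_tail(self, read: str, max_mismatch: int = 1):
        return self._lookup(self._tail, read, at_tail=True, max_mismatch=max_mismatch)


def _expand_degenerate(seq: str) -> list[str]:
    variants = [""]
    for ch in seq:
        if ch not in _IUPAC:
            raise ValueError(f"primer contains invalid base {ch!r}")
        variants = [v + b for v in variants for b in _IUPAC[ch]]
        if len(variants) > 64:
            raise ValueError("degenerate primer expands to more than 64 variants")
    return variants


# ---------------------------------------------------------------------------
# pair overlap and error correction
# ---------------------------------------------------------------------------


def _overlap_bounds(d: int, n1: int, n2: int) -> tuple[int, int]:
    """Overlap interval [lo, hi) in s1 coordinates for s2rc placed at offset d."""
    return max(0, d), min(n1, d + n2)


def find_overlap(
    s1: str, s2rc: str, min_overlap: int = 20, min_identity: float = 0.75
) -> int | None:
    """Ungapped overlap offset between read 1 and the reverse-complemented mate.

    Returns the signed offset ``d`` at which ``s2rc`` starts relative to
    ``s1`` (``d >= 0``: the mate starts inside read 1, the usual layout;
    ``d < 0``: the mate extends left of read 1, as happens after asymmetric
    primer trimming). The placement maximizing matching bases wins (ties to
    the longer overlap); it must span ``min_overlap`` bases at
    ``min_identity``. None when the mates do not overlap acceptably.
    """
    n1, n2 = len(s1), len(s2rc)
    if min(n1, n2) < min_overlap:
        return None
    a1 = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(s2rc.encode("ascii"), dtype=np.uint8)
    d_min, d_max = min_overlap - n2, n1 - min_overlap

    def score(d: int) -> tuple[int, int]:
        lo, hi = _overlap_bounds(d, n1, n2)
        return int((a1[lo:hi] == a2[lo - d : hi - d]).sum()), hi - lo

    # seed heuristic: anchor a short prefix of either sequence in the other
    candidates: set[int] = set()
    seed_len = 12
    for probe_start in (0, seed_len):
        if probe_start + seed_len <= n2:
            j = s1.find(s2rc[probe_start : probe_start + seed_len])
            while j != -1:
                candidates.add(j - probe_start)
                j = s1.find(s2rc[probe_start : probe_start + seed_len], j + 1)
        if probe_start + seed_len <= n1:
            m = s2rc.find(s1[probe_start : probe_start + seed_len])
            while m != -1:
                candidates.add(probe_start - m)
                m = s2rc.find(s1[probe_start : probe_start + seed_len], m + 1)
    best: tuple[int, int, int] | None = None  # (matches, overlap_len, d)
    for d in candidates:
        if not d_min <= d <= d_max:
            continue
        matches, ov = score(d)
        key = (matches, ov, d)
        if best is None or key > best:
            best = key
    if best is not None and best[0] >= min_identity * best[1]:
        return best[2]
    # exhaustive fallback (errors in the seed region, unusual layouts)
    for d in range(d_min, d_max + 1):
        matches, ov = score(d)
        if matches >= min_identity * ov and (best is None or (matches, ov, d) > best):
            best = (matches, ov, d)
    if best is not None and best[0] >= min_identity * best[1]:
        return best[2]
    return None


@dataclass
class PairStats:
    overlap: int | None = None
    n_diff: int = 0
    corrected: bool = False


def correct_pair(
    pair: ReadPair,
    min_overlap: int = 20,
    max_diffs: int = 2,
    min_identity: float = 0.75,
) -> tuple[ReadPair, PairStats]:
    """Reconcile mate disagreements inside the overlap by sequencer quality.

    If the mates differ at ``max_diffs`` or fewer positions, each differing
    position is set in *both* mates to the base with the higher quality score
    (ties keep read 1's base); with more differences the pair is returned
    unchanged. Non-overlapping tails are untouched.
    """
    s2rc = revcomp(pair.seq2)
    q2r = pair.qual2[::-1]
    d = find_overlap(pair.seq1, s2rc, min_overlap, min_identity)
    if d is None:
        return pair, PairStats(overlap=None)
    n1, n2 = len(pair.seq1), len(s2rc)
    lo, hi = _overlap_bounds(d, n1, n2)
    a1 = np.frombuffer(pair.seq1.encode("ascii"), dtype=np.uint8).copy()
    a2 = np.frombuffer(s2rc.encode("ascii"), dtype=np.uint8).copy()
    diffs = lo + np.flatnonzero(a1[lo:hi] != a2[lo - d : hi - d])
    stats = PairStats(overlap=hi - lo, n_diff=len(diffs))
    if len(diffs) == 0 or len(diffs) > max_diffs:
        return pair, stats
    q1 = pair.qual1.copy()
    q2 = q2r.copy()
    for i1 in diffs:
        i2 = i1 - d
        if q1[i1] >= q2[i2]:  # tie keeps read 1
            a2[i2] = a1[i1]
            q2[i2] = q1[i1]
        else:
            a1[i1] = a2[i2]
            q1[i1] = q2[i2]
    stats.corrected = True
    new = ReadPair(
        read_id=pair.read_id,
        seq1=a1.tobytes().decode("ascii"),
        qual1=q1,
        seq2=revcomp(a2.tobytes().decode("ascii")),
        qual2=q2[::-1],
    )
    return new, stats


def merge_pair(pair: ReadPair, min_overlap: int = 20, min_identity: float = 0.75) -> Fragment | None:
    """Merge mates into one fragment record; None when they do not overlap.

    The merged fragment spans the union of both mates at the best ungapped
    placement; inside the overlap the higher-quality base wins and matching
    bases take the larger of the two qualities.
    """
    s2rc = revcomp(pair.seq2)
    q2r = pair.qual2[::-1]
    d = find_overlap(pair.seq1, s2rc, min_overlap, min_identity)
    if d is None:
        return None
    n1, n2 = len(pair.seq1), len(s2rc)
    lo, hi = _overlap_bounds(d, n1, n2)
    a1 = np.frombuffer(pair.seq1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(s2rc.encode("ascii"), dtype=np.uint8)
    seg1, seg2 = a1[lo:hi], a2[lo - d : hi - d]
    q1seg, q2seg = pair.qual1[lo:hi], q2r[lo - d : hi - d]
    take2 = q2seg > q1seg
    overlap_bases = np.where(take2, seg2, seg1)
    overlap_quals = np.where(
        seg1 == seg2, np.maximum(q1seg, q2seg), np.where(take2, q2seg, q1seg)
    )
    mid = overlap_bases.tobytes().decode("ascii")
    if d >= 0:
        left_seq, left_qual = pair.seq1[:lo], pair.qual1[:lo]
    else:
        left_seq, left_qual = s2rc[: -d], q2r[: -d]
    if d + n2 >= n1:
        right_seq, right_qual = s2rc[hi - d :], q2r[hi - d :]
    else:
        right_seq, right_qual = pair.seq1[hi:], pair.qual1[hi:]
    seq = left_seq + mid + right_seq
    qual = np.concatenate([left_qual, overlap_quals, right_qual])
    return Fragment(frag_id=pair.read_id, seq=seq, qual=qual.astype(np.uint8))


# ---------------------------------------------------------------------------
# primer trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimReport:
    removed: list[str] = field(default_factory=list)  # primer ids, 5' then 3'
    bases_removed: int = 0


def trim_primers(
    seq: str,
    primers: PrimerSet,
    qual: np.ndarray | None = None,
    max_mismatch: int = 1,
) -> tuple[str, np.ndarray | None, TrimReport]:
    """Remove terminal primer occurrences; interior occurrences are untouched."""
    report = TrimReport()
    head = primers.match_head(seq, max_mismatch)
    if head is not None:
        length, pid, _ = head
        seq = seq[length:]
        if qual is not None:
            qual = qual[length:]
        report.removed.append(pid)
        report.bases_removed += length
    tail = primers.match_tail(seq, max_mismatch)
    if tail is not None:
        length, pid, _ = tail
        seq = seq[: len(seq) - length]
        if qual is not None:
            qual = qual[: len(qual) - length]
        report.removed.append(pid)
        report.bases_removed += length
    return seq, qual, report


# ---------------------------------------------------------------------------
# circularization and NUMT filtering
# ---------------------------------------------------------------------------


def circularize_reference(ref: MitoReference, pad: int) -> str:
    """Linearized circular reference: the sequence followed by its first ``pad`` bases.

    Alignment coordinates beyond L wrap back into [1, L] modulo L.
    """
    if not 0 < pad < len(ref):
        raise ValueError(f"pad must be in (0, {len(ref)}), got {pad}")
    return ref.sequence + ref.sequence[:pad]


def numt_candidates(alignments: list[AlignmentRecord]) -> set[str]:
    """Reads mapped to the nuclear reference, unclipped, with distance < 3."""
    return {
        a.read_id
        for a in alignments
        if a.mapped and not a.soft_clipped and a.lev_distance < 3
    }


def classify_numts(
    candidates: set[str],
    nuc_dist: dict[str, float],
    mito_dist: dict[str, float],
) -> set[str]:
    """Candidates strictly closer to the nuclear than the mitochondrial reference.

    Ties keep the read. Every candidate must carry both distances (unmapped
    mito alignments use the +inf sentinel); a missing entry is a pipeline
    ordering bug and raises.
    """
    missing = [r for r in candidates if r not in nuc_dist or r not in mito_dist]
    if missing:
        raise KeyError(f"candidates missing a distance: {sorted(missing)[:5]}")
    return {r for r in candidates if nuc_dist[r] < mito_dist[r]}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PreprocessConfig:
    min_overlap: int = 20
    max_pair_diffs: int = 2
    overlap_min_identity: float = 0.75
    primer_max_mismatch: int = 1
    circular_pad: int = 200
    aligner_k: int = 15


@dataclass
class PreprocessResult:
    pairs: list[ReadPair]
    fragments: list[Fragment]
    numt_removed_ids: set[str]
    metrics: dict


def preprocess_pairs(
    pairs: list[ReadPair] | "iter",
    primers: PrimerSet | None,
    mito: MitoReference,
    nuclear: str | None = None,
    config: PreprocessConfig | None = None,
    mito_aligner: KmerAligner | None = None,
) -> PreprocessResult:
    """Run correction -> trimming -> NUMT removal over a stream of read pairs.

    ``nuclear`` is a plain nuclear reference sequence (e.g. a mini NUMT
    catalogue); when None the NUMT stage is skipped. Returns the surviving
    pairs, their merged fragments, and stage metrics mirroring the count
    fields a run report carries (input reads, candidates, NUMTs removed).
    """
    cfg = config or PreprocessConfig()
    metrics = {
        "input_reads": 0,
        "pairs_corrected": 0,
        "pairs_no_overlap": 0,
        "pairs_over_diff_limit": 0,
        "reads_trimmed": 0,
        "primer_bases_removed": 0,
        "pairs_unmerged": 0,
        "numt_candidates": 0,
        "numts_removed": 0,
    }
    corrected: list[ReadPair] = []
    for pair in pairs:
        metrics["input_reads"] += 1
        pair, st = correct_pair(
            pair, cfg.min_overlap, cfg.max_pair_diffs, cfg.overlap_min_identity
        )
        if st.overlap is None:
            metrics["pairs_no_overlap"] += 1
        elif st.corrected:
            metrics["pairs_corrected"] += 1
        elif st.n_diff > cfg.max_pair_diffs:
            metrics["pairs_over_diff_limit"] += 1
        if primers is not None:
            s1, q1, rep1 = trim_primers(pair.seq1, primers, pair.qual1, cfg.primer_max_mismatch)
            s2, q2, rep2 = trim_primers(pair.seq2, primers, pair.qual2, cfg.primer_max_mismatch)
            if rep1.removed or rep2.removed:
                metrics["reads_trimmed"] += bool(rep1.removed) + bool(rep2.removed)
                metrics["primer_bases_removed"] += rep1.bases_removed + rep2.bases_removed
                pair = ReadPair(pair.read_id, s1, q1, s2, q2)
        corrected.append(pair)

    fragments: list[Fragment] = []
    frag_pairs: list[ReadPair] = []
    for pair in corrected:
        frag = merge_pair(pair, cfg.min_overlap, cfg.overlap_min_identity)
        if frag is None:
            # unmergeable pairs continue with read 1 as the fragment record
            metrics["pairs_unmerged"] += 1
            frag = Fragment(pair.read_id, pair.seq1, pair.qual1)
        fragments.append(frag)
        frag_pairs.append(pair)

    removed: set[str] = set()
    if nuclear is not None:
        nuc_aligner = KmerAligner(nuclear, circular=False, k=cfg.aligner_k)
        mito_aligner = mito_aligner or KmerAligner(
            mito.sequence, circular=True, k=cfg.aligner_k
        )
        nuc_records: list[AlignmentRecord] = []
        nuc_dist: dict[str, float] = {}
        for frag in fragments:
            pl = nuc_aligner.align(frag.seq)
            nuc_records.append(
                AlignmentRecord(frag.frag_id, "nuclear", pl.mapped, pl.soft_clipped, pl.lev)
            )
            nuc_dist[frag.frag_id] = pl.lev
        cands = numt_candidates(nuc_records)
        metrics["numt_candidates"] = len(cands)
        mito_dist = {
            frag.frag_id: mito_aligner.align(frag.seq).lev
            for frag in fragments
            if frag.frag_id in cands
        }
        removed = classify_numts(cands, nuc_dist, mito_dist)
        metrics["numts_removed"] = len(removed)
        fragments = [f for f in fragments if f.frag_id not in removed]
        frag_pairs = [p for p in frag_pairs if p.read_id not in removed]

    metrics["output_reads"] = len(frag_pairs)
    return PreprocessResult(
        pairs=frag_pairs, fragments=fragments, numt_removed_ids=removed, metrics=metrics
    )
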