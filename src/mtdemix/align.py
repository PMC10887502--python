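"""Desk-scale read aligner: exact k-mer seeding plus edit-distance verification.

The pipeline needs two alignments per fragment — one against the circularized
mitochondrial reference (for observation building and NUMT distance
comparison) and one against a small nuclear reference (for NUMT candidate
identification). Production deployments would use an external aligner and feed
SAM/BAM in; this built-in aligner covers mini references without external
binaries. It seeds with exact k-mers (default k=15), evaluates each candidate
placement ungapped, and verifies the best placement with an edlib global edit
distance.

Circular references are handled by wrapping coordinates modulo L, so amplicons
spanning the control-region junction align contiguously.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lowercase

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def seq_to_codes(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3; anything else 255)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


@dataclass
class Placement:
    """Result of aligning one read/fragment against one reference."""

    mapped: bool
    start0: int = -1  # 0-based start on the unpadded reference (wrapped)
    mismatches: int = -1  # ungapped mismatch count at the placement
    lev: float = float("inf")  # edit distance to the spanned reference window
    soft_clipped: bool = False


class KmerAligner:
    """Exact k-mer seeded aligner against one (optionally circular) reference.

    A read is *soft-clipped* when more than ``clip_tolerance`` contiguous
    terminal bases disagree with the reference at the best placement —
    mirroring SAM soft-clip semantics without a full affine aligner.
    """

    def __init__(
        self,
        ref_seq: str,
        circular: bool = False,
        k: int = 15,
        min_identity: float = 0.7,
        clip_tolerance: int = 2,
        max_seed_hits: int = 16,
    ) -> None:
        self.k = k
        self.circular = circular
        self.min_identity = min_identity
        self.clip_tolerance = clip_tolerance
        self.max_seed_hits = max_seed_hits
        self.L = len(ref_seq)
        self._codes = seq_to_codes(ref_seq)
        # index k-mers of the reference; for circular references also the
        # k-mers spanning the origin
        index: dict[str, list[int]] = {}
        indexable = ref_seq + (ref_seq[: k - 1] if circular else "")
        for p in range(len(indexable) - k + 1):
            index.setdefault(indexable[p : p + k], []).append(p % self.L if circular else p)
        self._index = index

    def _window(self, start0: int, n: int) -> np.ndarray:
        if self.circular:
            idx = np.arange(start0, start0 + n) % self.L
            return self._codes[idx]
        stop = min(start0 + n, self.L)
        return self._codes[start0:stop]

    def _candidates(self, seq: str) -> list[int]:
        n = len(seq)
        cands: list[int] = []
        seen: set[int] = set()
        for off in range(0, n - self.k + 1, self.k):
            hits = self._index.get(seq[off : off + self.k])
            if not hits:
                continue
            for p in hits[: self.max_seed_hits]:
                c = p - off
                if self.circular:
                    c %= self.L
                elif not 0 <= c <= self.L - 1:
                    continue
                if c not in seen:
                    seen.add(c)
                    cands.append(c)
            if len(cands) >= 1 and off >= self.k:
                break  # one confirmed seed region is enough for mini references
        return cands

    def align(self, seq: str) -> Placement:
        n = len(seq)
        if n < self.k:
            return Placement(mapped=False)
        cands = self._candidates(seq)
        if not cands:
            return Placement(mapped=False)
        codes = seq_to_codes(seq)
        best_start = -1
        best_mm = n + 1
        best_match: np.ndarray | None = None
        for c in cands:
            window = self._window(c, n)
            if len(window) < n:
                # linear reference overrun: missing bases count as mismatches
                match = np.zeros(n, dtype=bool)
                match[: len(window)] = codes[: len(window)] == window
            else:
                match = codes == window
            mm = int(n - match.sum())
            if mm < best_mm:
                best_mm, best_start, best_match = mm, c, match
        assert best_match is not None
        identity = 1.0 - best_mm / n
        if identity < self.min_identity:
            return Placement(mapped=False)
        # leading / trailing mismatch runs decide the soft-clip flag
        nz = np.flatnonzero(best_match)
        lead = int(nz[0]) if len(nz) else n
        trail = int(n - 1 - nz[-1]) if len(nz) else n
        clipped = lead > self.clip_tolerance or trail > self.clip_tolerance
        if best_mm <= 1:
            lev = float(best_mm)
        else:
            window = self._window(best_start, n)
            res = edlib.align(seq, codes_to_seq(window), mode="NW", task="distance")
            lev = float(min(best_mm, res["editDistance"]))
        return Placement(
            mapped=True, start0=best_start, mismatches=best_mm, lev=lev, soft_clipped=clipped
        )
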