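"""Joint EM estimation of contributor haplogroups and mixture proportions.

Each merged read fragment is reduced to its observations at phylogenetically
diagnostic positions: the observed base b and a Phred-derived error
probability eps = 10^(-Q/10). Under candidate haplogroup h with expected
allele a_h(p) (derived if p lies on h's cumulative path, reference otherwise),
the fragment log-likelihood is

    l_ih = sum_p [ log(1 - eps_ip)   if b_ip == a_h(p)
                   log(eps_ip / 3)   otherwise ]

— the standard independent-error read model. EM then alternates
responsibilities r_ih = pi_h exp(l_ih) / sum_h' pi_h' exp(l_ih') (computed in
log space) with the proportion update pi_h = mean_i r_ih, maximizing the
mixture likelihood over the simplex. Contributor selection iterates a
unique-fragment support filter and a proportion floor, refitting after each
round, and reports the survivors with their diagnostic SNPs and partial
haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .align import KmerAligner, seq_to_codes
from .phylo import SUBSTITUTION, KnownHaplotype, MitoReference, PhyloTree
from .preprocess import Fragment

__all__ = [
    "DeconvolveConfig",
    "ObservationMatrix",
    "EMState",
    "Contributor",
    "DeconvolutionResult",
    "build_observations",
    "expected_code_matrix",
    "fragment_log_likelihoods",
    "em_fit",
    "select_contributors",
    "deconvolute",
    "deconvolute_with_knowns",
    "report_diagnostics",
]

_EPS_FLOOR = 1e-6
_EPS_CEIL = 0.75


@dataclass
class DeconvolveConfig:
    """Tunable knobs of the EM fit and contributor selection."""

    tol: float = 1e-4  # convergence: max |delta pi|
    max_iter: int = 500
    min_prop: float = 0.01  # proportion floor for reported contributors
    min_unique_frags: int = 10  # fragments with responsibility > resp_threshold
    resp_threshold: float = 0.5
    min_prop_known: float = 0.001  # relaxed floors for grafted known haplotypes
    min_unique_frags_known: int = 3
    prune: bool = True  # drop candidates never near-best for any fragment
    prune_margin: float = math.log(1000.0)


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


@dataclass
class ObservationMatrix:
    """Per-fragment observed alleles and error probabilities at diagnostic positions.

    Only informative fragments (covering at least one diagnostic position with
    a called base) are indexed; the rest are tallied in the counters.
    """

    positions: np.ndarray  # (P,) 1-based diagnostic positions, ascending
    frag_ids: list[str]  # informative fragments, length N
    frag_index: np.ndarray  # (M,) observation -> fragment row
    pos_index: np.ndarray  # (M,) observation -> position column
    base_code: np.ndarray  # (M,) uint8 A=0 C=1 G=2 T=3
    eps: np.ndarray  # (M,) error probabilities in (0, 0.75]
    n_total: int = 0
    n_uninformative: int = 0
    n_unaligned: int = 0

    @property
    def n_fragments(self) -> int:
        return len(self.frag_ids)


def build_observations(
    fragments: list[Fragment],
    tree: PhyloTree,
    ref: MitoReference | None = None,
    aligner: KmerAligner | None = None,
) -> ObservationMatrix:
    """Align fragments to the circular reference and collect diagnostic-site observations.

    Fragments that fail to align are excluded and counted; fragments covering
    no diagnostic position are flagged uninformative. Ns and non-ACGT calls at
    a position skip that position for that fragment.
    """
    reference = ref or tree.reference
    if reference is None:
        raise ValueError("a mitochondrial reference is required (tree has none attached)")
    if aligner is None:
        aligner = KmerAligner(reference.sequence, circular=True)
    L = len(reference)
    positions = np.asarray(tree.diagnostic_positions(), dtype=np.int64)
    pos0 = positions - 1  # 0-based
    frag_ids: list[str] = []
    fi: list[np.ndarray] = []
    pi_: list[np.ndarray] = []
    bc: list[np.ndarray] = []
    ep: list[np.ndarray] = []
    n_total = n_uninf = n_unaligned = 0
    for frag in fragments:
        n_total += 1
        pl = aligner.align(frag.seq)
        if not pl.mapped:
            n_unaligned += 1
            continue
        n = len(frag.seq)
        start = pl.start0
        end = start + n
        if end <= L:
            sel = pos0[(pos0 >= start) & (pos0 < end)]
        else:  # fragment wraps the circular origin
            sel = np.concatenate([pos0[pos0 >= start], pos0[pos0 < end - L]])
        if len(sel) == 0:
            n_uninf += 1
            continue
        offsets = (sel - start) % L
        codes = seq_to_codes(frag.seq)[offsets]
        quals = frag.qual[offsets].astype(np.float64)
        ok = codes <= 3
        if not ok.any():
            n_uninf += 1
            continue
        sel, codes, quals = sel[ok], codes[ok], quals[ok]
        row = len(frag_ids)
        frag_ids.append(frag.frag_id)
        fi.append(np.full(len(sel), row, dtype=np.int64))
        pi_.append(np.searchsorted(positions, sel + 1))
        bc.append(codes)
        ep.append(np.clip(10.0 ** (-quals / 10.0), _EPS_FLOOR, _EPS_CEIL))
    cat = lambda parts, dt: (
        np.concatenate(parts).astype(dt) if parts else np.empty(0, dtype=dt)
    )
    return ObservationMatrix(
        positions=positions,
        frag_ids=frag_ids,
        frag_index=cat(fi, np.int64),
        pos_index=cat(pi_, np.int64),
        base_code=cat(bc, np.uint8),
        eps=cat(ep, np.float64),
        n_total=n_total,
        n_uninformative=n_uninf,
        n_unaligned=n_unaligned,
    )


# ---------------------------------------------------------------------------
# candidate models
# ---------------------------------------------------------------------------


def expected_code_matrix(
    tree: PhyloTree, candidates: list[str], positions: np.ndarray, ref: MitoReference
) -> np.ndarray:
    """(H, P) expected base codes: derived where a candidate's path carries a
    substitution at the position, reference base otherwise. Indel variants do
    not participate in the SNP likelihood and leave the reference base."""
    ref_codes = seq_to_codes(ref.sequence)[positions - 1]
    mat = np.tile(ref_codes, (len(candidates), 1))
    pos_col = {int(p): j for j, p in enumerate(positions)}
    for i, name in enumerate(candidates):
        for pos, var in tree.expected_variant_map(name).items():
            j = pos_col.get(pos)
            if j is not None and var.kind == SUBSTITUTION:
                mat[i, j] = seq_to_codes(var.derived)[0]
    return mat


def _collapse_duplicates(
    candidates: list[str], codes: np.ndarray, known_ids: frozenset[str]
) -> tuple[list[str], np.ndarray, dict[str, list[str]]]:
    """Merge candidates with identical expected profiles (EM cannot separate
    them and would freeze their uniform split). Known-haplotype labels win."""
    groups: dict[bytes, list[int]] = {}
    for i in range(len(candidates)):
        groups.setdefault(codes[i].tobytes(), []).append(i)
    keep: list[int] = []
    aliases: dict[str, list[str]] = {}
    for idxs in groups.values():
        names = [candidates[i] for i in idxs]
        known = sorted(n for n in names if n in known_ids)
        rep = known[0] if known else sorted(names)[0]
        keep.append(idxs[names.index(rep)])
        if len(names) > 1:
            aliases[rep] = sorted(n for n in names if n != rep)
    keep.sort()
    return [candidates[i] for i in keep], codes[keep], aliases


def fragment_log_likelihoods(obs: ObservationMatrix, expected_codes: np.ndarray) -> np.ndarray:
    """(N, H) per-fragment log-likelihoods under each candidate haplogroup."""
    N = obs.n_fragments
    H = expected_codes.shape[0]
    log_match = np.log1p(-obs.eps)
    log_miss = np.log(obs.eps / 3.0)
    ll = np.empty((N, H), dtype=np.float64)
    for h in range(H):
        match = expected_codes[h, obs.pos_index] == obs.base_code
        contrib = np.where(match, log_match, log_miss)
        ll[:, h] = np.bincount(obs.frag_index, weights=contrib, minlength=N)
    return ll


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


@dataclass
class EMState:
    candidates: list[str]
    pi: np.ndarray  # (H,) mixture proportions on the simplex
    resp: np.ndarray  # (N, H) responsibilities
    loglik: float
    ll_trace: list[float]
    n_fragments: int
    n_iter: int
    converged: bool
    aliases: dict[str, list[str]] = field(default_factory=dict)
    ll_matrix: np.ndarray | None = None


def em_fit(
    obs: ObservationMatrix,
    tree: PhyloTree,
    config: DeconvolveConfig | None = None,
    candidates: list[str] | None = None,
    ref: MitoReference | None = None,
) -> EMState:
    """Maximum-likelihood mixture fit over the candidate haplogroups.

    Initialization is uniform (deterministic); the log-likelihood trace is
    checked to be non-decreasing at every iteration.
    """
    cfg = config or DeconvolveConfig()
    reference = ref or tree.reference
    if obs.n_fragments == 0:
        raise ValueError("nothing to deconvolute: no informative fragments")
    cand = sorted(candidates) if candidates is not None else sorted(tree.nodes)
    codes = expected_code_matrix(tree, cand, obs.positions, reference)
    cand, codes, aliases = _collapse_duplicates(cand, codes, tree.known_ids)
    ll = fragment_log_likelihoods(obs, codes)
    if cfg.prune and len(cand) > 1:
        near_best = ll >= ll.max(axis=1, keepdims=True) - cfg.prune_margin
        keep = near_best.any(axis=0)
        for i, name in enumerate(cand):
            if name in tree.known_ids:
                keep[i] = True
        if keep.sum() >= 1 and not keep.all():
            cand = [c for c, k in zip(cand, keep) if k]
            ll = ll[:, keep]
    N, H = ll.shape
    pi = np.full(H, 1.0 / H)
    trace: list[float] = []
    converged = False
    it = 0
    resp = np.full((N, H), 1.0 / H)
    for it in range(1, cfg.max_iter + 1):
        a = np.log(np.maximum(pi, 1e-300)) + ll
        norm = logsumexp(a, axis=1)
        total = float(norm.sum())
        if trace and total < trace[-1] - 1e-6:
            raise AssertionError(f"EM log-likelihood decreased: {trace[-1]} -> {total}")
        trace.append(total)
        resp = np.exp(a - norm[:, None])
        new_pi = resp.mean(axis=0)
        delta = float(np.abs(new_pi - pi).max())
        pi = new_pi
        if delta < cfg.tol:
            converged = True
            break
    return EMState(
        candidates=cand,
        pi=pi,
        resp=resp,
        loglik=trace[-1],
        ll_trace=trace,
        n_fragments=N,
        n_iter=it,
        converged=converged,
        aliases=aliases,
        ll_matrix=ll,
    )


# ---------------------------------------------------------------------------
# contributor selection and reporting
# ---------------------------------------------------------------------------


@dataclass
class DiagnosticSNP:
    position: int
    expected_allele: str
    covering_fragments: int
    derived_fragments: int
    observed_fraction: float


@dataclass
class Contributor:
    haplogroup: str
    proportion: float  # renormalized over reported contributors
    raw_pi: float  # proportion in the final full fit
    n_strong_fragments: int
    is_known: bool
    aliases: list[str] = field(default_factory=list)
    diagnostics: list[DiagnosticSNP] = field(default_factory=list)
    partial_haplotype: list[str] = field(default_factory=list)
    no_coverage: bool = False


@dataclass
class DeconvolutionResult:
    contributors: list[Contributor]
    state: EMState
    warnings: list[str] = field(default_factory=list)
    n_fragments: int = 0
    n_uninformative: int = 0
    n_unaligned: int = 0

    def contributor_names(self) -> list[str]:
        return [c.haplogroup for c in self.contributors]

    def proportion_of(self, name: str) -> float | None:
        for c in self.contributors:
            if c.haplogroup == name or name in c.aliases:
                return c.proportion
        return None


def _strong_counts(state: EMState, threshold: float) -> np.ndarray:
    return (state.resp > threshold).sum(axis=0)


def select_contributors(
    state: EMState,
    obs: ObservationMatrix,
    tree: PhyloTree,
    config: DeconvolveConfig | None = None,
    ref: MitoReference | None = None,
) -> DeconvolutionResult:
    """Iteratively filter the EM fit down to the supported contributors.

    Phase 1 repeatedly drops candidates with fewer than ``min_unique_frags``
    fragments whose responsibility exceeds ``resp_threshold`` (these are the
    phantom candidates that only ride likelihood ties) and refits. Phase 2
    then drops candidates below the proportion floor and refits. Grafted
    known haplotypes are held to the relaxed ``*_known`` floors. Survivors are
    ranked by proportion (ties broken lexicographically).
    """
    cfg = config or DeconvolveConfig()
    warnings: list[str] = []
    st = state

    def floors(name: str) -> tuple[float, int]:
        if name in tree.known_ids:
            return cfg.min_prop_known, cfg.min_unique_frags_known
        return cfg.min_prop, cfg.min_unique_frags

    for phase in ("support", "proportion"):
        while True:
            strong = _strong_counts(st, cfg.resp_threshold)
            keep = []
            for i, name in enumerate(st.candidates):
                prop_floor, frag_floor = floors(name)
                if phase == "support":
                    ok = strong[i] >= frag_floor
                else:
                    ok = st.pi[i] >= prop_floor and strong[i] >= frag_floor
                if ok:
                    keep.append(name)
            if len(keep) == len(st.candidates):
                break
            if not keep:
                top = int(np.argmax(st.pi))
                keep = [st.candidates[top]]
                warnings.append(
                    "all candidates fell below support thresholds; reporting the "
                    "top candidate with low support"
                )
                st = em_fit(obs, tree, cfg, candidates=keep, ref=ref)
                break
            st = em_fit(obs, tree, cfg, candidates=keep, ref=ref)

    strong = _strong_counts(st, cfg.resp_threshold)
    order = sorted(range(len(st.candidates)), key=lambda i: (-st.pi[i], st.candidates[i]))
    total = float(st.pi.sum())
    contributors = [
        Contributor(
            haplogroup=st.candidates[i],
            proportion=float(st.pi[i] / total) if total > 0 else 0.0,
            raw_pi=float(st.pi[i]),
            n_strong_fragments=int(strong[i]),
            is_known=st.candidates[i] in tree.known_ids,
            aliases=st.aliases.get(st.candidates[i], []),
        )
        for i in order
    ]
    return DeconvolutionResult(
        contributors=contributors,
        state=st,
        warnings=warnings,
        n_fragments=obs.n_fragments,
        n_uninformative=obs.n_uninformative,
        n_unaligned=obs.n_unaligned,
    )


def report_diagnostics(
    result: DeconvolutionResult, obs: ObservationMatrix, tree: PhyloTree
) -> DeconvolutionResult:
    """Attach per-contributor diagnostic SNP tables and partial haplotypes.

    For each reported contributor, every expected diagnostic SNP covered by
    the data is listed with the fraction of covering fragments carrying the
    derived allele; the partial haplotype is the subset actually observed
    (at least one derived call). Contributors with no covered expected SNP
    are flagged ``no_coverage``.
    """
    pos_col = {int(p): j for j, p in enumerate(obs.positions)}
    cover = np.bincount(obs.pos_index, minlength=len(obs.positions))
    for contrib in result.contributors:
        contrib.diagnostics = []
        contrib.partial_haplotype = []
        for pos, var in sorted(tree.expected_variant_map(contrib.haplogroup).items()):
            if var.kind != SUBSTITUTION:
                continue
            j = pos_col.get(pos)
            if j is None or cover[j] == 0:
                continue
            sel = obs.pos_index == j
            code = seq_to_codes(var.derived)[0]
            derived = int((obs.base_code[sel] == code).sum())
            frac = derived / int(cover[j])
            contrib.diagnostics.append(
                DiagnosticSNP(
                    position=pos,
                    expected_allele=var.derived,
                    covering_fragments=int(cover[j]),
                    derived_fragments=derived,
                    observed_fraction=frac,
                )
            )
            if derived > 0:
                contrib.partial_haplotype.append(f"{pos}{var.derived}")
        contrib.no_coverage = len(contrib.diagnostics) == 0
    return result


# ---------------------------------------------------------------------------
# top-level entry points
# ---------------------------------------------------------------------------


def deconvolute(
    fragments: list[Fragment],
    tree: PhyloTree,
    ref: MitoReference | None = None,
    config: DeconvolveConfig | None = None,
    aligner: KmerAligner | None = None,
) -> DeconvolutionResult:
    """Full deconvolution of aligned, preprocessed fragments against a tree."""
    cfg = config or DeconvolveConfig()
    reference = ref or tree.reference
    obs = build_observations(fragments, tree, reference, aligner)
    state = em_fit(obs, tree, cfg, ref=reference)
    result = select_contributors(state, obs, tree, cfg, ref=reference)
    return report_diagnostics(result, obs, tree)


def deconvolute_with_knowns(
    fragments: list[Fragment],
    tree: PhyloTree,
    knowns: list[KnownHaplotype],
    ref: MitoReference | None = None,
    config: DeconvolveConfig | None = None,
    aligner: KmerAligner | None = None,
) -> DeconvolutionResult:
    """Deconvolution with investigator-supplied haplotypes grafted as candidates.

    Observations are rebuilt on the augmented tree: a known's private
    mutations become diagnostic for its grafted leaf, which is what lets the
    exact haplotype outcompete spurious haplogroups and surface trace
    contributors.
    """
    augmented = tree
    for kh in knowns:
        augmented = augmented.graft_known_haplotype(kh)
    return deconvolute(fragments, augmented, ref or tree.reference, config, aligner)
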