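"""Mitochondrial reference, variants, and the haplogroup phylotree.

The mtDNA phylogeny is a rooted tree whose branches carry haplogroup-defining
(diagnostic) variants. An individual's expected haplotype under a haplogroup is
the cumulative set of variants on the path from the root to that haplogroup's
node, with back-mutations (``7028T!``) removing the earlier variant at that
position. These cumulative sets are what the deconvolution scores reads
against.

Trees are read from a plain TSV dialect (one node per line: tab-indent for
depth, node name, then space-separated variant tokens such as ``16093C``,
``249d``, ``573.1C``; a ``!`` suffix marks a back-mutation). The dialect is
documented in the README; converters from other phylotree exports are left to
the user.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "MitoReference",
    "Variant",
    "HaplogroupNode",
    "PhyloTree",
    "KnownHaplotype",
    "PhyloParseError",
    "parse_variant_token",
    "parse_phylotree",
    "shared_diagnostic_fraction",
]

_VALID_BASES = set("ACGTN")

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


class PhyloParseError(ValueError):
    """Raised for malformed phylotree text; carries the offending line number."""


@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial reference sequence, rCRS-like numbering (1-based)."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside [1, {len(self.sequence)}]")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Variant:
    """A single difference from the reference at a 1-based position.

    ``derived`` is a base for substitutions, ``"-"`` for deletions, or the
    inserted sequence for insertions. ``back_mutation`` marks a reversion
    token (``X!``) which, during cumulative haplotype resolution, removes the
    variant previously acquired at this position.
    """

    position: int
    derived: str
    kind: str = SUBSTITUTION
    back_mutation: bool = False

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity used for set arithmetic: exact position + allele + kind."""
        return (self.position, self.derived, self.kind)

    def token(self) -> str:
        suffix = "!" if self.back_mutation else ""
        if self.kind == DELETION:
            return f"{self.position}d{suffix}"
        if self.kind == INSERTION:
            return f"{self.position}.1{self.derived}{suffix}"
        return f"{self.position}{self.derived}{suffix}"


_TOKEN_RE = re.compile(
    r"""^(?P<pos>\d+)
        (?:\.(?P<ins>\d+))?
        (?P<allele>[ACGTacgt]+|d)
        (?P<back>!?)$""",
    re.VERBOSE,
)


def parse_variant_token(token: str) -> Variant:
    """Parse a phylotree variant token (``16093C``, ``249d``, ``573.1C``, ``7028T!``)."""
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise ValueError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    allele = m.group("allele").upper()
    back = bool(m.group("back"))
    if allele == "D":
        allele = "d"
    if m.group("ins") is not None:
        if allele == "d":
            raise ValueError(f"malformed variant token {token!r}: insertion of a deletion")
        return Variant(pos, allele, INSERTION, back)
    if allele == "d":
        return Variant(pos, "-", DELETION, back)
    if len(allele) != 1:
        raise ValueError(f"malformed variant token {token!r}: multi-base substitution")
    return Variant(pos, allele, SUBSTITUTION, back)


@dataclass
class HaplogroupNode:
    name: str
    parent: str | None
    defining_variants: tuple[Variant, ...] = ()
    children: tuple[str, ...] = ()


@dataclass
class KnownHaplotype:
    """A contributor haplotype supplied by the investigator.

    ``variants`` are the full differences from the reference, including private
    mutations absent from the phylotree. ``heteroplasmies`` are optional
    (position, minor allele, minor-allele fraction) triples.
    """

    sample_id: str
    variants: tuple[Variant, ...] = ()
    heteroplasmies: tuple[tuple[int, str, float], ...] = ()

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(positions) != len(set(positions)):
            raise ValueError(f"known haplotype {self.sample_id}: duplicate variant positions")


class PhyloTree:
    """A rooted haplogroup tree plus the reference it is expressed against."""

    def __init__(
        self,
        nodes: dict[str, HaplogroupNode],
        root: str,
        reference: MitoReference | None = None,
        known_ids: frozenset[str] = frozenset(),
    ) -> None:
        self.nodes = nodes
        self.root = root
        self.reference = reference
        self.known_ids = known_ids
        self._expected_cache: dict[str, dict[int, Variant]] = {}
        self._validate()

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise ValueError(f"root {self.root!r} not among nodes")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise ValueError(f"cycle detected at node {name!r}")
            seen.add(name)
            stack.extend(self.nodes[name].children)
        orphans = set(self.nodes) - seen
        if orphans:
            raise ValueError(f"nodes unreachable from root: {sorted(orphans)}")

    # -- cumulative haplotypes -------------------------------------------------

    def _path(self, haplogroup: str) -> list[HaplogroupNode]:
        if haplogroup not in self.nodes:
            raise KeyError(f"unknown haplogroup {haplogroup!r}")
        path: list[HaplogroupNode] = []
        cursor: str | None = haplogroup
        while cursor is not None:
            node = self.nodes[cursor]
            path.append(node)
            cursor = node.parent
        path.reverse()
        return path

    def expected_variant_map(self, haplogroup: str) -> dict[int, Variant]:
        """Cumulative position -> variant map along the root-to-node path.

        A back-mutation token removes the variant at its position; a later
        plain token at an already-seen position overrides the earlier one.
        """
        cached = self._expected_cache.get(haplogroup)
        if cached is not None:
            return cached
        acc: dict[int, Variant] = {}
        for node in self._path(haplogroup):
            for v in node.defining_variants:
                if v.back_mutation:
                    acc.pop(v.position, None)
                else:
                    acc[v.position] = v
        self._expected_cache[haplogroup] = acc
        return acc

    def expected_variants(self, haplogroup: str) -> frozenset[Variant]:
        """The expected haplotype (set of variants) for a haplogroup."""
        return frozenset(self.expected_variant_map(haplogroup).values())

    def diagnostic_positions(self) -> list[int]:
        """All positions carried by any node's defining variants, ascending."""
        positions = {
            v.position for node in self.nodes.values() for v in node.defining_variants
        }
        return sorted(positions)

    # -- known haplotypes ------------------------------------------------------

    def graft_known_haplotype(self, kh: KnownHaplotype) -> "PhyloTree":
        """Return a new tree with ``kh`` attached as a leaf under the root.

        The leaf's cumulative expected variants equal ``kh.variants`` exactly;
        if the root itself carries variants, compensating back-mutations are
        added so the graft is faithful for arbitrary trees. Existing nodes are
        never mutated.
        """
        if kh.sample_id in self.nodes:
            raise ValueError(f"known haplotype id {kh.sample_id!r} collides with an existing node")
        root_acc = self.expected_variant_map(self.root)
        kh_positions = {v.position for v in kh.variants}
        defining = [replace(v, back_mutation=False) for v in kh.variants]
        for pos, v in root_acc.items():
            if pos not in kh_positions:
                defining.append(replace(v, back_mutation=True))
        nodes = dict(self.nodes)
        old_root = nodes[self.root]
        nodes[self.root] = replace(old_root, children=old_root.children + (kh.sample_id,))
        nodes[kh.sample_id] = HaplogroupNode(
            name=kh.sample_id, parent=self.root, defining_variants=tuple(defining)
        )
        return PhyloTree(
            nodes, self.root, self.reference, known_ids=self.known_ids | {kh.sample_id}
        )

    def parent_of(self, name: str) -> str | None:
        return self.nodes[name].parent

    def neighbors(self, name: str) -> set[str]:
        """The node itself, its parent, and its children (exact-or-adjacent scoring)."""
        node = self.nodes[name]
        out = {name, *node.children}
        if node.parent is not None:
            out.add(node.parent)
        return out


def parse_phylotree(tree_text: str, reference: MitoReference | None = None) -> PhyloTree:
    """Parse the phylotree TSV dialect into a :class:`PhyloTree`.

    One node per line; leading tab count gives the depth; the first
    whitespace-separated field is the node name, remaining fields are variant
    tokens. The first line must be the (unindented) root.
    """
    nodes: dict[str, HaplogroupNode] = {}
    root: str | None = None
    stack: list[str] = []  # stack[d] = most recent node at depth d
    for lineno, raw in enumerate(tree_text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        depth = len(raw) - len(raw.lstrip("\t"))
        fields = raw.strip().split()
        name, tokens = fields[0], fields[1:]
        if name in nodes:
            raise PhyloParseError(f"line {lineno}: duplicate node name {name!r}")
        try:
            variants = tuple(parse_variant_token(t) for t in tokens)
        except ValueError as exc:
            raise PhyloParseError(f"line {lineno}: {exc}") from exc
        if depth == 0:
            if root is not None:
                raise PhyloParseError(f"line {lineno}: second root {name!r} (tree must have one)")
            root = name
            parent = None
        else:
            if depth > len(stack):
                raise PhyloParseError(
                    f"line {lineno}: node {name!r} indented {depth} with no parent at depth {depth - 1}"
                )
            parent = stack[depth - 1]
            pnode = nodes[parent]
            nodes[parent] = replace(pnode, children=pnode.children + (name,))
        if reference is not None:
            _check_ref_alleles(variants, reference, lineno)
        nodes[name] = HaplogroupNode(name=name, parent=parent, defining_variants=variants)
        del stack[depth:]
        stack.append(name)
    if root is None:
        raise PhyloParseError("empty phylotree text")
    return PhyloTree(nodes, root, reference)


def _check_ref_alleles(variants: tuple[Variant, ...], ref: MitoReference, lineno: int) -> None:
    for v in variants:
        if not 1 <= v.position <= len(ref):
            raise PhyloParseError(
                f"line {lineno}: position {v.position} outside reference [1, {len(ref)}]"
            )
        if v.kind == SUBSTITUTION and not v.back_mutation:
            if ref.base_at(v.position) == v.derived:
                raise PhyloParseError(
                    f"line {lineno}: token {v.token()} matches the reference base"
                )


def shared_diagnostic_fraction(
    a: frozenset[Variant] | set[Variant],
    b: frozenset[Variant] | set[Variant],
    method: str = "jaccard",
) -> float:
    """Percent of haplogroup-defining SNPs shared between two expected haplotypes.

    Variants match on exact position + allele. ``method="jaccard"`` divides by
    the union size; ``method="min"`` by the smaller set size. Empty
    denominators yield 0.
    """
    ka = {v.key for v in a}
    kb = {v.key for v in b}
    inter = len(ka & kb)
    if method == "jaccard":
        denom = len(ka | kb)
    elif method == "min":
        denom = min(len(ka), len(kb))
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom == 0:
        return 0.0
    return 100.0 * inter / denom
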