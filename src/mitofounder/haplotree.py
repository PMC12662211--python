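"""Haplogroup classification and maximum-parsimony haplotype trees.

A haplogroup is a named clade of mtDNA lineages defined by a motif of derived
mutations relative to the rCRS.  Classification matches a sample's variant
profile against a reference motif tree (PhyloTree-style).  Tree building uses
greedy shared-variant agglomeration: the variant carried by the most unplaced
haplotypes founds the next internal node, recursively, which reconstructs the
perfect phylogeny exactly when the data are homoplasy-free.  An exhaustive
Fitch oracle over all rooted topologies (small n only) provides the
independent parsimony minimum for validation.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .mito_io import RCRS_LENGTH, ValidationError, Variant, VariantProfile, region_of


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference haplogroup tree

_MOTIF_RE = re.compile(r"^([ACGT])(\d+)([ACGT])(!?)$")


def parse_motif_token(token: str) -> tuple[int, str, str, bool]:
    """Parse a PhyloTree-style substitution token, e.g. ``A769G`` or ``T16189C!``.

    The trailing ``!`` marks a back mutation (return toward the ancestral
    state).  Returns (position, from_allele, to_allele, is_back).
    """
    m = _MOTIF_RE.match(token)
    if not m:
        raise ConfigurationError(f"unparseable motif token {token!r}")
    frm, pos, to, bang = m.group(1), int(m.group(2)), m.group(3), m.group(4)
    return pos, frm, to, bool(bang)


class ReferenceHaplogroupTree:
    """Motif tree: each node's defining variants are relative to its parent."""

    def __init__(self, nodes: Mapping[str, tuple[str | None, Sequence[str]]]):
        if not nodes:
            raise ConfigurationError("empty reference haplogroup tree")
        self.nodes = {label: (parent, tuple(motif)) for label, (parent, motif) in nodes.items()}
        roots = [lbl for lbl, (parent, _) in self.nodes.items() if parent is None]
        if len(roots) != 1:
            raise ConfigurationError(f"expected a single root, found {roots}")
        self.root = roots[0]
        self.children: dict[str, list[str]] = {lbl: [] for lbl in self.nodes}
        for lbl, (parent, _) in self.nodes.items():
            if parent is not None:
                if parent not in self.nodes:
                    raise ConfigurationError(f"unknown parent {parent!r} of {lbl!r}")
                self.children[parent].append(lbl)
        for kids in self.children.values():
            kids.sort()
        self._state_cache: dict[str, dict[int, str]] = {}

    def path_to_root(self, label: str) -> list[str]:
        out = []
        while label is not None:
            out.append(label)
            label = self.nodes[label][0]
        return out

    def depth(self, label: str) -> int:
        return len(self.path_to_root(label)) - 1

    def expected_states(self, label: str) -> dict[int, str]:
        """Cumulative derived substitution states (position -> allele) expected
        for a haplotype belonging to ``label``, relative to the tree root.
        Back-mutation tokens erase the expectation at their position."""
        if label in self._state_cache:
            return self._state_cache[label]
        parent, motif = self.nodes[label]
        states = dict(self.expected_states(parent)) if parent is not None else {}
        for token in motif:
            pos, _frm, to, back = parse_motif_token(token)
            if back:
                states.pop(pos, None)
            else:
                states[pos] = to
        self._state_cache[label] = states
        return states


def read_reference_tree(path: str | Path) -> ReferenceHaplogroupTree:
    """Tabular motif tree: TSV with columns label, parent, motif (space-separated
    tokens); an empty/absent parent marks the root."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    nodes = {}
    for row in df.itertuples():
        parent = row.parent if row.parent else None
        motif = row.motif.split() if getattr(row, "motif", "") else []
        nodes[row.label] = (parent, motif)
    return ReferenceHaplogroupTree(nodes)


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    best_label: str
    score: float  # fraction of expected defining variants observed
    path_depth: int


def classify(profile: VariantProfile, ref_tree: ReferenceHaplogroupTree) -> HaplogroupCall:
    """Assign the haplogroup whose cumulative motif best explains the profile.

    Each node is scored as (expected derived states observed) minus (expected
    states missing); the maximizing node wins, ties broken by greater depth
    then lexicographic label.  Only substitutions participate (profiles should
    be masked first).
    """
    observed = {v.position: v.alt_allele for v in profile.substitutions()}
    best: tuple[float, int, str] | None = None
    best_frac = 1.0
    for label in ref_tree.nodes:
        expected = ref_tree.expected_states(label)
        matched = sum(1 for pos, alt in expected.items() if observed.get(pos) == alt)
        mismatched = len(expected) - matched
        score = matched - mismatched
        depth = ref_tree.depth(label)
        key = (score, depth, _neg_lex(label))
        if best is None or key > best:
            best = key
            best_label = label
            best_frac = matched / len(expected) if expected else 1.0
            best_depth = depth
    return HaplogroupCall(profile.sample_id, best_label, best_frac, best_depth)


class _neg_lex(str):
    """Orders lexicographically *smaller* strings as larger, for max() keys."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Parsimony trees

VarKey = tuple[int, str, str]  # (position, from_allele, to_allele)


def _var_key(v: Variant) -> VarKey:
    return (v.position, v.ref_allele, v.alt_allele)


def relative_variants(profile: VariantProfile, root: VariantProfile) -> frozenset[VarKey]:
    """Mutations separating ``profile`` from the clade root haplotype.

    Variants present in the profile but not the root are forward mutations;
    root variants absent from the profile appear as back mutations with the
    alleles reversed.
    """
    p = {(_var_key(v)) for v in profile.variants}
    r = {(_var_key(v)) for v in root.variants}
    forward = p - r
    back = {(pos, to, frm) for (pos, frm, to) in (r - p)}
    return frozenset(forward | back)


class TreeNode:
    """Node of a mutation-labelled genealogy.

    ``edge_variants`` are the mutations on the branch above this node;
    ``sample_ids`` is nonempty for tips (identical haplotypes collapse onto one
    tip, so a tip may carry several sample ids).
    """

    __slots__ = ("name", "children", "edge_variants", "sample_ids", "time_years")

    def __init__(self, name: str = "", edge_variants: Sequence[VarKey] = (),
                 sample_ids: Sequence[str] = (), time_years: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.edge_variants: tuple[VarKey, ...] = tuple(edge_variants)
        self.sample_ids: tuple[str, ...] = tuple(sample_ids)
        self.time_years = time_years

    @property
    def is_tip(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def n_tips_below(self) -> int:
        """Samples subtended, counting multiplicity; a tip counts its own ids."""
        n = len(self.sample_ids)
        for c in self.children:
            n += c.n_tips_below()
        return n

    def n_haplotypes_below(self) -> int:
        n = 1 if self.is_tip else 0
        for c in self.children:
            n += c.n_haplotypes_below()
        return n


@dataclass
class ParsimonyTree:
    root: TreeNode
    root_label: str = "root"
    root_profile: VariantProfile | None = None

    @property
    def score(self) -> int:
        return sum(len(n.edge_variants) for n in self.root.walk())

    def tips(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_tip]

    def tip_path_variants(self) -> dict[str, frozenset[VarKey]]:
        """Root->tip mutation replay per sample, back mutations cancelling."""
        out: dict[str, frozenset[VarKey]] = {}

        def rec(node: TreeNode, state: dict[int, tuple[str, str]]):
            state = dict(state)
            for (pos, frm, to) in node.edge_variants:
                cur = state.get(pos)
                if cur is not None and cur[1] == frm and cur[0] == to:
                    del state[pos]  # back mutation cancels
                else:
                    state[pos] = (frm, to)
            if node.is_tip:
                keys = frozenset((pos, frm, to) for pos, (frm, to) in state.items())
                for sid in node.sample_ids:
                    out[sid] = keys
            for c in node.children:
                rec(c, state)

        rec(self.root, {})
        return out


def build_mp_tree(profiles: Sequence[VariantProfile],
                  root: VariantProfile | None = None,
                  root_label: str = "root") -> ParsimonyTree:
    """Greedy shared-variant agglomeration into a rooted mutation-labelled tree.

    At each node, the variant shared by the largest number of unplaced
    haplotypes (ties: lowest position, then alleles) founds a child clade;
    haplotypes sharing nothing hang off as tips carrying their private
    mutations.  Identical haplotypes collapse to one tip.  On homoplasy-free
    input this recovers the perfect phylogeny; with homoplasy, a recurrent
    mutation simply appears on more than one edge.
    """
    if not profiles:
        raise ValidationError("build_mp_tree requires at least one profile")
    if root is None:
        root = VariantProfile("root", ())
    # collapse identical haplotypes; sample ids kept sorted for determinism
    groups: dict[frozenset[VarKey], list[str]] = {}
    for p in sorted(profiles, key=lambda p: p.sample_id):
        groups.setdefault(relative_variants(p, root), []).append(p.sample_id)
    items = [(set(k), tuple(sids)) for k, sids in sorted(
        groups.items(), key=lambda kv: sorted(kv[1]))]

    root_node = TreeNode(name=root_label)
    _agglomerate(root_node, items)
    _name_internal(root_node, root_label)
    return ParsimonyTree(root_node, root_label, root)


def _agglomerate(node: TreeNode, items: list[tuple[set[VarKey], tuple[str, ...]]]) -> None:
    remaining = list(items)
    # haplotypes identical to this node's state become zero-edge tips
    for vs, sids in [it for it in remaining if not it[0]]:
        node.children.append(TreeNode(name=sids[0], sample_ids=sids))
    remaining = [it for it in remaining if it[0]]
    while remaining:
        counts: dict[VarKey, int] = {}
        for vs, _ in remaining:
            for v in vs:
                counts[v] = counts.get(v, 0) + 1
        best_var = min((v for v, c in counts.items() if c == max(counts.values())))
        if counts[best_var] >= 2:
            share = [it for it in remaining if best_var in it[0]]
            remaining = [it for it in remaining if best_var not in it[0]]
            # all variants with exactly this carrier set ride the same edge
            edge_vars = {
                v for v in share[0][0]
                if all(v in vs for vs, _ in share)
                and not any(v in vs for vs, _ in remaining)
            }
            child = TreeNode(edge_variants=tuple(sorted(edge_vars)))
            node.children.append(child)
            _agglomerate(child, [(vs - edge_vars, sids) for vs, sids in share])
        else:
            for vs, sids in remaining:
                node.children.append(TreeNode(
                    name=sids[0], edge_variants=tuple(sorted(vs)), sample_ids=sids))
            remaining = []


def _name_internal(root: TreeNode, root_label: str) -> None:
    i = 0
    for n in root.walk():
        if not n.is_tip and not n.name:
            i += 1
            n.name = f"{root_label}.n{i}"


# ---------------------------------------------------------------------------
# Exhaustive parsimony oracle

MAX_ORACLE_HAPLOTYPES = 8


def _rooted_topologies(n: int) -> Iterator:
    """All rooted binary leaf-labelled topologies on leaves 0..n-1 as nested
    pairs; there are (2n-3)!! of them."""

    def insert(t, leaf):
        yield (t, leaf)
        if isinstance(t, tuple):
            l, r = t
            for nl in insert(l, leaf):
                yield (nl, r)
            for nr in insert(r, leaf):
                yield (l, nr)

    def gen(k):
        if k == 1:
            yield 0
            return
        for t in gen(k - 1):
            yield from insert(t, k - 1)

    yield from gen(n)


def _fitch_masks(t, leaf_bits: list[int], full: int) -> tuple[int, int, int]:
    """Bitmask Fitch over all characters at once: returns (set-contains-0 mask,
    set-contains-1 mask, change count)."""
    if isinstance(t, int):
        v = leaf_bits[t]
        return (~v) & full, v, 0
    (l0, l1, lc) = _fitch_masks(t[0], leaf_bits, full)
    (r0, r1, rc) = _fitch_masks(t[1], leaf_bits, full)
    i0, i1 = l0 & r0, l1 & r1
    empty = full & ~(i0 | i1)
    m0 = i0 | (empty & (l0 | r0))
    m1 = i1 | (empty & (l1 | r1))
    return m0, m1, lc + rc + empty.bit_count()


def parsimony_oracle(profiles: Sequence[VariantProfile],
                     root: VariantProfile | None = None) -> int:
    """Minimum Fitch parsimony score over all rooted topologies, with the root
    state fixed to the ancestral haplotype.  Exhaustive — refuses more than
    8 distinct haplotypes."""
    if root is None:
        root = VariantProfile("root", ())
    hap_sets = sorted({relative_variants(p, root) for p in profiles},
                      key=lambda s: sorted(s))
    n = len(hap_sets)
    if n > MAX_ORACLE_HAPLOTYPES:
        raise ValidationError(
            f"parsimony_oracle limited to {MAX_ORACLE_HAPLOTYPES} distinct haplotypes, got {n}")
    chars = sorted(set().union(*hap_sets)) if hap_sets else []
    if not chars:
        return 0
    char_idx = {c: i for i, c in enumerate(chars)}
    full = (1 << len(chars)) - 1
    leaf_bits = []
    for s in hap_sets:
        bits = 0
        for c in s:
            bits |= 1 << char_idx[c]
        leaf_bits.append(bits)
    if n == 1:
        return leaf_bits[0].bit_count()
    best = None
    for topo in _rooted_topologies(n):
        m0, _m1, changes = _fitch_masks(topo, leaf_bits, full)
        score = changes + (full & ~m0).bit_count()  # root forced to ancestral state
        if best is None or score < best:
            best = score
    return best


# ---------------------------------------------------------------------------
# New-haplogroup proposal

MIN_SAMPLES = 5
MIN_HAPLOTYPES = 2


def propose_haplogroups(tree: ParsimonyTree) -> list[tuple[str, bool, str]]:
    """Screen internal nodes as candidate new haplogroups.

    A candidate is accepted only when it subtends at least five samples
    (counting multiplicity) and at least two distinct haplotypes, and its
    defining edge is not a control-region mutation alone.
    """
    out = []
    for node in tree.root.walk():
        if node.is_tip or node is tree.root:
            continue
        n_samples = node.n_tips_below()
        n_haps = node.n_haplotypes_below()
        has_coding = any(region_of(pos) == "coding" for pos, _f, _t in node.edge_variants)
        if n_samples < MIN_SAMPLES:
            out.append((node.name, False, "fewer than five samples"))
        elif n_haps < MIN_HAPLOTYPES:
            out.append((node.name, False, "fewer than two haplotypes"))
        elif node.edge_variants and not has_coding:
            out.append((node.name, False, "control region mutation alone"))
        elif not node.edge_variants:
            out.append((node.name, False, "no defining mutation"))
        else:
            out.append((node.name, True, "ok"))
    return out


# ---------------------------------------------------------------------------
# Output

def variant_token(v: VarKey) -> str:
    pos, frm, to = v
    if frm == "-":
        return f"{pos}.1{to}"
    if to == "-":
        return f"{pos}d"
    return f"{frm}{pos}{to}"


def to_newick(tree: ParsimonyTree) -> str:
    """Newick with the number of edge mutations as branch length and the
    mutation tokens in a comment block."""

    def rec(node: TreeNode) -> str:
        label = node.name if node.is_tip else node.name
        if node.children:
            inner = ",".join(rec(c) for c in node.children)
            s = f"({inner}){label}"
        else:
            s = label
        muts = " ".join(variant_token(v) for v in node.edge_variants)
        comment = f"[&mutations={muts}]" if muts else ""
        return f"{s}:{len(node.edge_variants)}{comment}"

    return rec(tree.root) + ";"


def edge_table(tree: ParsimonyTree) -> "pd.DataFrame":
    import pandas as pd

    rows = []

    def rec(node: TreeNode, parent_name: str):
        for c in node.children:
            rows.append({
                "child_node": c.name,
                "parent_node": node.name,
                "mutations": " ".join(variant_token(v) for v in c.edge_variants),
                "n_tips_below": c.n_tips_below(),
            })
            rec(c, node.name)

    rec(tree.root, "")
    return pd.DataFrame(rows, columns=["child_node", "parent_node", "mutations", "n_tips_below"])
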