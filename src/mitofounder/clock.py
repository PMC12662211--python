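"""Clade dating: the rho statistic, clock-constrained ML, and the mtDNA clock.

Two estimators of a clade's coalescence age are provided.

* **rho**: the mean number of mutations separating each sampled haplotype
  from the clade's root haplotype, with the genealogy-weighted Poisson
  heuristic for its standard error,

      rho    = (1/n) sum_j n_j m_j
      sigma^2 = (1/n^2) sum_j n_j^2 m_j

  over edges j of the mutation-labelled genealogy, where m_j is the number of
  mutations on edge j and n_j the number of sampled tips it subtends.  On a
  star genealogy this reduces to sigma^2 = rho/n.

* **ML**: maximum-likelihood node heights under a strict molecular clock on a
  fixed topology, with a Tamura-Nei (TN93) substitution model, optional
  invariant-sites fraction and discrete-gamma rate heterogeneity across
  sites (equal-probability categories, within-category mean rates), and
  separate model instances for the coding (577-16,023) and control
  (16,024-576, wrapping the origin) partitions.

Mutational distances convert to years through the whole-mitogenome clock of
one substitution per 3,624 years, optionally composed with a tabulated
monotone purifying-selection correction curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammainc, gammaincinv

from .haplotree import ParsimonyTree, TreeNode
from .mito_io import CODING_END, CODING_START, RCRS_LENGTH, ValidationError

YEARS_PER_SUBSTITUTION = 3624.0
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# rho / sigma


@dataclass(frozen=True)
class RhoResult:
    clade_id: str
    n: int
    rho: float
    sigma: float


def rho_sigma(tree: ParsimonyTree, clade_root: TreeNode | None = None,
              clade_id: str = "") -> RhoResult:
    """Average mutational distance of a clade's haplotypes from its root.

    Tip multiplicity (identical haplotypes collapsed onto one tip) is
    honoured: a tip carrying k sample ids counts k times.
    """
    node = clade_root if clade_root is not None else tree.root
    n = node.n_tips_below()
    if n == 0:
        raise ValidationError("empty clade")
    s1 = s2 = 0.0
    for child in node.children:
        for sub in child.walk():
            m_j = len(sub.edge_variants)
            n_j = sub.n_tips_below()
            s1 += n_j * m_j
            s2 += n_j * n_j * m_j
    rho = s1 / n
    sigma = math.sqrt(s2) / n
    return RhoResult(clade_id or node.name, n, rho, sigma)


# ---------------------------------------------------------------------------
# Clock model


@dataclass(frozen=True)
class ClockModel:
    """Maps uncorrected mutational distance (whole-genome substitutions) to years.

    The default is the linear clock of one substitution per 3,624 years.  A
    purifying-selection correction can be supplied as a two-column table
    (substitutions, years), strictly increasing in both columns; values are
    linearly interpolated and the curve is anchored at (0, 0).
    """

    years_per_substitution: float = YEARS_PER_SUBSTITUTION
    correction_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.years_per_substitution <= 0:
            raise ValidationError("years_per_substitution must be positive")
        if self.correction_table is not None:
            xs = [x for x, _ in self.correction_table]
            ys = [y for _, y in self.correction_table]
            if any(b <= a for a, b in zip(xs, xs[1:])) or any(
                b <= a for a, b in zip(ys, ys[1:])
            ):
                raise ValidationError("correction table must be strictly increasing")

    def to_years(self, substitutions: float) -> float:
        s = max(substitutions, 0.0)
        if self.correction_table is None:
            return s * self.years_per_substitution
        xs = np.array([0.0] + [x for x, _ in self.correction_table])
        ys = np.array([0.0] + [y for _, y in self.correction_table])
        if s <= xs[-1]:
            return float(np.interp(s, xs, ys))
        # extrapolate with the final slope
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + (s - xs[-1]) * slope)


def load_correction_table(path: str | Path) -> ClockModel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    table = tuple((float(a), float(b)) for a, b in zip(df[0], df[1]))
    return ClockModel(correction_table=table)


@dataclass(frozen=True)
class AgeEstimate:
    clade_id: str
    method: str  # "rho" or "ml"
    age_years: float
    ci_low_years: float
    ci_high_years: float
    flagged: bool = False
    note: str = ""

    def __post_init__(self):
        if not (0 <= self.ci_low_years <= self.age_years <= self.ci_high_years):
            raise ValidationError("age estimate must satisfy 0 <= low <= age <= high")


def rho_age(r: RhoResult, clock: ClockModel | None = None, z: float = 1.96) -> AgeEstimate:
    """Convert a rho result to years with a normal-approximation CI (rho ± z sigma,
    truncated at zero before the clock conversion)."""
    clock = clock or ClockModel()
    lo = clock.to_years(max(r.rho - z * r.sigma, 0.0))
    hi = clock.to_years(r.rho + z * r.sigma)
    return AgeEstimate(r.clade_id, "rho", clock.to_years(r.rho), lo, hi)


# ---------------------------------------------------------------------------
# Substitution models

_N_FREE_PARAMS = {"JC69": 0, "K80": 1, "HKY85": 4, "TN93": 5}


@dataclass(frozen=True)
class SubstitutionModel:
    """Nucleotide substitution model in the TN93 family.

    Rates are exchangeabilities: ``transition_rate_purines`` (A<->G),
    ``transition_rate_pyrimidines`` (C<->T) and ``transversion_rate``; the
    generator is scaled so the mean substitution rate is 1 and branch lengths
    are expected substitutions per site.  ``gamma_shape`` switches on
    discrete-gamma rate variation with ``n_categories`` equal-probability
    categories; ``p_invariant`` adds an invariant-site class.
    """

    kind: str = "TN93"
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    transition_rate_purines: float = 1.0
    transition_rate_pyrimidines: float = 1.0
    transversion_rate: float = 1.0
    gamma_shape: float | None = None
    n_categories: int = 32
    p_invariant: float | None = None

    def __post_init__(self):
        if self.kind not in _N_FREE_PARAMS:
            raise ValidationError(f"unknown model kind {self.kind}")
        pi = np.asarray(self.base_frequencies, float)
        if pi.shape != (4,) or abs(pi.sum() - 1) > 1e-6 or (pi <= 0).any():
            raise ValidationError("base frequencies must be 4 positive values summing to 1")
        if self.kind in ("JC69", "K80") and not np.allclose(pi, 0.25):
            raise ValidationError(f"{self.kind} requires equal base frequencies")
        if self.kind in ("JC69",) and not (
            self.transition_rate_purines
            == self.transition_rate_pyrimidines
            == self.transversion_rate
        ):
            raise ValidationError("JC69 requires equal rates")
        if self.kind in ("K80", "HKY85") and (
            self.transition_rate_purines != self.transition_rate_pyrimidines
        ):
            raise ValidationError(f"{self.kind} requires a single transition rate")
        if self.p_invariant is not None and not 0 <= self.p_invariant < 1:
            raise ValidationError("p_invariant must lie in [0, 1)")

    @property
    def n_free_params(self) -> int:
        k = _N_FREE_PARAMS[self.kind]
        if self.gamma_shape is not None:
            k += 1
        if self.p_invariant is not None:
            k += 1
        return k

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Normalised generator Q (rows sum to zero, mean rate 1)."""
        pi = np.asarray(self.base_frequencies, float)
        a1, a2, b = (
            self.transition_rate_purines,
            self.transition_rate_pyrimidines,
            self.transversion_rate,
        )
        # order A C G T: purine transitions A<->G, pyrimidine transitions C<->T
        R = np.array(
            [
                [0, b, a1, b],
                [b, 0, b, a2],
                [a1, b, 0, b],
                [b, a2, b, 0],
            ],
            float,
        )
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # reversible Q is symmetrizable by sqrt(pi); eigh for stability
        pi = np.asarray(self.base_frequencies, float)
        d = np.sqrt(pi)
        S = (self.rate_matrix * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((S + S.T) / 2)
        U = V / d[:, None] * 1.0
        U = (V.T / d[None, :]).T  # U = D^-1/2 V
        Uinv = (V.T * d[None, :])  # V^T D^1/2
        return w, U, Uinv

    def transition_probabilities(self, t: float | np.ndarray) -> np.ndarray:
        """P(t) = exp(Qt); broadcasts over an array of branch lengths."""
        w, U, Uinv = self._eigen
        t = np.asarray(t, float)
        E = np.exp(np.multiply.outer(t, w))  # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", U, E, Uinv)
        return np.clip(P, 0.0, None)

    @cached_property
    def category_rates(self) -> np.ndarray:
        """Discrete-gamma rates: equal-probability categories, each assigned
        its within-category mean; mean rate over categories is 1."""
        if self.gamma_shape is None:
            return np.array([1.0])
        a, K = self.gamma_shape, self.n_categories
        edges = gammaincinv(a, np.arange(0, K + 1) / K) / a  # mean-1 gamma quantiles
        upper = gammainc(a + 1, a * edges[1:])
        lower = gammainc(a + 1, a * edges[:-1])
        return (upper - lower) * K


def jc69(gamma_shape: float | None = None, n_categories: int = 32,
         p_invariant: float | None = None) -> SubstitutionModel:
    return SubstitutionModel("JC69", gamma_shape=gamma_shape,
                             n_categories=n_categories, p_invariant=p_invariant)


# ---------------------------------------------------------------------------
# Partitions


@dataclass(frozen=True)
class PartitionScheme:
    partitions: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self):
        seen: set[int] = set()
        for _, positions in self.partitions:
            if seen & positions:
                raise ValidationError("partitions must be disjoint")
            seen |= positions

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.partitions]

    @staticmethod
    def default() -> "PartitionScheme":
        coding = frozenset(range(CODING_START, CODING_END + 1))
        control = frozenset(range(16024, RCRS_LENGTH + 1)) | frozenset(range(1, 577))
        return PartitionScheme((("coding", coding), ("control", control)))

    @staticmethod
    def single(length: int, name: str = "all") -> "PartitionScheme":
        return PartitionScheme(((name, frozenset(range(1, length + 1))),))


# ---------------------------------------------------------------------------
# Clock trees (node heights in expected substitutions per site)


class ClockNode:
    __slots__ = ("name", "children", "height")

    def __init__(self, name: str = "", children: Sequence["ClockNode"] = (),
                 height: float = 0.0):
        self.name = name
        self.children = list(children)
        self.height = height

    @property
    def is_tip(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def internal_nodes(self) -> list["ClockNode"]:
        return [n for n in self.walk() if not n.is_tip]

    def find(self, name: str) -> "ClockNode":
        for n in self.walk():
            if n.name == name:
                return n
        raise KeyError(name)

    def copy(self) -> "ClockNode":
        return ClockNode(self.name, [c.copy() for c in self.children], self.height)


def clock_tree_from_topology(tree: ParsimonyTree) -> ClockNode:
    """Strip a parsimony tree to its topology; tips are collapsed haplotypes
    (one leaf per tip node, named by its first sample id)."""

    def rec(node: TreeNode) -> ClockNode:
        if node.is_tip:
            return ClockNode(node.name or node.sample_ids[0])
        kids = [rec(c) for c in node.children]
        return ClockNode(node.name, kids)

    root = rec(tree.root)
    # suppress unary passthroughs (root with a single child chain)
    while len(root.children) == 1 and not root.children[0].is_tip:
        child = root.children[0]
        root = ClockNode(root.name, child.children)
    return root


# ---------------------------------------------------------------------------
# Likelihood


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype="S1") == b.encode()] = i
    return arr


def compress_patterns(
    sequences: Mapping[str, str],
    parts: PartitionScheme,
    exclude_positions: Iterable[int] = (),
) -> dict[str, tuple[list[str], np.ndarray, np.ndarray]]:
    """Per partition: (taxon order, pattern matrix [n_taxa, n_patterns], counts).

    Sites are 1-based; ``exclude_positions`` (e.g. masked hotspots) are dropped
    from every partition.  States: 0..3 = ACGT, -1 = missing.
    """
    names = sorted(sequences)
    L = len(next(iter(sequences.values())))
    if any(len(s) != L for s in sequences.values()):
        raise ValidationError("alignment sequences differ in length")
    mat = np.stack([_encode(sequences[n]) for n in names])
    excluded = set(exclude_positions)
    out = {}
    for pname, positions in parts.partitions:
        cols = sorted(p - 1 for p in positions if 1 <= p <= L and p not in excluded)
        if not cols:
            continue
        sub = mat[:, cols]
        patterns, counts = np.unique(sub, axis=1, return_counts=True)
        out[pname] = (names, patterns, counts)
    return out


def _pruning_partials(node: ClockNode, patterns: np.ndarray, taxon_index: dict[str, int],
                      model: SubstitutionModel, rate: float,
                      parent_height: float | None) -> np.ndarray:
    """Partial likelihoods [n_patterns, 4] at ``node`` conditional on the
    subtree below, already multiplied through this node's branch."""
    if node.is_tip:
        obs = patterns[taxon_index[node.name]]
        L = np.zeros((patterns.shape[1], 4))
        miss = obs < 0
        L[np.arange(len(obs))[~miss], obs[~miss]] = 1.0
        L[miss] = 1.0
    else:
        L = np.ones((patterns.shape[1], 4))
        for c in node.children:
            L *= _pruning_partials(c, patterns, taxon_index, model, rate, node.height)
    if parent_height is None:
        return L
    t = max(parent_height - node.height, 0.0) * rate
    P = model.transition_probabilities(t)
    return L @ P.T


def _partition_loglik(root: ClockNode, names: list[str], patterns: np.ndarray,
                      counts: np.ndarray, model: SubstitutionModel) -> float:
    pi = np.asarray(model.base_frequencies)
    taxon_index = {n: i for i, n in enumerate(names)}
    p_inv = model.p_invariant or 0.0
    rates = model.category_rates
    if p_inv > 0:
        rates = rates / (1.0 - p_inv)  # keep overall mean rate at 1
    site_lik = np.zeros(patterns.shape[1])
    for rate in rates:
        L = _pruning_partials(root, patterns, taxon_index, model, float(rate), None)
        site_lik += (L @ pi) / len(rates)
    site_lik *= 1.0 - p_inv
    if p_inv > 0:
        # invariant class: pattern must be constant across its observed taxa
        inv = np.zeros(patterns.shape[1])
        for j in range(patterns.shape[1]):
            obs = patterns[:, j][patterns[:, j] >= 0]
            if obs.size == 0:
                inv[j] = 1.0
            elif (obs == obs[0]).all():
                inv[j] = pi[obs[0]]
        site_lik += p_inv * inv
    if (site_lik <= 0).any():
        return -np.inf
    return float(counts @ np.log(site_lik))


def tree_loglik(
    sequences: Mapping[str, str],
    tree: ClockNode,
    model: SubstitutionModel | Mapping[str, SubstitutionModel],
    parts: PartitionScheme | None = None,
    exclude_positions: Iterable[int] = (),
) -> float:
    """Felsenstein pruning log-likelihood of an alignment on a clock tree.

    ``model`` may be one SubstitutionModel for all partitions or a mapping
    partition-name -> model.  Partition log-likelihoods add.
    """
    L = len(next(iter(sequences.values())))
    parts = parts or PartitionScheme.single(L)
    data = compress_patterns(sequences, parts, exclude_positions)
    total = 0.0
    for pname, (names, patterns, counts) in data.items():
        m = model[pname] if isinstance(model, Mapping) else model
        total += _partition_loglik(tree, names, patterns, counts, m)
    return total


# ---------------------------------------------------------------------------
# Clock-constrained height fitting

MAX_HEIGHT = 10.0


@dataclass
class ClockFit:
    tree: ClockNode
    loglik: float
    converged: bool
    n_iter: int
    data: dict  # compressed patterns, kept for profile-likelihood reuse
    model: SubstitutionModel | Mapping[str, SubstitutionModel]


def _fit_loglik(root: ClockNode, data, model) -> float:
    total = 0.0
    for pname, (names, patterns, counts) in data.items():
        m = model[pname] if isinstance(model, Mapping) else model
        total += _partition_loglik(root, names, patterns, counts, m)
    return total


def _initial_heights(root: ClockNode, init: float) -> None:
    def depth(n: ClockNode) -> int:
        return 1 + max((depth(c) for c in n.children), default=0)

    def assign(n: ClockNode, h: float):
        if n.is_tip:
            n.height = 0.0
            return
        n.height = h
        for c in n.children:
            assign(c, h * (depth(c) - 1) / max(depth(n) - 1, 1))

    assign(root, max(init, 1e-8))


def fit_clock_heights(
    sequences: Mapping[str, str],
    topology: ParsimonyTree | ClockNode,
    model: SubstitutionModel | Mapping[str, SubstitutionModel],
    parts: PartitionScheme | None = None,
    exclude_positions: Iterable[int] = (),
    rel_tol: float = 1e-6,
    max_sweeps: int = 60,
    restarts: int = 1,
    seed: int = 0,
) -> ClockFit:
    """Maximise the likelihood over node heights under a strict clock.

    Coordinate-wise bounded scalar optimisation: each internal node's height
    is optimised within [max(children heights), parent height] (root capped
    at 10 substitutions/site), sweeping until the log-likelihood improves by
    less than ``rel_tol`` in relative terms.  Seeded random restarts guard
    against poor initialisation; non-convergence is flagged, never silent.
    """
    root0 = topology if isinstance(topology, ClockNode) else clock_tree_from_topology(topology)
    L = len(next(iter(sequences.values())))
    parts = parts or PartitionScheme.single(L)
    data = compress_patterns(sequences, parts, exclude_positions)
    rng = np.random.default_rng(seed)

    # crude initial height from mean pairwise difference
    names = sorted(sequences)
    mat = np.stack([_encode(sequences[n]) for n in names])
    ok = (mat[0] >= 0)
    p = float(np.mean([np.mean((mat[0] != mat[i]) & ok & (mat[i] >= 0))
                       for i in range(1, len(names))])) if len(names) > 1 else 0.0
    init0 = max(p, 1e-6)

    best: ClockFit | None = None
    for r in range(max(restarts, 1)):
        root = root0.copy()
        init = init0 if r == 0 else init0 * float(rng.uniform(0.2, 5.0))
        _initial_heights(root, init)
        ll = _fit_loglik(root, data, model)
        converged = False
        sweep = 0
        for sweep in range(1, max_sweeps + 1):
            parent_of: dict[int, ClockNode | None] = {id(root): None}
            for n in root.walk():
                for c in n.children:
                    parent_of[id(c)] = n
            for node in root.internal_nodes():
                lo = max((c.height for c in node.children), default=0.0)
                parent = parent_of[id(node)]
                hi = parent.height if parent is not None else MAX_HEIGHT
                if hi - lo < 1e-12:
                    node.height = lo
                    continue

                def neg(h, node=node):
                    node.height = h
                    return -_fit_loglik(root, data, model)

                coarse = max((hi - lo) * 1e-5, 1e-10)
                res = optimize.minimize_scalar(
                    neg, bounds=(lo, hi), method="bounded",
                    options={"xatol": coarse})
                # refine near the optimum so wide bounds don't limit precision
                x = float(res.x)
                lo2, hi2 = max(lo, x - 10 * coarse), min(hi, x + 10 * coarse)
                res = optimize.minimize_scalar(
                    neg, bounds=(lo2, hi2), method="bounded",
                    options={"xatol": max((hi2 - lo2) * 1e-6, 1e-12)})
                node.height = float(res.x)
            new_ll = _fit_loglik(root, data, model)
            if abs(new_ll - ll) <= rel_tol * (abs(ll) + 1.0):
                ll = new_ll
                converged = True
                break
            ll = new_ll
        fit = ClockFit(root, ll, converged, sweep, data, model)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _profile_loglik(fit: ClockFit, clade_name: str, h: float) -> float:
    """Re-optimise all other heights with the clade root's height pinned."""
    root = fit.tree.copy()
    target = root.find(clade_name)
    target.height = h

    # restore clock feasibility around the pin: descendants clamp down,
    # ancestors bubble up
    def clamp_down(n: ClockNode, ceiling: float):
        for c in n.children:
            if not c.is_tip and c.height > ceiling:
                c.height = ceiling
            clamp_down(c, c.height if not c.is_tip else ceiling)

    clamp_down(target, h)
    parent_of: dict[int, ClockNode | None] = {id(root): None}
    for n in root.walk():
        for c in n.children:
            parent_of[id(c)] = n
    node = target
    while parent_of[id(node)] is not None:
        p = parent_of[id(node)]
        if p.height < node.height:
            p.height = node.height
        node = p
    ll = _fit_loglik(root, fit.data, fit.model)
    for _ in range(12):
        for n in root.internal_nodes():
            if n is target:
                continue
            lo = max((c.height for c in n.children), default=0.0)
            parent = parent_of[id(n)]
            hi = parent.height if parent is not None else MAX_HEIGHT
            if hi - lo < 1e-12:
                n.height = max(lo, min(n.height, hi)) if hi >= lo else lo
                continue

            def neg(x, n=n):
                n.height = x
                return -_fit_loglik(root, fit.data, fit.model)

            res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                           options={"xatol": max((hi - lo) * 1e-4, 1e-10)})
            n.height = float(res.x)
        new_ll = _fit_loglik(root, fit.data, fit.model)
        if abs(new_ll - ll) <= 1e-6 * (abs(ll) + 1.0):
            return new_ll
        ll = new_ll
    return ll


def ml_age(
    fit: ClockFit,
    clade_root: str | None = None,
    clock: ClockModel | None = None,
    genome_length: int = RCRS_LENGTH,
    conf_drop: float = 1.92,
) -> AgeEstimate:
    """Convert a fitted clade-root height to years with a profile-likelihood CI.

    The 95% interval is the set of heights whose profile log-likelihood lies
    within 1.92 units of the maximum (chi-square with one degree of freedom).
    When no bracket is found, a curvature-based normal interval is returned
    and flagged.
    """
    clock = clock or ClockModel()
    root = fit.tree if clade_root is None else fit.tree.find(clade_root)
    name = root.name
    h_hat = root.height
    age = clock.to_years(h_hat * genome_length)
    ll_max = _profile_loglik(fit, name, h_hat)
    target = ll_max - conf_drop

    def g(h):
        return _profile_loglik(fit, name, h) - target

    flagged, note = False, ""
    # lower bound
    xtol = max(h_hat * 3e-3, 1e-9)
    if h_hat <= 1e-12 or g(0.0) >= 0:
        lo_h = 0.0
    else:
        lo_h = optimize.brentq(g, 0.0, h_hat, xtol=xtol)
    # upper bound: expand a bracket
    hi_b = max(h_hat * 1.5, h_hat + 1e-4)
    for _ in range(40):
        if g(hi_b) < 0 or hi_b > MAX_HEIGHT:
            break
        hi_b *= 1.5
    if g(hi_b) < 0:
        hi_h = optimize.brentq(g, max(h_hat, 1e-12), hi_b, xtol=xtol)
    else:
        # curvature fallback
        eps = max(h_hat, 1e-4) * 1e-3
        d2 = (_profile_loglik(fit, name, h_hat + eps) - 2 * ll_max
              + _profile_loglik(fit, name, max(h_hat - eps, 0.0))) / eps**2
        se = math.sqrt(-1 / d2) if d2 < 0 else h_hat
        hi_h = h_hat + 1.96 * se
        lo_h = max(h_hat - 1.96 * se, 0.0)
        flagged, note = True, "profile bracket not found; curvature CI"
    return AgeEstimate(
        name, "ml", age,
        clock.to_years(lo_h * genome_length),
        clock.to_years(hi_h * genome_length),
        flagged=flagged, note=note,
    )


# ---------------------------------------------------------------------------
# Model selection


def _empirical_frequencies(sequences: Mapping[str, str]) -> tuple[float, float, float, float]:
    counts = np.zeros(4)
    for s in sequences.values():
        e = _encode(s)
        for i in range(4):
            counts[i] += int((e == i).sum())
    counts = np.maximum(counts, 1.0)
    f = counts / counts.sum()
    return tuple(float(x) for x in f)


def _make_model(kind: str, freqs, theta: np.ndarray, with_gamma: bool,
                with_inv: bool, n_categories: int) -> SubstitutionModel:
    i = 0
    a1 = a2 = b = 1.0
    if kind in ("K80", "HKY85"):
        a1 = a2 = math.exp(theta[i]); i += 1
    elif kind == "TN93":
        a1 = math.exp(theta[i]); i += 1
        a2 = math.exp(theta[i]); i += 1
    shape = None
    if with_gamma:
        shape = math.exp(theta[i]); i += 1
    pinv = None
    if with_inv:
        pinv = 1 / (1 + math.exp(-theta[i])) * 0.95; i += 1
    if kind in ("JC69", "K80"):
        freqs = (0.25, 0.25, 0.25, 0.25)
    return SubstitutionModel(kind, freqs, a1, a2, b, gamma_shape=shape,
                             n_categories=n_categories, p_invariant=pinv)


def _n_theta(kind: str, with_gamma: bool, with_inv: bool) -> int:
    n = {"JC69": 0, "K80": 1, "HKY85": 1, "TN93": 2}[kind]
    return n + int(with_gamma) + int(with_inv)


@dataclass(frozen=True)
class BicEntry:
    kind: str
    with_gamma: bool
    with_invariant: bool
    loglik: float
    n_params: int
    bic: float
    model: SubstitutionModel


def bic_select(
    sequences: Mapping[str, str],
    topology: ParsimonyTree | ClockNode,
    candidates: Sequence[tuple[str, bool, bool]] = (("JC69", False, False), ("TN93", False, False)),
    parts: PartitionScheme | None = None,
    n_categories: int = 6,
    seed: int = 0,
) -> list[BicEntry]:
    """Rank candidate substitution models by the Bayesian information criterion.

    Each candidate is (kind, +gamma, +invariant).  For every candidate the
    clock heights and free model parameters are jointly maximised; BIC is
    -2 max-log-likelihood + k ln(n_sites), where k counts free model
    parameters plus the free node heights.  Ascending BIC; best first.
    """
    if not candidates:
        raise ValidationError("bic_select needs at least one candidate")
    root0 = topology if isinstance(topology, ClockNode) else clock_tree_from_topology(topology)
    L = len(next(iter(sequences.values())))
    parts = parts or PartitionScheme.single(L)
    freqs = _empirical_frequencies(sequences)
    n_sites = sum(len([p for p in positions if 1 <= p <= L])
                  for _, positions in parts.partitions)
    n_heights = len(root0.copy().internal_nodes())
    entries = []
    for kind, with_gamma, with_inv in candidates:
        nt = _n_theta(kind, with_gamma, with_inv)

        def fit_for(theta: np.ndarray) -> ClockFit:
            m = _make_model(kind, freqs, theta, with_gamma, with_inv, n_categories)
            return fit_clock_heights(sequences, root0.copy(), m, parts,
                                     rel_tol=1e-5, max_sweeps=30, seed=seed)

        if nt == 0:
            fit = fit_for(np.empty(0))
            ll, theta_best = fit.loglik, np.empty(0)
        else:
            def neg(theta):
                return -fit_for(np.asarray(theta)).loglik

            res = optimize.minimize(neg, x0=np.zeros(nt), method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-4,
                                             "maxiter": 200 * nt})
            ll, theta_best = -float(res.fun), np.asarray(res.x)
        model = _make_model(kind, freqs, theta_best, with_gamma, with_inv, n_categories)
        k = model.n_free_params + n_heights
        bic = -2 * ll + k * math.log(n_sites)
        entries.append(BicEntry(kind, with_gamma, with_inv, ll, k, bic, model))
    return sorted(entries, key=lambda e: e.bic)


# ---------------------------------------------------------------------------
# Consensus


@dataclass(frozen=True)
class ConsensusInterval:
    low: float
    high: float
    empty: bool

    def as_tuple(self):
        return None if self.empty else (self.low, self.high)


def consensus_interval(estimates: Sequence[AgeEstimate]) -> ConsensusInterval:
    """Overlap of the confidence intervals of several estimates: the interval
    [max of lower bounds, min of upper bounds], flagged empty when disjoint."""
    if not estimates:
        raise ValidationError("consensus_interval needs at least one estimate")
    lo = max(e.ci_low_years for e in estimates)
    hi = min(e.ci_high_years for e in estimates)
    return ConsensusInterval(lo, hi, empty=lo > hi)
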