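"""Coalescent clades with known node times and sequences, for validation.

Every stage of the founder analysis can be exercised against simulated truth:
genealogies are drawn from the single-population coalescent (constant size,
exponential growth, or piecewise-constant female effective size), mutations
fall on branches as a Poisson process calibrated to the whole-mitogenome
clock (one substitution per 3,624 years by default), and sequences are
emitted by replaying mutations from a root haplotype on rCRS coordinates.

Mutational hotspots (by default the masked positions 16182/16183/16519,
upweighted 20-fold) are simulated so that site masking demonstrably improves
dating accuracy.  The reference sequence shipped by :func:`synthetic_reference`
is a synthetic stand-in with human-mtDNA-like base composition on the rCRS
coordinate grid; real rCRS-aligned data drop in unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clock import ClockModel, SubstitutionModel, YEARS_PER_SUBSTITUTION
from .haplotree import ParsimonyTree, ReferenceHaplogroupTree, TreeNode
from .mito_io import (
    RCRS_LENGTH,
    ReferenceGenome,
    ValidationError,
    Variant,
    VariantProfile,
    write_fasta,
)

DEFAULT_GENERATION_YEARS = 25.0
DEFAULT_HOTSPOTS = frozenset({16182, 16183, 16519})
DEFAULT_HOTSPOT_MULTIPLIER = 20.0

# human mtDNA L-strand base composition, approximately
_BASE_COMPOSITION = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}


def synthetic_reference(seed: int = 20_20, length: int = RCRS_LENGTH,
                        name: str = "rCRS") -> ReferenceGenome:
    """A synthetic reference on the rCRS coordinate grid (16,569 bp, 1-based)
    with realistic base composition.  It is a stand-in, not the real rCRS."""
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASE_COMPOSITION))
    probs = np.array(list(_BASE_COMPOSITION.values()))
    probs = probs / probs.sum()
    seq = "".join(rng.choice(bases, size=length, p=probs))
    return ReferenceGenome(name=name, sequence=seq)


# ---------------------------------------------------------------------------
# Demography and genealogies


@dataclass(frozen=True)
class DemographyModel:
    """Female effective population size through time (haploid N for mtDNA).

    ``kind``: constant | exponential_growth | piecewise_constant.  For
    exponential growth, size at time t generations before present is
    N(t) = effective_size * exp(-growth_rate * t) (i.e. the population grew
    toward the present at ``growth_rate`` per generation).  ``change_points``
    for the piecewise model are (time_generations, size) with increasing
    times; the size before the first change point is ``effective_size``.
    """

    kind: str = "constant"
    effective_size: float = 1000.0
    growth_rate: float = 0.0
    change_points: tuple[tuple[float, float], ...] = ()
    generation_years: float = DEFAULT_GENERATION_YEARS

    def __post_init__(self):
        if self.kind not in ("constant", "exponential_growth", "piecewise_constant"):
            raise ValidationError(f"unknown demography kind {self.kind}")
        if self.effective_size <= 0 or any(s <= 0 for _, s in self.change_points):
            raise ValidationError("population sizes must be positive")
        times = [t for t, _ in self.change_points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError("change points must increase in time")


def _coalescence_wait(k: int, t: float, dem: DemographyModel, rng) -> float:
    """Waiting time (generations) to the next coalescence among k lineages,
    starting at time t before present."""
    pair_rate = k * (k - 1) / 2.0
    E = rng.exponential()
    if dem.kind == "constant":
        return E * dem.effective_size / pair_rate
    if dem.kind == "exponential_growth":
        g = dem.growth_rate
        if g == 0:
            return E * dem.effective_size / pair_rate
        # integrated rate from t to t+w: pair_rate/(g N0) * (e^{g(t+w)} - e^{g t})
        N0 = dem.effective_size
        val = math.exp(g * t) + E * g * N0 / pair_rate
        return math.log(val) / g - t
    # piecewise constant: step through epochs
    epochs = [(0.0, dem.effective_size)] + list(dem.change_points)
    cur = t
    remaining = E
    for i, (start, size) in enumerate(epochs):
        end = epochs[i + 1][0] if i + 1 < len(epochs) else math.inf
        if end <= cur:
            continue
        seg_start = max(cur, start)
        rate = pair_rate / size
        seg_len = end - seg_start
        if remaining <= rate * seg_len:
            return seg_start + remaining / rate - t
        remaining -= rate * seg_len
        cur = end
    raise AssertionError("unreachable: last epoch is unbounded")


def simulate_genealogy(n: int, demography: DemographyModel | None = None,
                       seed: int = 0) -> TreeNode:
    """Draw a standard coalescent genealogy for ``n`` tips.

    Node times are stored in years (``time_years``), tips at 0; the returned
    root's time is the clade TMRCA.  Same seed, same genealogy.
    """
    if n < 2:
        raise ValidationError("need at least 2 tips")
    dem = demography or DemographyModel()
    rng = np.random.default_rng(seed)
    lineages = [TreeNode(name=f"s{i:03d}", time_years=0.0) for i in range(n)]
    t = 0.0  # generations
    while len(lineages) > 1:
        k = len(lineages)
        t += _coalescence_wait(k, t, dem, rng)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode(time_years=t * dem.generation_years)
        parent.children = [lineages[i], lineages[j]]
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(parent)
    root = lineages[0]
    k = 0
    for nnode in root.walk():
        if not nnode.is_tip and not nnode.name:
            k += 1
            nnode.name = f"anc{k:03d}"
    return root


def star_genealogy(n: int, tmrca_years: float) -> TreeNode:
    """A star genealogy: n tips radiating from a single root at the given age
    (the instantaneous-expansion limit, where rho dating is exact)."""
    root = TreeNode(name="anc001", time_years=tmrca_years)
    root.children = [TreeNode(name=f"s{i:03d}", time_years=0.0) for i in range(n)]
    return root


def genealogy_to_newick(root: TreeNode) -> str:
    def rec(node: TreeNode, parent_time: float | None) -> str:
        if node.children:
            inner = ",".join(rec(c, node.time_years) for c in node.children)
            s = f"({inner}){node.name}"
        else:
            s = node.name
        if parent_time is None:
            return s
        return f"{s}:{parent_time - node.time_years:.6g}"

    return rec(root, None) + ";"


# ---------------------------------------------------------------------------
# Sequence evolution


@dataclass
class SimulatedClade:
    genealogy: TreeNode
    true_tmrca_years: float
    sequences: dict[str, str]
    true_profiles: list[VariantProfile]
    seed: int
    reference: ReferenceGenome
    n_mutations: int
    branch_mutations: dict[str, int] = field(default_factory=dict)


def simulate_sequences(
    genealogy: TreeNode,
    reference: ReferenceGenome | None = None,
    model: SubstitutionModel | None = None,
    clock: ClockModel | None = None,
    hotspot_positions: frozenset[int] | set[int] = DEFAULT_HOTSPOTS,
    hotspot_multiplier: float = DEFAULT_HOTSPOT_MULTIPLIER,
    seed: int = 0,
) -> SimulatedClade:
    """Drop mutations on a genealogy and emit tip sequences.

    Each branch receives Poisson(branch_years / years_per_substitution)
    mutations; positions are drawn proportionally to per-site rates (hotspots
    upweighted, masked sites deliberately eligible so masking can be tested);
    the target allele is drawn from the substitution model's rate matrix given
    the current base.  Recurrent and back mutations arise naturally.
    """
    ref = reference or synthetic_reference()
    model = model or SubstitutionModel("TN93", base_frequencies=(0.31, 0.31, 0.13, 0.25),
                                       transition_rate_purines=20.0,
                                       transition_rate_pyrimidines=20.0,
                                       transversion_rate=1.0)
    clock = clock or ClockModel()
    rng = np.random.default_rng(seed)
    L = len(ref)
    weights = np.ones(L)
    for p in hotspot_positions:
        if 1 <= p <= L:
            weights[p - 1] = hotspot_multiplier
    weights = weights / weights.sum()
    Q = model.rate_matrix
    jump = Q.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump / jump.sum(axis=1, keepdims=True)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    idx_base = "ACGT"

    root_arr = np.frombuffer(ref.sequence.encode(), dtype="S1").copy()
    sequences: dict[str, str] = {}
    n_mut = 0

    def rec(node: TreeNode, state: dict[int, str], parent_time: float):
        nonlocal n_mut
        branch_years = parent_time - node.time_years
        if branch_years < 0:
            raise ValidationError("node times must decrease root->tips")
        lam = branch_years / clock.years_per_substitution
        k = int(rng.poisson(lam)) if lam > 0 else 0
        n_mut += k
        branch_counts[node.name] = k
        state = dict(state)
        for pos0 in rng.choice(L, size=k, p=weights):
            pos = int(pos0) + 1
            cur = state.get(pos, ref.sequence[pos - 1])
            new = idx_base[int(rng.choice(4, p=jump[base_idx[cur]]))]
            if new == ref.sequence[pos - 1]:
                state.pop(pos, None)  # back to reference
            else:
                state[pos] = new
        if node.is_tip:
            arr = root_arr.copy()
            for pos, b in state.items():
                arr[pos - 1] = b.encode()
            sequences[node.name] = arr.tobytes().decode()
            profiles.append(VariantProfile(
                node.name,
                tuple(Variant(pos, ref.sequence[pos - 1], b) for pos, b in state.items()),
            ))
        for c in node.children:
            rec(c, state, node.time_years)

    profiles: list[VariantProfile] = []
    branch_counts: dict[str, int] = {}
    for c in genealogy.children:
        rec(c, {}, genealogy.time_years)
    profiles.sort(key=lambda p: p.sample_id)
    sequences = dict(sorted(sequences.items()))
    return SimulatedClade(
        genealogy=genealogy,
        true_tmrca_years=genealogy.time_years,
        sequences=sequences,
        true_profiles=profiles,
        seed=seed,
        reference=ref,
        n_mutations=n_mut,
        branch_mutations=branch_counts,
    )


# ---------------------------------------------------------------------------
# Fixture suite


def sahul_reference_tree() -> ReferenceHaplogroupTree:
    """A compact Sahul-focused haplogroup topology (no motifs) used by the
    route-attribution fixtures; subclades inherit routes through it."""
    edges = {
        "mt-MRCA": (None, []),
        "L3": ("mt-MRCA", []),
        "M": ("L3", []), "N": ("L3", []),
        "M25": ("M", []), "M27": ("M", []), "M28": ("M", []),
        "M29'Q": ("M", []), "Q": ("M29'Q", []),
        "Q1": ("Q", []), "Q2": ("Q", []),
        "M42'74": ("M", []), "M42": ("M42'74", []),
        "M42a": ("M42", []), "M42c": ("M42", []),
        "M14": ("M", []), "M15'16": ("M", []),
        "M15": ("M15'16", []), "M16": ("M15'16", []),
        "M7": ("M", []), "M7c3c": ("M7", []),
        "M73": ("M", []), "M73a2": ("M73", []),
        "E": ("M", []),
        "R": ("N", []), "P": ("R", []), "R12": ("R", []), "R14": ("R", []),
        "S": ("N", []), "S2": ("S", []),
        "O": ("N", []), "N13": ("N", []),
    }
    return ReferenceHaplogroupTree(edges)


def sahul_route_table() -> tuple[dict[str, str], dict[tuple[str, str], str]]:
    """Founder-route assignments and the region-specific intrusive overrides:
    ancestral M25/M27/M28/M29'Q/P/R14 northern; M42a/M42c/R12/S/O/M14/M15/M16
    and N13 southern; E, M7c3c, M73a2 intrusive everywhere; Q intrusive in
    Australia; some N13 and S2 lineages intrusive in New Guinea."""
    routes = {
        "M25": "northern", "M27": "northern", "M28": "northern",
        "M29'Q": "northern", "P": "northern", "R14": "northern",
        "M42a": "southern", "M42c": "southern", "R12": "southern",
        "S": "southern", "O": "southern", "M14": "southern",
        "M15": "southern", "M16": "southern", "N13": "southern",
        "E": "intrusive", "M7c3c": "intrusive", "M73a2": "intrusive",
    }
    overrides = {
        ("Australia", "Q"): "intrusive",
        ("New Guinea", "N13"): "intrusive",
        ("New Guinea", "S2"): "intrusive",
    }
    return routes, overrides


def route_fixture_samples() -> list[tuple[str, str, str]]:
    """Per-sample (id, region, haplogroup) table for the route scenario.

    Regional totals follow the study composition (635 New Guinea, 16
    Bismarcks/Solomons, 65 Australia) with ~7% intrusive lineages in New
    Guinea, ~3% (haplogroup Q) in Australia, and a 36/64 northern/southern
    founder split in Australia.
    """
    spec = {
        "New Guinea": [("P", 200), ("Q1", 150), ("Q2", 100), ("M27", 60), ("M28", 50),
                       ("M25", 20), ("M29'Q", 6), ("R14", 5),
                       ("E", 20), ("M7c3c", 12), ("M73a2", 6), ("N13", 3), ("S2", 3)],
        "Bismarcks-Solomons": [("P", 10), ("Q1", 6)],
        "Australia": [("P", 23),
                      ("S", 14), ("O", 9), ("M42a", 8), ("M42c", 3), ("M14", 1),
                      ("M15", 1), ("M16", 1), ("N13", 2), ("R12", 1),
                      ("Q1", 2)],
    }
    samples = []
    i = 0
    for region, haps in spec.items():
        for hg, count in haps:
            for _ in range(count):
                i += 1
                samples.append((f"ind{i:04d}", region, hg))
    return samples


@dataclass(frozen=True)
class FixtureConfig:
    star_n: int = 50
    star_tmrca_years: float = 60_000.0
    constant_n: int = 20
    constant_N: float = 2_000.0
    generation_years: float = DEFAULT_GENERATION_YEARS
    reference_seed: int = 20_20


def make_fixture_suite(config: FixtureConfig | None = None, seed: int = 1,
                       out_dir: str | Path = "fixtures") -> dict[str, Path]:
    """Write a self-contained on-disk bundle: FASTA + sample sheets + truth
    tables for (i) a star-expansion clade, (ii) a constant-size clade, and
    (iii) the northern/southern route scenario with its route truth table."""
    import pandas as pd

    config = config or FixtureConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = synthetic_reference(config.reference_seed)
    paths: dict[str, Path] = {}

    ref_path = out / "reference.fasta"
    write_fasta(ref_path, {ref.name: ref.sequence})
    paths["reference"] = ref_path

    scenarios = {
        "star": star_genealogy(config.star_n, config.star_tmrca_years),
        "constant": simulate_genealogy(
            config.constant_n,
            DemographyModel("constant", config.constant_N,
                            generation_years=config.generation_years),
            seed=seed,
        ),
    }
    for offset, (name, genealogy) in enumerate(scenarios.items()):
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        clade = simulate_sequences(genealogy, ref, seed=seed + offset)
        write_fasta(sdir / "sequences.fasta", clade.sequences)
        pd.DataFrame(
            {"sample_id": list(clade.sequences), "region_label": name}
        ).to_csv(sdir / "samples.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "scenario": name,
            "true_tmrca_years": clade.true_tmrca_years,
            "n_tips": len(clade.sequences),
            "n_mutations": clade.n_mutations,
            "seed": clade.seed,
        }]).to_csv(sdir / "truth.tsv", sep="\t", index=False)
        (sdir / "genealogy.nwk").write_text(genealogy_to_newick(genealogy) + "\n")
        paths[name] = sdir

    rdir = out / "routes"
    rdir.mkdir(exist_ok=True)
    routes, overrides = sahul_route_table()
    samples = route_fixture_samples()
    pd.DataFrame(samples, columns=["sample_id", "region_label", "haplogroup"]).to_csv(
        rdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"haplogroup": h, "route": r} for h, r in routes.items()]
    ).to_csv(rdir / "route_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"region": a, "haplogroup": b, "route": r} for (a, b), r in overrides.items()]
    ).to_csv(rdir / "overrides.tsv", sep="\t", index=False)
    tree = sahul_reference_tree()
    pd.DataFrame(
        [{"label": lbl, "parent": parent or "", "motif": " ".join(motif)}
         for lbl, (parent, motif) in tree.nodes.items()]
    ).to_csv(rdir / "reference_tree.tsv", sep="\t", index=False)
    paths["routes"] = rdir
    return paths
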