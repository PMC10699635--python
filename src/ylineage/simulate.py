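"""Synthetic genealogies, STR haplotypes, SNP placements and discovery fixtures.

The generator produces data with exactly the statistical structure the
downstream analyses assume, so every stage is testable without external
downloads:

* male genealogies, either star-like (one founder, simultaneous expansion)
  or two-level hierarchical (populations nested in groups, with shared
  drift time increasing up the hierarchy);
* Y-STR haplotypes evolving along genealogy branches under a strictly
  symmetric single-step stepwise mutation model (SMM): the number of
  mutations on a branch of length t generations is Poisson(mu*t) per locus
  and each mutation moves the repeat count by +1 or -1 with probability
  1/2 each;
* biallelic SNPs placed once on genealogy branches (infinite-sites), nested
  consistently with a haplogroup tree so that every derived carrier of a
  child marker is also derived at all ancestral markers;
* candidate-variant lists with planted pass/fail outcomes for the discovery
  filter, together with the repeat mask, the known-variant catalog and a
  manifest naming the expected survivors.

All randomness flows through explicit integer seeds; identical seeds give
identical outputs.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import VariantRecord
from .genotypes import ANCESTRAL, DERIVED, MISSING, SNPGenotypeTable
from .haplogroup import HaplogroupTree
from .profiles import STRProfile

#: 15-locus dating/network panel: the 17-locus Y-filer panel minus DYS385a/b.
DEFAULT_LOCI = (
    "DYS456", "DYS389I", "DYS390", "DYS389II", "DYS458", "DYS19",
    "DYS393", "DYS391", "DYS439", "DYS635", "DYS392", "GATA-H4",
    "DYS437", "DYS438", "DYS448",
)

#: Realistic modal repeat counts used as the default ancestral haplotype.
DEFAULT_ANCESTRAL_ALLELES = {
    "DYS456": 15, "DYS389I": 13, "DYS390": 24, "DYS389II": 29,
    "DYS458": 16, "DYS19": 13, "DYS393": 13, "DYS391": 10,
    "DYS439": 12, "DYS635": 21, "DYS392": 14, "GATA-H4": 11,
    "DYS437": 14, "DYS438": 11, "DYS448": 19,
}


@dataclass
class STRModel:
    """Stepwise mutation model for a panel of Y-STR loci.

    mu_per_locus_per_gen is the per-locus, per-generation mutation
    probability (the evolutionary calibration used for dating corresponds
    to 6.9e-4 per locus per 25-year generation). The step distribution is
    strictly symmetric single-step: +/-1 repeat with probability 1/2 each.
    """

    loci: tuple[str, ...] = DEFAULT_LOCI
    mu_per_locus_per_gen: float = 6.9e-4
    ancestral_alleles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRAL_ALLELES)
    )
    step_distribution: str = "symmetric_single_step"

    def __post_init__(self) -> None:
        if self.mu_per_locus_per_gen <= 0:
            raise ValueError("mutation rate must be positive")
        if self.step_distribution != "symmetric_single_step":
            raise ValueError("only the symmetric single-step SMM is supported")
        missing = [l for l in self.loci if l not in self.ancestral_alleles]
        if missing:
            raise ValueError(f"no ancestral allele for loci {missing}")
        for l in self.loci:
            if self.ancestral_alleles[l] < 1:
                raise ValueError(f"ancestral allele at {l} must be >= 1")


@dataclass
class GenealogySpec:
    """Shape and timing of a simulated male genealogy.

    topology="star": n_samples lineages split simultaneously from one
    founder age_generations ago. topology="two_level_hierarchy": groups
    contain populations contain samples; divergence_generations =
    (shared_group_branch, shared_population_branch) gives the drift time,
    in generations, shared by all members of a group resp. population;
    each sample's private branch is age_generations minus their sum.
    group_sizes lists population sizes per group, e.g. [[10, 10], [20]]
    for two groups with two and one populations.
    """

    topology: str
    n_samples: int
    age_generations: float
    group_sizes: Sequence | None = None
    divergence_generations: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in {"star", "two_level_hierarchy"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.age_generations < 0:
            raise ValueError("age_generations must be >= 0")
        if self.topology == "two_level_hierarchy":
            if self.group_sizes is None:
                raise ValueError("two_level_hierarchy requires group_sizes")
            sizes = self.populations_per_group()
            if sum(sum(g) for g in sizes) != self.n_samples:
                raise ValueError("group_sizes must sum to n_samples")
            if self.divergence_generations is None:
                raise ValueError("two_level_hierarchy requires divergence_generations")
            tg, tp = self.divergence_generations
            if tg < 0 or tp < 0 or tg + tp > self.age_generations:
                raise ValueError(
                    "divergence_generations must be non-negative and sum to "
                    "at most age_generations"
                )

    def populations_per_group(self) -> list[list[int]]:
        """group_sizes normalised to a list of per-group population-size lists."""
        sizes = []
        for entry in self.group_sizes or []:
            if isinstance(entry, (list, tuple)):
                sizes.append([int(x) for x in entry])
            else:
                sizes.append([int(entry)])
        return sizes


@dataclass
class Genealogy:
    """Rooted genealogy; a branch is identified by the node below it.

    `order` is a fixed topological ordering used for all random draws, so
    output is reproducible for a given seed regardless of dict ordering.
    """

    root: str
    parent: dict[str, str | None]
    branch_gens: dict[str, float]
    order: list[str]
    leaves: list[str]
    population_of: dict[str, str]
    group_of: dict[str, str]

    def children(self, name: str) -> list[str]:
        return [n for n in self.order if self.parent[n] == name]

    def leaves_under(self, name: str) -> list[str]:
        wanted, stack = [], [name]
        below = set()
        while stack:
            node = stack.pop()
            below.add(node)
            stack.extend(n for n in self.order if self.parent[n] == node)
        return [l for l in self.leaves if l in below]

    def descendants_or_self(self, name: str) -> list[str]:
        out, stack = [], [name]
        while stack:
            node = stack.pop(0)
            out.append(node)
            stack.extend(n for n in self.order if self.parent[n] == node)
        return out


def build_star_genealogy(spec: GenealogySpec) -> Genealogy:
    if spec.topology != "star":
        raise ValueError("spec.topology must be 'star'")
    leaves = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    parent = {"root": None, **{l: "root" for l in leaves}}
    branch = {"root": 0.0, **{l: float(spec.age_generations) for l in leaves}}
    return Genealogy(
        root="root",
        parent=parent,
        branch_gens=branch,
        order=["root", *leaves],
        leaves=leaves,
        population_of={l: "pop1" for l in leaves},
        group_of={l: "group1" for l in leaves},
    )


def build_structured_genealogy(spec: GenealogySpec) -> Genealogy:
    if spec.topology != "two_level_hierarchy":
        raise ValueError("spec.topology must be 'two_level_hierarchy'")
    tg, tp = spec.divergence_generations
    t_leaf = float(spec.age_generations) - tg - tp
    parent: dict[str, str | None] = {"root": None}
    branch: dict[str, float] = {"root": 0.0}
    order, leaves = ["root"], []
    population_of, group_of = {}, {}
    counter = 0
    for gi, pops in enumerate(spec.populations_per_group(), start=1):
        gname = f"G{gi}"
        parent[gname], branch[gname] = "root", float(tg)
        order.append(gname)
        for pi, size in enumerate(pops, start=1):
            pname = f"G{gi}P{pi}"
            parent[pname], branch[pname] = gname, float(tp)
            order.append(pname)
            for _ in range(size):
                counter += 1
                lname = f"S{counter:04d}"
                parent[lname], branch[lname] = pname, t_leaf
                order.append(lname)
                leaves.append(lname)
                population_of[lname] = pname
                group_of[lname] = gname
    return Genealogy(
        root="root",
        parent=parent,
        branch_gens=branch,
        order=order,
        leaves=leaves,
        population_of=population_of,
        group_of=group_of,
    )


def _net_steps(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Net displacement of a symmetric +/-1 walk with Poisson(lam) steps."""
    n_mut = rng.poisson(lam, size=size)
    up = rng.binomial(n_mut, 0.5)
    return 2 * up - n_mut


def simulate_str_profiles(
    genealogy: Genealogy, model: STRModel, seed: int
) -> list[STRProfile]:
    """Evolve STR haplotypes down a genealogy under the symmetric SMM.

    Mutations accumulate independently per locus along every branch; a
    leaf's haplotype is the ancestral haplotype plus the summed net steps
    on its root-to-leaf path. Repeat counts are floored at 1 (the reflecting
    boundary is effectively never hit at realistic rates).
    """
    rng = np.random.default_rng(seed)
    L = len(model.loci)
    disp: dict[str, np.ndarray] = {}
    for node in genealogy.order:
        own = _net_steps(rng, model.mu_per_locus_per_gen * genealogy.branch_gens[node], L)
        above = disp[genealogy.parent[node]] if genealogy.parent[node] else 0
        disp[node] = above + own
    ancestral = np.array([model.ancestral_alleles[l] for l in model.loci])
    profiles = []
    for leaf in genealogy.leaves:
        alleles = np.maximum(ancestral + disp[leaf], 1)
        profiles.append(
            STRProfile(
                sample_id=leaf,
                alleles={l: int(a) for l, a in zip(model.loci, alleles)},
                population=genealogy.population_of[leaf],
                group=genealogy.group_of[leaf],
            )
        )
    return profiles


def simulate_star_genealogy(spec: GenealogySpec, model: STRModel) -> list[STRProfile]:
    """STR profiles for a star genealogy: i.i.d. Poisson(mu*T) steps per locus."""
    return simulate_str_profiles(build_star_genealogy(spec), model, spec.seed)


def simulate_structured_populations(
    spec: GenealogySpec, model: STRModel
) -> list[STRProfile]:
    """STR profiles for populations nested in groups, labels attached."""
    return simulate_str_profiles(build_structured_genealogy(spec), model, spec.seed)


@dataclass
class PlacementResult:
    """SNP genotypes from placing haplogroup-tree markers on genealogy branches.

    `table` is the genotype table (the primary output); `branch_of_node`
    records which genealogy branch each tree node landed on and
    `expected_terminal` the deepest planted clade containing each sample —
    the oracle a classifier run on `table` must reproduce.
    """

    table: SNPGenotypeTable
    branch_of_node: dict[str, str]
    expected_terminal: dict[str, str]


def place_snps_on_genealogy(
    genealogy: Genealogy,
    tree: HaplogroupTree,
    seed: int = 0,
    branch_of_node: dict[str, str] | None = None,
    missing_rate: float = 0.0,
) -> PlacementResult:
    """Place each haplogroup-tree node once on a genealogy branch.

    The tree root lands on the genealogy root (all samples derived); every
    child node lands on a branch descending from (or equal to) its parent's
    branch, chosen uniformly at random unless `branch_of_node` pins it.
    Under infinite-sites this guarantees perfect nesting:
    derived(child) is a subset of derived(parent) for every edge.
    """
    rng = np.random.default_rng(seed)
    assignment = dict(branch_of_node or {})
    order = [tree.root] + [
        n for n in sorted(tree.nodes, key=tree.depth) if n != tree.root
    ]
    assignment.setdefault(tree.root, genealogy.root)
    for name in order[1:]:
        if name in assignment:
            continue
        parent_branch = assignment[tree.nodes[name].parent]
        choices = genealogy.descendants_or_self(parent_branch)
        assignment[name] = choices[rng.integers(len(choices))]

    carriers = {name: set(genealogy.leaves_under(b)) for name, b in assignment.items()}
    markers = [m for name in order for m in tree.nodes[name].markers]
    data = {}
    for name in order:
        for m in tree.nodes[name].markers:
            data[m] = [
                DERIVED if leaf in carriers[name] else ANCESTRAL
                for leaf in genealogy.leaves
            ]
    states = pd.DataFrame(data, index=genealogy.leaves, columns=markers)
    if missing_rate > 0:
        mask = rng.random(states.shape) < missing_rate
        states = states.mask(pd.DataFrame(mask, index=states.index, columns=states.columns), MISSING)

    expected = {}
    for leaf in genealogy.leaves:
        holding = [n for n in order if leaf in carriers[n]]
        expected[leaf] = max(holding, key=tree.depth) if holding else f"not {tree.root}"
    table = SNPGenotypeTable(
        states,
        populations=pd.Series(genealogy.population_of).reindex(genealogy.leaves),
        groups=pd.Series(genealogy.group_of).reindex(genealogy.leaves),
    )
    return PlacementResult(table=table, branch_of_node=assignment, expected_terminal=expected)


@dataclass
class DiscoveryFixture:
    """Planted input set for the candidate-SNP filter, with its oracle manifest."""

    variants: list[VariantRecord]
    known_catalog: set[tuple[str, int]]
    repeat_mask: dict[str, list[tuple[int, int]]]
    manifest: dict


def simulate_discovery_input(
    n_variants: int,
    fraction_known: float = 0.0,
    fraction_in_repeat: float = 0.0,
    fraction_near_other: float = 0.0,
    fraction_transition: float = 0.0,
    seed: int = 0,
    chrom: str = "chrY",
    window_nt: int = 3000,
) -> DiscoveryFixture:
    """Emit a variant list with planted pass/fail outcomes.

    Fractions allocate variants to failure classes (known catalog hit, repeat
    overlap, proximity pair, transition); the remainder are clean transversions
    expected to survive. Proximity plants come in pairs (a transversion with a
    close transversion or indel partner), so fraction_near_other is rounded
    down to an even count. Distinct plants are spaced farther apart than the
    field of view so classes cannot interfere; the construction is validated
    before returning.
    """
    for name, f in {
        "fraction_known": fraction_known,
        "fraction_in_repeat": fraction_in_repeat,
        "fraction_near_other": fraction_near_other,
        "fraction_transition": fraction_transition,
    }.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_known = int(round(fraction_known * n_variants))
    n_repeat = int(round(fraction_in_repeat * n_variants))
    n_near = int(round(fraction_near_other * n_variants))
    n_near -= n_near % 2
    n_trans = int(round(fraction_transition * n_variants))
    n_clean = n_variants - n_known - n_repeat - n_near - n_trans
    if n_clean < 0:
        raise ValueError("fractions allocate more variants than n_variants")

    classes = (
        ["known"] * n_known
        + ["repeat"] * n_repeat
        + ["near"] * (n_near // 2)  # each near slot expands to a pair
        + ["transition"] * n_trans
        + ["clean"] * n_clean
    )
    rng.shuffle(classes)

    transversions = [("C", "A"), ("A", "C"), ("G", "T"), ("T", "G"), ("C", "G"), ("A", "T")]
    transitions = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
    spacing = window_nt + 1000
    variants: list[VariantRecord] = []
    known: set[tuple[str, int]] = set()
    mask: list[tuple[int, int]] = []
    classified: dict[int, str] = {}
    survivors: list[int] = []
    pos = 100_000
    near_toggle = 0
    for cls in classes:
        pos += spacing + int(rng.integers(0, spacing // 4))
        ref, alt = transversions[int(rng.integers(len(transversions)))]
        if cls == "known":
            variants.append(VariantRecord(chrom, pos, ref, alt))
            known.add((chrom, pos))
            classified[pos] = "known"
        elif cls == "repeat":
            variants.append(VariantRecord(chrom, pos, ref, alt))
            mask.append((pos - 5, pos + 5))  # 0-based half-open, covers pos
            classified[pos] = "repeat"
        elif cls == "transition":
            tref, talt = transitions[int(rng.integers(len(transitions)))]
            variants.append(VariantRecord(chrom, pos, tref, talt))
            classified[pos] = "transition"
        elif cls == "near":
            offset = int(rng.integers(100, window_nt // 2))
            variants.append(VariantRecord(chrom, pos, ref, alt))
            if near_toggle % 2 == 0:
                partner = VariantRecord(chrom, pos + offset, "C", "CA")
                classified[pos + offset] = "near_indel"
            else:
                pref, palt = transversions[int(rng.integers(len(transversions)))]
                partner = VariantRecord(chrom, pos + offset, pref, palt)
                classified[pos + offset] = "near_partner"
            variants.append(partner)
            classified[pos] = "near"
            near_toggle += 1
            pos += offset
        else:
            variants.append(VariantRecord(chrom, pos, ref, alt))
            classified[pos] = "clean"
            survivors.append(pos)

    # construction sanity: clean plants must sit alone in their field of view
    all_pos = sorted(v.pos for v in variants)
    for p in survivors:
        i = all_pos.index(p)
        for q in all_pos[max(0, i - 1): i + 2]:
            if q != p and abs(q - p) <= window_nt // 2:
                raise RuntimeError("planted survivor violates spacing; regenerate with another seed")

    rng.shuffle(variants)
    manifest = {
        "n_variants": len(variants),
        "window_nt": window_nt,
        "survivors": sorted(survivors),
        "classes": {str(p): c for p, c in sorted(classified.items())},
    }
    return DiscoveryFixture(
        variants=variants,
        known_catalog=known,
        repeat_mask={chrom: mask},
        manifest=manifest,
    )
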