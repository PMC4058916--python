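"""Pedigree simulation with recombination, labeled cousin pairs and errors.

The generator emulates a population descended from 1000-Genomes-like
founders: founder haplotypes come from a neutral coalescent (msprime) so
that both the site-frequency spectrum (a large majority of rare variants)
and linkage disequilibrium (limited common-haplotype diversity per 30 kb
window) are realistic; a parametric i.i.d.-per-site model is available as
a light-weight alternative.  Founders then mate over ``generations``
non-polygamous generations; each transmitted haplotype is a recombinant
mosaic of the parent's two haplotypes with breakpoints drawn as a Poisson
process (default rate 1e-7 per bp per meiosis).  There is no de-novo
mutation.

Two mating schemes are provided:

``random``
    Random pairing of not-yet-mated individuals that share no ancestor
    within ``mating_unrelated_depth`` generations.  Fully outbred pairing
    ("no shared ancestor at all") caps a pedigree at log2(n_founders)
    generations, because strictly-outbred ancestor sets double every
    generation — no small founder pool can support 10 such generations.

``fission`` (default)
    An island-fission design built to make *exact*-degree cousin pairs
    exist and be abundant: the founders split into two islands that never
    exchange migrants (cross-island pairs are unrelated at every
    generation), and each island's population recursively splits into
    closed subpopulations at scheduled generations, with sibships divided
    across the two halves of every split.  Two individuals from
    subpopulations that separated g+1 generations ago share ancestral
    couples exactly g+1 generations up and nothing closer — they are
    degree-g cousins by the most-recent-shared-couple definition — while
    sharing the whole pre-split ancestor pool, which is what makes distant
    cousins detectable at all in a population descended from a small
    founder pool.

Sequencing errors flip the call at a polymorphic site (variant <->
reference) independently per site per haplotype; phasing errors follow the
standard switch-error model: at each heterozygous site the phase
orientation toggles with the switch probability and persists until the
next switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome_encoding import (
    EncodingParams,
    GenomicSet,
    PhasedIndividual,
    ReferenceGenome,
    build_genomic_set,
)
from .relatedness import similarity_from_values

__all__ = [
    "SimConfig",
    "SiteCatalog",
    "SimIndividual",
    "Pedigree",
    "CousinLabel",
    "CalibrationError",
    "generate_founders",
    "mate",
    "grow_pedigree",
    "label_pairs",
    "label_pair",
    "inject_errors",
    "calibrate_errors",
    "select_labeled_pairs",
    "encode_individuals",
    "segment_key_table",
    "pair_score_from_keys",
]


# ---------------------------------------------------------------------------
# Configuration and data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation.

    Defaults are the scaled study design: a 60 Mb single-chromosome genome
    (2 000 segments of 30 kb), 60 founders, 10 generations, recombination
    1e-7 per bp per meiosis.  Founder haplotypes default to a coalescent
    with human-like diversity (Ne = 10 000, mu = 1.25e-8, within-founder
    recombination 1e-8/bp).  Error defaults: 0.2% per-site sequencing error
    and 0.5% per-het-site phasing switch error.
    """

    genome_length: int = 60_000_000
    n_founders: int = 60
    generations: int = 10
    recombination_rate: float = 1e-7
    # founder model
    founder_model: str = "coalescent"  # or "iid_sites"
    effective_population_size: float = 10_000.0
    mutation_rate: float = 1.25e-8
    founder_recombination_rate: float = 1e-8
    # iid_sites model: site densities per bp and frequency ranges
    iid_common_density: float = 20 / 30_000
    iid_rare_density: float = 140 / 30_000
    iid_common_freq: Tuple[float, float] = (0.05, 0.5)
    iid_rare_freq: Tuple[float, float] = (0.002, 0.05)
    # errors
    seq_error_rate: float = 0.002
    switch_error_rate: float = 0.005
    # mating
    mating_scheme: str = "fission"
    mating_unrelated_depth: int = 2
    offspring_per_couple: int = 2
    max_offspring_per_couple: int = 4
    pop_size_target: int = 12
    n_islands: int = 2
    split_generations: Optional[Tuple[int, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.recombination_rate, self.seq_error_rate, self.switch_error_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative (0 = founders only)")
        if self.genome_length <= 0 or self.n_founders < 0:
            raise ValueError("genome length and founder count must be non-negative")

    def effective_split_generations(self) -> Tuple[int, ...]:
        if self.split_generations is not None:
            return self.split_generations
        # one split per cousin degree 1..6, as late as the pedigree allows
        first = max(2, self.generations - 6)
        return tuple(range(first, self.generations))

    def reference(self) -> ReferenceGenome:
        return ReferenceGenome("sim", (("1", self.genome_length),))


@dataclass(frozen=True)
class SiteCatalog:
    """All polymorphic sites of the simulation: positions and population
    allele frequencies (of the variant allele among founder haplotypes)."""

    positions: np.ndarray  # sorted int64 bp positions
    frequencies: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class SimIndividual:
    """One simulated diploid: haplotypes as sorted site-index arrays."""

    individual_id: str
    generation: int
    parents: Optional[Tuple[str, str]]  # None for founders
    hap1: np.ndarray
    hap2: np.ndarray
    pop: str = ""

    def to_phased(self, catalog: SiteCatalog) -> PhasedIndividual:
        return PhasedIndividual(
            self.individual_id,
            {
                "1": (
                    catalog.positions[self.hap1],
                    catalog.positions[self.hap2],
                )
            },
        )


@dataclass
class Pedigree:
    """A simulated pedigree: individuals, matings and the site catalog."""

    config: SimConfig
    catalog: SiteCatalog
    individuals: Dict[str, SimIndividual]
    matings: List[Tuple[str, str]]  # (parent_a, parent_b); order irrelevant
    _ancestor_cache: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def generation_members(self, gen: int) -> List[SimIndividual]:
        return [i for i in self.individuals.values() if i.generation == gen]

    @property
    def founders(self) -> List[SimIndividual]:
        return self.generation_members(0)

    def validate(self) -> None:
        mated: Dict[str, int] = {}
        for a, b in self.matings:
            mated[a] = mated.get(a, 0) + 1
            mated[b] = mated.get(b, 0) + 1
        if any(c > 1 for c in mated.values()):
            raise AssertionError("polygamy detected: an individual mated twice")
        for ind in self.individuals.values():
            if ind.parents is not None:
                pa, pb = ind.parents
                if pa == pb:
                    raise AssertionError("self-mating detected")
                for p in ind.parents:
                    if self.individuals[p].generation != ind.generation - 1:
                        raise AssertionError("parent not in previous generation")

    def ancestors(self, individual_id: str) -> Dict[str, int]:
        """Ancestor id -> minimal depth (0 = self, 1 = parent, ...)."""
        cached = self._ancestor_cache.get(individual_id)
        if cached is not None:
            return cached
        ind = self.individuals[individual_id]
        out: Dict[str, int] = {individual_id: 0}
        if ind.parents is not None:
            for p in ind.parents:
                for anc, d in self.ancestors(p).items():
                    nd = d + 1
                    if anc not in out or out[anc] > nd:
                        out[anc] = nd
        self._ancestor_cache[individual_id] = out
        return out


@dataclass(frozen=True)
class CousinLabel:
    """Pedigree relationship of an unordered pair.

    ``relationship`` is one of: self, parent-child, sibling,
    cousin-degree-<g>, other (unequal-depth relatives), unrelated.
    Degree-g cousins share a most recent ancestral couple exactly g+1
    generations above both individuals.
    """

    id_a: str
    id_b: str
    relationship: str

    @property
    def degree(self) -> Optional[int]:
        if self.relationship.startswith("cousin-degree-"):
            return int(self.relationship.rsplit("-", 1)[1])
        return None


class CalibrationError(RuntimeError):
    def __init__(self, msg: str, achieved: Tuple[float, float], rates: Tuple[float, float]):
        super().__init__(msg)
        self.achieved = achieved
        self.rates = rates


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def generate_founders(config: SimConfig) -> Tuple[SiteCatalog, List[SimIndividual]]:
    """Founder individuals plus the site catalog, deterministic under seed."""
    if config.n_founders == 0:
        empty = SiteCatalog(np.empty(0, dtype=np.int64), np.empty(0))
        return empty, []
    if config.founder_model == "coalescent":
        return _coalescent_founders(config)
    if config.founder_model == "iid_sites":
        return _iid_founders(config)
    raise ValueError(f"unknown founder model {config.founder_model!r}")


def _coalescent_founders(config: SimConfig) -> Tuple[SiteCatalog, List[SimIndividual]]:
    import msprime

    seed = (config.seed % (2**31 - 2)) + 1
    ts = msprime.sim_ancestry(
        samples=config.n_founders,
        population_size=config.effective_population_size,
        sequence_length=config.genome_length,
        recombination_rate=config.founder_recombination_rate,
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
    )
    positions = ts.sites_position.astype(np.int64)
    # collapse duplicate integer positions (multiple mutations in one bp)
    G = ts.genotype_matrix() > 0  # sites x haplotypes
    positions, keep = np.unique(positions, return_index=True)
    G = G[keep]
    freqs = G.mean(axis=1)
    catalog = SiteCatalog(positions, freqs)
    founders = []
    for i in range(config.n_founders):
        founders.append(
            SimIndividual(
                individual_id=f"F{i}",
                generation=0,
                parents=None,
                hap1=np.nonzero(G[:, 2 * i])[0].astype(np.int32),
                hap2=np.nonzero(G[:, 2 * i + 1])[0].astype(np.int32),
            )
        )
    return catalog, founders


def _iid_founders(config: SimConfig) -> Tuple[SiteCatalog, List[SimIndividual]]:
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    n_common = rng.poisson(config.iid_common_density * L)
    n_rare = rng.poisson(config.iid_rare_density * L)
    n_sites = n_common + n_rare
    positions = np.sort(rng.choice(L, size=min(n_sites, L), replace=False))
    lo_c, hi_c = config.iid_common_freq
    lo_r, hi_r = config.iid_rare_freq
    freqs = np.empty(len(positions))
    is_common = np.zeros(len(positions), dtype=bool)
    is_common[rng.choice(len(positions), size=min(n_common, len(positions)), replace=False)] = True
    freqs[is_common] = rng.uniform(lo_c, hi_c, is_common.sum())
    # rare frequencies log-uniform: neutral-spectrum-like excess of very rare sites
    nr = (~is_common).sum()
    freqs[~is_common] = np.exp(rng.uniform(np.log(lo_r), np.log(hi_r), nr))
    catalog = SiteCatalog(positions.astype(np.int64), freqs)
    founders = []
    for i in range(config.n_founders):
        h1 = np.nonzero(rng.random(len(positions)) < freqs)[0].astype(np.int32)
        h2 = np.nonzero(rng.random(len(positions)) < freqs)[0].astype(np.int32)
        founders.append(SimIndividual(f"F{i}", 0, None, h1, h2))
    return catalog, founders


# ---------------------------------------------------------------------------
# Meiosis and mating
# ---------------------------------------------------------------------------


def _meiosis(
    parent: SimIndividual, catalog: SiteCatalog, rate: float, L: int, rng: np.random.Generator
) -> np.ndarray:
    """One transmitted haplotype: a breakpoint mosaic of the parent's two."""
    n_breaks = rng.poisson(rate * L)
    start_hap = int(rng.integers(2))
    if n_breaks == 0:
        return (parent.hap1 if start_hap == 0 else parent.hap2).copy()
    breaks = np.sort(rng.uniform(0, L, n_breaks))
    bounds = np.concatenate([[0.0], breaks, [float(L)]])
    haps = (parent.hap1, parent.hap2)
    pieces = []
    pos = catalog.positions
    for seg in range(len(bounds) - 1):
        hap = haps[(start_hap + seg) % 2]
        lo = np.searchsorted(pos[hap], bounds[seg], side="left")
        hi = np.searchsorted(pos[hap], bounds[seg + 1], side="left")
        pieces.append(hap[lo:hi])
    return np.concatenate(pieces)


def mate(
    parent_a: SimIndividual,
    parent_b: SimIndividual,
    catalog: SiteCatalog,
    config: SimConfig,
    rng: np.random.Generator,
    child_id: str,
    pop: str = "",
) -> SimIndividual:
    """One child: an independent recombinant meiosis from each parent."""
    if parent_a.individual_id == parent_b.individual_id:
        raise ValueError("an individual cannot mate with itself")
    L = config.genome_length
    h1 = _meiosis(parent_a, catalog, config.recombination_rate, L, rng)
    h2 = _meiosis(parent_b, catalog, config.recombination_rate, L, rng)
    return SimIndividual(
        individual_id=child_id,
        generation=max(parent_a.generation, parent_b.generation) + 1,
        parents=(parent_a.individual_id, parent_b.individual_id),
        hap1=h1,
        hap2=h2,
        pop=pop,
    )


def _shallow_ancestors(ped: Pedigree, ind_id: str, depth: int) -> frozenset:
    """Ancestor ids within `depth` generations (excluding self)."""
    out = set()
    frontier = [ind_id]
    for _ in range(depth):
        nxt = []
        for x in frontier:
            parents = ped.individuals[x].parents
            if parents:
                nxt.extend(parents)
        out.update(nxt)
        frontier = nxt
    return frozenset(out)


def _eligible(ped: Pedigree, a: str, b: str, depth: int) -> bool:
    if depth <= 0:
        return True
    return not (_shallow_ancestors(ped, a, depth) & _shallow_ancestors(ped, b, depth))


def _pair_members(
    ped: Pedigree, members: List[str], depth: int, rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """Random greedy pairing of mutually eligible members, relaxing the
    eligibility depth only if no pairing is possible at the requested one."""
    for d in range(depth, -1, -1):
        order = list(members)
        rng.shuffle(order)
        used = set()
        pairs = []
        for a in order:
            if a in used:
                continue
            for b in order:
                if b == a or b in used:
                    continue
                if _eligible(ped, a, b, d):
                    pairs.append((a, b))
                    used.update((a, b))
                    break
        if pairs:
            return pairs
    return []


def _breed_pop(
    ped: Pedigree,
    members: List[str],
    n_children: int,
    gen: int,
    pop: str,
    config: SimConfig,
    rng: np.random.Generator,
    id_prefix: str,
) -> List[str]:
    """Mate one closed subpopulation and produce ~n_children offspring."""
    pairs = _pair_members(ped, members, config.mating_unrelated_depth, rng)
    if not pairs:
        raise RuntimeError(
            f"no valid unrelated pairing available in {pop or 'population'} "
            f"at generation {gen} ({len(members)} members)"
        )
    ped.matings.extend(pairs)
    children: List[str] = []
    per_couple = [0] * len(pairs)
    i = 0
    while len(children) < n_children:
        if per_couple[i % len(pairs)] < config.max_offspring_per_couple:
            idx = i % len(pairs)
            a, b = pairs[idx]
            cid = f"{id_prefix}I{len(children)}"
            child = mate(
                ped.individuals[a], ped.individuals[b], ped.catalog, config, rng, cid, pop
            )
            ped.individuals[cid] = child
            children.append(cid)
            per_couple[idx] += 1
        i += 1
        if i > n_children * len(pairs) + len(pairs):
            break  # all couples at their cap
    return children


def grow_pedigree(config: SimConfig) -> Pedigree:
    """Simulate the full pedigree under the configured mating scheme."""
    if config.n_founders < 4:
        raise ValueError("need at least 4 founders to form two initial couples")
    catalog, founders = generate_founders(config)
    ped = Pedigree(config=config, catalog=catalog, individuals={}, matings=[])
    for f in founders:
        ped.individuals[f.individual_id] = f
    if config.generations == 0:
        return ped
    if config.mating_scheme == "random":
        _grow_random(ped, config)
    elif config.mating_scheme == "fission":
        _grow_fission(ped, config)
    else:
        raise ValueError(f"unknown mating scheme {config.mating_scheme!r}")
    return ped


def _grow_random(ped: Pedigree, config: SimConfig) -> None:
    rng = np.random.default_rng((config.seed, 1))
    current = [f.individual_id for f in ped.founders]
    for gen in range(1, config.generations + 1):
        n_children = (len(current) // 2) * config.offspring_per_couple
        current = _breed_pop(
            ped, current, n_children, gen, "", config, rng, f"G{gen}"
        )


def _grow_fission(ped: Pedigree, config: SimConfig) -> None:
    rng = np.random.default_rng((config.seed, 2))
    splits = set(config.effective_split_generations())
    founders = [f.individual_id for f in ped.founders]
    half = len(founders) // 2
    pops: Dict[str, List[str]] = {"A": founders[:half], "B": founders[half:]}
    for f in ped.founders:
        f.pop = "A" if f.individual_id in set(pops["A"]) else "B"
    for gen in range(1, config.generations + 1):
        n_pops_after = {
            isl: 2 ** len([s for s in splits if s <= gen])
            for isl in ("A", "B")
        }
        new_pops: Dict[str, List[str]] = {}
        for pop_name, members in pops.items():
            island = pop_name[0]
            # target size chosen so every post-split subpopulation keeps
            # pop_size_target members; capped by fecundity
            target_total = config.pop_size_target * n_pops_after[island]
            n_pops_now = len([p for p in pops if p[0] == island])
            # keep a population at least as large as its parent until the
            # split schedule demands growth; never more than doubling
            target = min(
                max(target_total // n_pops_now, len(members)),
                2 * len(members),
            )
            cap = (len(members) // 2) * config.max_offspring_per_couple
            n_children = min(target, cap)
            children = _breed_pop(
                ped, members, n_children, gen, pop_name, config, rng,
                f"G{gen}{pop_name}",
            )
            if gen in splits:
                left, right = _split_sibships(ped, children, rng)
                new_pops[pop_name + "0"] = left
                new_pops[pop_name + "1"] = right
                for cid in left:
                    ped.individuals[cid].pop = pop_name + "0"
                for cid in right:
                    ped.individuals[cid].pop = pop_name + "1"
            else:
                new_pops[pop_name] = children
        pops = new_pops


def _split_sibships(
    ped: Pedigree, children: List[str], rng: np.random.Generator
) -> Tuple[List[str], List[str]]:
    """Partition a generation into two subpopulations, dividing every
    sibship across both halves so the parental couples become ancestral
    couples shared at exactly the split depth."""
    by_parents: Dict[Tuple[str, str], List[str]] = {}
    for cid in children:
        by_parents.setdefault(ped.individuals[cid].parents, []).append(cid)
    left: List[str] = []
    right: List[str] = []
    for sibs in by_parents.values():
        sibs = list(sibs)
        rng.shuffle(sibs)
        mid = len(sibs) // 2
        # alternate the larger half so sizes stay balanced
        if len(left) <= len(right):
            left.extend(sibs[: len(sibs) - mid])
            right.extend(sibs[len(sibs) - mid :])
        else:
            right.extend(sibs[: len(sibs) - mid])
            left.extend(sibs[len(sibs) - mid :])
    return left, right


# ---------------------------------------------------------------------------
# Relationship labels
# ---------------------------------------------------------------------------


def label_pair(ped: Pedigree, id_a: str, id_b: str) -> CousinLabel:
    if id_a == id_b:
        return CousinLabel(id_a, id_b, "self")
    anc_a = ped.ancestors(id_a)
    anc_b = ped.ancestors(id_b)
    if anc_a.get(id_b) == 1 or anc_b.get(id_a) == 1:
        return CousinLabel(id_a, id_b, "parent-child")
    shared = [(anc_a[x], anc_b[x]) for x in anc_a.keys() & anc_b.keys()]
    if not shared:
        return CousinLabel(id_a, id_b, "unrelated")
    equal = [da for da, db in shared if da == db]
    best_eq = min(equal) if equal else None
    best_any = min(min(da, db) for da, db in shared)
    if best_eq is None or best_any < best_eq:
        return CousinLabel(id_a, id_b, "other")
    if best_eq == 1:
        return CousinLabel(id_a, id_b, "sibling")
    return CousinLabel(id_a, id_b, f"cousin-degree-{best_eq - 1}")


def label_pairs(
    ped: Pedigree, ids: Optional[Sequence[str]] = None
) -> List[CousinLabel]:
    """Labels for every unordered pair among ``ids`` (default: everyone)."""
    ids = list(ids) if ids is not None else sorted(ped.individuals)
    out = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            out.append(label_pair(ped, a, b))
    return out


def select_labeled_pairs(
    ped: Pedigree,
    per_degree: int,
    n_unrelated: int,
    rng: np.random.Generator,
    degrees: Sequence[int] = (1, 2, 3, 4, 5, 6),
    n_sibling: int | None = None,
) -> Dict[str, List[Tuple[str, str]]]:
    """Sample labeled evaluation pairs by quota from the pedigree.

    Same-generation pairs are drawn in random order and labeled from the
    ancestry graph until every quota is met.  Unrelated pairs come from
    individuals with no shared ancestor (cross-island pairs in the fission
    design, founder pairs otherwise).
    """
    n_sibling = per_degree if n_sibling is None else n_sibling
    want = {f"cousin-degree-{g}": per_degree for g in degrees}
    want["sibling"] = n_sibling
    want["unrelated"] = n_unrelated
    got: Dict[str, List[Tuple[str, str]]] = {k: [] for k in want}
    by_gen: Dict[int, List[str]] = {}
    for ind in ped.individuals.values():
        by_gen.setdefault(ind.generation, []).append(ind.individual_id)
    for gen in sorted(by_gen, reverse=True):
        ids = sorted(by_gen[gen])
        if len(ids) < 2:
            continue
        n = len(ids)
        n_pairs = n * (n - 1) // 2
        order = rng.permutation(n_pairs)
        for flat in order:
            if all(len(got[k]) >= want[k] for k in want):
                return got
            i = int(n - 2 - math.floor(math.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5))
            j = int(flat + i + 1 - n * (n - 1) // 2 + (n - i) * (n - i - 1) // 2)
            a, b = ids[i], ids[j]
            lab = label_pair(ped, a, b).relationship
            if lab in got and len(got[lab]) < want[lab]:
                got[lab].append((a, b))
    return got


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------


def inject_errors(
    ind: SimIndividual,
    catalog: SiteCatalog,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimIndividual:
    """Apply sequencing (per-site flips) and phasing (switch) errors.

    Sequencing: each polymorphic site's call flips variant<->reference
    independently at ``seq_error_rate``, per haplotype.  Phasing: walking
    heterozygous sites in position order, the phase orientation toggles
    with ``switch_error_rate`` at each het site and persists until the
    next switch.
    """
    n = catalog.n_sites
    haps = []
    for hap in (ind.hap1, ind.hap2):
        if config.seq_error_rate > 0:
            n_flips = rng.binomial(n, config.seq_error_rate)
            flip = rng.choice(n, size=n_flips, replace=False)
            carrier = np.zeros(n, dtype=bool)
            carrier[hap] = True
            carrier[flip] = ~carrier[flip]
            haps.append(np.nonzero(carrier)[0].astype(np.int32))
        else:
            haps.append(hap.copy())
    h1, h2 = haps
    if config.switch_error_rate > 0:
        het = np.setdiff1d(np.union1d(h1, h2), np.intersect1d(h1, h2))
        if len(het):
            switches = rng.random(len(het)) < config.switch_error_rate
            flipped_state = np.cumsum(switches) % 2 == 1
            to_swap = het[flipped_state]
            in1 = np.isin(to_swap, h1)
            move_to_2 = to_swap[in1]
            move_to_1 = to_swap[~in1]
            h1 = np.union1d(np.setdiff1d(h1, move_to_2), move_to_1)
            h2 = np.union1d(np.setdiff1d(h2, move_to_1), move_to_2)
    return SimIndividual(
        individual_id=ind.individual_id,
        generation=ind.generation,
        parents=ind.parents,
        hap1=np.sort(h1).astype(np.int32),
        hap2=np.sort(h2).astype(np.int32),
        pop=ind.pop,
    )


# ---------------------------------------------------------------------------
# Encoding shortcut and error-rate calibration
# ---------------------------------------------------------------------------


def encode_individuals(
    inds: Iterable[SimIndividual],
    catalog: SiteCatalog,
    config: SimConfig,
    params: EncodingParams | None = None,
    *,
    with_errors: bool = False,
    error_rng: np.random.Generator | None = None,
) -> Dict[str, GenomicSet]:
    """Genomic sets for a collection of simulated individuals."""
    ref = config.reference()
    if params is None:
        params = EncodingParams(genome_length=config.genome_length)
    out: Dict[str, GenomicSet] = {}
    for ind in inds:
        use = ind
        if with_errors:
            if error_rng is None:
                raise ValueError("error injection requires an RNG")
            use = inject_errors(ind, catalog, config, error_rng)
        out[ind.individual_id] = build_genomic_set(use.to_phased(catalog), ref, params)
    return out


def segment_key_table(
    inds: Iterable[SimIndividual],
    catalog: SiteCatalog,
    config: SimConfig,
    segment_length: int = 30_000,
    *,
    with_errors: bool = False,
    error_rng: np.random.Generator | None = None,
) -> Dict[str, np.ndarray]:
    """Compact per-segment haplotype identity keys for fast pair scoring.

    Within a fixed segment index, two haplotypes produce equal set elements
    exactly when their variant-position patterns over the segment are equal
    (the element is the segment's bit pattern plus the shared segment start),
    so interning the (segment, positions) pattern into integer ids preserves
    all element equalities while avoiding 30 000-bit integer construction.
    Returns id -> (n_segments, 2) array of interned keys.
    """
    nseg = -(-config.genome_length // segment_length)
    interned: Dict[Tuple[int, bytes], int] = {}
    out: Dict[str, np.ndarray] = {}
    grid = np.arange(nseg + 1, dtype=np.int64) * segment_length
    for ind in inds:
        use = ind
        if with_errors:
            if error_rng is None:
                raise ValueError("error injection requires an RNG")
            use = inject_errors(ind, catalog, config, error_rng)
        keys = np.empty((nseg, 2), dtype=np.int64)
        for h, hap in enumerate((use.hap1, use.hap2)):
            pos = catalog.positions[hap]
            bounds = np.searchsorted(pos, grid)
            for j in range(nseg):
                pat = (j, pos[bounds[j] : bounds[j + 1]].tobytes())
                keys[j, h] = interned.setdefault(pat, len(interned))
        out[ind.individual_id] = keys
    return out


def pair_score_from_keys(keys_a: np.ndarray, keys_b: np.ndarray) -> int:
    """Total matched-segment score from two interned key arrays."""
    direct = (keys_a[:, 0] == keys_b[:, 0]).astype(np.int64) + (
        keys_a[:, 1] == keys_b[:, 1]
    )
    crossed = (keys_a[:, 0] == keys_b[:, 1]).astype(np.int64) + (
        keys_a[:, 1] == keys_b[:, 0]
    )
    return int(np.minimum(2, np.maximum(direct, crossed)).sum())


def _sharing_stats(
    config: SimConfig, seq_rate: float, switch_rate: float, n_pairs: int = 8
) -> Tuple[float, float]:
    """Mean matched-segment counts (sibling pairs, unrelated founder pairs)
    for a small simulation at the given error rates."""
    cfg = replace(
        config,
        mating_scheme="random",
        generations=1,
        seq_error_rate=seq_rate,
        switch_error_rate=switch_rate,
    )
    ped = grow_pedigree(cfg)
    rng = np.random.default_rng((cfg.seed, 99))
    gen1 = ped.generation_members(1)
    sib_pairs = []
    by_parents: Dict[Tuple[str, str], List[str]] = {}
    for ind in gen1:
        by_parents.setdefault(ind.parents, []).append(ind.individual_id)
    for sibs in by_parents.values():
        for i in range(len(sibs) - 1):
            sib_pairs.append((sibs[i], sibs[i + 1]))
    sib_pairs = sib_pairs[:n_pairs]
    founders = [f.individual_id for f in ped.founders]
    unrel_pairs = [(founders[2 * i], founders[2 * i + 1]) for i in range(min(n_pairs, len(founders) // 2))]
    need = {x for p in sib_pairs + unrel_pairs for x in p}
    sets = encode_individuals(
        [ped.individuals[x] for x in sorted(need)],
        ped.catalog,
        cfg,
        with_errors=True,
        error_rng=rng,
    )
    def mean_score(pairs):
        vals = []
        for a, b in pairs:
            sa, sb = sets[a], sets[b]
            per = similarity_from_values(
                [sa.segment_elements(j) for j in range(sa.n_segments)],
                [sb.segment_elements(j) for j in range(sb.n_segments)],
            )
            vals.append(sum(per))
        return float(np.mean(vals)) if vals else 0.0
    return mean_score(sib_pairs), mean_score(unrel_pairs)


def calibrate_errors(
    target_sibling_sharing: float,
    target_unrelated_sharing: float,
    config: SimConfig,
    *,
    max_rates: Tuple[float, float] = (0.01, 0.02),
    tolerance: float = 0.05,
    max_iter: int = 12,
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Fit error rates so simulated sharing matches target statistics.

    Bisects a single scale factor applied to ``max_rates`` (sequencing,
    switch): more error monotonically lowers matched-segment sharing.
    Returns ((seq_rate, switch_rate), (sibling_mean, unrelated_mean)).
    Raises CalibrationError with the closest achieved values when the
    targets are unreachable within the rate bounds and tolerance.
    """
    def stats(scale: float) -> Tuple[float, float]:
        return _sharing_stats(config, scale * max_rates[0], scale * max_rates[1])

    tol_units = max(1.0, tolerance * max(target_sibling_sharing, 1.0))
    lo, hi = 0.0, 1.0
    s_lo = stats(lo)
    if abs(s_lo[0] - target_sibling_sharing) <= tol_units:
        if abs(s_lo[1] - target_unrelated_sharing) <= tol_units:
            return (0.0, 0.0), s_lo
    s_hi = stats(hi)
    if not (s_hi[0] - tol_units <= target_sibling_sharing <= s_lo[0] + tol_units):
        closest = s_lo if abs(s_lo[0] - target_sibling_sharing) < abs(s_hi[0] - target_sibling_sharing) else s_hi
        rates = (0.0, 0.0) if closest is s_lo else max_rates
        raise CalibrationError(
            "sibling-sharing target outside the reachable range", closest, rates
        )
    best_scale, best = lo, s_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s_mid = stats(mid)
        if abs(s_mid[0] - target_sibling_sharing) < abs(best[0] - target_sibling_sharing):
            best_scale, best = mid, s_mid
        if s_mid[0] > target_sibling_sharing:
            lo = mid
        else:
            hi = mid
        if abs(s_mid[0] - target_sibling_sharing) <= tol_units:
            break
    if abs(best[0] - target_sibling_sharing) > tol_units or \
            abs(best[1] - target_unrelated_sharing) > tol_units:
        raise CalibrationError(
            "targets not reached within tolerance",
            best,
            (best_scale * max_rates[0], best_scale * max_rates[1]),
        )
    return (best_scale * max_rates[0], best_scale * max_rates[1]), best
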