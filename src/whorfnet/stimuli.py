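"""Synthetic grounding and word-form input patterns.

Each simulated concept is grounded in three binary activation patterns
("instances"), presented to the primary extrasylvian model areas (*V1 and
*M1_L).  Concrete concepts follow a *feature-overlap* structure: per area,
6 of the 12 active cells are shared by all three instances and 6 are unique
to each instance.  Abstract concepts follow a *family-resemblance*
structure: no cell is shared by all three instances; instead each unordered
pair of instances shares a 4-cell set and each instance has 4 unique cells.
Word-form (label) patterns are 12-cell patterns on the primary perisylvian
areas (*A1 and *M1_i), identical for the three instances of a concept.

Cells never recur across concepts: per area, each concept draws its own
disjoint pool of cells, so any between-concept similarity in the network's
responses must emerge from learning, not from the inputs.

Cell placement: each concept's 24-cell pool is drawn from one randomly
chosen 5 × 5 patch of the area's 25 × 25 grid (patches disjoint across
concepts).  Because excitatory connectivity is local (a Gaussian
neighbourhood kernel), co-activated cells must lie within one another's
projection range for Hebbian learning to bind them into an assembly; a
compact patch guarantees that, while spatially uniform cells would mostly
fall outside each other's kernels.  All overlap/correlation statistics are
unaffected by placement.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PatternSpec",
    "GroundingPattern",
    "GroundingSet",
    "WordformSet",
    "make_grounding_set",
    "make_wordform_set",
    "co_activation",
    "validate_pattern_set",
    "CheckResult",
    "ValidationReport",
    "GROUNDING_AREAS",
    "WORDFORM_AREAS",
]

#: Primary extrasylvian areas receiving conceptual grounding input.
GROUNDING_AREAS = ("*V1", "*M1_L")
#: Primary perisylvian areas receiving word-form (label) input.
WORDFORM_AREAS = ("*A1", "*M1_i")

_CELLS_PER_CONCEPT = 24  # distinct cells used by one concept per area
_INSTANCE_PAIRS = ((0, 1), (0, 2), (1, 2))
_GRID = 25    # areas are 25 × 25 grids
_MAX_CONCEPTS = 25  # smallest usable patch is 5 × 5 (≥ 24 cells)


def _patch_side(n_concepts: int) -> int:
    """Side of the square concept territories tiling the 25 × 25 grid.

    Territories are as large as the grid allows: fewer concepts get larger
    patches, so the local-kernel connectivity can recruit a proportionally
    larger halo of cells around each concept's active cells.
    """
    per_side = int(np.ceil(np.sqrt(n_concepts)))
    return _GRID // per_side


def _patch_pool(rng: np.random.Generator, n_concepts: int) -> list[np.ndarray]:
    """Per concept, a shuffled 24-cell pool inside its own grid patch."""
    side = _patch_side(n_concepts)
    per_side = _GRID // side
    patches = rng.choice(per_side * per_side, size=n_concepts, replace=False)
    pools = []
    for p in patches:
        pr, pc = divmod(int(p), per_side)
        cells = np.array(
            [
                (pr * side + i) * _GRID + (pc * side + j)
                for i in range(side)
                for j in range(side)
            ]
        )
        pools.append(rng.permutation(cells)[:_CELLS_PER_CONCEPT])
    return pools


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a grounding-pattern set.

    The structural counts (3 instances, 12 active cells per area,
    625 cells per area) are fixed by the experimental design; only the
    number of concepts, the semantic type and the seed vary.
    """

    n_concepts: int = 10
    instances_per_concept: int = 3
    active_per_area: int = 12
    area_size: int = 625
    semantic_type: str = "concrete"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.semantic_type not in ("concrete", "abstract"):
            raise ValueError(
                f"semantic_type must be 'concrete' or 'abstract', got "
                f"{self.semantic_type!r}"
            )
        if self.instances_per_concept != 3:
            raise ValueError(
                "the overlap structure is defined only for triplets of "
                f"instances (got instances_per_concept="
                f"{self.instances_per_concept})"
            )
        if self.active_per_area != 12:
            raise ValueError("active_per_area is fixed at 12")
        needed = _CELLS_PER_CONCEPT * self.n_concepts
        if needed > self.area_size or self.n_concepts > _MAX_CONCEPTS:
            raise ValueError(
                f"capacity violation in areas {GROUNDING_AREAS}: "
                f"{self.n_concepts} concepts need {needed} distinct cells "
                f"in {self.n_concepts} disjoint grid patches but each area "
                f"has only {self.area_size} cells / {_MAX_CONCEPTS} patches"
            )


@dataclass(frozen=True)
class GroundingPattern:
    """One instance of one concept: 12 active cells per stimulated area."""

    concept_id: int
    instance_id: int
    active_cells: dict[str, frozenset[int]]

    def cells(self, area: str) -> frozenset[int]:
        return self.active_cells[area]


@dataclass(frozen=True)
class GroundingSet:
    """All grounding patterns of one semantic type (n_concepts × 3)."""

    spec: PatternSpec
    patterns: tuple[GroundingPattern, ...]

    def get(self, concept_id: int, instance_id: int) -> GroundingPattern:
        return self.patterns[concept_id * self.spec.instances_per_concept + instance_id]

    def concept_instances(self, concept_id: int) -> tuple[GroundingPattern, ...]:
        k = self.spec.instances_per_concept
        return self.patterns[concept_id * k : (concept_id + 1) * k]

    # -- structural sub-groups used by the correlation analysis -----------

    def triple_shared(self, concept_id: int, area: str) -> frozenset[int]:
        """Cells active in all three instances of a concept (concrete: 6)."""
        i1, i2, i3 = (p.cells(area) for p in self.concept_instances(concept_id))
        return i1 & i2 & i3

    def pairwise_shared(self, concept_id: int, area: str) -> tuple[frozenset[int], ...]:
        """The three pair-shared sets (minus any triple-shared cells)."""
        inst = [p.cells(area) for p in self.concept_instances(concept_id)]
        triple = inst[0] & inst[1] & inst[2]
        return tuple((inst[i] & inst[j]) - triple for i, j in _INSTANCE_PAIRS)

    def pairwise_shared_union(self, concept_id: int, area: str) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for s in self.pairwise_shared(concept_id, area):
            out |= s
        return out

    def unique_cells(self, concept_id: int, instance_id: int, area: str) -> frozenset[int]:
        inst = [p.cells(area) for p in self.concept_instances(concept_id)]
        others: frozenset[int] = frozenset()
        for j, s in enumerate(inst):
            if j != instance_id:
                others |= s
        return inst[instance_id] - others

    def concept_cells(self, concept_id: int, area: str) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for p in self.concept_instances(concept_id):
            out |= p.cells(area)
        return out

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        """Documented JSON layout: concept → instance → area → sorted cells."""
        payload = {
            "semantic_type": self.spec.semantic_type,
            "n_concepts": self.spec.n_concepts,
            "area_size": self.spec.area_size,
            "seed": self.spec.seed,
            "concepts": [
                [
                    {a: sorted(p.cells(a)) for a in GROUNDING_AREAS}
                    for p in self.concept_instances(c)
                ]
                for c in range(self.spec.n_concepts)
            ],
        }
        return json.dumps(payload, indent=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (concept, instance, area, cell) for inspection."""
        rows = [
            (p.concept_id, p.instance_id, a, cell)
            for p in self.patterns
            for a in GROUNDING_AREAS
            for cell in sorted(p.cells(a))
        ]
        return pd.DataFrame(rows, columns=["concept", "instance", "area", "cell"])


@dataclass(frozen=True)
class WordformSet:
    """One 12-cell label pattern per concept on each perisylvian primary area.

    The same word form is used for all three instances of a concept, which
    is what makes the label perfectly correlated with the concept.
    """

    n_concepts: int
    area_size: int
    seed: int
    active_cells: tuple[dict[str, frozenset[int]], ...]  # indexed by concept

    def cells(self, concept_id: int, area: str) -> frozenset[int]:
        return self.active_cells[concept_id][area]

    def for_instance(self, concept_id: int, instance_id: int, area: str) -> frozenset[int]:
        # identical for every instance of the concept, by construction
        del instance_id
        return self.cells(concept_id, area)


def make_grounding_set(spec: PatternSpec) -> GroundingSet:
    """Generate a grounding set with the exact overlap structure of its type.

    Per area, a random permutation of the area's cell indices is cut into
    contiguous 24-cell pools, one per concept — cross-concept disjointness
    holds by construction.  The pool is then partitioned:

    * concrete: 6 triple-shared + 3 × 6 unique cells;
    * abstract: 3 × 4 pairwise-shared (one set per unordered instance
      pair) + 3 × 4 unique cells.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0]))
    k = spec.instances_per_concept
    per_area_instance_cells: dict[str, list[list[frozenset[int]]]] = {}
    for area in GROUNDING_AREAS:
        pools = _patch_pool(rng, spec.n_concepts)
        concepts: list[list[frozenset[int]]] = []
        for c in range(spec.n_concepts):
            pool = pools[c]
            if spec.semantic_type == "concrete":
                shared = frozenset(int(x) for x in pool[:6])
                inst = [
                    shared | frozenset(int(x) for x in pool[6 + 6 * i : 12 + 6 * i])
                    for i in range(k)
                ]
            else:
                pair_sets = [
                    frozenset(int(x) for x in pool[4 * j : 4 * j + 4]) for j in range(3)
                ]
                uniq = [
                    frozenset(int(x) for x in pool[12 + 4 * i : 16 + 4 * i])
                    for i in range(k)
                ]
                inst = []
                for i in range(k):
                    cells = uniq[i]
                    for j, (a, b) in enumerate(_INSTANCE_PAIRS):
                        if i in (a, b):
                            cells |= pair_sets[j]
                    inst.append(cells)
            concepts.append(inst)
        per_area_instance_cells[area] = concepts

    patterns = tuple(
        GroundingPattern(
            concept_id=c,
            instance_id=i,
            active_cells={a: per_area_instance_cells[a][c][i] for a in GROUNDING_AREAS},
        )
        for c in range(spec.n_concepts)
        for i in range(k)
    )
    return GroundingSet(spec=spec, patterns=patterns)


def make_wordform_set(n_concepts: int, seed: int, area_size: int = 625) -> WordformSet:
    """Generate disjoint 12-cell word-form patterns, one per concept."""
    needed = 12 * n_concepts
    if needed > area_size or n_concepts > _MAX_CONCEPTS:
        raise ValueError(
            f"capacity violation in areas {WORDFORM_AREAS}: {n_concepts} "
            f"word forms need {needed} distinct cells in {n_concepts} "
            f"disjoint grid patches but each area has only {area_size} "
            f"cells / {_MAX_CONCEPTS} patches"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF0]))
    per_area = {a: _patch_pool(rng, n_concepts) for a in WORDFORM_AREAS}
    concepts = tuple(
        {
            a: frozenset(int(x) for x in per_area[a][c][:12])
            for a in WORDFORM_AREAS
        }
        for c in range(n_concepts)
    )
    return WordformSet(
        n_concepts=n_concepts, area_size=area_size, seed=seed, active_cells=concepts
    )


# ---------------------------------------------------------------------------
# Co-activation probabilities (correlation structure of the inputs)
# ---------------------------------------------------------------------------

_SELECTORS = ("triple-shared", "pairwise-shared-union", "unique", "wordform")


def _select(
    grounding: GroundingSet,
    wordforms: WordformSet | None,
    selector: str,
    concept_id: int,
    area: str,
) -> list[int]:
    if selector == "triple-shared":
        return sorted(grounding.triple_shared(concept_id, area))
    if selector == "pairwise-shared-union":
        return sorted(grounding.pairwise_shared_union(concept_id, area))
    if selector == "unique":
        out: list[int] = []
        for i in range(grounding.spec.instances_per_concept):
            out.extend(grounding.unique_cells(concept_id, i, area))
        return sorted(out)
    if selector == "wordform":
        if wordforms is None:
            raise ValueError("selector 'wordform' requires a WordformSet")
        return sorted(wordforms.cells(concept_id, WORDFORM_AREAS[0]))
    raise ValueError(f"unknown selector {selector!r}; expected one of {_SELECTORS}")


def co_activation(
    grounding: GroundingSet,
    wordforms: WordformSet | None,
    group_a: str,
    group_b: str,
    concept_id: int = 0,
    area: str | None = None,
) -> float:
    """Mean pairwise co-occurrence probability between two cell groups.

    For every pair (a ∈ A, b ∈ B, a ≠ b) the fraction of the concept's
    three instance presentations in which both cells are active is taken;
    the mean over pairs is returned.  A word-form cell counts as active in
    all three presentations (the label is identical across instances).

    When both selectors are ``"pairwise-shared-union"`` only pairs drawn
    from two *different* pair-shared subsets enter the mean — the quantity
    of interest is the correlation between distinct shared features, and
    cells within the same subset are trivially co-active.
    """
    if area is None:
        area = GROUNDING_AREAS[0]
    cells_a = _select(grounding, wordforms, group_a, concept_id, area)
    cells_b = _select(grounding, wordforms, group_b, concept_id, area)
    if not cells_a or not cells_b:
        raise ValueError(
            f"empty group for selector pair ({group_a!r}, {group_b!r}) on "
            f"concept {concept_id}"
        )

    k = grounding.spec.instances_per_concept
    # membership[cell] = set of instance ids in which the cell is active
    membership: dict[int, set[int]] = {}
    for i, p in enumerate(grounding.concept_instances(concept_id)):
        for cell in p.cells(area):
            membership.setdefault(cell, set()).add(i)

    def active_in(cell: int, selector: str) -> set[int]:
        if selector == "wordform":
            return set(range(k))
        return membership[cell]

    restrict_cross_subset = group_a == group_b == "pairwise-shared-union"
    subsets = (
        grounding.pairwise_shared(concept_id, area) if restrict_cross_subset else None
    )

    def subset_of(cell: int) -> int:
        assert subsets is not None
        for j, s in enumerate(subsets):
            if cell in s:
                return j
        raise AssertionError("cell not in any pairwise-shared subset")

    total = 0.0
    n_pairs = 0
    for a, b in itertools.product(cells_a, cells_b):
        if group_a == group_b and a >= b:  # unordered, skip a == b
            continue
        if group_a != group_b and a == b:
            continue
        if restrict_cross_subset and subset_of(a) == subset_of(b):
            continue
        both = active_in(a, group_a) & active_in(b, group_b)
        total += len(both) / k
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no admissible cell pairs for the requested groups")
    return total / n_pairs


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append(CheckResult(name, passed, detail))

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]


def validate_pattern_set(
    grounding: GroundingSet, wordforms: WordformSet | None = None
) -> ValidationReport:
    """Check every structural invariant; never raises, reports failures."""
    report = ValidationReport()
    spec = grounding.spec
    n, k = spec.n_concepts, spec.instances_per_concept

    bad_size = [
        (p.concept_id, p.instance_id, a)
        for p in grounding.patterns
        for a in GROUNDING_AREAS
        if len(p.cells(a)) != spec.active_per_area
    ]
    report.add("pattern-size-12", not bad_size, f"offending (c,i,area): {bad_size}")

    bad_range = [
        (p.concept_id, p.instance_id, a)
        for p in grounding.patterns
        for a in GROUNDING_AREAS
        if p.cells(a) and not (0 <= min(p.cells(a)) and max(p.cells(a)) < spec.area_size)
    ]
    report.add("cells-in-range", not bad_range, f"offending (c,i,area): {bad_range}")

    # cross-concept disjointness per area
    clashes = []
    for a in GROUNDING_AREAS:
        for c1, c2 in itertools.combinations(range(n), 2):
            if grounding.concept_cells(c1, a) & grounding.concept_cells(c2, a):
                clashes.append((a, c1, c2))
    report.add(
        "cross-concept-disjoint", not clashes, f"offending (area, c1, c2): {clashes}"
    )

    for a in GROUNDING_AREAS:
        if spec.semantic_type == "concrete":
            bad_triple = [
                c for c in range(n) if len(grounding.triple_shared(c, a)) != 6
            ]
            report.add(
                f"concrete-triple-shared-6[{a}]",
                not bad_triple,
                f"concepts: {bad_triple}",
            )
            bad_unique = [
                (c, i)
                for c in range(n)
                for i in range(k)
                if len(grounding.unique_cells(c, i, a)) != 6
            ]
            report.add(
                f"concrete-unique-6[{a}]", not bad_unique, f"(c,i): {bad_unique}"
            )
            # pairwise intersections equal the triple intersection
            bad_pairwise = [
                c
                for c in range(n)
                if any(len(s) != 0 for s in grounding.pairwise_shared(c, a))
            ]
            report.add(
                f"concrete-pairwise-equals-triple[{a}]",
                not bad_pairwise,
                f"concepts: {bad_pairwise}",
            )
        else:
            bad_triple = [
                c for c in range(n) if len(grounding.triple_shared(c, a)) != 0
            ]
            report.add(
                f"abstract-triple-empty[{a}]", not bad_triple, f"concepts: {bad_triple}"
            )
            bad_pair = [
                c
                for c in range(n)
                if any(len(s) != 4 for s in grounding.pairwise_shared(c, a))
            ]
            report.add(
                f"abstract-pairwise-4[{a}]", not bad_pair, f"concepts: {bad_pair}"
            )
            bad_unique = [
                (c, i)
                for c in range(n)
                for i in range(k)
                if len(grounding.unique_cells(c, i, a)) != 4
            ]
            report.add(
                f"abstract-unique-4[{a}]", not bad_unique, f"(c,i): {bad_unique}"
            )

    if wordforms is not None:
        bad_wf = [
            (c, a)
            for c in range(wordforms.n_concepts)
            for a in WORDFORM_AREAS
            if len(wordforms.cells(c, a)) != 12
        ]
        report.add("wordform-size-12", not bad_wf, f"(c,area): {bad_wf}")
        wf_clash = []
        for a in WORDFORM_AREAS:
            for c1, c2 in itertools.combinations(range(wordforms.n_concepts), 2):
                if wordforms.cells(c1, a) & wordforms.cells(c2, a):
                    wf_clash.append((a, c1, c2))
        report.add(
            "wordform-cross-concept-disjoint",
            not wf_clash,
            f"(area, c1, c2): {wf_clash}",
        )
    return report
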