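"""Genealogy graph construction and relative classification.

The analysis classifies each proband's relatives by degree of relatedness
(first, second, third) and by lineage (maternal or paternal, judged by the
first parental step on the connecting path).  Conventions, made explicit
because they are genuinely choices:

* full siblings are first degree; half-siblings second degree;
* lineage is defined by the first parental step from the proband, so
  siblings and descendants — reachable through both parents or through
  neither — carry lineage ``none``;
* each relative keeps its minimal degree when reachable several ways;
* consanguineous pedigrees are classified by shortest-path degree with a
  warning; the kinship-band correspondence (degree d ↔ kinship 1/2^(d+1))
  holds only for outbred pedigrees and is checked there by the independent
  recursive :func:`kinship` oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import pandas as pd

from .errors import DataError, ParseError, PedigreeError

logger = logging.getLogger(__name__)

MATERNAL = "maternal"
PATERNAL = "paternal"
NO_LINEAGE = "none"


@dataclass(frozen=True)
class Individual:
    person_id: int
    sex: str  # 'M' or 'F'
    birth_year: int
    utah_born: bool
    mother_id: int | None = None
    father_id: int | None = None
    death_year: int | None = None
    emr_linked: bool = False
    dl_linked: bool = False


@dataclass
class RelativeSet:
    """Relatives of one proband, keyed by degree, each with a lineage tag."""

    proband_id: int
    by_degree: dict[int, dict[int, str]] = field(default_factory=dict)

    def degree_of(self, relative_id: int) -> int | None:
        for d, rels in self.by_degree.items():
            if relative_id in rels:
                return d
        return None

    def lineage_of(self, relative_id: int) -> str | None:
        for rels in self.by_degree.values():
            if relative_id in rels:
                return rels[relative_id]
        return None

    def all_ids(self) -> set[int]:
        return set().union(*(set(r) for r in self.by_degree.values()))


class PedigreeGraph:
    """Validated parent-child graph supporting relative and lineage queries."""

    def __init__(self, individuals: pd.DataFrame):
        required = {"person_id", "sex", "mother_id", "father_id"}
        missing = required - set(individuals.columns)
        if missing:
            raise DataError(f"individuals table missing columns {sorted(missing)}")
        if individuals["person_id"].duplicated().any():
            dupes = individuals.loc[
                individuals["person_id"].duplicated(), "person_id"
            ].tolist()
            raise DataError(f"duplicate person ids: {dupes[:5]}")

        self.individuals = individuals.set_index("person_id", drop=False)
        self._sex = self.individuals["sex"].to_dict()
        self._mother: dict[int, int | None] = {}
        self._father: dict[int, int | None] = {}
        self._children: dict[int, list[int]] = {pid: [] for pid in self._sex}

        for row in individuals.itertuples(index=False):
            pid = row.person_id
            for parent_attr, store, want_sex in (
                ("mother_id", self._mother, "F"),
                ("father_id", self._father, "M"),
            ):
                parent = getattr(row, parent_attr)
                parent = None if pd.isna(parent) else int(parent)
                if parent is not None:
                    if parent == pid:
                        raise PedigreeError(f"person {pid} is its own parent")
                    if parent not in self._sex:
                        raise PedigreeError(
                            f"person {pid}: dangling parent id {parent}"
                        )
                    if self._sex[parent] != want_sex:
                        raise PedigreeError(
                            f"person {pid}: {parent_attr[:-3]} {parent} has sex "
                            f"{self._sex[parent]!r}"
                        )
                    self._children[parent].append(pid)
                store[pid] = parent

        self._check_acyclic()
        self._check_birth_years()
        self.kinship = lru_cache(maxsize=None)(self._kinship)

    # -- validation -------------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._sex)
        for pid in self._sex:
            for parent in (self._mother[pid], self._father[pid]):
                if parent is not None:
                    g.add_edge(parent, pid)
            # cache the digraph for component / generation summaries
        self._digraph = g
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise PedigreeError(f"pedigree contains a cycle: {cycle}")

    def _check_birth_years(self) -> None:
        if "birth_year" not in self.individuals.columns:
            return
        years = self.individuals["birth_year"].to_dict()
        for pid in self._sex:
            for parent in (self._mother[pid], self._father[pid]):
                if parent is not None and years[parent] >= years[pid]:
                    raise PedigreeError(
                        f"parent {parent} (born {years[parent]}) not born before "
                        f"child {pid} (born {years[pid]})"
                    )

    # -- basic queries ----------------------------------------------------

    def __contains__(self, pid: int) -> bool:
        return pid in self._sex

    def _require(self, pid: int) -> None:
        if pid not in self._sex:
            raise DataError(f"unknown person id {pid}")

    def mother(self, pid: int) -> int | None:
        self._require(pid)
        return self._mother[pid]

    def father(self, pid: int) -> int | None:
        self._require(pid)
        return self._father[pid]

    def parents(self, pid: int) -> list[int]:
        self._require(pid)
        return [p for p in (self._mother[pid], self._father[pid]) if p is not None]

    def children(self, pid: int) -> list[int]:
        self._require(pid)
        return list(self._children[pid])

    def full_siblings(self, pid: int) -> set[int]:
        m, f = self._mother[pid], self._father[pid]
        if m is None or f is None:
            return set()
        return {
            c
            for c in self._children[m]
            if c != pid and self._father[c] == f
        }

    def half_siblings(self, pid: int, through: str) -> set[int]:
        """Siblings sharing exactly the mother ('maternal') or father ('paternal')."""
        own = self._mother[pid] if through == MATERNAL else self._father[pid]
        other_own = self._father[pid] if through == MATERNAL else self._mother[pid]
        if own is None:
            return set()
        out = set()
        for c in self._children[own]:
            if c == pid:
                continue
            other = self._father[c] if through == MATERNAL else self._mother[c]
            if other is None or other_own is None or other != other_own:
                out.add(c)
        return out

    def founders(self) -> list[int]:
        return [p for p in self._sex if not self.parents(p)]

    def descendants(self, pid: int, max_depth: int | None = None) -> set[int]:
        out: set[int] = set()
        frontier = [pid]
        depth = 0
        while frontier and (max_depth is None or depth < max_depth):
            frontier = [c for p in frontier for c in self._children[p]]
            out.update(frontier)
            depth += 1
        return out

    def ancestors(self, pid: int, max_depth: int | None = None) -> set[int]:
        out: set[int] = set()
        frontier = [pid]
        depth = 0
        while frontier and (max_depth is None or depth < max_depth):
            frontier = [a for p in frontier for a in self.parents(p)]
            out.update(frontier)
            depth += 1
        return out

    def summary(self) -> dict[str, int]:
        """Founder, generation-depth and connected-component counts."""
        undirected = self._digraph.to_undirected()
        depth = self.generation_depths()
        return {
            "n_individuals": len(self._sex),
            "n_founders": len(self.founders()),
            "n_generations": (max(depth.values()) + 1) if depth else 0,
            "n_components": nx.number_connected_components(undirected),
        }

    def generation_depths(self) -> dict[int, int]:
        """Depth of each person below the founders (founders are 0)."""
        depth: dict[int, int] = {}
        for pid in nx.topological_sort(self._digraph):
            parents = self.parents(pid)
            depth[pid] = 1 + max(depth[p] for p in parents) if parents else 0
        return depth

    # -- relative classification ------------------------------------------

    def relatives_by_degree(self, proband_id: int, max_degree: int = 3) -> RelativeSet:
        """Classify relatives up to ``max_degree`` with lineage tags.

        Degree 1: parents, full siblings, children.  Degree 2: grandparents,
        grandchildren, half-siblings, aunts/uncles, nieces/nephews.
        Degree 3: great-grandparents, great-grandchildren, first cousins,
        great-aunts/-uncles, half-aunts/-uncles, grand-nieces/-nephews.
        Each relative keeps its minimal degree; a relative reachable through
        both parental sides gets lineage ``none``.
        """
        self._require(proband_id)
        if not 1 <= max_degree <= 3:
            raise DataError(f"max_degree must be 1..3 (got {max_degree})")

        # collect (degree, relative, lineage) candidates, then reduce
        candidates: list[tuple[int, int, str]] = []
        sides = ((MATERNAL, self._mother[proband_id]),
                 (PATERNAL, self._father[proband_id]))

        for rel in self.parents(proband_id):
            side = MATERNAL if rel == self._mother[proband_id] else PATERNAL
            candidates.append((1, rel, side))
        for rel in self.full_siblings(proband_id):
            candidates.append((1, rel, NO_LINEAGE))
        for rel in self.children(proband_id):
            candidates.append((1, rel, NO_LINEAGE))

        if max_degree >= 2:
            for side, parent in sides:
                if parent is None:
                    continue
                for gp in self.parents(parent):
                    candidates.append((2, gp, side))
                for au in self.full_siblings(parent):
                    candidates.append((2, au, side))
                for hs in self.half_siblings(proband_id, side):
                    candidates.append((2, hs, side))
            for sib in self.full_siblings(proband_id):
                for neph in self.children(sib):
                    candidates.append((2, neph, NO_LINEAGE))
            for child in self.children(proband_id):
                for gc in self.children(child):
                    candidates.append((2, gc, NO_LINEAGE))

        if max_degree >= 3:
            for side, parent in sides:
                if parent is None:
                    continue
                for gp in self.parents(parent):
                    for ggp in self.parents(gp):
                        candidates.append((3, ggp, side))
                    for gau in self.full_siblings(gp):
                        candidates.append((3, gau, side))
                for au in self.full_siblings(parent):
                    for cousin in self.children(au):
                        candidates.append((3, cousin, side))
                for hau in self.half_siblings(parent, MATERNAL) | \
                        self.half_siblings(parent, PATERNAL):
                    candidates.append((3, hau, side))
            for sib in self.full_siblings(proband_id):
                for neph in self.children(sib):
                    for gn in self.children(neph):
                        candidates.append((3, gn, NO_LINEAGE))
            for child in self.children(proband_id):
                for gc in self.children(child):
                    for ggc in self.children(gc):
                        candidates.append((3, ggc, NO_LINEAGE))

        # minimal degree wins; within a degree, conflicting lineages -> none
        best: dict[int, tuple[int, str]] = {}
        consanguineous = False
        for degree, rel, lineage in candidates:
            if rel == proband_id:
                consanguineous = True
                continue
            if rel not in best or degree < best[rel][0]:
                best[rel] = (degree, lineage)
            elif degree == best[rel][0] and lineage != best[rel][1]:
                best[rel] = (degree, NO_LINEAGE)
                consanguineous = consanguineous or lineage in (MATERNAL, PATERNAL)
        if consanguineous:
            logger.warning(
                "proband %s: consanguinity detected; relatives classified by "
                "shortest-path degree",
                proband_id,
            )

        by_degree: dict[int, dict[int, str]] = {
            d: {} for d in range(1, max_degree + 1)
        }
        for rel, (degree, lineage) in best.items():
            by_degree[degree][rel] = lineage
        return RelativeSet(proband_id=proband_id, by_degree=by_degree)

    def lineage_of(self, proband_id: int, relative_id: int, max_degree: int = 3) -> str:
        """Lineage of one relative: the side of the first parental step."""
        relset = self.relatives_by_degree(proband_id, max_degree)
        lineage = relset.lineage_of(relative_id)
        if lineage is None:
            raise DataError(
                f"{relative_id} is not within degree {max_degree} of {proband_id}"
            )
        return lineage

    # -- kinship oracle ----------------------------------------------------

    def _kinship(self, a: int, b: int) -> float:
        """Recursive kinship coefficient phi(a, b) in [0, 1/2].

        phi(x, x) = (1 + phi(father, mother)) / 2; for distinct persons the
        deeper one is expanded through its parents.  Founders' missing
        parents contribute 0.  Memoised per graph instance.
        """
        self._require(a)
        self._require(b)
        if a == b:
            m, f = self._mother[a], self._father[a]
            inbreeding = self.kinship(f, m) if (m is not None and f is not None) else 0.0
            return 0.5 * (1.0 + inbreeding)
        if not hasattr(self, "_depth"):
            self._depth = self.generation_depths()
        # expand through the parents of the deeper individual; for equal
        # depths neither is an ancestor of the other so either works
        if self._depth[a] < self._depth[b]:
            a, b = b, a
        total = 0.0
        for parent in (self._mother[a], self._father[a]):
            if parent is not None:
                total += 0.5 * self.kinship(min(parent, b), max(parent, b))
        return total


def build_pedigree(individuals: pd.DataFrame) -> PedigreeGraph:
    """Validate an individuals table into a :class:`PedigreeGraph`."""
    return PedigreeGraph(individuals)


def kinship(graph: PedigreeGraph, a: int, b: int) -> float:
    """Kinship coefficient between two pedigree members (symmetric)."""
    return graph.kinship(min(a, b), max(a, b))


def genealogy_complete(
    graph: PedigreeGraph,
    pid: int,
    min_great_grandparents: int = 6,
) -> bool:
    """Ancestral-completeness eligibility filter.

    Default requirement: both parents, all four grandparents, and at least
    ``min_great_grandparents`` of the eight great-grandparent slots filled.
    Slots are positional, so a shared ancestor can fill more than one.
    """
    parents = [graph.mother(pid), graph.father(pid)]
    if any(p is None for p in parents):
        return False
    gps = [g for p in parents for g in (graph.mother(p), graph.father(p))]
    if any(g is None for g in gps):
        return False
    ggp_filled = sum(
        g2 is not None
        for g in gps
        for g2 in (graph.mother(g), graph.father(g))
    )
    return ggp_filled >= min_great_grandparents


# -- PED interchange -------------------------------------------------------

def to_ped(graph: PedigreeGraph) -> str:
    """Render the pedigree as PED-style text.

    Columns: family id (connected component), person id, father id,
    mother id, sex (1=male, 2=female), with 0 for missing parents.
    """
    undirected = graph._digraph.to_undirected()
    family = {}
    for i, comp in enumerate(sorted(nx.connected_components(undirected),
                                    key=lambda c: min(c)), start=1):
        for pid in comp:
            family[pid] = i
    lines = []
    for pid in sorted(graph._sex):
        sex_code = 1 if graph._sex[pid] == "M" else 2
        lines.append(
            f"{family[pid]}\t{pid}\t{graph.father(pid) or 0}\t"
            f"{graph.mother(pid) or 0}\t{sex_code}"
        )
    return "\n".join(lines) + "\n"


def from_ped(text: str) -> pd.DataFrame:
    """Parse PED-style text into an individuals table (no birth years)."""
    rows = []
    for lineno, line in enumerate(text.strip().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 5:
            raise ParseError(f"PED line {lineno}: expected >=5 fields")
        _, pid, father, mother, sex_code = parts[:5]
        try:
            sex = {"1": "M", "2": "F"}[sex_code]
        except KeyError:
            raise ParseError(f"PED line {lineno}: bad sex code {sex_code!r}") from None
        rows.append(
            {
                "person_id": int(pid),
                "sex": sex,
                "mother_id": int(mother) if mother != "0" else None,
                "father_id": int(father) if father != "0" else None,
            }
        )
    return pd.DataFrame(rows)
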