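"""Taxonomy-aware orthogroup filtering.

Assigns each orthogroup its last common ancestor (LCA) on a taxonomy table and
applies clade-composition rules to pull out lineage-specific orthogroup sets
(bilaterian-, arthropod-, vertebrate-, opisthokont-, metazoan- and
eumetazoan-specific), plus a coverage sweep that counts node-specific groups
as a function of the minimum number of species required.

The taxonomy is a plain ``taxid -> (parent, name)`` table in the NCBI taxdump
dialect (``nodes.dmp``/``names.dmp``) or a simplified 3-column TSV
(taxid, parent, name).  The simplified form is canonical for fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class UnknownTaxonError(KeyError):
    """Raised when a taxid or clade name is absent from the taxonomy table."""


class TaxonomyTable:
    """taxid -> parent mapping with named clades; supports LCA and membership.

    Exactly one root is required, encoded NCBI-style as ``parent == self``.
    """

    def __init__(self, parent: Mapping[int, int], names: Mapping[int, str]):
        self.parent = dict(parent)
        self.names = dict(names)
        roots = [t for t, p in self.parent.items() if t == p]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._name_to_taxid: dict[str, int] = {}
        for taxid, name in self.names.items():
            # clade labels used in filter rules must be unique
            if name in self._name_to_taxid:
                raise ValueError(f"duplicate clade name {name!r} in taxonomy")
            self._name_to_taxid[name] = taxid
        self._depth: dict[int, int] = {}
        for taxid in self.parent:
            self._compute_depth(taxid)

    def _compute_depth(self, taxid: int) -> int:
        d = self._depth.get(taxid)
        if d is not None:
            return d
        seen = []
        t = taxid
        while t not in self._depth and t != self.parent[t]:
            seen.append(t)
            t = self.parent[t]
        base = self._depth.get(t, 0)
        for i, s in enumerate(reversed(seen), start=1):
            self._depth[s] = base + i
        self._depth.setdefault(self.root, 0)
        return self._depth[taxid]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTable":
        """Read the simplified 3-column form: taxid <TAB> parent <TAB> name."""
        parent, names = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                taxid_s, parent_s, name = line.split("\t")[:3]
                parent[int(taxid_s)] = int(parent_s)
                names[int(taxid_s)] = name
        return cls(parent, names)

    @classmethod
    def from_taxdump(cls, nodes_path, names_path) -> "TaxonomyTable":
        """Read NCBI taxdump ``nodes.dmp`` and ``names.dmp`` (scientific names)."""
        parent = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.split("|")]
                if len(fields) < 2 or not fields[0]:
                    continue
                parent[int(fields[0])] = int(fields[1])
        names = {}
        with open(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.split("|")]
                if len(fields) < 4:
                    continue
                if fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]
        return cls(parent, names)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for taxid in sorted(self.parent):
                fh.write(f"{taxid}\t{self.parent[taxid]}\t{self.names.get(taxid, '')}\n")

    # -- queries -----------------------------------------------------------

    def taxid_of(self, name: str) -> int:
        try:
            return self._name_to_taxid[name]
        except KeyError:
            raise UnknownTaxonError(f"unknown clade name {name!r}") from None

    def lineage(self, taxid: int) -> list[int]:
        """Path from the root down to (and including) ``taxid``."""
        if taxid not in self.parent:
            raise UnknownTaxonError(f"unknown taxid {taxid}")
        path = [taxid]
        while taxid != self.parent[taxid]:
            taxid = self.parent[taxid]
            path.append(taxid)
        return path[::-1]

    def is_within(self, taxid: int, clade: int | str) -> bool:
        """True iff ``taxid`` is ``clade`` or a descendant of it."""
        clade_id = self.taxid_of(clade) if isinstance(clade, str) else clade
        return clade_id in self.lineage(taxid)

    def depth(self, taxid: int) -> int:
        if taxid not in self.parent:
            raise UnknownTaxonError(f"unknown taxid {taxid}")
        return self._depth[taxid]


def last_common_ancestor(taxids: Iterable[int], taxonomy: TaxonomyTable) -> int:
    """Deepest node ancestral to every input taxid (a singleton returns itself)."""
    taxids = list(taxids)
    if not taxids:
        raise ValueError("empty taxid set has no LCA")
    paths = [taxonomy.lineage(t) for t in taxids]
    lca = taxonomy.root
    for level in range(min(len(p) for p in paths)):
        node = paths[0][level]
        if all(p[level] == node for p in paths):
            lca = node
        else:
            break
    return lca


# -- clade composition -----------------------------------------------------

#: clade-count columns the built-in rules draw on
DEFAULT_CLADES = (
    "Deuterostomia", "Lophotrochozoa", "Ecdysozoa", "Fungi", "Cnidaria",
    "Ctenophora", "Chelicerata", "Crustacea", "Myriapoda", "Insecta",
    "Gnathostomata", "Bilateria", "Metazoa",
)


@dataclass
class CladeCounts:
    """Species (not sequence) counts per clade for one orthogroup."""

    og_id: str
    counts: dict[str, int]
    total_species: int


def orthogroup_composition(
    species: Iterable[int],
    taxonomy: TaxonomyTable,
    clades: Sequence[str] = DEFAULT_CLADES,
    og_id: str = "",
) -> CladeCounts:
    """Count distinct species per clade.

    ``clades`` entries of the form ``"non-X"`` count species *not* within
    clade X (used for exclusivity clauses such as "non-Bilateria = 0").
    """
    taxa = set(species)
    counts: dict[str, int] = {}
    for clade in clades:
        if clade.startswith("non-"):
            inner = clade[4:]
            counts[clade] = sum(1 for t in taxa if not taxonomy.is_within(t, inner))
        else:
            counts[clade] = sum(1 for t in taxa if taxonomy.is_within(t, clade))
    return CladeCounts(og_id=og_id, counts=counts, total_species=len(taxa))


# -- filter rules ----------------------------------------------------------


@dataclass
class FilterRule:
    """A clade-composition rule.

    ``minima``      -- clade -> required minimum species count.
    ``or_zero``     -- clade -> minimum that may alternatively be exactly 0
                       (the clade may be absent, but if present must meet it).
    ``maxima``      -- clade -> allowed maximum species count.
    ``exclusive_to``-- if set, zero species outside this clade are allowed.
    """

    name: str
    minima: dict[str, int] = field(default_factory=dict)
    or_zero: dict[str, int] = field(default_factory=dict)
    maxima: dict[str, int] = field(default_factory=dict)
    exclusive_to: str | None = None

    def required_clades(self) -> list[str]:
        clades = set(self.minima) | set(self.or_zero) | set(self.maxima)
        if self.exclusive_to:
            clades.add(f"non-{self.exclusive_to}")
        return sorted(clades)

    def scaled(self, factor: float) -> "FilterRule":
        """Scale minima/maxima for fixtures smaller than the full species roster.

        Minima scale as ceil(m * factor) with a floor of 1 so a clause never
        becomes vacuous; maxima scale the same way but keep explicit zeros.
        """
        if factor == 1.0:
            return self

        def _scale_min(v: int) -> int:
            return max(1, math.ceil(v * factor))

        def _scale_max(v: int) -> int:
            return 0 if v == 0 else max(1, math.ceil(v * factor))

        return FilterRule(
            name=self.name,
            minima={c: _scale_min(v) for c, v in self.minima.items()},
            or_zero={c: _scale_min(v) for c, v in self.or_zero.items()},
            maxima={c: _scale_max(v) for c, v in self.maxima.items()},
            exclusive_to=self.exclusive_to,
        )


#: the published composition rules, keyed by the lineage they select
BUILTIN_RULES: dict[str, FilterRule] = {
    "bilaterian": FilterRule(
        name="bilaterian",
        minima={"Deuterostomia": 7},
        or_zero={"Lophotrochozoa": 4, "Ecdysozoa": 4},
        exclusive_to="Bilateria",
    ),
    "arthropod": FilterRule(
        name="arthropod",
        minima={"Chelicerata": 2, "Myriapoda": 1, "Insecta": 5},
        exclusive_to="Arthropoda",
    ),
    "vertebrate": FilterRule(
        name="vertebrate",
        minima={"Gnathostomata": 40},
        exclusive_to="Vertebrata",
    ),
    "opisthokont": FilterRule(
        name="opisthokont",
        minima={"Fungi": 20, "Metazoa": 40, "Bilateria": 30},
        exclusive_to="Opisthokonta",
    ),
    "metazoan": FilterRule(
        name="metazoan",
        minima={"Metazoa": 40, "Bilateria": 30},
        maxima={"Fungi": 0},
        exclusive_to="Metazoa",
    ),
    "eumetazoan": FilterRule(
        name="eumetazoan",
        minima={"Bilateria": 30, "Cnidaria": 3},
        maxima={"Ctenophora": 2},
        exclusive_to="Eumetazoa",
    ),
}


def get_rule(name: str, scale: float = 1.0) -> FilterRule:
    try:
        rule = BUILTIN_RULES[name]
    except KeyError:
        raise KeyError(f"unknown filter rule {name!r}; known: {sorted(BUILTIN_RULES)}") from None
    return rule.scaled(scale)


def apply_lineage_filter(counts: CladeCounts, rule: FilterRule) -> bool:
    """Decide a rule from clade counts alone (pure function of ``counts``)."""
    c = counts.counts
    for clade, m in rule.minima.items():
        if c.get(clade, 0) < m:
            return False
    for clade, m in rule.or_zero.items():
        v = c.get(clade, 0)
        if v != 0 and v < m:
            return False
    for clade, m in rule.maxima.items():
        if c.get(clade, 0) > m:
            return False
    if rule.exclusive_to is not None:
        if c.get(f"non-{rule.exclusive_to}", 0) != 0:
            return False
    return True


# -- coverage sweep --------------------------------------------------------


def coverage_sweep(
    groups,
    node: str,
    taxonomy: TaxonomyTable,
    node_species_total: int,
):
    """Count node-specific orthogroups at every minimum-species threshold.

    A group is *specific* to ``node`` when every member species lies inside
    it.  For each threshold s = 1..node_species_total the table holds the
    number of specific groups with >= s species from the node; the 50% mark
    is the count at s = ceil(node_species_total / 2).  Counts are
    non-increasing in s by construction.
    """
    node_id = taxonomy.taxid_of(node)
    sizes = []
    for g in groups:
        taxa = {int(t) for t in g.species}
        if all(taxonomy.is_within(t, node_id) for t in taxa):
            sizes.append(len(taxa))
    table = {
        s: sum(1 for n in sizes if n >= s)
        for s in range(1, node_species_total + 1)
    }
    half = math.ceil(node_species_total / 2)
    return table, table.get(half, 0)
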