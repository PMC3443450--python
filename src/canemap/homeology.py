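"""Homo(eo)logous group assembly from shared EST-SSR loci.

In a polyploid, the several co-segregation groups deriving from one set of
homologous/homoeologous chromosomes can be recognized because multiallelic
EST-SSR loci scatter their alleles across the homologs: two CGs carrying
alleles of at least two of the same SSR loci are taken as core members of
one homo(eo)logous group (HG); a CG sharing a single locus with an HG is
attached as a putative member.  HGs receive Roman numerals (largest marker
count first); within an HG the CGs are renamed ``<numeral>-k`` in
descending cM length, and CGs with no SSR evidence become unassigned
``U-k`` groups, also by descending length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import MarkerSystem, parse_marker_name
from .linkagemap import LinkageMap
from .multipoint import OrderedCG

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def to_roman(n: int) -> str:
    if n < 1:
        raise ValueError("Roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def ssr_locus_of(marker_id: str, known_loci: list[str] | None = None) -> str:
    """Locus code of an EST-SSR marker name (allele size stripped).

    Locus code and allele size are concatenated without a separator
    (``ESTB94279`` = locus ``ESTB94``, 279 bp allele), so the split is
    ambiguous in general.  When ``known_loci`` is given, the longest
    declared code that prefixes the name (leaving a valid size) wins;
    otherwise the trailing three digits are assumed to be the allele size.
    """
    name = parse_marker_name(marker_id)
    core = marker_id.split("-", 1)[1] if name.cross_prefix else marker_id
    if not core.startswith(("EST", "CV")):
        raise ValueError(f"{marker_id!r} is not an EST-SSR marker name")
    if known_loci:
        hits = [
            loc for loc in known_loci
            if core.startswith(loc) and core[len(loc):].isdigit() and core != loc
        ]
        if hits:
            return max(hits, key=len)
    return name.system_code


@dataclass
class HomeologyGroup:
    name: str                                   # Roman numeral
    core_cgs: list[str]
    putative_cgs: list[str]
    #: (cg_a, cg_b) -> shared SSR locus codes backing the assignment
    shared_loci: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def cgs(self) -> list[str]:
        return self.core_cgs + self.putative_cgs


def cg_ssr_loci(
    cgs: list[OrderedCG],
    system_of: dict[str, str],
    known_loci: list[str] | None = None,
) -> dict[str, set[str]]:
    """Distinct SSR locus codes present in each CG."""
    out: dict[str, set[str]] = {}
    for cg in cgs:
        loci = set()
        for m in cg.markers:
            if system_of.get(m) == MarkerSystem.EST_SSR.value:
                try:
                    loci.add(ssr_locus_of(m, known_loci))
                except ValueError:
                    pass
        out[cg.name] = loci
    return out


def assemble_hgs(
    cgs: list[OrderedCG],
    ssr_loci: dict[str, set[str]],
    min_shared: int = 2,
) -> tuple[list[HomeologyGroup], list[str], dict[str, str]]:
    """Group CGs into HGs by shared SSR loci and apply the naming scheme.

    A CG graph is weighted by the number of distinct shared locus codes;
    components over edges of weight >= ``min_shared`` form HG cores
    (transitive closure: a locus chain through different CG pairs merges
    cores), then weight-1 CGs attach as putative members to the core
    sharing most loci with them.  Duplicated loci inside one CG never
    create evidence on their own (sets, no self-edges).

    Returns the HGs, the unassigned CG names, and the renaming map from
    provisional CG names to final ``<HG>-k`` / ``U-k`` names.
    """
    names = [cg.name for cg in cgs]
    length = {cg.name: cg.length_cm for cg in cgs}
    n_markers = {cg.name: len(cg.markers) for cg in cgs}
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = ssr_loci.get(a, set()) & ssr_loci.get(b, set())
            if shared:
                g.add_edge(a, b, shared=shared, weight=len(shared))
    core_graph = g.edge_subgraph(
        [(a, b) for a, b, d in g.edges(data=True) if d["weight"] >= min_shared]
    ).copy()
    cores = [sorted(c) for c in nx.connected_components(core_graph)]

    assigned = {m for c in cores for m in c}
    groups: list[dict] = [
        {"core": core, "putative": [], "shared": {}} for core in cores
    ]
    for gi, core in enumerate(cores):
        for a, b, d in core_graph.subgraph(core).edges(data=True):
            groups[gi]["shared"][(a, b)] = set(d["shared"])
    # putative attachment: one shared locus with any core member
    for cg_name in names:
        if cg_name in assigned:
            continue
        best = None
        for gi, core in enumerate(cores):
            total = set()
            for member in core:
                if g.has_edge(cg_name, member):
                    total |= g[cg_name][member]["shared"]
            if total and (best is None or len(total) > best[1]):
                best = (gi, len(total), total)
        if best is not None:
            gi = best[0]
            groups[gi]["putative"].append(cg_name)
            assigned.add(cg_name)
            for member in cores[gi]:
                if g.has_edge(cg_name, member):
                    groups[gi]["shared"][(cg_name, member)] = set(
                        g[cg_name][member]["shared"]
                    )

    def group_size(grp) -> int:
        return sum(n_markers[c] for c in grp["core"] + grp["putative"])

    groups.sort(key=lambda grp: (-group_size(grp), grp["core"][0]))
    hgs: list[HomeologyGroup] = []
    rename: dict[str, str] = {}
    for gi, grp in enumerate(groups):
        numeral = to_roman(gi + 1)
        members = sorted(
            grp["core"] + grp["putative"], key=lambda c: (-length[c], c)
        )
        for k, cg_name in enumerate(members, start=1):
            rename[cg_name] = f"{numeral}-{k}"
        hgs.append(
            HomeologyGroup(
                name=numeral,
                core_cgs=[rename_key for c in grp["core"] for rename_key in [rename[c]]],
                putative_cgs=[rename[c] for c in grp["putative"]],
                shared_loci={
                    (rename[a], rename[b]): s for (a, b), s in grp["shared"].items()
                },
            )
        )
    unassigned = sorted(
        (c for c in names if c not in assigned), key=lambda c: (-length[c], c)
    )
    for k, cg_name in enumerate(unassigned, start=1):
        rename[cg_name] = f"U-{k}"
    return hgs, [rename[c] for c in unassigned], rename


def build_linkage_map(
    ordered_cgs: list[OrderedCG],
    system_of: dict[str, str],
    cross_type_of: dict[str, str],
    unlinked: list[str] | None = None,
    known_loci: list[str] | None = None,
    min_shared: int = 2,
) -> tuple[LinkageMap, list[HomeologyGroup]]:
    """Assemble the final map: HG assembly, CG renaming, annotations."""
    loci = cg_ssr_loci(ordered_cgs, system_of, known_loci)
    hgs, _, rename = assemble_hgs(ordered_cgs, loci, min_shared=min_shared)
    renamed: list[OrderedCG] = []
    for cg in ordered_cgs:
        cg.name = rename[cg.name]
        renamed.append(cg)
    hg_of: dict[str, str] = {}
    for hg in hgs:
        for c in hg.cgs:
            hg_of[c] = hg.name
    for cg in renamed:
        hg_of.setdefault(cg.name, "U")
    renamed.sort(key=lambda c: c.name)
    lmap = LinkageMap(
        ordered_cgs=renamed,
        hg_of=hg_of,
        system_of=system_of,
        cross_type_of=cross_type_of,
        unlinked=list(unlinked or []),
    )
    return lmap, hgs
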