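"""The assembled linkage map: ordered co-segregation groups + HG naming."""

from __future__ import annotations

from dataclasses import dataclass, field

from .multipoint import OrderedCG


@dataclass
class LinkageMap:
    """Ordered co-segregation groups with homeology-group assignments.

    ``hg_of`` maps final CG name -> HG name (Roman numeral or ``U``);
    ``system_of`` / ``cross_type_of`` map marker -> annotation, used by the
    text exporters and the summary statistics.
    """

    ordered_cgs: list[OrderedCG]
    hg_of: dict[str, str] = field(default_factory=dict)
    system_of: dict[str, str] = field(default_factory=dict)
    cross_type_of: dict[str, str] = field(default_factory=dict)
    unlinked: list[str] = field(default_factory=list)

    @property
    def n_cgs(self) -> int:
        return len(self.ordered_cgs)

    @property
    def n_linked_markers(self) -> int:
        return sum(len(cg.markers) for cg in self.ordered_cgs)

    @property
    def total_length_cm(self) -> float:
        return sum(cg.length_cm for cg in self.ordered_cgs)

    def cg(self, name: str) -> OrderedCG:
        for c in self.ordered_cgs:
            if c.name == name:
                return c
        raise KeyError(name)
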