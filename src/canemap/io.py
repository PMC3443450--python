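"""Marker score matrix I/O and marker nomenclature.

The on-disk dialect is a plain TSV close in spirit to OneMap raw files:

.. code-block:: text

    #individuals:\tind1\tind2\t...
    marker_id\tsystem\tp1\tp2\tscore_1\tscore_2\t...

Scores are ``1`` (band present), ``0`` (band absent) and ``-`` (missing),
for the two parents and then for every F1 individual declared in the
header.  Marker order and individual order are preserved exactly; nothing
is ever sorted implicitly.

Marker names follow the field convention of primer/enzyme code followed by
the fragment molecular size in bp, optionally prefixed by the cross type,
e.g. ``D1-E35M47510`` (AFLP, Keygene primer pair E35/M47, 510 bp band) or
``D2-DIsIvLI385`` (DraI digest, retrotransposon LTR primer, 385 bp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

PRESENT = 1
ABSENT = 0
MISSING = -1

_SCORE_TO_CODE = {PRESENT: "1", ABSENT: "0", MISSING: "-"}
_CODE_TO_SCORE = {"1": PRESENT, "0": ABSENT, "-": MISSING}

#: Enzyme abbreviations that may start a retrotransposon marker code
#: (AluI, DraI, SspI, RsaI).
RT_ENZYME_CODES = ("AI", "DI", "SI", "RI")


class MarkerSystem(str, Enum):
    """Marker system that produced a band."""

    AFLP = "AFLP"
    EST_SSR = "EST_SSR"
    RT = "RT"


class ParseError(ValueError):
    """Malformed marker table; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class MarkerRecord:
    """One dominant (presence/absence) marker scored across the population.

    ``parent1_band``/``parent2_band`` are the parental gel scores (parent 1
    is the male 'IAC66-6', parent 2 the female 'TUC71-7'); ``scores`` holds
    one code per F1 individual, in the table's individual order.
    """

    marker_id: str
    system: MarkerSystem
    parent1_band: int
    parent2_band: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int8)
        for b in (self.parent1_band, self.parent2_band):
            if b not in (PRESENT, ABSENT, MISSING):
                raise ValueError(f"invalid parental score {b!r}")
        bad = ~np.isin(self.scores, (PRESENT, ABSENT, MISSING))
        if bad.any():
            raise ValueError(
                f"marker {self.marker_id}: invalid score codes {self.scores[bad][:5]}"
            )


@dataclass
class MarkerTable:
    """A full genotyping matrix: markers x individuals."""

    individuals: list[str]
    records: list[MarkerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.individuals) < 2:
            raise ValueError("a marker table needs at least 2 individuals")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        seen: set[str] = set()
        n = len(self.individuals)
        for rec in self.records:
            if rec.marker_id in seen:
                raise ValueError(f"duplicate marker id {rec.marker_id}")
            seen.add(rec.marker_id)
            if rec.scores.shape != (n,):
                raise ValueError(
                    f"marker {rec.marker_id}: {rec.scores.size} scores for "
                    f"{n} individuals"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def marker_ids(self) -> list[str]:
        return [r.marker_id for r in self.records]

    def record(self, marker_id: str) -> MarkerRecord:
        for r in self.records:
            if r.marker_id == marker_id:
                return r
        raise KeyError(marker_id)

    def score_matrix(self) -> np.ndarray:
        """(n_markers, n_individuals) int8 matrix of 1/0/-1 codes."""
        if not self.records:
            return np.empty((0, self.n_individuals), dtype=np.int8)
        return np.stack([r.scores for r in self.records])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerTable):
            return NotImplemented
        if self.individuals != other.individuals:
            return False
        if len(self.records) != len(other.records):
            return False
        for a, b in zip(self.records, other.records):
            if (
                a.marker_id != b.marker_id
                or a.system != b.system
                or a.parent1_band != b.parent1_band
                or a.parent2_band != b.parent2_band
                or not np.array_equal(a.scores, b.scores)
            ):
                return False
        return True


@dataclass(frozen=True)
class MarkerName:
    """Parsed marker nomenclature: optional cross prefix, code, size in bp."""

    cross_prefix: str | None
    system_code: str
    fragment_size_bp: int

    def __post_init__(self) -> None:
        if self.fragment_size_bp <= 0:
            raise ValueError("fragment size must be positive")


def read_marker_table(path, dialect: str = "tsv") -> MarkerTable:
    """Read a marker score matrix from the TSV dialect described above."""
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty file", 1)
    header = lines[0].split("\t")
    if header[0] != "#individuals:":
        raise ParseError("header must start with '#individuals:'", 1)
    individuals = header[1:]
    if len(individuals) < 2:
        raise ParseError("fewer than 2 individuals declared", 1)
    n = len(individuals)
    records: list[MarkerRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 4 + n:
            raise ParseError(
                f"expected {4 + n} fields (id, system, 2 parents, {n} scores), "
                f"got {len(fields)}",
                lineno,
            )
        marker_id, system_s, p1_s, p2_s = fields[:4]
        if marker_id in seen:
            raise ParseError(f"duplicate marker id {marker_id!r}", lineno)
        seen.add(marker_id)
        try:
            system = MarkerSystem(system_s)
        except ValueError:
            raise ParseError(f"unknown marker system {system_s!r}", lineno) from None
        try:
            p1 = _CODE_TO_SCORE[p1_s]
            p2 = _CODE_TO_SCORE[p2_s]
            scores = np.array([_CODE_TO_SCORE[c] for c in fields[4:]], dtype=np.int8)
        except KeyError as exc:
            raise ParseError(f"unknown score code {exc.args[0]!r}", lineno) from None
        records.append(MarkerRecord(marker_id, system, p1, p2, scores))
    return MarkerTable(individuals=individuals, records=records)


def write_marker_table(table: MarkerTable, path) -> None:
    """Write ``table`` so that :func:`read_marker_table` recovers it exactly."""
    if len(table.individuals) == 0:
        raise ValueError("cannot write a table with no individuals")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#individuals:\t" + "\t".join(table.individuals) + "\n")
        for rec in table.records:
            codes = [_SCORE_TO_CODE[int(s)] for s in rec.scores]
            fh.write(
                "\t".join(
                    [
                        rec.marker_id,
                        rec.system.value,
                        _SCORE_TO_CODE[rec.parent1_band],
                        _SCORE_TO_CODE[rec.parent2_band],
                    ]
                    + codes
                )
                + "\n"
            )


_PREFIX_RE = re.compile(r"^(D1|D2|C)-(.+)$")
_AFLP_RE = re.compile(r"^(E\d{2}M\d{2})(\d+)?$")     # Keygene primer pair + size
_LETTER_CODE_RE = re.compile(r"^([A-Za-z]+)(\d+)$")  # enzyme/primer or SSR code
_FALLBACK_RE = re.compile(r"^(.+?)(\d+)$")


def parse_marker_name(name: str) -> MarkerName:
    """Split a marker name into cross prefix, system code and fragment size.

    Code and size are concatenated without a separator, so the split uses
    the shapes of the field's naming conventions: Keygene AFLP primer
    pairs (``E35M47510`` -> ``E35M47`` + 510), all-letter enzyme/primer
    codes for element-anchored markers (``DIsIvLI385`` -> ``DIsIvLI`` +
    385), EST-SSR locus codes with a 3-digit allele size
    (``ESTB94279`` -> ``ESTB94`` + 279), and as a last resort the maximal
    trailing integer.
    """
    if not name:
        raise ValueError("empty marker name")
    prefix = None
    core = name
    pm = _PREFIX_RE.match(name)
    if pm:
        prefix, core = pm.groups()
    am = _AFLP_RE.match(core)
    if am:
        code, size = am.groups()
        if size is None:
            raise ValueError(f"no fragment size in {name!r}")
        return MarkerName(prefix, code, int(size))
    lm = _LETTER_CODE_RE.match(core)
    if lm:
        letters, digits = lm.groups()
        if letters.startswith(("EST", "CV")) and len(digits) > 3:
            # SSR locus number and allele size are both in the digit run
            return MarkerName(prefix, letters + digits[:-3], int(digits[-3:]))
        return MarkerName(prefix, letters, int(digits))
    fm = _FALLBACK_RE.match(core)
    if fm is None:
        raise ValueError(f"no trailing fragment size in {name!r}")
    code, size = fm.groups()
    return MarkerName(prefix, code, int(size))


def export_map_text(linkage_map, path, format: str = "tsv") -> None:
    """Export an ordered map as TSV or MapChart-style text.

    TSV columns: HG, CG, marker, position_cM, system, cross_type.  The
    MapChart flavour writes one ``group`` header per co-segregation group
    followed by ``marker<tab>position`` lines, the text input map-drawing
    software consumes.
    """
    if format not in ("tsv", "mapchart"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for cg in linkage_map.ordered_cgs:
        if cg.positions_cm is None:
            raise ValueError(f"co-segregation group {cg.name} is not ordered")
        hg = linkage_map.hg_of.get(cg.name, "-") if linkage_map.hg_of else "-"
        for mk, pos in zip(cg.markers, cg.positions_cm):
            rows.append((hg, cg.name, mk, pos))
    with open(path, "wt", encoding="utf-8") as fh:
        if format == "tsv":
            fh.write("HG\tCG\tmarker\tposition_cM\tsystem\tcross_type\n")
            for hg, cgn, mk, pos in rows:
                system = linkage_map.system_of.get(mk, "-")
                ctype = linkage_map.cross_type_of.get(mk, "-")
                fh.write(f"{hg}\t{cgn}\t{mk}\t{pos:.2f}\t{system}\t{ctype}\n")
        else:
            current = None
            for hg, cgn, mk, pos in rows:
                if cgn != current:
                    if current is not None:
                        fh.write("\n")
                    fh.write(f"group {cgn}\n")
                    current = cgn
                fh.write(f"{mk}\t{pos:.2f}\n")


def table_from_arrays(
    individuals: Sequence[str],
    marker_ids: Iterable[str],
    systems: Iterable[MarkerSystem],
    parent1: Iterable[int],
    parent2: Iterable[int],
    scores: np.ndarray,
) -> MarkerTable:
    """Assemble a :class:`MarkerTable` from parallel arrays (simulator helper)."""
    records = [
        MarkerRecord(mid, sys_, int(p1), int(p2), row)
        for mid, sys_, p1, p2, row in zip(marker_ids, systems, parent1, parent2, scores)
    ]
    return MarkerTable(individuals=list(individuals), records=records)
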