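"""Tabular I/O: domain annotations, pair lists, prediction tables, SIF export.

All tables are TSV, UTF-8, with optional ``#`` comment lines. These are
deliberately minimal dialects (two or three columns) with hard validation —
self-pairs and duplicate rows are rejected rather than silently merged, so
curation errors surface at load time with line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .decision import DirectionCall

__all__ = [
    "ParseError",
    "ProteinDomainMap",
    "DirectedPairSet",
    "UndirectedPairSet",
    "read_domain_map",
    "read_directed_pairs",
    "read_undirected_pairs",
    "write_domain_map",
    "write_directed_pairs",
    "write_predictions",
    "read_predictions",
    "export_sif",
]

PREDICTIONS_HEADER = "#protein_a\tprotein_b\tcall\tscore_a_to_b\tscore_b_to_a"


class ParseError(ValueError):
    """Malformed or inconsistent input table; carries path and line number."""

    def __init__(self, path, line_no: Optional[int], message: str):
        self.path = str(path)
        self.line_no = line_no
        loc = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{loc}: {message}")


@dataclass
class ProteinDomainMap:
    """Protein identifier -> set of domain accessions (possibly empty)."""

    entries: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def domains(self, protein: str) -> FrozenSet[str]:
        """Domain set of ``protein``; empty for unknown proteins."""
        return self.entries.get(protein, frozenset())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DirectedPairSet:
    """Ordered (upstream, downstream, optional type tag) records.

    Both orientations of the same unordered pair may legitimately coexist as
    separate records; exact duplicates and self-pairs may not.
    """

    pairs: List[Tuple[str, str, Optional[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> set:
        """Unordered identities of all records."""
        return {tuple(sorted((u, d))) for u, d, _ in self.pairs}


@dataclass
class UndirectedPairSet:
    """Deduplicated unordered pairs, stored with lexicographically sorted ids."""

    pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def _data_lines(path) -> Iterable[Tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield line_no, line


def read_domain_map(path) -> ProteinDomainMap:
    """Read a protein→domains table: ``protein<TAB>comma-separated domains``.

    An empty second field means an empty domain set. Repeated lines for one
    protein are merged when their domain sets agree; conflicting repeats are
    an error.
    """
    entries: Dict[str, FrozenSet[str]] = {}
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, line_no, f"expected >=2 tab-separated columns, got {len(fields)}")
        protein = fields[0].strip()
        if not protein:
            raise ParseError(path, line_no, "empty protein identifier")
        domain_field = fields[1].strip()
        domains = frozenset(d.strip() for d in domain_field.split(",") if d.strip()) if domain_field else frozenset()
        if protein in entries and entries[protein] != domains:
            raise ParseError(
                path, line_no,
                f"conflicting domain sets for protein {protein!r}: "
                f"{sorted(entries[protein])} vs {sorted(domains)}",
            )
        entries[protein] = domains
    return ProteinDomainMap(entries=entries)


def read_directed_pairs(path) -> DirectedPairSet:
    """Read directed (upstream, downstream[, type]) records, order preserved."""
    pairs: List[Tuple[str, str, Optional[str]]] = []
    seen = set()
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, line_no, f"expected >=2 tab-separated columns, got {len(fields)}")
        up, down = fields[0].strip(), fields[1].strip()
        tag = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
        if not up or not down:
            raise ParseError(path, line_no, "empty protein identifier")
        if up == down:
            raise ParseError(path, line_no, f"self-pair ({up}, {down}) is not allowed")
        record = (up, down, tag)
        if record in seen:
            raise ParseError(path, line_no, f"duplicate directed record {record}")
        seen.add(record)
        pairs.append(record)
    return DirectedPairSet(pairs=pairs)


def read_undirected_pairs(path) -> UndirectedPairSet:
    """Read unordered pairs; the two columns may appear in either order."""
    pairs: List[Tuple[str, str]] = []
    seen = set()
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, line_no, f"expected >=2 tab-separated columns, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(path, line_no, "empty protein identifier")
        if a == b:
            raise ParseError(path, line_no, f"self-pair ({a}, {b}) is not allowed")
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    return UndirectedPairSet(pairs=pairs)


def write_domain_map(domain_map: ProteinDomainMap, path) -> None:
    """Write a protein→domains table in deterministic (sorted) order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein\tdomains\n")
        for protein in sorted(domain_map.entries):
            fh.write(f"{protein}\t{','.join(sorted(domain_map.entries[protein]))}\n")


def write_directed_pairs(pair_set: DirectedPairSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#upstream\tdownstream\ttype\n")
        for up, down, tag in pair_set.pairs:
            fh.write(f"{up}\t{down}\t{tag or ''}\n")


def write_predictions(bags, path) -> None:
    """Write fused direction calls, one pair per row.

    Columns: the two protein ids, the call token (``A->B``, ``B->A``,
    ``<->`` or ``?`` for undetermined), then the two decision scores to six
    decimals. Every bag must carry both scores and a call.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(PREDICTIONS_HEADER + "\n")
        for bag in bags:
            if bag.call is None or bag.score_fwd is None or bag.score_rev is None:
                raise ValueError(f"bag ({bag.a}, {bag.b}) has no fused call/scores")
            fh.write(f"{bag.a}\t{bag.b}\t{bag.call.token}\t{bag.score_fwd:.6f}\t{bag.score_rev:.6f}\n")


def read_predictions(path) -> List[Tuple[str, str, DirectionCall, float, float]]:
    """Parse a predictions table back into (a, b, call, score_fwd, score_rev)."""
    rows = []
    for line_no, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(path, line_no, f"expected 5 columns, got {len(fields)}")
        a, b, token, s_ab, s_ba = fields
        try:
            rows.append((a, b, DirectionCall.from_token(token), float(s_ab), float(s_ba)))
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc)) from exc
    return rows


def export_sif(bags, path, include_ambiguous: bool = False) -> None:
    """Write directed calls as Cytoscape SIF: ``upstream<TAB>directs<TAB>downstream``.

    By default bidirectional and undetermined calls are omitted (as in
    network figures that only draw resolved arrows); with
    ``include_ambiguous`` a bidirectional call emits both orientations and
    undetermined calls are still omitted.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for bag in bags:
            if bag.call is DirectionCall.A_TO_B:
                fh.write(f"{bag.a}\tdirects\t{bag.b}\n")
            elif bag.call is DirectionCall.B_TO_A:
                fh.write(f"{bag.b}\tdirects\t{bag.a}\n")
            elif bag.call is DirectionCall.BIDIRECTIONAL and include_ambiguous:
                fh.write(f"{bag.a}\tdirects\t{bag.b}\n")
                fh.write(f"{bag.b}\tdirects\t{bag.a}\n")
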