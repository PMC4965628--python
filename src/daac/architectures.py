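"""Domain architecture construction from InterPro-style domain hits.

A protein's domain architecture (DA) is the ordered, N-to-C list of the
InterPro domain entries found on its sequence.  Unannotated stretches longer
than a configurable threshold (30 aa by default) are marked with a reserved
``GAP`` pseudo-domain, standing in for domains that may not yet have been
discovered.  The DA is the sequence unit every downstream alignment and
classification step operates on.

This module also computes inverse domain frequency weights,

    A_d = log2(N_t / N_d),

where ``N_t`` is the number of proteins in the corpus and ``N_d`` the number
of proteins containing domain ``d`` at least once.  Promiscuous domains —
those present in many unrelated proteins — receive weights near zero and
contribute little to alignment scores.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

#: Reserved token for an unannotated region longer than ``gap_min_len``.
GAP = "GAP"

_ACCESSION_RE = re.compile(r"^IPR\d{6}$")

#: InterPro entry types; only ``domain`` hits enter architectures.
ENTRY_TYPES = ("domain", "family", "repeat", "site")


@dataclass(frozen=True)
class DomainHit:
    """One InterPro entry hit on a protein sequence (1-based, inclusive)."""

    protein_id: str
    entry_id: str
    entry_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates [{self.start},{self.end}] for "
                f"{self.entry_id} on {self.protein_id}: need 1 <= start <= end"
            )
        if not _ACCESSION_RE.match(self.entry_id):
            raise ValueError(f"not an InterPro accession: {self.entry_id!r}")

    @property
    def is_domain(self) -> bool:
        """True for ``domain``-type entries; families/repeats/sites are
        parsed but excluded from architectures downstream."""
        return self.entry_type == "domain"


@dataclass(frozen=True)
class ProteinRecord:
    """Protein identifier and sequence length (needed to place terminal GAPs)."""

    protein_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id}: length must be >= 1")


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered element list for one protein.

    Elements are InterPro accessions or the :data:`GAP` token.  Invariants:
    no two consecutive GAP tokens, and at least one real domain (GAP-only
    architectures are never emitted).
    """

    protein_id: str
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if not any(e != GAP for e in self.elements):
            raise ValueError(
                f"architecture for {self.protein_id} has no real domain"
            )
        for a, b in zip(self.elements, self.elements[1:]):
            if a == GAP and b == GAP:
                raise ValueError(
                    f"architecture for {self.protein_id} has consecutive GAPs"
                )

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[str]:
        return iter(self.elements)


def count_domains(arch: DomainArchitecture) -> int:
    """Number of real (non-GAP) elements, counting recurrences."""
    return sum(1 for e in arch.elements if e != GAP)


@dataclass(frozen=True)
class WeightTable:
    """Inverse domain frequency weights over a training corpus.

    ``weights[d] == log2(n_total / n_by_domain[d])``; the GAP token carries
    no weight (GAP columns are scored by a fixed penalty, unweighted).
    """

    weights: Mapping[str, float]
    n_total: int
    n_by_domain: Mapping[str, int] = field(default_factory=dict)

    def weight(self, accession: str, strict: bool = True) -> float:
        """Weight for ``accession``.

        In strict mode an unknown accession raises :class:`KeyError`
        (training corpora must be self-consistent); in lenient mode it
        returns 1.0 with a warning, so that novel domains on query proteins
        do not abort an annotation run.
        """
        try:
            return self.weights[accession]
        except KeyError:
            if strict:
                raise KeyError(
                    f"accession {accession} absent from weight table"
                ) from None
            logger.warning(
                "accession %s absent from weight table; using weight 1.0",
                accession,
            )
            return 1.0


@dataclass(frozen=True)
class ColumnMap:
    """Column indices for tabular hit input.

    The default matches the six-column layout
    (protein_id, protein_length, interpro_accession, entry_type, start, end).
    Raw InterProScan 15-column TSV can be read with
    ``ColumnMap(protein_id=0, length=2, entry_id=11, entry_type=None,
    start=6, end=7)`` (entry type then defaults to ``domain``).
    """

    protein_id: int = 0
    length: int = 1
    entry_id: int = 2
    entry_type: Optional[int] = 3
    start: int = 4
    end: int = 5
    default_entry_type: str = "domain"


def parse_hits(
    stream: Union[TextIO, Iterable[str]],
    columns: ColumnMap = ColumnMap(),
) -> tuple[list[ProteinRecord], list[DomainHit]]:
    """Parse a tab-separated domain-hit table.

    Returns one :class:`ProteinRecord` per distinct protein id (first-seen
    order) and all hits, including non-domain entry types (flagged via
    :attr:`DomainHit.is_domain` so callers can filter).  A header line is
    skipped if its coordinate fields are non-numeric.  Malformed lines raise
    :class:`ValueError` naming the line number.
    """
    proteins: dict[str, ProteinRecord] = {}
    hits: list[DomainHit] = []
    needed = max(
        columns.protein_id, columns.length, columns.entry_id,
        columns.start, columns.end,
        columns.entry_type if columns.entry_type is not None else 0,
    ) + 1
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < needed:
            raise ValueError(
                f"line {lineno}: expected at least {needed} tab-separated "
                f"columns, got {len(parts)}"
            )
        start_f, end_f = parts[columns.start], parts[columns.end]
        if lineno == 1 and not (_is_int(start_f) and _is_int(end_f)):
            continue  # header
        if not (_is_int(start_f) and _is_int(end_f) and _is_int(parts[columns.length])):
            raise ValueError(
                f"line {lineno}: non-integer coordinate or length "
                f"({parts[columns.length]!r}, {start_f!r}, {end_f!r})"
            )
        pid = parts[columns.protein_id]
        length = int(parts[columns.length])
        entry_type = (
            parts[columns.entry_type].strip().lower()
            if columns.entry_type is not None
            else columns.default_entry_type
        )
        try:
            hit = DomainHit(
                protein_id=pid,
                entry_id=parts[columns.entry_id],
                entry_type=entry_type,
                start=int(start_f),
                end=int(end_f),
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        if pid not in proteins:
            proteins[pid] = ProteinRecord(protein_id=pid, length=length)
        elif proteins[pid].length != length:
            raise ValueError(
                f"line {lineno}: conflicting length {length} for {pid} "
                f"(previously {proteins[pid].length})"
            )
        hits.append(hit)
    return list(proteins.values()), hits


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def build_architecture(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    gap_min_len: int = 30,
) -> Optional[DomainArchitecture]:
    """Linearize a protein's domain-type hits into a DA.

    Hits are ordered by (start, end, accession).  Overlapping or abutting
    hits of the same accession are merged into a single element occurrence;
    distinct accessions each contribute one element in start order.  A GAP
    element is inserted for every maximal uncovered region strictly longer
    than ``gap_min_len`` residues (including the N- and C-terminal ends).
    Returns ``None`` when the protein has no domain-type hit.
    """
    if gap_min_len < 1:
        raise ValueError("gap_min_len must be >= 1")
    for h in hits:
        if h.protein_id != protein.protein_id:
            raise ValueError(
                f"hit {h.entry_id} belongs to {h.protein_id}, "
                f"not {protein.protein_id}"
            )
        if not h.is_domain:
            raise ValueError(
                f"protein {protein.protein_id}: non-domain hit "
                f"{h.entry_id} ({h.entry_type}) passed to build_architecture"
            )
        if h.end > protein.length:
            raise ValueError(
                f"protein {protein.protein_id}: hit {h.entry_id} ends at "
                f"{h.end} beyond protein length {protein.length}"
            )
    if not hits:
        return None

    ordered = sorted(hits, key=lambda h: (h.start, h.end, h.entry_id))

    # Merge same-accession runs that overlap or abut (adjacent residues).
    merged: list[list] = []  # [start, end, accession]
    for h in ordered:
        for m in merged:
            if m[2] == h.entry_id and h.start <= m[1] + 1 and h.end >= m[0] - 1:
                m[0] = min(m[0], h.start)
                m[1] = max(m[1], h.end)
                break
        else:
            merged.append([h.start, h.end, h.entry_id])
    merged.sort(key=lambda m: (m[0], m[1], m[2]))

    # Coverage union over *all* hit spans determines uncovered regions.
    union: list[list[int]] = []
    for m in sorted(merged):
        if union and m[0] <= union[-1][1] + 1:
            union[-1][1] = max(union[-1][1], m[1])
        else:
            union.append([m[0], m[1]])

    gap_starts: list[int] = []
    if union[0][0] - 1 > gap_min_len:
        gap_starts.append(1)
    for (s1, e1), (s2, e2) in zip(union, union[1:]):
        if s2 - e1 - 1 > gap_min_len:
            gap_starts.append(e1 + 1)
    if protein.length - union[-1][1] > gap_min_len:
        gap_starts.append(union[-1][1] + 1)

    events = [(m[0], 1, m[2]) for m in merged] + [(s, 0, GAP) for s in gap_starts]
    events.sort()
    return DomainArchitecture(
        protein_id=protein.protein_id,
        elements=tuple(acc for _, _, acc in events),
    )


def build_architectures(
    proteins: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    gap_min_len: int = 30,
) -> dict[str, DomainArchitecture]:
    """Build DAs for a whole corpus, keeping only domain-type hits.

    Proteins with no domain hit produce no DA (they carry no architectural
    signal) and are simply absent from the returned mapping.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.is_domain:
            by_protein.setdefault(h.protein_id, []).append(h)
    das: dict[str, DomainArchitecture] = {}
    n_skipped = 0
    for p in proteins:
        arch = build_architecture(p, by_protein.get(p.protein_id, []), gap_min_len)
        if arch is None:
            n_skipped += 1
        else:
            das[p.protein_id] = arch
    if n_skipped:
        logger.info(
            "%d protein(s) without domain-type hits produced no DA", n_skipped
        )
    return das


def compute_weights(
    architectures: Sequence[DomainArchitecture],
) -> WeightTable:
    """Inverse domain frequency weights, A_d = log2(N_t / N_d).

    ``N_d`` counts proteins containing ``d`` at least once (recurrence
    within a protein counts once); GAP is excluded.
    """
    if not architectures:
        raise ValueError("cannot compute weights from an empty corpus")
    n_total = len(architectures)
    n_by_domain: dict[str, int] = {}
    for arch in architectures:
        for acc in set(arch.elements) - {GAP}:
            n_by_domain[acc] = n_by_domain.get(acc, 0) + 1
    weights = {
        acc: math.log2(n_total / n_d) for acc, n_d in n_by_domain.items()
    }
    return WeightTable(weights=weights, n_total=n_total, n_by_domain=n_by_domain)


# ---------------------------------------------------------------------------
# Plain-text persistence (bit-exact across runs)

def write_da_table(das: Mapping[str, DomainArchitecture], stream: TextIO,
                   header: Optional[str] = None) -> None:
    """Write one row per protein: protein_id <TAB> comma-joined elements."""
    if header:
        stream.write(f"# {header}\n")
    for pid in das:
        stream.write(f"{pid}\t{','.join(das[pid].elements)}\n")


def read_da_table(stream: Union[TextIO, Iterable[str]]) -> dict[str, DomainArchitecture]:
    das: dict[str, DomainArchitecture] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            pid, elements = line.split("\t")
        except ValueError:
            raise ValueError(f"line {lineno}: expected 2 columns") from None
        das[pid] = DomainArchitecture(
            protein_id=pid, elements=tuple(elements.split(","))
        )
    return das


def write_weight_table(table: WeightTable, stream: TextIO,
                       header: Optional[str] = None) -> None:
    if header:
        stream.write(f"# {header}\n")
    stream.write(f"# n_total\t{table.n_total}\n")
    for acc in sorted(table.weights):
        stream.write(
            f"{acc}\t{table.n_by_domain.get(acc, 0)}\t{table.weights[acc]:.12g}\n"
        )


def read_weight_table(stream: Union[TextIO, Iterable[str]]) -> WeightTable:
    n_total = 0
    weights: dict[str, float] = {}
    n_by_domain: dict[str, int] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("# n_total"):
            n_total = int(line.split("\t")[1])
            continue
        if line.startswith("#"):
            continue
        acc, n_d, w = line.split("\t")
        weights[acc] = float(w)
        n_by_domain[acc] = int(n_d)
    return WeightTable(weights=weights, n_total=n_total, n_by_domain=n_by_domain)
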