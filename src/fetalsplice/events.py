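"""Cassette-exon event model.

A splice event is a skipped (cassette) exon together with optional flanking
exons. Coordinates are 1-based and fully inclusive throughout the package;
conversion to 0-based half-open happens only at I/O boundaries that require
it (never internally). Strand is not modeled: events on the same chromosome
are merged by interval overlap.

Event identifiers follow the gene-symbol-plus-variant-suffix convention:
multiple events in the same gene carry a trailing lowercase letter
(``SORBS1a``, ``SORBS1b``, ``MBNL2c``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Tuple

__all__ = [
    "SpliceEvent",
    "EventTable",
    "exon_length",
    "frame_disrupting",
    "count_unique_genes",
    "merge_cassette_exons",
    "load_event_table",
    "load_dm1_cortex_events",
    "write_event_gff",
    "read_event_gff",
    "strip_variant_suffix",
]

_COORD_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")
# gene symbol (uppercase/digits, may contain '-') followed by an optional
# single lowercase variant letter, e.g. SORBS1a
_EVENT_ID_RE = re.compile(r"^(?P<gene>[A-Z0-9][A-Z0-9\-\.]*)(?P<suffix>[a-z])?$")

DIRECTIONS = ("increased", "decreased", "unknown")


def exon_length(start: int, end: int) -> int:
    """Length in bp of a 1-based, fully inclusive interval: end - start + 1."""
    if start <= 0 or end <= 0:
        raise ValueError(f"coordinates must be positive, got {start}-{end}")
    if start > end:
        raise ValueError(f"coordinate order error: start {start} > end {end}")
    return end - start + 1


def frame_disrupting(length: int) -> bool:
    """True iff including/excluding an exon of this length changes the reading frame."""
    if length < 1:
        raise ValueError(f"exon length must be >= 1, got {length}")
    return length % 3 != 0


def strip_variant_suffix(event_id: str) -> str:
    """Gene symbol of an event id (``MBNL2b`` -> ``MBNL2``)."""
    m = _EVENT_ID_RE.match(event_id)
    if m is None:
        raise ValueError(f"unparseable event id: {event_id!r}")
    return m.group("gene")


@dataclass(frozen=True)
class SpliceEvent:
    """A cassette exon with optional flanking exons (1-based inclusive)."""

    event_id: str
    chrom: str
    skipped_start: int
    skipped_end: int
    dm1_direction: str = "unknown"
    upstream_exon: Optional[Tuple[int, int]] = None
    downstream_exon: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        exon_length(self.skipped_start, self.skipped_end)  # validates
        if self.dm1_direction not in DIRECTIONS:
            raise ValueError(
                f"{self.event_id}: direction must be one of {DIRECTIONS}, "
                f"got {self.dm1_direction!r}"
            )
        for exon in (self.upstream_exon, self.downstream_exon):
            if exon is not None:
                exon_length(*exon)

    @property
    def gene(self) -> str:
        return strip_variant_suffix(self.event_id)

    @property
    def length(self) -> int:
        return exon_length(self.skipped_start, self.skipped_end)

    @property
    def frame_disrupting(self) -> bool:
        return frame_disrupting(self.length)


class EventTable:
    """Ordered collection of :class:`SpliceEvent` with unique ids."""

    def __init__(self, events: Iterable[SpliceEvent]):
        self.events = list(events)
        seen = set()
        for ev in self.events:
            if ev.event_id in seen:
                raise ValueError(f"duplicate event_id: {ev.event_id}")
            seen.add(ev.event_id)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SpliceEvent]:
        return iter(self.events)

    def __getitem__(self, event_id: str) -> SpliceEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)

    @property
    def event_ids(self) -> list[str]:
        return [ev.event_id for ev in self.events]


def count_unique_genes(table: EventTable) -> int:
    """Number of distinct gene symbols, variant suffixes stripped."""
    if len(table) == 0:
        raise ValueError("empty event table")
    return len({ev.gene for ev in table})


def merge_cassette_exons(table: EventTable) -> int:
    """Count unique cassette exons after merging overlapping skipped intervals.

    Skipped exons on the same chromosome whose intervals overlap (identical
    intervals and shared boundaries included) are one exon; events whose
    cassette differs only by a variable 5' or 3' end collapse together.
    Row order does not matter.
    """
    if len(table) == 0:
        raise ValueError("empty event table")
    n_groups = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ev in table:
        by_chrom.setdefault(ev.chrom, []).append((ev.skipped_start, ev.skipped_end))
    for intervals in by_chrom.values():
        intervals.sort()
        current_end = None
        for start, end in intervals:
            if current_end is None or start > current_end:
                n_groups += 1
                current_end = end
            else:
                current_end = max(current_end, end)
    return n_groups


def _parse_coordinates(text: str) -> Tuple[str, int, int]:
    m = _COORD_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed coordinate string: {text!r}")
    return m.group("chrom"), int(m.group("start")), int(m.group("end"))


def load_event_table(path: str | Path) -> EventTable:
    """Read an event TSV (event_id, coordinates, length, dm1_direction).

    Every row's printed length is validated against the 1-based inclusive
    coordinate arithmetic; a mismatch is a parse error naming the row.
    """
    path = Path(path)
    events = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["event_id", "coordinates", "length", "dm1_direction"]
        if header[: len(required)] != required:
            raise ValueError(f"{path}: expected header {required}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            event_id, coords, length_str, direction = fields[:4]
            try:
                chrom, start, end = _parse_coordinates(coords)
                ev = SpliceEvent(event_id, chrom, start, end, direction.lower())
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno} ({event_id}): {exc}") from exc
            if ev.length != int(length_str):
                raise ValueError(
                    f"{path}:{lineno} ({event_id}): printed length {length_str} "
                    f"!= end - start + 1 = {ev.length}"
                )
            events.append(ev)
    if not events:
        raise ValueError(f"{path}: no event rows found")
    return EventTable(events)


def load_dm1_cortex_events() -> EventTable:
    """The packaged table of 34 DM1-relevant developmental splice events.

    Cassette exons in the adult frontal cortex whose inclusion differs both
    between DM1 patients and unaffected adults and between prenatal and
    postnatal healthy donors (hg38 coordinates). Flanking exons are not part
    of the packaged table and are left unset.
    """
    ref = resources.files("fetalsplice.data").joinpath("dm1_cortex_events.tsv")
    with resources.as_file(ref) as path:
        return load_event_table(path)


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write an event TSV in the same four-column format `load_event_table` reads."""
    with Path(path).open("w") as fh:
        fh.write("event_id\tcoordinates\tlength\tdm1_direction\n")
        for ev in table:
            fh.write(
                f"{ev.event_id}\t{ev.chrom}:{ev.skipped_start}-{ev.skipped_end}"
                f"\t{ev.length}\t{ev.dm1_direction}\n"
            )


def write_event_gff(table: EventTable, path: str | Path) -> None:
    """Write MISO-style GFF3 annotation: per event one gene and two isoforms.

    The inclusion isoform carries upstream + cassette + downstream exons, the
    exclusion isoform only the flanks. Requires flanking exons on every event.
    """
    lines = ["##gff-version 3"]
    for ev in table:
        if ev.upstream_exon is None or ev.downstream_exon is None:
            raise ValueError(
                f"{ev.event_id}: flanking exons required to write a GFF annotation"
            )
        up, down = ev.upstream_exon, ev.downstream_exon
        gene_start = min(up[0], ev.skipped_start, down[0])
        gene_end = max(up[1], ev.skipped_end, down[1])
        gid = ev.event_id
        lines.append(
            f"{ev.chrom}\tfetalsplice\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\t"
            f"ID={gid};Name={gid}"
        )
        for iso, exons in (
            ("inclusion", [up, (ev.skipped_start, ev.skipped_end), down]),
            ("exclusion", [up, down]),
        ):
            mrna_id = f"{gid}.{iso}"
            lines.append(
                f"{ev.chrom}\tfetalsplice\tmRNA\t{gene_start}\t{gene_end}\t.\t+\t.\t"
                f"ID={mrna_id};Parent={gid}"
            )
            for i, (s, e) in enumerate(exons, start=1):
                lines.append(
                    f"{ev.chrom}\tfetalsplice\texon\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_gff(path: str | Path) -> EventTable:
    """Read back a GFF3 written by :func:`write_event_gff` (lossless round-trip)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="error"
    )
    events = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = {
            mrna.id: sorted(
                (e.start, e.end) for e in db.children(mrna, featuretype="exon")
            )
            for mrna in db.children(gene, featuretype="mRNA")
        }
        inc = exons.get(f"{gene.id}.inclusion")
        if inc is None or len(inc) != 3:
            raise ValueError(
                f"{gene.id}: inclusion isoform must have exactly 3 exons"
            )
        up, cassette, down = inc
        events.append(
            SpliceEvent(
                gene.id, gene.seqid, cassette[0], cassette[1],
                upstream_exon=up, downstream_exon=down,
            )
        )
    return EventTable(events)
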