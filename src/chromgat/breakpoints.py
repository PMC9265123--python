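"""Reading and normalizing COSMIC-style structural-variant breakpoint tables.

A breakpoint table has one row per chromosomal aberration: a sample name, a
cancer-type label, a mutation type, and the two breakpoints ("Location From",
"Location To") written as ``chrom:start..end``.  Only the chromosome identity
of each breakpoint is used downstream; base-pair coordinates are parsed and
retained for forward compatibility.

Chromosomes live in a fixed 24-node universe: autosomes 1-22, X -> 23,
Y -> 24.  Mitochondrial and unplaced contigs are rejected (and counted as
skips by the reader).
"""

from __future__ import annotations

import csv
import json
import re
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

N_CHROMOSOMES = 24

#: The seven-value mutation vocabulary used by COSMIC structural exports.
MUTATION_TYPES = (
    "inverted orientation",
    "noninverted orientation",
    "inversion",
    "deletion",
    "tandem duplication",
    "insertion",
    "unknown",
)

#: Default logical-field -> column-name mapping for COSMIC-style exports.
DEFAULT_COLUMN_MAP = {
    "sample_id": "Sample name",
    "cancer_type": "Primary site",
    "mutation_type": "Mutation Type",
    "location_from": "Location From",
    "location_to": "Location To",
}


class ColumnMapError(KeyError):
    """A mapped column is missing from the table header."""


class LabelConflictError(ValueError):
    """A sample carries more than one cancer-type label."""


def normalize_chromosome(token: str) -> Optional[int]:
    """Map a chromosome token to its index in 1..24, or ``None`` if rejected.

    ``chr`` prefixes and case are ignored; ``"1"``..``"22"`` map to
    themselves, ``"X"`` -> 23 and ``"Y"`` -> 24.  Anything else (MT, unplaced
    contigs, malformed tokens) is rejected with ``None`` so callers can count
    skips instead of catching exceptions.
    """
    if not token:
        return None
    t = token.strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    t = t.upper()
    if t == "X":
        return 23
    if t == "Y":
        return 24
    if t.isdigit():
        i = int(t)
        if 1 <= i <= 22:
            return i
    return None


@dataclass(frozen=True)
class CRERecord:
    """One chromosomal rearrangement endpoint pair (one aberration).

    ``chrom_from``/``chrom_to`` are indices in 1..24 (X=23, Y=24).
    Interchromosomal aberrations always carry mutation type ``"unknown"``
    (the COSMIC convention); the six typed kinds occur only within one
    chromosome.
    """

    sample_id: str
    cancer_type: str
    chrom_from: int
    chrom_to: int
    mutation_type: str = "unknown"
    pos_from: Optional[int] = None
    pos_to: Optional[int] = None

    def __post_init__(self) -> None:
        for c in (self.chrom_from, self.chrom_to):
            if not 1 <= c <= N_CHROMOSOMES:
                raise ValueError(f"chromosome index {c} outside 1..{N_CHROMOSOMES}")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mutation_type!r}")
        if self.chrom_from != self.chrom_to and self.mutation_type != "unknown":
            raise ValueError(
                "interchromosomal aberrations must have mutation type 'unknown'"
            )

    @property
    def is_intra(self) -> bool:
        return self.chrom_from == self.chrom_to


def classify_rearrangement(record: CRERecord) -> str:
    """Classify one aberration as ``"intra"`` (within one chromosome, a
    self-loop in the graph encoding) or ``"inter"`` (between two)."""
    return "intra" if record.chrom_from == record.chrom_to else "inter"


_LOCATION_RE = re.compile(r"^\s*([^:]+):(\d+)(?:\.\.(\d+))?\s*$")


def parse_location(text: str) -> Optional[tuple[int, int]]:
    """Parse ``chrom:start..end`` into ``(chrom_index, start)``.

    Returns ``None`` when the chromosome token is outside the 24-chromosome
    universe or the string is malformed.  Coordinates are kept 1-based as
    printed.
    """
    m = _LOCATION_RE.match(text or "")
    if m is None:
        return None
    chrom = normalize_chromosome(m.group(1))
    if chrom is None:
        return None
    return chrom, int(m.group(2))


@dataclass
class ReadResult:
    """Records surviving ingestion plus a skip report."""

    records: list[CRERecord]
    n_rows: int = 0
    n_skipped: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def skip_report(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_records": len(self.records),
            "n_skipped": self.n_skipped,
            "skip_reasons": dict(self.skip_reasons),
        }


def _infer_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_breakpoints(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> ReadResult:
    """Read a breakpoint table into :class:`CRERecord` objects.

    Rows whose chromosome token falls outside the 24-node universe (e.g. MT)
    or whose locations do not parse are skipped and counted, never fatal.
    A mapped column missing from the header raises :class:`ColumnMapError`
    naming the column.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    delim = delimiter if delimiter is not None else _infer_delimiter(path)

    result = ReadResult(records=[])
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            return result  # empty file -> empty list
        for logical, col in cmap.items():
            if col not in reader.fieldnames:
                raise ColumnMapError(
                    f"column {col!r} (mapped from {logical!r}) not in header"
                )
        for row in reader:
            result.n_rows += 1
            loc_from = parse_location(row[cmap["location_from"]])
            loc_to = parse_location(row[cmap["location_to"]])
            if loc_from is None or loc_to is None:
                result.n_skipped += 1
                result.skip_reasons["unparseable_location"] = (
                    result.skip_reasons.get("unparseable_location", 0) + 1
                )
                continue
            chrom_from, pos_from = loc_from
            chrom_to, pos_to = loc_to
            mtype = (row[cmap["mutation_type"]] or "unknown").strip().lower()
            if mtype not in MUTATION_TYPES:
                mtype = "unknown"
            if chrom_from != chrom_to:
                # COSMIC reports every interchromosomal event as unknown type.
                mtype = "unknown"
            result.records.append(
                CRERecord(
                    sample_id=row[cmap["sample_id"]].strip(),
                    cancer_type=row[cmap["cancer_type"]].strip(),
                    chrom_from=chrom_from,
                    chrom_to=chrom_to,
                    mutation_type=mtype,
                    pos_from=pos_from,
                    pos_to=pos_to,
                )
            )
    return result


@dataclass
class SampleTable:
    """Mapping from sample_id to (cancer_type, ordered list of records)."""

    samples: "OrderedDict[str, tuple[str, list[CRERecord]]]"

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples.items())

    def labels(self) -> dict[str, str]:
        return {sid: label for sid, (label, _) in self.samples.items()}


def group_by_sample(records: Iterable[CRERecord]) -> SampleTable:
    """Group records by sample, preserving input order within each sample.

    Every sample must carry a single cancer-type label; a conflict raises
    :class:`LabelConflictError` naming the sample.
    """
    samples: OrderedDict[str, tuple[str, list[CRERecord]]] = OrderedDict()
    for rec in records:
        if rec.sample_id not in samples:
            samples[rec.sample_id] = (rec.cancer_type, [rec])
        else:
            label, recs = samples[rec.sample_id]
            if rec.cancer_type != label:
                raise LabelConflictError(
                    f"sample {rec.sample_id!r} has conflicting labels "
                    f"{label!r} and {rec.cancer_type!r}"
                )
            recs.append(rec)
    return SampleTable(samples=samples)


def format_location(chrom: int, pos: Optional[int]) -> str:
    token = {23: "X", 24: "Y"}.get(chrom, str(chrom))
    p = pos if pos is not None else 0
    return f"{token}:{p}..{p}"


def write_breakpoints(
    records: Iterable[CRERecord],
    path: str | Path,
    delimiter: str | None = None,
) -> None:
    """Write records back to the tabular format read by :func:`read_breakpoints`.

    Round-trips: re-reading the written file reproduces identical chromosome
    and type fields (coordinates collapse to their start positions).
    """
    path = Path(path)
    delim = delimiter if delimiter is not None else _infer_delimiter(path)
    cols = DEFAULT_COLUMN_MAP
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(
            [cols["sample_id"], cols["cancer_type"], cols["mutation_type"],
             cols["location_from"], cols["location_to"]]
        )
        for r in records:
            writer.writerow(
                [r.sample_id, r.cancer_type, r.mutation_type,
                 format_location(r.chrom_from, r.pos_from),
                 format_location(r.chrom_to, r.pos_to)]
            )


def write_skip_report(result: ReadResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.skip_report(), indent=2) + "\n")
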