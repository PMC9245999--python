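"""Data model and I/O for Y-STR haplotype tables.

Y-STR alleles are named by repeat count. Microvariant alleles (incomplete
repeat units) carry a decimal suffix, e.g. ``"27.2"`` means 27 full repeats
plus a 2-base partial repeat; the suffix is a nomenclature token, not a
measurement, so designations are stored exactly as an integer pair rather
than as floats. Multi-copy loci (DYS385a/b, DYS527a/b) yield an unordered
pair of designations per male, canonicalized ascending.

The canonical table dialect is tab-delimited: a header row
``SampleID[<tab>PopulationID]<tab><locus>...``, one row per male, multi-copy
cells joined by ``","`` and missing calls written as empty cells.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError, LookupError_, ValidationError

__all__ = [
    "Allele",
    "AlleleCall",
    "LocusDef",
    "Haplotype",
    "HaplotypeTable",
    "MISSING",
    "parse_panel",
    "parse_allele",
    "read_haplotype_table",
    "write_haplotype_table",
    "write_square_matrix",
    "read_square_matrix",
    "load_agcu_y30_panel",
    "adjust_dys389",
]


@dataclass(frozen=True, order=True)
class Allele:
    """One allele designation: integer repeats plus a microvariant suffix.

    ``Allele(27, 2)`` renders as ``"27.2"`` and has numeric value 27.2 for
    ordering and repeat-distance purposes.
    """

    repeats: int
    fractional: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise FormatError(f"negative repeat count: {self.repeats}")
        if not 0 <= self.fractional <= 9:
            raise FormatError(f"fractional part out of range: {self.fractional}")

    @property
    def value(self) -> float:
        return self.repeats + self.fractional / 10.0

    @property
    def is_microvariant(self) -> bool:
        return self.fractional > 0

    def __str__(self) -> str:
        if self.fractional:
            return f"{self.repeats}.{self.fractional}"
        return str(self.repeats)

    @classmethod
    def parse(cls, token: str) -> "Allele":
        token = token.strip()
        head, dot, tail = token.partition(".")
        try:
            repeats = int(head)
            fractional = int(tail) if dot else 0
        except ValueError:
            raise FormatError(f"non-numeric allele designation: {token!r}") from None
        if dot and (len(tail) != 1):
            raise FormatError(f"microvariant suffix must be one digit: {token!r}")
        return cls(repeats, fractional)


@dataclass(frozen=True)
class AlleleCall:
    """The call at one locus in one male: 0 (missing), 1, or 2 designations.

    For copy-number-2 loci the pair is stored sorted ascending so that
    ``"13,14"`` and ``"14,13"`` compare equal.
    """

    values: tuple[Allele, ...] = ()

    @property
    def missing(self) -> bool:
        return not self.values

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(sorted(self.values)))

    def render(self, pair_sep: str = ",") -> str:
        return pair_sep.join(str(a) for a in self.values)

    def __str__(self) -> str:
        return self.render()


MISSING = AlleleCall()


@dataclass(frozen=True)
class LocusDef:
    """A locus in the typing panel.

    copy_number is 2 for multi-copy loci amplified from duplicated regions.
    mutability_class is annotation only and never enters any computation.
    """

    name: str
    copy_number: int = 1
    mutability_class: str = "moderate"

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("locus name must be nonempty")
        if self.copy_number not in (1, 2):
            raise FormatError(
                f"{self.name}: copy_number must be 1 or 2, got {self.copy_number}"
            )


@dataclass(frozen=True)
class Haplotype:
    """One male's joint profile over a fixed panel."""

    sample_id: str
    population_id: str
    calls: dict[str, AlleleCall]

    def call(self, locus: str) -> AlleleCall:
        return self.calls[locus]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Haplotype):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.population_id == other.population_id
            and self.calls == other.calls
        )

    def __hash__(self) -> int:
        return hash((self.sample_id, self.population_id,
                     tuple(sorted(self.calls.items(), key=lambda kv: kv[0]))))


DEFAULT_POPULATION = "pop0"


@dataclass
class HaplotypeTable:
    """Samples x loci matrix of allele calls; the universal exchange object."""

    panel: list[LocusDef]
    rows: list[Haplotype] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise FormatError("duplicate locus name in panel")
        seen: set[str] = set()
        for row in self.rows:
            if row.sample_id in seen:
                raise FormatError(f"duplicate sample id: {row.sample_id}")
            seen.add(row.sample_id)
            if set(row.calls) != set(names):
                raise ValidationError(
                    f"sample {row.sample_id}: calls do not cover the panel"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.rows)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def locus(self, name: str) -> LocusDef:
        for l in self.panel:
            if l.name == name:
                return l
        raise LookupError_(name)

    @property
    def population_ids(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row.population_id not in out:
                out.append(row.population_id)
        return out

    def population(self, pop_id: str) -> list[Haplotype]:
        rows = [r for r in self.rows if r.population_id == pop_id]
        if not rows:
            raise LookupError_(pop_id)
        return rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeTable):
            return NotImplemented
        return self.panel == other.panel and self.rows == other.rows


def parse_panel(stream: IO[str] | str | os.PathLike) -> list[LocusDef]:
    """Read a two-column (name, copy_number) TSV into a locus panel.

    Order is preserved; duplicate names and copy numbers outside {1, 2}
    are format errors. A third optional column carries the mutability
    annotation.
    """
    with _ensure_text_stream(stream, "r") as fh:
        panel: list[LocusDef] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"panel line {lineno}: expected 2 columns")
            name = parts[0].strip()
            try:
                copy_number = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"panel line {lineno}: copy_number not an integer"
                ) from None
            if name in seen:
                raise FormatError(f"panel line {lineno}: duplicate locus {name}")
            seen.add(name)
            extra = {"mutability_class": parts[2].strip()} if len(parts) > 2 else {}
            panel.append(LocusDef(name, copy_number, **extra))
    return panel


def parse_allele(text: str, copy_number: int, pair_sep: str = ",") -> AlleleCall:
    """Parse one cell: '' (missing), 'R', 'R.f', or 'A,B' for copy number 2.

    A reader option accepts '-' as the pair separator for compatibility with
    common haplotype-table exports (pass pair_sep='-').
    """
    text = text.strip()
    if not text:
        return MISSING
    tokens = [t for t in text.split(pair_sep)]
    if len(tokens) != copy_number:
        raise FormatError(
            f"expected {copy_number} designation(s), got {len(tokens)}: {text!r}"
        )
    return AlleleCall(tuple(Allele.parse(t) for t in tokens))


def read_haplotype_table(
    stream: IO[str] | str | os.PathLike,
    panel: Sequence[LocusDef],
    pair_sep: str = ",",
) -> HaplotypeTable:
    """Read a delimited haplotype table against a known panel.

    The header must start with SampleID, optionally followed by
    PopulationID, then one column per panel locus (extra columns are
    ignored). Round-trips with :func:`write_haplotype_table` after
    canonicalization.
    """
    panel = list(panel)
    with _ensure_text_stream(stream, "r") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError("empty haplotype table") from None
        if not header or header[0] != "SampleID":
            raise FormatError("first column must be SampleID")
        has_pop = len(header) > 1 and header[1] == "PopulationID"
        locus_cols = {name: i for i, name in enumerate(header)}
        for locus in panel:
            if locus.name not in locus_cols:
                raise FormatError(f"missing locus column: {locus.name}")
        rows: list[Haplotype] = []
        for record in reader:
            if not record or not any(c.strip() for c in record):
                continue
            sample_id = record[0]
            population_id = record[1] if has_pop else DEFAULT_POPULATION
            calls = {
                locus.name: parse_allele(
                    record[locus_cols[locus.name]], locus.copy_number, pair_sep
                )
                for locus in panel
            }
            rows.append(Haplotype(sample_id, population_id, calls))
    return HaplotypeTable(panel, rows)


def write_haplotype_table(table: HaplotypeTable, stream: IO[str] | str | os.PathLike) -> None:
    """Write the canonical tab-delimited dialect (see module docstring)."""
    with _ensure_text_stream(stream, "w") as fh:
        names = table.locus_names
        fh.write("\t".join(["SampleID", "PopulationID", *names]) + "\n")
        for row in table.rows:
            cells = [row.sample_id, row.population_id]
            cells.extend(row.calls[name].render() for name in names)
            fh.write("\t".join(cells) + "\n")


def write_square_matrix(
    labels: Sequence[str],
    matrix: np.ndarray,
    stream: IO[str] | str | os.PathLike,
    format: str = "csv",
) -> None:
    """Write a symmetric zero-diagonal matrix as CSV or square PHYLIP.

    The PHYLIP variant (first line = taxon count) is readable by standard
    distance-matrix consumers.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if len(set(labels)) != n:
        raise ValidationError("labels must be unique")
    if matrix.shape != (n, n):
        raise ValidationError(f"matrix shape {matrix.shape} != ({n}, {n})")
    if np.max(np.abs(matrix - matrix.T)) > 1e-9:
        raise ValidationError("matrix asymmetric beyond 1e-9")
    if np.max(np.abs(np.diag(matrix))) > 1e-9:
        raise ValidationError("matrix diagonal must be zero")
    if format not in ("csv", "phylip"):
        raise ValidationError(f"unknown matrix format: {format}")
    with _ensure_text_stream(stream, "w") as fh:
        if format == "csv":
            fh.write("," + ",".join(labels) + "\n")
            for i, lab in enumerate(labels):
                fh.write(lab + "," + ",".join(f"{v:.6f}" for v in matrix[i]) + "\n")
        else:
            fh.write(f"{n}\n")
            width = max(len(l) for l in labels)
            for i, lab in enumerate(labels):
                row = " ".join(f"{v:.6f}" for v in matrix[i])
                fh.write(f"{lab:<{width}} {row}\n")


def read_square_matrix(stream: IO[str] | str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read back a labeled square matrix written in the CSV dialect."""
    with _ensure_text_stream(stream, "r") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        labels = header[1:]
        rows = []
        for record in reader:
            if not record:
                continue
            rows.append([float(v) for v in record[1:]])
    return labels, np.asarray(rows, dtype=float)


def load_agcu_y30_panel() -> list[LocusDef]:
    """The bundled 30-amplicon forensic panel (26 single-copy loci plus the
    multi-copy DYS385a/b and DYS527a/b, i.e. 28 locus definitions)."""
    ref = resources.files("ystrpop").joinpath("data/agcu_y30_panel.tsv")
    with ref.open("r") as fh:
        return parse_panel(fh)


def adjust_dys389(
    table: HaplotypeTable,
    locus_i: str = "DYS389I",
    locus_ii: str = "DYS389II",
) -> HaplotypeTable:
    """Subtract DYS389I from DYS389II in every row, returning a new table.

    The DYS389II amplicon physically contains DYS389I, so repeat-difference
    distance models are distorted unless the shared stretch is removed.
    Off by default throughout the package; apply explicitly before distance
    computation when wanted. Rows where either call is missing keep
    DYS389II missing.
    """
    names = table.locus_names
    if locus_i not in names or locus_ii not in names:
        raise LookupError_(f"{locus_i}/{locus_ii} not both in panel")
    new_rows = []
    for row in table.rows:
        a, b = row.calls[locus_i], row.calls[locus_ii]
        calls = dict(row.calls)
        if a.missing or b.missing:
            calls[locus_ii] = MISSING
        else:
            diff = b.values[0].repeats - a.values[0].repeats
            if diff < 0:
                raise ValidationError(
                    f"sample {row.sample_id}: {locus_ii} < {locus_i}"
                )
            calls[locus_ii] = AlleleCall((Allele(diff, b.values[0].fractional),))
        new_rows.append(replace(row, calls=calls))
    return HaplotypeTable(list(table.panel), new_rows, table.provenance)


class _StreamContext:
    """Uniform 'path or open file' handling; never closes a caller's stream."""

    def __init__(self, stream, mode: str):
        self._stream = stream
        self._mode = mode
        self._own = isinstance(stream, (str, os.PathLike))
        self._fh: IO[str] | None = None

    def __enter__(self) -> IO[str]:
        if self._own:
            self._fh = open(self._stream, self._mode, encoding="utf-8", newline="")
            return self._fh
        if isinstance(self._stream, io.TextIOBase) or hasattr(self._stream, "read") or hasattr(self._stream, "write"):
            return self._stream
        raise TypeError(f"expected path or text stream, got {type(self._stream)}")

    def __exit__(self, *exc) -> None:
        if self._fh is not None:
            self._fh.close()


def _ensure_text_stream(stream, mode: str) -> _StreamContext:
    return _StreamContext(stream, mode)
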