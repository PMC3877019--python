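"""Readers and writers for the text formats the pipeline touches.

Supported formats:

* expression matrices as TSV (first column probe id, one column per sample)
  and as GEO series-matrix text (``!``-prefixed metadata lines around a
  ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` block);
* probe annotation tables (probe id, gene symbol, transcript accession,
  optional control flag) as TSV;
* gene sets, one symbol per line or ``name<TAB>symbol``;
* binned per-gene tables, round-trippable including the set of genes dropped
  by the duplicate-consistency filter.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from orthobin.errors import FormatError

ACCESSION_RE = re.compile(r"^[A-Z]{2}_\d+$")
CURATED_PREFIX = "NM_"

_MISSING_DEFAULT = "NA"


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; idempotent."""
    return symbol.strip().upper()


@dataclass
class ExpressionMatrix:
    """Log2 intensities for one dataset: probes x samples, NaN = missing."""

    dataset_id: str
    species: str
    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = _first_duplicate(self.probe_ids)
            raise FormatError(f"duplicate probe id {dupes!r} in {self.dataset_id}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id {dupes!r} in {self.dataset_id}")
        if not self.sample_ids:
            raise FormatError(f"dataset {self.dataset_id} has no samples")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        all_missing = np.all(np.isnan(self.values), axis=1)
        if all_missing.any():
            probe = self.probe_ids[int(np.flatnonzero(all_missing)[0])]
            raise FormatError(f"probe {probe!r} has no non-missing values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    gene_symbol: str
    transcript_accession: str
    is_control: bool = False

    @property
    def has_curated_accession(self) -> bool:
        return self.transcript_accession.startswith(CURATED_PREFIX)


@dataclass
class AnnotationTable:
    """Probe -> (gene symbol, transcript accession, control flag) mapping."""

    records: dict[str, ProbeRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe_id, rec in self.records.items():
            if rec.probe_id != probe_id:
                raise FormatError(f"annotation key {probe_id!r} != record {rec.probe_id!r}")
            acc = rec.transcript_accession
            if acc and not ACCESSION_RE.match(acc):
                raise FormatError(f"malformed accession {acc!r} for probe {probe_id!r}")

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.records

    def __getitem__(self, probe_id: str) -> ProbeRecord:
        return self.records[probe_id]

    def __iter__(self) -> Iterator[ProbeRecord]:
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneSet:
    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise FormatError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "symbols", frozenset(normalize_symbol(s) for s in self.symbols))


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    raise ValueError("no duplicate present")


def read_expression_tsv(
    path: str | Path,
    dataset_id: str,
    species: str,
    missing_token: str = _MISSING_DEFAULT,
) -> ExpressionMatrix:
    """Read a probes-x-samples TSV with a header row into an ExpressionMatrix.

    The first column holds probe ids; every other column is a sample. Cells
    equal to *missing_token* (or empty) become NaN; anything else must parse
    as a float.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header has no sample columns")
    sample_ids = [h.strip() for h in header[1:]]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, found {len(cells)}"
            )
        probe_ids.append(cells[0].strip())
        row: list[float] = []
        for col, cell in zip(sample_ids, cells[1:]):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                row.append(math.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}"
                ) from None
        rows.append(row)
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"{path}: duplicate probe id {_first_duplicate(probe_ids)!r}")
    if not probe_ids:
        raise FormatError(f"{path}: no data rows")
    return ExpressionMatrix(dataset_id, species, probe_ids, sample_ids, np.array(rows))


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(
    path: str | Path,
    dataset_id: str | None = None,
    species: str = "",
    log2_transform: bool = False,
    missing_token: str = "null",
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Parse a GEO series-matrix text file.

    Returns the expression matrix plus the ``!``-prefixed metadata as a
    key -> values mapping. Values are taken as deposited (assumed log2);
    with ``log2_transform=True`` linear-scale deposits are log2-transformed
    (non-positive entries become missing).
    """
    path = Path(path)
    metadata: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    for raw in path.read_text().splitlines():
        if raw.startswith(_TABLE_BEGIN):
            in_table, saw_begin = True, True
            continue
        if raw.startswith(_TABLE_END):
            in_table, saw_end = False, True
            continue
        if in_table:
            if raw.strip():
                table_lines.append(raw)
        elif raw.startswith("!"):
            key, _, value = raw[1:].partition("\t")
            metadata.setdefault(key, []).append(value.strip().strip('"'))
    if not saw_begin or not saw_end:
        raise FormatError(f"{path}: missing series-matrix table delimiters")
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table")

    header = [c.strip().strip('"') for c in table_lines[0].split("\t")]
    sample_ids = header[1:]
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(table_lines[1:], start=2):
        cells = [c.strip().strip('"') for c in line.split("\t")]
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: ragged table row {lineno} "
                f"({len(cells)} cells, expected {len(header)})"
            )
        probe_ids.append(cells[0])
        row = []
        for cell in cells[1:]:
            if cell in ("", missing_token, "NA", "NaN"):
                row.append(math.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} in table row {lineno}"
                    ) from None
        rows.append(row)
    values = np.array(rows, dtype=float)
    if log2_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(values > 0, np.log2(values), np.nan)
    if dataset_id is None:
        accession = metadata.get("Series_geo_accession", [""])[0]
        dataset_id = accession or path.stem
    matrix = ExpressionMatrix(dataset_id, species, probe_ids, sample_ids, values)
    return matrix, metadata


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a probe annotation TSV.

    Expected columns: probe_id, gene_symbol, transcript_accession and an
    optional is_control column. Symbols are uppercased and stripped; a
    non-empty accession that does not match ``XX_digits`` triggers a warning
    and is treated as empty.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"probe_id", "gene_symbol", "transcript_accession"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    records: dict[str, ProbeRecord] = {}
    for row in frame.itertuples(index=False):
        probe_id = str(row.probe_id).strip()
        if probe_id in records:
            raise FormatError(f"{path}: duplicate probe_id {probe_id!r}")
        accession = str(row.transcript_accession).strip()
        if accession and not ACCESSION_RE.match(accession):
            warnings.warn(
                f"{path}: malformed accession {accession!r} for probe "
                f"{probe_id!r}; treating as empty",
                stacklevel=2,
            )
            accession = ""
        is_control = False
        if "is_control" in frame.columns:
            is_control = str(getattr(row, "is_control")).strip().lower() in (
                "1",
                "true",
                "yes",
            )
        records[probe_id] = ProbeRecord(
            probe_id=probe_id,
            gene_symbol=normalize_symbol(str(row.gene_symbol)),
            transcript_accession=accession,
            is_control=is_control,
        )
    return AnnotationTable(records)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe_id\tgene_symbol\ttranscript_accession\tis_control\n")
        for rec in table:
            fh.write(
                f"{rec.probe_id}\t{rec.gene_symbol}\t{rec.transcript_accession}\t"
                f"{int(rec.is_control)}\n"
            )


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets: either one symbol per line or ``name<TAB>symbol`` rows.

    A single-column file becomes one set named after the file stem.
    """
    path = Path(path)
    grouped: dict[str, set[str]] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            name, symbol = line.split("\t", 1)
            grouped.setdefault(name.strip(), set()).add(normalize_symbol(symbol))
        else:
            grouped.setdefault(path.stem, set()).add(normalize_symbol(line))
    if not grouped:
        raise FormatError(f"{path}: no gene-set entries")
    return {name: GeneSet(name, frozenset(symbols)) for name, symbols in grouped.items()}


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path,
                         missing_token: str = _MISSING_DEFAULT) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe_id, row in zip(matrix.probe_ids, matrix.values):
            cells = [missing_token if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(probe_id + "\t" + "\t".join(cells) + "\n")


def write_binned_table(binned, path: str | Path,
                       provenance: Mapping[str, str] | None = None) -> None:
    """Serialize a BinnedDataset to TSV; ``read_binned_table`` reverses it.

    Metadata (dataset id, species, cutoffs, dropped genes) rides in ``#``
    header lines so the gene table itself stays a plain four-plus-column TSV.
    """
    with Path(path).open("w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}={value}\n")
        fh.write(f"# dataset_id={binned.dataset_id}\n")
        fh.write(f"# species={binned.species}\n")
        fh.write(f"# cutoffs={','.join(repr(float(c)) for c in binned.cutoffs)}\n")
        fh.write(
            "# dropped_inconsistent="
            + ",".join(sorted(binned.dropped_inconsistent))
            + "\n"
        )
        fh.write(
            "gene_symbol\tmean_log2\tpercentile\tbin\tn_probes\thas_curated_accession\n"
        )
        for symbol in sorted(binned.genes):
            g = binned.genes[symbol]
            fh.write(
                f"{g.gene_symbol}\t{g.mean_log2!r}\t{g.percentile!r}\t{g.bin}\t"
                f"{g.n_probes}\t{int(g.has_curated_accession)}\n"
            )


def read_binned_table(path: str | Path):
    """Read a TSV written by :func:`write_binned_table` back to a BinnedDataset."""
    from orthobin.binning import BinnedDataset, Cutoffs, GeneSummary

    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    genes: dict[str, GeneSummary] = {}
    cutoffs = Cutoffs()
    lines = path.read_text().splitlines()
    for raw in lines:
        if raw.startswith("# "):
            key, _, value = raw[2:].partition("=")
            meta[key] = value
            continue
        if header is None:
            header = raw.split("\t")
            expected = ["gene_symbol", "mean_log2", "percentile", "bin"]
            if header[: len(expected)] != expected:
                raise FormatError(f"{path}: unexpected binned-table header {header!r}")
            if "cutoffs" in meta:
                cutoffs = Cutoffs(*(float(c) for c in meta["cutoffs"].split(",")))
            continue
        cells = raw.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}: ragged binned-table row {cells!r}")
        row = dict(zip(header, cells))
        symbol = row["gene_symbol"]
        if symbol in genes:
            raise FormatError(f"{path}: duplicate gene {symbol!r}")
        genes[symbol] = GeneSummary(
            gene_symbol=symbol,
            mean_log2=float(row["mean_log2"]),
            percentile=float(row["percentile"]),
            bin=row["bin"],
            n_probes=int(row.get("n_probes", 1)),
            has_curated_accession=bool(int(row.get("has_curated_accession", 0))),
            cutoffs=cutoffs,
        )
    if header is None:
        raise FormatError(f"{path}: no header row")
    dropped = {s for s in meta.get("dropped_inconsistent", "").split(",") if s}
    return BinnedDataset(
        dataset_id=meta.get("dataset_id", path.stem),
        species=meta.get("species", ""),
        genes=genes,
        dropped_inconsistent=dropped,
        cutoffs=cutoffs,
    )
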