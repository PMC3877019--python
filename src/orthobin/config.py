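"""Pipeline configuration: dataset registry, cutoffs, references, outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from orthobin.binning import Cutoffs
from orthobin.errors import ConfigError, FormatError


@dataclass
class DatasetConfig:
    dataset_id: str
    species: str
    path: Path
    annotation: Path
    format: str = "tsv"  # "tsv" | "series_matrix"
    log2_transform: bool = False
    missing_token: str = "NA"

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        self.annotation = Path(self.annotation)
        if self.format not in ("tsv", "series_matrix"):
            raise ConfigError(
                f"dataset {self.dataset_id!r}: unknown format {self.format!r}"
            )


@dataclass
class PipelineConfig:
    datasets: list[DatasetConfig]
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    references: dict[str, str] = field(default_factory=dict)
    gene_sets: list[Path] = field(default_factory=list)
    output_dir: Path = Path("orthobin_out")
    seed: int = 0

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.gene_sets = [Path(p) for p in self.gene_sets]
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"dataset ids are not unique: {ids}")
        for species, ref_id in self.references.items():
            if ref_id not in ids:
                raise ConfigError(
                    f"reference {ref_id!r} for species {species!r} is not a "
                    f"configured dataset"
                )

    def dataset(self, dataset_id: str) -> DatasetConfig:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise ConfigError(f"unknown dataset id {dataset_id!r}")

    def validate_paths(self) -> None:
        """Collect every missing input file before aborting."""
        problems = []
        for d in self.datasets:
            if not d.path.exists():
                problems.append(f"dataset {d.dataset_id!r}: missing file {d.path}")
            if not d.annotation.exists():
                problems.append(
                    f"dataset {d.dataset_id!r}: missing annotation {d.annotation}"
                )
        for p in self.gene_sets:
            if not p.exists():
                problems.append(f"missing gene-set file {p}")
        if problems:
            raise ConfigError("; ".join(problems))

    def content_hash(self) -> str:
        payload = {
            "datasets": [
                {
                    "dataset_id": d.dataset_id,
                    "species": d.species,
                    "path": str(d.path),
                    "annotation": str(d.annotation),
                    "format": d.format,
                    "log2_transform": d.log2_transform,
                    "missing_token": d.missing_token,
                }
                for d in self.datasets
            ],
            "cutoffs": list(self.cutoffs),
            "references": self.references,
            "gene_sets": [str(p) for p in self.gene_sets],
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config; relative paths resolve from it."""
    path = Path(path)
    try:
        payload = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse config ({exc})") from exc
    if not isinstance(payload, dict) or "datasets" not in payload:
        raise ConfigError(f"{path}: config must be a mapping with a 'datasets' list")
    root = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else root / q

    datasets = []
    for entry in payload["datasets"]:
        try:
            datasets.append(
                DatasetConfig(
                    dataset_id=entry["dataset_id"],
                    species=entry["species"],
                    path=resolve(entry["path"]),
                    annotation=resolve(entry["annotation"]),
                    format=entry.get("format", "tsv"),
                    log2_transform=bool(entry.get("log2_transform", False)),
                    missing_token=entry.get("missing_token", "NA"),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: dataset entry missing key {exc}") from exc
    cut = payload.get("cutoffs", [10, 50, 90])
    if len(cut) != 3:
        raise ConfigError(f"{path}: cutoffs must be three numbers, got {cut}")
    return PipelineConfig(
        datasets=datasets,
        cutoffs=Cutoffs(*(float(c) for c in cut)),
        references=dict(payload.get("references", {})),
        gene_sets=[resolve(p) for p in payload.get("gene_sets", [])],
        output_dir=resolve(payload.get("output_dir", "orthobin_out")),
        seed=int(payload.get("seed", 0)),
    )
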