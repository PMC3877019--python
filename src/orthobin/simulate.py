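"""Two-species synthetic expression data with known ground truth.

The generator plants, on top of a shared log-normal-style baseline:

* species-specific genes — far inside the top decile of one species and the
  bottom decile of the other;
* decoy specific-pattern genes that must be rejected downstream, either for
  lacking a curated (NM_) accession or for carrying an inconsistent
  duplicate probe;
* genes whose bins differ between the species by a configured distance;
* consistent duplicate probes (small jitter) and inconsistent duplicates
  (displaced to a non-adjacent bin);
* per-array affine distortions and i.i.d. log2 noise.

Everything is reproducible from the config seed, and the returned truth
object records exactly which genes belong to which planted category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from orthobin.binning import BINS, Cutoffs, assign_bins, percentile_rank
from orthobin.errors import ConfigError
from orthobin.io import (
    AnnotationTable,
    ExpressionMatrix,
    ProbeRecord,
    write_annotation,
    write_expression_tsv,
)

# bin centers (percentile) used when placing shifted genes
_BIN_CENTER = {"VL": 5.0, "L": 30.0, "M": 70.0, "H": 95.0}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 1000
    n_samples_a: int = 7
    n_samples_b: int = 3
    n_specific_a: int = 0
    n_specific_b: int = 3
    n_noncurated_decoys: int = 0
    n_inconsistent_decoys: int = 0
    n_shifted_pairs: int = 0
    shift_bins: int = 2
    frac_duplicate_probes: float = 0.0
    frac_inconsistent_duplicates: float = 0.0
    frac_noncurated: float = 0.0
    noise_sd: float = 0.0
    array_distortion: tuple[tuple[float, float], tuple[float, float]] | None = (
        (0.8, 1.2),
        (-1.0, 1.0),
    )
    species_a: str = "human"
    species_b: str = "mouse"
    plant_margin: float = 2.0
    duplicate_jitter_sd: float = 0.02
    n_controls: int = 8
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("n_genes must be at least 10")
        if min(self.n_samples_a, self.n_samples_b) < 1:
            raise ConfigError("each species needs at least one sample")
        for name in ("n_specific_a", "n_specific_b", "n_noncurated_decoys",
                     "n_inconsistent_decoys", "n_shifted_pairs", "n_controls"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("frac_duplicate_probes", "frac_inconsistent_duplicates",
                     "frac_noncurated"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 1 <= self.shift_bins <= 3:
            raise ConfigError("shift_bins must be between 1 and 3")
        decile = self.n_genes // 10
        decoys = self.n_noncurated_decoys + self.n_inconsistent_decoys
        load_top_a, load_top_b = self.n_specific_a, self.n_specific_b + decoys
        if max(load_top_a, load_top_b) > decile:
            raise ConfigError(
                f"planted extreme genes exceed decile capacity "
                f"({max(load_top_a, load_top_b)} > {decile})"
            )
        if self._n_planted() > self.n_genes // 2:
            raise ConfigError("planted categories exceed half the gene count")

    def _n_planted(self) -> int:
        n = self.n_genes
        return (
            self.n_specific_a + self.n_specific_b + self.n_noncurated_decoys
            + self.n_inconsistent_decoys + self.n_shifted_pairs
            + round(self.frac_duplicate_probes * n)
            + round(self.frac_inconsistent_duplicates * n)
            + round(self.frac_noncurated * n)
        )


@dataclass
class SyntheticTruth:
    species_a: str
    species_b: str
    specific_genes_a: set[str] = field(default_factory=set)
    specific_genes_b: set[str] = field(default_factory=set)
    shifted_genes: dict[str, tuple[str, str]] = field(default_factory=dict)
    inconsistent_genes: set[str] = field(default_factory=set)
    noncurated_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        categories = [
            self.specific_genes_a,
            self.specific_genes_b,
            set(self.shifted_genes),
            self.inconsistent_genes,
            self.noncurated_genes,
        ]
        for i, x in enumerate(categories):
            for y in categories[i + 1:]:
                if x & y:
                    raise ConfigError(
                        f"planted categories overlap: {sorted(x & y)[:3]}"
                    )

    def specific_genes(self, species: str) -> set[str]:
        if species == self.species_a:
            return self.specific_genes_a
        if species == self.species_b:
            return self.specific_genes_b
        raise ConfigError(f"unknown species {species!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species_a": self.species_a,
            "species_b": self.species_b,
            "specific_genes_a": sorted(self.specific_genes_a),
            "specific_genes_b": sorted(self.specific_genes_b),
            "shifted_genes": {s: list(v) for s, v in sorted(self.shifted_genes.items())},
            "inconsistent_genes": sorted(self.inconsistent_genes),
            "noncurated_genes": sorted(self.noncurated_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            species_a=payload["species_a"],
            species_b=payload["species_b"],
            specific_genes_a=set(payload["specific_genes_a"]),
            specific_genes_b=set(payload["specific_genes_b"]),
            shifted_genes={
                s: (v[0], v[1]) for s, v in payload["shifted_genes"].items()
            },
            inconsistent_genes=set(payload["inconsistent_genes"]),
            noncurated_genes=set(payload["noncurated_genes"]),
        )


@dataclass
class GeneratedData:
    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    annotation_a: AnnotationTable
    annotation_b: AnnotationTable
    truth: SyntheticTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the standard TSVs plus truth and config JSON; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression_a": outdir / "expression_a.tsv",
            "expression_b": outdir / "expression_b.tsv",
            "annotation_a": outdir / "annotation_a.tsv",
            "annotation_b": outdir / "annotation_b.tsv",
            "truth": outdir / "truth.json",
            "config": outdir / "config.json",
        }
        write_expression_tsv(self.matrix_a, paths["expression_a"])
        write_expression_tsv(self.matrix_b, paths["expression_b"])
        write_annotation(self.annotation_a, paths["annotation_a"])
        write_annotation(self.annotation_b, paths["annotation_b"])
        self.truth.to_json(paths["truth"])
        cfg = asdict(self.config)
        paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
        return paths


def _mouse_style(symbol: str) -> str:
    """Mouse nomenclature analogue: only the first letter capitalized."""
    return symbol.capitalize()


def generate(config: SyntheticConfig) -> GeneratedData:
    """Generate the two-species dataset pair described by *config*."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    symbols = [f"GENE{i:05d}" for i in range(n)]
    base = rng.normal(config.baseline_mean, config.baseline_sd, n)

    n_dup = round(config.frac_duplicate_probes * n)
    n_inc = round(config.frac_inconsistent_duplicates * n)
    n_noncur = round(config.frac_noncurated * n)

    perm = list(rng.permutation(n))
    take = lambda k: [perm.pop() for _ in range(k)]  # noqa: E731
    idx_spec_a = take(config.n_specific_a)
    idx_spec_b = take(config.n_specific_b)
    idx_dec_nc = take(config.n_noncurated_decoys)
    idx_dec_inc = take(config.n_inconsistent_decoys)
    idx_shift = take(config.n_shifted_pairs)
    idx_inc = take(n_inc)
    idx_dup = take(n_dup)
    idx_noncur = take(n_noncur)

    means_a = base.copy()
    means_b = base.copy()
    hi, lo = base.max(), base.min()
    margin = config.plant_margin

    def plant_extreme(indices: list[int], high_in_a: bool, lane: int) -> None:
        # spaced offsets keep planted values distinct
        for k, i in enumerate(indices):
            delta = margin + 0.05 * (lane + 1) + 0.01 * (k + 1)
            if high_in_a:
                means_a[i], means_b[i] = hi + delta, lo - delta
            else:
                means_a[i], means_b[i] = lo - delta, hi + delta

    plant_extreme(idx_spec_a, high_in_a=True, lane=0)
    plant_extreme(idx_spec_b, high_in_a=False, lane=1)
    plant_extreme(idx_dec_nc, high_in_a=False, lane=2)
    plant_extreme(idx_dec_inc, high_in_a=False, lane=3)

    # shifted genes: source bin in species A, displaced shift_bins down in B
    source_bin = "H" if config.shift_bins == 3 else "M"
    target_bin = BINS[max(0, {"M": 2, "H": 3}[source_bin] - config.shift_bins)]
    designed_shift = {}
    for k, i in enumerate(idx_shift):
        means_a[i] = float(np.quantile(base, _BIN_CENTER[source_bin] / 100.0)) + 0.001 * (k + 1)
        means_b[i] = float(np.quantile(base, _BIN_CENTER[target_bin] / 100.0)) + 0.001 * (k + 1)
        designed_shift[symbols[i]] = (source_bin, target_bin)

    truth = SyntheticTruth(
        species_a=config.species_a,
        species_b=config.species_b,
        specific_genes_a={symbols[i] for i in idx_spec_a},
        specific_genes_b={symbols[i] for i in idx_spec_b},
        shifted_genes=designed_shift,
        inconsistent_genes={symbols[i] for i in idx_inc} | {symbols[i] for i in idx_dec_inc},
        noncurated_genes={symbols[i] for i in idx_noncur} | {symbols[i] for i in idx_dec_nc},
    )
    _verify_planting(config, truth, symbols, means_a, means_b,
                     idx_spec_a, idx_spec_b, idx_dec_nc, idx_dec_inc, idx_shift)

    noncurated = {symbols[i] for i in idx_noncur} | {symbols[i] for i in idx_dec_nc}

    probes_a, values_a, ann_a = _assemble_probes(
        config, rng, symbols, means_a, base, species_tag="A",
        duplicate_idx=set(idx_dup), inconsistent_idx=set(idx_inc),
        noncurated=noncurated, style=str,
    )
    probes_b, values_b, ann_b = _assemble_probes(
        config, rng, symbols, means_b, base, species_tag="B",
        duplicate_idx=set(idx_dup),
        inconsistent_idx=set(idx_inc) | set(idx_dec_inc),
        noncurated=noncurated, style=_mouse_style,
    )

    matrix_a = _hybridize(config, rng, probes_a, values_a, config.n_samples_a,
                          dataset_id="synthetic_a", species=config.species_a)
    matrix_b = _hybridize(config, rng, probes_b, values_b, config.n_samples_b,
                          dataset_id="synthetic_b", species=config.species_b)
    return GeneratedData(matrix_a, matrix_b, ann_a, ann_b, truth, config)


def _verify_planting(config, truth, symbols, means_a, means_b,
                     idx_spec_a, idx_spec_b, idx_dec_nc, idx_dec_inc, idx_shift):
    """Check designed bins are realized on the noiseless gene means."""
    cutoffs = Cutoffs()
    bins_a = assign_bins(percentile_rank(means_a), cutoffs)
    bins_b = assign_bins(percentile_rank(means_b), cutoffs)
    for i in idx_spec_a:
        if bins_a[i] != "H" or bins_b[i] != "VL":
            raise ConfigError("over-committed planting: specific gene misplaced")
    for i in idx_spec_b + idx_dec_nc + idx_dec_inc:
        if bins_b[i] != "H" or bins_a[i] != "VL":
            raise ConfigError("over-committed planting: specific gene misplaced")
    for i in idx_shift:
        designed = truth.shifted_genes[symbols[i]]
        if (bins_a[i], bins_b[i]) != designed:
            raise ConfigError(
                f"over-committed planting: shifted gene realized "
                f"{(bins_a[i], bins_b[i])}, designed {designed}"
            )


def _assemble_probes(config, rng, symbols, means, base, species_tag,
                     duplicate_idx, inconsistent_idx, noncurated, style):
    """Build the probe list (primaries, duplicates, controls) and annotation."""
    q_low = float(np.quantile(base, 0.02))
    q_high = float(np.quantile(base, 0.97))
    median = float(np.median(base))

    probe_ids: list[str] = []
    probe_means: list[float] = []
    records: dict[str, ProbeRecord] = {}

    def accession(i: int) -> str:
        prefix = "XR_" if symbols[i] in noncurated else "NM_"
        return f"{prefix}{100000 + i}"

    for i, symbol in enumerate(symbols):
        pid = f"{species_tag}_P{i:06d}"
        probe_ids.append(pid)
        probe_means.append(means[i])
        records[pid] = ProbeRecord(pid, style(symbol), accession(i))
        if i in duplicate_idx:
            did = f"{pid}_D1"
            probe_ids.append(did)
            probe_means.append(means[i] + float(rng.normal(0.0, config.duplicate_jitter_sd)))
            records[did] = ProbeRecord(did, style(symbol), accession(i))
        if i in inconsistent_idx:
            did = f"{pid}_DX"
            probe_ids.append(did)
            # displace the duplicate to a non-adjacent bin
            probe_means.append(q_low if means[i] >= median else q_high)
            records[did] = ProbeRecord(did, style(symbol), accession(i))

    for c in range(config.n_controls):
        pid = f"{species_tag}_CTRL{c:03d}"
        probe_ids.append(pid)
        probe_means.append(float(rng.normal(4.0, 1.0)))
        records[pid] = ProbeRecord(pid, "", "", is_control=True)

    return probe_ids, np.array(probe_means), AnnotationTable(records)


def _hybridize(config, rng, probe_ids, probe_means, n_samples, dataset_id, species):
    """Turn per-probe true means into replicate arrays with distortion+noise."""
    n_probes = probe_means.size
    X = np.empty((n_probes, n_samples))
    for j in range(n_samples):
        scale, offset = 1.0, 0.0
        if config.array_distortion is not None:
            (s_lo, s_hi), (o_lo, o_hi) = config.array_distortion
            scale = float(rng.uniform(s_lo, s_hi))
            offset = float(rng.uniform(o_lo, o_hi))
        col = scale * probe_means + offset
        if config.noise_sd > 0:
            col = col + rng.normal(0.0, config.noise_sd, n_probes)
        X[:, j] = col
    return ExpressionMatrix(dataset_id, species, list(probe_ids), _sample_ids(dataset_id, n_samples), X)


def _sample_ids(dataset_id: str, n_samples: int) -> list[str]:
    return [f"{dataset_id}_s{j + 1}" for j in range(n_samples)]


def evaluate_recovery(calls, truth: SyntheticTruth, species: str) -> tuple[float, float]:
    """Precision and recall of specificity calls against the planted truth."""
    called = {c.gene_symbol for c in calls}
    expected = truth.specific_genes(species)
    tp = len(called & expected)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(expected) if expected else 1.0
    return precision, recall
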