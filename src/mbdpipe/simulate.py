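"""Seeded synthetic data with planted truth for end-to-end verification.

The generator emulates the study design the pipeline targets: five sample
groups (8 normal, 12 tumor-adjacent, and 13/12/7 low/high/very-high-risk
tumors), 100-bp binned enrichment counts with negative-binomial noise, and
per-group differential-expression tables.  Methylation shifts are planted as
multiplicative fold changes on the expected count, confined to a contiguous
bin run inside one named region of one gene and to the tumor samples of the
affected risk groups; normals and adjacents always sit at baseline.
Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (DEFAULT_BIN_SIZE, GeneModel, GeneRegions, RegionClass,
                         assign_bins_to_regions, partition_gene_regions)
from .cdmp import make_label
from .coverage import BinMatrix, SampleRecord
from .dmr import Dmr, DmrCallParams

#: Cohort sizes of the study design the generator emulates.
DEFAULT_SAMPLES_PER_GROUP = {"N": 8, "ADJ": 12, "L": 13, "H": 12, "VH": 7}
DEFAULT_PLANTED_DEGS = {"L": (20, 10), "H": (30, 20), "VH": (15, 25)}

GENE_PITCH = 210_000     # >= 204 kb so adjacent distal windows cannot collide
CHROM_MARGIN = 220_000


@dataclass(frozen=True)
class PlantedDmr:
    """One planted methylation shift with resolved genomic coordinates."""

    gene_id: str
    region: RegionClass
    direction: str                       # "hyper" | "hypo" (relative to tumor)
    chrom: str
    start: int
    end: int
    n_bins: int
    shift: float                         # fold change > 1; applied as 1/shift for hypo
    affected_groups: tuple[str, ...]


@dataclass
class SimTruth:
    """Machine-readable ground truth for recovery scoring."""

    dmrs: list[PlantedDmr] = field(default_factory=list)
    cdmp_labels: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    deg_up: dict[str, list[str]] = field(default_factory=dict)
    deg_down: dict[str, list[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "dmrs": [
                {**asdict(d), "region": d.region.value,
                 "affected_groups": list(d.affected_groups)}
                for d in self.dmrs
            ],
            "cdmp_labels": {
                f"{g}|{tg}": sorted(labels)
                for (g, tg), labels in sorted(self.cdmp_labels.items())
            },
            "deg_up": {g: sorted(v) for g, v in sorted(self.deg_up.items())},
            "deg_down": {g: sorted(v) for g, v in sorted(self.deg_down.items())},
        }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 50
    n_chroms: int = 2
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_GROUP))
    baseline_mean: float = 5.0           # expected raw reads per 100-bp bin
    dispersion: float = 0.1              # NB: var = m + dispersion * m^2
    bin_size: int = DEFAULT_BIN_SIZE
    n_planted_dmrs: int = 0              # auto-generated plants (ignored if planted set)
    planted: list[PlantedDmr] | None = None
    plant_shift: float = 4.0
    planted_degs: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_DEGS))
    low_expr_fraction: float = 0.05      # non-planted genes flagged cpm<1 in >150 samples
    adj_attenuation: float = 0.0         # fraction of the plant effect leaking into ADJ
    gene_span_range: tuple[int, int] = (5_000, 20_000)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chroms < 1:
            raise ValueError("n_genes and n_chroms must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(v < 1 for v in self.samples_per_group.values()):
            raise ValueError("every group needs at least one sample")


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping gene territories on synthetic chromosomes.

    Genes sit on a fixed pitch of 210 kb so the 100-kb distal windows of
    neighbours can never overlap; spans are drawn from ``gene_span_range``
    (>= 5 kb keeps every genic region non-empty) with random strands.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per_chrom = -(-config.n_genes // config.n_chroms)
    models: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n_here = min(per_chrom, config.n_genes - gi)
        chrom_sizes[chrom] = CHROM_MARGIN + per_chrom * GENE_PITCH
        for j in range(n_here):
            base = 110_000 + j * GENE_PITCH
            span = int(rng.integers(config.gene_span_range[0],
                                    config.gene_span_range[1] + 1))
            if base + span + 101_000 > chrom_sizes[chrom]:
                raise ValueError("infeasible packing; use larger chromosomes")
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            name = f"gene{gi:04d}"
            if strand == "+":
                models.append(GeneModel(name, chrom, "+", base, base + span))
            else:
                models.append(GeneModel(name, chrom, "-", base + span, base))
    return models, chrom_sizes


def partition_all(models: Sequence[GeneModel],
                  chrom_sizes: Mapping[str, int]) -> list[GeneRegions]:
    return [partition_gene_regions(m, chrom_sizes[m.chrom]) for m in models]


# ---------------------------------------------------------------------------
# Plants


def make_planted_dmrs(
    regions: Sequence[GeneRegions],
    rng: np.random.Generator,
    n_plants: int,
    shift: float = 4.0,
    params: DmrCallParams = DmrCallParams(),
    region_cycle: Sequence[RegionClass] = (RegionClass.TSS, RegionClass.DISTAL,
                                           RegionClass.GENIC, RegionClass.TES),
    group_cycle: Sequence[str] = ("L", "H", "VH"),
) -> list[PlantedDmr]:
    """Auto-generate detectable plants: one per chosen gene, cycling regions,
    directions and affected risk groups; runs span the minimum length plus
    one to three extra bins."""
    if n_plants > len(regions):
        raise ValueError("more plants than genes")
    chosen = rng.choice(len(regions), size=n_plants, replace=False)
    plants = []
    for k, idx in enumerate(sorted(chosen.tolist())):
        gr = regions[idx]
        region = region_cycle[k % len(region_cycle)]
        direction = "hyper" if k % 2 == 0 else "hypo"
        group = group_cycle[k % len(group_cycle)]
        plant = plant_in_region(gr, region, direction, group, rng,
                                shift=shift, params=params)
        if plant is not None:
            plants.append(plant)
    return plants


def plant_in_region(
    gr: GeneRegions,
    region: RegionClass,
    direction: str,
    group: str,
    rng: np.random.Generator,
    shift: float = 4.0,
    n_bins: int | None = None,
    params: DmrCallParams = DmrCallParams(),
) -> PlantedDmr | None:
    """Place one plant on a random contiguous bin run inside the named region."""
    bins = np.sort(assign_bins_to_regions(gr, params.bin_size)[region])
    if n_bins is None:
        n_bins = params.min_run(region) + int(rng.integers(1, 4))
    if bins.size < n_bins:
        return None
    offset = int(rng.integers(0, bins.size - n_bins + 1))
    run = bins[offset:offset + n_bins]
    return PlantedDmr(
        gene_id=gr.gene_id, region=region, direction=direction, chrom=gr.chrom,
        start=int(run[0]) * params.bin_size,
        end=(int(run[-1]) + 1) * params.bin_size,
        n_bins=n_bins, shift=shift, affected_groups=(group,),
    )


def _implied_cdmp_labels(plants: Sequence[PlantedDmr]) -> dict[tuple[str, str], set[str]]:
    """Labels forced by the plants: TSS state joined with each partner state,
    per (gene, affected tumor group)."""
    state: dict[tuple[str, str], dict[RegionClass, str]] = {}
    for p in plants:
        for g in p.affected_groups:
            state.setdefault((p.gene_id, g), {})[p.region] = p.direction
    labels: dict[tuple[str, str], set[str]] = {}
    for key, by_region in state.items():
        tss = by_region.get(RegionClass.TSS)
        if tss is None:
            continue
        labs = {make_label(tss, r, st) for r, st in by_region.items()
                if r != RegionClass.TSS}
        if labs:
            labels[key] = labs
    return labels


# ---------------------------------------------------------------------------
# Counts


def sample_names(samples_per_group: Mapping[str, int]) -> list[SampleRecord]:
    records = []
    for group in ("N", "ADJ", "L", "H", "VH"):
        for i in range(samples_per_group.get(group, 0)):
            records.append(SampleRecord(sample_id=f"{group}{i + 1:02d}", group=group))
    return records


def simulate_methylation_counts(
    regions: Sequence[GeneRegions],
    config: SimulationConfig,
    plants: Sequence[PlantedDmr],
    rng: np.random.Generator,
) -> tuple[BinMatrix, SimTruth, list[SampleRecord]]:
    """Draw negative-binomial counts for every region bin of every gene.

    Expected count is ``baseline_mean`` everywhere, multiplied by the
    plant's fold change (1/shift for hypo) in the planted bins for samples
    of the affected tumor groups; ADJ receives ``adj_attenuation`` of the
    effect (0 by default) and N never shifts.  Counts come from the
    gamma-Poisson mixture so the dispersion knob is exact.
    """
    records = sample_names(config.samples_per_group)
    samples = [r.sample_id for r in records]
    group_of = {r.sample_id: r.group for r in records}
    bs = config.bin_size

    bins_by_chrom: dict[str, set[int]] = {}
    for gr in regions:
        rb = assign_bins_to_regions(gr, bs)
        dest = bins_by_chrom.setdefault(gr.chrom, set())
        for arr in rb.values():
            dest.update(arr.tolist())

    chrom_data = {}
    for chrom in sorted(bins_by_chrom):
        bins = np.array(sorted(bins_by_chrom[chrom]), dtype=np.int64)
        mean = np.full((bins.size, len(samples)), float(config.baseline_mean))
        for p in plants:
            if p.chrom != chrom:
                continue
            lo = np.searchsorted(bins, p.start // bs)
            hi = np.searchsorted(bins, (p.end - 1) // bs, side="right")
            effect = p.shift if p.direction == "hyper" else 1.0 / p.shift
            for j, s in enumerate(samples):
                g = group_of[s]
                if g in p.affected_groups:
                    mean[lo:hi, j] *= effect
                elif g == "ADJ" and config.adj_attenuation > 0:
                    mean[lo:hi, j] *= effect ** config.adj_attenuation
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean * config.dispersion)
        counts = rng.poisson(lam).astype(float)
        chrom_data[chrom] = (bins, counts)

    matrix = BinMatrix(bs, samples, chrom_data)
    truth = SimTruth(dmrs=list(plants), cdmp_labels=_implied_cdmp_labels(plants))
    return matrix, truth, records


# ---------------------------------------------------------------------------
# Expression


def simulate_de_table(
    models: Sequence[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], dict[str, list[str]], dict[str, list[str]]]:
    """Fabricate one DE table per tumor group with planted up/down DEGs.

    Planted DEGs get p < 0.05 and |log2fc| drawn in (0.6, 3); everything
    else gets p > 0.05 and |log2fc| <= 0.5.  A ``low_expr_fraction`` of the
    non-planted genes is flagged low-expressed (> 150 samples below 0
    log2-cpm) so the exclusion filter is exercised.
    """
    genes = [m.gene_id.upper() for m in models]
    tables: dict[str, pd.DataFrame] = {}
    up_truth: dict[str, list[str]] = {}
    down_truth: dict[str, list[str]] = {}
    for group in ("L", "H", "VH"):
        n_up, n_down = config.planted_degs.get(group, (0, 0))
        if n_up + n_down > len(genes):
            raise ValueError("more planted DEGs than genes")
        perm = rng.permutation(len(genes))
        up_idx = set(perm[:n_up].tolist())
        down_idx = set(perm[n_up:n_up + n_down].tolist())
        rest = perm[n_up + n_down:]
        n_low = int(round(config.low_expr_fraction * rest.size))
        low_idx = set(rest[:n_low].tolist())

        log2fc = np.empty(len(genes))
        p_value = np.empty(len(genes))
        n_low_samples = np.empty(len(genes), dtype=int)
        for i in range(len(genes)):
            if i in up_idx:
                log2fc[i] = rng.uniform(0.6, 3.0)
                p_value[i] = rng.uniform(1e-6, 0.049)
            elif i in down_idx:
                log2fc[i] = -rng.uniform(0.6, 3.0)
                p_value[i] = rng.uniform(1e-6, 0.049)
            else:
                log2fc[i] = rng.uniform(-0.5, 0.5)
                p_value[i] = rng.uniform(0.051, 1.0)
            n_low_samples[i] = (rng.integers(151, 300) if i in low_idx
                                else rng.integers(0, 151))
        tables[group] = pd.DataFrame({
            "gene_id": genes, "log2fc": np.round(log2fc, 6),
            "p_value": np.round(p_value, 8), "n_low_expr_samples": n_low_samples,
        })
        up_truth[group] = sorted(genes[i] for i in up_idx)
        down_truth[group] = sorted(genes[i] for i in down_idx)
    return tables, up_truth, down_truth


# ---------------------------------------------------------------------------
# Whole datasets and fixture files


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    models: list[GeneModel]
    chrom_sizes: dict[str, int]
    regions: list[GeneRegions]
    records: list[SampleRecord]
    matrix: BinMatrix
    truth: SimTruth
    de_tables: dict[str, pd.DataFrame]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator from one seed: genome, plants, counts, DE tables."""
    rng = np.random.default_rng(config.seed)
    models, chrom_sizes = simulate_genome(config, rng)
    regions = partition_all(models, chrom_sizes)
    if config.planted is not None:
        plants = list(config.planted)
    elif config.n_planted_dmrs:
        plants = make_planted_dmrs(regions, rng, config.n_planted_dmrs,
                                   shift=config.plant_shift)
    else:
        plants = []
    matrix, truth, records = simulate_methylation_counts(regions, config, plants, rng)
    de_tables, up, down = simulate_de_table(models, config, rng)
    truth.deg_up, truth.deg_down = up, down
    return SimulatedDataset(config, models, chrom_sizes, regions, records,
                            matrix, truth, de_tables)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete fixture tree and return its checksum manifest.

    Emits annotation BED12, chrom.sizes, a sample sheet with totals, one
    bedGraph per sample, one DE table per tumor group, the truth JSON, and a
    manifest with sha256 checksums of every file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)

    bed = out_dir / "annotation.bed"
    with open(bed, "w") as fh:
        for m in ds.models:
            start, end = min(m.tss, m.tes), max(m.tss, m.tes)
            fh.write(f"{m.chrom}\t{start}\t{end}\t{m.gene_id}\t0\t{m.strand}\t"
                     f"{start}\t{end}\t0\t1\t{end - start},\t0,\n")

    sizes = out_dir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom in sorted(ds.chrom_sizes):
            fh.write(f"{chrom}\t{ds.chrom_sizes[chrom]}\n")

    sheet = out_dir / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\tgroup\ttotal_reads\n")
        for r in ds.records:
            fh.write(f"{r.sample_id}\t{r.group}\t"
                     f"{int(ds.matrix.total_reads[r.sample_id])}\n")

    bg_paths = ds.matrix.write_bedgraphs(out_dir / "bedgraphs")

    de_paths = {}
    for group, table in ds.de_tables.items():
        p = out_dir / f"de_{group}.tsv"
        table.to_csv(p, sep="\t", index=False)
        de_paths[group] = p

    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(ds.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    files = [bed, sizes, sheet, truth_path, *de_paths.values(), *bg_paths.values()]
    manifest = {
        "seed": config.seed,
        "n_genes": config.n_genes,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Recovery scoring


def score_recovery(
    truth: SimTruth,
    called: Sequence[Dmr],
    risk_groups: Sequence[str] = ("L", "H", "VH"),
) -> dict:
    """Score called DMRs against the planted truth.

    A call matches a plant when gene, region and direction agree, the call's
    tumor group is among the plant's affected groups, and the intervals
    overlap.  Only calls from single-risk-group comparisons are scored (the
    pooled ALL group dilutes single-group plants and has no clean truth).
    Recall is over plants (recovered by a call versus either control);
    precision over scored calls.
    """
    scored = [c for c in called
              if c.comparison is not None and c.comparison[0] in risk_groups]
    recovered = set()
    n_true_calls = 0
    n_mismatch = 0
    for c in scored:
        hit = False
        near_miss = False
        for i, p in enumerate(truth.dmrs):
            if (c.gene_id != p.gene_id or c.comparison[0] not in p.affected_groups
                    or not (c.start < p.end and p.start < c.end)):
                continue
            if c.region == p.region and c.direction == p.direction:
                recovered.add(i)
                hit = True
            else:
                near_miss = True
        if hit:
            n_true_calls += 1
        elif near_miss:
            n_mismatch += 1
    n_plants = len(truth.dmrs)
    return {
        "n_plants": n_plants,
        "n_called": len(scored),
        "n_recovered": len(recovered),
        "n_direction_region_mismatch": n_mismatch,
        "recall": len(recovered) / n_plants if n_plants else float("nan"),
        "precision": n_true_calls / len(scored) if scored else float("nan"),
    }
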