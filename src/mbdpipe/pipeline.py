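"""End-to-end orchestration: annotation -> coverage -> DMRs -> CDMPs -> expression.

Every stage reads files and writes files into the run directory, so a stage
can be rerun in isolation from the cached outputs of the previous one, and
two runs from identical inputs produce byte-identical output trees.
Progress is logged to stderr only; no timestamps enter any output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import cdmp as cdmp_mod
from . import coverage as cov
from . import expression as expr
from .dmr import Dmr, DmrCallParams, call_gene_dmrs, dmr_mean_profile, \
    gene_region_status, union_across_controls, write_dmr_bed

log = logging.getLogger("mbdpipe")

DEFAULT_COMPARISONS = [(tg, ctrl) for tg in ("ALL", "L", "H", "VH")
                       for ctrl in ("N", "ADJ", "N+ADJ")]


@dataclass
class RunConfig:
    annotation: str
    chrom_sizes: str
    sample_sheet: str
    out_dir: str
    coverage_dir: str | None = None
    coverage_matrix: str | None = None
    annotation_format: str | None = None
    de_tables: Mapping[str, str] = field(default_factory=dict)
    comparisons: Sequence[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COMPARISONS))
    dmr_params: DmrCallParams = field(default_factory=DmrCallParams)
    deg_p_threshold: float = expr.DEG_P_THRESHOLD
    deg_min_abs_log2fc: float = expr.DEG_MIN_ABS_LOG2FC
    max_low_expr_samples: int = expr.MAX_LOW_EXPR_SAMPLES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "dmr_params" in raw:
            raw["dmr_params"] = DmrCallParams(**raw["dmr_params"])
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        missing = []
        for name in ("annotation", "chrom_sizes", "sample_sheet"):
            if not Path(getattr(self, name)).exists():
                missing.append(f"{name}: {getattr(self, name)}")
        if self.coverage_dir is None and self.coverage_matrix is None:
            missing.append("coverage_dir or coverage_matrix must be set")
        for src in (self.coverage_dir, self.coverage_matrix):
            if src is not None and not Path(src).exists():
                missing.append(f"coverage input: {src}")
        for g, p in self.de_tables.items():
            if not Path(p).exists():
                missing.append(f"de_tables[{g}]: {p}")
        if missing:
            raise FileNotFoundError("missing inputs: " + "; ".join(missing))
        if not self.comparisons:
            raise ValueError("empty comparison plan")


def _comp_tag(tg: str, ctrl: str) -> str:
    return f"{tg}_vs_{ctrl.replace('+', '')}"


# ---------------------------------------------------------------------------
# Stages


def stage_regions(config: RunConfig, out_dir: Path) -> list[ann.GeneRegions]:
    models = ann.load_gene_models(config.annotation, config.annotation_format)
    selected = ann.select_unique_transcripts(models)
    sizes = ann.read_chrom_sizes(config.chrom_sizes)
    regions = [ann.partition_gene_regions(m, sizes[m.chrom]) for m in selected]
    ann.write_region_table(regions, out_dir / "regions.tsv")
    log.info("regions: %d transcripts -> %d genes", len(models), len(selected))
    return regions


def load_matrix(config: RunConfig, records: Sequence[cov.SampleRecord]) -> cov.BinMatrix:
    bin_size = config.dmr_params.bin_size
    totals = {r.sample_id: r.total_reads for r in records
              if r.total_reads is not None}
    if len(totals) != len(records):
        totals = None  # fall back to sums over the matrix itself
    if config.coverage_matrix:
        return cov.BinMatrix.from_matrix_tsv(config.coverage_matrix, bin_size,
                                             totals=totals)
    cov_dir = Path(config.coverage_dir)
    paths = {}
    for r in records:
        for cand in (cov_dir / f"{r.sample_id}.bedGraph",
                     cov_dir / f"{r.sample_id}.bedGraph.gz"):
            if cand.exists():
                paths[r.sample_id] = cand
                break
        else:
            raise FileNotFoundError(f"no bedGraph for sample {r.sample_id} "
                                    f"in {cov_dir}")
    return cov.BinMatrix.from_bedgraphs(paths, bin_size, totals=totals)


def stage_dmrs(
    regions: Sequence[ann.GeneRegions],
    matrix: cov.BinMatrix,
    by_group: Mapping[str, Sequence[str]],
    config: RunConfig,
    out_dir: Path,
) -> dict[tuple[str, str], list[Dmr]]:
    """Call DMRs for every planned comparison; write BEDs, statuses, profiles."""
    params = config.dmr_params
    dmrs_by_comp: dict[tuple[str, str], list[Dmr]] = {}
    status_rows = []
    region_order = (ann.RegionClass.DISTAL, ann.RegionClass.TSS,
                    ann.RegionClass.GENIC, ann.RegionClass.TES)
    for tg, ctrl in config.comparisons:
        tumor_ids = cov.resolve_group(tg, by_group)
        control_ids = cov.resolve_group(ctrl, by_group)
        calls: list[Dmr] = []
        for gr in regions:
            calls.extend(call_gene_dmrs(gr, matrix, (tumor_ids, control_ids),
                                        params, comparison=(tg, ctrl)))
        dmrs_by_comp[(tg, ctrl)] = calls
        tag = _comp_tag(tg, ctrl)
        write_dmr_bed(calls, out_dir / f"dmrs_{tag}.bed")
        by_gene_region: dict[tuple[str, str], list[Dmr]] = {}
        for d in calls:
            by_gene_region.setdefault((d.gene_id, d.region.value), []).append(d)
        for gr in regions:
            for r in region_order:
                ds = by_gene_region.get((gr.gene_id, r.value), [])
                st = gene_region_status(ds, gr.gene_id, r)
                if st != "none":
                    status_rows.append((gr.gene_id, r.value, tg, ctrl, st))
        if calls:
            prof = dmr_mean_profile(calls, matrix, by_group)
            pdf = pd.DataFrame(prof)
            pdf.insert(0, "offset_bp", np.arange(-len(pdf) // 2, len(pdf) // 2)
                       * matrix.bin_size)
            pdf.to_csv(out_dir / f"profile_{tag}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        log.info("dmrs: %s vs %s -> %d DMRs", tg, ctrl, len(calls))
    pd.DataFrame(status_rows, columns=["gene_id", "region", "tumor_group",
                                       "control", "status"]) \
        .to_csv(out_dir / "statuses.tsv", sep="\t", index=False)
    return dmrs_by_comp


def stage_cdmp(out_dir: Path) -> pd.DataFrame:
    """Classify CDMPs from the cached statuses.tsv and regions.tsv."""
    statuses = pd.read_csv(out_dir / "statuses.tsv", sep="\t")
    regions = ann.read_region_table(out_dir / "regions.tsv")

    assignments: list[cdmp_mod.CdmpAssignment] = []
    for (tg, ctrl), sub in statuses.groupby(["tumor_group", "control"], sort=True):
        per_gene: dict[str, dict[ann.RegionClass, str]] = {}
        for row in sub.itertuples(index=False):
            per_gene.setdefault(row.gene_id, {})[ann.RegionClass(row.region)] = row.status
        assignments.extend(cdmp_mod.classify_cdmp(per_gene, (tg, ctrl)))

    rows = [(a.gene_id, a.comparison[0], a.comparison[1], label)
            for a in assignments for label in sorted(a.labels)]
    pd.DataFrame(rows, columns=["gene_id", "tumor_group", "control", "label"]) \
        .sort_values(["label", "tumor_group", "control", "gene_id"]) \
        .to_csv(out_dir / "cdmp_assignments.tsv", sep="\t", index=False)

    counts = cdmp_mod.summarize_pattern_counts(assignments)
    counts.to_csv(out_dir / "pattern_counts.tsv", sep="\t", index=False)

    # overlap tests within each partner region, over union gene sets
    gene_sets = cdmp_mod.label_gene_sets(assignments)
    testable = _testable_universe(regions)
    frames = []
    for region in cdmp_mod.PARTNER_REGIONS:
        code = cdmp_mod.PARTNER_CODE[region]
        sets = {}
        for label in cdmp_mod.CDMP_LABELS:
            if label[2] != code:
                continue
            union = set()
            for genes in gene_sets[label].values():
                union |= genes
            sets[label] = union
        universe = testable[region]
        sets = {l: s & universe for l, s in sets.items()}
        df = cdmp_mod.pairwise_overlap_tests(sets, universe)
        if not df.empty:
            frames.append(df)
    overlaps = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["label_a", "label_b", "universe",
                                           "size_a", "size_b", "overlap",
                                           "p_value", "log10_p"]))
    overlaps.to_csv(out_dir / "overlaps.tsv", sep="\t", index=False,
                    float_format="%.6g")
    log.info("cdmp: %d assignments, %d overlap tests", len(assignments),
             len(overlaps))
    return counts


def _testable_universe(regions: Sequence[ann.GeneRegions]
                       ) -> dict[ann.RegionClass, set[str]]:
    """Genes with testable bins in both TSS and the partner region."""
    out = {r: set() for r in cdmp_mod.PARTNER_REGIONS}
    for gr in regions:
        bins = ann.assign_bins_to_regions(gr)
        if not bins[ann.RegionClass.TSS].size:
            continue
        for r in cdmp_mod.PARTNER_REGIONS:
            if bins[r].size:
                out[r].add(gr.gene_id)
    return out


def stage_mean_matrix(
    regions: Sequence[ann.GeneRegions],
    matrix: cov.BinMatrix,
    by_group: Mapping[str, Sequence[str]],
    out_dir: Path,
) -> None:
    mm = cdmp_mod.group_region_mean_matrix(matrix, regions, by_group)
    mm.to_csv(out_dir / "mean_matrix.tsv", sep="\t", float_format="%.6g")


def stage_expression(config: RunConfig, out_dir: Path) -> dict:
    """Cross-tabulate DEGs with the cached CDMP assignments."""
    asg = pd.read_csv(out_dir / "cdmp_assignments.tsv", sep="\t")
    label_sets: dict[str, dict[str, set[str]]] = {l: {} for l in cdmp_mod.CDMP_LABELS}
    for row in asg.itertuples(index=False):
        label_sets[row.label].setdefault(row.tumor_group, set()).add(
            str(row.gene_id).upper())

    deg_sets: dict[str, expr.DegSet] = {}
    universe: set[str] = set()
    for group, path in sorted(config.de_tables.items()):
        table = expr.load_de_table(path, group)
        kept = expr.filter_low_expression(table, config.max_low_expr_samples)
        universe |= set(kept["gene_id"])
        deg_sets[group] = expr.flag_degs(kept, group, config.deg_p_threshold,
                                         config.deg_min_abs_log2fc)
    crosstab = expr.cross_tabulate(deg_sets, label_sets, universe)
    crosstab.to_csv(out_dir / "expression_crosstab.tsv", sep="\t", index=False)

    venn_rows = []
    for label in cdmp_mod.CDMP_LABELS:
        union = set()
        for genes in label_sets[label].values():
            union |= genes
        if not union:
            continue
        uniq = expr.risk_unique_degs(deg_sets, restrict_to=union)
        for tg in sorted(uniq):
            venn_rows.append((label, tg, len(uniq[tg]),
                              ";".join(sorted(uniq[tg]))))
    pd.DataFrame(venn_rows, columns=["label", "tumor_group", "n_unique", "genes"]) \
        .to_csv(out_dir / "risk_unique_degs.tsv", sep="\t", index=False)

    summary = {
        "n_expression_genes": len(universe),
        "deg_counts": {g: {"up": len(d.up), "down": len(d.down)}
                       for g, d in sorted(deg_sets.items())},
    }
    log.info("expression: %d genes, %d groups", len(universe), len(deg_sets))
    return summary


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    The summary JSON records parameters, per-stage gene counts, DMR counts
    per comparison, the 12 pattern counts, and (when DE tables are given)
    the expression cross-tab headline numbers.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    try:
        regions = stage_regions(config, out_dir)
    except Exception as exc:
        fail("regions", exc)
    try:
        records = cov.read_sample_sheet(config.sample_sheet)
        by_group = cov.group_samples(records)
        pd.DataFrame([(r.sample_id, r.group,
                       r.total_reads if r.total_reads is not None else "")
                      for r in records],
                     columns=["sample_id", "group", "total_reads"]) \
            .to_csv(out_dir / "samples_resolved.tsv", sep="\t", index=False)
        matrix = load_matrix(config, records)
    except Exception as exc:
        fail("coverage", exc)
    try:
        dmrs = stage_dmrs(regions, matrix, by_group, config, out_dir)
        stage_mean_matrix(regions, matrix, by_group, out_dir)
    except Exception as exc:
        fail("dmr", exc)
    try:
        counts = stage_cdmp(out_dir)
    except Exception as exc:
        fail("cdmp", exc)
    expr_summary = None
    if config.de_tables:
        try:
            expr_summary = stage_expression(config, out_dir)
        except Exception as exc:
            fail("expression", exc)

    any_counts = counts[(counts["tumor_group"] == "ANY")]
    summary = {
        "parameters": {
            "dmr": {f.name: getattr(config.dmr_params, f.name)
                    for f in fields(DmrCallParams)},
            "deg_p_threshold": config.deg_p_threshold,
            "deg_min_abs_log2fc": config.deg_min_abs_log2fc,
            "max_low_expr_samples": config.max_low_expr_samples,
            "seed": config.seed,
        },
        "n_genes": len(regions),
        "n_samples": len(records),
        "samples_per_group": {g: len(s) for g, s in sorted(by_group.items())},
        "dmr_counts": {_comp_tag(tg, ctrl): len(calls)
                       for (tg, ctrl), calls in sorted(dmrs.items())},
        "pattern_counts": {row.label: int(row.n_genes)
                           for row in any_counts.itertuples(index=False)},
    }
    if expr_summary is not None:
        summary["expression"] = expr_summary
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    generate_report(out_dir)
    return out_dir


def generate_report(run_dir: str | Path) -> Path:
    """Render a markdown report from a completed run directory."""
    run_dir = Path(run_dir)
    required = ["summary.json", "pattern_counts.tsv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing: {missing}")
    with open(run_dir / "summary.json") as fh:
        summary = json.load(fh)
    counts = pd.read_csv(run_dir / "pattern_counts.tsv", sep="\t")

    lines = ["# Methylation pattern analysis report", ""]
    lines.append(f"Genes analyzed: {summary['n_genes']}; "
                 f"samples: {summary['n_samples']} "
                 f"({summary['samples_per_group']}).")
    lines.append("")
    lines.append("## DMR counts per comparison")
    lines.append("")
    total_dmrs = sum(summary["dmr_counts"].values())
    if total_dmrs == 0:
        lines.append("No DMRs were called in any comparison.")
    else:
        lines.append("| comparison | n DMRs |")
        lines.append("|---|---|")
        for comp, n in sorted(summary["dmr_counts"].items()):
            lines.append(f"| {comp} | {n} |")
    lines.append("")
    lines.append("## Genes per collaborative pattern (any tumor group, either control)")
    lines.append("")
    lines.append("| pattern | n genes |")
    lines.append("|---|---|")
    any_rows = counts[counts["tumor_group"] == "ANY"]
    for row in any_rows.itertuples(index=False):
        lines.append(f"| {row.label} | {row.n_genes} |")
    lines.append("")
    if (run_dir / "overlaps.tsv").exists():
        ov = pd.read_csv(run_dir / "overlaps.tsv", sep="\t")
        if not ov.empty:
            lines.append("## Pattern gene-set overlaps (hypergeometric)")
            lines.append("")
            lines.append("| A | B | overlap | log10 p |")
            lines.append("|---|---|---|---|")
            for row in ov.itertuples(index=False):
                lines.append(f"| {row.label_a} | {row.label_b} | {row.overlap} "
                             f"| {row.log10_p:.3g} |")
            lines.append("")
    if (run_dir / "expression_crosstab.tsv").exists():
        ct = pd.read_csv(run_dir / "expression_crosstab.tsv", sep="\t")
        nz = ct[ct["n_labeled"] > 0]
        lines.append("## Differentially expressed genes per pattern")
        lines.append("")
        lines.append("| pattern | tumor group | labeled | DEG | up | down |")
        lines.append("|---|---|---|---|---|---|")
        for row in nz.itertuples(index=False):
            lines.append(f"| {row.label} | {row.tumor_group} | {row.n_labeled} "
                         f"| {row.n_deg} | {row.n_up} | {row.n_down} |")
        lines.append("")
    else:
        lines.append("_No differential-expression tables were provided; "
                     "the expression section is omitted._")
        lines.append("")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
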