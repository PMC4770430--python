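"""Collaborative differential methylation patterns (CDMPs) and set overlaps.

A CDMP is a joint label of a gene's TSS methylation state (S1 hyper / S0
hypo) with the state of one partner region: Distal (D), Genic (G) or TES
(E), each hyper (1) or hypo (0) — twelve TSS-anchored labels in all (S1D1,
S1G1, S1E1, S1D0, S1G0, S1E0, S0D1, S0G1, S0E1, S0D0, S0G0, S0E0).  Genes
whose TSS (or partner) status mixes directions across runs ("both") are
excluded from the single-direction classes and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .annotation import GeneRegions, RegionClass, assign_bins_to_regions
from .coverage import BinMatrix

PARTNER_CODE = {RegionClass.DISTAL: "D", RegionClass.GENIC: "G", RegionClass.TES: "E"}
PARTNER_REGIONS = tuple(PARTNER_CODE)
STATE_CODE = {"hyper": "1", "hypo": "0"}

#: The twelve TSS-anchored labels, TSS state major, partner region minor.
CDMP_LABELS = tuple(
    f"S{s}{PARTNER_CODE[r]}{p}"
    for s in ("1", "0")
    for r in PARTNER_REGIONS
    for p in ("1", "0")
)


def make_label(tss_state: str, partner_region: RegionClass, partner_state: str) -> str:
    return f"S{STATE_CODE[tss_state]}{PARTNER_CODE[partner_region]}{STATE_CODE[partner_state]}"


@dataclass(frozen=True)
class CdmpAssignment:
    gene_id: str
    comparison: tuple[str, str]
    labels: frozenset[str]


@dataclass(frozen=True)
class OverlapTestResult:
    set_a_label: str
    set_b_label: str
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float
    log10_p: float


def classify_cdmp(
    statuses: Mapping[str, Mapping[RegionClass, str]],
    comparison: tuple[str, str],
) -> list[CdmpAssignment]:
    """Label each gene from its per-region DMR statuses for one comparison.

    ``statuses`` maps gene -> region -> one of {hyper, hypo, both, none}.
    Only genes with a clean hyper or hypo TSS status receive labels; one
    label is emitted per partner region with a clean status.
    """
    out = []
    for gene_id, by_region in statuses.items():
        tss = by_region.get(RegionClass.TSS, "none")
        if tss not in ("hyper", "hypo"):
            continue
        labels = set()
        for region in PARTNER_REGIONS:
            st = by_region.get(region, "none")
            if st in ("hyper", "hypo"):
                labels.add(make_label(tss, region, st))
        if labels:
            out.append(CdmpAssignment(gene_id=gene_id, comparison=comparison,
                                      labels=frozenset(labels)))
    return out


def summarize_pattern_counts(
    assignments: Iterable[CdmpAssignment],
) -> pd.DataFrame:
    """Count distinct genes per (label, tumor group, control), plus unions.

    Returns a tidy frame with columns label, tumor_group, control, n_genes.
    Per-label rows with control ``"N|ADJ"`` count the union over the two
    controls for that tumor group; tumor group ``"ANY"`` rows count the union
    over tumor groups (the gene sets the expression stage consumes).
    """
    sets: dict[tuple[str, str, str], set[str]] = {}
    for a in assignments:
        tg, ctrl = a.comparison
        for label in a.labels:
            sets.setdefault((label, tg, ctrl), set()).add(a.gene_id)
    tumor_groups = sorted({k[1] for k in sets})
    controls = sorted({k[2] for k in sets})
    rows = []
    for label in CDMP_LABELS:
        any_union: set[str] = set()
        for tg in tumor_groups:
            union_ctrl: set[str] = set()
            for ctrl in controls:
                genes = sets.get((label, tg, ctrl), set())
                union_ctrl |= genes
                rows.append((label, tg, ctrl, len(genes)))
            rows.append((label, tg, "N|ADJ", len(union_ctrl)))
            any_union |= union_ctrl
        rows.append((label, "ANY", "N|ADJ", len(any_union)))
    return pd.DataFrame(rows, columns=["label", "tumor_group", "control", "n_genes"])


def label_gene_sets(
    assignments: Iterable[CdmpAssignment],
    controls: Sequence[str] = ("N", "ADJ"),
) -> dict[str, dict[str, set[str]]]:
    """label -> tumor group -> genes carrying the label versus any control."""
    out: dict[str, dict[str, set[str]]] = {lab: {} for lab in CDMP_LABELS}
    for a in assignments:
        tg, ctrl = a.comparison
        if controls and ctrl not in controls:
            continue
        for label in a.labels:
            out[label].setdefault(tg, set()).add(a.gene_id)
    return out


def hypergeom_overlap(set_a: set, set_b: set, universe: set,
                      label_a: str = "A", label_b: str = "B") -> OverlapTestResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    p = P(X >= |A ∩ B|) with X hypergeometric(population |universe|,
    successes |A|, draws |B|); summed in log space so p-values far below
    float underflow still report a finite log10.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    M, K, N = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    if k == 0:
        return OverlapTestResult(label_a, label_b, M, K, N, 0, 1.0, 0.0)
    support = np.arange(k, min(K, N) + 1)
    logp = logsumexp(hypergeom.logpmf(support, M, K, N))
    logp = min(logp, 0.0)
    return OverlapTestResult(label_a, label_b, M, K, N, k,
                             float(np.exp(logp)), float(logp / np.log(10)))


def pairwise_overlap_tests(
    gene_sets: Mapping[str, set],
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric overlap for every unordered pair of labeled gene sets."""
    labels = [l for l in gene_sets if gene_sets[l]]
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            r = hypergeom_overlap(gene_sets[la], gene_sets[lb], universe, la, lb)
            rows.append((r.set_a_label, r.set_b_label, r.universe_size, r.size_a,
                         r.size_b, r.overlap, r.p_value, r.log10_p))
    return pd.DataFrame(rows, columns=["label_a", "label_b", "universe", "size_a",
                                       "size_b", "overlap", "p_value", "log10_p"])


def group_region_mean_matrix(
    matrix: BinMatrix,
    genes: Sequence[GeneRegions],
    samples_by_group: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Mean rpm per gene over each (group, region) cell.

    One row per gene, one column per group x region combination (20 columns
    for the five groups); empty regions yield NaN.  The table feeds external
    clustering/heatmap tooling.
    """
    groups = list(samples_by_group)
    cols = [f"{g}.{r.value}" for g in groups for r in
            (RegionClass.DISTAL, RegionClass.TSS, RegionClass.GENIC, RegionClass.TES)]
    data = np.full((len(genes), len(cols)), np.nan)
    index = []
    for gi, gene in enumerate(genes):
        index.append(gene.gene_id)
        bins_by_region = assign_bins_to_regions(gene, matrix.bin_size)
        ci = 0
        for g in groups:
            samples = list(samples_by_group[g])
            for r in (RegionClass.DISTAL, RegionClass.TSS, RegionClass.GENIC,
                      RegionClass.TES):
                bins = bins_by_region[r]
                if bins.size and samples:
                    data[gi, ci] = matrix.rpm_values(gene.chrom, bins, samples).mean()
                ci += 1
    return pd.DataFrame(data, index=pd.Index(index, name="gene_id"), columns=cols)
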