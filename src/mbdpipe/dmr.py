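"""Per-bin rank-sum testing and consecutive-bin DMR calling.

The caller follows the threshold/run rule directly: each 100-bp bin is
tested between a tumor group and a control group with a two-sided Wilcoxon
rank-sum test on rpm values; a bin qualifies when p < 0.05, |log2FC| >= 1
and the group means differ.  A DMR is a maximal run of consecutive
qualifying bins of uniform direction, at least 3 bins long (5 in the genic
region), whose run-averaged rpm in the higher-methylated group is at least
0.2.  Bin p-values are deliberately uncorrected for multiple testing: the
run-length requirement is the error control.

Rank-sum p-values use the exact Mann-Whitney U null distribution (dynamic
programming over rank assignments) when both groups have <= 10 samples and
the combined values are tie-free, and otherwise a normal approximation with
tie correction and a 0.5 continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from scipy.special import erfc

from .annotation import GeneRegions, RegionClass, assign_bins_to_regions
from .coverage import BinMatrix

HYPER, HYPO, NONE = "hyper", "hypo", "none"
EXACT_MAX_N = 10


@dataclass(frozen=True)
class DmrCallParams:
    """Thresholds of the DMR caller (defaults are the published values)."""

    bin_size: int = 100
    p_threshold: float = 0.05
    min_mean_rpm_high: float = 0.2
    min_log2fc: float = 1.0
    min_run_default: int = 3
    min_run_genic: int = 5
    fc_pseudocount: float = 0.1

    def __post_init__(self) -> None:
        for name in ("bin_size", "p_threshold", "min_mean_rpm_high",
                     "min_log2fc", "min_run_default", "min_run_genic",
                     "fc_pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_run_genic < self.min_run_default:
            raise ValueError("min_run_genic must be >= min_run_default")

    def min_run(self, region: RegionClass) -> int:
        return self.min_run_genic if region == RegionClass.GENIC else self.min_run_default


# ---------------------------------------------------------------------------
# Rank-sum test


@lru_cache(maxsize=None)
def _u_null_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the tie-free null.

    Built by the standard recursion N(n1, n2, u) = N(n1-1, n2, u-n2) +
    N(n1, n2-1, u) over the C(n1+n2, n1) equally likely rank assignments.
    """
    max_u = n1 * n2
    # table[i][j] = counts over u for i of group-1 and j of group-2
    prev = [np.array([1.0]) for _ in range(n2 + 1)]
    for i in range(1, n1 + 1):
        cur = [np.zeros(1)] * (n2 + 1)
        cur[0] = np.array([1.0])
        for j in range(1, n2 + 1):
            a = np.zeros(i * j + 1)
            # last element from group 1: U contribution j
            src = prev[j]
            a[j:j + src.size] += src
            # last element from group 2: U unchanged
            src = cur[j - 1]
            a[:src.size] += src
            cur[j] = a
        prev = cur
    counts = prev[n2]
    cdf = np.cumsum(counts) / counts.sum()
    assert cdf.size == max_u + 1
    return cdf


def _exact_two_sided(u: float, n1: int, n2: int) -> float:
    cdf = _u_null_cdf(n1, n2)
    max_u = n1 * n2
    u = int(round(u))
    lower = cdf[u]
    upper = 1.0 - (cdf[u - 1] if u > 0 else 0.0)
    return min(1.0, 2.0 * min(lower, upper))


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two rpm vectors.

    Exact when both groups have <= 10 observations and there are no ties;
    normal approximation with tie and continuity corrections otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    p, _, _ = _rank_sum_bulk(a[np.newaxis, :], b[np.newaxis, :])
    return float(p[0])


def _rank_sum_bulk(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized rank-sum over rows; returns (p, mean_a, mean_b).

    ``A`` is ``(n_rows, n_a)`` and ``B`` ``(n_rows, n_b)``.  Rows qualify for
    the exact branch individually (small n and tie-free); the rest use the
    tie-corrected normal approximation with continuity correction.
    """
    n1, n2 = A.shape[1], B.shape[1]
    n = n1 + n2
    X = np.concatenate([A, B], axis=1)
    ranks = rankdata(X, axis=1)
    U = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0

    # tie statistics per row: sum(t^3 - t) = sum over elements of t^2 minus n
    eq_counts = (X[:, :, np.newaxis] == X[:, np.newaxis, :]).sum(axis=2)
    tie_term = (eq_counts.astype(float) ** 2).sum(axis=1) - n
    has_ties = tie_term > 0

    mu = n1 * n2 / 2.0
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(U - mu) - 0.5, 0.0) / sigma
    p = erfc(z / math.sqrt(2.0))
    p = np.where(sigma > 0, np.minimum(p, 1.0), 1.0)

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        exact_rows = np.nonzero(~has_ties)[0]
        if exact_rows.size:
            cdf = _u_null_cdf(n1, n2)
            u = np.rint(U[exact_rows]).astype(int)
            lower = cdf[u]
            upper = 1.0 - np.where(u > 0, cdf[np.maximum(u - 1, 0)], 0.0)
            p[exact_rows] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p, A.mean(axis=1), B.mean(axis=1)


# ---------------------------------------------------------------------------
# Per-bin test results


@dataclass(frozen=True)
class BinTestResult:
    bin: int
    p_value: float
    mean_a: float
    mean_b: float
    log2fc: float
    direction: str


class BinTestTable:
    """Columnar sequence of :class:`BinTestResult` (arrays under the hood)."""

    __slots__ = ("bins", "p", "mean_a", "mean_b", "log2fc", "direction")

    def __init__(self, bins, p, mean_a, mean_b, log2fc, direction):
        self.bins = np.asarray(bins, dtype=np.int64)
        self.p = np.asarray(p, dtype=float)
        self.mean_a = np.asarray(mean_a, dtype=float)
        self.mean_b = np.asarray(mean_b, dtype=float)
        self.log2fc = np.asarray(log2fc, dtype=float)
        self.direction = np.asarray(direction, dtype=np.int8)  # +1 hyper, -1 hypo, 0 none

    def __len__(self) -> int:
        return self.bins.size

    def __getitem__(self, i: int) -> BinTestResult:
        d = {1: HYPER, -1: HYPO, 0: NONE}[int(self.direction[i])]
        return BinTestResult(int(self.bins[i]), float(self.p[i]),
                             float(self.mean_a[i]), float(self.mean_b[i]),
                             float(self.log2fc[i]), d)

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def test_region_bins(
    values_a: np.ndarray,
    values_b: np.ndarray,
    bins: Sequence[int],
    params: DmrCallParams = DmrCallParams(),
) -> BinTestTable:
    """Rank-sum test every bin of a region between group A (tumor) and B (control).

    ``values_a``/``values_b`` are ``(n_bins, n_samples)`` rpm arrays aligned
    with ``bins``.  log2FC is computed on group means with the pseudocount c:
    ``log2((mean_a + c) / (mean_b + c))``.
    """
    A = np.atleast_2d(np.asarray(values_a, dtype=float))
    B = np.atleast_2d(np.asarray(values_b, dtype=float))
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if A.shape[0] != len(bins) or B.shape[0] != len(bins):
        raise ValueError("value arrays must align with the bin list")
    if len(bins) == 0:
        return BinTestTable([], [], [], [], [], [])
    p, mean_a, mean_b = _rank_sum_bulk(A, B)
    c = params.fc_pseudocount
    log2fc = np.log2((mean_a + c) / (mean_b + c))
    direction = np.sign(mean_a - mean_b).astype(np.int8)
    return BinTestTable(bins, p, mean_a, mean_b, log2fc, direction)


# ---------------------------------------------------------------------------
# Run scanning


@dataclass(frozen=True)
class Dmr:
    """A maximal run of qualifying consecutive bins."""

    gene_id: str | None
    region: RegionClass
    chrom: str | None
    start: int
    end: int
    n_bins: int
    direction: str
    min_p: float
    max_p: float
    mean_rpm_high: float
    run_log2fc: float
    comparison: tuple[str, str] | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_runs(
    results: BinTestTable,
    region: RegionClass,
    params: DmrCallParams = DmrCallParams(),
) -> list[Dmr]:
    """Call DMRs as maximal runs of qualifying bins with uniform direction.

    A bin qualifies iff p < p_threshold, |log2fc| >= min_log2fc and its
    direction is not none.  Candidate runs are maximal (never split or merged
    across a non-qualifying bin or a direction flip) and are emitted iff they
    reach the region's minimum length and the run-averaged rpm of the
    higher-methylated group is at least min_mean_rpm_high.
    """
    n = len(results)
    if n == 0:
        return []
    qual = (results.p < params.p_threshold) \
        & (np.abs(results.log2fc) >= params.min_log2fc) \
        & (results.direction != 0)
    state = np.where(qual, results.direction, 0)
    out: list[Dmr] = []
    min_run = params.min_run(region)
    c = params.fc_pseudocount
    i = 0
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j < n and state[j] == state[i]:
            j += 1
        run = slice(i, j)
        n_bins = j - i
        if n_bins >= min_run:
            direction = HYPER if state[i] > 0 else HYPO
            rm_a = results.mean_a[run].mean()
            rm_b = results.mean_b[run].mean()
            mean_high = rm_a if direction == HYPER else rm_b
            if mean_high >= params.min_mean_rpm_high:
                run_bins = results.bins[run]
                lo, hi = int(run_bins.min()), int(run_bins.max())
                out.append(Dmr(
                    gene_id=None, region=region, chrom=None,
                    start=lo * params.bin_size,
                    end=(hi + 1) * params.bin_size,
                    n_bins=n_bins, direction=direction,
                    min_p=float(results.p[run].min()),
                    max_p=float(results.p[run].max()),
                    mean_rpm_high=float(mean_high),
                    run_log2fc=float(np.log2((rm_a + c) / (rm_b + c))),
                ))
        i = j
    return out


def call_gene_dmrs(
    gene: GeneRegions,
    matrix: BinMatrix,
    groups: tuple[Sequence[str], Sequence[str]],
    params: DmrCallParams = DmrCallParams(),
    comparison: tuple[str, str] | None = None,
) -> list[Dmr]:
    """Call DMRs in all four regions of one gene for one group comparison.

    ``groups`` is (tumor sample ids, control sample ids).  The rank test runs
    once over the concatenated region bins, then runs are scanned per region.
    """
    tumor_ids, control_ids = groups
    region_bins = assign_bins_to_regions(gene, params.bin_size)
    labels, all_bins, offsets = [], [], []
    pos = 0
    for label, bins in region_bins.items():
        labels.append(label)
        all_bins.append(bins)
        offsets.append((pos, pos + bins.size))
        pos += bins.size
    cat = np.concatenate(all_bins) if pos else np.array([], dtype=np.int64)
    if cat.size == 0:
        return []
    va = matrix.rpm_values(gene.chrom, cat, list(tumor_ids))
    vb = matrix.rpm_values(gene.chrom, cat, list(control_ids))
    table = test_region_bins(va, vb, cat, params)
    out: list[Dmr] = []
    for label, (lo, hi) in zip(labels, offsets):
        if hi == lo:
            continue
        sub = BinTestTable(table.bins[lo:hi], table.p[lo:hi],
                           table.mean_a[lo:hi], table.mean_b[lo:hi],
                           table.log2fc[lo:hi], table.direction[lo:hi])
        for dmr in scan_runs(sub, label, params):
            out.append(replace(dmr, gene_id=gene.gene_id, chrom=gene.chrom,
                               comparison=comparison))
    return out


# ---------------------------------------------------------------------------
# Gene-level summaries


def gene_region_status(dmrs: Iterable[Dmr], gene_id: str, region: RegionClass) -> str:
    """Summarize one gene's DMRs in one region: hyper, hypo, both, or none."""
    has_hyper = has_hypo = False
    for d in dmrs:
        if d.gene_id == gene_id and d.region == region:
            if d.direction == HYPER:
                has_hyper = True
            elif d.direction == HYPO:
                has_hypo = True
    if has_hyper and has_hypo:
        return "both"
    if has_hyper:
        return HYPER
    if has_hypo:
        return HYPO
    return NONE


def union_across_controls(status_vs_n: str, status_vs_adj: str) -> str:
    """Mark a gene differential if it is so versus normal *or* adjacent.

    Conflicting directions across the two controls yield ``both`` (such
    genes are excluded from single-direction pattern classes downstream).
    """
    s = {status_vs_n, status_vs_adj}
    if "both" in s or s == {HYPER, HYPO}:
        return "both"
    if HYPER in s:
        return HYPER
    if HYPO in s:
        return HYPO
    return NONE


def dmr_mean_profile(
    dmrs: Sequence[Dmr],
    matrix: BinMatrix,
    samples_by_group: Mapping[str, Sequence[str]],
    half_window: int = 500,
) -> dict[str, np.ndarray]:
    """Per-group mean rpm profile over bins centered at DMR midpoints.

    Each DMR contributes a window of ``2 * half_window / bin_size`` bins with
    the midpoint-containing bin opening the downstream half; windows are
    averaged across DMRs.  Missing bins contribute zeros.
    """
    if not dmrs:
        raise ValueError("empty DMR list")
    samples_by_group = {g: s for g, s in samples_by_group.items() if len(s)}
    bs = matrix.bin_size
    half_bins = half_window // bs
    offsets = np.arange(-half_bins, half_bins)
    profiles = {g: np.zeros(offsets.size) for g in samples_by_group}
    for d in dmrs:
        mid_bin = ((d.start + d.end) // 2) // bs
        bins = mid_bin + offsets
        for g, samples in samples_by_group.items():
            vals = matrix.rpm_values(d.chrom, bins, list(samples))
            profiles[g] += vals.mean(axis=1)
    return {g: v / len(dmrs) for g, v in profiles.items()}


# ---------------------------------------------------------------------------
# Output


def write_dmr_bed(dmrs: Sequence[Dmr], path) -> None:
    """Write DMRs as BED6+ : name=gene|region|tumor_vs_control, score=-10 log10(min p)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tn_bins\tdirection\t"
                 "mean_rpm_high\trun_log2fc\n")
        for d in sorted(dmrs, key=lambda d: (d.chrom or "", d.start,
                                             d.gene_id or "", d.region.value)):
            comp = f"{d.comparison[0]}_vs_{d.comparison[1]}" if d.comparison else "NA"
            name = f"{d.gene_id}|{d.region.value}|{comp}"
            score = min(1000, int(round(-10.0 * math.log10(max(d.min_p, 1e-300)))))
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score}\t.\t"
                     f"{d.n_bins}\t{d.direction}\t{d.mean_rpm_high:.6g}\t"
                     f"{d.run_log2fc:.6g}\n")
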