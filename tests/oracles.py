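"""Independent brute-force oracles used by the unit and acceptance tests."""

from itertools import combinations
from math import comb

import numpy as np

from mbdpipe.dmr import HYPER, HYPO, BinTestTable, Dmr, DmrCallParams


def brute_force_ranksum(values_a, values_b) -> float:
    """Two-sided rank-sum p by enumerating every split of the combined values.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) over all C(n, n_a) equally
    likely assignments of the pooled values to group A.
    """
    a = list(values_a)
    b = list(values_b)
    pooled = a + b
    n, na = len(pooled), len(a)

    def u_stat(group_a):
        rest = list(pooled)
        for x in group_a:
            rest.remove(x)
        return sum(1.0 for x in group_a for y in rest if x > y) \
            + 0.5 * sum(1 for x in group_a for y in rest if x == y)

    u_obs = u_stat(a)
    us = [u_stat([pooled[i] for i in idx])
          for idx in combinations(range(n), na)]
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs + 1e-9) / total
    upper = sum(1 for u in us if u >= u_obs - 1e-9) / total
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_hypergeom(universe_size, size_a, size_b, overlap) -> float:
    """P(|B' ∩ A| >= overlap) by counting all size_b subsets of the universe."""
    total = comb(universe_size, size_b)
    count = sum(
        comb(size_a, k) * comb(universe_size - size_a, size_b - k)
        for k in range(overlap, min(size_a, size_b) + 1)
    )
    return count / total


def brute_force_scan(results: BinTestTable, region, params: DmrCallParams):
    """Enumerate every sub-interval; keep maximal qualifying runs, then filter.

    Independent of scan_runs' single-pass scanner: checks each candidate
    interval for all-qualifying uniform direction and non-extendability.
    """
    n = len(results)

    def qualifies(i):
        return (results.p[i] < params.p_threshold
                and abs(results.log2fc[i]) >= params.min_log2fc
                and results.direction[i] != 0)

    out = []
    for i in range(n):
        for j in range(i, n):
            idx = range(i, j + 1)
            if not all(qualifies(k) for k in idx):
                continue
            dirs = {int(results.direction[k]) for k in idx}
            if len(dirs) != 1:
                continue
            d = dirs.pop()
            # maximality: not extendable left or right in the same direction
            if i > 0 and qualifies(i - 1) and int(results.direction[i - 1]) == d:
                continue
            if j < n - 1 and qualifies(j + 1) and int(results.direction[j + 1]) == d:
                continue
            n_bins = j - i + 1
            min_run = params.min_run(region)
            if n_bins < min_run:
                continue
            rm_a = results.mean_a[i:j + 1].mean()
            rm_b = results.mean_b[i:j + 1].mean()
            direction = HYPER if d > 0 else HYPO
            mean_high = rm_a if direction == HYPER else rm_b
            if mean_high < params.min_mean_rpm_high:
                continue
            run_bins = results.bins[i:j + 1]
            c = params.fc_pseudocount
            out.append(Dmr(
                gene_id=None, region=region, chrom=None,
                start=int(run_bins.min()) * params.bin_size,
                end=(int(run_bins.max()) + 1) * params.bin_size,
                n_bins=n_bins, direction=direction,
                min_p=float(results.p[i:j + 1].min()),
                max_p=float(results.p[i:j + 1].max()),
                mean_rpm_high=float(mean_high),
                run_log2fc=float(np.log2((rm_a + c) / (rm_b + c))),
            ))
    return out


def random_bin_table(rng, max_len=30, p_small_frac=0.5) -> BinTestTable:
    """A random per-bin statistics table with internally consistent fields."""
    n = int(rng.integers(1, max_len + 1))
    # group means on a coarse grid so exact ties in direction occur
    mean_a = rng.choice([0.0, 0.05, 0.1, 0.3, 0.6, 1.2, 2.5], size=n)
    mean_b = rng.choice([0.0, 0.05, 0.1, 0.3, 0.6, 1.2, 2.5], size=n)
    c = 0.1
    log2fc = np.log2((mean_a + c) / (mean_b + c))
    direction = np.sign(mean_a - mean_b).astype(np.int8)
    # mixture of small and uniform p-values to produce runs
    small = rng.random(n) < p_small_frac
    p = np.where(small, rng.uniform(1e-6, 0.05, n), rng.uniform(0.05, 1.0, n))
    start = int(rng.integers(0, 1000))
    bins = np.arange(start, start + n)
    return BinTestTable(bins, p, mean_a, mean_b, log2fc, direction)
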