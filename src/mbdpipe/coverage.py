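"""Binned MBD-seq coverage: sample sheets, grid-aligned counts, rpm normalization.

Coverage enters the pipeline already binned (one count per 100-bp genomic
bin per sample), either as 4-column bedGraph files aligned to the bin grid
or as a wide bin-by-sample TSV.  Counts are normalized to reads per million
(rpm = count * 1e6 / total reads of the sample); bins absent from the input
are zero coverage, which for an enrichment assay is informative
(unmethylated or unmappable), not missing data.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("N", "ADJ", "L", "H", "VH")
TUMOR_GROUPS = ("L", "H", "VH")
#: Ordered clinical risk scale used by the max-combiner.
RISK_ORDER = {"L": 0, "H": 1, "VH": 2}


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    group: str
    total_reads: int | None = None
    risk_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.sample_id}")
        if self.total_reads is not None and self.total_reads <= 0:
            raise ValueError(f"total_reads must be > 0 for {self.sample_id}")


def assign_risk_group(risk_labels: Sequence[str]) -> str:
    """Combine per-method clinical risk calls by taking the highest risk."""
    if not list(risk_labels):
        raise ValueError("empty risk label list")
    calls = [str(r).upper() for r in risk_labels]
    for c in calls:
        if c not in RISK_ORDER:
            raise ValueError(f"unknown risk label {c!r}")
    return max(calls, key=RISK_ORDER.__getitem__)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a sample sheet TSV with at least sample_id and group columns.

    Optional columns: ``total_reads`` and any number of ``risk*`` columns
    holding per-method clinical calls (L/H/VH).  A blank group with risk
    columns present is filled by the max-risk combiner.  Group tokens are
    normalized case-insensitively.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "group" not in cols:
        raise ValueError(f"{path}: sample sheet needs sample_id and group columns")
    risk_cols = [c for c in df.columns if c.lower().startswith("risk")]
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row[cols["sample_id"]]).strip()
        if sid in seen:
            raise ValueError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        risk = None
        if risk_cols:
            vals = [str(row[c]).strip().upper() for c in risk_cols
                    if pd.notna(row[c]) and str(row[c]).strip()]
            if vals:
                risk = tuple(vals)
        grp_raw = row[cols["group"]]
        if (pd.isna(grp_raw) or not str(grp_raw).strip()) and risk:
            grp = assign_risk_group(risk)
        else:
            grp = str(grp_raw).strip().upper()
            if grp not in GROUPS:
                raise ValueError(f"unknown group token {grp_raw!r} for {sid}")
        total = None
        if "total_reads" in cols and pd.notna(row[cols["total_reads"]]):
            tok = str(row[cols["total_reads"]]).strip()
            if tok:
                total = int(float(tok))
        records.append(SampleRecord(sample_id=sid, group=grp, total_reads=total,
                                    risk_labels=risk))
    return records


def group_samples(records: Iterable[SampleRecord]) -> dict[str, list[str]]:
    """Map each group label to its ordered sample ids."""
    out: dict[str, list[str]] = {g: [] for g in GROUPS}
    for rec in records:
        out[rec.group].append(rec.sample_id)
    return out


def resolve_group(name: str, by_group: Mapping[str, Sequence[str]]) -> list[str]:
    """Expand a comparison-plan group name into sample ids.

    ``ALL`` pools the three tumor risk groups; ``N+ADJ`` pools both controls.
    """
    name = name.upper()
    if name == "ALL":
        return [s for g in TUMOR_GROUPS for s in by_group.get(g, [])]
    if name in ("N+ADJ", "NADJ", "N_ADJ"):
        return list(by_group.get("N", [])) + list(by_group.get("ADJ", []))
    if name not in by_group:
        raise KeyError(f"unknown group {name!r}")
    return list(by_group[name])


# ---------------------------------------------------------------------------
# Binned count readers


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_bedgraph(path: str | Path, bin_size: int = 100) -> dict[str, dict[int, float]]:
    """Read one sample's grid-aligned bedGraph into ``{chrom: {bin: count}}``.

    Every interval must start on a multiple of ``bin_size`` and span exactly
    one bin; off-grid intervals and negative counts raise ``ValueError``
    naming the interval.
    """
    out: dict[str, dict[int, float]] = {}
    path = Path(path)
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path.name}: bedGraph needs 4 columns: {line!r}")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start % bin_size != 0 or end - start != bin_size:
                raise ValueError(
                    f"{path.name}: interval {chrom}:{start}-{end} is off the "
                    f"{bin_size}-bp bin grid")
            if value < 0:
                raise ValueError(f"{path.name}: negative count at {chrom}:{start}-{end}")
            out.setdefault(chrom, {})[start // bin_size] = value
    return out


def read_bin_counts(path: str | Path, bin_size: int = 100):
    """Read binned counts from a bedGraph (one sample) or a bin-matrix TSV.

    A file whose header starts with ``chrom<TAB>bin_start`` is treated as a
    multi-sample matrix and returned as a :class:`BinMatrix`; otherwise the
    file is parsed as bedGraph and a per-chromosome sparse mapping is
    returned.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
    if first.startswith("chrom\tbin_start"):
        return BinMatrix.from_matrix_tsv(path, bin_size=bin_size)
    return read_bedgraph(path, bin_size=bin_size)


def normalize_rpm(raw, total_reads: float):
    """Scale raw counts to reads-per-million: ``raw * 1e6 / total_reads``."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return np.asarray(raw, dtype=float) * (1e6 / float(total_reads))


# ---------------------------------------------------------------------------
# The bin-by-sample matrix


class BinMatrix:
    """Sparse-by-bin, dense-by-sample matrix of raw counts with rpm on demand.

    Per chromosome the matrix stores a sorted array of occupied bin indices
    and an aligned ``(n_bins, n_samples)`` array of raw counts.  rpm values
    are computed lazily as ``raw * 1e6 / total_reads``; bins not stored are
    zero for every sample.
    """

    def __init__(
        self,
        bin_size: int,
        samples: Sequence[str],
        chrom_data: Mapping[str, tuple[np.ndarray, np.ndarray]],
        totals: Mapping[str, float] | None = None,
    ) -> None:
        self.bin_size = int(bin_size)
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self._index = {s: i for i, s in enumerate(self.samples)}
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bins, counts) in chrom_data.items():
            bins = np.asarray(bins, dtype=np.int64)
            counts = np.asarray(counts, dtype=float)
            if counts.shape != (bins.size, len(self.samples)):
                raise ValueError(f"{chrom}: counts shape {counts.shape} does not "
                                 f"match {bins.size} bins x {len(self.samples)} samples")
            order = np.argsort(bins, kind="stable")
            self._chroms[chrom] = (bins[order], counts[order])
        if totals is None:
            sums = np.zeros(len(self.samples))
            for _, counts in self._chroms.values():
                sums += counts.sum(axis=0)
            totals = {s: float(sums[i]) for s, i in self._index.items()}
        self.total_reads = {s: float(totals[s]) for s in self.samples}
        for s, t in self.total_reads.items():
            if t <= 0:
                raise ValueError(f"non-positive total reads for {s}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_bedgraphs(
        cls,
        paths_by_sample: Mapping[str, str | Path],
        bin_size: int = 100,
        totals: Mapping[str, float] | None = None,
    ) -> "BinMatrix":
        samples = list(paths_by_sample)
        per_sample = {s: read_bedgraph(p, bin_size) for s, p in paths_by_sample.items()}
        chroms = sorted({c for d in per_sample.values() for c in d})
        chrom_data = {}
        for chrom in chroms:
            bins = sorted({b for d in per_sample.values() for b in d.get(chrom, {})})
            arr = np.zeros((len(bins), len(samples)))
            pos = {b: i for i, b in enumerate(bins)}
            for j, s in enumerate(samples):
                for b, v in per_sample[s].get(chrom, {}).items():
                    arr[pos[b], j] = v
            chrom_data[chrom] = (np.array(bins, dtype=np.int64), arr)
        return cls(bin_size, samples, chrom_data, totals)

    @classmethod
    def from_matrix_tsv(cls, path: str | Path, bin_size: int = 100,
                        totals: Mapping[str, float] | None = None) -> "BinMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["chrom", "bin_start"]:
            raise ValueError(f"{path}: matrix TSV must start with chrom, bin_start")
        samples = list(df.columns[2:])
        if (df["bin_start"] % bin_size != 0).any():
            bad = df.loc[df["bin_start"] % bin_size != 0].iloc[0]
            raise ValueError(f"{path}: bin_start {bad['bin_start']} off the grid")
        chrom_data = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            bins = (sub["bin_start"].to_numpy() // bin_size).astype(np.int64)
            chrom_data[str(chrom)] = (bins, sub[samples].to_numpy(dtype=float))
        return cls(bin_size, samples, chrom_data, totals)

    # -- accessors ---------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def _sample_cols(self, samples: Sequence[str] | None) -> np.ndarray:
        if samples is None:
            return np.arange(len(self.samples))
        try:
            return np.array([self._index[s] for s in samples])
        except KeyError as exc:
            raise KeyError(f"unknown sample_id {exc.args[0]!r}") from None

    def raw_values(self, chrom: str, bins: Sequence[int],
                   samples: Sequence[str] | None = None) -> np.ndarray:
        """Raw counts as a ``(len(bins), len(samples))`` array; absent bins are 0."""
        cols = self._sample_cols(samples)
        bins = np.asarray(bins, dtype=np.int64)
        out = np.zeros((bins.size, cols.size))
        if chrom in self._chroms and bins.size:
            stored, counts = self._chroms[chrom]
            pos = np.searchsorted(stored, bins)
            pos_c = np.clip(pos, 0, stored.size - 1)
            hit = (pos < stored.size) & (stored[pos_c] == bins)
            if hit.any():
                out[hit] = counts[np.ix_(pos_c[hit], cols)]
        return out

    def rpm_values(self, chrom: str, bins: Sequence[int],
                   samples: Sequence[str] | None = None) -> np.ndarray:
        """rpm-normalized counts, same layout as :meth:`raw_values`."""
        sel = self.samples if samples is None else list(samples)
        raw = self.raw_values(chrom, bins, sel)
        scale = np.array([1e6 / self.total_reads[s] for s in sel])
        return raw * scale[np.newaxis, :]

    # -- writer ------------------------------------------------------------

    def write_matrix_tsv(self, path: str | Path) -> None:
        frames = []
        for chrom in self.chroms:
            bins, counts = self._chroms[chrom]
            df = pd.DataFrame(counts, columns=self.samples)
            df.insert(0, "bin_start", bins * self.bin_size)
            df.insert(0, "chrom", chrom)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                    float_format="%.10g")

    def write_bedgraphs(self, out_dir: str | Path) -> dict[str, Path]:
        """Write one grid-aligned bedGraph per sample; returns sample -> path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for j, s in enumerate(self.samples):
            p = out_dir / f"{s}.bedGraph"
            with open(p, "w") as fh:
                for chrom in self.chroms:
                    bins, counts = self._chroms[chrom]
                    col = counts[:, j]
                    for b, v in zip(bins.tolist(), col.tolist()):
                        if v != 0:
                            start = b * self.bin_size
                            fh.write(f"{chrom}\t{start}\t{start + self.bin_size}\t{v:.10g}\n")
            paths[s] = p
        return paths


def region_values(matrix: BinMatrix, chrom: str, bins: Sequence[int],
                  samples: Sequence[str]) -> np.ndarray:
    """Per-bin rpm vectors across ``samples`` (rows follow ``bins`` order)."""
    return matrix.rpm_values(chrom, bins, samples)
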