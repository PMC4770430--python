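"""Transcript models and strand-aware partitioning into the four gene-anchored regions.

Every analyzable transcript is split into four disjoint genomic regions,
measured along its own strand:

* ``DISTAL`` — 2–100 kb upstream of the TSS,
* ``TSS``    — 2 kb either side of the transcription start site,
* ``GENIC``  — from 2 kb downstream of the TSS to 1 kb upstream of the TES
  (empty for transcripts spanning 3 kb or less),
* ``TES``    — 1 kb either side of the transcription end site.

All coordinates are 0-based half-open (BED convention); GTF input is
converted on load.  Bins are genome-anchored: bin *i* covers
``[i*bin_size, (i+1)*bin_size)`` and belongs to a region iff its start
coordinate lies inside the region's interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DISTAL_REACH = 100_000
TSS_FLANK = 2_000
TES_FLANK = 1_000
DEFAULT_BIN_SIZE = 100


class RegionClass(str, Enum):
    """The four gene-anchored region labels."""

    DISTAL = "Distal"
    TSS = "TSS"
    GENIC = "Genic"
    TES = "TES"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Minimum consecutive-bin run length for a DMR, by region class (genic runs
#: must be longer; see the dmr module).
REGION_ORDER = (RegionClass.DISTAL, RegionClass.TSS, RegionClass.GENIC, RegionClass.TES)


@dataclass(frozen=True)
class GeneModel:
    """One transcript reduced to its strand-aware start and end sites.

    ``tss`` is the 5' end on the transcript's strand and ``tes`` the 3' end,
    so ``tss < tes`` on ``+`` and ``tes < tss`` on ``-``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if not self.chrom:
            raise ValueError(f"empty chromosome for {self.gene_id}")
        if min(self.tss, self.tes) < 0:
            raise ValueError(f"negative coordinate for {self.gene_id}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"+ strand requires tss < tes ({self.gene_id})")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"- strand requires tes < tss ({self.gene_id})")

    @property
    def span(self) -> int:
        return abs(self.tes - self.tss)


Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneRegions:
    """The four half-open intervals of one gene; an empty interval has start == end."""

    gene_id: str
    chrom: str
    strand: str
    distal: Interval
    tss_region: Interval
    genic: Interval
    tes_region: Interval

    def intervals(self) -> dict[RegionClass, Interval]:
        return {
            RegionClass.DISTAL: self.distal,
            RegionClass.TSS: self.tss_region,
            RegionClass.GENIC: self.genic,
            RegionClass.TES: self.tes_region,
        }


# ---------------------------------------------------------------------------
# Readers


def _parse_bed_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:
        fields = line.split()
    if len(fields) < 6:
        raise ValueError(f"line {lineno}: BED record needs >= 6 columns")
    chrom, start, end, name, _score, strand = fields[:6]
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand symbol {strand!r}")
    tss, tes = (s, e) if strand == "+" else (e, s)
    return GeneModel(gene_id=name, chrom=chrom, strand=strand, tss=tss, tes=tes,
                     transcript_id=name)


def _parse_refflat_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ValueError(f"line {lineno}: refFlat record needs >= 6 columns")
    gene_name, tx_name, chrom, strand, tx_start, tx_end = fields[:6]
    try:
        s, e = int(tx_start), int(tx_end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand symbol {strand!r}")
    tss, tes = (s, e) if strand == "+" else (e, s)
    return GeneModel(gene_id=gene_name, chrom=chrom, strand=strand, tss=tss,
                     tes=tes, transcript_id=tx_name)


def _load_gtf(path: str | Path) -> list[GeneModel]:
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df
    if "Feature" in df.columns:
        tx = df[df["Feature"] == "transcript"]
        if tx.empty:
            # fall back to exon spans grouped by transcript
            ex = df[df["Feature"] == "exon"]
            if ex.empty:
                raise ValueError(f"{path}: no transcript or exon features")
            grp = ex.groupby("transcript_id", sort=True)
            tx = grp.agg(
                Chromosome=("Chromosome", "first"),
                Strand=("Strand", "first"),
                Start=("Start", "min"),
                End=("End", "max"),
                gene_id=("gene_id", "first"),
            ).reset_index()
    else:  # pragma: no cover - defensive
        raise ValueError(f"{path}: malformed GTF (no Feature column)")
    models = []
    for row in tx.itertuples(index=False):
        strand = str(row.Strand)
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {strand!r} in {path}")
        start, end = int(row.Start), int(row.End)  # pyranges is already 0-based
        tss, tes = (start, end) if strand == "+" else (end, start)
        gene_id = str(getattr(row, "gene_id", "") or row.transcript_id)
        models.append(GeneModel(gene_id=gene_id, chrom=str(row.Chromosome),
                                strand=strand, tss=tss, tes=tes,
                                transcript_id=str(row.transcript_id)))
    return models


def load_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Load transcript records from refFlat, BED12/BED6, or GTF.

    ``format`` is one of ``{"refflat", "bed12", "gtf"}``; inferred from the
    file suffix when omitted.  Raises ``ValueError`` naming the offending
    line for unparseable records or unknown strand symbols.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".bed",):
            format = "bed12"
        elif suffix in (".gtf", ".gff"):
            format = "gtf"
        elif suffix in (".refflat", ".txt"):
            format = "refflat"
        else:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    format = format.lower()
    if format == "gtf":
        return _load_gtf(path)
    parser = {"bed12": _parse_bed_line, "bed": _parse_bed_line,
              "refflat": _parse_refflat_line}.get(format)
    if parser is None:
        raise ValueError(f"unknown annotation format {format!r}")
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            models.append(parser(line, lineno))
    return models


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column UCSC chrom.sizes TSV into ``{chrom: length}``."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: need chrom and length")
            sizes[parts[0]] = int(parts[1])
    return sizes


# ---------------------------------------------------------------------------
# Transcript selection


def select_unique_transcripts(
    models: Sequence[GeneModel],
    *,
    cross_gene: bool = True,
    within_gene: str = "longest",
) -> list[GeneModel]:
    """Keep transcripts with unique start and end sites; one record per gene.

    Transcripts whose (chrom, tss) is shared with a transcript of a
    *different* gene are dropped (likewise for (chrom, tes)); among isoforms
    of one gene the longest is kept (``within_gene="longest"``, the default)
    with deterministic coordinate tie-breaking, or all retained with
    ``within_gene="keep"``.  ``cross_gene=False`` disables the cross-gene
    collision filter.
    """
    kept = list(models)
    if cross_gene:
        tss_owners: dict[tuple[str, int], set[str]] = {}
        tes_owners: dict[tuple[str, int], set[str]] = {}
        for m in kept:
            tss_owners.setdefault((m.chrom, m.tss), set()).add(m.gene_id)
            tes_owners.setdefault((m.chrom, m.tes), set()).add(m.gene_id)
        kept = [
            m for m in kept
            if tss_owners[(m.chrom, m.tss)] == {m.gene_id}
            and tes_owners[(m.chrom, m.tes)] == {m.gene_id}
        ]
    if within_gene == "longest":
        best: dict[str, GeneModel] = {}
        order: list[str] = []
        for m in kept:
            cur = best.get(m.gene_id)
            if cur is None:
                best[m.gene_id] = m
                order.append(m.gene_id)
            else:
                key = (-m.span, min(m.tss, m.tes), max(m.tss, m.tes))
                cur_key = (-cur.span, min(cur.tss, cur.tes), max(cur.tss, cur.tes))
                if key < cur_key:
                    best[m.gene_id] = m
        kept = [best[g] for g in order]
    elif within_gene != "keep":
        raise ValueError(f"unknown within_gene policy {within_gene!r}")
    return kept


# ---------------------------------------------------------------------------
# Region partitioning


def _clip(start: int, end: int, chrom_length: int) -> Interval:
    s = min(max(start, 0), chrom_length)
    e = min(max(end, 0), chrom_length)
    if s >= e:
        return (s, s)
    return (s, e)


def partition_gene_regions(model: GeneModel, chrom_length: int) -> GeneRegions:
    """Split one transcript into Distal / TSS / Genic / TES intervals.

    On ``+``: tss_region = [tss-2k, tss+2k), genic = [tss+2k, tes-1k),
    tes_region = [tes-1k, tes+1k), distal = [tss-100k, tss-2k); mirrored on
    ``-``.  Intervals are clipped to ``[0, chrom_length)``; the genic
    interval is empty when the transcript spans 3 kb or less.
    """
    tss, tes = model.tss, model.tes
    if model.strand == "+":
        tss_iv = (tss - TSS_FLANK, tss + TSS_FLANK)
        genic = (tss + TSS_FLANK, tes - TES_FLANK)
        tes_iv = (tes - TES_FLANK, tes + TES_FLANK)
        distal = (tss - DISTAL_REACH, tss - TSS_FLANK)
    else:
        tss_iv = (tss - TSS_FLANK, tss + TSS_FLANK)
        genic = (tes + TES_FLANK, tss - TSS_FLANK)
        tes_iv = (tes - TES_FLANK, tes + TES_FLANK)
        distal = (tss + TSS_FLANK, tss + DISTAL_REACH)
    return GeneRegions(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        distal=_clip(*distal, chrom_length),
        tss_region=_clip(*tss_iv, chrom_length),
        genic=_clip(*genic, chrom_length),
        tes_region=_clip(*tes_iv, chrom_length),
    )


def assign_bins_to_regions(
    regions: GeneRegions, bin_size: int = DEFAULT_BIN_SIZE
) -> dict[RegionClass, np.ndarray]:
    """Map each region to its ordered genome-anchored bin indices.

    A bin belongs to a region iff its start coordinate lies inside the
    region's half-open interval.  Lists run 5'->3' along the strand, i.e.
    descending genomic order on ``-``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out: dict[RegionClass, np.ndarray] = {}
    for label, (start, end) in regions.intervals().items():
        first = -(-start // bin_size)   # ceil division
        last_excl = -(-end // bin_size)
        bins = np.arange(first, last_excl, dtype=np.int64)
        if regions.strand == "-":
            bins = bins[::-1]
        out[label] = bins
    return out


def write_region_table(regions: Iterable[GeneRegions], path: str | Path) -> None:
    """Write one row per (gene, region): gene_id, chrom, strand, region, start, end."""
    rows = []
    for gr in regions:
        for label, (start, end) in gr.intervals().items():
            rows.append((gr.gene_id, gr.chrom, gr.strand, label.value, start, end))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "region",
                                     "start", "end"])
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> list[GeneRegions]:
    """Inverse of :func:`write_region_table`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        by_label = {row.region: (int(row.start), int(row.end))
                    for row in sub.itertuples(index=False)}
        out.append(GeneRegions(
            gene_id=str(gene_id),
            chrom=str(sub["chrom"].iloc[0]),
            strand=str(sub["strand"].iloc[0]),
            distal=by_label[RegionClass.DISTAL.value],
            tss_region=by_label[RegionClass.TSS.value],
            genic=by_label[RegionClass.GENIC.value],
            tes_region=by_label[RegionClass.TES.value],
        ))
    return out
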