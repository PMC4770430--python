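# Methods

This note records the model and procedure `mbdpipe` implements, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the method left room.

## Region model

A transcript is reduced to its strand-aware TSS (5' end) and TES (3' end)
and partitioned into four half-open intervals on the 0-based BED coordinate
system:

| region | + strand | width before clipping |
|---|---|---|
| Distal | [TSS−100000, TSS−2000) | 98,000 bp |
| TSS | [TSS−2000, TSS+2000) | 4,000 bp |
| Genic | [TSS+2000, TES−1000) | span − 3,000 bp |
| TES | [TES−1000, TES+1000) | 2,000 bp |

and the exact mirror on the − strand. The four intervals tile
[TSS−100 kb, TES+1 kb) with no gaps or overlaps (a tested invariant). The
genic interval is empty for transcripts spanning ≤ 3 kb; such genes simply
have no genic tests. Intervals are clipped at chromosome edges. Bins are
genome-anchored (bin *i* = [100·i, 100·(i+1))) and belong to a region iff
their start coordinate lies in it — a deliberate convention making bin
membership unambiguous and the four bin lists disjoint. The 100-kb distal
window of one gene may overlap a neighbouring gene's territory; no masking
is applied, so a bin can serve as Distal context for several genes.

Transcript selection keeps transcripts whose TSS and TES coordinates are not
shared with a different gene (colliding records are dropped on both sides),
then keeps the longest isoform per gene, so downstream gene-level logic sees
one record per gene. Both behaviours can be disabled
(`select_unique_transcripts(cross_gene=..., within_gene=...)`).

## Coverage and normalization

The pipeline starts from binned counts (grid-aligned bedGraph per sample, or
a bin-by-sample TSV); alignment and multi-mapper recovery are upstream
concerns. Counts are normalized per sample to rpm = count × 10⁶ /
total reads. When the sample sheet does not provide totals they default to
the sum of that sample's bin counts, in which case each sample's rpm sums to
exactly 10⁶. Bins absent from the input are zeros everywhere: in an
enrichment assay, absence of coverage is informative (unmethylated or
unmappable), not missing data. No CpG-density or GC correction is applied —
the method operates on relative rpm only.

## Per-bin test and DMR call

Each bin is compared between a tumor group and a control group with a
two-sided Wilcoxon rank-sum test on rpm values:

* **exact** null distribution of the Mann–Whitney U statistic (dynamic
  programming over rank assignments; two-sided p = 2·min(P(U≤u), P(U≥u)),
  capped at 1) when both groups have ≤ 10 samples and the combined values
  are tie-free;
* otherwise the **normal approximation** with the standard tie correction
  and a 0.5 continuity correction. When every value is tied the variance is
  zero and p is defined as 1.

With the cohort's group sizes (7–20 per side) both branches are exercised.
The implementation is vectorised across the bins of a gene; tests verify it
against `scipy.stats.mannwhitneyu` and against brute-force permutation
enumeration.

A bin **qualifies** iff p < 0.05, |log₂FC| ≥ 1 and the group means differ;
log₂FC = log₂((m̄_tumor + c)/(m̄_control + c)) with pseudocount c = 0.1 rpm
(configurable) to handle zero coverage. A **DMR** is a maximal run of
consecutive qualifying bins of uniform direction, emitted iff it has ≥ 3
bins (≥ 5 in the genic region) and the run-averaged rpm of the
higher-methylated group is ≥ 0.2. Choices worth making explicit:

* p and log₂FC gate **per bin**; the 0.2-rpm floor is averaged **over the
  run** — the closest literal reading of the three thresholds, of which only
  the rpm one is stated "on average". All thresholds sit in
  `DmrCallParams`.
* Runs are maximal and never merged across a failing bin or a direction
  flip; sub-runs of a failing candidate are not rescued.
* Bin p-values are **not** corrected for multiple testing: the
  consecutive-run requirement is the method's error control. On the null
  simulation (cohort sample sizes, 500 genes, no planted signal) the
  fraction of genes acquiring any DMR is ≈ 0.2%, well under the 2%
  calibration bound the tests enforce.

A gene's per-region status is hyper / hypo / both / none from its DMRs;
"both" (mixed directions) is excluded from single-direction pattern classes
and reported separately. A gene counts as differential for a tumor group if
it is so versus normal **or** adjacent controls (set-level union after
classification); conflicting directions across the two controls again yield
"both". The pooled N+ADJ control pools samples before testing, not a
meta-analysis of two tests.

## CDMP classification and overlaps

Of the 24 conceivable two-region joint patterns only the 12 anchored at the
TSS are classified: S⟨1|0⟩⟨D|G|E⟩⟨1|0⟩, TSS state first. A gene receives one
label per partner region with a clean status; labels with different partner
regions coexist. The hypergeometric overlap test between two label gene sets
uses the upper tail P(X ≥ overlap), summed from log-pmf terms with
log-sum-exp so that p-values far below double underflow still report a
usable log₁₀. The test's universe is the set of genes with testable bins in
both TSS and the partner region — the smallest defensible universe; it is
recorded in the output table.

## Expression integration

DE tables are consumed, not computed (the upstream tool's schema — gene,
log₂FC, p, and either a precomputed low-expression count or per-sample
log₂-cpm columns — is the contract). "< 0 cpm" is read as log₂-cpm < 0,
i.e. cpm < 1, since raw cpm cannot be negative; genes with more than 150
such samples are excluded (strictly more, so 150 is retained). A DEG is
p < 0.05 with |log₂FC| > 0.5 applied two-sidedly, the sign giving the
direction — the only reading consistent with reporting both up- and
down-regulated counts from one rule. Gene identifiers are matched by exact
string after case normalization; no alias mapping. Risk-group-unique DEGs
are the Venn-exclusive zones of the three groups' DEG sets, optionally
within one pattern's gene set.

## Synthetic data

The generator emulates the motivating study design: five groups with 8 N,
12 ADJ, 13 L, 12 H and 7 VH samples; 100-bp bin counts with
negative-binomial noise (var = m + φm², φ = 0.1, mean 5 reads/bin — drawn
via the gamma–Poisson mixture so the dispersion knob is exact); genes of
5–20 kb placed on a 210-kb pitch so neighbouring distal windows cannot
collide. Methylation shifts are planted as ×4 (or ×¼) fold changes on the
expected count over a contiguous bin run inside one named region, confined
to the tumor samples of the affected risk group; N is always baseline and
ADJ receives a configurable fraction of the effect (default 0, mimicking
adjacent tissue behaving like normal). Auto-generated plants span the
region's minimum run length plus one to three bins. DE tables plant DEGs
with |log₂FC| ∈ (0.6, 3) and p < 0.05 against a background inside both
thresholds, plus a 5% low-expressed fraction drawn among non-planted genes
so planted counts remain exactly recoverable. Everything is byte-reproducible
from the seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: fragment-size and CpG-density structure,
mappability artefacts (optional zero stretches exist but default off),
correlated noise between neighbouring bins, partial-effect plants below the
caller's thresholds, and any real coupling between methylation and
expression (DE tables are planted independently of the methylation plants
unless a test constructs them jointly).

## Verification problem sizes

The acceptance checks run at sizes chosen to exercise the full method while
staying desk-scale: 1,000 random bin-statistic sequences against the
brute-force window oracle; exhaustive rank-sum enumeration for all group
sizes ≤ 6; exhaustive hypergeometric enumeration for universes ≤ 12; 1,000
random genes for region geometry; 500 genes × 52 samples × 6 comparisons
(≈ 3 × 10⁶ bin tests) for planted-signal recovery (recall ≈ 0.99 at the ≥
0.90 bound, precision ≈ 0.99 at the ≥ 0.80 bound) and for null calibration;
and a 12-gene full pipeline run executed twice for bytewise determinism.
Recovery is scored on single-risk-group comparisons only: plants affect one
risk group, so the pooled ALL group sees a diluted effect with no clean
expected outcome.

## Known limitations

* The caller is exactly the threshold/run rule — no smoothing, HMM
  segmentation or beta-binomial modelling — so single noisy bins can split
  long true regions into two calls.
* Rank-sum power is limited at the smallest group sizes (7 VH samples);
  borderline plants can be missed against one control and caught against
  the other, which the union rule absorbs.
* The distal window of a gene may overlap other genes' territories; calls
  there are not attributed uniquely.
* Assembly-agnostic by design: no lift-over, and no exon/intron
  substructure beyond the four regions.
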