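# Methods

This note records the model assumptions, parameter defaults, numerical
choices and known limitations behind `guidepeak`.

## Data model

A GUIDE-seq experiment yields two paired-end libraries (forward and
reverse) per treatment, amplified off opposite strands of the dsODN
integrated at double-strand breaks. Read 2 begins at the
genomic/dsODN junction, so its 5′-most aligned base is taken as the
integration position and its strand as the event strand. Read 1 starts
at the distal adaptor ligation point; the outermost aligned base of
read 1 is the ligation position. A unique molecule is the triple (UMI,
ligation position, integration position) within one library; read
pairs identical on that key are PCR duplicates and collapse to one
unique cleavage event whose `support` records the multiplicity. UMIs
are compared exactly — no 1-mismatch clustering — because duplicate
identification is by identity of the ligation event, and UMI error
correction is out of scope here.

Coordinates are 0-based half-open internally and in all BED output;
the off-target report uses 1-based inclusive positions (spreadsheet
convention), stated in each writer's header.

## Pair filters

Defaults: dsODN tag required on read 2 (`require_tag`), mapping quality
≥ 30 on both mates, aligned span ≥ 30 bp per mate, pair span ≤ 1000 bp,
mates on one chromosome (cross-chromosome pairs fall under the span
rule). The criteria are standard; the numeric values are this package's
defaults, exposed as flags, since they are tuning knobs rather than
fixed constants of the method. Each removed pair is counted once under
the first failing rule, in the order no_tag → mapq → aligned_length →
span, so the removal stats are a partition of the removed set.

## Peak calling

Events from both libraries are pooled per strand. A window of
`window_size` (default 20 bp) slides at step 1; windows holding ≥
`min_reads` (default 5) events qualify. Maximal runs of overlapping
qualifying windows reduce to the single window with the largest event
sum — leftmost on ties — rather than splitting multi-modal runs,
because a peak's height is defined as the event sum within one window.
The summit is the window centre, `floor((start+end−1)/2)`. Window
starts are unconstrained integers; near a chromosome start a window may
conceptually overhang position 0 (it can only ever count real events).

Each peak is tested against a local Poisson background: b = same-strand
events within ±B/2 of the summit (B = `background_window`, default
5000 bp), expected height λ = b·w/B, p = P(X ≥ height) for
X ~ Poisson(λ) via the scipy survival function, SNratio =
height / max(λ, w/B) — the floor corresponds to a one-event background
and keeps isolated peaks finite. The peak's own window is included in
the background by default (conservative: inflates λ, never deflates
it); exclusion is available behind `background_excludes_peak`. Peaks
with p ≤ `p_cutoff` (default 0.05) are kept; no multiple-testing
adjustment by default (the per-peak Poisson tail is already extreme for
any real signal at these defaults), with optional Benjamini-Hochberg
behind `adjust_p`. SNratio is always reported but only filtered when
`snratio_cutoff` is set, since no sensible universal threshold exists.

Library chemistry places minus-strand (Crick) events upstream of the
cut and plus-strand (Watson) events downstream, so merging requires
that polarity: each Crick peak greedily (left to right) pairs with the
nearest downstream unused Watson peak whose summit lies strictly
after its own and within `merge_distance` (default 40 bp). Merged
score = sum of strand heights; span = union of windows. Unpaired peaks
are dropped under `require_pair` (default), as are merged peaks whose
contributing events come from only one of two supplied libraries.
Sample peaks overlapping a nuclease-free control's merged peaks by
≥ 1 bp are removed as integration hotspots.

## Homology search and assignment

The flank searched is 20 bp on each side of the merged-peak span
(`flank`). Every window of guide_length + pam_size on both strands is
decomposed per the PAM geometry (3′ or 5′ of the protospacer) and
accepted iff guide mismatches ≤ `max_mismatch_guide` (default 6 — up to
six mismatches can be functional for SpCas9), PAM mismatches vs the
canonical PAM's IUPAC classes ≤ `max_mismatch_pam` (default 2), and the
candidate PAM matches at least one mask in `pam_pattern` (default: the
canonical PAM itself; a list of IUPAC masks serves as alternation —
enough for single-position constraints and NAG/NGA-style relaxations
without a regex engine). Matching is Hamming-only; guide/genome bulges
are not searched. Mismatch positions are numbered 1-based from the
PAM-distal end regardless of PAM location, matching the scoring models.
The predicted cut is blunt, `cut_offset` (default 3) bases from the
PAM-proximal protospacer end; staggered Cpf1 cuts are reduced to this
single coordinate.

When several candidates fall in one peak's region the assignment ranks
by (fewest guide mismatches, fewest PAM mismatches, smallest distance
from predicted cut to peak midpoint, leftmost); this tie-break is a
package choice, and `report_all` keeps every candidate instead. Peaks
with no candidate are retained in a separate "peaks without homology"
output rather than silently dropped — with default budgets these are
typically hotspots or artefacts.

## Cleavage scoring

The position-weight score is
`Π_{p∈mm}(1−w_p) × 1/(((L−1−d̄)/(L−1))·4+1) × 1/n²` with d̄ the mean
pairwise distance between mismatch positions and L the guide length
(denominator 19 for a 20-nt guide). For n = 1 the distance term is
defined as 1 (avoiding 0/0), and n = 0 scores exactly 1. The packaged
`hsu_zhang_2013` weight vector is the published SpCas9 vector,
checksum-validated at load. The CFD-style path multiplies
per-(position, guide base, genome base) factors and a PAM factor; the
packaged `cfd_2016` table is a clearly labelled synthetic stand-in with
the real table's structure (factors in [0,1], canonical PAM factor 1,
PAM-proximal positions penalised more, transitions tolerated more) —
the published factors should be supplied through the user-matrix TSV
interface for real CFD predictions. Guides longer than a model are
handled by padding neutral values (weight 0 / factor 1) at the
PAM-distal start. Scores are reported on [0, 1], not ×100.

## Annotation and comparison

Gene/exon overlap is strand-agnostic (a lesion disrupts the gene
whichever strand the protospacer matched) and requires ≥ 1 bp against
the protospacer interval; "in intron" means inside a gene body but
touching no exon. Per-transcript resolution is reduced to gene
symbol + id. Cross-experiment combination clusters sites by
single-linkage interval overlap (≥ 1 bp, configurable), not exact
coordinates, so peak-boundary jitter between runs does not split a
shared locus; a clustered row carries each member sample's maximum peak
score. Venn region counts partition the combined rows; diagram
rendering (plain matplotlib, 2–3 sets) is an optional layer over the
counts table.

## Synthetic data

The simulator emulates the structural features the pipeline exploits:
Crick-before-Watson event polarity with integration positions jittered
within 3 bp of the cut, per-molecule UMIs with PCR-duplicate copies
sharing the full dedup key (copies ~ 1 + Poisson(mean−1), mean 3),
alternating library assignment per event (so any site with ≥ 2 events
per strand has two-library support), uniform background events (default
10⁻⁴/bp — isolated singletons well below the peak threshold), and
hotspot loci mirrored into a nuclease-free control. Defaults: 200-kb
genome at GC 0.45, fragment length 150–250 bp, 50-bp reads, 8-nt UMIs.
A single NumPy RNG stream keyed by the seed drives all sampling in a
documented order, so outputs are byte-identical per seed.

Deliberately not modelled — and therefore not demonstrated by passing
tests: sequencing errors and mapping ambiguity, indel-bearing
integration junctions, realistic insert-size and duplication-rate
distributions, chromatin- or cell-type-dependent capture biases. Tests
against these fixtures show the algorithmic contracts (filtering,
dedup, aggregation, merging, search, ranking) hold, not that real-data
noise regimes are handled optimally.

## Problem sizes

The bundled test suite and the acceptance script run on synthetic
instances sized for exactness of their oracles: brute-force
equivalence checks use up to 10⁴ random elements, and the end-to-end
recovery fixture is a 200-kb genome with 8 planted sites (abundances
2–50 per strand) plus two hotspots — large enough that every pipeline
stage is exercised with non-trivial background, small enough that
exhaustive reference implementations remain feasible.

## Known limitations

- Alignment is delegated to an external paired-end aligner; the
  package starts from SAM/BAM.
- No UMI error correction and no bulge-aware homology search.
- The p-value/SNratio defaults are package choices (the distribution is
  standard; published cutoffs are not), flagged in the run log.
- The packaged CFD-style factor table is synthetic (see above).
- Single-library runs pass the library-support filter vacuously, with a
  logged notice.
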