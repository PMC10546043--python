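# Methods

## The measurement model

A methylation-dependent restriction endonuclease (MspJI by default) binds a
4-bp recognition motif anchored on a methylated cytosine — mCNNR on either
strand — and cleaves both strands downstream of the motif: the strand
carrying the mC is cut 13 bp from it, the opposite strand 17 bp, leaving a
4-nt 5′ overhang with a terminal phosphate. Sticky-end adapters ligate only
to such enzymatic ends, so after paired-end sequencing each fragment end
marks one digestion event. Because the cut geometry is fixed, the 5′ base of
a confidently aligned read falls exactly 10 bp from the near edge of the
motif whose cytosine triggered the cut (to the right of a forward-strand
motif, to the left of a reverse-strand one). Counting read 5′ starts at
those exact offsets therefore estimates, per motif site, how many genome
copies were methylated and cut there.

Analysis is restricted by default to the CpG-context subset of the motif,
CGNR (top strand) and its bottom-strand mirror (YNCG on the top strand),
because mammalian methylation is overwhelmingly at CpG.

All coordinates in the package are 0-based, half-open, on the top strand
(BED convention); SAM's 1-based positions are converted at the I/O boundary.
A forward site with mC at p has scissions after p+12 (top) and p+16
(bottom); the fragment right of the cut begins at p+13 and the fragment left
of it, after fill-in, ends at p+17 (half-open). Reverse sites mirror this.
This is the unique assignment consistent with the four printed anchors:
13/17-bp cut distances, 4-nt 5′ overhang, 10-bp read-start offset, and the
21/32-bp canonical insert lengths.

## Region scores

Per-region hit counts c_i (sum of hits at sites whose mC coordinate lies
inside the region; both orientations of a palindromic CpG count unless the
CpG straddles the boundary) are normalized to reads per million per motif:

    RPMPM_i = 1e6 * (c_i / m_i) / D

where m_i is the region's motif count and D the library-wide total of hits
assigned to *all* analysis-pattern sites, not the within-region-set sum.
Displayed and clustered values are log10(RPMPM + 1). Regions with no motifs
are retained with score 0. Differential testing is deliberately exported
(count + motif tables in a form consumable by negative-binomial frameworks),
not reimplemented.

## The simulator and what it does (not) emulate

`digest()` draws, per genome copy and site, methylation ~ Bernoulli(site
fraction) and then cutting ~ Bernoulli(digestion_prob), separating the
biological fraction from enzymatic efficiency so that expected per-site hits
are n_copies × fraction × digestion_prob — the basis of the parameter-
recovery test. Forward and reverse sites of one CpG share a fraction by
default (symmetric CpG methylation) but are cut independently, since the
enzyme recognizes each strand's mC separately.

A cut requires its enzyme footprint — motif through the far scission — to be
intact duplex, so a cut whose footprint overlaps the single-stranded
overhang zone left by an already-applied cut is suppressed; candidate cuts
are attempted in uniformly random order. This is what caps the
motif-flanking minimum insert at 21 bp: a second site placed immediately
after a cut's overhang can only produce a fragment when it points the same
way, giving cut_near + cut_far − overhang + 4 = 21 bp. A known caveat: two
*convergent* cuts (a forward site and a reverse site ≥ 34 bp downstream)
bound a fragment containing neither motif, which can be as short as 9 bp
while still carrying two enzymatic overhangs; the 21-bp figure is specific
to the flanking configuration, and `minimum_flanking_insert()` enumerates
exactly that. Such convergent short pieces are rare in realistic site
registries and are mostly removed downstream by the read-length triage.

Fragments bounded by a contig end lack the enzymatic phosphorylated overhang
and are unligatable — hence an unmethylated genome yields no library, the
in-silico analogue of the no-library controls. Degenerate pieces whose two
4-nt overhangs would leave no duplex (length < 9) are also unligatable.
After fill-in, both fragments flanking a cut contain the 4 overhang bases,
so per copy the fragment lengths sum to contig length + 4 × cuts (they do
not partition the contig).

Reads are error-free by default (an optional uniform substitution-rate knob
exists); read 1 is the top-strand prefix of the insert, read 2 the
bottom-strand prefix from the right end. A configurable fraction of pairs is
replaced by 4-bp random inserts to emulate adapter dimers. Not simulated:
PCR duplication and overamplification artifacts, adapter chemistry
(uracil excision, PCR suppression), size selection beyond the optional
insert_min/insert_max window, and base-conversion platforms' chemistry.
A green round-trip test therefore establishes coordinate/assignment
correctness and the stochastic count model, not robustness to alignment
error, duplicates, or trimming artifacts.

## Read triage

Read pairs are classed as adapter dimers (insert ≤ 10 bp), too short
(insert < 19 bp, the aligner's minimum seed), unaligned, poorly aligned
(MAPQ < 10, posterior < 0.9 by MAPQ = −10·log10 P(wrong)), or confidently
aligned; only the last are assigned. Offset matching is strictly exact by
default (a tolerance flag exists, default 0); mates are assigned
independently; secondary/supplementary alignments are ignored; no duplicate
marking is applied. Under the literal offset rule the canonical 32-bp
palindromic fragment's own ends (both proximal, 16-bp offset) score no hits
— the flanking fragments carry those hits — and the package keeps that
literal behavior.

## Cross-platform statistics

Platform scores per region: coverage-weighted percent methylation
(Σ n_meth / Σ n_total) for base-conversion data, fragment-center counts for
immunoprecipitation data, unweighted mean probe β for arrays; uncovered
regions are missing, not zero, and are dropped listwise before clustering.
The most variable regions are selected by Pearson χ² on the groups ×
(methylated, unmethylated) count table (ties broken by region order); each
platform matrix is linearly scaled to (0, 1) over the whole matrix (a
per-feature flag exists; the whole-matrix form is the default because the
scaling is described per platform matrix). Clustering is UPGMA — average
linkage with cluster-size weighting — on Pearson distances 1 − r, with the
deterministic lowest-index tie-break; the hand-rolled implementation is
cross-checked in tests against scipy's average-linkage as an independent
oracle. Separation is summarized by the ratio silhouette: nearest
other-class distance ÷ mean within-class distance, which is *not* the
classical silhouette; values > 1 mean a sample sits nearer its own class.

## Defaults and tunables

| parameter | default | why |
|---|---|---|
| recognition / analysis motif | CNNR / CGNR | MspJI; CpG-context analysis |
| cut_near / cut_far / overhang | 13 / 17 / 4 bp | enzyme geometry |
| countable offset | 10 bp | cut_near − (motif length − 1) |
| min MAPQ | 10 | posterior 0.9 |
| min seed / dimer insert | 19 / 10 bp | aligner seed length; dimer definition |
| n_copies | 100 | desk-scale library depth |
| digestion_prob | 0.9 | efficient but incomplete digestion |
| adapter_dimer_rate | 0.01 | minor dimer contamination |
| read_length | 61 nt | short-read run geometry |
| profile | Beta(2, 2) per CpG | broad unimodal methylome |
| cpg_enrichment | 0 | independent dinucleotides; promoter-like CpG density |

Numerical notes: RPMPM requires a positive denominator and rejects hits in
zero-motif regions; subsampling is multivariate hypergeometric (without
replacement) and deterministic per seed; UPGMA tie-breaks and the single
global seed (with named per-stage substreams) make every pipeline output
byte-reproducible.

## Limitations

Real-aligner effects (soft clipping, mapping bias), PCR duplicates, 5hmC vs
5mC, non-CpG methylation contexts, and genome-scale region annotations are
out of scope; alignment and differential testing are consumed from, or
exported to, external tools.
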