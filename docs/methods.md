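# Methods

This note documents the models and procedures implemented in
`exotarget`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the package's known limitations.

## Coordinate model and read handling

Internal coordinates are 0-based half-open (BED convention); GFF3 I/O
converts its 1-based closed coordinates at the boundary.  Every read is
a stranded interval; a library carries a `total_mapped` denominator so
per-million quantities remain correct when reads are filtered.
Antisense signal is never merged into sense counts: a read whose only
overlap is on the opposite strand is tallied separately per feature,
because antisense cross-linking is a real, distinguishable signal.
Read-to-feature assignment is single-assignment with a deterministic
tie-break — maximal overlap, then smaller feature (a specific annotation
beats a broad one), then lexicographic id.

## CRAC binding analysis

**Clusters.** A cluster is a maximal interval with per-base read
coverage ≥ `min_height` (default 5), merged across gaps < 3 nt and
discarded below `min_length` (12 nt).  The defaults are deliberately
permissive — cluster calling here feeds a composition analysis, not a
peak atlas — and all three are configurable.

**Hexamer enrichment.** Observed counts sum overlapping occurrences of
each k-mer (k = 6) across cluster sequences.  The null model preserves
each cluster's mononucleotide composition: every cluster sequence is
independently letter-permuted `n_shuffles` (100) times and recounted.
Per k-mer we report z = (obs − bg_mean)/bg_sd, an empirical p with the
+1/+1 correction ((1 + #shuffles ≥ obs)/(1 + n_shuffles), never 0), and
a BH-adjusted q over all k-mers observed at least once.  A k-mer whose
count is shuffle-invariant (e.g. a homopolymer in a homopolymeric
cluster) has bg_sd = 0 and is reported with z = NaN, p = 1.  A
dinucleotide-preserving shuffle is not implemented; mononucleotide
shuffling matches the scale of composition bias the simulation
produces, and with 100 shuffles the empirical-p floor is 1/101 — rank
and z, not q, are the meaningful statistics at that resolution.

**Abundance-normalized enrichment.** enrichment = CRAC count /
(abundance + 0.1).  The pseudocount bounds ratios for transcripts absent
from the abundance table's dynamic range; features missing from the
table entirely are excluded from ranking and counted in the log.

**pA classification.** Both abundance tables (oligo-dT-selected and
total RNA) are divided by their median over shared features, and
R = normalized oligo-dT / normalized total is compared to a 5.0-fold
cutoff.  The default reading is that *depletion* from the oligo-dT
fraction defines pA− (R ≤ 1/5); the opposite reading (pA+ requires
R ≥ 5) is available behind a flag, since the convention is genuinely
ambiguous.  Median normalization makes the classification invariant to
rescaling either table.

## Differential expression

DE is a defined NB Wald test rather than a wrapper around an external
tool, so its behaviour is fully specified and testable:

- **Size factors**: median-of-ratios over features nonzero in all
  samples, rescaled to geometric mean 1; total-count fallback when no
  such feature exists.
- **Dispersion**: per-gene method-of-moments α = (v − m)/m² on
  normalized counts, averaged over conditions.  Raw values are kept
  unclipped (they may be negative) when building a running-mean trend
  over genes ranked by expression (window 101), so the trend stays
  unbiased; the per-gene value is then α_trend + 0.2·(α_raw − α_trend),
  clipped to [1e-8, 10].  The small residual weight keeps genuine
  per-gene signal without letting 3v3 moment noise dominate; with a true
  constant dispersion this estimator gives a type-I error of ~0.05 at
  α = 0.05 (the suite checks [0.03, 0.07]).  A `pooled` mode replaces
  the trend by the global mean.
- **Test**: log2FC from normalized condition means with pseudocount 0.5;
  SE from the delta method, var(log μ̂) ≈ (1/μ + α)/r; two-sided normal
  p.  A gene with an all-zero condition is flagged, p set to 1, log2FC
  clamped to ±10.
- **Calls**: up iff fold > 1.5 (strict) and p < 0.05; down symmetric.
  The call rule uses raw p, matching the reported convention for the
  tallies; q-values are reported alongside.
- **Tallies**: per-direction class percentages use round-half-up
  (159/147/135 of 445 → 36/33/30).

Gene-set enrichment is the upper-tail hypergeometric P(X ≥ k), delegated
to `scipy.stats.hypergeom` and verified against exhaustive enumeration.

## Intron retention

A 5′SS boundary read spans the exon–intron junction at the intron's
transcript-orientation 5′ end with ≥ 3 nt on each side (the overhang
rule is a package choice; it is configurable).  Boundary counts are
reported per million mapped reads; replicates are pooled before RPM and
FPKM computation because these metrics are descriptive — inference
lives in the DE stage.  FPKM = count · 10⁹ / (length · total_mapped);
intron and exon read counts use read-midpoint membership, with exon
FPKM over the union of the gene's exons.

The WT→mutant change at each intron is classified with two 2-fold
thresholds (0.1 RPM pseudocount on boundary RPM, 0.01 on ratios):
boundary up without a ratio increase is *stabilized* (the whole
precursor accumulates, so intron and exon signal rise together);
boundary and ratio both up is a *splicing defect* (splicing efficiency
itself dropped).  The ratio threshold of 2.0 operationalizes "did not
change noticeably"; only the 5′SS is counted, not the 3′SS.

## Readthrough

The downstream window is [3′end, 3′end + 300 nt) in transcript
orientation, truncated at the first same-strand annotated feature to
prevent bleed-through; a fully occluded window yields NA and no class.
Reads are counted by midpoint to avoid double-counting boundary
straddlers.  A gene with downstream fold > 2.0 (0.1 RPM pseudocount)
receives class 1/2/3 according to its gene-body DE call
(up/unchanged/down); everything else is class none.  The three classes
form a partition by construction.

## Decay-promoting introns

The caller intersects three evidence lines per intron: (i) the gene's
intronic CRAC binding fraction (midpoint-in-intron / midpoint-in-gene)
≥ 0.5, (ii) ≥ 1 sense-strand DSR motif in the intron, and (iii) an IR
call of stabilized or splicing defect.  One motif suffices — the
single-site case is the biologically decisive one — and missing
evidence makes its criterion false rather than silently passing.  The
0.5 binding cutoff is a package choice ("binding within intronic
regions" has no published numeric threshold); it is configurable and
echoed in the per-criterion evidence columns.  The three-criterion rule
is a defined operationalization, not a reconstruction of any particular
published supplementary list.

## Synthetic data: what it emulates

The generator builds the statistical structure the analysis assumes,
with a known truth set, at a scale that runs in minutes on one CPU:
2 × 250 kb chromosomes; 150 features (84 mRNA, 36 ncRNA, 2 snRNA,
4 snoRNA, 24 unannotated "intergenic" transcripts); 45% of mRNAs carry
1–2 short introns (60–150 nt; 160–260 nt for motif-bearing introns);
50 k CRAC reads; 200 k RNA-seq reads per library, in triplicate.

Planted truth (all sets disjoint): 12 decay-intron genes (1–6
sense-strand T(T/C/G)AAAC copies in one intron, CRAC affinity 50×,
mutant log2FC +2, IR category *stabilized*); 20 exonic-target
ncRNA/intergenic transcripts (1–3 exonic motif copies, affinity 50×,
log2FC +2); 6 splicing-defect genes (unspliced read fraction 0.08 →
0.35 in the mutant, log2FC 0); 6 readthrough genes per class
(downstream reads at 30% of body depth in the mutant vs 2% in WT, with
body log2FC +2/0/−1.5 for classes 1/2/3); 20 downregulated genes
(log2FC −1.5); half of ncRNA/intergenic transcripts pA− (oligo-dT
abundance = total/20, placing both classes far from the 5-fold cutoff).

Expression is log-uniform over three orders of magnitude (1–1000), with
three deliberate exceptions.  Exonic-target transcripts are drawn
low-abundance (1–100): the binding-vs-abundance anticorrelation is the
system's signature, and affinity independent of expression then yields
it automatically.  Intron-containing genes are drawn well-expressed
(50–1000): junction metrics are count-based and only informative at
moderate coverage, and the intron-containing genes of interest in this
system are ribosomal-protein-class, i.e. well-expressed.  Genes
carrying a planted mutant effect (decay introns, readthrough) sit in a
moderate band (80–400): measurable, but not so abundant that their
accumulation dominates mutant library depth.  Even so, the mutant
libraries come out ~1.4× deeper than WT, which compresses all
per-million fold changes — a real compositional effect that the
boundary-read and readthrough metrics inherit by construction (DE is
protected by size factors).  At the documented default seed the planted
IR categories are recovered at ~95% accuracy; across arbitrary seeds
this fluctuates by a few genes (roughly 87–97%) because low-coverage
junctions sit near the 2-fold threshold under Poisson noise.

RNA-seq counts are NB with variance μ + αμ² (α = 0.05, a typical
bulk-RNA-seq replicate dispersion); CRAC reads are multinomial over
genes with rate ∝ affinity × expression and start positions
Normal(motif, σ = 15 nt) truncated to the feature for motif genes,
uniform over exons otherwise.  Everything is deterministic under a
fixed seed, down to byte-identical output files.

**What it does not emulate** — and therefore what passing tests do not
show about real data: sequencing errors, fragment-length and positional
bias, spliced (exon–exon) junction reads, multi-mapping, overlapping
gene models, genuine cross-link-site chemistry (deletions/mutations at
the cross-link), pA-site heterogeneity, and any correlation structure
between neighbouring genes.  Real CRAC libraries also need untagged
controls, which the pipeline does not model.

## Numerical choices and degenerate inputs

Pseudocounts: 0.1 on abundance (enrichment), 0.5 on normalized means
(log2FC), 0.1 RPM on boundary/downstream RPM, 0.01 on intron/exon
ratios.  Zero-read genes give NaN intronic fractions (not 0), which the
decay caller treats as failed evidence.  N bases never match any motif
character and k-mer windows containing N are skipped.  Ties in k-mer
ranking are broken lexicographically; BH uses a stable sort.  All
randomness flows from a single integer seed through named
`SeedSequence` streams per stage, so stages are independently
reproducible.

## Known limitations

- The NB Wald test with 3 replicates relies on trend-moderated
  dispersions; for very low counts (μ < ~10) its p-values become
  conservative and calls should not be over-interpreted.
- The empirical k-mer p-value resolution is bounded by the shuffle
  count; q-values at 100 shuffles cannot fall much below ~0.1 when many
  k-mers tie at the floor.
- Per-million normalization makes boundary and readthrough folds
  sensitive to library-composition shifts between conditions; this is
  inherent to the metric's definition.
- The decay-intron caller's three thresholds (0.5 binding fraction,
  1 motif, 2-fold boundary) are defined operating points, not fitted
  quantities; changing them changes the call set monotonically.
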