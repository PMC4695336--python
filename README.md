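# exotarget

Identification of nuclear-exosome RNA decay targets and decay-promoting
introns from CRAC and RNA-seq data.

## The problem

In fission yeast, the YTH-family RNA-binding protein Mmi1 marks specific
transcripts — meiotic mRNAs, many non-coding RNAs, and transcripts from
intergenic regions — for degradation by the nuclear exosome.  Binding is
guided by the DSR (determinant of selective removal) hexamer
U(U/C/G)AAAC, written in DNA as T(T/C/G)AAAC (the broader TNAAAC form is
used for genome-wide censuses).  Some of these binding sites sit inside
introns: when splicing is slow, the retained intron recruits the decay
machinery and suppresses the output of the spliced mRNA — a
"decay-promoting intron".

`exotarget` implements the computational side of this analysis as a
tested, reusable pipeline for anyone analysing CRAC/CLIP-type
protein–RNA cross-linking data together with WT-vs-mutant RNA-seq:

1. **Binding** (`exotarget.binding`) — assign uniquely mapped CRAC reads
   to annotated features (strand-specific, with antisense and intergenic
   tallies), call read clusters (per-base coverage ≥ *h*, merged over
   < 3 nt gaps, length ≥ *l*), rank hexamers by a z-score against
   mononucleotide-shuffled cluster backgrounds, normalize binding to
   transcript abundance (enrichment = count / (abundance + 0.1)), and
   classify transcripts pA+/pA− from oligo-dT vs total RNA abundance
   (5.0-fold cutoff, median-normalized).
2. **Differential expression** (`exotarget.diffexpr`) — a defined
   negative-binomial Wald test (median-of-ratios size factors,
   trend-moderated method-of-moments dispersions, delta-method SE),
   BH adjustment, the > 1.5-fold & p < 0.05 call rule, per-class tallies
   with round-half-up percentages, and hypergeometric gene-set
   enrichment.
3. **Intron retention** (`exotarget.splicing`) — 5′SS exon–intron
   boundary reads per million (≥ 3 nt overhang each side), intron/exon
   FPKM ratios, and classification of each intron's WT→mutant change as
   *stabilized* (boundary > 2-fold up, ratio unchanged) or
   *splicing defect* (both up).
4. **Readthrough** (`exotarget.readthrough`) — signal in a window
   downstream of each 3′ end (truncated at the next same-strand
   feature), with three classes: downstream up with gene body up (1),
   unchanged (2), or down (3, a termination defect).
5. **Decay-intron caller** (`exotarget.decay`) — motif scanning and the
   three-way intersection: intronic CRAC binding fraction ≥ 0.5, ≥ 1
   sense-strand motif in the intron, and precursor stabilization (or a
   splicing defect) in the mutant.
6. **Synthetic data** (`exotarget.simulate`) — a toy genome +
   annotation + truth set with planted motifs, fold changes, intron
   retention and readthrough classes, plus simulated CRAC and replicate
   RNA-seq libraries (NB counts, variance = μ + αμ²), so the entire
   pipeline is testable end to end without any downloads.

All coordinates are 0-based half-open internally; GFF3 (1-based closed)
is converted at the I/O boundary.  Reads are strand-specific throughout.

## Worked example

```python
from exotarget import SimConfig, run_pipeline, evaluate_run

res = run_pipeline(SimConfig(seed=1))
print(len(res.clusters))                                  # 250
print([(s.kmer, round(s.z, 1)) for s in res.kmers[:3]])
# [('TCAAAC', 12.2), ('TGAAAC', 10.8), ('TTAAAC', 10.7)]
called = [c for c in res.decay_calls if c.verdict]
print(len(called))                                        # 11
print(called[0])
# DecayIntronCall(intron_id='mRNA_015.i1', intronic_fraction=1.0,
#                 motif_count=1, ir_call='stabilized', verdict=True,
#                 evidence={'binding': True, 'motif': True, 'ir': True})
ev = evaluate_run(res)
print(ev["decay_precision"], ev["decay_recall"])          # 1.0 0.917
```

The three top-ranked hexamers are exactly the three planted DSR variants
T(C/G/T)AAAC, recovered from the read clusters alone.  Of the 12 planted
decay-promoting introns, 11 are called (one stabilized intron narrowly
misses the 2-fold boundary-read threshold in this seed), and no
non-decay intron is called.

The same stages are available from the shell:

```sh
exotarget simulate --seed 1 --outdir run/
exotarget bind --reads run/crac.bed --genome run/genome.fa \
    --annotation run/annotation.gff3 --outdir run/bind/
exotarget run-all --seed 1 --outdir run/        # everything + manifest
```

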