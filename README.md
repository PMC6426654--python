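# retrotrace

Quantitative analysis of stress-induced **tRNA retrograde transport** —
the movement of cytoplasmic tRNAs back into the nucleus, opposite to the
canonical export direction. Oxidative stress drives this pathway in human
cells and it is selective for particular tRNA species, predominantly those
missing part of their 3′ end. `retrotrace` provides the two measurement
arms such a study needs, for computational biologists working with
nucleus/cytosol-fractionated small-RNA sequencing and tFISH microscopy:

1. **Truncation-aware tRNA-seq profiling.** Mature tRNAs universally end
   in CCA. Reads are assigned uniquely to tRNA genes together with the
   number of missing 3′ nucleotides *k* (0 = intact, 1 = missing the
   terminal A, 3 = missing the whole CCA, up to *K* = 13), by matching
   against a reference that enumerates every 3′-truncated transcript
   variant. Per-(gene, *k*) counts feed median-of-ratios normalization,
   depth filters, per-compartment log₂ fold changes (treated vs control),
   a negative-binomial Wald test with method-of-moments dispersion,
   Benjamini–Hochberg adjustment, and a replicate-consistency call
   (|log₂FC| > 0.75 with one sign in every replicate).

2. **tFISH N/C quantification.** Nuclei are segmented on the DAPI channel
   (Otsu, one dilation, hole filling, ≥ 500 px particles, border
   exclusion), cytoplasm on the probe channel with a *non-merging*
   dilation that never fuses neighbouring cells. Each cell's
   nuclear:cytoplasmic probe ratio is computed either from disjoint masks,

   N/C = mean(I<sub>nuc</sub>) / mean(I<sub>cyt</sub>),

   or from raw integrated densities of nucleus and whole cell,

   N/C = (RID<sub>Nuc</sub>/Area<sub>Nuc</sub>) / ((RID<sub>Cyt</sub> − RID<sub>Nuc</sub>)/(Area<sub>Cyt</sub> − Area<sub>Nuc</sub>)),

   which agree exactly on the same masks. Group comparisons use an
   unpaired two-tailed t test or Dunnett's many-to-one test.

A first-class synthetic-data generator (`retrotrace.simulate`) produces
tRNA gene sets, per-sample read sets with known truncation spectra and
fold changes under negative-binomial noise, and microscopy fields with
known per-cell N/C truth — every downstream check compares against these
machine-readable truth tables.

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/profile_reads.py` simulates a 2-replicate
nucleus/cytosol × control/treated experiment at 50 000 reads per sample,
profiles it, and prints the pooled 3′-truncation spectra:

```
assigned reads per sample: 45841..58096
cytosol/control  intact=0.500  missing 5-8 nt=0.110
cytosol/treated  intact=0.483  missing 5-8 nt=0.118
nucleus/control  intact=0.600  missing 5-8 nt=0.131
nucleus/treated  intact=0.300  missing 5-8 nt=0.461
```

"Intact" is the fraction of reads ending exactly at the mature CCA
terminus. Treatment halves the nuclear intact fraction and moves the mass
to deep truncations (5–8 missing nt) while the cytosol barely changes —
the signature of retrograde import of 3′-defective tRNAs that the
statistics layer then calls per gene. `python
examples/differential_localization.py` continues to the localization
table and recovers the planted responder:

```
planted responder chr17-tr009 (defective): log2FC nucleus=+3.78 (truth +3.91),
cytosol=-1.45 (truth -1.38), call=up
```

A thin CLI mirrors the library for shell use: `retrotrace build-ref`,
`retrotrace profile`, `retrotrace localize`, `retrotrace imagequant`,
`retrotrace simulate {genes,reads,images}`.

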