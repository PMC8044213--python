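# methdyn — methylome dynamics from WGBS and TAB-Seq

`methdyn` is a toolkit for analysing DNA methylation dynamics across
cell states from whole-genome bisulfite sequencing (WGBS) count data,
built around the question of which parts of a methylome are *stable*
(a shared, foundational layer of hypomethylated regions on a
hypermethylated background) and which parts are *dynamic* (regulatory
elements — typically enhancers — whose methylation is actively
maintained by the de novo methyltransferase DNMT3A and erased when it is
lost). It targets the three-condition experimental design
(progenitor, wild-type mature, DNMT3A-knockout mature) in which that
distinction becomes observable.

It is aimed at computational epigenomics practitioners who have per-CpG
count tables (methcounts-style text) and want a tested, reusable,
pure-Python implementation of the full chain:

1. **I/O** — methcounts tables, BED, bedGraph; symmetric CpG-dyad
   merging; bisulfite conversion rate from non-CpG cytosines.
2. **Segmentation** — hypomethylated regions (HMRs) called with a
   two-state hidden Markov model whose emissions are beta-binomial:
   at coverage *n*, the methylated count *k* ~ Binomial(*n*, *p*) with
   *p* ~ Beta(α_s, β_s) per state *s* ∈ {hypo, hyper}, fitted by
   Baum–Welch EM and decoded by posterior marginals. HMRs ≥ 3.5 kb are
   methylation **canyons**.
3. **Differential methylation** — per-CpG score
   *P*(p_A > p_B) under independent Beta(k+1, n−k+1) posteriors
   (exact finite sum); DMRs assembled from HMR set differences with the
   ≥ 10 CpGs / ≥ 5 significant CpGs filter; three-condition
   **DNMT3A-dependent DMRs (DDMRs)** by union-merging the pairwise DMR
   sets and annotating per-condition means.
4. **Pattern classification** — each DDMR's 3-vector of condition means
   is assigned to one of 12 template pattern vectors over
   {low = 0.2, intermediate = 0.5, high = 0.8} by maximum Pearson
   correlation (ties broken by Euclidean distance); no region gets more
   than one pattern.
5. **5hmC deconvolution** — paired WGBS + TAB-Seq tracks are inverted
   to per-CpG or per-region (unmethylated, 5mC, 5hmC) fractions, with
   TET-oxidation / glucosylation / conversion efficiencies estimated
   from pure-5hmC, pure-5mC and unmethylated spike-in controls.
6. **Interval statistics** — base-pair Jaccard, reciprocal overlap,
   nearest-TSS and genomic-feature annotation, Fisher exact gene-set
   overlap tests, and binned meta-profiles (centered or
   length-normalized).
7. **Synthetic data** — a generator that plants a foundational +
   dynamic methylome with full truth tables, so every stage above is
   testable end-to-end without any sequencing data.

## Worked example

Simulate a three-condition study for one lineage, segment the wild-type
methylome, and classify the DNMT3A-dependent regions:

```python
from methdyn.simulate import default_fixture, simulate_wgbs
from methdyn.segmentation import BetaBinomialHMM, call_canyons
from methdyn.differential import construct_ddmrs
from methdyn.patterns import assign_patterns, summarize_patterns

arch, truth, config = default_fixture(seed=1, scale=0.5)
tracks = {c: simulate_wgbs(arch, truth, "B1a", c, config)
          for c in config.conditions}

result = BetaBinomialHMM(tracks["WT"]).fit(seed=1)
print(result.summary())

hmrs = result.call_hmrs()
canyons = call_canyons(hmrs)
print(f"{len(hmrs)} HMRs, {len(canyons)} canyons "
      f"(median length {int((hmrs['end'] - hmrs['start']).median())} bp)")

hmr_sets = {c: BetaBinomialHMM(t).fit(seed=1).call_hmrs()
            for c, t in tracks.items()}
ddmrs = construct_ddmrs(tracks, hmr_sets)
print(summarize_patterns(assign_patterns(ddmrs, truth.pattern_catalog)))
```

which prints:

```
Two-state beta-binomial HMM segmentation
============================================
observations (covered CpGs): 11499
log-likelihood: -12808.154   iterations: 10   converged: True

state       mean     alpha      beta  self-trans
hypo      0.1476     0.859     4.961     0.97787
hyper     0.8488   138.182    24.620     0.99619

37 HMRs, 1 canyons (median length 830 bp)

pattern_id  count  fraction
        P1      7      0.35
        P4      2      0.10
        P6      1      0.05
        P7      9      0.45
        P9      1      0.05
```

The fitted states sit at mean methylation 0.15 / 0.85 — the
hypomethylated regulatory state against the methylated genomic
background. All 20 planted dynamic enhancer intervals are recovered as
DDMRs, and every one is assigned its generating pattern: P1
(high → low, stays low in the knockout) and P7 (high → intermediate,
completed to low in the knockout) dominate, i.e. 80% of the dynamic
layer in this lineage loses methylation during development — the
hallmark the pipeline is designed to quantify.

The same operations are available from the shell:

```bash
methdyn simulate --seed 1 --out fixture/
methdyn hmr fixture/wgbs_B1a_WT.meth --out hmrs.bed
methdyn canyon hmrs.bed --min-length 3500
methdyn methdiff fixture/wgbs_B1a_proB.meth fixture/wgbs_B1a_WT.meth --out scores.tsv
methdyn jaccard a.bed b.bed
```

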