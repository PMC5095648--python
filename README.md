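# risprofile

Profiling of retroviral vector integration sites (RIS). Gene-therapy
vectors integrate their payload into host chromatin; where they land
determines genotoxic risk. Vectors retargeted toward heterochromatin — for
example foamy-virus vectors whose integrase is fused to chromobox protein
homolog 1 (CBX1), a reader of H3K9me3 — should integrate into satellite
repeats and away from genes and proto-oncogenes. `risprofile` implements
the complete desk-side analysis that tests such claims:

- **read preprocessing** — junction read-pair merging and quality
  truncation at the 3rd base with Phred Q < 27 (error p ≥ 0.002);
- **site calling** — collapse of scored alignments into unique RIS with a
  repeat-ambiguity rule: a read is ambiguous when its second-best alignment
  score exceeds 95 % of the best (90 % when the best score is < 100);
  ambiguous sites are excluded everywhere except repeat/centromere
  proximity;
- **annotation** — per-site distances and memberships against RefSeq-style
  genes, TSSs (< 10 kb), CpG islands (≤ 1 kb), repeat classes (LINE, SINE,
  LTR, DNA, Satellite), centromeres (< 1 Mbp), proto-oncogene TSSs
  (< 50 kb / < 500 kb) and ChIP-seq peak sets sorted into 10 strength
  deciles, with "near peak" meaning within 50 kb (inclusive);
- **hotspots** — ≥ 3 RIS within a 5 kb or 50 kb window, counted on
  non-overlapping random matched-size subsets (mean ± SEM);
- **clonality** — per-clone capture frequency (reads per unique site /
  total reads), clones ≥ 1 % reported;
- **enrichment** — χ² goodness-of-fit of a site set's category counts
  against proportions from a uniform random control (classically 10,000
  sites): χ² = Σ (Oᵢ − Eᵢ)² / Eᵢ, Eᵢ = N·pᵢ, df = k − 1;
- **synthetic data** — a generator for genomes, tethering-mixture site
  sets and junction reads with full ground-truth bookkeeping, so every
  stage is testable without downloads.

## Worked example

```python
from risprofile import (Annotator, TetherModel, compare_profiles,
                        generate_reference, sample_random_sites,
                        simulate_sites, summarize_profile)

reference = generate_reference(seed=1)          # 3 x 10 Mb synthetic genome
sites, _ = simulate_sites(TetherModel.retargeted(), reference, 1000, seed=2)
random_sites = sample_random_sites(10_000, reference.bundle.layout, seed=3)

annotator = Annotator(reference.bundle)
test = summarize_profile(annotator.annotate(sites))
control = summarize_profile(annotator.annotate(random_sites))
for cat in ("in_gene", "repeat:Satellite", "near_peak:H3K9me3"):
    res = compare_profiles(test, control, cat)
    print(cat, round(test.percentages[cat], 1),
          round(control.percentages[cat], 1), res.stars)
```

prints

```
in_gene 10.1 28.7 ***
repeat:Satellite 46.1 4.7 ***
near_peak:H3K9me3 49.6 4.7 ***
```

— the retargeted signature: only 10.1 % of simulated retargeted sites fall
in genes versus 28.7 % of uniform random sites, while satellite membership
and strong-peak proximity are enriched roughly tenfold, each with
three-star (p < 0.001) χ² significance. The `examples/` directory holds
one short script per capability, from read merging to the end-to-end
read-level pipeline.

A thin CLI wraps the same functions
(`risprofile simulate | preprocess | call-sites | hotspots | clonality |
run-all`); `run-all` consumes a YAML run config whose defaults are the
standard thresholds above.

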