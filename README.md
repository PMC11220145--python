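# cagmosaic

Quantification of **somatic CAG-repeat instability** at an HTT-exon-1-like
locus from amplicon sequencing, for researchers studying trinucleotide
repeat expansion (Huntington disease alleles and the intermediate 27–35 CAG
range in particular).

The expanded CAG tract is unstable in somatic tissue: over a lifetime, cells
accumulate repeats beyond the inherited length, and the degree of that
mosaicism tracks inherited length, age, and tissue. Measuring it from PCR
amplicons is confounded by polymerase slippage ("stutter"), which creates
expansion-like products from perfectly stable templates. This package
implements the full measurement and inference chain:

1. **Read decomposition** — each read is anchored by the constant flanks and
   greedily decomposed into `(CAG)n (CAACAG)m (CCGCCA)k (CCG)p (CCT)q`,
   separating the canonical interruption structure from
   loss-of-interruption variants.
2. **Genotyping** — stutter-aware peak calling on the
   (structure, CAG-length) read histogram yields the two inherited alleles.
3. **Expansion ratio** — for an inherited allele with `n` reads at its
   length and `n₊ᵢ` reads at `+i` CAG (same structure),

   `ratio = Σᵢ₌₁¹⁰ n₊ᵢ / n`

   with an eligibility rule that excludes alleles whose window is
   contaminated by backward stutter from a longer same-structure allele.
4. **Stutter baseline** — a branching-process PCR model, calibrated so a
   single 33 CAG template yields 2.3 % +1 artifact products, provides the
   expected stutter-only ratio; a measured ratio is *genuine* somatic
   expansion only above that baseline. Per-offset tissue contrasts
   (fold changes) are included.
5. **Cohort models** — per-category (normal / intermediate /
   reduced-penetrance / full-penetrance) OLS of ratio on inherited CAG and
   age with a CAG×age interaction, a per-CAG age-effect scan, and a
   covariate-adjusted (ANCOVA) two-group comparison.

A first-class synthetic-data module generates every input the pipeline
needs — single-molecule and bulk stutter read sets (FASTQ), a ten-tissue
brain fixture, and cohort tables — with recorded ground truth, so the whole
chain is testable without any external data. See `docs/methods.md` for the
models and calibrations.

## Worked example

Simulate the putamen and cerebellum samples of the shipped ten-tissue
fixture (a heterozygous 18/33 CAG carrier), run the pipeline, and compare
against the stutter baseline; then fit the intermediate-allele cohort model:

```python
from cagmosaic import (compute_expansion_ratio, fit_category_regression,
                       is_genuine_expansion, load_scenario)
from cagmosaic.pipeline import PipelineConfig, genotype_reads
from cagmosaic.synthetic_data import scenario_cohort, scenario_tissue_readsets

spec = load_scenario("family-A-ten-tissues")
spec["tissues"] = {k: spec["tissues"][k] for k in ("putamen", "cerebellum")}
cfg = PipelineConfig()
for tissue, rs in scenario_tissue_readsets(spec, seed=42).items():
    gt = genotype_reads(rs.reads)
    profile = compute_expansion_ratio(gt.histogram_by_structure, gt.allele_long)
    baseline = cfg.baseline_for(profile.inherited_cag)
    genuine, margin = is_genuine_expansion(profile, baseline)
    print(f"{tissue:11s} genotype {gt.allele_short.cag}/{gt.allele_long.cag} CAG  "
          f"ratio {profile.ratio:.3f}  baseline {baseline.baseline_ratio:.3f}  "
          f"genuine {genuine} (margin {margin:+.3f})")

table, _ = scenario_cohort(load_scenario("IA-cohort-135"), seed=42)
fit = fit_category_regression(table, "intermediate")
print(f"intermediate: n={fit.n}  beta_cag={fit.beta_cag:.4f}  "
      f"beta_age={fit.beta_age:.6f}  R2={fit.r2:.3f}")
```

Output:

```
cerebellum  genotype 18/33 CAG  ratio 0.049  baseline 0.023  genuine True (margin +0.025)
putamen     genotype 18/33 CAG  ratio 0.105  baseline 0.023  genuine True (margin +0.082)
intermediate: n=135  beta_cag=0.0041  beta_age=0.000152  R2=0.729
```

Reading this: in the putamen sample 10.5 % of the DNA molecules carry more
CAGs than the inherited 33 — far above the 2.3 % that PCR stutter alone
would produce — while the cerebellum shows about half that. In the
simulated blood cohort the expansion ratio rises by ~0.004 per inherited
CAG and ~0.0001 per year of age.

The same stages are available as a CLI:

```bash
cagmosaic simulate-reads --scenario family-A-ten-tissues --seed 7 -o out/
cagmosaic genotype --fastq out/putamen.fastq -o out/putamen
cagmosaic ratio --genotypes out/putamen.genotype.tsv \
                --histogram out/putamen.histogram.tsv -o out/profiles.tsv
cagmosaic simulate-cohort --scenario IA-cohort-135 --seed 7 -o cohort.tsv
cagmosaic regress --cohort cohort.tsv --mode table1 -o report.json
cagmosaic compare --cohort two_groups.tsv -o comparison.json
cagmosaic run --fastq s1.fastq --fastq s2.fastq --metadata meta.tsv -o out/
```

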