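# dietbarcode

Quantitative DNA-metabarcoding diet analysis for insectivores, validated
against camera-recorded diets.

## The problem

Field ecologists studying generalist insectivores (for example nest-box
songbirds such as the pied flycatcher *Ficedula hypoleuca*) need to know not
just *which* arthropod taxa are eaten but *how much* each contributes.
COI metabarcoding of feces detects prey taxa well, but whether sequencing
read counts can be read quantitatively — as relative ingested biomass —
requires validation against an independent diet record.  The natural
benchmark is nest-camera footage, where each delivered prey item is scored
by taxon and by size relative to the bill, giving a relative scaled biomass
contribution (RSBC) per taxon per session.

`dietbarcode` implements the full analysis chain needed for such a
validation, plus a ground-truth simulator so that every stage is testable
end to end without any external data:

* **amplicon processing** — merge read pairs (posterior quality
  `Q = Q1 + Q2` on agreement, `|Q1 − Q2|` on disagreement, capped at 41),
  truncate 25 bp primers from each end and to 220 bp, filter on expected
  errors `EE = Σ 10^(−Q/10) ≤ 0.4`, dereplicate (strand-aware, singletons
  removed), greedy centroid clustering at 97% identity with two-parent
  chimera removal, map reads back at 97%, and subtract pooled
  negative-control counts with a floor at zero;
* **taxonomy** — megablast-style best-hit search against a local reference
  library (28-bp exact word seed, linear gap cost, Karlin–Altschul
  e-values) scored with the weighted grade
  `0.5·coverage + 0.25·escore(e) + 0.25·identity`, with reliability bands
  at grades 97 and 90;
* **diet metrics** — relative read abundance (RRA) per sample at order or
  family rank with parasite-order exclusion, two-step averaging
  (percentage per sample first, then an unweighted mean), frequency of
  occurrence (FOO), camera RSBC, alpha diversity and rarefaction;
* **community statistics** — Pearson correlations with Fisher-z CIs,
  Bray–Curtis distances, NMDS (Kruskal stress-1), beta-dispersion
  permutation tests, PERMANOVA pseudo-F, and the FOO contingency
  chi-square (no continuity correction, restricted to taxa with FOO ≥ 3);
* **synthetic data** — mock communities with Dirichlet biomass, per-taxon
  amplification efficiencies, camera sessions whose delivery probability is
  proportional to biomass/size (so size-weighted counts recover biomass),
  and paired FASTQ reads with configurable per-base error, chimeras, host
  reads and control-shared contamination, all with a complete truth table.

## Worked example

```python
from dietbarcode import datasets
from dietbarcode.stats import foo_contingency_chisq
from dietbarcode.pipeline import RunConfig, run_pipeline
from dietbarcode.synthetic import SimulationConfig

# Published digestion check: gizzard vs intestine FOO of 17 common genera
g, i = datasets.gizzard_intestine_foo()
res = foo_contingency_chisq(g, i, min_foo=3)
print(f"chi2 = {res.statistic:.3f}, df = {res.df:.0f}, p = {res.p:.2f}")

# Small synthetic validation run, end to end
config = RunConfig(
    seed=42, n_orders=6, n_parasite_orders=1, n_taxa=8,
    n_sessions=5, items_per_session=100,
    simulation=SimulationConfig(
        read_depth_per_sample=2000, per_base_error_rate=0.005,
        chimera_rate=0.02, host_read_fraction=0.05,
        control_contamination_reads=70, sample_contamination_reads=5,
    ),
)
summary = run_pipeline(config)["summary"]
v = summary["validation"]["order"]
print(f"OTUs: {summary['otu_count']} (true taxa: {summary['n_true_taxa']})")
print(f"unassigned read fraction: {summary['unassigned_fraction']:.4f}")
print(f"non-arthropod reads pruned: {summary['pruned_read_fraction']:.4f}")
print(f"mean RRA vs mean RSBC (order level): r = {v['r']:.3f} "
      f"(95% CI {v['ci'][0]:.2f}-{v['ci'][1]:.2f}, n = {v['n_taxa']} orders)")
```

prints

```
chi2 = 3.721, df = 16, p = 1.00
OTUs: 9 (true taxa: 8)
unassigned read fraction: 0.0178
non-arthropod reads pruned: 0.0525
mean RRA vs mean RSBC (order level): r = 0.989 (95% CI 0.83-1.00, n = 5 orders)
```

The chi-square of 3.721 on 16 df says gizzard and intestine FOO of common
genera are statistically indistinguishable (no digestive bias).  In the
synthetic run the pipeline recovers one OTU per simulated prey taxon plus
one host OTU (pruned away by class), leaves only chimeric reads unmapped,
and the per-order read abundances track the camera-derived scaled biomass
closely — the property that justifies reading RRA as relative biomass.

A command-line interface mirrors the stages:

```bash
dietbarcode all --out run_dir --seed 1          # full synthetic study
dietbarcode simulate --out sim_dir --seed 1     # FASTQ + truth tables only
dietbarcode sweep --out sweep_dir --seed 1      # EE/truncation sweep
```

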