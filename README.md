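# pbmkit

Analysis of transcription-factor DNA-binding specificity from universal
protein-binding microarrays (PBMs), built for comparing a reference
protein against a variant allele — the motivating case being the SIX1
homeodomain and its Wilms-tumour Q177R variant, whose single substitution
switches the preferred binding site from a `GGGTATCA`-type motif to a
`GTGT`-core motif. The package also quantifies electrophoretic mobility
shift assay (EMSA) titrations and estimates binding affinities (Kd) so
that the two proteins' affinities for a probe can be compared as a fold
ratio.

Because raw array scans are not portable, the package ships a synthetic
data generator: probe intensities are simulated from a known
position-weight-matrix (PWM) occupancy model on a universal all-10-mer
array design, so every analysis stage can be validated against ground
truth.

## What it computes

**E-score.** For a DNA word *w* (8-mers by default, collapsed with
reverse complements), split probes into foreground *F* (contain *w* on
either strand) and background *B* (the rest). Keep the brightest
⌈|F|/2⌉ and ⌈|B|/2⌉ probes of each group, rank them jointly, and rescale
the Mann–Whitney *U* statistic:

    E(w) = U / (|F½| · |B½|) − 1/2   ∈ [−0.5, 0.5]

A rank statistic, so invariant under any monotone transform of the
intensities. A **pattern E-score** is the same statistic with *F* defined
by matches to an arbitrary IUPAC pattern (e.g. `NGTGTNNN`) instead of a
single word.

**Seed-and-Wobble.** The top-scoring 8-mer class seeds a PWM: every
position in a seed ± 3-bp window is substituted ("wobbled") base by base,
and each variant's background-subtracted median probe intensity becomes
the base's column weight. A secondary motif is derived after masking
probes that match the primary consensus.

**EMSA.** Percent bound per lane is 100·bound/(bound+unbound); a
titration is fitted with a 1:1 Langmuir isotherm
`percent(P) = f_max·P/(Kd+P)` (optional Hill slope), and affinities are
compared as Kd ratios.

## Worked example

```python
import pbmkit

design = pbmkit.design_array(k=10, probe_length=36, seed=0)   # ~39k probes
truth = pbmkit.GroundTruth(pbmkit.consensus_pwm("GGGTATCA", 0.85),
                           noise_sigma=0.2, rng_seed=1)
exp = pbmkit.simulate_pbm(design, truth, protein_label="SIX1-ref")

res = pbmkit.SeedAndWobble(exp).fit(secondary=False)
print(res.summary())
```

```
Seed-and-Wobble fit: SIX1-ref (replicate 1)
  probes: 38837
  defined 8-mer classes: 32643 / 32896
  max E-score: 0.5000
  primary seed 8-mer: GGGTATCA
  primary consensus: YTMGGGTATCAVBM (14 columns, 9.34 bits total)
```

The planted consensus is recovered exactly as the seed, embedded in the
14-column wobble window (the near-uniform flanks contribute the
degenerate IUPAC codes). Pattern E-scores separate the two allele motifs
on this reference-allele experiment:

```python
pbmkit.pattern_escore(exp, "GGGTATCA")   # 0.5    (own motif: maximal)
pbmkit.pattern_escore(exp, "TGTGTCAT")   # 0.024  (variant motif: ~null)
```

EMSA titrations on the standard 1–300 nM ladder, with a 10-fold true
affinity difference:

```python
weak  = pbmkit.fit_kd(pbmkit.simulate_emsa_curve(200.0, noise_sd=2.0, rng_seed=1))
tight = pbmkit.fit_kd(pbmkit.simulate_emsa_curve(20.0,  noise_sd=2.0, rng_seed=2))
print(tight.summary())
print(pbmkit.affinity_ratio(weak, tight))   # 9.87
```

```
Langmuir isotherm fit
  lanes: 10  (concentrations 1-300 nM)
  Kd    =      19.84 nM  (SE 1.52)
  f_max =        100 %   (SE 1.83)
  RSS   =      48.16
  converged: True
```

The whole two-allele comparison (duplicate simulated arrays per allele,
E-score tables, motifs, pattern E-score panel, optional EMSA fits, JSON
report) runs as one command:

```sh
pbmkit run-all --outdir results/demo
```

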