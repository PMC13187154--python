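# aeroferm

Comparative analysis of aerobic fermentation (the Crabtree/Warburg-type
rapid-glycolysis phenotype) across budding yeasts.  The package implements
the computational stages of a cross-species study of glycolytic rate, for
researchers who measure extracellular acidification on plate readers and
want to relate it to gene content, expression and promoter architecture:

1. **ECAR quantification** (`aeroferm.plate`) — phenol-red absorbance
   kinetics → pH via an affine standard curve → per-well OLS slopes (pH/h)
   → dextrose-dependent ECAR as the paired carbon-minus-control slope
   difference, aggregated to species means.
2. **Phylogenetic comparative analysis** (`aeroferm.comparative`) —
   Pearson and PGLS correlation of gene-family copy numbers with ECAR.
   PGLS fits y = β₀ + β₁x + ε with ε ~ N(0, σ²C_λ), where C is the
   Brownian-motion covariance of the phylogeny (C[i,j] = shared root-to-MRCA
   branch length) and Pagel's λ scales its off-diagonal (λ=1 default, ML
   profiling optional).
3. **Orthogroup expression** (`aeroferm.expression`) — HTSeq-style counts
   summed per orthogroup along with member gene lengths; TPM per sample
   (each sample sums to 10⁶); Welch t-tests on log2(TPM+1) against a
   reference species.
4. **Promoter motif scanning** (`aeroferm.motifs`) — 1 kb upstream windows
   of coding sequences, strand-aware, scanned for exact matches to an IUPAC
   degenerate consensus (default Gal4p site CGG-N₁₁-CCG, which is its own
   reverse complement); per-family summaries take each species' best
   ortholog; binding-site ablation for reporter-construct design.
5. **Synthetic data** (`aeroferm.simulate`) — seeded generators with
   recorded ground truth for every stage, so the full analysis runs and is
   testable without external downloads.

See `docs/methods.md` for models, assumptions and design choices.

## Worked example

Simulate a plate assay for a rapid fermenter (true ECAR −0.032 pH/h, three
biological replicates, absorbance noise 0.005 sd) and quantify it:

```python
from aeroferm import plate, simulate

cfg = simulate.SimConfig(seed=101, true_slopes={
    "Sat_dispora": (-0.034, -0.002),   # carbon, control slopes in pH/h
    "K_pastoris": (0.020, -0.002),
})
sim = simulate.simulate_plate(cfg)
replicates, trait = plate.process_plate(sim.plate, sim.layout, sim.calibration)
print(trait[["strain", "mean_ecar", "sd_ecar", "n_replicates"]])
```

```
        strain  mean_ecar   sd_ecar  n_replicates
0   K_pastoris   0.020865  0.002707             3
1  Sat_dispora  -0.032122  0.003435             3
```

The rapid fermenter's mean ECAR is recovered within ±0.005 pH/h of the true
−0.032; the positive value marks a respiring, non-acidifying species.  The
same objects feed the comparative stage:

```python
from aeroferm import comparative
ts = simulate.simulate_tree_trait_counts(simulate.SimConfig(seed=202))
pgls = comparative.pgls_by_family(ts.trait, ts.counts, ts.tree, lam=1.0)
print(pgls.loc[pgls.family == "total", ["beta", "se", "r_signed", "p"]])
```

```
        beta        se  r_signed             p
13 -0.001045  0.000042 -0.976132  1.880027e-21
```

i.e. the fitted trait change per extra glycolytic gene copy (true value
−0.001 pH/h per copy) with its GLS standard error, signed correlation and
p-value under the Brownian covariance.

The full narrative analysis lives in `analysis/01_ecar_assay.py` through
`analysis/04_promoter_motifs.py`; each script simulates its stage's inputs,
runs the pipeline, prints what it found and writes tables under `results/`.
A command-line interface (`aeroferm ecar|comparative|ogexpr|motif|simulate`)
wraps the same functions for file-based use.

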