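# scarsig

Detection of homologous-recombination (HR) deficiency from paired
tumor/control sequencing. HR-deficient tumors ("BRCAness") respond to PARP
inhibition and platinum, but many lack the classic biallelic *BRCA1/2*
lesions — so the case for HR deficiency has to be built from compound genomic
evidence. `scarsig` implements that evidence chain as a tested, reusable
library and CLI for cancer genomics analysts:

1. **Mutational catalogs** — somatic SNVs binned into the canonical 96
   trinucleotide channels, with triplet-motif correction between capture
   regions and whole genome.
2. **Supervised signature decomposition** — non-negative least squares
   against known signatures, v ≈ W·h with h ≥ 0, run twice with
   per-signature relative-exposure cutoffs for specificity, plus 95%
   profile-likelihood confidence intervals per exposure, per-Mbp
   normalisation, and Fisher/Benjamini–Hochberg cohort enrichment.
3. **Purity / ploidy / allele-specific copy numbers** — grid inversion of
   the mixture model r = [ρ·TCN + 2(1−ρ)]/[ρ·ψ + 2(1−ρ)] and
   b = [ρ·CN_B + (1−ρ)]/[ρ·TCN + 2(1−ρ)] over ρ ∈ [0.15, 1], ψ ∈ [1, 6.5],
   scored by length-weighted distance to allowed integer copy-number states,
   with decrease-of-heterozygosity (DH ≤ 1) and non-negativity exclusions.
4. **Genomic-scar scores** — HRD-LOH (subchromosomal LOH segments > 15 Mbp)
   and large-scale state transitions (LST: state switches between adjacent
   > 10 Mbp segments not explained by whole-arm events), after 3 Mbp
   smoothing; their sum is the combined instability score.
5. **HR-gene events** — biallelic-inactivation calls from germline ACMG
   classes plus somatic second hits over a 23-gene candidate panel, and a
   paired-biopsy variant look-up (shared vs private variant sets under a 20×
   coverage rule).

A synthetic cohort generator (`scarsig.synthetic`) produces every input with
recorded ground truth, so the full pipeline is testable without
controlled-access patient data. See `docs/methods.md` for models,
assumptions, and limitations.

## Worked example

Simulate a three-sample cohort from two active signatures, then decompose
with confidence intervals:

```python
import pandas as pd, scarsig as ss

W = ss.make_signature_matrix(10, seed=11)            # 96 x 10 signatures
cfg = ss.SimulationConfig(seed=42, n_samples=3,
    active_signatures={"S1": (0.4, 0.6), "S3": (0.2, 0.3)})
E = ss.sample_cohort_exposures(cfg, W.columns)       # true exposures
cat = ss.simulate_catalog(W, E, seed=43)             # multinomial catalogs
cuts = pd.Series(0.05, index=W.columns)              # relative-exposure cutoffs
fits = ss.decompose_with_ci(cat, W, cuts)
print(ss.exposures_to_frame(fits).query("retained").round(3).to_string(index=False))
```

```
   sample signature  absolute  relative   ci_lo   ci_hi  retained  ci_excludes_zero
sample_01        S1   224.281     0.733 207.520 241.042      True              True
sample_01        S3    87.396     0.286  74.020 100.773      True              True
sample_02        S1   245.802     0.604 225.893 265.710      True              True
sample_02        S3   168.887     0.415 153.101 184.672      True              True
sample_02       S10    21.685     0.053   1.736  41.635      True              True
sample_03        S1    43.460     0.762  35.570  51.350      True              True
sample_03        S3    21.308     0.374  15.011  27.605      True              True
```

Each row is one retained signature in one sample: `absolute` is the number
of mutations attributed to the signature (true values here were 212.4/93.6,
250.7/156.3 and 36.2/20.8 for S1/S3 — all inside the 95% CIs), `relative` is
that count divided by the sample's burden, and `ci_excludes_zero` marks
confident detections. The spurious S10 call in sample_02 shows why
signature-specific cutoffs matter: with the packaged defaults
(`ss.default_cutoffs()`) rather than a flat 0.05, weakly supported
signatures need much stronger evidence to survive the second pass.

The same generator drives the copy-number branch:

```python
genome = ss.toy_genome()
events = (ss.CNEvent("chr1", 0, 25_000_000, 2, 0),)   # copy-neutral LOH
cfg = ss.SimulationConfig(seed=5, tcc=0.6, ploidy=2.0, cn_events=events)
prof = ss.simulate_cn_profile(cfg, genome)
fit = ss.grid_fit_tcc_ploidy(ss.summarize_segments(prof.segments, prof.snps))
print(fit.selected)
# {'tcc': 0.61, 'psi': 2.0, 'distance': 0.0324}  -- truth was (0.60, 2.0)
res = ss.score_sample(fit.segments, genome)
print(res.hrd_loh, res.lst, res.combined)
# 1 0 1  -- the single interstitial 25 Mbp LOH segment scores one HRD-LOH event
```

Shell equivalents: `scarsig simulate`, `scarsig fit-signatures`,
`scarsig fit-cn`, `scarsig score-hrd`, `scarsig classify-hr`,
`scarsig lookup-vaf` (see `scarsig --help`).

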