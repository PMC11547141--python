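# trbdisorder

Survival stratification of cancer cases from the intrinsic-disorder chemistry
of blood-sourced T-cell-receptor-beta (TRB) variable regions.

Immunologically cold tumors (uveal melanoma, *MYCN*-amplified neuroblastoma)
resist stratification by conventional immune-infiltrate measures. This
package implements an alternative: recover TRB V(D)J recombination reads from
a patient's blood-derived nucleotide reads, reconstruct each receptor's full
variable-region peptide, score its intrinsic disorder, average per patient,
and test whether the upper and lower halves of the cohort differ in overall
survival (OS).

## Method

For each sequencing read, the miner looks (on both strands) for an exact
anchored match to a germline V gene segment — the longest suffix of the V
nucleotide sequence ending at the conserved-cysteine codon found in the read
(default ≥ 20 nt) — and, downstream, to a J gene segment — the longest
suffix of the J 5' region ending at the glycine codon of the FGXG motif
(default ≥ 15 nt). The CDR3 is translated from the cysteine codon through
the doublet-phenylalanine codon and kept only if *productive*: span a
multiple of 3 (no frameshift) and stop-free.

Each CDR3 is then stitched into a full V-CDR3-J peptide. The anchored
longest common substring (LCS) between the CDR3 and the V — required to
begin at the V's conserved cysteine, hence equal to the longest common
prefix of the CDR3 and the V suffix from that cysteine — is removed from the
V together with everything after it, and the full CDR3 is appended; the J is
trimmed to start at its FG doublet and appended without duplicating the
shared phenylalanine. Sequences whose LCS is the bare single `C` are
excluded as unreliable junction calls.

Sequences are scored two ways:

* **mean disorder** — per-residue disorder-probability tracks from external
  predictors (IUPred2/ANCHOR2-style TSV; the predictors are inputs, not
  re-implemented), averaged over the residues of the full V-CDR3-J peptide;
* **residue-set fractions** of the CDR3 alone — fractions of
  disorder-promoting (T A G R D H Q K S E P), α-helix-promoting (M A L E K),
  β-turn-promoting (N P G S D) and β-sheet-promoting (V I T Y F W L)
  residues.

A case's value is the unweighted mean over all its sequences (one value per
read). Cases are split at the 50th percentile (n = 64 → 32/32; n = 53 →
27/26), arms are compared with Kaplan–Meier curves and the log-rank test,
and effects are checked against clinical covariates with Cox
proportional-hazards regression (Efron ties), admitting only covariates with
a univariate p ≤ 0.1.

A fully seeded synthetic-cohort generator (`trbdisorder.synthetic_data`)
emits reads with planted recombination junctions in random background,
stand-in disorder tracks, and survival times whose hazard jumps by a
configurable ratio between the disorder halves — the ground truth used
throughout the test suite.

## Worked example

```python
from trbdisorder import CohortConfig, simulate_cohort, run_pipeline

cohort = simulate_cohort(CohortConfig(seed=1))   # 64 cases, HR 4, 20% censoring
result = run_pipeline(cohort.reads, cohort.reference, cohort.clinical,
                      tracks=cohort.tracks, parameter="track:disorder")
r = result.report
print(f"arms {r.n_lower}/{r.n_upper}, "
      f"median OS {r.median_os_lower:.1f} vs {r.median_os_upper:.1f} months, "
      f"log-rank chi2 {r.chi_square:.2f}, p {r.p_value:.2e}")
```

prints

```
arms 32/32, median OS 38.0 vs 8.4 months, log-rank chi2 25.88, p 3.64e-07
```

— the cohort splits into equal arms, the low-disorder arm survives markedly
longer (its KM median is 38.0 months against 8.4), and the log-rank test
rejects equality decisively, as expected for the simulated hazard ratio
of 4.

The same analysis is available as a shell pipeline:

```sh
trbdisorder simulate --out cohort --seed 9
trbdisorder mine     --reads cohort/manifest.tsv --reference cohort/ref.fa --out reads.tsv
trbdisorder assemble --reads reads.tsv --reference cohort/ref.fa --out regions.tsv --fasta regions.fa
trbdisorder score    --regions regions.tsv --tracks cohort/tracks \
                     --params disorder_fraction,track:disorder --out case_scores.tsv
trbdisorder survive  --scores case_scores.tsv --clinical cohort/clinical.tsv \
                     --parameter track:disorder --out report --plot
```

`regions.fa` is a peptide FASTA suitable as input to external disorder
predictors; their per-residue output drops back in as `--tracks`.

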