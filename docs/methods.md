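# Methods notes

## Pipeline model and assumptions

The package treats a patient's blood-derived short reads as a sample from a
mixture of genomic background and rearranged TRB loci. A read is called a
recombination read when one strand carries exact germline evidence for a V
segment and a J segment in the correct order with a productive CDR3 between
the anchors. Three assumptions follow:

* **Exact anchored matching.** Matches are exact substrings, anchored at the
  biologically fixed points — the V match must end at the conserved-cysteine
  codon, the J match at the glycine codon of the FGXG motif. Anchoring pins
  the reading frame and both CDR3 boundaries in one step, so no separate
  frame search is needed. Exactness is conservative: sequencing errors or
  allelic mismatch near an anchor lose the read rather than corrupt the
  call. Because occurrence of a length-L anchored suffix implies occurrence
  of every shorter one, the longest match is found by bisection.
* **Both strands, first productive call wins.** The forward orientation is
  tried first; calls are strand-symmetric because a read and its reverse
  complement yield the same (V, J, CDR3) triple. Equal-scoring segment
  matches resolve to the lexicographically smallest id, and output order is
  (case, read), so mining is deterministic.
* **Productivity.** A CDR3 is kept iff the anchored span is a multiple of 3
  and its translation is stop-free; failures are logged with a reason
  (`frameshift`, `stop_codon`, `anchors_out_of_order`,
  `anchor_outside_read`, `unmatched`) and every input read is accounted for
  exactly once.

## Stitching

The variable-region peptide is `v_prefix + cdr3 + j_suffix`. The V/CDR3
overlap is the *anchored* longest common substring: it must start at the V's
conserved cysteine and at CDR3 position 0, which reduces it to the longest
common prefix of the CDR3 and the V suffix from the cysteine — unique by
construction, so no tie-break is needed. Single-`C` overlaps are excluded
(junction calls with no germline corroboration beyond the cysteine are
unreliable); a CDR3 whose leading residue is not the V's cysteine is a
`no_overlap` rejection.

On the J side the trimmed germline suffix starts `FG` while the CDR3 already
ends at the doublet phenylalanine. The J suffix is therefore joined from its
glycine, reconstructing the canonical `...FGXG...` junction without a doubled
F. (The alternative reading — tolerate the doubled F — was rejected because
it produces a peptide that no in-frame translation of the locus could
generate.)

## Scoring

Disorder tracks are external per-residue probabilities in [0, 1]
(IUPred2-style TSV: comment lines, 1-based position, residue, one or two
score columns, positions consecutive from 1). The per-sequence statistic is
the arithmetic mean over residues of the full V-CDR3-J peptide, matching how
long-sequence disorder predictors are summarised. Residue-set fractions
(disorder/helix/turn/sheet-promoting) are computed on the CDR3 alone by
default, where full-length predictors are unreliable; both statistics accept
either input. The four sets intentionally overlap (e.g. A promotes both
disorder and helices). Case values are unweighted means over the case's
sequence values, one value per read — recurrent identical clonotypes count
once per read, on the view that the read multiset is the sample.

## Survival analysis

Cases are ranked by the case-level parameter (ties broken by case id) and
the first ⌈n/2⌉ form the lower arm, so 64 cases split 32/32 and 53 split
27/26. Clinical cases with no recovered TRB read have no score; they are
excluded from stratification and logged. Kaplan–Meier estimation, the
two-group log-rank test and Cox regression are delegated to lifelines; the
KM median is the smallest time with S(t) ≤ 0.5 and is reported as undefined
when the curve never reaches 0.5. Cox models use Efron tie handling (the
standard default; the tie burden at monthly resolution is small) and report
hazard ratios with Wald 95% CIs. Constant covariates are dropped with a
warning rather than fit. The univariate screen admits a covariate into the
multivariate model only when its single-covariate Cox p ≤ 0.1. All p-values
are two-sided and deliberately uncorrected across the disorder parameters;
reports carry that caveat explicitly.

## Synthetic cohorts

The generator emulates the pipeline's inputs with full ground truth:

* **Reference** — `n_v = 3` V segments (30 aa, cysteine at index 26, three
  germline residues beyond it) and `n_j = 2` J segments (FG doublet at index
  5, eight-residue framework tail), random but seeded; nucleotide sequences
  are fixed-codon back-translations (lexicographically first codon per
  amino acid), which keeps plants stop-free and byte-reproducible.
* **Reads** — 64 cases × (20 recombination + 80 background) reads of 150 nt
  by default. A plant is germline V (30 nt before the cysteine-codon end,
  plus 3 germline residues into the CDR3), a back-translated junction middle
  of 2–6 aa, and germline J from 4 residues before the doublet to its 3'
  end, embedded at a random offset in uniform-random background, random
  strand. Each case draws a disorder propensity ρ ~ U(0.25, 0.85) governing
  whether middle residues come from the disorder-promoting or
  order-promoting pool — the between-case signal. A configurable fraction of
  plants is made non-productive (inserted nucleotide or in-frame TAA) to
  exercise rejection paths.
* **Tracks** — the stand-in scorer assigns `0.25 + 0.5·1[disorder-promoting]
  + N(0, 0.05)` per residue, clipped to [0, 1]: monotone in the
  disorder-promoting fraction, which is all the pipeline requires of a
  predictor.
* **Survival** — exponential event times, baseline mean 60 months, hazard
  multiplied by the configured ratio (default 4) for the upper half of true
  case-mean disorder (direction flag defaults to "low disorder → longer
  survival"; the reverse is available). Censoring is an independent
  Uniform(0, m) time with m solved numerically so the expected censored
  fraction matches the configuration (default 20%).

What the generator does *not* emulate: sequencing error, quality scores,
coverage structure, allelic diversity, clonal expansion, somatic
hypermutation, or any realistic relationship between receptor chemistry and
hazard beyond the planted step function. Passing tests therefore demonstrate
correctness of the machinery and calibration of the statistics under ideal
reads — not that the disorder–survival association holds in real cohorts,
which requires protected patient data and external predictors.

## Numerical choices and problem sizes

* Match thresholds 20 nt (V) / 15 nt (J): at 4^-20 per offset, a false
  V match in ≤ 10^5 background reads is essentially impossible, keeping
  mining precision exact while staying below the typical germline content of
  a 150-nt junction-spanning read.
* The log-rank statistic's null calibration is checked over 2,000
  two-arm exponential simulations (50 + 50 cases); detection power over 200
  end-to-end replicates at hazard ratio 4, n = 64, 20% censoring, with 6
  recombination + 4 background reads per case — sizes chosen so the whole
  suite runs in about two minutes while keeping Monte-Carlo error small
  relative to the asserted bands.
* The permutation cross-check of the log-rank p uses 15 + 15 cases: large
  enough that the chi-square approximation and the exact permutation null
  agree; at very small sizes (e.g. 3 + 3) they legitimately diverge, which
  bounds where the asymptotic p should be trusted.
* Cox coefficients are cross-checked against a direct grid maximisation of
  the partial likelihood, and the Cox score test at β = 0 against the
  log-rank chi-square (an algebraic identity on tie-free data, asserted to
  1e-6).

## Known limitations

* Exact matching cannot rescue reads with sequencing errors inside the
  anchor regions; real-data recall depends on error rate and germline
  coverage of the read.
* One frame per V record; references with leader sequences or frame-shifted
  exports must be pre-trimmed.
* The V amino-acid prefix used in stitching is the reference's full prefix
  before the cysteine; region boundaries (e.g. whether the leader is
  included) are a property of the supplied reference, not of this code.
* Cox results at very small n with near-separated covariates have unstable
  Wald statistics; the univariate gate may then exclude a covariate whose
  log-rank p is small. This mirrors the behaviour of any Wald-based screen.
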