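# Methods

## Model and pipeline

The package treats a venom gland as a set of transcripts with relative
abundances and asks whether two independent measurements of those
abundances agree: fragment counts from RNA-seq, and peptide identification
events from LC/MS of the secreted venom. The pipeline stages and their
order are fixed: FPKM quantification → low-abundance retention filter →
six-frame search-space construction → peptide matching → fractional
length-normalized scoring → bootstrap contaminant threshold → log–log
Pearson correlation, with an optional reciprocal-best-hit (RBH) robustness
comparison against an external protein reference.

Assumptions worth stating explicitly:

- **Fragment-level counts.** The count table is assumed to be paired-end
  fragment units (RSEM-style), already resolved to transcripts;
  multi-mapping resolution and isoform EM are out of scope. FPKM uses the
  full transcript length, with no effective-length correction.
- **Detection independence.** With adequate chromatographic separation,
  peptides are detected independently of one another, so protein scores
  are *not* normalized by the experiment-wide event total. This makes the
  score degree-1 homogeneous in counts (doubling every identification
  event doubles every score), which the tests assert exactly.
- **Fractional attribution.** An identification event whose peptide
  occurs in several proteins is split equally among them. Totals are
  conserved to floating-point precision; a documented consequence is that
  duplicating a protein halves each copy's score.
- **One predicted protein per transcript.** The six-frame search space
  necessarily contains junk ORFs from non-coding frames. For the
  transcript–protein comparison, each transcript is represented by its
  best-scoring retained ORF; other ORFs are search-space artifacts, not
  additional proteins. Without this rule, chance matches of short peptides
  onto junk ORFs of abundant transcripts enter the scatter as spurious
  points.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| FPKM retention threshold | 1.0 | FPKM | standard low-abundance cut; values exactly at the threshold survive ("less than" is removed) |
| enzymes | trypsin, chymotrypsin, Glu-C, none | — | cleavage after R/K, F/L/W/Y, D/E respectively; no proline exception by default (available as an option), matching the stated specificities; Glu-C has an E-only dialect option |
| missed cleavages | 2 | sites | typical search-engine setting |
| peptide length window | 6–50 | residues | typical LC/MS detectability |
| I/L equivalence | off | — | the searched databases distinguish I and L by sequence; MS cannot, so an option exists |
| bootstrap confidence | 0.999 | — | the contaminant interval is a 99.9% CI |
| bootstrap resamples | 10,000 | — | stable 99.95th percentile |
| bootstrap statistic | mean | — | percentile CI of the mean contaminant score; median and a tolerance-interval reading are options |
| correlation transform | log10 | — | both quantities span decades; identity and rank (Spearman) are options |
| zero handling | exclude + tally | — | no pseudocount by default; a pseudocount would be an option a user sets deliberately |
| RBH matrix / gaps | BLOSUM62, 11/1 | score | standard protein local-alignment parameters; gap of length k costs open + (k−1)·extend |
| RBH score floor | 50 | raw score | stands in for an E-value acceptance cut; at desk-scale database sizes Karlin–Altschul E-values are both unnecessary and unstable, so results are *not* BLAST-equivalent, and ties are excluded rather than broken |

## The synthetic venome generator

`GeneratorConfig` defaults define the simulated study conditions:

- 300 transcripts; relative abundances log-uniform over six decades
  (`abundance_log10_range=(0, 6)`), normalized to sum to 1. A
  class-structured mixture is deliberately not the default; the log-uniform
  prior is the simplest distribution with the right dynamic range.
- Each transcript is a random open reading frame (start codon, random
  sense codons, stop codon), 240–1500 nt; its protein is the frame +1
  translation. Optionally a fraction of transcripts are mutated copies of
  earlier ones (`paralog_fraction`, `paralog_identity`), which induces
  shared peptides and exercises fractional attribution.
- 10⁶ sequencing fragments drawn from a single multinomial with category
  probabilities ∝ abundance × length.
- 10 contaminant proteins, drawn as random-ORF translations so their
  residue composition (hence digestion statistics) matches the rest of the
  proteome, placed at the 0.05 quantile of the biological abundance
  distribution — present, but much less abundant than the major venom
  components.
- Detection: each candidate peptide from each (protein, enzyme) digestion
  has expected identification count
  `kappa · abundance^exponent · exp(N(0, σ))`, realized as a Poisson draw;
  zero counts are omitted and identical (peptide, enzyme) observations
  from different proteins are summed. Defaults: exponent 1, σ = 0.5,
  `kappa = 1e5`. The rate constant is set so the contaminant panel sits at
  the detection limit: contaminants are detected at low level while
  essentially every protein above contaminant abundance yields peptides,
  the qualitative regime the pipeline is designed for.

What the generator does **not** emulate: raw reads or assembly error,
spectra and search-engine scoring (identified peptides appear directly),
retention times or digestion-efficiency differences between proteins
(enzyme bias enters only through which peptides exist), signal peptides
(synthetic proteins have none; the effective-length convention is
exercised by unit tests instead), UTRs (synthetic transcripts are pure
coding sequence), and incomplete transcripts. Passing recovery tests
therefore show that the statistical machinery is correct under the stated
model, not that real venom data will reach the same correlation strengths
— real data add digestion bias, post-translational modification, and
timing differences between tissue and venom sampling.

## Numerical choices

- **Percentiles** in the bootstrap use the inverse empirical CDF (numpy's
  `higher`/`lower` methods). On small discrete resample spaces this makes
  the percentile of the bootstrap distribution agree exactly with
  exhaustive enumeration of all n^n resamples (e.g. for scores {1,2,3},
  the upper 99.95th percentile of the 27 equally likely resample means is
  3.0), which the tests exploit; linear interpolation would instead return
  values between atoms.
- **Degenerate contaminant sets**: one score degenerates the interval to
  that value with a warning; an empty set is an error. The end-to-end
  drivers fall back to a zero threshold (no filtering) when fewer than two
  contaminant scores exist, and log that.
- **Zero variance / too few pairs** in the correlation raise typed errors
  rather than returning NaN.
- **Local alignment scores** are floored at zero (the empty alignment is
  always admissible) and tie-broken nowhere: ambiguous best hits are
  dropped.
- **Determinism**: every stochastic stage derives its own substream from
  the single configured seed; pipeline outputs carry a header with
  version, configuration hash (analysis parameters only, not the output
  path) and seed, and reruns are byte-identical.
- **Matching** uses a 4-mer index with verification, equivalent by
  construction (and by test) to a full substring scan; peptides shorter
  than the seed fall back to a direct scan.

## Problem sizes

Recovery experiments run at the simulated study scale (300 transcripts,
10⁶ fragments, three enzymes plus the no-enzyme channel) and are replicated
over 20 seeds in the test suite and 5 seeds per condition in
`scripts/acceptance.py`; the RBH robustness check uses 40 proteins mutated
at 10% of residues. These sizes were chosen so a full run of suite plus
acceptance script completes in minutes on one core while keeping every
stage's statistics meaningful.

## Known limitations

- The detection model is a stand-in: the underlying study gives no
  quantitative model of LC/MS detection, so the Poisson/log-normal choice
  and its parameters are not calibrated to any instrument.
- Under abundance-independent detection (exponent 0), every protein scores
  near the contaminant level; the threshold then retains only a small,
  fluctuating subset, and the null correlation is estimated on few pairs.
  This is faithful behavior — the filter is doing its job — but it makes
  the null experiment's r noisy across seeds.
- Whether counts should be summed across enzymes and replicate runs before
  scoring is not externally specified; the default sums everything, and a
  distinct-peptide-species mode exists.
- The RBH score floor is a raw-score stand-in for an E-value cut; users
  comparing against real BLAST results should expect differences.
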