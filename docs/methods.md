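# Methods

## Library construct model and in-silico PCR

The SELEX library is modelled as a fixed-flank construct: a 21 nt
constant 5' region, a 20 bp random insert (written as an N run in the
single-stranded template), and a 22 nt constant 3' region. In-silico
PCR finds, for each primer, the longest 3'-terminal suffix that matches
the template exactly and returns the top strand of the extended duplex
(forward primer sequence + inter-site template span + reverse
complement of the reverse primer). Two deliberate rules:

- **N handling.** N in a template is a wildcard for matching and is
  preserved verbatim in the product, so design checks run directly on
  the N-containing template. However, an annealing site must pair at
  least `min_anneal` (default 15) *non-N* template positions: wildcards
  contribute no base pairing, and without this floor a long primer
  would "anneal" anywhere inside the 20-base random region.
- **Exactness.** Annealing is exact matching of the 3' suffix — no
  mismatches, no thermodynamics. The reference primers match their
  targets perfectly, so melting-temperature modelling adds nothing to
  the construct arithmetic (83 bp cycle-0 product, 144 bp sequencing
  library). Multiple candidate sites for one primer raise an ambiguity
  error rather than guessing.

Coordinates are 0-based, half-open. Barcodes are stored exactly as
printed in the reverse primers; whether an instrument reports the i7
index as-is or reverse-complemented is left to the caller (the
demultiplexer takes the observed barcode from a read tag or the read's
3' end). Default demultiplexing allows 0 mismatches: the built-in set
has minimum pairwise Hamming distance 4, but a general set is only
guaranteed unambiguous at distance ≥ 2, where one mismatch cannot be
resolved; with `max_mismatch=1` a read matching two barcodes is left
unassigned.

## Read pre-processing

Trimming reproduces a fixed-length insert workflow: (1) optional exact
5'-prefix clip for runs whose reads start upstream of the insert, (2)
removal of the maximal 3' run of bases below the quality threshold
(default Phred 30) — only the tail, because the insert occupies the 5'
end of a single-end read, (3) hard trim keeping the first
`post_trim_length` bases (default 20), (4) rejection below
`min_read_length` (default 20). With the defaults every survivor is
exactly the 20 bp insert, the step is idempotent on its own output, and
input = passed + rejected always holds. Output is FASTA by default
(qualities are spent after trimming); original read ids are preserved.

## K-mer quantification

All 4^k k-mers are tallied per sample using 2-bit codes (A=0, C=1,
G=2, T=3, leftmost base most significant). Reads are concatenated with
N separators and windows are scanned vectorially; windows containing N
(or spanning read boundaries) are skipped and excluded from the window
total, so Σ occurrence = n_windows exactly. Three outputs per sample:

- `occurrence[w]`: total windows equal to w;
- `presence[w]`: reads containing w at least once. The **presence
  fraction** presence/n_reads is the abundance statistic used
  downstream: bounded in [0,1], robust to within-read repeats, and
  standard for fixed-length SELEX inserts. Occurrence counts are kept
  alongside so an occurrence-frequency statistic can be derived if
  preferred.
- a per-position base-frequency matrix (the "model"), a QC object that
  exposes positional composition bias; it requires uniform read length
  and flags all-N columns.

k is capped at 10: the exhaustive 4^k table (~1.05 M entries at k=10)
is the practical limit for dense counting on a workstation, and the cap
is surfaced as an explicit capability error. Strand collapsing onto
canonical k-mers (min of a code and its reverse complement) is
available but off by default: counts reflect the sequenced strand.
Ranking is deterministic — fraction descending, ties broken by
ascending code.

## Enrichment

FC(w) = [(p_s(w)+α)/(n_s+α)] / [(p_r(w)+α)/(n_r+α)] with pseudocount
α = 1 on presence counts, so absent k-mers give finite, symmetric fold
changes; α = 0 is allowed only when the reference has no zero counts.
Each cycle-N sample is referenced by default to the cycle-0 sample of
its *own replicate library* (every starting library has a slightly
different sequence distribution; pooling cycle-0 libraries is available
as an option). No-protein controls pass through the same computation
and are reported as their own rows — the control is a comparison, not a
correction, so it is never subtracted or used to rescale.

The A/T summary groups k-mers by their count of A/T letters (k+1
categories; at k=5 the six categories have C(5,j)·2^5 members). Within
each (protein, cycle, category) the fold change is first averaged over
k-mers per replicate library; the report is the mean of the replicate
means and their standard deviation (ddof=1) as the
technical-variability bar. Because category membership is identical
across replicates the two averaging orders coincide; the per-replicate
path is used so the dispersion is a genuine between-library statistic.
A single replicate reports SD 0 with a warning.

## Sequencing-depth analysis

Sub-sampling is uniform without replacement (a shallower sequencing run
of the same pool), deterministic per depth from one seed. Concordance
is the squared Spearman rank correlation (average ranks on ties)
between sub-sampled and full-depth presence-fraction vectors, per
(depth, k); fractions rather than raw counts are correlated, though
ranks are identical within a fixed read count. At full depth no
sampling occurs and the report is exactly 1. The squared convention
matches how rank concordance is usually plotted for this analysis; raw
ρ is available for sign inspection. A top-m overlap statistic
(shared fraction of top-ranked k-mers, deterministic tie rule)
complements the correlation for shallow-depth comparisons.

## Simulator

The simulator generates the full experimental design: per replicate a
uniform-random cycle-0 insert pool, then for each selection round

    p(read) = b + (1 - b) · s · max over windows of affinity(window)

followed by resampling with replacement back to the per-sample read
count (PCR amplification, no per-sequence bias — the negative control
exists precisely to detect such bias empirically). The no-protein
control lineage undergoes b-only retention plus the same
amplification. Max-over-windows models single-site occupancy; b is the
wash-resistant background. Affinity models:

- consensus: λ^HammingDistance(window, consensus), λ ∈ (0,1) (specific
  binder, default λ = 0.1);
- A/T content: (n_AT/k)^γ (promiscuous A/T-rich binder, default γ = 1,
  window 5), floored at ε = 10⁻⁶ so all-G/C windows stay selectable.

Reads are emitted as insert + constant 3' flank truncated to 40 nt
(the sequencing primer sits at the 5' flank, so the read starts at the
insert; a flag prepends the 5' flank for prefix-clip testing), with
per-base substitution errors (default 10⁻³), constant quality 40, and
the sample's 8 bp barcode attached as a read tag. Quality-trimming
behaviour is tested with dedicated low-quality fixtures, not the
simulator.

Defaults are the targeted study design: 20 bp insert, 3 replicate
libraries, 6 cycles with cycles 0/1/3/6 sequenced — 3 cycle-0 samples
plus protein and control triples at each later cycle, 21 samples
matching the 21-barcode table — and 20,000 reads per sample, the
midpoint of the 10,000–50,000 depth band that the depth analysis shows
is sufficient for short k-mers. Selection strength 0.5 and background
capture 0.05 give a clear but non-saturating enrichment signal while
keeping the control bottleneck mild (b·n = 1000 retained reads per
round). All randomness derives from a single seed through spawned
sub-streams (per replicate: pool generation, protein lineage, control
lineage, sequencing error), making outputs byte-identical across runs
of the same configuration.

What the simulator does *not* emulate: PCR sequence bias and
heteroduplex artifacts, bead-capture kinetics, concentration-dependent
(thermodynamic) binding, quality-score degradation along the read, and
optical/index-hopping noise. Passing pipeline tests on simulated data
therefore validates the computational contracts (counting, pairing,
normalization, rank concordance), not the wet-lab behaviour of a given
protein.

## Numerical and design notes

- Presence-pair deduplication uses a read-id × 4^k integer key; safe
  for < 2⁶³/4^k ≈ 8.8·10¹² reads at k = 10.
- Fold changes are finite and positive by construction (α > 0);
  mismatched k or canonical flags between sample and reference are
  errors, not coercions.
- `coverage_analysis` derives per-depth child seeds from one seed, so
  adding a depth does not perturb the others.
- Problem sizes in the test suite (50,000 reads/sample for
  planted-motif recovery, 100,000 reads for depth concordance, 10,000
  for null calibration) were chosen to give comfortable signal-to-noise
  margins for the properties under test at k = 5–10.

## Known limitations

- k ≤ 10; gapped k-mers and probabilistic motif models (PWM/HMM
  discovery) are out of scope.
- Single-end reads only; the 20 bp insert does not need paired ends.
- No statistical significance testing of enrichment; fold change with
  replicate dispersion and a negative control is the intended readout.
- The in-silico PCR is a construct-arithmetic tool, not a mispriming or
  melting-temperature predictor.
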