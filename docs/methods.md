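# Methods

## Background and scope

N7-methylguanosine (m7G) on internal RNA positions can be converted to an
abasic site by mild NaBH4 reduction. During reverse transcription the abasic
site is read through with near-random incorporation, so the modification is
recorded as a mutation — a substitution, insertion or deletion — in the cDNA,
and shows up in sequencing as an elevated per-position mutation rate in
treated samples relative to untreated controls. `m7gmap` implements the
computational half of that experiment: it consumes multi-sample
`samtools mpileup` text (alignment and pileup construction are upstream,
with per-Base Alignment Quality applied there), estimates error-aware
mutation frequencies per position and condition, tests treated-vs-control
differences and replicate consistency, and calls candidate modified
positions. A simulator and a power module make every statistical property
testable without sequencing data.

## Pileup grammar

The tokenizer resolves the full mpileup base-string grammar: `.`/`,` are
strand-resolved reference matches, letters are mismatches, `^X` (mapping
quality consumed, discarded) and `$` mark read boundaries, `*`/`#` are
deletion placeholders (each consumes a quality character and is classified
as a deletion observation), `>`/`<` are reference skips (quality consumed,
no observation), and `+n seq` / `-n seq` are indel tokens attached to the
preceding observation. An insertion token upgrades its anchor observation to
kind *insertion* — the token is the only place the inserted bases exist. A
deletion token does **not** upgrade its anchor: the deleted positions carry
their own `*` placeholders on their own rows, and upgrading the anchor would
count one deleted read twice; with this rule the parser's per-site counts
are identical to what samtools itself reports on a constructed alignment
(verified in the test suite against a real `samtools mpileup` run). Reads
observed as `N` are discarded before modelling — under the two-class model
below they carry no information. Indels have no quality character of their
own in mpileup, so an insertion-upgraded observation keeps its anchor's
error probability, the only defensible per-read proxy.

Coordinates are 1-based inclusive throughout (mpileup's native convention,
matching rRNA position numbering such as SSU 527); the only 0-based
conversion happens in the BED6 export.

## The two-class mixture likelihood and EM estimator

Each observation at a site is modelled as a draw from a mixture: with
probability `f` the read derives from a mutated template, with `1 - f` from
the reference template. With `e` the Phred-derived error probability of the
read base (`10^(-Q/10)`, capped at 0.75 to keep the classes identifiable):

| observation  | P(obs \| reference) | P(obs \| mutated) |
|--------------|---------------------|-------------------|
| match        | `1 - e`             | `e / 3`           |
| substitution | `e`                 | `1 - e/3`         |
| indel        | `e`                 | `1 - e`           |

The `e/3` factor is the uniform-miscall convention on the 4-letter channel;
indels sit outside that channel, hence no `/3`. All non-reference kinds are
pooled into one "mutated" class because the biological signal is itself a
mixture of all mutation types.

`f` is fitted by EM: E-step posterior `w_i = f p_mut,i / (f p_mut,i +
(1-f) p_ref,i)`, M-step `f <- mean(w_i)`; initialization at the raw mutated
fraction, tolerance 1e-8 on `f`, at most 200 iterations. With all `e = 0`
the estimate is exactly `k/n`. Plain EM converges only linearly when the
optimum sits at the `f = 0` boundary (clean controls), so each pair of EM
steps is followed by an Aitken delta-squared extrapolation that is accepted
only if it does not decrease the log-likelihood — the monotone-ascent
guarantee is preserved and boundary sites converge in a handful of steps.
Observations are stored run-length-compressed over unique (class, quality)
pairs and all computations are count-weighted; this is exactly equivalent to
the per-read formulation (reads are exchangeable given class and `e`) and is
what makes genome-scale runs and large power simulations cheap. An empty
observation set yields an undefined estimate (NaN), not an error.

## Likelihood-ratio tests

*Between conditions* (df = 1): H0 one shared `f` for pooled treated +
control observations, H1 one `f` per condition, each condition pooling its
replicates (the ML fit under a shared per-condition rate; per-replicate
variation is the within-test's job). *Within a condition* (df = k-1 for k
informative replicates): H0 one shared `f`, H1 one per replicate. Both
statistics are `2(l1 - l0)`, clamped at 0 (numerical noise from the EM
tolerance can produce tiny negatives), referred to the chi-square upper
tail. The test is two-sided in the rate difference; the calling step later
requires the difference to be positive. When the shared estimate sits at the
`f = 0` boundary the plain chi-square reference is used rather than the
50:50 mixture — a conservative choice. p-values are floored at 1e-320 and
`-10 log10(p)` capped at 3200 to stay printable.

With error-free observations both tests reduce exactly to the classical
binomial LRTs, which the test suite exploits as an independent closed-form
oracle.

## Filters and calling

Per position the pipeline reports depths, `f_treated`, `f_control`, the rate
difference `delta`, the between-group p-value and both within-group
p-values, then sets independent filter flags:

- `low_depth` — combined treated + control depth must strictly exceed 1500
  (default; 500 in single-replicate mode, the rRNA-style analysis where
  within-replicate tests are undefined and skipped);
- `high_control_rate` — the unweighted mean of per-replicate control
  estimates must be below 1%;
- `replicate_inconsistent` — either within-group p-value below 1e-5;
- `untestable` — a condition with zero observations.

Candidates require all filters passed, `delta >= 0.5%` (inclusive at the
cutoff) and between-group `p < 1e-50`, restricted to reference-G positions
by default (other bases stay in the table — NaBH4 also hits dihydrouridine
and m1A gives similar signals — and `--all-bases` lifts the restriction).
Depth is counted as parsed usable observations, not the raw mpileup depth
column. All thresholds are CLI-overridable; the defaults are the tRNA/mRNA
analysis values.

## Simulator

The generator factorizes the signal at a modified position into
stoichiometry `theta` (fraction of molecules modified — what a mixing
experiment varies) and detection level `r` (per-fully-modified-molecule
mutation yield, which varies with sequence context; observed values for
real m7G sites span roughly 0.5-25%). A treated read at a modified position
is mutated with probability `theta * r`: an indel for a configurable
fraction of mutation events (default 0.25, split evenly between insertions
and deletions — read-through of abasic sites produces a broad mutation-type
mixture), otherwise a uniformly chosen non-reference base. Every base-bearing
read then passes a symmetric error channel at rate `10^(-Q/10)`
(`error_phred`, default Q30 = 1e-3); control samples receive error only.
Depths are Poisson (default mean 2000 per sample), strands Bernoulli(1/2),
references i.i.d. with a configurable GC fraction, and every draw comes from
one seeded generator, so output is byte-reproducible. The truth ledger
records planted and realized non-reference counts per (position, sample);
at error 0 parsed counts equal planted counts exactly, which the tests
assert site by site.

`quality_phred` decouples the *written* quality characters from the error
channel. By default they match; setting quality above the channel rate
emulates the realistic post-BAQ regime in which true background mutations
(RT misincorporation, residual misalignment) exceed what per-base qualities
claim — this is precisely why the method tests treated against control
rather than trusting qualities alone. Null-calibration checks use background
1e-3 with Q40 reads: with qualities exactly matching the background the
error-absorbing likelihood makes the tests strongly conservative (measured
rejection at nominal 0.05 is ~0.004), which is safe for calling but not a
calibration regime.

What the simulator does not emulate: read-level structure (fragment
lengths, position-dependent coverage, strand bias), PCR-duplicate families,
RT-stop attrition at modified sites (small for the RT used in this
protocol), and context-dependent error. Passing tests therefore demonstrate
the statistics are correct under the model's assumptions, not that real
libraries satisfy those assumptions.

## Power

Power for one position is estimated by Monte Carlo: treated counts
`Binomial(depth, theta*r + background)`, control `Binomial(depth,
background)` (defaults: background 1e-3, read qualities Q40), each pair run
through the between-group LRT, power = fraction below `alpha` (default
1e-5, the significance level used for single-position claims). p-values are
memoized over the discrete count pairs — exact, since the LRT depends on
the data only through them — which makes dense grids cheap. At `theta = 0`
the estimate recovers the nominal level; at zero error it matches the exact
binomial tail with the critical count obtained by brute-force test
inversion (both asserted within 3 Monte-Carlo SE).

## Preprocessing

Reads begin with a 7-nt random barcode plus two fixed bases: the barcode
moves into the read name (suffix after `_`) and a sidecar TSV, 9 bases are
trimmed, and any read with an N in the barcode or shorter than the trim is
discarded (counted). Duplicate collapsing keeps one alignment per
(reference, leftmost position, strand, barcode) group. Strand is included
in the key — leftmost coordinates of opposite-strand reads rarely collide,
but treating them as one molecule would be wrong when they do. The retained
record is the lexicographically smallest read name, making the operation
deterministic, order-independent and idempotent; barcode-less reads are
kept ungrouped and counted. Small-RNA libraries (no barcode in the adapter)
simply skip both steps.

## Problem sizes used in tests

The recovery benchmark uses a 10 kb reference, 3+3 replicates at mean depth
2000 per sample, and 20 planted sites with detection levels drawn uniformly
from [0.05, 0.25] — about 2,500 G positions, of which ~2,480 are unmodified
negatives. Calibration uses 2,000 null sites at depth 1000 per group;
mixing-linearity uses 6 planted sites per stoichiometry level at depth
5000; power grids use 300-1,500 simulations per cell. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping the full suite around a minute.

## Known limitations

- The likelihood treats observations as independent given the template
  class; overlapping mates and local misalignment clusters violate this.
- The chi-square reference is asymptotic; at very low depths the tests are
  conservative (the depth filter removes that regime from calling).
- Base qualities are consumed as given. Quality re-estimation from data is
  not implemented; if qualities are badly miscalibrated upward, rates are
  underestimated (treated and control alike, so the difference is partially
  protected).
- Candidate calling identifies NaBH4-reactive positions; m7G specificity
  relative to dihydrouridine/m1A requires the base identity (G restriction)
  and, where available, knockout or annotation evidence.
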