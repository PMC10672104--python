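# Methods

This note records the models, conventions and numerical choices behind
`vnarpan`, and what the simulation-based tests do and do not establish.

## Read filtering and frame selection

Amplicon reads carry the VNAR cassette inside constant vector context, so
filters act on the *anchored VNAR span*, not the whole read:

* **Length**: strictly greater than 400 bp ("longer than" read as a strict
  inequality). The filter is applied before translation; length and
  stop-codon filters commute, so the order is immaterial (tested).
* **Frame**: the three forward frames are translated with the standard
  genetic code; the frame whose translation contains both CDR3 anchors
  (FR3b and FR4 motifs) is selected, ties broken by the lowest frame
  index. Phagemid amplicons are directional, so reverse-complement frames
  are searched only behind a `--revcomp` flag.
* **Stops and ambiguity**: a `*` (stop) anywhere within the span from the
  FR1 anchor (or, if FR1 is absent, the FR3b anchor) to the end of the FR4
  anchor rejects the read as `internal_stop`; a codon touching an `N`
  translates to `X` — deliberately *not* IUPAC-resolved — and rejects the
  read as `ambiguous_base` if inside the span. Ns outside the span are
  tolerated: only the scored region must be unambiguous. Stop takes
  precedence over ambiguity when both occur.

## Annotation

Framework anchors are full-segment regular-expression motifs (data, not
code; JSON-retargetable). Regions are the half-open intervals between
consecutive anchor matches, 0-based internally; reports render 1-based
positions from the FR1 start. Multiple matches of one anchor use the
leftmost and record a warning on the domain rather than raising.

The two *canonical* cysteines are the first Cys inside the FR1 anchor
match and the terminal Cys of the FR3b anchor; every other Cys in the
annotated span is *noncanonical*. VNAR types are assigned by a
configurable, ordered, first-match-wins rule table. The default table is

| order | type | rule |
|---|---|---|
| 1 | I | noncanonical Cys in FR2 **and** FR4, even CDR3 Cys count |
| 2 | III | CDR1 Cys, exactly one CDR3 Cys, Trp adjacent to the CDR1 Cys |
| 3 | II | CDR1 Cys, exactly one CDR3 Cys |
| 4 | V | ≥ 2 CDR3 Cys, no CDR1 Cys |
| 5 | IV | no noncanonical Cys at all |

with `unknown` as the fall-through. III precedes II because it is the
Trp-refined special case of II; with the listed order reversed type III
would be unreachable. The table is configuration because cysteine-pattern
taxonomies differ between labs.

CDR3 descriptors use the aromatic set {Ile, Tyr, Phe, Trp} by default —
Ile is not chemically aromatic but this is the counting convention the
analysis reproduces; a strict {F, Y, W} set is selectable. Net charge
counts R/K as +1, D/E as −1, His as 0. Residue comparisons are Hamming
distances; unequal-length CDR3s are reported non-comparable (a `None`
sentinel), never an exception.

## Abundance and fold change

Abundance is kept at full precision internally and rendered to three
decimals in percent. "Not detected" is *zero reads after all filters* and
is stored as NaN — an explicit marker distinct from 0 — so downstream
censoring logic is unambiguous.

Fold change divides abundances; the reference pool is always N3. A
CDR3 undetected in the reference gets a denominator floored at **one
reference read** (`100 / N_ref`), and the quotient is flagged censored:
it means "fold change ≥ value". This is the simplest detection-limit
reading of an n.d. denominator. A censored bound qualifies for selection
when the floored value itself clears the threshold: an undetected
reference can only understate enrichment, and the floor is the most
conservative resolution of that one-sided uncertainty.

Selection is the conjunction of input-n.d., `FC > 10` (strict) and
external binding activity. Binding is an input table because it is an
experimental fact about a clone, not something derivable from reads; the
simulator supplies it from ground truth (affinity ≥ the declared activity
threshold, 0.05 by default).

The heat-map matrix rows are ordered by round-3 abundance descending with
lexicographic tie-breaks — a deterministic replacement for ordering rows
by an external multiple-sequence alignment, which would add a tool
dependency without changing any computed number. A user-supplied row
order can be passed instead. Clone identity is keyed strictly on the CDR3
string; identical CDR3s on different frameworks would merge (the
simulator enforces unique CDR3s per clone).

## The panning simulator

One round under condition *c* transforms clone counts `n_i`:

1. **Preheat survival** (condition H only): `n_i ~ Binomial(n_i, s_i)`
   with per-clone survival `s_i`.
2. **Binding**: capture probability `p_i = clip(a_i · m_{i,c}, 0, 1]`
   (base affinity × condition modifier). The bound pool is a multinomial
   of size `min(bound capacity, Σ n_i p_i)` with weights `n_i p_i` —
   multinomial rather than Poisson so counts are conserved exactly and
   oracle checks stay sharp.
3. **Amplification**: weights `bound_i · b_i · LogNormal(0, σ)` with
   per-clone expression bias `b_i`, renormalised to the input pool size by
   another multinomial.

Sequencing draws reads clone-proportionally, back-translates each clone's
cassette with a fixed highest-frequency-codon table (determinism over
codon realism; translation round-trips exactly), embeds it in constant
vector flanks, substitutes bases at the error rate (positions sampled
with replacement — collisions are negligible at these rates), and
truncates a fraction of reads to ≤ 400 nt. Every read's source clone and
injected error positions go into the ledger.

### Reference study scenario and its calibration

`reference_scenario(seed)` builds: ~2,000 background clones
(Dirichlet(0.5) long-tailed frequencies; Beta(0.4, 40) affinities;
log-normal σ = 0.8 expression bias, spanning two orders of magnitude
across the library; mild log-normal condition jitter), one dominant
generalist binder (high affinity, high bias, abundant in the input — the
clone conventional picking would find), and one planted clone per
condition L/S/H whose advantage exists only under its own pressure
(16× capture modifier for L/S; near-full preheat survival against a
0.5–6 % surviving background for H). Urea confers no clone-specific
advantage, so the U pools are statistical replicates of N.

Planted initial frequencies are set by a deterministic expectation
recursion (`f ∝ f · s · p · b` per round — bottleneck caps and
renormalisation scale all clones alike) so each plant lands at an
expected **0.018 %** abundance in its own round-3 pool, inside the
0.010–0.020 % window that defines "rescuable but invisible to colony
picking". The calibration is linear in the initial frequency, so two
passes converge.

Scales are desk-sized in *compute*, not in phage: the library holds 10¹¹
in-silico phage (all arithmetic is on per-clone counts) with a 10⁹ bound
capacity. The pool must be this large because the planted clones need to
satisfy two opposing constraints at once — hundreds of physical copies in
the input (else round-1 bottleneck noise dominates their trajectories)
and an input frequency far below the sequencing detection limit (else
they fail the input-n.d. criterion). A 10⁷ pool cannot satisfy both.

### Study problem sizes

The recovery study sequences the Input pool at 50,000 reads and each
round-3 pool at 200,000 reads. At 200k reads a clone at 0.018 % abundance
expects ≈ 32 CDR3 reads while the censored fold-change threshold needs
≈ 11, giving comfortable Poisson margin; the input depth of 50k keeps the
planted input frequencies (~10⁻⁸–10⁻⁷) below one expected read. The
neutral-null study runs 50 seeds at clone-count level with a multinomial
sequencing draw — the read-level channel is already exercised by the
recovery study, and the null is a statement about count statistics.

## 4PL fitting

Unweighted least squares on the linear concentration scale (no weighting
scheme is assumed); replicates are averaged per concentration first, and
the triplicate SD is reported but not used as weights. Concentrations are
normalised by their geometric mean inside the optimiser, making the fit
exactly scale-equivariant and well-conditioned from nanomolar to
millimolar. Initialisation takes the asymptotes from the min/max
response, EC50 from the concentration nearest mid-response, and tries
hill = ±1 (the 4PL is symmetric under swapping asymptotes with a hill
sign flip; the lower-RSS start wins). A fit is *unconverged* — and its
EC50 withheld — when the data are flat, the optimiser fails, or EC50
escapes the tested concentration range by more than 100×. EC50 is
reported in molar, two significant figures in summaries.

The recovery experiment simulates 7-point, 6-fold serial dilutions from
10⁻⁴ M in triplicate with Gaussian noise at 2 % of the response range,
over EC50 ∈ [10⁻⁸, 10⁻⁵] M.

## What the synthetic studies do and do not show

The generator reproduces the *mechanisms* that make rare-clone rescue
hard — expression bias compounding over rounds, bottleneck sampling
noise, sequencing errors creating singleton CDR3 variants, truncated
reads — with clone-level phenotypes. It does not model sequence-dependent
affinity (affinity is a clone attribute, not computed from the CDR3),
PCR chimeras, quality-score structure, or paired-end artefacts. Passing
tests therefore demonstrate that the analysis recovers planted truth
under realistic count statistics and channel noise, not that any
particular wet-lab library obeys this generative model.

## Degenerate inputs and tie-breaks

Empty pools raise; an empty abundance table is representable (total 0)
and downstream operations must handle it. Top-N ties break
lexicographically on the CDR3 string, making every ranking reproducible
under input permutation. Enrichment records sort selected-first, then
fold change descending, then CDR3. All randomness flows from a single
integer seed through named `SeedSequence` streams, so FASTQ files,
ledgers and every output table are byte-identical across reruns.
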