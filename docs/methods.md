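# Methods

## The simulation process

`recombsim` evolves a genome forward in time along a user-supplied rooted
phylogeny.  The root genome is either generated (i.i.d. bases; each
position is G/C with probability `gc`, split evenly, else A/T split
evenly) or read from FASTA; it is treated as an in-frame concatenate of
protein-coding genes with no intergenic DNA.  At each internal node the
parent genome is copied verbatim to every child; no events occur at nodes
themselves.

Branch lengths are read as expected substitutions per site and may be
multiplied by a rescaling coefficient (`scale`).  The tree is then cut
into *time segments* at every distinct node depth.  This is the minimal
cut rule that makes branch membership constant within a segment, which is
the property the recombination model needs: only lineages alive in the
same segment may exchange DNA.  Each branch contributes its overlap
length `l` to every segment it crosses, and these overlaps sum exactly to
the branch length (asserted to 1e-9 in the tests).

Non-ultrametric trees are accepted.  A leaf shallower than the deepest
one simply stops appearing in later segments: the lineage is frozen — it
receives no further events and can neither donate nor receive
recombination, which is the only reading consistent with restricting
recombination to co-existing sequences.  Zero-length branches are legal
and receive zero expected events.

## Event budgets

For a branch segment of overlap `l` and current genome length `L`, the
substitution count is `M ~ Poisson(l*L)` and the recombination-attempt
count is `R ~ Poisson(rho*l*L)`: attempts per expected substitution equal
`rho`, the recombination rate defined *relative to* the substitution
rate.  `L` is the lineage's current total gene content, so genomes that
have gained accessory DNA receive proportionally more events.  Budgets
are drawn per branch segment rather than once per branch; Poisson
additivity makes the two schemes distributionally identical.

Within a segment the budgets are spent one event at a time: a uniformly
random lineage among those with remaining events is picked, then one of
its remaining events with probability proportional to its remaining
mutation vs recombination counts.  All lineages of a segment therefore
evolve simultaneously, and a recombination donor sees the donor genome
*as of the moment of the event*.

## Substitution models

Because the event count is fixed by the Poisson draw, the substitution
models reduce to conditional target distributions: given that a
substitution hits a site with base *i*, the probability that the new base
is *j*.  A substitution always changes the base, and multiple hits at a
site are allowed (each acts on the current state).

- JC69: all three alternatives 1/3.
- K2P: the transition target has weight κ, the two transversion targets
  weight 1; rows normalized.  κ = 1 reproduces JC69 exactly.
- K3P: transitions weighted κ₁, the A↔T and G↔C transversions κ₂, the
  remaining transversions (A↔C, G↔T) weight 1.  No standard labelling of
  the two transversion classes exists for this parameterization; this
  convention is fixed here and documented.
- GTR: weight(i→j) ∝ exchangeability(i,j) × frequency(j), with six rates
  (order ac, ag, at, cg, ct, gt) and equilibrium frequencies defaulting
  to ((1−gc)/2, gc/2, gc/2, (1−gc)/2) for (A, C, G, T), overridable in
  the control file.

Under non-uniform models the realized base composition drifts toward the
model's stationary distribution on long trees; this is left uncorrected
(it is the behaviour of the process being modelled), and at the
divergences used in the examples the drift is negligible.

Codon-position selection: the probability that an event lands on codon
position k is proportional to the configured weight of position k,
uniform among sites of that class.  This reweights *where* events land
only — the total is imposed by the branch lengths — which mimics
purifying selection concentrating observable change at third positions.
The genome length is always a multiple of 3 and every gene is in frame,
so position class is simply site index mod 3.

## Recombination

Tract start is uniform on the recipient; tract length is geometric on
support {1, 2, ...} with success probability 1/δ, so its mean is exactly
δ.  Genomes are linear, so a tract running past the right end is
truncated (not redrawn, not wrapped); truncation slightly lowers the
realized mean tract length, which is reported in the stats output.  The
donor is uniform among the other lineages of the segment; a lineage alone
in its segment gets `no_donor` events that are counted but change
nothing.  Events are strictly non-reciprocal: the donor is never touched.

With divergence bias enabled, the candidate tract is accepted with
probability `10^(-pi*phi)`, where `pi` is the donor–recipient per-site
difference fraction over the *homologous portion of the tract* — local
divergence, since the molecular mechanism (mismatch rejection during
strand invasion) senses the sequence it touches, not genome averages.
Rejected attempts are discarded (logged, sequence unchanged), so bias
lowers the realized recombination rate; both attempted and accepted
counts are reported so the realized rate is visible.  The default slope
Φ = 18.1 is the experimentally inferred value for *Streptococcus
pneumoniae*, intermediate among species with measured Φ.  An alternative
design would resample rejected events to preserve the attempt count;
discarding was chosen because the bias is a *probability of recombining*,
not a filter on an otherwise fixed event count.

### Accessory semantics

Tract positions inside genes the donor lacks are skipped — recombination
never writes sequence the recipient has no homolog for, so no partial
indels can arise.  When both tract breakpoints fall inside genes shared
by donor and recipient, whole accessory genes strictly between the
breakpoint genes are exchanged as units: recipient-only genes are
deleted, and donor-only genes are inserted (a full copy of the donor's
sequence), each anchored immediately after the nearest preceding donor
gene also present in the recipient.  If the two breakpoint genes appear
in the opposite relative order in the donor (possible after independent
gains), no insertions are made; shared genes are never deleted by this
mechanism.

## Gene gain and loss

Gains and losses are Poisson with means `gain_rate*l` and `loss_rate*l`.
A gain mints a brand-new gene id and a fresh random sequence of length
`gene_length` (default 999 bp; the root genome is likewise partitioned
into genes of this fixed length, the last gene absorbing any remainder)
inserted at a uniformly random rank in the gene order — the field has no
consensus on insertion loci, and rank only affects tract placement, not
the core alignment, which always follows gene-id order.  A loss removes a
uniformly chosen gene; "core" is a property of the final dataset, not a
protection during simulation.  Within a segment, a branch's flux events
are applied (in random gain/loss order) before its substitution and
recombination budgets; the budgets then see the updated genome length.
Accessory genes evolve like core genes: they mutate and recombine
whenever donor and recipient share them.

## Statistics

η is the per-site SNP density of accepted tracts: total SNPs exchanged
divided by total homologous bp recombined.  The per-event reading
("average SNPs per event") equals η·(mean tract length) and is reported
alongside, but only the per-site reading makes `r/m = ρ·η·δ`
dimensionally correct: expected recombination events scale as ρ×
(expected mutations), each moves ≈δ bp with SNP density η, so SNPs from
recombination per SNP from mutation is ρ·η·δ.  r/m is reported both via
this formula and as the direct count (SNPs exchanged / mutations); tract
truncation, bias rejection and donor-less attempts make the formula drift
above the direct count, so the direct count is labelled authoritative.
The two agree to within a few percent on contemporaneous (ultrametric)
trees, where no lineage is ever without a donor.

## Numerical and I/O choices

- Sequences are numpy `uint8` arrays (A, C, G, T = 0–3); genomes store
  one concatenate plus gene-boundary offsets, so mutations are O(1) and
  tract copies are vectorized slices.
- One `numpy.random.Generator` seeded from the config drives the whole
  run, consumed in a fixed documented order (root sequence; then per
  segment: flux, budgets, event loop).  Identical config + seed gives
  byte-identical output files; `run.log` additionally records the
  destination path and is the one file that differs between re-runs into
  different directories.
- Depth arithmetic merges node depths closer than 1e-12 (relative) when
  cutting segments, and branch terminations are matched to segment
  boundaries within 1e-9 — floating-point sums of decimal branch lengths
  are not exact.
- Event-log coordinates are 0-based, half-open, on the recipient's
  concatenate at event time (stated in each log header).
- Control files are `key = value` lines with `#` comments; unknown keys,
  missing required keys and invalid values are line-numbered errors.
  Defaults: JC69, uniform codon rates, δ = 100, bias off (Φ = 18.1 when
  enabled), flux 0, scale 1, gene_length 999, seed 0.

## What the tests exercise, and on what

All tests run on synthetic trees and generated sequences; no external
data.  The suite verifies the machinery against independent oracles
(brute-force substitution-matrix construction, position-by-position tract
diffs, a from-scratch two-lineage mutation simulator, closed-form
binomial/Poisson/geometric expectations, all stochastic checks at 4
standard errors) and the end-to-end parameter-recovery properties: GC,
codon-position spectrum and κ recovered from event logs, geometric tract
means, r/m self-consistency across ρ, and recovery of an 8-leaf input
topology by neighbor joining under low ρ in ≥90% of replicates.
Problem sizes were chosen so each check has the statistical power it
needs while the whole suite stays quick: 100 kb root sequences for
composition checks, 30–45 kb genomes and trees of total length ~0.5–4
substitutions/site (≥10⁵ events) for event-log statistics, 3–6 kb
genomes for replicate-heavy distributional and topology checks.

What passing does *not* show: the generator emulates idealized data —
a known, correct genealogy; equal-length in-frame genes; no intergenic
DNA, paralogy, duplication, rate variation beyond codon position, or
within-gene indels; recombination only from within the dataset.  Real
bacterial datasets violate all of these to varying degrees, so
conclusions about detector performance on simulated output transfer to
real data only insofar as these idealizations are acceptable.

## Known limitations

- No Wright–Fisher population dynamics, selection coefficients or
  demography: the input tree *is* the genealogy, and selection enters
  only through codon-position rates.
- No amino-acid models, gamma rate mixtures, or indels within genes.
- Recombination from external (out-of-dataset) donors is not modelled;
  gene gain is the only external DNA source.
- Under strong divergence bias most attempts are rejected; the realized
  r/m then depends on the divergence structure of the tree and is best
  read from the direct count, not the formula.
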