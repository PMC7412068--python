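# Methods

## Diagnostic sites

A diagnostic site for species *s* is an alignment column where every record
of *s* carries the same concrete base and no record of any other species
carries that base. Records with a gap or `N` at the column are excluded
from the tally; if exclusions exceed half of either the target or the
non-target group the column is skipped — with small, clean reference sets
this never triggers, but it guards field data. Ambiguity codes in
non-target records count as carrying the target allele whenever the code's
set contains it, which conservatively disqualifies the column: a primer
anchored on a maybe-shared allele is not species-specific. Fixation within
the target is required strictly (no minor-allele tolerance): an anchor that
some target individuals lack would produce false negatives.

Coordinates are 0-based, half-open, on the plus strand throughout; product
sizes are 1-based lengths in bp.

## Primer design

The forward primer's 3'-terminal base sits on the diagnostic allele; the
body is read 5'-ward from the target species' consensus with gaps removed.
Core length (default range 18–26 nt) is the shortest whose melting
temperature falls in the target window, defaulting to 52–60 °C; if no
length reaches the window, the closest-Tm length is used with a warning.
The assay anneals well below such Tm values, so the window is generous —
it mainly keeps the primer set thermally homogeneous.

Tm is nearest-neighbor thermodynamics with the unified Allawi & SantaLucia
(1997) parameter set at 50 mM monovalent salt and 0.25 µM oligo, salt
entering through the entropic correction 0.368·(N−1)·ln[Na⁺]. The tail is
excluded: Tm is a property of the template-matching core. The test suite
cross-checks the implementation against Biopython's `Tm_NN` with the same
table as an independent second computation.

### Engineered mismatch

`add_engineered_mismatch` substitutes the base third from the 3' end. The
replacement differs from the template base of every species at that column
when the alphabet allows (guaranteed when species share one template base;
otherwise the base avoiding the most species is chosen). Ties prefer
purine↔purine / pyrimidine↔pyrimidine primer:template pairings — the most
destabilizing mispairs — then alphabetical order. During panel assembly
the mismatch is applied to any primer whose 3'-terminal five bases would
otherwise mismatch some non-target species fewer than two times: primers
that already differ twice near the 3' end don't need the extra
destabilization. The offset-3 position never touches the terminal or
penultimate base, so the diagnostic anchor and the binding model's 3'
window are unaffected on true targets.

### GC-tail ladder

Tails are whole multiples (0–3) of the validated 26-nt unit; fractional
tails are not used, so any tailed primer reuses a synthesis-proven
sequence. `assign_gc_tails` enumerates all unit assignments (≤ 4⁵ for a
five-plex) and picks the one separating every pairwise product size by
`min_gap`, tailing the fewest primers first, then the least total tail
length, with a deterministic lexicographic tie-break. Defaults: `min_gap`
60 bp and `size_tolerance` ±10 bp, matching what a 2% agarose gel with a
100-bp ladder resolves comfortably (the packaged ladder's smallest gap is
95 bp).

### Panel assembly

`build_panel` processes species in sorted order (making the build
independent of record order). Candidate anchors are diagnostic sites whose
full upstream core window is gap-free and fixed within the target species,
which guarantees every target record matches its designed core exactly
before the engineered mismatch — and hence that the assembled panel
verifies. Among candidates, the greedy choice maximizes the minimum
distance between untailed product sizes already chosen, then prefers the
best Tm fit; the GC-tail optimizer resolves any residual collisions.

## Binding model and in-silico PCR

A primer core binds a template window when (i) total mismatches ≤ 3 and
(ii) the 3'-terminal 2 bases are mismatch-free (all four thresholds
configurable). Stringency is the computational analog of annealing
temperature: relaxing any threshold can only add binding sites, mirroring
how lower annealing temperatures reveal more (eventually nonspecific)
bands. The defaults tolerate the engineered offset-3 mismatch on true
targets — offset 3 lies outside the default window — while a mismatch at
the diagnostic 3'-terminal base vetoes binding outright. Binding is
threshold-Boolean; no extension-efficiency model is attempted, since no
quantitative efficiency data exist for the assay.

Ambiguity semantics: a template IUPAC code matches a primer base iff the
base is in the code's set. `N` matches everything but each N-matched
position counts half toward the total budget, summed and rounded up —
two Ns cost one mismatch. Inside the 3' window an `N` counts as a match;
the half-counts apply to the total only.

Amplicons are all convergent plus/minus site pairs within the product-size
cap (default 2000 bp). `genomic_span` runs from the forward primer's 5'
position to the reverse primer's 5' position inclusive;
`product_len = genomic_span + both tail lengths`, always. Pairs that are
not a forward-orientation primer against the reverse primer (e.g. one
primer on both strands) are reported but flagged nonspecific and never
counted as diagnostic bands.

The scanner is vectorized (sliding windows over an integer-encoded
template); the test suite proves it equal to an exhaustive per-window
scorer across strands, thresholds and ambiguity codes on 500+ random
instances.

## Species calling

Exactly one band matching exactly one expected size (± tolerance, nearest
wins) → that species; zero bands → `unknown`; anything else → `ambiguous`.
Multiple bands that all match the same species collapse to a single call
with a warning (tandem sites); bands matching different species, a band
matching no expected size, or a tolerance tie all yield `ambiguous`. The
partition is exhaustive and exclusive. `batch_report` aggregates calls
into a per-location concordance table in "called/total" form against
sequencing truth, with a totals row equal to the column sums.

## Distances

K2P: d = −½·ln((1−2P−Q)·√(1−2Q)) with P, Q the transition/transversion
proportions over pairwise-comparable columns (gap, N and ambiguity codes
deleted pairwise — per-pair deletion keeps more signal on ragged field
data than complete deletion). A non-positive log argument raises a
saturation error; matrix construction flags such pairs instead of
guessing. Neighbor joining is delegated to scikit-bio with negative branch
lengths clamped to zero; 3-taxon instances and additive matrices are
recovered exactly (tested). Maximum-likelihood trees, substitution-model
selection and bootstrap resampling are out of scope — the K2P/NJ pair is a
desk-scale surrogate used to corroborate `unknown` verdicts, not a
phylogenetics replacement.

## Synthetic data generator

`generate_complex` emulates the design substrate: a 684-bp AT-rich
(A=T=0.33, C=G=0.17) alignment of 5 species, 3 records each, with the
universal primer landing sites embedded in conserved flanks (LCO-1490 at
the 5' end, the reverse complement of HCO-2198 at the 3' end). Species
diverge from a common ancestor at 0.06 substitutions/site and records add
0.005 substitutions/site of intraspecies noise; both use a Jukes–Cantor
style process with a 2:1 transition bias (κ = 2) so K2P estimates are
nontrivial. Three diagnostic columns per species are planted by forcing a
species-private allele; the ledger records them along with every record's
mutations. Everything is deterministic given the seed.

Two generator policies go beyond the obvious: (i) intraspecies noise
avoids all planted columns **and the 26-column upstream shadow of the
record's own species' anchors** — a mutation inside a primer footprint
would stochastically delete a true band, which curated reference panels
avoid by construction; (ii) `generate_field_sample` re-scans the alignment
for diagnostic columns so the shadows cover any anchor a designer could
have chosen, and forces its outgroup sequences to mismatch every
diagnostic target allele (falling back to the least-matched base in the
rare case all four bases are claimed), emulating taxa outside the panel
whose COI is still amplifiable by the universal primers.

What passing tests on this generator show: the discovery→design→simulate→
call loop is internally consistent, specific and deterministic under the
stated divergences. What they do not show: robustness to alignment error,
indels, heteroplasmy, degraded field DNA, intraspecific variation at
anchor columns, or incomplete lineage sorting between siblings — all of
which require real sequence panels to assess.

## Packaged stand-in references

The GenBank design and validation sequences behind the packaged panel are
user-supplied inputs. For offline demonstration and testing, the package
constructs synthetic stand-ins (`synthetic_reference_templates`,
`synthetic_validation_sample`): a fixed random backbone carrying the
universal reverse site at its 3' end, with each species' forward core
embedded at the offset that yields exactly the published product size
(706/238/611/502/365 bp). The backbone seed is part of the package
contract and was chosen so every primer's 3'-anchor column is diagnostic
against the shared backbone. The validation sample mirrors the original
study's layout — per-species counts 2/49/7/30/11 plus 12 divergent
specimens that carry no allele-specific site. These objects exercise the
real computation path end to end; they are not the GenBank records, and
results on them say nothing about wet-lab performance.

## Problem sizes and numerical choices

Default simulations: 684-bp templates, five-plex panels, 10-seed
end-to-end runs with 40 queries/species + 12 outgroups — a desk-scale
workload chosen to mirror the original study's dimensions. Consensus ties
break alphabetically; species are processed in sorted order; all RNG is
`numpy.random.default_rng` seeded explicitly (the CLI requires `--seed`);
Tm agreement with the independent implementation is exact to ~1e-9 °C and
K2P matches its closed form to better than 1e-12.

## Known limitations

* Binding is mismatch-count thermodynamics-free; primer–dimer and hairpin
  screening beyond the tail/anchor logic is not attempted.
* The packaged panel's engineered-mismatch bases are embedded in the
  printed core sequences; the original-vs-substituted annotation is not
  recoverable and is stored as `null`.
* No degenerate-base primers, probe design, FASTQ input, or indel-aware
  simulation.
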