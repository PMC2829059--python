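# Methods

## Scope and model

`nhejsim` simulates extrachromosomal double-strand-break repair of designed
reporter plasmids and analyzes the repaired junctions. It covers substrate
construction, restriction digestion and ligation, stochastic repair under a
genotype profile, junction decomposition, emulated readouts, and cohort
summaries with parameter recovery. It deliberately excludes chromatin,
cell-cycle phase, homologous recombination, telomere biology, kinetic
binding models, gel migration physics, and sequencing-error handling.

## Substrate construction

The two reporters are generated from a seed. Architecture (feature order,
paired HindIII / inverted I-SceI sites around the internal exon, terminal
6-bp repeats, primer placement) is fixed; all other sequence is drawn
uniformly at ~50% GC and then scrubbed by single-base mutation until no
unsanctioned HindIII/I-SceI/BstXI/primer match remains on either strand.
Scrubbing never touches designed sites, splice signals, start/stop codons,
or the GFP reading frame (mutations inside exons are re-checked against a
stop-codon scan and rolled back if they break the frame).

Key geometry defaults (all configurable):

| parameter | default | note |
|---|---|---|
| intron span (donor through acceptor) | 2400 nt | the GFP-splitting intron |
| internal (Ad2-like) exon | 200 nt | begins with an in-frame stop, so retention kills GFP |
| HindIII–I-SceI spacing | 20 nt | within each site pair |
| intron arms outside the cassette | ~1030 nt each | the "buffer" for junction scars |
| GFP exons | 300 + 399 nt | codon multiples; spliced ORF is ATG…stop, stop-free |
| repeat-reporter fragment | 2400 nt | blunt, `GCTGAT` at both termini |
| amplicon / diagnostic | 180 / 120 bp | junction PCR and BstXI fragment |

The 6-bp terminal repeat is forced to `GCTGAT` by the blunt-cutter
geometry: AfeI (`AGC^GCT`) leaves `GCT…` at the downstream terminus and
EcoRV (`GAT^ATC`) leaves `…GAT` upstream, and `CCA·GCTGAT·TGG` is a valid
BstXI (`CCANNNNNNTGG`) site. Coordinates are 0-based, half-open, top
strand; cut offsets index the bond 5' of the named base; circular
arithmetic is modulo length. Enzyme geometries are the standard REBASE
definitions (cross-checked against `Bio.Restriction` in the tests, which
serve as an independent oracle, never as the implementation). AfeI and its
isoschizomer Eco47III are one entry.

A `LinearFragment` stores the full top strand including single-stranded
overhang regions, so digestion conserves top-strand content exactly and
cohesive ligation is concatenation with the annealed overhang written once.

## Repair simulation

Per attempt, with one seeded generator per cohort and a fixed draw order
(pathway choice, then the join's draws):

1. **Pathway choice.** Ku captures the ends with probability
   `κ·ku / (κ·ku + a)`. Captured + downstream machinery intact → C-NHEJ.
   Captured + machinery absent → unrepaired, except a small `leak_prob`
   escape to A-NHEJ. Not captured → A-NHEJ.
2. **C-NHEJ.** Compatible ends religate untouched with probability
   `cnhej_direct_prob` (default 0.25); otherwise each overhang is
   independently filled in or trimmed (uniform choice), each side may lose
   0–`small_indel_max` nt (uniform, default cap 8), and with probability
   0.2 a random insert of 1–`small_indel_max` nt is added at the junction.
   Note that fill/trim combinations on cohesive ends can regenerate the
   perfect sequence or duplicate the overhang, so perfect joins and
   overhang-length inserts both arise from processing — a deliberate
   property, since chance microhomology at classic junctions is real.
3. **A-NHEJ (commit-then-anneal).** Each end independently commits a
   resection extent drawn from a geometric distribution with mean
   `resection_mean`, resampled above `resection_max` (truncation) and above
   half the fragment length minus a 40-nt guard (so deletions from the two
   ends can never meet). Annealing then searches for a direct repeat
   (≥ `mh_min_anneal`, default 2 nt; repeats longer than 16 nt are not
   considered) whose copies lie within `mh_window` (default 25 nt) of the
   two stall points; among candidates the pair minimizing total deletion
   wins, ties broken by longer repeat, then leftmost. If no candidate
   exists the resections are re-drawn, up to `max_anneal_attempts` times,
   after which the event is unrepaired. The product keeps one repeat copy
   at the junction; the truth record satisfies
   `deletion = resection_used_left + resection_used_right − mh`.

The commit-then-anneal design is the package's resolution of a genuine
modeling fork: a global minimum-deletion search over the whole resected
region would make junction deletions independent of the resection scale,
destroying the link between deletion spectra and resection that the
recovery estimator (and the hyper-resection phenotype) relies on. Searching
only at the stall point keeps deletions proportional to resection while
still using parsimony to pick among local candidates.

Shipped genotype profiles (`data/profiles.yaml`) encode the panel of cell
lines as parameter sets: wild type (`ku=1`, capacity on, resection mean
350 nt), Ku heterozygotes (`ku=0.5`, 450 nt), Ku86-null (`ku=0.05` —
conditional knockouts retain residual protein — 690 nt hyper-resection),
DNA-PKcs/XLF/LIGIV nulls (capacity off, `leak_prob=0.02`), and a
LIGIV-null with reduced Ku. `resection_max` defaults to 900 nt, inside the
~1030-nt intron arms, reflecting limited resection processivity; this also
means junction scars stay within the intron's buffering capacity, so GFP
scoring measures joining, not scar size. The wet-lab deletion medians and
percentages these profiles echo are treated as directions, not targets: the
package asserts orderings (Ku-null ≥ WT repair, nulls ≤ 15% of WT,
microhomology elevated in nulls, Ku reduction rescues the ligase-null), not
the printed numbers.

## Junction classification

The reference is the transfected linear substrate; the product is a circle.
The product is anchored by a unique 40-mer from the middle of the
reference, rotated, and decomposed as
`product = circ(ref[k:j] + insertion)` by maximal exact prefix/suffix
matching. When the flanks overlap, the junction can slide: calls are
canonicalized to the leftmost placement, `ambiguity_shift` counts the
alternatives, and the shared run is reported as the junction microhomology
(for pure deletions the shift and the microhomology length coincide — both
measure the same flank-shared sequence). Insertions take precedence: a
junction with inserted bases is categorized `insertion` with
microhomology 0 under the canonical decomposition. Categories:
`perfect` (sequence-identical to the designed religation; only reachable on
the cohesive substrate), else `insertion`, else `microhomology` if the
shared run ≥ `mh_category_min` (default 2 nt — single-base matches occur by
chance half the time and are treated as imperfect), else `imperfect`.
Anchoring is exact by default (`max_mismatch_scan` is exposed but
sequencing error is out of scope). Products whose mid-reference anchor is
destroyed or ambiguous are reported unclassifiable, not guessed.

An exhaustive enumeration oracle (every (k, j, insertion) decomposition of
random products ≤ 200 nt) backs the classifier in the tests: reported
deletion and insertion are minimal, the placement is leftmost, and the
ambiguity count matches the number of equivalent decompositions.

## Readouts

* **Re-digestion**: perfect iff exactly one recognition site remains and
  the sequence equals the designed religation circle (any rotation);
  fragment sizes come from the in-silico digest. Band quantification is
  exact counting (no densitometry noise).
* **GFP/splicing**: positive iff exon1+donor and acceptor+exon2 are intact
  and the internal exon is absent; splicing is exact donor-to-acceptor
  excision with no cryptic sites. The percent repair is
  `100 × double-positive / red-positive` over simulated co-transfected
  cells; the red-positive denominator is the declared convention.
  Unrepaired events count as GFP-negative. Partial-digestion background is
  off by default.
* **PCR + BstXI**: the amplicon spans exact unique primer matches across
  the junction (destroyed primer → no amplicon); the cleaved fraction is
  the exact count ratio, and the repeat-collapse amplicon yields the
  120-bp diagnostic fragment.

## Parameter recovery

`recover_parameters` estimates, from junction calls alone:

* the A-NHEJ fraction `a` — the observed microhomology-category fraction
  corrected for the chance rate `c` at which classic-only junctions land in
  that category, with `c` measured from a matched classic-only null
  simulation (the laboratory workflow applies no such correction; it is an
  artifact addition needed for unbiased recovery):
  `â = (f − c)/(1 − c)`;
* the resection scale — by simulated method of moments: the
  contamination-corrected mean deletion of microhomology-category calls is
  matched against A-NHEJ-only re-simulations of the same substrate over a
  bracketing search. Re-simulation, rather than the naive closed form
  `mean deletion ≈ 2·resection_mean − E[mh]`, automatically accounts for
  resection truncation and annealing-window undershoot without tuned
  constants.

Standard errors come from a moment-level bootstrap mapped through the
locally estimated slope of the simulated response. On a grid of
`a ∈ {0.1, 0.5, 0.9} × resection_mean ∈ {200, 800}` at n = 1000 (three
seeds averaged) both estimates recover within 15% relative error in the
test suite.

## Numerical and statistical conventions

* Medians use the lower-middle convention for even n.
* Deletion statistics exclude perfect joins by default (flag available).
* Monte-Carlo checks use 3 binomial/empirical standard errors.
* Seeds: one `numpy` Generator per cohort; derived seeds stay below 2³¹.
* Problem sizes in the shipped tests (cohorts of 300–1500, recovery at
  n = 1000, oracle sweep of 1000 products ≤ 200 nt) were chosen as the
  smallest sizes at which the statistical assertions have comfortable
  margins.

## What the synthetic data does and does not show

The generator emulates the *logic* of the reporter experiments — construct
architecture, end chemistry, pathway competition, resection/annealing
bookkeeping, and the three readouts — with clean sequence, exact enzymes,
error-free "sequencing" and no transfection-batch effects. Passing tests
demonstrate internal consistency (simulator ↔ classifier ↔ assays) and
recoverability of the generative parameters; they do not validate the
biological parameter values themselves, which in real cells are confounded
by transfection efficiency, plasmid nuclease exposure, FACS saturation
(the laboratory standard-curve correction is not modeled), and repair
events with no microhomology requirement. A real A-NHEJ junction spectrum
is also more repeat-collapse-biased on the direct-repeat substrate than
the committed-resection model produces, since annealing in vivo can occur
as soon as resection exposes the terminal repeats; the canonical collapse
product is therefore exposed as a deterministic construction as well as a
stochastic outcome.

## Known limitations

* One break per molecule; no intermolecular joins or translocations.
* No third pathway is modeled; microhomology-free products arise only from
  classic joining and annealing failures.
* The geometric resection model and its 900-nt cap are phenomenological;
  only directions (hyper-resection when Ku is absent) are asserted.
* `ends_compatible` requires exact reverse-complement overhangs; partial
  annealing and mismatched ligation are out of scope.
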