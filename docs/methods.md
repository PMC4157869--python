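# Methods

## Scope and model

pollenkit implements four connected computational pieces around one
biological question — which rice genes are expressed only in pollen, and do
their promoters drive pollen-specific expression:

1. a multi-stage, cross-platform specificity pipeline over gene × tissue
   abundance tables;
2. a literal cis-element scanner over promoter windows;
3. a double-stranded DNA cloning simulator (restriction digestion with
   overhang bookkeeping, T-vector preparation, A-tailing, TA ligation,
   virtual PCR);
4. Livak ΔΔCT relative quantification.

A synthetic-data module generates all inputs with planted truth, so every
stage is testable without external databases.

## Specificity pipeline

Stages run in a fixed order: specificity call on the MPSS-style table →
high-expression selection → microarray inconsistency screen → RNA-Seq
anther-fold verification. Each stage only removes genes, so survivor
counts are monotonically non-increasing; this is asserted in tests.

Parameters (`SpecificityCriteria`, all TPM-scale):

| parameter | default | meaning |
|---|---|---|
| `tau_on` | 5 | min abundance in ≥1 pollen library to count as expressed |
| `tau_off` | 0 | max abundance tolerated in every non-pollen library (inclusive) |
| `min_tpm_high` | 1000 | high-expression cut, strict `>` ("more than 1,000") |
| `array_ratio` | 1.0 | vegetative/pollen ratio at or above which the array profile contradicts the call ("similar or higher") |
| `array_abs_ceiling` | off | optional absolute vegetative ceiling that flags genes with high vegetative signal even when pollen is higher still |
| `fold_required` | 5 | anther fold over best other tissue, inclusive `>=` ("at least 5 times") |
| `pseudocount` | 1.0 | added to numerator and denominator of every ratio |

Design choices made where the procedure was genuinely open:

- The specificity call itself has no canonical numeric definition; the
  minimal reading — expressed in at least one pollen library, silent in all
  others — is implemented with both thresholds exposed rather than
  hard-coded.
- The boundary of the high-expression cut is strict (`1000` is dropped,
  `1001` kept) and configurable.
- Microarray status is computed for every called gene so the
  probe-coverage count is reported at the stage where probe availability
  matters, but only highly expressed genes can be *excluded* by an
  inconsistent profile; genes without a probe advance. This matches the
  narrative order in which inconsistent genes are removed before RNA-Seq
  verification.
- `pseudocount=0` is allowed; a zero denominator then yields +inf fold,
  which passes (a gene detected only in anther is maximally
  anther-specific).

The heat-map transform is `log2((v + c)/(v_control + c))`; the control
column is set to exactly 0.0 rather than relying on floating-point
cancellation.

## Motif scanning

The five preloaded motifs (AGAAA, GTGA, AAATGA, AGGTCA, TGTGGTT) are
literal strings; no PWM machinery is warranted for 4–7-mers. Positions are
counted from the base immediately 5' of the start codon (position 1),
increasing upstream, so "within 1.5 kb of the start codon" is
`upstream_pos <= 1500` (boundary inclusive). All overlapping occurrences
are counted; presence fractions collapse to a per-promoter boolean, so the
overlap rule cannot change them. Scanning is forward-strand by default —
strand handling for such elements is convention-dependent — with
`both_strands` exposed; a reverse-strand hit is defined as a forward match
of the motif's reverse complement, which is asserted as a property test.

## Cloning simulator

A duplex is stored as its top strand plus one end descriptor per end.  An
overhang's sequence is recorded 5'→3' along the protruding strand.  At the
left end a 5' overhang protrudes on the top strand and a 3' overhang on
the bottom; at the right end the roles swap.  Consequences that make the
algebra simple and are enforced by tests:

- Two ends ligate iff polarities match and one overhang equals the reverse
  complement of the other (blunt–blunt also joins).  3'-T anneals 3'-A;
  3'-T does not anneal 3'-T, which is what forbids T-vector
  self-circularization.
- Joined top strands concatenate exactly, so every overhang base is
  counted once and ligation product length = vector + insert length.
- Digestion conserves the total top-strand base count across fragments.

Enzymes are registry data: IUPAC pattern plus top/bottom cut offsets
(AhdI GACNNN/NNGTC → offsets 6/5; XcmI CCANNNNN/NNNNTGG → 8/7; HindIII,
NcoI, SpeI). Offsets are not parsed from slash notation at call time —
notation dialects vary — but an import-time self-test asserts each entry
against its notation, and that every registered pattern equals its own
reverse complement (so a single top-strand scan finds all sites).
Within-site cutters only; enzymes that cut outside their recognition site
are out of scope.

The T-vector rule falls out of the cut geometry: AhdI's 6/5 offsets leave
a one-base 3' extension equal to the site's central base. A site spelled
GACAATAAGTC (central T) leaves 3'-T on its upstream fragment and 3'-A on
its downstream fragment. Only when a plasmid's two sites are *inverted*
does the backbone fragment receive the T from both; `make_t_vector`
validates both ends and rejects same-orientation constructs with an
explanatory error. Fragment selection is by length (the backbone is the
"around 10 kb" gel band); ties break toward the leftmost fragment.

Virtual PCR anneals primers by exact full-length match only — sufficient
and fully deterministic for orientation logic; no thermodynamics, no
mismatch tolerance. Circular templates are scanned across the origin and
amplicons longer than the template are rejected. Orientation verification
declares a ligation product correct iff the insert-forward ×
reporter-reverse primer pair yields exactly one amplicon.

## ΔΔCT

Replicates are averaged on the CT scale before ΔCT, efficiency is fixed at
perfect doubling (plain Livak; no standard-curve or Pfaffl correction),
and the calibrator defaults to the first sample and is set to exactly 1.
Shift invariance (adding a constant to all CTs) and monotonicity (lower
target CT never lowers the amount) are property-tested.

## Synthetic data: what it emulates and what it does not

Panels mirror the surveyed tissue layouts: 12 MPSS-like libraries with one
mature-pollen library, 8- and 3-sample microarray panels, and a 10-tissue
RNA-Seq panel with a single anther sample. Planted specific genes sit at
`specific_level` (default 2,000 TPM, so they clear the 1,000-TPM cut) in
pollen/anther tissues and `background_level` (default 1 TPM) elsewhere;
noise is multiplicative log-normal, `value = level · exp(N(0, noise_sd²))`
(default sd 0.25), chosen because all three platforms report non-negative
abundances and the displays are log2-based. "Leaky" genes additionally
express one vegetative tissue at `specific_level` in microarray panels
only — emulating genes whose array profile contradicts a sequencing-based
call — and probe-missing genes are dropped from microarray tables only.

Because planted genes carry a small positive background everywhere,
truth-recovery runs set `tau_off = background_level`; the inclusive
`<=` comparison then admits exactly the planted genes at noise 0.

A separate deterministic builder (`simulate_stagecount_panel`) composes a
panel directly from cohort counts (how many specific, probe-less, highly
expressed, inconsistent, and low-fold genes) so stage-count bookkeeping
can be checked at realistic cohort sizes; its defaults use a 1,013-gene
candidate set with 212 probe-less, 70 highly expressed, 3 inconsistent and
anther folds 2.6/2.9 for the two below-threshold genes.

What the generators do **not** model — and hence what passing tests do not
show about real data: platform-specific probe effects and saturation,
count noise at low TPM, correlated tissues and batch structure, genomic
base composition (promoter background is i.i.d. uniform, so chance motif
frequencies are higher than in AT-rich rice intergenic sequence), read or
probe-level error, partial digestion and ligation inefficiency.

The test plasmid lays out HindIII site — forward AhdI site (position 13) —
1,305-bp stuffer — inverted AhdI site (position 1,329) — NcoI site whose
internal ATG starts a reporter-ORF placeholder — random backbone.  Random
filler is cleaned by redrawing only the bases under chance
AhdI/HindIII/NcoI matches, leaving the annotated sites as the only ones.
The reporter is a placeholder ORF; the actual GFP coding sequence is
irrelevant to every computation here.

## Numerical and degenerate-input choices

- Ratios use a symmetric pseudocount; `0/0` with pseudocount 1 maps to
  fold 1 (fails the 5× rule) rather than an error.
- All-zero expression rows are valid inputs everywhere; missing cells are
  a validation error (no imputation).
- Digestion refuses molecules whose staggered-cut regions overlap
  (ambiguous products) and names the offending positions.
- Generator determinism: every generator is a pure function of parameters
  and seed (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs.
- Test and sweep problem sizes (500-gene panels over 20 seeds, 200 random
  molecules, one hundred 2-kb promoters) are chosen so the full suite runs
  in seconds while covering every code path at cohort-realistic scale.

## Known limitations

- The specificity call is a thresholding rule, not a statistical test; no
  variance model or multiple-testing control is applied (none is defined
  for the single-replicate tables the pipeline targets).
- Primer annealing is exact-match; primers with mismatches or secondary
  sites in real templates need external primer-design checks.
- The enzyme registry covers the five enzymes the workflow needs;
  outside-cutters (BciVI, BfiI, HphI, MnlI, TaaI) are not modeled.
- Real-data headline percentages (motif presence fractions, pass rates)
  depend on the external expression databases and genome sequence; the
  package reproduces the *procedures* and their arithmetic, and its
  synthetic fractions are not estimates of the real ones.
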