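# Methods

This note documents the model implemented by `daac`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Domain architectures

A domain architecture (DA) is the ordered list of InterPro *domain*-type
entries on a protein, N to C terminus. Family, repeat and site entries are
parsed but never enter architectures. Coordinates are 1-based inclusive
(InterProScan convention).

Linearization rules, fixed here because overlap handling is underdetermined
by the concept itself:

- hits are ordered by (start, end, accession);
- overlapping or abutting hits of the *same* accession merge into one
  element occurrence (they are one detection, fragmented);
- overlapping hits of *distinct* accessions each contribute one element, in
  start order — ties broken by end, then lexicographic accession, so DAs
  are reproducible;
- recurrent domains appear once per occurrence.

Every maximal unannotated region **strictly longer than `gap_min_len`
residues (default 30)** — N-terminal, internal, or C-terminal, measured on
the union of all hit spans — becomes a `GAP` pseudo-domain, a placeholder
for domains not yet discovered. A 30 aa region does not qualify; a 31 aa
region does. Proteins with zero domain hits yield no DA and are excluded
from training and querying: a GAP-only architecture carries no signal.

## Inverse domain frequency

`A_d = log2(N_t / N_d)`, with `N_d` counting proteins that contain `d` at
least once (within-protein recurrence does not inflate the count). A domain
present in every protein gets weight 0 and its columns become score sinks;
this is kept deliberately — such a domain is maximally promiscuous and
should contribute nothing. `GAP` has no weight; its columns are scored by a
fixed penalty (below).

## Alignment and similarity

Global alignment over the element strings with affine gap penalties,
computed by three-state (substitution / gap-in-1 / gap-in-2) dynamic
programming; distinct opening and extension penalties cannot be expressed
by single-penalty Needleman–Wunsch. The scoring scheme is a fixed ratio
family on a unit match score:

| parameter | default | meaning |
|---|---|---|
| match | +1.0 | same accession in one column |
| mismatch | −1.0 | different accessions (= −match) |
| gap opening | −0.5 | first column of a gap run (= mismatch/2) |
| gap extension | −0.25 | later columns of a run (= opening/2) |
| GAP-element column | −0.5 | any column pairing a `GAP` with anything |

Substitution values are multiplied by the inverse-frequency weights of both
domains; gap penalties and GAP-element columns are **not** weighted. The
substitution matrix is built on the fly over just the elements of the pair.

Normalization uses the self-alignment scores and the minimum score
`Smn = [Gop + (n2−1)Gext] + [Gop + (n1−1)Gext]` of the all-gap alignment
(GAP elements occupy columns, so they count toward n1/n2):

    SIM = min_i (S − Smn) / (Sself_i − Smn),  clamped to [0, 1].

The all-gap alignment is inside the space the DP maximizes over, so
`Smn ≤ S` always; `SIM(a, a) = 1` exactly.

Numerical/behavioural notes:

- **Co-optimal tracebacks** prefer substitution columns, then gaps in the
  second sequence, then gaps in the first; this affects only the reported
  column list, never the score.
- **GAP-bearing disjoint pairs are mildly similar.** A GAP column costs
  −0.5 while consuming one element of each DA, which can beat placing both
  elements into separate gap runs (e.g. `[A]` vs `[X, GAP]` gives
  S = −1.0 > Smn = −1.25, SIM ≈ 0.11). Accession-disjoint pairs therefore
  have SIM = 0 only when both DAs are GAP-free (given weights ≥ 1). This is
  a direct consequence of the mild GAP penalty — unknown regions may hide
  shared domains — and is verified against the enumeration oracle, not a
  numerical artifact.
- **Unknown accessions** (absent from the weight table) are an error during
  training, where the corpus must be self-consistent, but fall back to
  weight 1.0 with a warning during prediction so novel query domains cannot
  abort an annotation run.

## Ontology handling

The GO graph is read from OBO 1.2 (via `obonet`), keeping non-obsolete
terms and `is_a` + `part_of` edges (`part_of` can be switched off; the
standard GO annotation propagation relations are both). Annotations come
from GAF 2.x; rows with a `NOT` qualifier are dropped — a negation is not
an annotation — and alternate ids resolve to primary ids. Only
experimental evidence codes (EXP, IDA, IPI, IMP, IGI, IEP) back training
classes. Each annotation is propagated to all non-root ancestors; the
three namespace roots carry no information and never appear in propagated
sets.

## Classification

One independent binary classifier per GO term (multi-label overall):
members are the annotated proteins that possess a DA; terms with fewer
than `min_members` (default 3) members form no class.

Threshold tuning per class: stratified k-fold cross-validation (default 5
folds; reduced when the class cannot support 5, untrainable below 2) over
all training proteins, negatives being every non-member (closed world).
Each held-out protein is scored by its mean similarity to the members in
the retained folds (a held-out positive is never averaged against itself).
Confusion counts are pooled across folds at every grid threshold
(0 to 1, step 0.02) and the F-score-maximizing threshold is selected,
**ties resolved toward the largest threshold** — the precision-favoring
choice, since false positive annotations are costlier than missed ones in
an annotation pipeline. Pooling (rather than averaging per-fold F-scores)
keeps small classes stable. The per-class AUC comes from the pooled
held-out scores.

Prediction: a query with more than `max_domains` (default 8) real domains
(GAP excluded from the count) is dropped — similarity over very complex
architectures is unreliable. For every class with cross-validated
F-score strictly above `f_min` (default 0.7), the query's mean similarity
to the class members is compared with the tuned threshold; `≥` is used so
the grid endpoints remain reachable. Predicted term sets are *not*
ancestor-expanded at output time: each class is an independent classifier,
and expansion would manufacture predictions no classifier made. (A
consistency expansion can be applied by the caller via
`daac.ancestors`.)

Determinism: all randomness is the CV shuffle, seeded by `random_state`;
two runs with equal configuration produce byte-identical model directories
and prediction files.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes:
classes of proteins sharing an architecture core, promiscuous domains
scattered everywhere, unannotated regions, multi-label proteins, and
proteins with no functional signal. Defaults (the acceptance conditions):
200 proteins, 60-domain alphabet, 20 planted terms, motifs of 2–3 domains,
10% promiscuous domains, 30% noise-insertion rate, 30% GAP-region rate,
15% negatives, 25% multi-label carriers, 70/30 train/test split with at
least 3 training carriers per term. Domain spans are 50–150 aa and linker
lengths deliberately include 29/30/31 aa so the GAP boundary is exercised
on both sides. The ontology is a shallow DAG (3 roots, a branch layer,
planted leaves, one alt_id, one obsolete term, some `part_of` links), so
propagation, alt-id resolution and obsolete handling all do real work.

Recovery is scored micro-averaged on the held-out split against the
planted terms; a predicted non-root ancestor of a planted term counts as
correct (it is implied by the planted annotation) but recall is owed only
for the planted terms themselves.

What passing does **not** show: the benchmark has clean, planted structure —
real InterPro signatures have correlated frequencies, real GO has far
deeper topology and annotation is incomplete (open-world negatives), and
real proteomes are redundant. Recovery ≈ 0.92–0.97 here demonstrates that
the machinery is implemented correctly and is learnable end to end, not
that these figures transfer to UniProtKB-scale corpora.

## Known limitations

- Class negatives are closed-world at training time; unannotated true
  members depress measured precision on real data.
- Zero-weight (ubiquitous) domains contribute nothing to any score; two
  proteins consisting only of such domains normalize degenerately and are
  rejected rather than scored.
- The per-class threshold is a step function of the grid (0.02); classes
  whose optimal operating point falls between grid points lose up to one
  grid step of F-score.
- Alignment cost is O(n₁ n₂) per pair and O(N²) pairs for training; the
  implementation is pure Python and sized for corpora of thousands, not
  millions, of proteins.
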