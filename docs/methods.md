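# Methods

This note documents the models, conventions and design choices behind
`npevo`: what each stage computes, which parameters matter, what the
synthetic data do and do not emulate, and where the design was genuinely
open.

## Precursor model and excision grammar

A single-copy neuropeptide precursor is modeled as

    signal peptide | (propeptide) | N-flank | mature core | (Gly) | C-flank | tail

where the flanks are mono- to tetrabasic prohormone-convertase motifs over
{K, R} and the optional Gly is the amide donor for C-terminal amidation.
Coordinates are 0-based half-open throughout.  The signal-peptide boundary
is an *input* (from an external predictor or from simulator ground truth);
`crude_signal_end` offers only a labeled, fixed-prefix fallback.

Each family rule records: the core's location (`post_signal`, `c_terminal`,
`internal`, `post_propeptide`), the sets of accepted N-/C-flank motifs
(order-specific alternates are set members), whether the peptide may run to
the precursor end (AST-CC), whether a basic motif at the signal boundary is
part of the peptide rather than a cleavage site (CCHamide-2), amidation and
pyroglutamate expectations, and an advisory mature-length range.  Monobasic
sites are honored only where a family lists them; unrestricted monobasic
scanning would over-fragment precursors.  HanSolin's rare monobasic-R
C-flank variant is deliberately absent from the default registry for the
same reason: with it, the conserved GQPLRW C-terminus would be truncated at
its internal Arg.  The sNPF rule carries its potential secondary cleavage
site (Arg3) as an annotation that is reported but never applied.

### Site finding

Convertases recognize *runs* of basic residues, so the excision engine
anchors sites on maximal K/R runs downstream of the signal peptide rather
than on greedy left-to-right motif matches.  Within a run, an N-flank motif
is matched at its rightmost occurrence (the core starts immediately after
it) and a C-flank motif at its leftmost occurrence (the core ends where it
starts).  This convention is what keeps site assignment stable in the two
situations that break greedy scanning:

* a substitution adjacent to a motif extends the run (KKR or KRK around a
  planted KR) — the motif is still found at the correct boundary;
* a short motif of one set occurs inside a longer motif of the other set
  (the KR inside a C-terminal RKR) — the run is classified once, not twice.

The public `scan_cleavage_sites` operation, by contrast, implements the
plain longest-match, non-overlapping, left-to-right scan of a motif set;
it is the user-facing primitive and its semantics are kept simple.

### Candidate selection

Per the family's location, candidate segments are enumerated (first
C-flank-terminated segment after the signal for `post_signal`; last
workable N-flank for `c_terminal`; nearest N-/C-flank pair for `internal`
and `post_propeptide`).  When several segments satisfy the grammar —
typical once linkers are allowed to evolve basic residues — candidates are
ranked by evidence tiers:

1. amide-donor Gly present (amidated families only), and length within the
   family's advisory range;
2. amide Gly present;
3. length within the advisory range;
4. any segment of at least 4 residues.

The advisory length range is never a hard filter (families have documented
exceptions, e.g. the duodecapeptide ACP of one webspinner); it only breaks
ties between otherwise grammatical segments.  A CRF-DH-style precursor with
no N-flank site (the earwig situation) falls back to the C-flank-terminated
segment from the signal boundary and is flagged low-confidence.  Excision is
fully deterministic.

### PTM annotation

`amidated` is true iff the residue immediately after the core and before the
C-flank is Gly; the Gly is excluded from the core.  The source material
marks amidation but not its mechanism; the peptide–Gly–basic convention is
standard prohormone biology and is adopted explicitly.  `pglu` is true iff
the core starts with Gln in a family where the conversion is documented
(ACP, corazonin, myosuppressin); partial conversion is not quantified.  An
amidated family without a Gly yields a warning, not an error.

## Conservation statistics

AED is the mean of per-pair Poisson-corrected distances d = −ln(1 − p) over
all unordered pairs — not the Poisson correction of the mean p — matching
the "over all sequence pairs" semantics of the statistic.  `p` is computed
under pairwise deletion: sites where either sequence holds `-`, `X` or `?`
are removed for that pair only.  Gaps are treated exactly like ambiguities
because amino-acid alignment gaps carry no substitution information here.
Undefined pairs (no comparable sites, or p = 1 where the correction
diverges) are excluded from the mean with a logged count; merged cross-order
alignments can contain saturated pairs and should not abort.

Standard errors bootstrap alignment *columns* (sites) with replacement —
the standard phylogenetic convention — with 500 replicates by default and a
mandatory seed on the CLI.  The SE is the sample standard deviation of
replicate AEDs.  Medians over an even number of groups are the mean of the
two central values.  The exact sub-options of the originating desktop tool
(duplicate-sequence handling, uniform rates) are not published, so
equivalence is established against an independent brute-force implementation
(double loop, 1e-12) rather than against that tool.

Without an external aligner, `merge_alignments` stacks per-group alignments
after terminal-gap padding.  This is a documented approximation: it keeps
within-group columns intact but does not align across groups, so
cross-group AED values under padding are upper-bound-ish.  A subprocess hook
(`mafft` command template with `{in}`/`{out}` placeholders, or a
stdin→stdout filter) provides true re-alignment for users who want parity
with published alignments; alignment itself is never re-implemented.
Peptide columns are selected through gap-aware coordinate maps with a union
rule (a column is kept if any row's core covers it), preserving indels
inside peptides.

## Logos, consensus, ancestral depth

Per-column information content is log2(20) − H(freqs) in bits over non-gap
characters (`X`/`?` count as gaps); letter heights are frequency × info.  No
small-sample correction is applied by default so the closed forms stay
exact; the usual e_n = 19/(2 ln 2 · n) correction is an option flag.

Consensus uses the plurality non-gap residue where its fraction reaches the
threshold (default 0.5; ties and all-gap columns mask to lowercase `x`).

Ancestral-depth calls use exact string matching (PTM flags ignored) over a
per-order presence map plus outgroup hits.  The depth ladder is
Polyneoptera → Pterygota (requires a Zygentoma hit) → Hexapoda (requires
Remipedia or a deeper arthropod, which also sets a `pre_hexapod` flag; the
ladder deliberately stops at Hexapoda).  Because the presence criterion in
the source analyses is verbal ("found in most orders"), the minimum order
count is configurable (`min_orders`, default 5 of the ~11 groups) and is
reported with every call; the default is an interpretation, not a measured
constant.

## Synthetic data

Substitutions follow a 20-state equal-rates (Jukes–Cantor-type) model: on a
branch of length t, a site with rate multiplier r substitutes with
probability (19/20)(1 − exp(−(20/19) r t)) to a uniformly chosen different
residue.  This kernel composes exactly along paths, so the pairwise
expected p over a path T is the same closed form with t = T — which is what
makes Poisson-corrected AED the matched estimator and enables analytic
parameter-recovery checks.  No exchangeability matrix is used; richer
models would blur the estimator/generator correspondence without adding
testable structure.

The phylogeny is a star of taxon groups, each group a star of taxa.
Default conditions: ten polyneopteran order labels with group depths between
0.05 (relict orders: Grylloblattodea, Mantophasmatodea) and 0.30
(Dermaptera, Plecoptera) expected substitutions/site, six taxa per group at
within-group depth 0.05, core rate multiplier 0.05 versus linker/signal 1.0,
cleavage motifs and the amide Gly protected (rate 0), no indels and no
masking.  Indels, when enabled, are confined to linker regions and the
planted coordinates are tracked through them; random `?`-masking emulates
incomplete transcripts and flags records incomplete.  Protection of motifs
is what makes 100% planted-coordinate recovery a meaningful contract; with
`protect_motifs=False` the grammar itself erodes and recovery claims no
longer apply.

For families where only a conserved C-terminal fragment is documented
(elevenin, HanSolin, NPF-1/2, and the CRF-DH consensus), the simulator's
default ancestral core embeds the fragment at the C-terminus of a neutral,
basic-free peptide extended to the family's minimum typical length.
Simulating the bare fragment would contradict the family's own length
range and is not what those precursors look like.  The golden reference
fixtures, by contrast, always use the bare printed sequences.

What the simulator does *not* emulate: codon-level evolution, realistic
tree topology (the real order tree is only a label/depth preset),
alignment error, assembly artifacts, or biased amino-acid composition.
Passing tests on synthetic data therefore demonstrate internal consistency
of the pipeline and estimator correctness under the matched model — not
robustness to real transcriptome noise.

## Numerical conventions

* Tabular output: TSV, fixed column order, floats to 5 decimals.
* Bootstrap and simulation RNG: numpy `default_rng`; group-level bootstrap
  seeds are spawned from the master seed via `SeedSequence`, so per-group
  results are independent but fully reproducible.
* Cores shorter than 4 residues are rejected as degenerate.
* An all-gap alignment column contributes to no pair and never changes AED.
* Problem sizes used by the self-checks (panels of 6–10 families, 6–10
  groups, 4–10 taxa, 200-column linkers for parameter recovery) were chosen
  as the smallest sets on which the statistics stabilize.

## Known limitations

* Terminal-gap padding is not an alignment; cross-group AED without a
  realign hook is approximate by construction.
* Signal-peptide prediction is out of scope; wrong `signal_end` inputs
  shift post-signal cores silently.
* Disulfide connectivity (AST-CC/CCAP/trissin Cys pairs) is noted in the
  grammars' domain but not modeled.
* The ancestral-depth call is presence-based, not a tree-based maximum
  likelihood reconstruction; it mirrors consensus reasoning, with its
  sensitivity to `min_orders`.
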