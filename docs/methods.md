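# Methods

## The precursor model

`mytimine` targets secreted peptide precursors with the four-part
architecture `signal | mature core | dibasic site | anionic tail`.
The mature region of such families is hypervariable, so discovery is
driven entirely by physicochemistry, not homology. The pipeline is a
conjunction of gates; every ORF entering it is logged with the furthest
gate it reached, which makes false-negative analysis and the decoy
benchmark possible.

### ORF extraction

All six frames of each transcript are scanned. An ORF runs from the
first ATG after the previous in-frame stop to the next stop
(longest-per-stop convention: nested ATGs are absorbed). The codon-length
gate is **strict** — more than `min_codons` (50) and fewer than
`max_codons` (120), i.e. 51–119 codons inclusive — reflecting a literal
reading of the length window for molluscan AMP precursors; both bounds
are configurable. Codon length counts amino acids, excluding the stop.
ORFs running off the transcript end are kept by default
(`has_stop_codon=False`), since assembled contigs are often
3′-incomplete; `--require-stop` drops them. Coordinates are 0-based
half-open on the forward strand; frames are numbered 0–2 per strand.
Codons containing `N` translate to `X` unconditionally (no ambiguity
resolution, unlike Biopython's translator, so e.g. `GGN → X`); `X`
counts toward length but toward no named residue in any composition
fraction.

### Signal-peptide heuristic

The secretion gate is a deliberately explicit, offline heuristic rather
than a neural predictor: (a) the protein starts with Met; (b) some
8-residue window within positions 2–20 has mean Kyte–Doolittle
hydropathy ≥ 1.5 (the h-region); (c) the smallest cleavage position
p ∈ 15..30 satisfies the von Heijne (−3,−1) rule with the −1 residue in
{A,G,S} and the −3 residue in {A,G,S,T,V,C,I,L}. Proteins shorter than
18 residues are never called. Restricting the −1 set to the three
strictly small residues is what places the cleavage of the family's
consensus signal (`MKGXXLLLLTIXXALCMIXECEG`, X→A) at position 23, after
the `…C-E-G` motif, rather than mid-helix at the Cys in position 15.
Users with access to a dedicated predictor can inject its calls through
a TSV of `protein_id → cleavage_pos` overrides, which take precedence
and are labelled `source=external`.

### Cationicity window filter

The filter slides a 15-residue window over the region **after** the
predicted signal cleavage (signal peptides are hydrophobic, not
cationic; a `window_region=full` switch exists). A candidate passes if
the maximal combined Arg+Pro window fraction exceeds 0.30 — an
`either_R_or_P` mode requires a single residue type to exceed the
threshold instead — or if the maximal window isoelectric point exceeds
8. Window pI uses **side chains only**: a window is an internal
fragment, not a free peptide, so its termini do not ionize. Windows
whose charge curve never crosses zero score a sentinel: 14 when always
positive (purely basic — maximally cationic), 0 when always negative or
chargeless. Whole-peptide pI, by contrast, includes both termini and
honors the amidation flag.

### Charge, pI and pKa values

Net charge is the Henderson–Hasselbalch sum over ionizable groups
(N-terminus, K, R, H basic; C-terminus, D, E, C, Y acidic); C-terminal
amidation removes the C-terminal carboxylate. The default pKa set is
the Bjellqvist-style table used by the ExPASy Compute pI tool
(C-term 3.55; D 4.05; E 4.45; H 5.98; C 9.00; Y 10.00; K 10.00; R 12.00;
N-term 7.50, residue-independent); it is named, documented and
swappable via a JSON config, and the family-level claims reproduced by
the tests (pI > 11 for the reference mature peptides) hold across
standard tables. pI is found by bisection on [0, 14] — the charge curve
is strictly decreasing — iterated to an interval width of ~1e-14 so the
returned pH satisfies |Z| < 1e-3 even for charge-dense peptides; a
0.0005-pH-grid scan serves as the independent oracle in tests.
Percentages destined for reports are truncated (floored), so 10/35
prints as 28%, never 29%.

### Annotation and maturation

Dibasic sites are all (possibly overlapping) occurrences of KR, RR, RK,
KK after the signal cleavage; Lys-Arg is the canonical motif, but the
other pairs are accepted because the family conserves the site "nearly"
always. Among sites leaving a mature core of at least 10 residues and a
tail of at least 5, the **first** whose downstream tail has negative net
charge at pH 7 (side chains only) is selected. Anionicity is a charge
criterion, not a D/E-fraction cutoff — no fraction threshold is
established for these tails — though the tail's D+E fraction is
reported for diagnostics. Rejections carry machine-readable reasons
(`no_dibasic`, `mature_too_short`, `tail_not_anionic`).

Maturation: the convertase cuts **after** the second basic residue (the
only order that turns a planted `…G-K-R|tail` junction into an amidated
peptide, as the family's `-NH2` products require); CPE then iteratively
removes exposed C-terminal K/R; PAM removes exactly one terminal Gly (a
single amide donor, even for `…GG`) and amidates the preceding residue
— whatever it is. If that residue is basic, the amide cap blocks
further CPE action, so an amidated peptide may legitimately end in
Lys/Arg; a free-acid mature peptide never does. Re-applying the cascade
to a processed peptide is a no-op (idempotence): an amidated terminus is
a substrate for neither enzyme.

### Subfamily classifier

Rules are evaluated in the order A → B → D → C, first match winning,
over composition fractions of the mature peptide:

| label | predicate |
|---|---|
| A | R > 10%, P > 10%, Y > 10% |
| B | R > 10%, P > 10%, T > 10%, Y ≤ 10%, W ≤ 5% |
| D | R > 10%, P > 10%, and (W > 5% or T > 10%) |
| C | R > 10%, P ≤ 5% |

"Nearly devoid of Pro" is quantified as P ≤ 5%. The B/D descriptions
overlap (both Thr-rich compositions qualify); the A→B→D→C order plus
the explicit Trp/Thr tie-breakers resolve this, the reference peptides'
labels are invariant to the choice, and the whole table is replaceable
via a JSON config. The call is a pure function of composition, so
residue permutation never changes a label; each call carries the full
predicate-evaluation trace.

### Consensus and pseudogene screen

The 50% majority-rule consensus takes the most frequent symbol per
column (ties broken alphabetically and reported), drops gap-majority
columns — yielding an ungapped consensus as used for signal-peptide
summaries — and masks columns whose winner falls below 50% support with
`X`. The pseudogene screen counts `*` at non-final positions; one or
more internal stops is a pseudogene verdict.

## The synthetic benchmark

The generator emulates the *conditions* of the original discovery
setting, not its sequencing noise: planted precursors use the family's
consensus signal template (X positions drawn from {A,L,S,V}, up to two
extra hydrophobic substitutions inside the Leu run, preserving the
heuristic's conditions), a subfamily-constrained mature core of 23–42
residues, an amidation Gly with probability 0.7, a Lys-Arg site and an
anionic tail of 35–75 residues at ~30% Asp/Glu. Cores use Arg as their
only basic residue, never adjacent to another basic and never terminal,
so the planted Lys-Arg pair is provably the only dibasic site and
recovery of the planted boundaries is guaranteed by construction rather
than by filtering against the pipeline. Core and tail lengths are
sampled jointly so the precursor stays inside the 51–119-codon gate
(the individual ranges would otherwise sum past it). Precursors are
reverse-translated with uniform synonymous codons (the pipeline is
codon-usage-agnostic), wrapped in random UTRs with an in-frame stop
immediately 5′ of the ATG (pinning the reported ORF start), and
strand-flipped with probability 0.5.

Decoys come in four classes, each violating exactly one gate:
`no_signal` (hydrophilic N-terminus), `low_cationicity` (no basic
residues, acidic residues patterned every third position so *every*
window is anionic), `no_dibasic`, and `cationic_but_basic_tail`
(Lys-rich, acid-free tail, so no downstream site can look anionic).
The default mix is 50 planted / 500 decoys, seed 42, subfamily mix
A 0.35, B 0.05, C 0.35, D 0.25 (B is the rare singleton subfamily).

What passing does and does not show: on this benchmark the pipeline
attains sensitivity 1.0 with byte-exact mature-sequence recovery, and
each decoy protein fails its named gate. Real transcriptomes add
assembly errors, incomplete ORFs, codon bias and signal peptides that
the heuristic was not tuned for, so benchmark sensitivity does not
transfer to real data; the benchmark validates the *logic* of the
chain, not a real-world detection rate. Reverse-complement byproducts
of planted/decoy coding sequences occasionally satisfy all four gates
(anionic-tail codons reverse-complement to hydrophobic, signal-like
stretches), so benchmark precision sits slightly below 1; these
survivors are genuine positives of the filter definition, and the
rejection log lets any survivor's gates be re-verified.

## Numerical and interface choices

* Strict ORF bounds; 0-based half-open coordinates everywhere.
* Bisection depth 50 on [0,14]; pI sentinels 14.0 / 0.0 with a
  `defined` flag available via `return_flag=True`.
* Truncation (floor) for all reported percentages, one decimal in TSVs.
* Consensus tie-break: lexicographic, `-` sorting before letters; tied
  columns are listed in the result.
* Degenerate inputs: empty FASTA is an error at the library level but an
  empty (successful) run for `mine`; sequences shorter than the window
  collapse to a single whole-sequence window; proteins with `*` are
  excluded from physicochemistry (no defined chemistry) but legal in the
  pseudogene screen.
* CLI exit codes: 0 success, 1 usage error (including missing files),
  2 malformed input. Every run writes a summary JSON with the config
  echo, seed and SHA-256 input hashes.
* Benchmark problem sizes (50/500 transcripts, 200 oracle transcripts,
  100 oracle peptides) are the package's default study conditions; all
  complete in seconds on one CPU.

## Known limitations

* The signal heuristic is a rule-based stand-in tuned to this family's
  consensus; it is not a general-purpose predictor (no signal-anchor
  discrimination, no score calibration). External calls can be injected
  via the override TSV.
* Convertase recognition is restricted to adjacent dibasic pairs; the
  broader R-X-X-R motif class is out of scope.
* Subfamily C reference peptide C10 ends in acidic residues (`…LNTED`),
  suggesting the family's own mature-region boundary for group C may
  not coincide with the dibasic-site model; `characterize`/`classify`
  therefore operate on supplied sequences verbatim, and the discovery
  pipeline may produce a shorter C-type core than curated references.
* No coding-potential scoring, homology search, phylogenetics or
  expression quantification — the pipeline gates on physicochemistry
  only.
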