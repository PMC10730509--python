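# Methods

## Chimera design model

An optoXR is assembled by walking the backbone's topology annotation
(N-terminus, TM1–7, ICL1–3, ECL1–3, optional H8, C-terminus; contiguous,
non-overlapping, in canonical N-to-C order) and, for each maximal run of
residues assigned to the target receptor, substituting the homologous target
region. Homology is defined by a residue-level alignment column map: a
target-sourced run spanning backbone residues `[s, e]` is replaced by target
residues `[t(s), t(e)]`, where `t(·)` reads the target index aligned in the
same column, shifting toward the run interior when the target carries a gap
at a boundary column. Insertions in the target that fall inside an exchanged
run are therefore included — the swap takes the whole homologous region, as
a cut-and-paste of aligned sequences does.

Rule sets are declarative: a source (backbone or target) per segment plus
two boundary offsets.

* `proximal_tm_offset` (default **2** residues): how far a swapped
  intracellular loop extends into each flanking TM helix. Published designs
  exchange loops "with proximal TM residues" but exact counts per receptor
  are not standardized; the default is an explicit assumption and is
  configurable per design.
* `cterm_cut_shift` (default **8** residues, V2 only): how far the
  C-terminal exchange point moves from the TM7/C-terminus boundary into
  TM7, capturing G-protein contact sites identified in evolutionary
  analyses of receptor–G-protein complexes. Also an assumption, also
  configurable. H8, when annotated, is grouped with the C-terminus.

The V1 preset swaps ICL1–3 and the C-terminus (a `--v1-keep-icl1` variant
retains ICL1, reproducing two-loop legacy designs); the V2 preset retains
the backbone ICL1 and sets `cterm_cut_shift > 0`. Both append the 1D4
epitope `TETSQVAPA` by default so chimeras can be immunolabeled with
anti-rhodopsin antibodies; the epitope is configurable or removable.

Unknown residues (`X`) are accepted on input but rejected inside any region
selected for exchange — stitching unknown residues would produce an
unsynthesizable design. Every chimera residue carries a provenance record
(source sequence, source index, segment), and the design validates that
provenance-addressed residues reproduce the chimera string exactly before
returning.

The shipped rhodopsin topology TSV is an implementer-provided approximation
of the 348-residue bovine rhodopsin helix/loop architecture. Published
chimera sets define their exact boundaries only implicitly through their
final sequences, so users reproducing a specific published design should
supply their own topology table (`--topology`) and, if desired, their own
alignment (`--alignment`).

## Alignment

Cut-site projection uses an internally implemented Gotoh three-state
affine-gap global aligner rather than an external alignment program, so
designs are deterministic and testable with no runtime binaries. Scoring:
`sum of substitution scores − Σ_gaps (gap_open + (len−1)·gap_extend)`;
terminal gaps are penalized like internal ones. Defaults are BLOSUM62
(loaded from Biopython's matrix collection; any NCBI-format matrix file can
be supplied), gap open 11, gap extend 1 — conventional protein alignment
parameters. Traceback ties are broken by a fixed preference
(substitution > gap-in-target > gap-in-backbone, evaluated at each cell), so
the returned column map is bit-stable. Externally computed pairwise
alignments can be imported from aligned FASTA for exact reproduction of a
specific program's output; the score is then recomputed under the same
scoring scheme. The aligner is verified against an independent exhaustive
enumeration of all global alignment paths: all sequence pairs with lengths
≤ 3 over a four-letter alphabet (7056 pairs) plus 1000 seeded random pairs
of lengths 4–5 — ~8000 pairs total, chosen to keep the check exhaustive
where enumeration is cheap and representative where it is not.

## Back-translation

`most_frequent` mode picks each amino acid's most used codon (ties broken
alphabetically); `weighted` mode samples codons proportionally to usage from
a seeded generator. The shipped default table contains approximate human
codon usage fractions, renormalized on load; any `aa<TAB>codon<TAB>freq`
table can be substituted. Every codon is validated against the standard
genetic code, so `translate(back_translate(p)) == p` holds by construction.

## Plate quantification

Each well is normalized to the mean of its first `baseline_reads` reads
(default 3, matching the usual three pre-stimulus luminescence
measurements); the RLU maximum is the raw post-stimulus maximum of the
normalized trace, with no smoothing and no fixed upper window (an explicit
choice — the whole post-stimulus window is used). Normalization is
scale-invariant by construction.

Dose–response and light-intensity–response data are fitted with the
four-parameter logistic by least squares (lmfit/Levenberg–Marquardt).
Initialization is deterministic: `bottom = min(y)`, `top = max(y)`,
`ec50 =` the dose whose response lies nearest the half-maximum, `hill = 1`,
with `ec50` bounded to `[min(dose)/10, max(dose)·10]`. On monotone data
this initialization converges to the global optimum (spot-checked against
differential evolution). The 4PL identity — the fitted curve passes through
`(top+bottom)/2` at the fitted EC50 — holds analytically and is asserted in
tests.

Action spectra group per-well RLU maxima by stimulation wavelength; the
peak is the smallest wavelength achieving the maximum mean (fixed tie
rule). BRET2 traces are summarized as the GFP2-acceptor / RLuc8-donor ratio
and its change relative to the pre-stimulus baseline mean.

## Behavior and imaging statistics

All count-based indices follow the standard formulas: preference
`(n_odor − n_blank)/n_total` (mid-zone animals count toward the total
only), learning `LI = (Pref_paired − Pref_unpaired)/2`, performance
`(n_CS+ − n_CS−)/n_total` with reciprocal-trial averaging, and the rolling
(escape) fraction with a Wilson 95% interval (Wilson rather than Wald
because trial sizes are small). The indices are antisymmetric under label
swap, which is fuzz-tested.

Locomotion summaries use per-frame centroid tables (10 frames/s by
default): mean velocity is the mean consecutive-frame displacement times
the frame rate, with no smoothing, over the first 30 s of each animal's
track; cumulative bending sums absolute bending angles over the same
window. Tracker bending-angle sign conventions vary, so absolute values are
used — a documented assumption. Fluorescence traces are normalized as
ΔF/F with `F0` the mean of the first `baseline_frames` frames (default 95,
the confocal protocol; 50 for the intact-larva two-photon variant) and
`ΔF_max` the post-stimulus maximum.

## Synthetic fixtures

Generators are pure functions of parameters + seed. Toy receptors draw TM
segments from a hydrophobic-biased pool (`AVILMFWGC`) and loops from a polar
pool (`DEKRNQSTHPGY`), so helices anchor toy alignments the way real
topologies do. Homologous pairs derive the target from the backbone with
segment-wise point substitutions (10% in helices, 30% in loops) and small
indels confined to loops — emulating the divergence structure of a receptor
family, not its actual biophysics. Simulated plates place baseline reads at
a constant level and scale post-stimulus reads by the 4PL fold-change at the
well's dose, with optional multiplicative Gaussian noise; simulated
fluorescence rises linearly to the exact peak over ~1 s and decays
exponentially. What passing tests show is therefore that the *computations*
are correct on data whose generating process is known; they do not validate
receptor biology, reporter kinetics, or tracker segmentation on real data.

## Numerical and design choices

* EC50 recovery calibration: the noiseless grid check spans EC50 ∈ {5, 50,
  500} × Hill ∈ {0.5, 1, 2} on a 9-level log-spaced dose grid
  (0.5–5000), where all four parameters are recovered to ≤ 1% relative
  error. The Monte-Carlo calibration (100 seeded runs, Gaussian noise with
  sd = 5% of the top plateau) uses the same grid with triplicate wells per
  level — mirroring the minimum-three-replicates practice of plate assays —
  and yields a median relative EC50 error of ~8–9%. Sparser designs
  (5 levels, or series skewed to one side of the EC50) are statistically
  incapable of ~15% median accuracy at this noise level regardless of the
  fitter; dose design, not optimization, is the limiting factor.
* Wavelength-peak and codon ties break to the smallest/alphabetically first
  candidate; alignment traceback ties break by the documented state order.
  All tie rules exist to make outputs reproducible, not because the
  alternatives are wrong.
* Problem sizes in the test suite (200 receptor pairs for round trips, ~8000
  aligner pairs, 1000 back-translations, 100 Monte-Carlo fits) keep the full
  suite in the tens of seconds while leaving the estimators' behavior
  clearly resolved.

## Known limitations

* The design rules are purely sequence-based; structure-guided refinement,
  retinal-binding-pocket integrity, expression/function prediction, and DNA
  restriction-site or GC-content optimization are out of scope.
* The aligner is strictly pairwise and global; it does not reproduce any
  specific external MSA program's columns. For exact reproduction of a
  published chimera, import the published alignment and topology.
* The default rhodopsin topology and codon table are documented stand-ins,
  not author-provided data.
* Group-level inferential statistics (ANOVA, t-tests, rank tests) are
  deliberately not included; the package computes the quantities those tests
  compare.
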