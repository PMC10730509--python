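# optoxr

Design and quantification toolkit for optogenetically functionalized
G-protein-coupled receptors (optoXRs).

## The problem

Neuromodulators such as dopamine act through class-A GPCRs, and dissecting
their receptor- and cell-type-specific signaling requires tools that can be
switched on with light. A proven strategy is the chimeric optoXR: take a
light-sensitive opsin backbone (bovine rhodopsin, Rho) and graft onto it the
intracellular, G-protein-coupling segments of the receptor of interest. The
design problem is where to cut. `optoxr` automates the sequence-based design:

* **V1** (legacy rules): all three intracellular loops (ICL1–3, each with a
  configurable number of proximal transmembrane residues on both flanks) and
  the C-terminus are replaced by the target receptor's segments.
* **V2** (optimized rules): ICL1 contributes little to G-protein binding, so
  the backbone ICL1 is retained, while ICL2, ICL3 and the C-terminus come
  from the target and the C-terminal exchange point is moved into TM7 to
  capture additional G-protein contact sites.

Both presets append the rhodopsin 1D4 epitope (`TETSQVAPA`) for
immunodetection. Cut sites defined on the backbone topology are projected
onto the target through an affine-gap Needleman–Wunsch global alignment
(BLOSUM62, gap open 11 / extend 1 by default), and every chimera residue
carries a provenance record. Designs can be exported as FASTA + GFF3 and
back-translated into codon-optimized DNA.

The package also implements the quantification math for the assays used to
characterize such receptors: baseline-normalized luminescence fold-changes
(RLU) from chimeric-Gα cAMP reporter plates, four-parameter logistic (4PL)
dose/light-intensity response fits
`R(d) = bottom + (top − bottom) / (1 + (EC50/d)^hill)`,
wavelength action spectra, BRET2 acceptor/donor ratios, and the behavioral
readouts used in vivo (preference index, learning index
`LI = (Pref_paired − Pref_unpaired)/2`, T-maze performance index, escape
(rolling) contingencies with Wilson intervals, locomotion summaries from
tracker tables, and fluorescence ΔF/F).

## Worked example

Design a V2 chimera for a synthetic receptor pair and fit a simulated
light-intensity response, entirely from the command line:

```bash
optoxr fixtures gpcr --seed 1 --out backbone
optoxr fixtures gpcr --seed 2 --out target
optoxr design --backbone backbone.fasta --target target.fasta \
    --topology backbone.topology.tsv --ruleset V2 \
    --out-fasta chimera.fasta --out-gff3 chimera.gff3 --out-dna chimera.fna
optoxr fixtures plate --seed 3 --out plate.csv
optoxr assay dose --plate plate.csv --out fit.json
```

This prints:

```
wrote toy (154 residues) -> backbone.fasta/.topology.tsv
wrote toy (154 residues) -> target.fasta/.topology.tsv
designed opto_toy_V2: 163 residues, 22 provenance blocks
wrote 489 nt coding sequence to chimera.fna
simulated plate (5 doses x 3 replicates) -> plate.csv
4PL fit: ec50=50, hill=1 -> fit.json
```

The chimera is 163 residues: the 154-residue backbone with its ICL2/ICL3
(plus two proximal TM residues per flank) and C-terminal group replaced by
the homologous target segments, plus the 9-residue 1D4 epitope. The GFF3
maps every residue back to its source; the simulated plate was generated
from a 4PL truth with EC50 = 50 nM, which the fit recovers exactly in the
noiseless default.

The same operations are available as a library (`optoxr.design_chimera`,
`optoxr.fit_dose_response`, ...); see `docs/methods.md` for the model and
parameter conventions.

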