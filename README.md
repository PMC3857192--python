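# sslock

Toolkit for engineering conformation-locking disulfide bonds in two-state
protein complexes, and for verifying and quantifying them:

- **structure** — deterministic fixed-column PDB parsing (first model,
  standard residues, highest-occupancy altloc), Cβ lookup with optional
  virtual Cβ for glycine, construct↔author numbering maps.
- **screen** — Cβ–Cβ distance screening of inter-chain residue pairs across
  a closed/open structure pair: a candidate is bondable in the closed state
  (default ≤ 12 Å) and widely separated in the open state (default ≥ 20 Å),
  ranked by the distance contrast; side-chain polar-contact / salt-bridge
  detection.
- **ms** — point-mutation application with reference checking, in-silico
  proteolysis (trypsin with Keil proline rule, Asp-N with D or D/E
  specificity, sequential digests, missed cleavages), monoisotopic peptide
  masses, disulfide-crosslinked species enumeration (−2.01565 Da), m/z per
  charge state, and ppm peak matching against observed peak lists.
- **assay** — geometric-mean fluorescence, net normalized fluorescence
  intensity (NNFI = background-subtracted GMFI / relative receptor
  expression), percent inhibition, and moments-based ellipse fitting of cell
  masks (elliptical form factor = major/minor axis).
- **fixtures** — synthetic ground-truth generators (toy two-state structure
  pairs with a hinge rotation, wild-type/Cys-mutant sequence pairs,
  log-normal flow events, rasterized ellipse masks) so the whole test suite
  runs offline.

## CLI

```bash
# screen a closed/open pair for candidate disulfide positions
sslock scan --closed closed.pdb --open open.pdb --chains A:B \
    --closed-max 12 --open-min 20 --out candidates.tsv

# in-silico digestion
sslock digest --fasta subunits.fa --enzymes trypsin,aspn_de --missed 2 \
    --out digest.tsv

# diagnostic crosslinked species for an engineered Cys pair
sslock xlink --fasta subunits.fa --mutations "A:K321C,B:R360C" \
    --enzymes trypsin,aspn_de --missed 2 --charges 1-4 \
    --peaks peaks.csv --ppm 10 --out xlinks.tsv

# flow-cytometry NNFI and cell-mask morphometry
sslock nnfi --input flow.csv --out nnfi.csv
sslock shape --masks cell1.png --masks cell2.csv --out shape.csv

# synthetic two-state fixture with known truth
sslock fixtures --toy-pair toy/ --seed 7 --hinge 60
```

Every output is written atomically with a `*.manifest.json` recording the
inputs, parameters and package version. Logging goes to stderr; results go
only to files.

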