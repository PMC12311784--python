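# histoform

Top-down and bottom-up annotation of histone proteoforms from deconvolved
mass-spectrometry data, built for organisms without reference annotations.
The package covers the full desk-side workflow:

- **masscore** — monoisotopic residue/modification chemistry, proteoform
  masses, m/z conversion, a/b/c/y/z/z• fragment ladders, and a round-trip
  proteoform text notation (`N-acS K12ac K20me2`).
- **annotate_ms1** — explains deconvolved MS1 neutral-mass shifts as PTM
  combinations or single amino-acid substitutions and enumerates localized
  proteoform candidates for MS/MS scoring.
- **fragmatch** — matches theoretical fragment ladders to observed peaks
  (ppm tolerance, one peak ↔ one fragment) and computes the four proteoform
  scores: %SC, %SVP, %IC, and MS = %SC × %IC / 100.
- **isoquant** — finds isomer-specific reporter ions within mass-degenerate
  proteoform groups and splits the shared MS1 area into per-isomer relative
  abundances.
- **denovo_homology** — spectrum-graph sequence-tag extraction from fragment
  mass ladders and an ungapped HSP homology search (match +2 / mismatch −1,
  I≡L, K≡Q) against a FASTA database.
- **bottomup** — in-silico propionylation (two rounds), Arg-C-like trypsin
  digestion, m/z target lists, and precursor-filtered b/y confirmation.
- **synthetic_data** — seeded generators for MS1 envelopes, partial ECD/CID
  fragment spectra with ppm jitter and noise, and chimeric isomer mixtures,
  each returning the planted ground truth.
- **io_cli** — FASTA/MGF/TSV/CSV/JSON/YAML readers and writers plus the
  `histoform` command-line interface.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: analytic checks of
printed reference values (PTM deltas, the K↔R substitution shift, the QC
peptide m/z values) and seeded statistical recovery experiments
(planted-proteoform ranking, isomer-fraction recovery, homology rank-1
recovery, score invariants on 10,000 random fixtures).

## CLI

```bash
histoform simulate --seed 7 --seq seq.fasta --proteoform "N-acS K12ac" \
    --completeness 0.8 --jitter-ppm 2 --out spectrum.tsv --truth-out truth.json
histoform annotate-ms1 --envelope envelope.tsv --seq seq.fasta --out labels.csv
histoform score --spectrum spectrum.tsv --seq seq.fasta \
    --proteoform "N-acS K12ac" --out scores.csv
histoform quantify-isomers --spectrum mix.tsv --seq seq.fasta \
    --isomer "N-acS K12ac" --isomer "N-acS K16ac" --ms1-area 100 --out quant.csv
histoform denovo --spectrum fragments.tsv --out tags.tsv
histoform blast --tags tags.tsv --db histones.fasta --out hits.csv
histoform bottomup-targets --seq protein.fasta --charges 2,3 --out targets.csv
histoform bottomup-confirm --targets targets.csv --spectra spectra.mgf --out confirm.csv
```

Spectra are two-column neutral-mass TSV (`neutral_mass<TAB>intensity`) or
MGF (m/z mode); envelopes are the same TSV dialect. All reports are CSV with
a `# config_hash=` provenance line. Exit status is 0 on success, 2 on input
errors.
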