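# mirkit

Homology-based plant miRNA discovery and characterization, built as a
desk-scale, fully testable pipeline:

1. **Homology search** — ungapped placement of known mature miRNAs on both
   strands of a transcript set (Hamming distance ≤ 2 by default), with a
   megablast-style score and Karlin–Altschul expectation filter
   (`E < 1e-2` or `score > 32`).
2. **Precursor candidates** — a grid of flanking windows around each hit,
   strand-resolved, plus overlap-merging of transcript fragments guided by
   a shared precursor alignment.
3. **MFE folding** — Zuker-style dynamic programming over a simplified,
   swappable nearest-neighbor table (stacks + affine loop penalties, no
   dangles), with a Vienna-dialect adapter for external folders.
4. **Hairpin criteria** — MFE ≤ −15 kcal/mol, MFEI > 0.5, 30–70 % A+U,
   mature in one arm, < 6 mature:miRNA\* duplex mismatches; the best
   passing window per locus is kept.
5. **Catalog** — family assignment against the reference set (≤ 4
   mismatches), letter-suffixed member naming, and summary statistics
   (length histogram, 5′-U fraction, MFEI moments, family sizes). A
   34-record conserved-miRNA catalog ships as a packaged fixture.
6. **Targets** — penalizing-score scanning (WC 0, G:U 0.5, mismatch 1,
   gap 2; doubled at seed positions 2–7; sites ≤ 3 kept), cleavage-site
   mapping opposite miRNA positions 10/11, and Figure-style alignment
   rendering.
7. **Expression** — comparative-Ct (2^−ΔΔCt) quantification against a
   reference gene and calibrator sample.
8. **Synthetic data** — deterministic generators for transcriptomes with
   planted hairpins and shuffled-context decoys, engineered target sites of
   exact penalty, and Ct tables with known fold changes.

## CLI

```bash
mirkit simulate   --seed 1 --out sim/
mirkit discover   --transcripts sim/transcripts.fasta \
                  --reference ref_matures.fasta --out run/
mirkit summarize  --catalog run/catalog.tsv --out run/summary.json
mirkit targets    --mirnas matures.fasta --transcripts mrnas.fasta \
                  --score-cut 3.0 --out targets/
mirkit expression --ct sim/ct.tsv --reference rRNA5S --calibrator stem \
                  --out expr.tsv
mirkit run-all    --seed 1 --out full/
```

`discover` writes `catalog.tsv`, `precursors.fasta`, `structures.txt`
(dot-bracket), `loci.gff3`, `rejections.tsv` (the filtering ledger) and a
resolved `config_resolved.yaml`; thresholds are configurable via
`--config config.yaml` mirroring `mirkit.pipeline.PipelineConfig`.

## Notes

- Coordinates are 0-based half-open on the + strand internally; GFF3 output
  is 1-based inclusive.
- RNA (`U`) is canonical internally; DNA input is normalized on read.
- The folding parameter table (`mirkit/data/energy_params.yaml`) is
  deliberately simplified; absolute energies differ from full Turner-model
  folders, so published per-precursor energies are treated as given inputs
  rather than re-derivable values.
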