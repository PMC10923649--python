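# plastrec

Toolkit for plastome structural variation driven by short inverted repeats:

* **Quadripartite structure detection** — finds the maximal-arm large
  inverted repeat of a circular plastome and reports the LSC/IRb/SSC/IRa
  partition in a deterministic canonical rotation (with an optional
  homology-based override for labelling the LSC of rearranged molecules).
* **Short repeat discovery** — exact, maximal direct/inverted repeat pairs
  inside a region (the recombination substrates), with homopolymer-placement
  accounting.
* **Recombination conformers** — partitions the LSC into areas A/B/C around
  an inverted pair and enumerates, with explicitly spliced sequences, the
  spacer inversion, the head-to-head dimer intermediate, the two resolution
  products (the giant IR-expanded / area-C-deleted molecule and its
  mass-conserving reciprocal), and the flip-flop SSC isomer; predicts gene
  loss/duplication from an annotation.
* **Junction support** — builds diagnostic junction references (core plus
  flanks) for each conformer and counts junction-spanning reads with a
  built-in k-mer-anchored ungapped matcher.
* **Heteroplasmy** — estimates per-conformer depth and mixture proportions
  from region-depth arithmetic (area C vs SSC on the parent reference),
  either from a standard three-column depth table or from raw reads via an
  internal mapper.
* **Synthetic data** — toy quadripartite genomes with a planted repeat pair
  (rejection-sampled to be unique and exactly maximal), independently
  spliced conformers, and a seeded paired-end read simulator with
  substitution errors — the ground-truth engine for the test suite.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form
structural arithmetic, gene-count deltas, the repeat worked example,
dual-construction and brute-force-equivalence property tests, negative
junction tests, and mixture-recovery bias bounds).

## CLI

```sh
plastrec structure ref.fasta                      # quadripartite report
plastrec repeats ref.fasta --region lsc --min-arm 11 --max-spacer 200
plastrec conformers ref.fasta --annotation ann.gff3
plastrec junctions ref.fasta reads_1.fastq --reads2 reads_2.fastq
plastrec heteroplasmy ref.fasta --depth-table depth.tsv
plastrec simulate --prop-a 0.7 --depth 100 --seed 1 -o sim/
plastrec run --reference ref.fasta --reads1 sim/reads_1.fastq -o out/
plastrec report out/report.json
```

`plastrec run` executes every stage whose inputs are present and writes a
machine-readable `report.json` plus a rendered `report.txt`; all randomness
flows from the single `--seed`.

## Conventions

* Coordinates are 0-based half-open internally; reports print 1-based
  inclusive.
* Canonical rotation: LSC first, region order LSC→IRb→SSC→IRa; of the two
  flip-flop isomers the one with the lexicographically smaller SSC forward
  strand is canonical.
* Conformer sequences are reported in canonical circular form (rotation and
  global strand normalised) so independent constructions compare
  byte-identically.
* The internal read mapper assigns IR multi-mapping reads to the leftmost
  best position; heteroplasmy arithmetic only consumes single-copy regions
  (area C and the SSC), with area B excluded and region ends trimmed.
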