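# molcomplexity

Coding-based complexity measures for molecular data representations, built to
test one question: does a string **assembly index** (minimal number of
concatenation steps needed to build a string from its symbols, reusing
previously built pieces) classify structured vs. random data any better than
the classic statistical compression family it belongs to?

The package provides:

- **`molcomplexity.synthetic`** — seeded generators for length-matched
  modular/random string corpora, binary peak matrices (template-based vs.
  i.i.d.) and molecule graphs (polymer chains vs. uniform random trees).
- **`molcomplexity.encodings`** — representations and flattening: 8-bit ASCII
  binarisation of identifier text, MOL V2000 reading/writing, bond
  (shortest-path) distance matrices, row-major matrix-to-sequence conversion.
- **`molcomplexity.measures`** — block Shannon entropy, run-length encoding,
  Huffman coding, LZ77/LZ78 parsing and LZW, each with a decoder (losslessness
  is tested) and a scalar size proxy.
- **`molcomplexity.assembly`** — the assembly index: exact minimum via
  branch-and-bound over closed substring sets, a greedy longest-repeat upper
  bound, an LZ78-derived constructive upper bound and the `ceil(log2 n)`
  doubling lower bound; every method returns a replayable witness pathway.
- **`molcomplexity.ctm_bdm`** — reduced-scale Coding Theorem Method tables
  from exhaustive enumeration of small 2-symbol Turing machines (a packaged
  exhaustive (3,2) table covers ~7.5M machines), plus the Block Decomposition
  Method for longer sequences.
- **`molcomplexity.stats`** — one-tailed Pearson correlations, rank AUC /
  Cliff's delta group separation, and a reproducible end-to-end pipeline
  (generate → encode → measure → statistics) with a run manifest.

## CLI

```sh
# seeded synthetic corpora (strings | spectra | molecules) + groups.csv
molcomplexity generate --kind strings --n 100 --seed 42 --out corpus/

# measures over a corpus directory, tidy CSV out
molcomplexity compute --input corpus/ --repr raw-text \
    --measures rle,huffman,lz78,lzw,assembly --out results.csv

# assembly index of a single string (exact / greedy / bounds)
molcomplexity assembly --string ABRACADABRA --exact --json

# build a CTM table by exhaustive enumeration (states <= 3)
molcomplexity ctm --states 2 --max-steps 107 --out ctm22.csv

# full pipeline and statistics re-runs
molcomplexity run --config cfg.yml --out run/
molcomplexity stats --results run/results.csv --out stats/
```

## Notes

- Identifier strings are treated as opaque ASCII text; no chemical
  interpretation of InChI/SMILES is attempted, and assembly indexes of real
  molecules enter the pipeline only as an externally supplied column.
- Exact assembly search is capped at 20 symbols by default
  (super-exponential); the pipeline uses the greedy bound by default
  (`assembly_method: exact|greedy|auto` in the run config).
- All generators are pure functions of their arguments, with randomness
  drawn from numpy's seed-sequence scheme — identical seeds give
  byte-identical outputs.
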