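# kcvkit

Analysis toolkit for miniature viral K⁺ channel (*kcv*) gene families,
covering the full path from raw isolate sequences to channel biophysics:

- **`seq_io`** — FASTA I/O, IUPAC-aware sequence records, translation,
  reverse complement, primer degeneracy.
- **`insilico_pcr`** — degenerate-primer matching against template panels,
  amplicon prediction, primer-pair coverage scoring, GC%/Wallace-rule Tm.
  A bundled panel of the nine degenerate primers used to amplify *kcv*
  genes ships with the package.
- **`msa`** — affine-gap global pairwise alignment (Gotoh, deterministic
  tie-breaks), progressive multiple alignment with a 3-mer single-linkage
  guide, and column conservation profiles.
- **`diversity`** — exact-identity unique-sequence collapse with
  multiplicities, variable-site counts, alignment-based pairwise
  difference counts, protein length histograms, K⁺ selectivity-filter
  motif classification (`TT.G[YF]G[DN].`), domain-interval transfer, and
  per-domain conservation.
- **`phylo`** — p-distance matrices, canonical neighbor joining (exact on
  additive metrics, deterministic tie-breaks, nonnegative branch
  lengths), Newick output, monophyly queries.
- **`channel`** — two-state voltage-dependent gating simulator
  (exponential dwell times, Gaussian noise, cascaded single-pole
  low-pass), half-amplitude idealization, open probability, open-level
  I/V fitting of unitary conductance, and a flicker-gating artifact check
  (fast unresolved gating depresses the apparent negative-branch
  conductance).
- **`synthetic_data`** — seeded generator of *kcv*-like families with
  known ground truth: domain-structured substitution rates, duplicate
  isolate clusters, in-frame turret insertions, C-terminal extensions,
  and flanks carrying planted primer binding sites.
- **`cli`** — `kcvkit` command with subcommands `synth`, `pcr`,
  `collapse`, `align`, `diversity`, `tree`, `channel-sim`,
  `channel-analyze`, and `run` (full pipeline).

## Test

```sh
python -m pytest tests/
```

The suite is fully self-contained: every fixture is generated
programmatically. The real-data integration tests run only if a FASTA of
the deposited coding sequences is placed at `tests/data/kcv_cds.fasta`;
they are skipped otherwise.

## Example

```sh
# synthetic family with ground truth, then the full pipeline
kcvkit synth --seed 1 --out-dir out/family
kcvkit run --seed 1 --out-dir out/run     # collapse → translate → align → tree

# primer panel coverage on the generated templates
kcvkit pcr out/family/family_with_flanks.fasta --out out/panel.tsv

# single-channel simulation and conductance estimation
kcvkit channel-sim --gamma 87 --voltage 40 --voltage 80 --voltage 120 \
    --seed 3 --out-dir out/traces
kcvkit channel-analyze out/traces/trace_*.tsv --out-json out/estimate.json
```

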