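# regmine

Integrative transcription-factor binding-site (TFBS) discovery. `regmine`
combines four lines of evidence that are individually weak but jointly
strong:

1. **Regulatory-network inference** — mutual information (MI) between a
   TF's expression profile and every gene, with Data Processing
   Inequality (DPI) pruning of indirect edges and a bootstrap-consensus
   significance test, yields a set of *activated targets* per TF.
2. **Dual cross-species conservation** — target promoters are masked
   down to their conserved fraction two ways at matched DNA coverage:
   by a per-base conservation score track (alignment-based), and by
   discovery of 8-base patterns recurring across orthologous promoters
   (alignment-free, robust to binding-site turnover). The union of the
   two is the *combined-conservation* set.
3. **Discriminative motif evaluation** — a motif's quality is the
   classification relative error `err = (FPR + FNR) / 2` of its best
   score cutoff separating target promoters from matched random
   background promoters, with permutation-test p-values.
4. **De novo PWM discovery** — a coarse-to-fine search (overrepresented
   word seeding, lattice-column beam search, local refinement) directly
   minimizing `err`, run on both the conservation-free and
   combined-conservation sets; results are merged and re-ranked, each
   motif keeping its best err and a label saying which set produced it.

## Worked example

Everything below runs on a synthetic dataset with planted ground truth
(no downloads). Generate a complete input bundle, then run the
pipeline:

```python
from regmine import RunConfig, run_pipeline, write_synthetic_bundle

bundle = write_synthetic_bundle("demo_bundle", n_samples=200, seed=5)
config = RunConfig(min_targets=12, bootstraps=40, n_background=30,
                   library_permutations=199, motif_lengths=(8,),
                   seed_words=100, beam_width=10, refine_max_iter=8,
                   rng_seed=5)
report = run_pipeline(config, bundle.inputs, denovo_pvalues=False)
print(report.to_frame().head(4).to_string(index=False))
```

Output (the planted motif is `TGACGTCATC`; `denovo_w8_GATGACGT` is its
reverse-complement core, recovered de novo from the
combined-conservation set and matched back to the library):

```
 tf  rank              motif            source_set      err   cutoff     p  matches_known known_match
TF1     1 denovo_w8_GATGACGT combined-conservation 0.052632 6.306405 1.000           True     planted
TF1     2 denovo_w8_ACGTCATC combined-conservation 0.103947 3.347964 1.000           True     planted
TF1     3            planted combined-conservation 0.131579 8.513106 0.005           True     planted
TF1     4 denovo_w8_TATAGTCG     conservation-free 0.151316 6.782774 1.000          False
```

The same run through the CLI:

```bash
regmine run \
  --expression demo_bundle/expression.tsv --tfs demo_bundle/tfs.txt \
  --annotations demo_bundle/annotations.tsv --genome demo_bundle/genome.fa \
  --masks demo_bundle/masks.bed --track demo_bundle/conservation.bedGraph \
  --orthologs demo_bundle/orthologs --library demo_bundle/library.transfac \
  --out report.tsv --seed 5 --min-targets 12 --bootstraps 40 \
  --n-background 30 --library-permutations 199 --motif-lengths 8 \
  --seed-words 100 --beam-width 10 --refine-max-iter 8 --no-denovo-pvalues
```

Individual stages are also exposed: `regmine network`, `regmine
promoters`, `regmine conserve`, `regmine evaluate` (library enrichment)
and `regmine discover` (de novo). `--seed` is required for `discover`
and `run`.

## Inputs

| Input | Format |
|---|---|
| Expression matrix (genes × samples) | TSV |
| TF list | one gene id per line |
| Gene annotations (gene, chrom, tss, strand) | TSV |
| Genome / promoter sequences | FASTA (soft-masked) |
| Repeat / coding-exon masks | BED |
| Conservation scores (promoter-local, per gene) | bedGraph / fixedStep wiggle |
| Orthologous promoters | one FASTA per gene (`<gene>.fa`, reference first) |
| Known-motif library | TRANSFAC matrix flat file |

De novo motifs are written in MEME minimal format.

## Reproduction

All headline behavior is covered by seeded property-based tests in
`tests/test_acceptance.py` (oracle equivalence of the core primitives,
planted-motif recovery, the turnover benchmark, permutation-test
calibration, network recovery, coverage calibration). The same
quantities can be computed standalone:

```bash
python scripts/acceptance.py --seed 0 --out acceptance.json
```

Every generator and every pipeline stage is a pure function of its
inputs and the seed; re-running with the same seed yields byte-identical
reports.

See `docs/methods.md` for the statistical model, parameter defaults and
their rationale, and known limitations.
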