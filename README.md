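# rrnatax

PCR-independent taxonomic analysis of small-subunit (SSU) rRNA sequence
fragments.

## The problem

PCR amplification of SSU rRNA genes with "universal" primers is the
standard route to a microbiome profile, but it is biased twice over:
templates differ in per-cycle amplification efficiency, and primers miss
taxa whose binding sites have diverged. Sequencing reverse-transcribed
rRNA molecules directly (random-primed cDNA) avoids both biases, at the
cost of producing *randomly fragmented* reads that start anywhere on the
molecule, come from either strand and vary widely in length — a shape of
data that amplicon classifiers handle poorly.

`rrnatax` is a toolkit for exactly this kind of data. It provides:

* **Fragment classification** — quality-region salvage (keep the good
  parts of a read instead of discarding it), exact dereplication, k-mer
  word similarity search against a reference database, and projection of
  near-best hits onto the reference taxonomy by lowest common ancestor
  (LCA), with rank-level *read density* tables (percent of weighted reads
  per taxon, normalised per domain or overall).
* **Chimera detection** for amplicon datasets: a read is flagged when a
  two-parent prefix/suffix explanation beats its best single-reference
  similarity by a margin.
* **Primer-site auditing** — locate universal-primer binding sites (e.g.
  63f `GCCTAACACATGCAAGTC`, 518r `ATTACCGCGGCTGCTGG`) on each read's
  best-matching reference, count substitutions and indels inside the site
  from the read/reference alignment, and roll mismatch ratios up by taxon.
* **PCR-bias simulation** — a mock community of cloned genes amplified
  with per-template efficiencies `e_i` (`copies_i(n) = copies_i(0)·(1+e_i)^n`,
  or per-molecule Bernoulli duplication), read out through qPCR standard
  curves `Ct = a + b·log10(copies)` with efficiency
  `(10^(−1/b) − 1)·100 %`.
* **Synthetic data** with complete truth tables, so every stage is
  testable without downloads.

## Core quantities

For a query fragment *q* and reference *r*, the similarity score is the
query-normalised shared-word fraction

    S(q, r) = |W_k(q) ∩ W_k(r)| / |W_k(q)|

over distinct k-mers (default k = 8), evaluated on both strands. All hits
within `top_window` (default 0.02) of the best score vote; the assignment
is the LCA of the voters' lineages, or *unclassified* when the best score
falls below `min_similarity` (default 0.40). The chimera score of a read
is `max_b min(S(q[:b]), S(q[b:])) − S_full`, maximised over breakpoints
*b* and parent references.

## Worked example

```python
from rrnatax import (generate_reference_set, fragment_reads,
                     run_rtrna_pipeline, PipelineConfig)

refs = generate_reference_set(5, length=1500, divergence=0.10, seed=11)
reads, truth = fragment_reads(refs, [0.1, 0.15, 0.2, 0.25, 0.3], 2000,
                              ("uniform", 60, 400), seed=12)
result = run_rtrna_pipeline(reads, refs, PipelineConfig(ranks=("domain", "genus")))
print(f"classified {result.report.classified_weight:.0f} of "
      f"{result.report.input_reads} fragments")
for taxon, weight, density in result.tables["genus"].rows:
    print(f"{taxon.split(';')[-1]:>8}  {weight:6.0f}  {density:6.2f}%")
```

prints

```
classified 2000 of 2000 fragments
 Genus05     642   32.10%
 Genus04     471   23.55%
 Genus03     395   19.75%
 Genus02     293   14.65%
 Genus01     199    9.95%
```

Five genera at 10 % pairwise-root divergence were sampled at proportions
10/15/20/25/30 %; the recovered read densities match the sampling
proportions to within binomial noise (e.g. 32.10 % observed vs 30 %
drawn for Genus05).

The same pipelines are available from the shell:

```sh
rrnatax synth --n-taxa 5 --n-reads 2000 --seed 11 --out-dir demo
rrnatax classify-rtrna --reads demo/reads.fastq --refs demo/references.fasta \
    --taxonomy demo/taxonomy.tsv --out-dir demo_out
rrnatax pcr-sim --config pcr.yaml --out-dir sim_out
```

## Layout

| module | responsibility |
| --- | --- |
| `rrnatax.seq_io` | FASTA/FASTQ, taxonomy tables, TSV reports |
| `rrnatax.cleaning` | quality-region salvage, filters, dereplication |
| `rrnatax.similarity` | word index, similarity search, banded aligner |
| `rrnatax.classify` | LCA projection, region screening, abundance tables |
| `rrnatax.chimera` | reference-based chimera detection |
| `rrnatax.primer_audit` | primer-window location and mismatch accounting |
| `rrnatax.pcr_sim` | amplification bias and qPCR quantification |
| `rrnatax.synthetic_data` | reference/read generators with truth tables |
| `rrnatax.pipeline` / `rrnatax.cli` | orchestration and command line |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
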