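# axonedit

Statistical pipeline for A-to-I RNA editing from per-site base counts, with
two workflows:

* **differential** — per-site editing levels (`G / (A+G)`) in two neuronal
  compartments (e.g. giant axon vs giant fiber lobe), a per-sample coverage
  filter (total depth ≥ 20 in every sample by default), global summaries
  (unweighted mean editing and the coverage-weighted editing index
  `ΣG / Σ(A+G)`), and a site-by-site differential call: two one-tailed
  two-sample t-tests (Welch by default, paired optional), each tail
  Benjamini–Hochberg-adjusted separately, with a call at FDR ≤ 0.1.
* **assay** — detection of site-specific editing on an amplicon against a
  binomial sequencing-error null (error rate 0.1% for Q>30 calls): exact
  upper-tail binomial p per adenosine, BH correction within each replicate
  dataset, an event is real when adjusted p < 0.001; replicate groups are
  then averaged (mean ± SEM as percentages) and reported with
  fold-over-control. Two combination rules are reported side by side:
  edited in ≥ k experimental replicates (default k = 3/5) and the
  fold>2-on-means reporting rule.
* **simulate** — synthetic count tables with the structure both analyses
  assume: negative-binomial coverage, optional beta overdispersion of
  replicate editing levels, a 0.1% base-call error floor, paired
  compartment replicates, and error-only amplicon controls.

A converter from samtools text pileup to quality-filtered base counts
(`axonedit.io.counts_from_pileup`, Phred ≥ 30 by default) is included.

## CLI

```sh
# generate a synthetic paired-compartment dataset
axonedit simulate --mode compartment --n-sites 10000 --seed 1 --out-dir sim/

# differential editing between the two compartments
axonedit differential --counts sim/counts.tsv --design sim/design.tsv \
    --out-dir diff/ --min-coverage 20 --fdr 0.1 --test welch

# amplicon assay detection (5 experimental + 5 control replicate TSVs)
axonedit simulate --mode assay --edited "10:0.1,20:0.008" --seed 1 --out-dir asim/
axonedit assay --out-dir det/ \
    --experimental asim/axoplasm_1.tsv ... --control asim/control_1.tsv ... \
    --p0 0.001 --adjusted-p 0.001 --min-replicates-detected 3
```

All inputs and outputs are TSV; every run writes a `run_metadata.json`
recording thresholds, the test variant and the seed. Exit codes:
0 success, 2 validation error, 1 runtime error.

### File formats

* site table: `transcript_id  position  ref_base  [in_vivo_level]`
  (1-based positions, sense strand, ref_base must be `A`)
* count table: `transcript_id  position  sample_id  a_count  c_count
  g_count  t_count`
* design table: `sample_id  compartment  [pair_id]`
* assay replicate table: `position  a_count  g_count`

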