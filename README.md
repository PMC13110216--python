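# trnkit

Toolkit for reconstructing transcriptional regulatory networks from expression
data and ranking master regulators, with the downstream integration and
morphometry stages needed to study a direct-reprogramming experiment end to
end — exercised entirely on synthetic data with planted ground truth.

Pipeline stages:

1. **simdata** — synthetic gene×sample count matrices (negative-binomial, with
   planted regulator→target regulons, signed modes and condition-specific
   activity patterns), ChIP peak intervals with answer keys, SWC neurite
   morphologies with exact geometric truth, and qPCR Ct tables.
2. **diffexpr** — median-of-ratios normalization, a simplified NB Wald test,
   BH adjustment, and strict DEG gates (|log2FC| > 1, padj < 0.01).
3. **trn** — mutual information (rank + equal-frequency binning, plug-in
   estimator), permutation significance filtering, bootstrap stability
   filtering, data-processing-inequality triplet pruning, and two-tailed
   running-sum regulon-activity scoring.
4. **centrality** — undirected TRN graph, unnormalized Brandes betweenness,
   top-N regulator ranking, and five-way condition-activity pattern classes
   (orange / magenta / red / blue / turquoise).
5. **targets** — ChIP peak → promoter-window (±1 kb TSS) assignment, DEG
   intersection with Venn counts, set algebra with provenance, and
   hypergeometric term enrichment with BH.
6. **morpho** — SWC parsing/validation, Sholl intersection profiles at 1 μm
   shells, branch-point and primary-neurite metrics, soma-area category
   classification (85/200/500/1000/1600 a.u. bins), two-sample KS and Welch t.
7. **qpcr** — ΔΔCt relative expression with reference-gene and
   reference-condition normalization.
8. **pipeline** — orchestration with YAML config, deterministic seeding, and
   checksummed run manifests.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact oracle
equivalence (DPI vs. triplet enumeration, betweenness vs. brute-force path
counting, hypergeometric vs. combinatorial enumeration, KS vs. CDF stepping),
seeded statistical calibration (permutation null retention, NB null FDR),
planted-parameter recovery (edge precision/recall ≥ 0.8, activity-pattern
recovery ≥ 90%, regulator-vs-target betweenness separation), closed-form
Sholl geometry, closure identities, and byte-identical rerun manifests.

## CLI

Each stage is a subcommand (`trnkit --help` for the full list):

```bash
trnkit simulate --outdir sim --n-tfs 10 --targets-per-tf 30 --seed 1
trnkit de sim/counts.tsv sim/samples.tsv --condition mir124_isx9_d7 --reference astro_d1
trnkit trn sim/counts.tsv tfs.txt --n-perm 500 --p-cut 0.005 --n-boot 100
trnkit rank sim/counts.tsv regulons.tsv sim/samples.tsv --top-n 20 --sif trn.sif
trnkit targets peaks.bed tss.tsv --window-bp 1000
trnkit morpho cells/*.swc --step-um 1.0
trnkit qpcr ct.tsv --ref-gene Actb --ref-condition control
trnkit run-all --outdir run --seed 0
```

`run-all` executes simulate → de → trn → rank → targets → morpho → qpcr and
writes `manifest.json` with SHA-256 checksums of every output; reruns with the
same seed are byte-identical.

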