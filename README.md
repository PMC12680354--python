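# lrquant

Long-read RNA-seq isoform quantification by error-tolerant pseudoalignment
on a compacted transcriptome de Bruijn graph.

Long-read platforms (ONT, PacBio) deliver full-length transcript reads at
per-base error rates of a few percent — enough that classical exact-k-mer
pseudoalignment underperforms. `lrquant` is for transcriptomics researchers
who want fast, alignment-free isoform-level quantification of long reads,
plus a self-contained simulator and metric suite to characterize how
accuracy responds to sequencing error.

## Method

1. **Index.** The reference transcriptome is decomposed into a transcriptome
   de Bruijn graph (T-DBG) at a long, odd k (default **k = 63**), compacted
   into unitigs split so that every unitig carries a single *transcript
   compatibility class* (TCC) — the set of transcripts containing its
   k-mers. K-mers are stored canonically (min of forward and reverse
   complement). Longer k-mers dissolve short repeats, so the graph has fewer
   nodes and edges and smaller classes than at k = 31.

2. **Pseudoalignment.** Each read's k-mers are looked up with a
   contig-skipping strategy (first/middle/end k-mer per contig-consistent
   stretch, with exhaustive fallback on disagreement). The read's TCC comes
   from a decision cascade: the **intersection** of its k-mers' TCCs if
   non-empty; otherwise the **mode among uniquely-mapping k-mers** if any
   exist (ties to the first transcript in the reference); otherwise the
   **mode over all hit k-mers**. Reads containing a k-mer from an optional
   distinguishing list (d-list) of non-transcriptome sequence are vetoed.

3. **Effective lengths.** Transcript-specific, estimated from the data:
   l_e(t) = Σ l_rt / Σ 1_rt − k over the first 1,000,000 mapped reads whose
   class contains t (annotated length − k as fallback, clamped ≥ 1).
   Length normalization is **off by default** — it helps only at low,
   uniform error rates.

4. **EM.** Class counts n_c are apportioned by iterating
   α_t ← Σ_c n_c · (α_t/l_t) / Σ_{u∈c} α_u/l_u. The `longread` mode runs EM
   on multi-transcript classes only and adds uniquely-mapping counts after
   convergence; the `default` mode includes them from the start.

5. **Evaluation.** Lin's concordance correlation coefficient (CCC), Pearson
   r, Spearman ρ, normalized RMSE, median relative difference (MRD), and
   percent expressed transcripts (PET), computed on log2(x+1)-transformed
   values where appropriate.

The bundled simulator generates full-length (or fragment) reads with
Binomial(length, rate) error events typed by platform presets
(ONT: 38.5% del / 38.5% sub / 23% ins; PacBio: 24.5% / 52.4% / 23.1%) at
uniform positions.

## Worked example

```python
from lrquant import (build_index, generate_transcriptome, sample_expression,
                     generate_reads, inject_errors, ErrorProfile, quantify,
                     evaluate)

ts = generate_transcriptome(30, length_range=(500, 1500),
                            shared_blocks=[(0, 1, 300)], seed=5)
index = build_index(ts, k=63)
truth = sample_expression(ts, 1500, model="lognormal", seed=6)
reads, _ = generate_reads(ts, truth, seed=7)
reads, _ = inject_errors(reads, ErrorProfile.preset("ont", 0.03), seed=8)
result = quantify(index, reads, em_mode="longread")
print(f"mapping rate: {result.mapping_rate:.3f}")
print(result.table.head(3).to_string(index=False))
```

prints

```
mapping rate: 0.991
target_id  length  eff_length  est_counts           tpm
       t0    1171         1.0        72.0  48419.636853
       t1    1305         1.0       157.0 105581.708137
       t2     522         1.0         5.0   3362.474781
```

99.1% of the 3%-error reads were assigned a class, and the estimated counts
track the simulated truth (t0 truly emitted 72 reads here). Scoring the
whole table with `evaluate(truth.to_frame(), result.table, unit="counts")`
gives CCC ≈ 1.00 and Spearman ≈ 1.00 at 3% error, degrading visibly at 10%
(see `examples/04_evaluate.py`).

The same workflow is available from the shell:

```bash
lrquant index --ref ref.fa --k 63 --out index.lrk
lrquant simulate --ref ref.fa --n-reads 1500 --expr lognormal \
        --profile ont --error-rate 0.03 --seed 6 --out sim
lrquant quant --index index.lrk --reads sim.reads.fastq --out quantdir
lrquant eval --truth sim.truth.tsv --est quantdir/abundance.tsv \
        --unit counts --out report.json
lrquant graph-stats --index index.lrk --tsv stats.tsv
```

Each `examples/*.py` script is a short narrative of one capability.

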