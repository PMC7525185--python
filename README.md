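# circlink

Prediction of circRNA–disease associations by multi-kernel similarity
fusion and a convolutional pair classifier.

Circular RNAs (circRNAs) are stable, covalently closed non-coding RNAs
whose dysregulation accompanies many diseases, making them attractive
biomarkers — but experimentally validating circRNA–disease links is slow.
`circlink` is for computational biologists who want to prioritize candidate
links from the evidence that is already available: known associations,
circRNA–miRNA and disease–miRNA interactions, circRNA sequences and
expression profiles, and a disease term hierarchy.

## Method

Let `A ∈ {0,1}^{nc×nd}` hold known circRNA–disease associations, and
`Y ∈ {0,1}^{nc×nm}`, `O ∈ {0,1}^{nd×nm}` the circRNA–miRNA and
disease–miRNA interaction profiles.

1. **Similarity kernels.** Four circRNA kernels — sequence alignment
   (`SC_Seq`), shared-miRNA regulatory similarity (`SC_RG`), expression
   correlation (`SC_EP`), Gaussian interaction profile
   `SC_GIP(i,j) = exp(−γc‖Y_i − Y_j‖²)` — and up to seven disease kernels:
   DAG-based semantic similarity (`SD_Dss`), `SD_GIP` over `O`, plus any
   precomputed disease similarity matrices supplied as TSV files.
2. **Similarity kernel fusion (SKF).** Each kernel stack is fused by
   iterative cross-diffusion: with column-normalized kernels `NS_m` and
   top-k row-normalized sparse kernels `F_m`,
   `S_m ← α F_m · mean_{r≠m}(S_r) · F_mᵀ + (1−α) mean_{r≠m}(NS_r)`
   (α = 0.1, 36 neighbors, 10 iterations — the relative change per kernel
   falls below 1e−10), then averaged, masked by mutual-neighbor weights
   {1, 0.5, 0} and symmetrized into `Sc*` and `Sd*`.
3. **Pair features.** Each pair (cᵢ, dⱼ) becomes a 2×(nc+nd+np) matrix:
   `[Sc*[i,·] ; A[·,j]ᵀ] | [A[i,·] ; Sd*[j,·]] | [PCA(Y[i,·]) ; PCA(O[j,·])]`
   with np = 50 principal-component scores of the miRNA profiles. By
   default the cell A[i,j] itself is masked out of the feature so training
   labels never leak into inputs.
4. **Classifier.** A two-layer CNN (8 filters 2×32, then 8 filters 1×16,
   ReLU, global max-pool, dropout 0.5, softmax), implemented in pure numpy
   with seed-reproducible training; evaluated by repeated 5-fold
   cross-validation with per-repetition negative resampling (precision,
   sensitivity, accuracy, F1, MCC, AUC).

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

Because curated circRNA resources cannot be redistributed, the package
ships a generator of self-contained synthetic studies with planted
community structure (see `docs/methods.md`). The full pipeline on the
default study (40 circRNAs, 15 diseases, 60 miRNAs, 3 planted blocks):

```python
from circlink import (SkfConfig, SyntheticSpec, assemble_kernel_stacks,
                      cross_validate, generate_study, skf_fuse)
from circlink.model import CnnConfig

study = generate_study(SyntheticSpec(seed=7))
circ_k, dis_k = assemble_kernel_stacks(
    study.network, expression=study.expression, sequences=study.sequences,
    dag=study.dag, precomputed=study.precomputed,
)
print([k.name for k in circ_k], [k.name for k in dis_k])
Sc = skf_fuse(circ_k, SkfConfig(), name="Sc")
print(f"fusion converged to {Sc.trace.final():.2e}")
Sd = skf_fuse(dis_k, SkfConfig(), name="Sd")
report = cross_validate(study.network, Sc.kernel.matrix, Sd.kernel.matrix,
                        cnn_config=CnnConfig(), folds=5, repetitions=1, seed=1)
print(report.summary().round(3))
```

which prints

```
['SC_Seq', 'SC_RG', 'SC_EP', 'SC_GIP'] ['SD_Dss', 'SD_GIP', 'SD_Syn1', 'SD_Syn2', 'SD_Syn3', 'SD_Syn4', 'SD_Syn5']
fusion converged to 1.20e-12
        Pre    Sen    Acc     F1    MCC    AUC
mean  0.784  0.869  0.815  0.822  0.638  0.889
std   0.036  0.099  0.049  0.055  0.102  0.028
```

The four circRNA and seven disease kernels fuse with a final per-iteration
relative change of ~1e−12; held-out planted associations are recovered with
mean AUC 0.889 across the five folds, with MCC 0.64 at the 0.5 score
threshold. A label-shuffled control of the same protocol yields AUC ≈ 0.5.

The same pipeline is available from the shell:

```bash
circlink synth --out-dir study/
circlink kernels --network-dir study/ --fasta study/sequences.fasta \
    --expr study/expression.tsv --dag study/dag_edges.tsv \
    --dag-mapping study/dag_mapping.tsv --out-dir study/kernels/
circlink fuse --kernels study/kernels/SC_Seq.tsv --kernels study/kernels/SC_RG.tsv \
    --kernels study/kernels/SC_EP.tsv --kernels study/kernels/SC_GIP.tsv \
    --out study/Sc.tsv
circlink cv --network-dir study/ --fused-circ study/Sc.tsv \
    --fused-dis study/Sd.tsv --reps 10 --seed 0 --out study/cv.tsv
```

To run on real data, supply your own edge lists (two-column TSV), FASTA
sequences, expression matrix, DAG edges and optional precomputed disease
kernel TSVs to the same commands.

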