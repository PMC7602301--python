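# m5cpred

SVM-based prediction of RNA 5-methylcytosine (m5C) sites from sequence.

5-methylcytosine is one of the most common post-transcriptional RNA
modifications, involved in RNA stability, export and translation.
Experimental mapping (bisulfite sequencing, Aza-IP, miCLIP, RBS-seq) is
slow and expensive, so sequence-based classifiers that score candidate
cytosines are widely used to prioritize sites. This package implements
such a predictor as a tested Python library plus a thin CLI: it trains on
cytosine-centered RNA fragments, selects an informative feature subset by
greedy forward search, and scans arbitrary FASTA sequences for candidate
sites.

## The method

Every candidate site is a fragment `R_λ(C) = N_{-λ} … N_{-1} C N_{1} … N_{λ}`
of length `2λ+1` (default λ = 20, i.e. 41 nt) centered on a cytosine;
flanks running off the sequence end are filled with `N`. Six feature
families encode a fragment:

| family | what it measures | dimension (λ=20) |
|---|---|---|
| KNF (`4NF`) | frequencies of all 4^K k-mers, `N(kmer)/(L−K+1)` | 256 (K=4) |
| KSNPF (`kSNPF`) | frequencies of the 16 nucleotide pairs spaced by exactly K positions | 16 |
| PSNP | per-position lookup into `X = M⁺ − M⁻`, the difference of the classes' position-specific nucleotide frequency matrices | 41 |
| KSPSDP (`kSPSDP`) | the gapped-dinucleotide analogue of PSNP (K=0 is PSDP) | 40 − K |
| PseDNC | dinucleotide composition plus λ_pse tiered correlation factors from three z-scored dinucleotide properties (free energy, hydrophilicity, stacking energy) | 16 + λ_pse |
| CPD | per-position chemical triple (ring, H-bond, functional group) plus cumulative-prefix nucleotide density | 164 |

The classifier is an RBF-kernel SVM, `K(x,y) = exp(−‖x−y‖²/s²)`, with box
constraint C and kernel scale s searched over powers of two
(C ∈ 2⁻⁵…2¹⁵, s ∈ 2⁻¹⁰…2⁶) by mean stratified 10-fold cross-validated
AUROC. Feature subsets are chosen by sequential forward selection (SFS)
over the families, also scored by CV AUROC. Inside every CV fold the
propensity matrices and the feature scaler are refitted on the nine
training folds only — held-out fragments never influence their own
encoding, and each fitted propensity model carries a fingerprint of its
training data so this is checkable.

Species presets bundle the published optimal subsets: *H. sapiens*
`PSNP + 4NF + 5SNPF + PseDNC`, *M. musculus* `CPD + 4NF + 1SPSDP`,
*A. thaliana* `PseDNC + 3SPSDP + 4NF + 1SNPF + PSNP`.

A bundled synthetic-data module generates labeled fragment datasets with
controllable position-specific enrichment, global compositional bias and
gapped-pair motifs, so the whole pipeline is testable without downloading
the GEO-derived benchmark sets (which are supported as plain FASTA input
but not shipped).

## Worked example

`examples/02_train_and_evaluate.py` simulates a benchmark-shaped dataset
(269+269 fragments, split 200+200 training / 69+69 independent test) with
a planted position-specific motif, trains the *H. sapiens* preset subset
and evaluates it:

```
training on 200+200 fragments, subset 'PSNP + 4NF + 5SNPF + PseDNC', 30-point grid
10-fold CV: AUROC 0.966, Acc 90.8%, Mcc 0.817 (BC 8, KS 64)
independent test (69+69): AUROC 0.971, Acc 93.5%, Sn 89.9%, Sp 97.1%
```

The CV line reports the cross-validated area under the ROC curve,
accuracy and Matthews correlation at the selected box constraint (BC) and
kernel scale (KS); the test line shows the same model scored once on the
held-out fragments. The other examples cover fragment extraction and
encoding (`01`), feature selection and the position-vs-composition
contrast (`03`), and FASTA site scanning (`04`).

The same pipeline is available from the shell:

```bash
m5cpred simulate --spec spec.json --out-dir bench/
m5cpred train --pos bench/train_pos.fasta --neg bench/train_neg.fasta \
              --species h_sapiens --model-out model.npz
m5cpred evaluate --model model.npz --pos bench/test_pos.fasta --neg bench/test_neg.fasta
m5cpred predict --model model.npz --fasta query.fa --out sites.tsv
```

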