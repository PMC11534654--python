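# dcrisk

Coding-sequence compositional encoding and CNN-based classification of
variant pathogenicity, built around the **dinucleotide composition
representation (DCR)** of a gene's coding sequence.

`dcrisk` is aimed at researchers studying genotype–phenotype association
for genes implicated in adolescent idiopathic scoliosis (and comparable
monogenic settings): it takes a curated, ClinVar-style table of coding
variants for one gene, reconstructs each variant's full coding sequence
(CDS), converts every sequence into fixed-length compositional feature
vectors, and trains a small 3D convolutional network that separates
high-risk (Pathogenic) from low-risk (Benign / Likely benign) variants
— which can then score variants of uncertain significance.

## The model

Every reconstructed CDS is decomposed into five trait vectors:

| trait | length | definition |
|---|---|---|
| DNT | 48 | 16 dinucleotides × 3 codon-phase classes: positions (1,2), (2,3), and (3, next codon's 1); each class block normalised to sum 1 |
| DCR | 1,536 | 256 ordered dinucleotide pairs × 6 positional classes (first-dinucleotide phase ∈ {1,2,3} × second-dinucleotide offset ∈ {+1 overlapping, +2 adjacent}); each class block normalised to sum 1 |
| codon | 64 | `freq(c) = count(c) · 64 · 3 / L` over all 64 codons |
| codon pair | 3,721 | 61 × 61 ordered pairs of consecutive in-frame sense codons, `freq = count · 3721 · 3 / L` |
| AA | 20 | amino-acid usage of the frame-0 translation, `freq = count · 20 · 3 / L` |

Nucleotides are ordered T, C, A, G throughout.

For classification the 1,536-dimension DCR vector is reshaped to a
`(6, 16, 16)` tensor — (positional class, first dinucleotide, second
dinucleotide) — and passed through two rounds of 3D convolution
(kernel `(1,3,3)`, padding `(0,1,1)`, stride `(1,1,1)`) with `(1,2,2)`
average pooling, growing channels 1 → 4 → 8 so the feature map flattens
to 8·6·4·4 = **768** units, followed by fully connected layers
768 → **192** → **2** and a softmax
`f(x_i) = e^{x_i} / Σ_j e^{x_j}` over the two risk classes
(1 = high risk, 0 = low risk). Training uses cross-entropy loss and
Adam with 100 epochs, learning rate 0.005, batch size 20, a 0.2
validation split and optional stratified 5-fold cross-validation;
classes are balanced by random downsampling first.

A synthetic-data module generates gene-scale reference CDS and
ClinVar-like variant tables with class-correlated mutational signal
(frameshift deletions/duplications, nonsense substitutions and a biased
SNV spectrum for the pathogenic-like groups), so the whole pipeline is
testable without any database download. Unsupervised views (UMAP/PCA
embeddings, hierarchical clustering) and downstream risk analytics
(false-stop and variant-class summaries, substitution spectra and their
correlation, positional and secondary-structure distributions) round
out the toolkit.

## Worked example

```python
import numpy as np
import dcrisk as d

# synthetic study conditions: one 8,601-nt reference CDS and a
# ClinVar-style variant table with implanted class signal
cfg = d.SimulationConfig(seed=1)
ref = d.generate_reference(cfg)
table, truth = d.generate_variant_table(ref, cfg)
table.to_csv("variants.tsv", sep="\t", index=False)

# parse (intron rows removed), reconstruct each variant's full CDS
records = d.parse_variant_table("variants.tsv")
variants = d.reconstruct_all(ref, records)

# DCR-encode the labelled training groups
keep = [v for v in variants if v.record.significance in
        ("Pathogenic", "Benign", "Benignlikely")]
X = np.stack([d.count_dcr(v.sequence).values for v in keep])
y = np.array([1 if v.record.significance == "Pathogenic" else 0
              for v in keep])

results = d.DCRClassifier(X, y, d.ModelConfig(seed=1)).fit()
print(results.summary())
```

This takes about a minute on a laptop CPU and prints:

```
DCR 3D-CNN classifier results
==============================================
training samples            640
held-out samples            160
epochs / lr / batch         100 / 0.005 / 20
final mean epoch loss       0.1844
held-out AUC                0.9612
accuracy low risk (0)       0.9875
accuracy high risk (1)      0.8625
confusion matrix (rows true 0/1, cols predicted 0/1)
        79      1
        11     69
```

The held-out AUC of 0.96 says the network recovered the implanted
compositional class signal almost completely; low-risk variants are
nearly all called correctly, while the hardest high-risk variants (a
single biased missense base change in 8.6 kb barely moves the
composition) account for the misses. The fitted results object then
scores unlabelled variants via `results.predict_proba(...)`, or through
`dcrisk.predict_batch(results, variants)` for reconstructed CDS
objects.

The same pipeline is available from the shell:

```bash
dcr simulate --seed 1 --out fixtures/
dcr parse  --ref fixtures/reference.fa --variants fixtures/variants.tsv --out parsed/
dcr encode --trait dcr --fasta parsed/variant_cds.fa --out feats.csv
dcr train  --features feats.csv --labels labels.tsv --out model/
dcr predict --model model/model --ref fixtures/reference.fa \
            --variants fixtures/variants.tsv --out predictions/
```

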