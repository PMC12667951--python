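# proteobridge

Cross-platform proteomics imputation with a joint variational autoencoder.

Large cohorts are increasingly profiled on one of two affinity proteomics
platforms — antibody/PEA panels (Olink, NPX units on a log2 scale) or
aptamer panels (SomaScan, RFU units) — and the two often disagree at the
individual-protein level. That fragments meta-analysis: a protein measured
on one platform simply has no value in a cohort run on the other.
`proteobridge` learns a shared latent representation from samples measured
on *both* platforms and then imputes either platform's full profile from
the other, so cohorts measured on different platforms can be analysed as
one harmonised dataset.

The package is aimed at computational biologists running cross-cohort
proteomic association studies, and ships everything around the model:
preprocessing and cohort standardisation, KNN and WNN/sPCA baseline
imputers with a permuted negative control, a quantitative evaluation
battery (correlation distributions, phenotype-association preservation,
z-score meta-analysis workflows), attribution-based interpretability
against reference protein-association networks, and a ground-truth
synthetic-data generator.

## The model

Paired profiles x_i^A ∈ R^{d_A}, x_i^B ∈ R^{d_B} are encoded by
platform-specific encoders into diagonal-Gaussian posteriors
q(z | x^•) = N(μ_•, diag σ_•²) in one shared latent space, and decoded by
either platform's decoder; decoding z_A with the B decoder performs the
imputation. Training minimises

    L_total = λ_rec·L_rec + λ_KL·L_KL + λ_align·L_align + λ_cross·L_cross

an ℓ2 self-reconstruction term, a matching cross-reconstruction term, a
KL pull towards the N(0, I) prior, and an MMD alignment term (unbiased
U-statistic, RBF kernel, median-heuristic bandwidth) that matches the two
platforms' aggregated posteriors so that latent codes are interchangeable
between decoders. Defaults: λ_rec = 0.90, λ_cross = 1.4, λ_KL = 1.4e-4,
λ_align = 1.9; AdamW, Xavier initialisation, early stopping on a dedicated
split. See `docs/methods.md` for the full treatment.

The model, its losses and the attribution methods run on a small
reverse-mode autodiff engine over numpy included in the package
(`proteobridge.autodiff`), so there is no deep-learning framework
dependency; everything is CPU-friendly at study scale.

## Worked example

Train on a synthetic paired cohort with known ground truth and compare the
VAE against the baselines on the held-out test split:

```python
import numpy as np
import proteobridge as pb
from proteobridge.jvae import NetworkConfig
from proteobridge.training import TrainConfig
from proteobridge.baselines import median_neighbor_distance
from proteobridge.synthetic import concordant_probes

paired, gt = pb.generate_preset("medium", seed=5)   # N=3000, 300 probes, K=30
prep = pb.prepare(paired, seed=5)                   # log2 + Z-score, 60/10/10/20 split

net = NetworkConfig(d_a=300, d_b=300, d_z=16, hidden=128)
cfg = TrainConfig(seed=5, network=net, max_epochs=60, patience=10, learning_rate=3e-3)
model, history = pb.fit_jvae(prep, network=net, config=cfg)

te, tr = prep.split.test, prep.split.train
cp = concordant_probes(gt)                          # probes truly shared across platforms

xb_vae = pb.impute(prep.xa[te], "A2B", model)
r_vae = np.nanmedian(pb.correlation_report(xb_vae, prep.xb[te]).feature_r[cp])

knn_cfg = pb.KnnConfig(k=15, bandwidth=median_neighbor_distance(prep.xa[tr]))
xb_knn = pb.knn_impute(prep.xa[te], prep.xa[tr], prep.xb[tr], knn_cfg)
r_knn = np.nanmedian(pb.correlation_report(xb_knn, prep.xb[te]).feature_r[cp])

print(f"median feature-wise r  VAE {r_vae:.3f}  KNN {r_knn:.3f}")
```

```
median feature-wise r  VAE 0.819  KNN 0.796
```

Each number is the median, over concordant probes, of the Pearson
correlation between imputed and actually measured (standardized) values on
the 600 held-out samples — the package's primary accuracy metric. The
generator's expected cross-platform concordance at the default noise level
is ≈ 0.8, so an imputer at ≈ 0.8 is extracting most of the shared signal;
the permuted negative control sits near 0 (median |r| ≈ 0.03).

The same pipeline is scriptable from the shell:

```bash
proteobridge simulate --preset medium --seed 5 --out data/
proteobridge train --platform-a data/platform_a.tsv --platform-b data/platform_b.tsv --out run/
proteobridge impute --checkpoint run/checkpoint --input data/platform_b.tsv \
    --direction B2A --out imputed_a.tsv
```

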