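# cedr — consensus multi-omics subtyping via ensemble dimensionality reduction

Cancer subtyping from multi-omics data (e.g. mRNA, miRNA, DNA
methylation profiled on the same patients) has to cope with three
things at once: each omics layer is high-dimensional and noisy, layers
live on different scales, and no single dimensionality-reduction method
captures every aspect of the shared structure. `cedr` addresses this
with a three-stage consensus pipeline:

1. **Ensemble dimensionality reduction.** Four complementary channels —
   a denoising autoencoder (DAE), a sparse autoencoder (SAE), PCA and
   FastICA — each reduce every layer `A_k ∈ R^{n×p_k}` to `n × m_k`
   features, concatenated per channel into an integrated matrix `H`.
2. **Robust model-based clustering.** Each `H` is clustered with a
   robust improper maximum likelihood estimator: the pseudo-density
   `ψ_δ(h) = π₀δ + Σ_j π_j φ(h; μ_j, Σ_j)` adds an improper uniform
   component `δ` that absorbs outliers. The fit is constrained (an
   eigenratio bound `γ` on the covariances, a cap `π_max` on the noise
   mass), `δ` is tuned so clustered points look maximally Gaussian, and
   the number of clusters `G` is chosen by the Calinski–Harabasz index.
   This yields one base partition per channel, with label 0 = outlier.
3. **Mixture-of-partitions consensus.** The base partitions form an
   `n × S` categorical matrix modelled as a mixture of multivariate
   multinomials `P(y_i) = Σ_q α_q Π_l ν_lq(y_il)`, fit by EM; BIC picks
   the number of consensus clusters `Q`, and each sample gets the
   posterior-argmax consensus label. Samples flagged as outliers by
   every channel are trimmed and reported.

The package ships the simulation benchmark used to validate the
method — 3 layers × 200 samples × 1000 features with four planted
subtypes, block-structured signal features and Gaussian noise — so the
whole pipeline is testable offline. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import cedr

# one benchmark dataset: 6% signal features, sigma^2 = 2
config = cedr.build_scenario("SimData1", "low")
dataset = cedr.generate_dataset(config, seed=1)

result = cedr.run_cedr(dataset, cedr.CEDRConfig(seed=1))
labels = result.consensus_labels()

print("consensus clusters:", result.consensus.model.Q)
print("trimmed samples:", len(result.consensus.trimmed_ids))
print("NMI vs planted subtypes:",
      round(cedr.nmi(dataset.true_labels, labels), 3))
for method, base in result.base.items():
    print(f"  {method}: G={base.G}, "
          f"NMI={cedr.nmi(dataset.true_labels, base.labels):.3f}")
```

Output:

```
consensus clusters: 4
trimmed samples: 0
NMI vs planted subtypes: 1.0
  DAE: G=4, NMI=1.000
  SAE: G=4, NMI=1.000
  PCA: G=2, NMI=0.637
  ICA: G=2, NMI=0.637
```

The consensus recovers the four planted subtypes exactly even though
the two linear channels only see coarser splits — the ensemble keeps
the agreement of the autoencoder channels and is not dragged down by
the weaker ones. NMI (normalized mutual information,
`I(U,V)/√(H(U)H(V))`) is 1 for a perfect match.

The same pipeline runs from the shell:

```bash
cedr simulate --scenario SimData1 --noise low --seed 1 --out data/
cedr run --in data/ --out results/          # consensus.tsv + report.json
cedr benchmark --scenario SimData1 --noise high --reps 20 --seed 7
```

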