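"""Cross-signature analyses over a small signature ensemble.

Builds an ensemble of FSFS signatures derived at several (C, sigma) cells,
validates each by k-fold, then computes the ensemble summaries: top
signatures by validation log loss, scaled gene-appearance frequencies,
the frequency-vs-mutual-information correlation, and the removal weight
of one gene.
"""

from radsig import (
    GenePanel,
    HyperParams,
    SignatureCollection,
    SimConfig,
    discretize_expression,
    frequency_mi_correlation,
    fsfs,
    gene_frequency,
    gene_removal_weight,
    generate_dataset,
    kfold_validate_signature,
    mid_rank,
    preprocess_pipeline,
    top_signatures,
)

matrix, labels, truth = generate_dataset(SimConfig(seed=7))
(proc,) = preprocess_pipeline([matrix], GenePanel(matrix.row_ids))
ranking = mid_rank(discretize_expression(proc), labels, 50)

entries = []
for C, sigma in [(1, 1), (10, 1), (100, 10)]:
    sig, _ = fsfs(ranking, proc, labels, HyperParams(C=C, sigma=sigma),
                  criterion="log_loss", seed=7, dataset_id="sim")
    report = kfold_validate_signature(proc, labels, sig, k=5,
                                      params=sig.params, repeats=3, seed=7)
    entries.append((sig, {"sim": report}))

collection = SignatureCollection(entries)
best = top_signatures(collection, n=2)
print("top signatures by mean validation log loss:")
for sig, reports in best.entries:
    print(f"  (C={sig.params.C:g}, sigma={sig.params.sigma:g}) "
          f"{len(sig.genes)} genes, log loss "
          f"{reports['sim'].log_loss:.3f} nats")

freqs = gene_frequency(collection)
print("\nscaled gene frequencies (1.0 = most frequent in its group):")
print(freqs.sort_values("sim", ascending=False).head(8).to_string())

mi = dict(zip(ranking.table["gene"], ranking.table["relevance_nats"]))
rho = frequency_mi_correlation(freqs, mi)
print(f"\nPearson correlation between appearance frequency and "
      f"MI with dose: {rho:.3f}")

sig0 = collection.entries[0][0]
gene = sig0.genes[0]
deltas = gene_removal_weight(sig0, gene, [("sim", proc, labels)], k=5,
                             repeats=3, seed=7)
print(f"\nremoval weight of {gene} (positive = gene was helping):")
print(deltas.to_string())
# Delta-GoF is suppressed (NaN) on the dataset the signature was derived
# from, where dose distance was never the optimized quantity.
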