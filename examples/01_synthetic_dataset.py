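"""Generate a planted drug-disease dataset and inspect its summary statistics.

The generator plants low-rank structure: nonnegative latent factors for
drugs and diseases produce the adjacency matrix by thresholding, and the
chemical/semantic similarity matrices are the cosine similarities between
factor rows — exactly the structure the factorization model assumes.
"""

from ddicmf import dataset_summary, generate_synthetic, save_dataset

im, s_drug, s_disease = generate_synthetic(
    n=60, m=40, k_true=4, density=0.05, noise=0.0, seed=1
)
summary = dataset_summary(im)
print("dataset summary:", summary.to_json())
# n_interactions / (n_drugs * n_diseases) = sparsity; 0.05 was requested.

save_dataset(im, s_drug, s_disease, "Y.tsv", "SD.tsv", "SDIS.tsv")
print("wrote Y.tsv (60x40 adjacency), SD.tsv (60x60), SDIS.tsv (40x40)")
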