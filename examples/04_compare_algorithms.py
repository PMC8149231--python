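"""Compare the four classifiers on one synthetic cohort.

Rows mirror the study comparison: the plain clonal-selection prototype
classifier is cheapest but least accurate; the grid-searched SVM is strong;
the immune-optimized SVM (feature screening + tuned kernel) is the most
accurate; PCA+SVM sits in between.  Per-class accuracies show the difficulty
ordering normal >= cirrhosis >= cancer.
"""

from immunotexture import IaConfig, compare_algorithms, generate_dataset
from immunotexture.classifiers import default_grid

data = generate_dataset(n_per_class=30, seed=11, size=256)
cfg = IaConfig(seed=11, max_generations=10, target_affinity=0.99)
table = compare_algorithms(data, ia_config=cfg, grid=default_grid(10, 10), pca_components=10, seed=11)
print(table.to_string(float_format=lambda v: f"{v:.4f}"))
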