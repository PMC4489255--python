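"""Node scores and edge probabilities from differential expression.

Reproduces the reference worked example: under a normal fit to the log
fold changes with mean -0.036 and standard deviation 1.255, strongly
regulated genes score near 1 and the probability of the edge joining
them is the product of the endpoint scores.
"""
from subnetx import ExpressionStats, edge_probability, gene_score

stats = ExpressionStats(mu=-0.036, sigma=1.255)

for gene, lfc in [("nhaA", -2.80), ("nhaR", -2.00), ("narG", 5.17)]:
    print(f"Score_{gene} (lfc {lfc:+.2f}) = {gene_score(lfc, stats):.4f}")

p = edge_probability(gene_score(-2.80, stats), gene_score(-2.00, stats))
print(f"P_edge(nhaA, nhaR) = {p:.4f}")
print(
    "\nScores are |1 - 2*Phi(D)| in [0, 1]: ~0 means expression at the "
    "distribution centre,\n~1 means extreme differential expression; the "
    "edge probability is high only when both\nendpoints are strongly "
    "differentially expressed."
)
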