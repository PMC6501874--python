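"""Published glucosinolate-sulfatase MK contingency counts (worked examples).

The diamondback moth (*Plutella xylostella*) carries three tandem
glucosinolate-sulfatase genes (*PxGSS1/2/3*) derived from an ancestral
arylsulfatase *SulfC*.  The published study reports McDonald-Kreitman
contingency counts for each gene against outgroup/ancestral references
(with Jukes-Cantor-corrected substitution counts) and for pooled pairwise
gene comparisons.  Those printed counts serve as fixed worked-example
inputs for the MK statistics here; the Neutrality Index and chi-square
columns they imply are recomputed, never stored.

``POLYMORPHISM[gene] = (Ps, Pn)`` within-species counts
(sample sizes: PxGSS1 N=60, PxGSS2 N=24, PxGSS3 N=40).
``OUTGROUP_DIVERGENCE`` rows: (gene, reference, Ds, Dn) corrected counts.
``PAIRWISE`` rows: (gene_a, gene_b, Ps, Pn, Ds, Dn) pooled comparisons.
"""

POLYMORPHISM: dict[str, tuple[float, float]] = {
    "PxGSS1": (56.0, 3.0),
    "PxGSS2": (86.0, 12.0),
    "PxGSS3": (97.0, 8.0),
}

SAMPLE_SIZES = {"PxGSS1": 60, "PxGSS2": 24, "PxGSS3": 40}

OUTGROUP_DIVERGENCE: list[tuple[str, str, float, float]] = [
    ("PxGSS2", "YcC", 899.0, 378.1),
    ("PxGSS3", "YcC", 562.8, 354.0),
    ("PxGSS1", "PaGSS1/2", 17.6, 19.2),
    ("PxGSS2", "PaGSS1/2", 22.0, 23.4),
    ("PxGSS3", "PaGSS3", 38.9, 10.1),
]

PAIRWISE: list[tuple[str, str, float, float, float, float]] = [
    ("PxGSS1", "PxGSS2", 142.0, 15.0, 5.1, 6.0),
    ("PxGSS1", "PxGSS3", 153.0, 11.0, 168.2, 205.9),
    ("PxGSS2", "PxGSS3", 183.0, 20.0, 165.9, 207.3),
]
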