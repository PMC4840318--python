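"""How long must a random barcode be to label every transcript uniquely?

The birthday problem over 4^L barcodes: for a study-scale pool of 250,000
transcripts, 20-nt barcodes leave a 97.2% chance that no two transcripts
share a label.
"""

from ablineage import unique_labeling_probability

pool = 250_000
for length in (8, 12, 16, 20):
    p = unique_labeling_probability(pool, length)
    print(f"barcode length {length:2d}: unique-labeling probability {p:.4f}")

exact = unique_labeling_probability(pool, 20, method="exact")
approx = unique_labeling_probability(pool, 20, method="approx")
print(f"exact vs exponential approximation at L=20: {abs(exact - approx):.2e}")
# Short barcodes collide almost surely at this scale; 20 nt gives ~10^12
# labels and keeps the whole pool uniquely tagged with high probability.
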