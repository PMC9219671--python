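"""Generate the default synthetic three-class SERS dataset and write it
to the wide-CSV dialect (one column per spectrum, sidecar label table).

The dataset mimics 197 acquisitions of the same glycoprotein (ACE) from
seminal fluid, lung and heart: shared major bands, small class-exclusive
bands, smooth baseline drift and Gaussian noise, plus six planted
cosmic-ray spikes whose indices are the ground truth for outlier removal.
"""

from pathlib import Path

from serslda import default_profiles, generate_dataset, inject_spikes, write_spectra

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

dataset = generate_dataset(default_profiles(), seed=0)
dataset, spiked = inject_spikes(dataset, n_spectra=6, spike_height=20.0, seed=1)
write_spectra(dataset, out / "spectra.csv", out / "labels.csv")

counts = {c: int((dataset.labels == c).sum()) for c in sorted(set(dataset.labels))}
print(f"wrote {len(dataset)} spectra x {dataset.axis.n_points} points to {out}/")
print(f"class counts: {counts}")
print(f"spiked spectrum indices (ground truth): {spiked}")
# Expect 197 spectra split 66/66/65 and six distinct spiked indices.
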