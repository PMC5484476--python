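"""Preprocess spectra and screen out a corrupted replicate with Dixon's Q-test.

One replicate is deliberately corrupted with a gross additive offset; after
Savitzky-Golay smoothing and region selection, the per-wavenumber Dixon screen
flags it at far more than 50% of wavenumbers and drops it, while every clean
replicate survives.
"""

from igspec import (
    PRESETS,
    PopulationConfig,
    generate_dataset,
    inject_outlier,
    preprocess_set,
    screen_spectra,
)

dataset = generate_dataset(PopulationConfig(n_samples=60), seed=7)
corrupted = inject_outlier(dataset, "S05", 1, magnitude=0.15)  # ~50x the noise level

processed = preprocess_set(corrupted.spectra, PRESETS["smooth"])
kept, report = screen_spectra(processed)

print(f"spectra in:        {len(processed)}  ({processed.grid.size} retained wavenumbers each)")
print(f"spectra kept:      {len(kept)}")
print(f"excluded:          {report.excluded_keys()}  (replicate flagged at >50% of wavenumbers)")
worst = report.table.nlargest(3, "flagged_fraction")[["key", "flagged_fraction"]]
print("highest flagged fractions (fraction of wavenumbers where the spectrum is the")
print("Dixon-extreme at 95% confidence; exclusion needs > 0.5):")
print(worst.to_string(index=False))
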