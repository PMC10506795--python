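"""Sweep oscillating stimuli through fast and slow HRFs.

Builds the packaged family of six double-gamma HRFs, simulates the BOLD
response to sinusoidal drives across 0.01-0.5 Hz, and prints the
high/low-frequency amplitude ratio A(0.2 Hz)/A(0.05 Hz) per kernel. Faster
(narrower, earlier-peaking) kernels pass relatively more high-frequency
power — the mechanism that makes resting-state spectra informative about
hemodynamic speed.
"""

from hemospec import HRFParams, load_hrf_table, make_double_gamma_hrf, sweep_spectrum

table = load_hrf_table()
print(f"{'HRF':<8}{'TTP (s)':>8}{'FWHM (s)':>10}{'A(0.2)/A(0.05)':>16}")
for row in table.itertuples():
    kernel = make_double_gamma_hrf(HRFParams(row.ttp_s, row.fwhm_s, row.peak_psc), dt=0.1)
    spec = sweep_spectrum(kernel, [0.05, 0.2], stimulus_mode="flat", hrf_name=row.name)
    ratio = spec.amplitude[1] / spec.amplitude[0]
    print(f"{row.name:<8}{row.ttp_s:>8.2f}{row.fwhm_s:>10.2f}{ratio:>16.3f}")
print("\nA larger ratio means the kernel attenuates high frequencies less:")
print("the fastest HRF retains the most 0.2 Hz power relative to 0.05 Hz.")
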