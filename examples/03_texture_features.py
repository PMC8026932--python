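"""GLCM texture of a parametric map.

Quantizes the ASD parametric map of one slice onto its fixed 16-level gray
scale and prints the four co-occurrence statistics (averaged over distances
1-4 and angles 0/45/90/135).  Energy near 1 and contrast near 0 would mean a
homogeneous map; speckle-driven estimate variation produces intermediate
values.
"""

from qusrecur import simulate, spectra, texture

acq = simulate.AcquisitionSpec()
exam = simulate.simulate_exam(
    acq, simulate.TissueSpec(effective_scatterer_radius=25e-6),
    n_slices=1, seed=2)
phantom = simulate.simulate_phantom(acq, seed=123)
sf = spectra.extract_slice(exam.slices[0], exam.masks[0],
                           spectra.PhantomReference(phantom.slices), acq)

q = texture.quantize_map(sf.maps["ASD"], texture.QUANTIZATION_RANGES["ASD"])
feats = texture.glcm_features(q)
print(f"ASD map lattice {sf.maps['ASD'].shape}, "
      f"{sf.n_windows} defined cells, 16 gray levels on "
      f"{texture.QUANTIZATION_RANGES['ASD']} um")
for k, v in feats.items():
    print(f"  ASD-{k}: {v:.4f}")
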