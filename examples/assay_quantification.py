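"""Quantify the wet-lab readouts used to validate a regulatory variant.

Fits a qPCR standard curve from a simulated dilution series (known
amplification efficiency), converts ChIP Ct values to percent input,
computes a TaqMan allelic-ratio enrichment, normalizes a dual-luciferase
plate, and expresses a growth curve as fold change over t0.
"""

from locuspipe import assay_quant as aq, synthetic_data as sd

plate, truth = sd.simulate_qpcr(
    ["binding_site"], {"binding_site": 0.92}, noise_sd=0.05, seed=10
)
curve = aq.fit_standard_curve(plate["quantity"], plate["ct"])
print("standard curve:")
print(
    f"  slope {curve.slope:.3f} Ct/log10(q), efficiency "
    f"{curve.efficiency:.3f} (true {truth.qpcr_efficiency['binding_site']}), "
    f"R2 {curve.r_squared:.4f}"
)

pct = aq.percent_input(
    ct_ip=27.5, curve=curve, ct_input=26.0, input_dilution_factor=100.0
)
print(f"ChIP recovery: {pct:.2f}% of input "
      "(input was a 1% chromatin aliquot)")

enr = aq.allelic_enrichment(
    ip_ratios=[2.9, 3.3, 3.1, 2.8], input_ratios=[1.0, 1.1, 0.95, 1.05]
)
print(
    f"allelic (A/G) enrichment in IP vs input: {enr.enrichment:.2f}-fold, "
    f"p = {enr.p:.3g}"
)

fold = aq.luciferase_fold(
    firefly=[420, 455, 430], renilla=[100, 105, 98],
    ev_firefly=[100, 95, 102], ev_renilla=[99, 101, 100],
)
print(f"luciferase activity over empty vector: {fold.round(2)}")

growth = aq.growth_normalize([1.0e4, 1.9e4, 4.1e4, 7.8e4])
print(f"growth fold change vs 0 h: {growth.round(2)}")
# Each number is on the scale its assay reports: percent input for ChIP,
# fold enrichment for TaqMan ratios, fold over empty vector for luciferase,
# fold over t0 for growth.
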