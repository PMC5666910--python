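"""Estimate every sample-size parameter from a pilot dataset.

Pilot images here are 16x16 voxel fields so the spatially sparse
subsample still contains enough voxels to identify the Dirichlet
precision; toy grids much smaller than this leave the precision
essentially unidentified.

Generates a synthetic pilot of 30 mask quadruples (algorithms A and B, a
low-quality reference L and a high-quality reference H) from the package's
own generative model, then runs the full estimation pipeline: pooled label
statistics, the per-image variance with its conservative upper bound, the
design factor, and the spatially-sparse Dirichlet precision fit.
"""

from segpower import (
    EstimationConfig,
    ReferenceErrorModel,
    SimulationConfig,
    StudyDesign,
    build_spatial_model,
    estimate_all,
    generate_synthetic_pilot,
    sample_size_dirichlet,
)

spatial = build_spatial_model((16, 16), sigma_rho=0.7)
config = SimulationConfig.from_delta_psi(
    spatial, delta=0.03, psi=0.15, omega=128.0, n_images=30, seed=42
)
ref_model = ReferenceErrorModel(
    pa=0.246, pb=0.195, pl=0.210, ph=0.214, cov_ab_lh=-0.0029
)
pilot = generate_synthetic_pilot(config, ref_model)

est = estimate_all(
    pilot,
    delta_mdd_H=0.05,
    config=EstimationConfig(gamma=80.0, sigma_rho=0.7, seed=7),
)
print(f"psi_hat      = {est.psi_hat:.4f}   (A-B disagreement)")
print(f"delta_hat    = {est.delta_hat:.4f}   (accuracy difference vs L)")
print(f"sigma2_hat   = {est.sigma2_hat:.6f} (var of per-image d_bar)")
print(f"sigma2 upper = {est.sigma2_upper:.6f} (80% conservative bound)")
print(f"f_hat        = {est.f_hat:.4f}   (design factor)")
print(f"omega_hat    = {est.omega_hat:.1f}    (Dirichlet precision)")
print(f"rho_bar_hat  = {est.rho_bar_hat:.4f}   (avg voxel correlation)")
print(f"delta_mdd_hat= {est.delta_mdd_hat:.5f}  (MDD corrected for L)")

res = sample_size_dirichlet(
    est.psi_hat, StudyDesign(delta_mdd=est.delta_mdd_hat), est.f_hat
)
print(f"\nsample size from these estimates: n = {res.n} images")
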