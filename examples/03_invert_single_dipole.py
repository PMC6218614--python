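"""Reconstruct one simulated dipole with minimum norm and cortical LORETA.

A single dipole is simulated at a triangle barycenter (never at an inverse
node - no inverse crime), reconstructed with the depth-weighted minimum norm
and with cortical LORETA (unweighted graph Laplacian), and compared by
localization error, goodness of fit and local-maxima count.
"""

import numpy as np

import cortical_loreta as cl
from cortical_loreta.inverse import alpha_from_sci
from cortical_loreta.pipeline import barycentric_source_space, simulate_datasets

mesh = cl.make_cortex_like_surface(1000, seed=0)
montage = cl.make_equidistant_montage(64, 85.0, 130.0)
L = cl.spherical_leadfield(montage, cl.SourceSpace(mesh.vertices, mesh=mesh))
sim_space = barycentric_source_space(mesh)
L_sim = cl.spherical_leadfield(montage, sim_space)
ds = simulate_datasets(sim_space, L_sim, 1, seed=3,
                       inverse_positions=mesh.vertices)[0]
print(f"true source at {np.round(ds.true_position, 1)} mm")

omega = cl.depth_weights(L, sqrt_variant=True)
B = cl.assemble_stiffness(mesh, "uw-graph")
weightings = {
    "depth-weighted minimum norm": cl.build_weighting(omega, None, None, "depth-only"),
    "cortical LORETA (uw-graph)": cl.build_weighting(omega, B, 0.3, "cortical"),
}
for name, W in weightings.items():
    G = L.matrix @ W.solve(L.matrix.T)
    svals = np.linalg.svd(0.5 * (G + G.T), compute_uv=False)
    _, alpha = alpha_from_sci(svals, 1)  # zero only the smallest singular value
    T = cl.inverse_operator_tsvd(L, W, alpha)
    est = cl.estimate_sources(T, ds.data, L)
    res = cl.evaluate_estimate(est.j, mesh, montage, ds.true_position,
                               ds.data, est.b_hat)
    print(f"\n{name}:")
    print(f"  localization error (max-amplitude node): "
          f"{res.localization_error_ma:5.1f} mm")
    print(f"  localization error (center of mass):     "
          f"{res.localization_error_com:5.1f} mm")
    print(f"  goodness of fit: {res.gof:6.2f} %   "
          f"local maxima: {res.n_local_maxima}")
# With noiseless data and only the null singular value truncated, both
# methods reproduce the data exactly (GOF 100%); they differ in where the
# reconstructed power concentrates.
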