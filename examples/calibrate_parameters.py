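"""Fit the LIE weights on synthetic calibration data with known truth.

Generates calibration systems whose experimental free energies follow the
LIE model exactly under alpha=0.46, beta=0.09, then fits with and without
observation noise.  The noiseless fit inverts the forward model exactly;
the noisy fit shows the scale of parameter uncertainty at a realistic
0.5 kcal/mol experimental error.
"""

from snplie import LIEParameters, fit_parameters
from snplie.synth import gen_calibration_set

truth = LIEParameters(alpha=0.46, beta=0.09)

clean = fit_parameters(gen_calibration_set(truth, n_systems=10, noise_sd=0.0, seed=1))
print(f"noiseless fit : alpha={clean.params.alpha:.6f} beta={clean.params.beta:.6f} "
      f"rmse={clean.rmse:.2e}")

noisy = fit_parameters(gen_calibration_set(truth, n_systems=20, noise_sd=0.5, seed=1))
print(f"noisy fit     : alpha={noisy.params.alpha:.4f} beta={noisy.params.beta:.4f} "
      f"rmse={noisy.rmse:.3f}")
print("(truth is alpha=0.46, beta=0.09; the noisy estimate scatters around it)")

grid = fit_parameters(gen_calibration_set(truth, n_systems=10, noise_sd=0.0, seed=1),
                      method="grid")
print(f"grid scan     : alpha={grid.params.alpha:.3f} beta={grid.params.beta:.3f} "
      "(agrees with least squares to one 0.01 lattice step)")
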