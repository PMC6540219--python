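"""Reduce a 4096-long feature vector to 2054 wavelet coefficients.

One level of the Daubechies-7 DWT splits a feature vector into approximation
(cA) and detail (cD) halves of 2054 coefficients each; the cA half — the
low-frequency, identity-carrying part — is what the classifier consumes.
Perfect reconstruction from both halves confirms no information is lost by
the transform itself; the dimension reduction comes from keeping cA only.
"""

import numpy as np

from wavelstm import daubechies_filters, dwt_single_level, idwt_single_level

rng = np.random.default_rng(0)
x = rng.random(4096)

filters = daubechies_filters(7)
print(f"db7 filter length: {filters.length}, "
      f"lowpass sum: {filters.lowpass.sum():.12f} (sqrt(2) = {np.sqrt(2):.12f})")

coeffs = dwt_single_level(x, filters)
print(f"signal length {x.size} -> cA {coeffs.cA.size}, cD {coeffs.cD.size}")

recon = idwt_single_level(coeffs, filters)
print(f"perfect reconstruction error: {np.abs(recon - x).max():.2e}")

energy = np.sum(x ** 2)
print(f"energy split: cA {np.sum(coeffs.cA**2)/energy:.1%}, "
      f"cD {np.sum(coeffs.cD**2)/energy:.1%}")
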