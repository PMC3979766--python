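"""Recover the four QPSK constellation components automatically.

A 512-sample QPSK signal at 15 dB SNR is a planar 4-component Gaussian
mixture.  The splitting-while-merging mixture algorithm starts from two
components, grows by deterministic injection, prunes by weight
annihilation and selects the candidate with the minimal message length —
no cluster count is supplied anywhere.
"""

import numpy as np

from smartclust.metrics import adjusted_rand_index, silhouette
from smartclust.simulate import QpskSpec, gen_qpsk
from smartclust.smart import SmartConfig, run_smart2

data, truth = gen_qpsk(QpskSpec(n=512, snr_db=15.0),
                       np.random.default_rng(7))
result = run_smart2(data, SmartConfig(seed=0))

print("candidates (k, message length in nats):")
for cand in result.candidates:
    print(f"  k={cand.k_nz}  L={cand.message_length:9.2f}")
print(f"selected number of clusters: {result.k_selected}")
print(f"adjusted Rand index vs truth: "
      f"{adjusted_rand_index(truth, result.labels):.3f}")
print(f"silhouette index:             "
      f"{silhouette(data, result.labels):.3f}")
print()
print("The message length drops sharply while genuine components are")
print("added and flattens once the four constellation corners are")
print("covered; ARI 1.0 means no sample was mis-assigned.")
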