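"""The typical-leaf acceptance test: size score F and architecture score G.

Fits the two PCA shape models on a population of similar leaves, then
scores a mean-sized leaf, an oversized leaf and a tiny newborn.  The
acceptance band requires 0.25 < 1 + F < 1.25 (size) and
0.25 Gbar < G < 1.25 Gbar (architecture).
"""

import numpy as np

from leafmorph import TraitVector, detect_typical, fit_shape_model

rng = np.random.default_rng(3)
rows = []
for _ in range(10):
    f = rng.uniform(0.95, 1.05)  # leaves on one plant are close in size
    rows.append(TraitVector(s=1885 * f**2, c=159 * f, l=60 * f, w=40 * f))
model = fit_shape_model(rows)
print("scale-trait weights a :", np.round(model.a, 3))
print("ratio-trait weights b :", np.round(model.b, 3))
print(f"mean G over fit set   : {model.mean_g:.2f}")

candidates = {
    "mean leaf": TraitVector(s=1885, c=159, l=60, w=40),
    "oversized (+40% linear)": TraitVector(s=1885 * 1.4**2, c=159 * 1.4,
                                           l=60 * 1.4, w=40 * 1.4),
    "newborn (15% linear)": TraitVector(s=1885 * 0.15**2, c=159 * 0.15,
                                        l=60 * 0.15, w=40 * 0.15),
}
for name, tv in candidates.items():
    res = detect_typical(tv, model)
    print(f"{name:24s} 1+F={1 + res.f_score:6.3f}  G={res.g_score:6.2f} "
          f"-> {'TYPICAL' if res.is_typical else 'rejected (' + res.reason + ')'}")
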