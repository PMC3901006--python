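"""The parametric response-shape family and its PCA basis.

A response prototype r(t) is a continuous piecewise half-cosine curve:
latency, optional initial dip, rise to a plateau at 1, decay into an
optional undershoot, recovery to 0.  Sweeping the eight parameters over
user intervals yields a shape library; the first L principal directions of
that library form the signal block of the design matrix.
"""

import numpy as np

from vsdikit import ShapeIntervals, ShapeParams, response_shape
from vsdikit.model_builder import generate_shape_library, shape_basis

t = np.linspace(0, 1.5, 300)
proto = ShapeParams(alpha1=0.05, alpha3=0.15, alpha4=0.3,
                    alpha5=0.25, alpha6=0.25, alpha8=0.15)
r = response_shape(t, proto)
print(f"prototype: peak {r.max():.2f} at t={t[r.argmax()]:.2f} s, "
      f"undershoot {r.min():.2f}, support ends at {proto.support_end:.2f} s")

intervals = ShapeIntervals()
library = generate_shape_library(intervals, t)
print(f"sweep: {intervals.grid_size} parameter combinations -> "
      f"{library.shape[0]} non-degenerate shapes")

basis = shape_basis(library)  # L chosen to capture 99% of library energy
proj = library @ basis @ basis.T
worst = np.max(np.linalg.norm(library - proj, axis=1)
               / np.linalg.norm(library, axis=1))
print(f"PCA basis: L={basis.shape[1]} components; worst per-shape "
      f"reconstruction error {100*worst:.2f}% of shape norm")
# A handful of components represents hundreds of plausible response shapes,
# letting one linear model accommodate responses it was never told about.
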