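"""Published point estimates bundled for worked examples.

These are the reported two-dimension EAP estimates from an exploratory
nominal factor analysis of a reduced four-item Learning Style Inventory
(4 categories per item, N = 448), under simple constraints with reference
category 4 and the echelon identification pattern (item 1 category 1 slope
fixed at 1 on dimension 1 and 0 on dimension 2; item 1 category 2 slope
fixed at 1 on dimension 2).  They serve as inputs to the parameterization
transform and rotation examples; the underlying response data are not
distributed.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParameters

__all__ = ["lsi_two_dim_estimates", "lsi_deviation_slopes", "lsi_rotated_slopes"]

# item, category, intercept, a1, a2 (published EAPs, 2 decimals)
_LSI_SIMPLE = np.array(
    [
        [1, 1, 3.41, 1.00, 0.00],
        [1, 2, 2.38, 0.82, 1.00],
        [1, 3, 1.51, 0.35, 0.52],
        [1, 4, 0.00, 0.00, 0.00],
        [2, 1, 5.24, 1.77, -1.55],
        [2, 2, 1.77, 0.89, 0.88],
        [2, 3, -0.70, 0.53, 3.89],
        [2, 4, 0.00, 0.00, 0.00],
        [3, 1, 2.91, 1.57, -1.63],
        [3, 2, 2.42, 0.96, 0.80],
        [3, 3, 0.61, 0.34, 3.27],
        [3, 4, 0.00, 0.00, 0.00],
        [4, 1, 1.22, 0.75, -0.11],
        [4, 2, 0.24, 1.05, 4.19],
        [4, 3, 0.57, 0.55, 2.67],
        [4, 4, 0.00, 0.00, 0.00],
    ]
)

# Published deviation-constraint slopes (a1, a2) for the same model,
# item-major, categories 1..4.
_LSI_DEVIATION = np.array(
    [
        [0.46, -0.38], [0.27, 0.62], [-0.19, 0.14], [-0.54, -0.38],
        [0.98, -2.36], [0.10, 0.07], [-0.27, 3.09], [-0.80, -0.81],
        [0.85, -2.24], [0.24, 0.19], [-0.38, 2.66], [-0.72, -0.61],
        [0.16, -1.80], [0.46, 2.50], [-0.04, 0.98], [-0.59, -1.69],
    ]
)

# Published slopes after the 72-degree clockwise orthogonal rotation.
_LSI_ROTATED = np.array(
    [
        [0.50, 0.32], [-0.50, 0.45], [-0.20, -0.14], [0.20, -0.63],
        [2.54, 0.20], [-0.04, 0.11], [-3.02, 0.69], [0.52, -1.01],
        [2.40, 0.11], [-0.11, 0.29], [-2.65, 0.46], [0.36, -0.87],
        [1.76, -0.40], [-2.24, 1.21], [-0.95, 0.27], [1.43, -1.08],
    ]
)


def lsi_two_dim_estimates() -> ModelParameters:
    """Simple-constraint (reference category 4) published estimates, J=4, K=4, D=2."""
    c = _LSI_SIMPLE[:, 2].reshape(4, 4)
    a = _LSI_SIMPLE[:, 3:5].reshape(4, 4, 2)
    return ModelParameters(c.copy(), a.copy(), "simple", reference_category=4)


def lsi_deviation_slopes() -> np.ndarray:
    """Published deviation-constraint slopes as a (4, 4, 2) array."""
    return _LSI_DEVIATION.reshape(4, 4, 2).copy()


def lsi_rotated_slopes() -> np.ndarray:
    """Published 72-degree clockwise-rotated slopes as a (4, 4, 2) array."""
    return _LSI_ROTATED.reshape(4, 4, 2).copy()
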