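"""Built-in worked-example data.

Two small reference correlation matrices used for worked examples and
regression tests of the significance-classification logic:

* an 8-gene circadian-clock set (Nr1d1, Cry2, Per1, Npas2, Arntl, Cry1,
  Clock, Per2) — pairwise Pearson correlations of dorsal-striatum
  expression profiles across 18 RNA-Seq samples.  Its documented property:
  at alpha = 0.05 every gene correlates significantly with at least two
  others, except Clock with none, and the classification is identical
  whether the t test uses 16 or 17 degrees of freedom.

* a 5-gene striatum-marker set (Darpp-32, Penk, Drd2, Drd1, Pdyn) of
  dopamine- and opioid-pathway genes across the same 18 samples.
"""

from __future__ import annotations

import numpy as np

from .covariation import CorrelationMatrix

__all__ = ["circadian_clock_matrix", "striatal_marker_matrix"]

_CIRCADIAN_GENES = ["Nr1d1", "Cry2", "Per1", "Npas2", "Arntl", "Cry1", "Clock", "Per2"]

_CIRCADIAN_R = [
    [1.000, 0.603, 0.312, -0.247, -0.620, -0.288, -0.305, 0.025],
    [0.603, 1.000, 0.656, -0.087, -0.392, 0.179, -0.138, 0.447],
    [0.312, 0.656, 1.000, -0.226, -0.474, 0.297, 0.126, 0.669],
    [-0.247, -0.087, -0.226, 1.000, 0.552, 0.510, 0.223, 0.065],
    [-0.620, -0.392, -0.474, 0.552, 1.000, 0.325, 0.369, -0.067],
    [-0.288, 0.179, 0.297, 0.510, 0.325, 1.000, 0.323, 0.786],
    [-0.305, -0.138, 0.126, 0.223, 0.369, 0.323, 1.000, 0.274],
    [0.025, 0.447, 0.669, 0.065, -0.067, 0.786, 0.274, 1.000],
]

_MARKER_GENES = ["Darpp-32", "Penk", "Drd2", "Drd1", "Pdyn"]

_MARKER_R = [
    [1.000, 0.858, 0.914, 0.863, 0.723],
    [0.858, 1.000, 0.925, 0.838, 0.867],
    [0.914, 0.925, 1.000, 0.886, 0.777],
    [0.863, 0.838, 0.886, 1.000, 0.717],
    [0.723, 0.867, 0.777, 0.717, 1.000],
]


def circadian_clock_matrix(n: int = 18) -> CorrelationMatrix:
    """The 8-gene circadian-clock Pearson matrix (18 samples)."""
    return CorrelationMatrix(
        genes=list(_CIRCADIAN_GENES), r=np.array(_CIRCADIAN_R, dtype=float), n=n
    )


def striatal_marker_matrix(n: int = 18) -> CorrelationMatrix:
    """The 5-gene dopamine/opioid striatal-marker Pearson matrix (18 samples)."""
    return CorrelationMatrix(
        genes=list(_MARKER_GENES), r=np.array(_MARKER_R, dtype=float), n=n
    )
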