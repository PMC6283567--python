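"""Tiny deterministic instances with hand-computed expected values.

These fixtures are shared by the test-suite and by the worked examples;
every expected number was derived by hand (or by exhaustive enumeration)
from the defining formulas, so they double as executable documentation of
the statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_fixture"]


def make_fixture(name: str) -> dict:
    """Return a named hand-verified fixture.

    Available fixtures
    ------------------
    score_4:
        N=4 burden score instance with U=1, V=1/3, Q=3.
    kbac_4:
        N=4 (2 cases / 2 controls) single-carrier instance whose KBAC
        statistic, summing over all genotype classes including wild type,
        is 0.0625 (carrier-class weight 0.5, wild-type weight 1).
    skat_4:
        N=4 instance with two indicator variants where Q(rho=0) = 0.5.
    podkat_kernel:
        three positions whose triangular proximity entries at radius
        1,000 bp are 1, 0.75 and 0.
    weights_ctrl:
        N=4, N0=2 control-MAF weighting instance where the pseudo-count
        estimator gives MAF0 = 0.5 and hence weight 1.
    """
    if name == "score_4":
        return {
            "S": np.array([1.0, 1.0, 0.0, 0.0]),
            "Y": np.array([1, 1, 0, 0], dtype=np.int8),
            "mu": np.full(4, 0.5),
            "U": 1.0,
            "V": 1.0 / 3.0,
            "Q": 3.0,
        }
    if name == "kbac_4":
        # individuals: 1 case carrier, 1 case wild type, 2 control wild type
        X = np.array([[1], [0], [0], [0]], dtype=np.int8)
        Y = np.array([1, 1, 0, 0], dtype=np.int8)
        return {"X": X, "Y": Y, "statistic": 0.0625, "carrier_weight": 0.5}
    if name == "skat_4":
        X = np.array([[1, 0], [0, 1], [0, 0], [0, 0]], dtype=np.int8)
        Y = np.array([1, 1, 0, 0], dtype=np.int8)
        return {"X": X, "Y": Y, "mu": np.full(4, 0.5), "Q_rho0": 0.5}
    if name == "podkat_kernel":
        return {
            "positions": np.array([100, 350, 1400]),
            "radius": 1_000.0,
            "A_01": 0.75,  # distance 250
            "A_02": 0.0,  # distance 1300 >= radius
        }
    if name == "weights_ctrl":
        X = np.array([[2], [1], [1], [1]], dtype=np.int8)  # controls carry 2 alleles
        Y = np.array([1, 1, 0, 0], dtype=np.int8)
        return {"X": X, "Y": Y, "maf0": 0.5, "weight": 1.0}
    raise KeyError(f"unknown fixture {name!r}")
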