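"""Small built-in datasets for demonstrations and tests."""

from __future__ import annotations

import numpy as np

from .markers import MarkerMatrix, Phenotype

__all__ = ["two_locus_demo"]


def two_locus_demo() -> tuple[MarkerMatrix, Phenotype]:
    """Five lines scored at two loci, with phenotypes.

    A minimal worked example on which OLS, eRRBLUP-1 (λ1 = λ2 = 1) and
    eRRBLUP-2 (λ1 = 0, λ2 = 1) can be fitted by hand under the raw and
    the column-mean-centered coding to see which estimates move when the
    coding is translated.
    """
    M = MarkerMatrix(
        np.array([[2.0, 2.0], [1.0, 2.0], [2.0, 0.0],
                  [2.0, 1.0], [1.0, 0.0]]),
        line_ids=[f"ind{i}" for i in range(1, 6)],
        marker_ids=["M1", "M2"],
    )
    y = Phenotype(np.array([-0.72, 2.34, 0.08, -0.89, 0.86]),
                  list(M.line_ids))
    return M, y
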