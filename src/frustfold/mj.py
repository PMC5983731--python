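"""Miyazawa-Jernigan knowledge-based residue-residue contact energies.

The 20x20 table below is the widely used statistical contact-energy matrix
e_ij (RT units) estimated from residue-pair frequencies in folded
structures.  Attractive entries are negative; strongly hydrophobic pairs
(e.g. F-F, L-L) are the most attractive.  Within this package the table
only ever enters through ratios: native-contact couplings are |e_ij|
rescaled so their mean over the contact list is a prescribed value
(0.18 eps0 by default), so any overall positive rescaling of the table
leaves the model unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MJTable", "AA_ORDER", "mj_contact_energies"]

#: Residue ordering of the raw table rows/columns (one-letter codes).
AA_ORDER = "CMFILVWYAGTSNQDEHRKP"

# Upper triangle (row i, columns i..19) of the contact-energy matrix.
_UPPER = [
    # C      M      F      I      L      V      W      Y      A      G      T      S      N      Q      D      E      H      R      K      P
    [-5.44, -4.99, -5.80, -5.50, -5.83, -4.96, -4.95, -4.16, -3.57, -3.16, -3.11, -2.86, -2.59, -2.85, -2.41, -2.27, -3.60, -2.57, -1.95, -3.07],
    [       -5.46, -6.56, -6.02, -6.41, -5.32, -5.55, -4.91, -3.94, -3.39, -3.51, -3.03, -2.95, -3.30, -2.57, -2.89, -3.98, -3.12, -2.48, -3.45],
    [              -7.26, -6.84, -7.28, -6.29, -6.16, -5.66, -4.81, -4.13, -4.28, -4.02, -3.75, -4.10, -3.48, -3.56, -4.77, -3.98, -3.36, -4.25],
    [                     -6.54, -7.04, -6.05, -5.78, -5.25, -4.58, -3.78, -4.03, -3.52, -3.24, -3.67, -3.17, -3.27, -4.14, -3.63, -3.01, -3.76],
    [                            -7.37, -6.48, -6.14, -5.67, -4.91, -4.16, -4.34, -3.92, -3.74, -4.04, -3.40, -3.59, -4.54, -4.03, -3.37, -4.20],
    [                                   -5.52, -5.18, -4.62, -4.04, -3.38, -3.46, -3.05, -2.83, -3.07, -2.48, -2.67, -3.58, -3.07, -2.49, -3.32],
    [                                          -5.06, -4.66, -3.82, -3.42, -3.22, -2.99, -3.07, -3.11, -2.84, -2.99, -3.98, -3.41, -2.69, -3.73],
    [                                                 -4.17, -3.36, -3.01, -3.01, -2.78, -2.76, -2.97, -2.76, -2.79, -3.52, -3.16, -2.60, -3.19],
    [                                                        -2.72, -2.31, -2.32, -2.01, -1.84, -1.89, -1.70, -1.51, -2.41, -1.83, -1.31, -2.03],
    [                                                               -2.24, -2.08, -1.82, -1.74, -1.66, -1.59, -1.22, -2.15, -1.72, -1.15, -1.87],
    [                                                                      -2.12, -1.96, -1.88, -1.90, -1.80, -1.74, -2.42, -1.90, -1.31, -1.90],
    [                                                                             -1.67, -1.58, -1.49, -1.63, -1.48, -2.11, -1.62, -1.05, -1.57],
    [                                                                                    -1.68, -1.71, -1.68, -1.51, -2.08, -1.64, -1.21, -1.53],
    [                                                                                           -1.54, -1.46, -1.42, -1.98, -1.80, -1.29, -1.73],
    [                                                                                                  -1.21, -1.02, -2.32, -2.29, -1.68, -1.33],
    [                                                                                                         -0.91, -2.15, -2.27, -1.80, -1.26],
    [                                                                                                                -3.05, -2.16, -1.35, -2.25],
    [                                                                                                                       -1.55, -0.59, -1.70],
    [                                                                                                                              -0.12, -0.97],
    [                                                                                                                                     -1.75],
]


def _build_matrix() -> np.ndarray:
    m = np.zeros((20, 20))
    for i, row in enumerate(_UPPER):
        for k, v in enumerate(row):
            j = i + k
            m[i, j] = v
            m[j, i] = v
    return m


class MJTable:
    """Symmetric residue-pair contact-energy lookup.

    Parameters
    ----------
    matrix:
        20x20 symmetric matrix in the ordering of ``order``.  Defaults to
        the embedded statistical table.
    order:
        One-letter residue codes labelling rows/columns.
    """

    def __init__(self, matrix: np.ndarray | None = None, order: str = AA_ORDER):
        if matrix is None:
            matrix = _build_matrix()
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(order), len(order)):
            raise ValueError("matrix shape does not match residue ordering")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("contact-energy matrix must be symmetric")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("contact-energy matrix must be finite")
        self.matrix = matrix
        self.order = order
        self._index = {aa: i for i, aa in enumerate(order)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return float(self.matrix[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"unknown residue letter {exc.args[0]!r}") from None

    @classmethod
    def uniform(cls, value: float = -1.0) -> "MJTable":
        """A flat table: every pair gets the same energy (useful for the
        unflavored limit, where every normalized coupling equals the mean)."""
        return cls(np.full((20, 20), float(value)))

    def scaled(self, factor: float) -> "MJTable":
        return MJTable(self.matrix * factor, self.order)


def mj_contact_energies() -> MJTable:
    """The default embedded contact-energy table."""
    return MJTable()
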