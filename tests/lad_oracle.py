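"""Independent least-absolute-deviation oracle.

Solves min_p Σ_i |(Mᵀp)_i − o_i| over the probability simplex exactly as a
linear program (auxiliary variables e_i ≥ ±residual), via scipy's HiGHS
solver.  Used only to cross-check the exhaustive grid search — it shares no
code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def lad_simplex_optimum(M: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact continuous LAD optimum over the simplex.

    M has one row per source, one column per fatty acid.  Returns the
    optimal proportions and the optimal summed absolute deviation.
    """
    k, f = M.shape
    # variables: p (k), e (f); minimise Σ e
    c = np.concatenate([np.zeros(k), np.ones(f)])
    # e_i ≥ (Mᵀp − o)_i  →  Mᵀp − e ≤ o ;  e_i ≥ −(Mᵀp − o)_i → −Mᵀp − e ≤ −o
    A_ub = np.block([[M.T, -np.eye(f)], [-M.T, -np.eye(f)]])
    b_ub = np.concatenate([obs, -obs])
    A_eq = np.concatenate([np.ones(k), np.zeros(f)])[None, :]
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
        bounds=[(0, 1)] * k + [(0, None)] * f, method="highs",
    )
    assert res.success, res.message
    return res.x[:k], float(res.fun)
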