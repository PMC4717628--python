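"""Independent exact LP oracle: rational vertex enumeration.

For small flux polytopes {v : S v = 0, lb <= v <= ub} with *finite*
bounds, the maximum of a linear objective is attained at a basic feasible
solution: fix n - rank(S) variables at a bound and solve the equalities
for the rest.  Everything runs in exact rational arithmetic (sympy), so
the result is a ground truth the floating-point solvers are compared to.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product

import sympy


def exact_lp_max(S, lb, ub, c):
    """Exact maximum of c.v over {S v = 0, lb <= v <= ub}.

    All inputs are sequences of rationals with finite bounds.  Returns a
    :class:`fractions.Fraction`, or ``None`` when the polytope is empty.
    """
    n = len(lb)
    lb = [sympy.Rational(Fraction(x)) for x in lb]
    ub = [sympy.Rational(Fraction(x)) for x in ub]
    c = [sympy.Rational(Fraction(x)) for x in c]
    M = sympy.Matrix([[sympy.Rational(Fraction(x)) for x in row] for row in S])
    if M.rows == 0:
        M = sympy.zeros(0, n)
    rref, pivots = M.rref()
    R = rref[: len(pivots), :]  # independent equality rows
    r = len(pivots)
    best = None
    if r == 0:
        # pure box: optimum at the bound matching the sign of c
        val = sum((ub[j] if c[j] > 0 else lb[j]) * c[j] for j in range(n))
        return Fraction(val)
    for basic in combinations(range(n), r):
        A = R[:, list(basic)]
        if A.det() == 0:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        Ainv = A.inv()
        for choice in product((0, 1), repeat=len(nonbasic)):
            xN = [lb[j] if side == 0 else ub[j] for j, side in zip(nonbasic, choice)]
            rhs = sympy.Matrix([
                -sum(R[i, j] * xN[k] for k, j in enumerate(nonbasic))
                for i in range(r)
            ])
            xB = Ainv * rhs
            if any(xB[i] < lb[basic[i]] or xB[i] > ub[basic[i]] for i in range(r)):
                continue
            v = [None] * n
            for i, j in enumerate(basic):
                v[j] = xB[i]
            for k, j in enumerate(nonbasic):
                v[j] = xN[k]
            val = sum(c[j] * v[j] for j in range(n))
            if best is None or val > best:
                best = val
    return None if best is None else Fraction(best)


def model_lp_max(model, target_reaction_id):
    """Run the oracle on a :class:`hymep.MetabolicModel` with finite bounds."""
    from hymep.model import stoichiometric_matrix

    S, _, rxn_ids = stoichiometric_matrix(model, exact=True)
    lb = [Fraction(model.reactions[r].lower_bound) for r in rxn_ids]
    ub = [Fraction(model.reactions[r].upper_bound) for r in rxn_ids]
    c = [Fraction(1) if r == target_reaction_id else Fraction(0) for r in rxn_ids]
    return exact_lp_max(S.tolist(), lb, ub, c)
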