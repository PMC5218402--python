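"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithmic shortcuts: the HMM
oracle enumerates every origin configuration; the regression oracles solve
the normal equations directly.
"""

import itertools

import numpy as np

from epiqtl.maps import haldane_recombination

STATELIST = list(itertools.product("EW", repeat=2))


def enumerate_posterior(query_sexavg, marker_info, obs, dam, sire):
    """Line-origin posterior at one position by exhaustive enumeration.

    marker_info: list of (sexavg, female, male, marker_name) sorted by
    position; obs: marker -> unordered pair or None; dam/sire: PhasedF1.
    Returns (p(EE), p(EW), p(WW)).
    """
    pts = sorted(marker_info + [(query_sexavg, None, None, "__query__")],
                 key=lambda t: t[0])
    # interpolate query sex positions from markers, extending the slope of
    # the nearest interval beyond the terminal markers (the package's map
    # geometry; the quantity under test is the HMM inference itself)
    ms = np.array([m[0] for m in marker_info], float)
    mf = np.array([m[1] for m in marker_info], float)
    mm = np.array([m[2] for m in marker_info], float)

    def _interp(q, x, y):
        keep = np.concatenate([[True], np.diff(x) > 1e-12])
        x, y = x[keep], y[keep]
        if len(x) == 1:
            return y[0] + (q - x[0])
        if q < x[0]:
            s = (y[1] - y[0]) / (x[1] - x[0])
            return y[0] + s * (q - x[0])
        if q > x[-1]:
            s = (y[-1] - y[-2]) / (x[-1] - x[-2])
            return y[-1] + s * (q - x[-1])
        return float(np.interp(q, x, y))

    pts = [(p[0],
            _interp(p[0], ms, mf) if p[3] == "__query__" else p[1],
            _interp(p[0], ms, mm) if p[3] == "__query__" else p[2],
            p[3]) for p in pts]

    def emission(mk, state):
        if mk == "__query__":
            return 1.0
        o = obs.get(mk)
        if o is None:
            return 1.0
        dam_opts = dam.assignments.get(mk)
        sire_opts = sire.assignments.get(mk)
        if dam_opts is None or sire_opts is None:
            return 1.0
        total = 0.0
        for dE, dW in dam_opts:
            for sE, sW in sire_opts:
                tr = {"E": (dE, sE), "W": (dW, sW)}
                a = tr[state[0]][0]
                b = tr[state[1]][1]
                if sorted((repr(a), repr(b))) == sorted((repr(o[0]), repr(o[1]))):
                    total += 1.0
        return total / (len(dam_opts) * len(sire_opts))

    marg = {s: 0.0 for s in STATELIST}
    for cfg in itertools.product(range(4), repeat=len(pts)):
        pr = 0.25
        for t in range(len(pts)):
            s = STATELIST[cfg[t]]
            pr *= emission(pts[t][3], s)
            if pr == 0.0:
                break
            if t > 0:
                s0 = STATELIST[cfg[t - 1]]
                rf = haldane_recombination(max(pts[t][1] - pts[t - 1][1], 0.0))
                rm = haldane_recombination(max(pts[t][2] - pts[t - 1][2], 0.0))
                pr *= (rf if s0[0] != s[0] else 1 - rf)
                pr *= (rm if s0[1] != s[1] else 1 - rm)
        else:
            qi = next(t for t in range(len(pts)) if pts[t][3] == "__query__")
            marg[STATELIST[cfg[qi]]] += pr
    z = sum(marg.values())
    return np.array([marg[("E", "E")] / z,
                     (marg[("E", "W")] + marg[("W", "E")]) / z,
                     marg[("W", "W")] / z])


def ols_normal_equations(X, y):
    """beta and SSE from the normal equations, nothing shared with the
    package's fitting code."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def f_test_joint(X_full, y, test_cols):
    """Classical extra-sum-of-squares F for a column subset."""
    keep = [j for j in range(X_full.shape[1]) if j not in test_cols]
    _, sse_full = ols_normal_equations(X_full, y)
    _, sse_red = ols_normal_equations(X_full[:, keep], y)
    df1 = len(test_cols)
    df2 = len(y) - X_full.shape[1]
    return ((sse_red - sse_full) / df1) / (sse_full / df2)
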