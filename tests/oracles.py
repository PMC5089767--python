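"""Independent brute-force oracles used by the test suite.

The cohort-model oracle enumerates every possible state path over a small
number of cycles and sums probability-weighted accruals directly, without
any matrix bookkeeping, so it exercises the same accounting conventions
through an entirely different computation.
"""

from typing import Dict, List, Sequence

SP, RV, SR, D = "SP", "RV", "SR", "D"


def enumerate_cohort(
    m: float,
    r: float,
    p: Sequence[float],
    qx: Sequence[float],
    u_succ: float,
    u_rev: float,
    fu_primary: float,
    fu_postrev: float,
    c_primary: float,
    c_revision: float,
    rate: float,
    cycles: int,
) -> Dict[str, object]:
    """Exhaustive path enumeration of the four-state model.

    ``p[t-1]`` and ``qx[t]`` apply in cycle t (t >= 1).  Returns totals of
    discounted cost/QALYs and per-cycle state occupancy.
    """
    occupancy: List[Dict[str, float]] = [dict.fromkeys((SP, RV, SR, D), 0.0) for _ in range(cycles)]
    totals = {"cost": 0.0, "qaly": 0.0}

    def accrue(t, prob, cost, qaly):
        disc = 1.0 / (1.0 + rate) ** t
        totals["cost"] += prob * cost * disc
        totals["qaly"] += prob * qaly * disc

    def walk(t, state, prob):
        occupancy[t][state] += prob
        if t == cycles - 1:
            return
        nt = t + 1
        q = qx[nt]
        if state == SP:
            pt = p[nt - 1]
            walk(nt, D, prob * q)
            accrue(nt, prob * (1 - q) * pt * m, c_revision, 0.0)
            walk(nt, D, prob * (1 - q) * pt * m)
            pr_rv = prob * (1 - q) * pt * (1 - m)
            accrue(nt, pr_rv, c_revision, u_rev)
            walk(nt, RV, pr_rv)
            pr_sp = prob * (1 - q) * (1 - pt)
            accrue(nt, pr_sp, fu_primary, u_succ)
            walk(nt, SP, pr_sp)
        elif state == RV:
            walk(nt, D, prob * q)
            pr_sr = prob * (1 - q)
            accrue(nt, pr_sr, fu_postrev, u_succ)
            walk(nt, SR, pr_sr)
        elif state == SR:
            walk(nt, D, prob * q)
            accrue(nt, prob * (1 - q) * r * m, c_revision, 0.0)
            walk(nt, D, prob * (1 - q) * r * m)
            pr_rv = prob * (1 - q) * r * (1 - m)
            accrue(nt, pr_rv, c_revision, u_rev)
            walk(nt, RV, pr_rv)
            pr_sr = prob * (1 - q) * (1 - r)
            accrue(nt, pr_sr, fu_postrev, u_succ)
            walk(nt, SR, pr_sr)
        else:
            walk(nt, D, prob)

    # cycle 0: primary operation; everyone pays the primary procedure cost
    accrue(0, 1.0, c_primary, 0.0)
    accrue(0, 1.0 - m, fu_primary, u_succ)
    walk(0, SP, 1.0 - m)
    walk(0, D, m)
    return {"cost": totals["cost"], "qaly": totals["qaly"], "occupancy": occupancy}
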