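"""Shared independent oracles for the test suite."""

from __future__ import annotations


def brute_force_frontier(results) -> set[str]:
    """Non-dominated set by exhaustive convex-combination testing.

    An arm is excluded iff some other arm weakly dominates it, or some
    convex combination of two other arms does (weakly better on both axes,
    strictly on one).  The feasible mixing-weight interval is solved
    analytically per pair; independent of the production algorithm.
    """
    eps = 1e-9
    keep = set()
    for x in results:
        excluded = False
        others = [r for r in results if r.arm != x.arm]
        for a in others:
            if (
                a.cost <= x.cost + eps
                and a.qaly >= x.qaly - eps
                and (a.cost < x.cost - eps or a.qaly > x.qaly + eps)
            ):
                excluded = True
                break
        if not excluded:
            for i, a in enumerate(others):
                for b in others[i + 1 :]:
                    lo, hi = 0.0, 1.0
                    # cost: t*ca + (1-t)*cb <= cx
                    dc = a.cost - b.cost
                    rc = x.cost - b.cost
                    if abs(dc) < eps:
                        if b.cost > x.cost + eps:
                            continue
                    elif dc > 0:
                        hi = min(hi, rc / dc)
                    else:
                        lo = max(lo, rc / dc)
                    # qaly: t*qa + (1-t)*qb >= qx
                    dq = a.qaly - b.qaly
                    rq = x.qaly - b.qaly
                    if abs(dq) < eps:
                        if b.qaly < x.qaly - eps:
                            continue
                    elif dq > 0:
                        lo = max(lo, rq / dq)
                    else:
                        hi = min(hi, rq / dq)
                    if lo > hi + eps:
                        continue
                    t = 0.5 * (max(lo, 0.0) + min(hi, 1.0))
                    cc = t * a.cost + (1 - t) * b.cost
                    qq = t * a.qaly + (1 - t) * b.qaly
                    if (
                        cc <= x.cost + eps
                        and qq >= x.qaly - eps
                        and (cc < x.cost - eps or qq > x.qaly + eps)
                    ):
                        excluded = True
                        break
                if excluded:
                    break
        if not excluded:
            keep.add(x.arm)
    return keep
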