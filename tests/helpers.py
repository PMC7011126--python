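"""Shared oracles and builders used by several test modules."""

import itertools

import numpy as np
import pandas as pd


def make_events(rows):
    df = pd.DataFrame(rows, columns=["student_id", "timestamp", "venue", "direction", "amount"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def events_from_times(times_by_student, day="2017-12-01"):
    """Canteen events at the given second offsets from midnight of ``day``."""
    rows = []
    base = pd.Timestamp(day)
    for sid, times in times_by_student.items():
        for t in times:
            rows.append((sid, base + pd.Timedelta(seconds=float(t)), "canteen", "n/a", 5.0))
    return make_events(rows)


def brute_force_social(times_by_student, T):
    """Literal double-loop definition of the co-swipe count matrix."""
    ids = sorted(times_by_student)
    n = len(ids)
    R = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for a in times_by_student[ids[i]]:
                for b in times_by_student[ids[j]]:
                    if abs(a - b) <= T:
                        R[i, j] += 1
    return ids, R


def exact_mwu_enumeration(x, y):
    """Independent oracle: U of x and the exact two-sided permutation p.

    Enumerates every assignment of the pooled values into groups of sizes
    (n1, n2); p is the fraction of labelings whose U is at least as extreme
    (two-sided, by distance from the mean n1*n2/2).
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in idx if i not in subset]
        gt = sum(1 for a in xs for b in ys if a > b)
        ties = sum(1 for a in xs for b in ys if a == b)
        return gt + 0.5 * ties

    u_obs = u_of(set(range(n1)))
    mu = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - mu)
    us = [u_of(set(s)) for s in itertools.combinations(idx, n1)]
    p = sum(1 for u in us if abs(u - mu) >= dev - 1e-12) / len(us)
    return u_obs, p
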