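"""Independent, literal loop-based oracles.

Deliberately unvectorized straight-line transcriptions of the defining
formulas (time-domain HRV indices, the distance-evaluation weighting chain,
one-way ANOVA), kept free of any code from the package so they can serve as
independent references in equivalence tests.
"""

import math


def oracle_time_domain(intervals):
    """(sdnn, rmssd, sdsd, pnn50) by explicit loops, N-1 denominators."""
    n = len(intervals)
    mean = sum(intervals) / n
    ss = 0.0
    for v in intervals:
        ss += (v - mean) ** 2
    sdnn = math.sqrt(ss / (n - 1))

    diffs = [intervals[i + 1] - intervals[i] for i in range(n - 1)]
    nd = len(diffs)
    ms = 0.0
    for d in diffs:
        ms += d * d
    rmssd = math.sqrt(ms / nd)

    dmean = sum(diffs) / nd
    ssd = 0.0
    for d in diffs:
        ssd += (d - dmean) ** 2
    sdsd = math.sqrt(ssd / (nd - 1))

    count = 0
    for d in diffs:
        if abs(d) > 50.0:
            count += 1
    pnn50 = 100.0 * count / nd
    return sdnn, rmssd, sdsd, pnn50


def oracle_class_stats(groups):
    """Per-class per-feature (u, delta, d, tau) by explicit loops.

    groups: list over classes of list-of-rows (each row: M feature values).
    Returns four Y x M nested lists.
    """
    Y = len(groups)
    M = len(groups[0][0])
    u = [[0.0] * M for _ in range(Y)]
    delta = [[0.0] * M for _ in range(Y)]
    d = [[0.0] * M for _ in range(Y)]
    tau = [[0.0] * M for _ in range(Y)]
    for y in range(Y):
        rows = groups[y]
        N = len(rows)
        for m in range(M):
            s = 0.0
            for nidx in range(N):
                s += rows[nidx][m]
            u[y][m] = s / N

            ss = 0.0
            for nidx in range(N):
                ss += (rows[nidx][m] - u[y][m]) ** 2
            delta[y][m] = math.sqrt(ss / (N - 1))

            cd = []
            for nidx in range(N):
                for r in range(N):
                    if nidx != r:
                        cd.append(abs(rows[nidx][m] - rows[r][m]))
            npairs = N * (N - 1)
            s = 0.0
            for c in cd:
                s += c
            d[y][m] = s / npairs
            ss = 0.0
            for c in cd:
                ss += (c - d[y][m]) ** 2
            tau[y][m] = math.sqrt(ss / (npairs - 1))
    return u, delta, d, tau


def oracle_feature_weights(groups, mode="center_distance", eps=1e-12):
    """eta and eta_norm by a literal transcription of the weighting chain."""
    u, delta, d, tau = oracle_class_stats(groups)
    Y = len(groups)
    M = len(groups[0][0])

    clt_inner = [0.0] * M
    f_inner = [0.0] * M
    for m in range(M):
        s = 0.0
        for y in range(Y):
            s += delta[y][m]
        clt_inner[m] = s / Y
        dmax = max(delta[y][m] for y in range(Y))
        dmin = min(delta[y][m] for y in range(Y))
        f_inner[m] = dmax / max(dmin, eps)

    clt_outer = [0.0] * M
    f_outer = [0.0] * M
    for m in range(M):
        vals = []
        for y in range(Y):
            for c in range(Y):
                if y != c:
                    if mode == "center_distance":
                        vals.append(abs(u[y][m] - u[c][m]))
                    else:
                        vals.append(abs(tau[y][m] - tau[c][m]))
        if mode == "center_distance":
            s = 0.0
            for v in vals:
                s += v
            clt_outer[m] = s / len(vals)
        else:
            ss = 0.0
            for v in vals:
                ss += v * v
            clt_outer[m] = math.sqrt(ss / (Y * (Y - 1)))
        f_outer[m] = max(vals) / max(min(vals), eps)

    fi_max = max(f_inner)
    fo_max = max(f_outer)
    eta = [0.0] * M
    for m in range(M):
        comp = 1.0 / (f_inner[m] / max(fi_max, eps) + f_outer[m] / max(fo_max, eps))
        eta[m] = comp * clt_outer[m] / max(clt_inner[m], eps)
    eta_max = max(eta)
    if eta_max > 0:
        eta_norm = [e / eta_max for e in eta]
    else:
        eta_norm = [0.0] * M
    return eta, eta_norm


def oracle_anova(groups):
    """(F, df_between, df_within, p=None) by a textbook two-pass computation.

    p is left to the caller (requires the F distribution); only the statistic
    and degrees of freedom are derived here.
    """
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / N
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        gm = sum(g) / len(g)
        ssb += len(g) * (gm - grand) ** 2
        for v in g:
            ssw += (v - gm) ** 2
    df_b = k - 1
    df_w = N - k
    if ssw == 0.0:
        F = math.inf if ssb > 0 else 0.0
    else:
        F = (ssb / df_b) / (ssw / df_w)
    return F, df_b, df_w
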