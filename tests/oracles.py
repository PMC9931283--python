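"""Independent direct-definition reference implementations used as test oracles.

Everything here is written from the feature/statistic definitions using plain
Python loops and math.fsum, deliberately avoiding the vectorized code paths of
the package under test.
"""

from __future__ import annotations

import math


def mean(v):
    return math.fsum(v) / len(v)


def sample_sd(v):
    m = mean(v)
    return math.sqrt(math.fsum((x - m) ** 2 for x in v) / (len(v) - 1))


def pop_sd(v):
    m = mean(v)
    return math.sqrt(math.fsum((x - m) ** 2 for x in v) / len(v))


def quantile(v, q):
    s = sorted(v)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (s[hi] - s[lo]) * (h - lo)


def pearson(a, b):
    if max(a) == min(a) or max(b) == min(b):
        return 0.0
    ma, mb = mean(a), mean(b)
    va = math.fsum((x - ma) ** 2 for x in a)
    vb = math.fsum((y - mb) ** 2 for y in b)
    if va == 0.0 or vb == 0.0:
        return 0.0
    cov = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    return cov / math.sqrt(va * vb)


def crossings(v, level):
    count = 0
    for i in range(len(v) - 1):
        if (v[i] - level) * (v[i + 1] - level) < 0:
            count += 1
    return count


def feature_oracle(samples, duration_s=30.0):
    """All 76 features of one (n, 3) epoch, by direct definition."""
    xs = [float(s[0]) for s in samples]
    ys = [float(s[1]) for s in samples]
    zs = [float(s[2]) for s in samples]
    rs = [math.sqrt(x * x + y * y + z * z) for x, y, z in zip(xs, ys, zs)]
    out = {}

    out["ENMOtrunc"] = mean([max(r - 1.0, 0.0) for r in rs])
    out["ENMOabs"] = mean([abs(r - 1.0) for r in rs])

    series = {"": rs, "x": xs, "y": ys, "z": zs}
    for p, s in series.items():
        m = mean(s)
        sd = sample_sd(s)
        out[f"{p}Mean"] = m
        out[f"{p}Sd"] = sd
        out[f"{p}Min"] = min(s)
        out[f"{p}Max"] = max(s)
        out[f"{p}25thp"] = quantile(s, 0.25)
        out[f"{p}Median"] = quantile(s, 0.5)
        out[f"{p}75thp"] = quantile(s, 0.75)
        out[f"{p}coefvariation"] = sd / m if (sd > 0.0 and m != 0.0) else 0.0
        out[f"{p}RMS"] = math.sqrt(mean([v * v for v in s]))
        out[f"{p}MCR"] = crossings(s, m) / duration_s
        hi = 0.5 * (m + max(s))
        lo = 0.5 * (m + min(s))
        out[f"{p}MMCR"] = 0.5 * (crossings(s, hi) / duration_s + crossings(s, lo) / duration_s)
        out[f"{p}autocorr"] = pearson(s[:-1], s[1:])
        if p == "":
            dev = [v - m for v in s]
            m2 = mean([d * d for d in dev])
            out["MAD"] = mean([abs(d) for d in dev])
            out["MPD"] = math.sqrt(m2)
            out["skew"] = mean([d**3 for d in dev]) / m2**1.5 if m2 > 0 else 0.0
            out["kurt"] = mean([d**4 for d in dev]) / m2**2 - 3.0 if m2 > 0 else 0.0
            out["TAC"] = math.fsum(max(v - 1.0, 0.0) for v in s)
        else:
            out[f"{p}Range"] = max(s) - min(s)
            out[f"{p}TAC"] = math.fsum(abs(v - m) for v in s)

    for pair in ("xy", "xz", "yz"):
        a, b = series[pair[0]], series[pair[1]]
        ma, mb = mean(a), mean(b)
        out[f"Cov{pair}"] = mean([(u - ma) * (v - mb) for u, v in zip(a, b)])
        out[f"corr{pair}"] = pearson(a, b)

    mx, my, mz = mean(xs), mean(ys), mean(zs)
    if mx == my == mz == 0.0:
        for angle in ("pitch", "roll", "yaw"):
            out[f"{angle}g"] = out[f"avg{angle}"] = out[f"sd{angle}"] = 0.0
        return out

    def pitch(x, y, z):
        return math.degrees(math.atan2(x, math.sqrt(y * y + z * z)))

    def roll(x, y, z):
        return math.degrees(math.atan2(y, math.sqrt(x * x + z * z)))

    def yaw(x, y, z):
        return math.degrees(math.atan2(z, math.sqrt(x * x + y * y)))

    for name, fn in (("pitch", pitch), ("roll", roll), ("yaw", yaw)):
        per = [fn(x, y, z) for x, y, z in zip(xs, ys, zs)]
        out[f"{name}g"] = fn(mx, my, mz)
        out[f"avg{name}"] = mean(per)
        out[f"sd{name}"] = sample_sd(per)
    return out


def concordance_oracle(times, events, scores):
    """All-pairs enumeration of Harrell's C by its definition."""
    num = 0.0
    den = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def walking_runs_oracle(walking_flags):
    """Brute-force scan over all indices for maximal walking runs."""
    runs = []
    n = len(walking_flags)
    i = 0
    while i < n:
        if walking_flags[i]:
            start = i
            while i < n and walking_flags[i]:
                i += 1
            runs.append((start, i - start))
        else:
            i += 1
    return runs


def breslow_loglik(beta, x, times, events):
    """Cox partial log-likelihood at scalar beta (Breslow tie handling)."""
    ll = 0.0
    n = len(times)
    for i in range(n):
        if events[i]:
            risk = math.fsum(math.exp(x[j] * beta) for j in range(n) if times[j] >= times[i])
            ll += x[i] * beta - math.log(risk)
    return ll


def grid_argmax_beta(x, times, events, lo=-5.0, hi=5.0):
    """Two-stage grid search maximizer of the partial likelihood (1 covariate)."""
    coarse = [lo + k * 0.01 for k in range(int((hi - lo) / 0.01) + 1)]
    best = max(coarse, key=lambda b: breslow_loglik(b, x, times, events))
    fine = [best - 0.02 + k * 1e-5 for k in range(4001)]
    return max(fine, key=lambda b: breslow_loglik(b, x, times, events))
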