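"""Independent elementwise-loop implementations of the 23 segment features.

Deliberately written as plain Python loops over samples, sharing no code
with the package, so they can serve as an oracle for the vectorised
implementations.
"""

import math


def oracle_features(y, fs, mo_order=3):
    y = [float(v) for v in y]
    n = len(y)
    dt = 1.0 / fs
    out = {}

    # temporal
    m = sum(y) / n
    out["M"] = m
    out["SD"] = math.sqrt(sum((v - m) ** 2 for v in y) / (n - 1))
    out["MA"] = max(y)
    out["MI"] = min(y)
    out["DR"] = out["MA"] - out["MI"]
    d1 = []
    for k in range(n):
        if k == 0:
            d1.append((y[1] - y[0]) * fs)
        elif k == n - 1:
            d1.append((y[-1] - y[-2]) * fs)
        else:
            d1.append((y[k + 1] - y[k - 1]) * fs / 2.0)
    d2 = [(y[k + 2] - 2 * y[k + 1] + y[k]) * fs * fs for k in range(n - 2)]
    m1 = sum(d1) / len(d1)
    m2_ = sum(d2) / len(d2)
    out["D1"] = max(abs(v) for v in d1)
    out["D2"] = max(abs(v) for v in d2)
    out["D1M"] = m1
    out["D2M"] = m2_
    out["D1SD"] = math.sqrt(sum((v - m1) ** 2 for v in d1) / (len(d1) - 1))
    out["D2SD"] = math.sqrt(sum((v - m2_) ** 2 for v in d2) / (len(d2) - 1))

    # morphological
    out["AL"] = sum(
        math.sqrt(dt * dt + (y[k + 1] - y[k]) ** 2) for k in range(n - 1)
    )
    out["IN"] = sum(
        0.5 * (abs(y[k]) + abs(y[k + 1])) * dt for k in range(n - 1)
    )
    ap = sum(v * v for v in y) / n
    out["AP"] = ap
    out["RMS"] = math.sqrt(ap)
    out["IL"] = out["AL"] / out["IN"] if out["IN"] != 0 else float("nan")
    energy = sum(v * v for v in y) * dt
    out["EL"] = energy / out["AL"] if out["AL"] != 0 else float("nan")

    # statistical
    mu2 = sum((v - m) ** 2 for v in y) / n
    mu3 = sum((v - m) ** 3 for v in y) / n
    mu4 = sum((v - m) ** 4 for v in y) / n
    if mu2 == 0:
        out["SK"] = float("nan")
        out["KU"] = float("nan")
        out["MO"] = 0.0
    else:
        out["SK"] = mu3 / mu2**1.5
        out["KU"] = mu4 / mu2**2
        out["MO"] = sum((v - m) ** mo_order for v in y) / n

    # frequency: plain DFT periodogram of the demeaned series, one-sided
    z = [v - m for v in y]
    df = fs / n
    nfreq = n // 2 + 1
    power = []
    for j in range(nfreq):
        re = sum(z[k] * math.cos(2 * math.pi * j * k / n) for k in range(n))
        im = -sum(z[k] * math.sin(2 * math.pi * j * k / n) for k in range(n))
        p = (re * re + im * im) / (n * fs)
        if 0 < j and not (n % 2 == 0 and j == nfreq - 1):
            p *= 2.0  # one-sided doubling except DC and Nyquist
        power.append(p)
    for name, lo, hi in (("F1", 0.1, 0.2), ("F2", 0.2, 0.3), ("F3", 0.3, 0.4)):
        s = 0.0
        for j in range(nfreq):
            f = j * df
            if lo <= f < hi:
                s += power[j] * df
        out[name] = s
    return out
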