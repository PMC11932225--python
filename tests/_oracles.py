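"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as naive loops over plain Python
floats, sharing no code path with the package implementation, so that
agreement between the two is evidence of correctness rather than of shared
bugs.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# Waveform feature oracles
# ---------------------------------------------------------------------------


def naive_peaks(x, prominence):
    """Left-edge indices of local maxima with at least the given prominence
    (prominence bases extend to the first strictly higher sample or the
    signal border, matching the standard topographic definition)."""
    n = len(x)
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                v = x[i]
                m_left = v
                k = i - 1
                while k >= 0 and x[k] <= v:
                    m_left = min(m_left, x[k])
                    k -= 1
                m_right = v
                k = j + 1
                while k < n and x[k] <= v:
                    m_right = min(m_right, x[k])
                    k += 1
                if v - max(m_left, m_right) >= prominence:
                    peaks.append(i)
            i = j + 1
        else:
            i += 1
    return peaks


def _naive_line(ids, ys):
    n = len(ids)
    sx = sum(ids)
    sy = sum(ys)
    sxx = sum(i * i for i in ids)
    sxy = sum(i * y for i, y in zip(ids, ys))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    return slope, intercept


def naive_contact_time(x, i_min, p0, p1, dt):
    """Sub-sample contact time: intersection of straight-line fits to the
    two flanks of sqrt(distance) around the minimum sample."""
    left = [i for i in (i_min - 3, i_min - 2, i_min - 1) if i > p0]
    right = [i for i in (i_min + 1, i_min + 2, i_min + 3) if i < p1]
    if len(left) >= 2 and len(right) >= 2:
        bl, al = _naive_line(left, [math.sqrt(max(x[i], 0.0)) for i in left])
        br, ar = _naive_line(right, [math.sqrt(max(x[i], 0.0)) for i in right])
        if bl < -1e-9 and br > 1e-9:
            pos = (ar - al) / (bl - br)
            if abs(pos - i_min) <= 2.0:
                pos = min(max(pos, p0 + 0.5), p1 - 0.5)
                return pos * dt
    return i_min * dt


def naive_taps(x, rate, prominence):
    """(contact_time, contact_value, peak_time_pre, peak_val_pre,
    peak_time_post, peak_val_post) tuples, one per tap event."""
    dt = 1.0 / rate
    peaks = naive_peaks(x, prominence)
    events = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        if b - a < 2:
            continue
        i_min = a + 1
        for k in range(a + 1, b):
            if x[k] < x[i_min]:
                i_min = k
        t = naive_contact_time(x, i_min, a, b, dt)
        events.append((t, x[i_min], a * dt, x[a], b * dt, x[b]))
    return events


def naive_total_distance(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def naive_mean(v):
    return sum(v) / len(v)


def naive_sd(v):
    m = naive_mean(v)
    return math.sqrt(sum((a - m) ** 2 for a in v) / (len(v) - 1))


def naive_ols_slope(t, v):
    tm = naive_mean(t)
    vm = naive_mean(v)
    num = sum((a - tm) * (b - vm) for a, b in zip(t, v))
    den = sum((a - tm) ** 2 for a in t)
    return num / den


def naive_local_max_stats(events):
    seen = {}
    for (_, _, tp, vp, tf, vf) in events:
        seen[tp] = vp
        seen[tf] = vf
    times = sorted(seen)
    values = [seen[t] for t in times]
    if len(values) < 2:
        return (math.nan, math.nan, math.nan)
    return naive_mean(values), naive_sd(values), naive_ols_slope(times, values)


def naive_interval_stats(events):
    n = len(events)
    if n < 2:
        return (float(n), math.nan, math.nan, math.nan)
    contacts = [e[0] for e in events]
    gaps = [b - a for a, b in zip(contacts[:-1], contacts[1:])]
    ave = naive_mean(gaps)
    return (float(n), ave, 1.0 / ave, naive_sd(gaps))


def naive_wrap(angle):
    while angle <= -180.0:
        angle += 360.0
    while angle > 180.0:
        angle -= 360.0
    return angle


def naive_circular_sd_deg(devs):
    c = naive_mean([math.cos(math.radians(d)) for d in devs])
    s = naive_mean([math.sin(math.radians(d)) for d in devs])
    rbar = math.hypot(c, s)
    if rbar <= 1e-12:
        return math.nan
    return math.degrees(math.sqrt(-2.0 * math.log(rbar)))


def naive_phase_sd(left_events, right_events, anti_phase):
    if len(left_events) < 3 or len(right_events) < 3:
        return math.nan
    lefts = [e[0] for e in left_events]
    rights = [e[0] for e in right_events]
    target_deg = 180.0 if anti_phase else 0.0
    devs = []
    for k in range(len(rights) - 1):
        c = rights[k + 1] - rights[k]
        if c <= 0:
            continue
        target_t = rights[k] + (c / 2.0 if anti_phase else 0.0)
        best = min(lefts, key=lambda t: abs(t - target_t))
        if abs(best - target_t) > c:
            continue
        devs.append(naive_wrap(360.0 * (best - rights[k]) / c - target_deg))
    if not devs:
        return math.nan
    return naive_circular_sd_deg(devs)


def naive_features(trial, prominence=4.0):
    """All nine parameters of a trial via the naive loops; returns a dict
    keyed like the package's long-format parameter names plus hand."""
    out = {}
    events = {}
    for hand in ("left", "right"):
        x = [float(v) for v in (trial.left if hand == "left" else trial.right)]
        ev = naive_taps(x, trial.sampling_rate, prominence)
        events[hand] = ev
        n, ave_iti, freq, sd_iti = naive_interval_stats(ev)
        ave_pk, sd_pk, slope = naive_local_max_stats(ev)
        out[hand] = {
            "total_traveling_distance": naive_total_distance(x),
            "ave_local_max_distance": ave_pk,
            "sd_local_max_distance": sd_pk,
            "slope_local_max": slope,
            "number_of_taps": n,
            "ave_tapping_interval": ave_iti,
            "frequency_of_taps": freq,
            "sd_inter_tapping_interval": sd_iti,
        }
    out["sd_phase_difference"] = naive_phase_sd(
        events["left"], events["right"], trial.task.value == "anti_phase"
    )
    return out


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------


def naive_chi_square(table):
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sum = [sum(r) for r in table]
    col_sum = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sum[i] * col_sum[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat, (rows - 1) * (cols - 1)


def naive_auc(predictor, states):
    pos = [x for x, s in zip(predictor, states) if s == 1]
    neg = [x for x, s in zip(predictor, states) if s == 0]
    score = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                score += 1.0
            elif p == q:
                score += 0.5
    return score / (len(pos) * len(neg))


def naive_youden(predictor, states):
    distinct = sorted(set(predictor))
    pos = sum(1 for s in states if s == 1)
    neg = len(states) - pos
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        thr = (a + b) / 2.0
        tp = sum(1 for x, s in zip(predictor, states) if s == 1 and x >= thr)
        tn = sum(1 for x, s in zip(predictor, states) if s == 0 and x < thr)
        sn = tp / pos
        sp = tn / neg
        yi = sn + sp - 1.0
        if best is None or yi > best[3] + 1e-12:
            best = (thr, sn, sp, yi)
    return best


def naive_pearson_r(x, y):
    xm = naive_mean(x)
    ym = naive_mean(y)
    num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - xm) ** 2 for a in x) * sum((b - ym) ** 2 for b in y)
    )
    return num / den
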