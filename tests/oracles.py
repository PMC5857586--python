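"""Independent brute-force oracles used by the test suite.

Everything here is written as naive, loop-based reference code — no shared
helpers with the package — so that agreement between the two routes is
meaningful. The fixation oracle implements the published two-parameter
windowed-velocity filter rule directly from its description; the pupil oracle
applies the four cleaning steps one sample at a time; the stats oracle
evaluates textbook closed forms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Fixation filter


def naive_velocities(x, y, valid, window):
    """Two-mean windowed velocity by explicit loops; NaN where undefined."""
    n = len(x)
    out = [math.nan] * n
    for i in range(n):
        if i < window or i + window > n:
            continue
        idx = list(range(i - window, i + window))
        if not all(valid[j] and math.isfinite(x[j]) and math.isfinite(y[j]) for j in idx):
            continue
        bx = sum(x[j] for j in range(i - window, i)) / window
        by = sum(y[j] for j in range(i - window, i)) / window
        ax = sum(x[j] for j in range(i, i + window)) / window
        ay = sum(y[j] for j in range(i, i + window)) / window
        out[i] = math.hypot(ax - bx, ay - by)
    return out


def naive_fixations(t, x, y, valid, velocity_threshold=35.0, distance_threshold=35.0,
                    window=5, min_duration=1):
    """Reference fixation detection.

    Valid-gaze runs are segmented at the (first) velocity maximum of each
    maximal super-threshold velocity run; segments become candidates whose
    centroid is the mean member position; consecutive candidates merge when
    their centroids are closer than the distance threshold and any invalid
    gap between them is shorter than the window; candidates shorter than
    min_duration are dropped. Returns (onset_t, offset_t, cx, cy, n) tuples.
    """
    n = len(t)
    ok = [bool(valid[i]) and math.isfinite(x[i]) and math.isfinite(y[i]) for i in range(n)]
    v = naive_velocities(x, y, ok, window)

    # Maximal runs of valid samples.
    segments = []
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            segments.append((i, j))
            i = j + 1
        else:
            i += 1

    candidates = []  # list of lists of member indices
    for a, b in segments:
        cuts = []
        i = a
        while i <= b:
            if math.isfinite(v[i]) and v[i] >= velocity_threshold:
                j = i
                while j + 1 <= b and math.isfinite(v[j + 1]) and v[j + 1] >= velocity_threshold:
                    j += 1
                vmax = max(v[k] for k in range(i, j + 1))
                best = i
                # first sample within tolerance of the run maximum
                for k in range(i, j + 1):
                    if v[k] >= vmax - 1e-6:
                        best = k
                        break
                cuts.append(best)
                i = j + 1
            else:
                i += 1
        start = a
        for k in cuts:
            if k >= start:
                candidates.append(list(range(start, k + 1)))
            start = k + 1
        if start <= b:
            candidates.append(list(range(start, b + 1)))

    def centroid(members):
        return (
            sum(x[i] for i in members) / len(members),
            sum(y[i] for i in members) / len(members),
        )

    merged = []
    current = candidates[0] if candidates else None
    for nxt in candidates[1:]:
        gap = nxt[0] - current[-1] - 1
        cx, cy = centroid(current)
        nx, ny = centroid(nxt)
        if gap < window and math.hypot(cx - nx, cy - ny) < distance_threshold:
            current = current + nxt
        else:
            merged.append(current)
            current = nxt
    if current is not None:
        merged.append(current)

    out = []
    for members in merged:
        if len(members) < min_duration:
            continue
        cx, cy = centroid(members)
        out.append((t[members[0]], t[members[-1]], cx, cy, len(members)))
    return out


def random_trace(rng, n_max=200):
    """Randomized gaze trace mixing steady clusters, saccades and invalid runs."""
    n = int(rng.integers(20, n_max + 1))
    x = np.empty(n)
    y = np.empty(n)
    valid = np.ones(n, bool)
    cx, cy = rng.uniform(100, 1800), rng.uniform(100, 900)
    i = 0
    while i < n:
        kind = rng.random()
        length = int(rng.integers(1, 40))
        j = min(n, i + length)
        if kind < 0.6:  # steady cluster with jitter
            x[i:j] = cx + rng.normal(0, rng.uniform(0.5, 8.0), j - i)
            y[i:j] = cy + rng.normal(0, rng.uniform(0.5, 8.0), j - i)
        elif kind < 0.8:  # saccade to a new location
            nx_, ny_ = rng.uniform(0, 1920), rng.uniform(0, 1080)
            frac = np.linspace(0, 1, j - i + 2)[1:-1]
            x[i:j] = cx + frac * (nx_ - cx)
            y[i:j] = cy + frac * (ny_ - cy)
            cx, cy = nx_, ny_
        else:  # invalid run
            x[i:j] = np.nan
            y[i:j] = np.nan
            valid[i:j] = False
        i = j
    t = np.arange(n) / 60.0
    return t, x, y, valid


# ---------------------------------------------------------------------------
# Pupil cleaning


def naive_clean(values, lo=2.5, hi=5.5, max_step=1.0, max_gap=10, ma_window=10):
    """The four cleaning steps applied one sample at a time."""
    n = len(values)
    x = [float(v) for v in values]
    # Step 1: range filter (bounds retained).
    for i in range(n):
        if not math.isnan(x[i]) and (x[i] < lo or x[i] > hi):
            x[i] = math.nan
    # Step 2: step filter against the last retained value.
    last = math.nan
    for i in range(n):
        if math.isnan(x[i]):
            continue
        if not math.isnan(last) and abs(x[i] - last) > max_step:
            x[i] = math.nan
        else:
            last = x[i]
    # Step 3: interpolate interior gaps shorter than max_gap.
    i = 0
    while i < n:
        if math.isnan(x[i]):
            j = i
            while j + 1 < n and math.isnan(x[j + 1]):
                j += 1
            length = j - i + 1
            if i > 0 and j < n - 1 and length < max_gap:
                left, right = x[i - 1], x[j + 1]
                for k in range(i, j + 1):
                    frac = (k - i + 1) / (length + 1)
                    x[k] = left + frac * (right - left)
            i = j + 1
        else:
            i += 1
    # Step 4: moving average [i-5, i+4] truncated at edges and gaps.
    before = ma_window // 2
    after = ma_window - 1 - before
    out = [math.nan] * n
    for i in range(n):
        if math.isnan(x[i]):
            continue
        a = i
        while a > max(0, i - before) and not math.isnan(x[a - 1]):
            a -= 1
        b = i
        while b < min(n - 1, i + after) and not math.isnan(x[b + 1]):
            b += 1
        window_vals = x[a : b + 1]
        out[i] = sum(window_vals) / len(window_vals)
    return out


# ---------------------------------------------------------------------------
# Closed-form statistics


def closed_form_one_sample_t(values, mu=0.0):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    t = (mean - mu) / math.sqrt(var / n)
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, n - 1, p


def closed_form_two_sample_t(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def closed_form_pearson(x, y):
    pairs = [(a, b) for a, b in zip(x, y) if math.isfinite(a) and math.isfinite(b)]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, n, p


def closed_form_skewness(values):
    """Adjusted Fisher–Pearson standardized third moment."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    g1 = m3 / m2 ** 1.5
    return g1 * math.sqrt(n * (n - 1)) / (n - 2)
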