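"""Independent oracles used to cross-check the package implementation.

These deliberately share no code with :mod:`actcomp`: the non-wear oracles
enumerate candidate windows directly from the rule's definition — a window of
>= 90 sub-100-cpm minutes, at most 2 nonzero (1-99 cpm) minutes in total,
every maximal nonzero stretch flanked by >= 30 consecutive zero minutes on
both sides *within the window*.  Every minute covered by some qualifying
window is non-wear.
"""

from __future__ import annotations

import numpy as np


def _window_ok(counts, a: int, b: int, flank: int) -> bool:
    """Flanking-zeros check for window [a, b) (assumes all counts < 100)."""
    i = a
    while i < b:
        if counts[i] > 0:
            j = i
            while j < b and counts[j] > 0:
                j += 1
            zl = 0
            k = i - 1
            while k >= a and counts[k] == 0:
                zl += 1
                k -= 1
            zr = 0
            k = j
            while k < b and counts[k] == 0:
                zr += 1
                k += 1
            if zl < flank or zr < flank:
                return False
            i = j
        else:
            i += 1
    return True


def brute_force_nonwear_cubic(
    counts, window: int = 90, tolerance: int = 2, flank: int = 30
) -> np.ndarray:
    """Every-window enumeration with a from-scratch check per window (slow)."""
    counts = np.asarray(counts)
    n = counts.size
    nonwear = np.zeros(n, dtype=bool)
    for a in range(n):
        if counts[a] >= 100:
            continue
        nz = 0
        for b in range(a + 1, n + 1):
            c = counts[b - 1]
            if c >= 100:
                break
            if c > 0:
                nz += 1
                if nz > tolerance:
                    break
            if b - a >= window and _window_ok(counts, a, b, flank):
                nonwear[a:b] = True
    return nonwear


def brute_force_nonwear_scan(
    counts, window: int = 90, tolerance: int = 2, flank: int = 30
) -> np.ndarray:
    """Same enumeration with an incremental per-start state (O(n^2) total).

    For each window start ``a``, extend the end one minute at a time and
    maintain: the running nonzero-minute total, whether any interruption has
    been *frozen* with an insufficient flank (insufficient left flank at
    group start, or a new group starting before the previous group accrued
    ``flank`` trailing zeros), and the zeros accumulated since the last
    interruption.  The window qualifies when long enough, not frozen-bad, and
    the trailing interruption (if any) already has its right flank.
    """
    counts = np.asarray(counts)
    n = counts.size
    nonwear = np.zeros(n, dtype=bool)
    for a in range(n):
        if counts[a] >= 100:
            continue
        nz = 0
        bad = False
        in_group = False
        have_group = False
        zeros_since = 0  # zeros since window start or since last group ended
        longest_ok = -1
        for b in range(a + 1, n + 1):
            c = counts[b - 1]
            if c >= 100:
                break
            if c > 0:
                nz += 1
                if nz > tolerance:
                    break
                if not in_group:
                    if zeros_since < flank:
                        bad = True  # left flank (or previous right flank) too short
                    in_group = True
                    have_group = True
                    zeros_since = 0
            else:
                in_group = False
                zeros_since += 1
            if b - a >= window and not bad:
                if not have_group or (not in_group and zeros_since >= flank):
                    longest_ok = b
        if longest_ok > 0:
            nonwear[a:longest_ok] = True
    return nonwear


def random_block_series(rng: np.random.Generator, max_len: int = 200) -> np.ndarray:
    """Block-structured random cpm series over {0, 50, 150}.

    Blocks of a constant value with geometric-ish lengths make long zero runs
    (and hence candidate bouts, tolerated interruptions and edge cases)
    common, unlike iid sampling.
    """
    n = int(rng.integers(30, max_len + 1))
    out = np.empty(n, dtype=np.int64)
    pos = 0
    while pos < n:
        value = rng.choice([0, 50, 150], p=[0.6, 0.2, 0.2])
        length = int(rng.integers(1, 61))
        end = min(n, pos + length)
        out[pos:end] = value
        pos = end
    return out


def recount_exposure(counts, worn, tod, day_ord, date_ord: int, w_start: int, w_end: int,
                     sed_max: int = 180, light_max: int = 3360):
    """Plain per-minute recount of one window's category minutes."""
    st = lpa = mvpa = wear = 0
    for i in range(len(counts)):
        if day_ord[i] != date_ord or not worn[i]:
            continue
        if not (w_start <= tod[i] < w_end):
            continue
        wear += 1
        c = counts[i]
        if c <= sed_max:
            st += 1
        elif c <= light_max:
            lpa += 1
        else:
            mvpa += 1
    return wear, st, lpa, mvpa
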