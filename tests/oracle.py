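"""Independent straight-line re-implementation of the five-class decision rules.

Deliberately naive (per-transcript loops, no vectorisation, no shared code
with the package) so it can serve as an oracle for the classifier.
"""

from __future__ import annotations

import math


def naive_classify_one(
    p_row,
    rips,
    lips,
    fc_max,
    emp_p,
    fc_cutoff: float = 1.0,
    emp_p_cutoff: float = 0.05,
) -> str:
    """Class label for one transcript.

    p_row: per-tissue expression probabilities; rips/lips: per-tissue
    cutoffs; fc_max/emp_p: the candidate statistics (may be None when the
    decision does not need them).
    """
    n = len(p_row)
    k = 0
    for i in range(n):
        if p_row[i] >= rips[i]:
            k += 1
    kmax = math.floor(0.5 * n)
    if k == 0:
        all_below = True
        for i in range(n):
            if not (p_row[i] < lips[i]):
                all_below = False
        return "Null" if all_below else "Low"
    if k > kmax:
        return "Wide"
    if fc_max >= fc_cutoff and emp_p <= emp_p_cutoff:
        return "TSp" if k == 1 else "TEn"
    return "Low"
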