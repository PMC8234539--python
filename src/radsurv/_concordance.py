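"""Pairwise concordance machinery shared by screening and survstats.

Harrell's C is computed from an explicit enumeration of usable pairs:
a pair (i, j) is usable when the patient with the shorter observed time
had the event, or when the times are tied and exactly one of the two had
the event.  Score ties receive half credit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["concordance_index", "pair_row_stats"]


def _pair_masks(time: np.ndarray, event: np.ndarray):
    """Boolean matrices of usable pairs and their 'i should rank higher' roles.

    Returns (usable, i_first) where ``usable[i, j]`` marks an ordered pair
    with i the patient expected to have the higher risk score.
    """
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None].astype(bool)
    e_j = event[None, :].astype(bool)

    # i fails strictly earlier with an observed event
    earlier = (t_i < t_j) & e_i
    # tied times, exactly one event: the event case should score higher
    tied = (t_i == t_j) & e_i & ~e_j
    usable = earlier | tied
    np.fill_diagonal(usable, False)
    return usable


def concordance_index(score, time, event) -> float:
    """Harrell's concordance index via O(n^2) pair counting.

    ``score`` is oriented so that larger values mean higher hazard.
    Raises ``ValueError`` when there are no events or no usable pairs.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not (len(score) == len(time) == len(event)):
        raise ValueError("score, time and event must have equal length")
    if event.sum() < 1:
        raise ValueError("concordance undefined: no events")

    usable = _pair_masks(time, event)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("concordance undefined: no usable pairs")

    s_i = score[:, None]
    s_j = score[None, :]
    conc = (usable & (s_i > s_j)).sum()
    ties = (usable & (s_i == s_j)).sum()
    return (conc + 0.5 * ties) / n_usable


def pair_row_stats(score, time, event):
    """Per-patient credit/weight row sums for jackknifing C.

    Returns ``(credit_rows, weight_rows, credit_total, weight_total)`` where
    removing patient k from the sample removes ``credit_rows[k]`` credit and
    ``weight_rows[k]`` usable-pair weight (pairs are unordered; each touches
    two patients).
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)

    usable = _pair_masks(time, event)
    s_i = score[:, None]
    s_j = score[None, :]
    credit = usable * ((s_i > s_j) + 0.5 * (s_i == s_j))
    weight = usable.astype(float)

    credit_rows = credit.sum(axis=1) + credit.sum(axis=0)
    weight_rows = weight.sum(axis=1) + weight.sum(axis=0)
    return credit_rows, weight_rows, credit.sum(), weight.sum()
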