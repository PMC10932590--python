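"""Pairing of responses with their in-window event histories.

Both the synthetic generator and the deconvolutional model need, for every
response, the set of preceding events (same participant, delay >= 0) that
fall inside a history window bounded by a maximum event count and a maximum
age in seconds.  This module builds that pairing as flat index arrays
suitable for vectorized convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HistoryPairs", "build_history_pairs"]


class HistoryPairs:
    """Flat (response, event) pair arrays plus a CSR-style response pointer.

    pair_resp[k]  : response row of pair k (pairs sorted by response)
    pair_event[k] : event row of pair k
    delay[k]      : response time - event time, in seconds (>= 0)
    resp_ptr      : length n_responses + 1; pairs of response i occupy
                    slice resp_ptr[i]:resp_ptr[i+1]
    """

    def __init__(self, pair_resp, pair_event, delay, n_responses):
        self.pair_resp = pair_resp
        self.pair_event = pair_event
        self.delay = delay
        self.n_responses = n_responses
        counts = np.bincount(pair_resp, minlength=n_responses)
        self.resp_ptr = np.concatenate(([0], np.cumsum(counts)))

    def __len__(self):
        return len(self.pair_resp)

    def gather(self, resp_idx):
        """Pair rows for a subset of responses.

        Returns (rows, local): ``rows`` indexes into the pair arrays,
        ``local[k]`` gives the position within ``resp_idx`` that pair
        ``rows[k]`` belongs to.
        """
        starts = self.resp_ptr[resp_idx]
        lens = self.resp_ptr[resp_idx + 1] - starts
        total = int(lens.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        rows = np.repeat(starts, lens) + (
            np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        )
        local = np.repeat(np.arange(len(resp_idx)), lens)
        return rows, local


def build_history_pairs(
    event_participant,
    event_time,
    resp_participant,
    resp_time,
    max_events,
    max_seconds,
):
    """Pair every response with its in-window preceding events.

    Events with delay exactly 0 (the currently-read word) are included.
    Within each participant, event times must be sorted ascending; the
    function groups by participant internally, so rows may be blocked in
    any participant order.
    """
    event_participant = np.asarray(event_participant)
    event_time = np.asarray(event_time, float)
    resp_participant = np.asarray(resp_participant)
    resp_time = np.asarray(resp_time, float)
    if max_events <= 0 or max_seconds <= 0:
        raise ValueError("history window must be positive")

    pr, pe = [], []
    for part in np.unique(event_participant):
        ev_rows = np.flatnonzero(event_participant == part)
        rs_rows = np.flatnonzero(resp_participant == part)
        if len(rs_rows) == 0:
            continue
        t_ev = event_time[ev_rows]
        if np.any(np.diff(t_ev) < 0):
            raise ValueError("event times must be sorted within participant")
        t_rs = resp_time[rs_rows]
        hi = np.searchsorted(t_ev, t_rs, side="right")
        lo = np.searchsorted(t_ev, t_rs - max_seconds, side="left")
        lo = np.maximum(lo, hi - max_events)
        lens = hi - lo
        total = int(lens.sum())
        if total == 0:
            continue
        local_ev = np.repeat(lo, lens) + (
            np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        )
        pe.append(ev_rows[local_ev])
        pr.append(np.repeat(rs_rows, lens))
    if pr:
        pair_resp = np.concatenate(pr)
        pair_event = np.concatenate(pe)
        order = np.argsort(pair_resp, kind="stable")
        pair_resp = pair_resp[order]
        pair_event = pair_event[order]
    else:
        pair_resp = np.empty(0, dtype=np.int64)
        pair_event = np.empty(0, dtype=np.int64)
    delay = resp_time[pair_resp] - event_time[pair_event]
    return HistoryPairs(pair_resp, pair_event, delay, len(resp_time))
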