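"""Reading measures, response filtering, and data partitioning.

Fixation-duration measures are pure functions of a scan path (the
time-ordered sequence of fixations to word regions):

  * scan path duration - time from entering a word region (from either
    direction) until entering a different region; consecutive fixations on
    the same region merge into one visit;
  * first-pass duration - scan-path duration restricted to a region's
    first visit when it was entered from the left (a lower-indexed region,
    or the start of the record);
  * go-past duration - for a region first entered from the left, the time
    from that entry until first entering any higher-indexed region,
    including all intervening regressive fixation time.

Filters mirror the protocols used for published self-paced reading / Maze /
eye-tracking corpora (RT bounds, boundary exclusions, outlier saccades,
blink interruption, comprehension accuracy, per-participant minimum
counts); filtering applies to response vectors only, never to the event
(predictor) stream.  The train/validation/test partition cycles on
i = (sentence + participant) mod 4: train for i in {0, 1}, validation for
i = 2, test for i = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Fixation",
    "FilterConfig",
    "PartitionLabel",
    "scan_path_durations",
    "first_pass_durations",
    "go_past_durations",
    "apply_filters",
    "assign_partition",
    "assign_partitions",
]


@dataclass(frozen=True)
class Fixation:
    """A fixation on a word region: 0-based region index in text order,
    start and end times in seconds."""

    region_index: int
    start: float
    end: float

    def __post_init__(self):
        if self.region_index < 0:
            raise ValueError("region_index must be >= 0")
        if not self.end > self.start:
            raise ValueError("fixation end must exceed start")


def _validate_path(path):
    for prev, cur in zip(path, path[1:]):
        if cur.start < prev.end:
            raise ValueError("fixations must be time-ordered and non-overlapping")


def _visits(path):
    """Merge maximal runs of consecutive same-region fixations.

    Returns a list of (region, entry_time, next_entry_or_record_end,
    own_span_end) tuples.  Durations are entry-to-entry (saccade gaps are
    part of the visit they leave from); the final visit ends at its own
    last fixation's end.
    """
    _validate_path(path)
    runs = []
    for fx in path:
        if runs and runs[-1][0] == fx.region_index:
            runs[-1][2] = fx.end
        else:
            runs.append([fx.region_index, fx.start, fx.end])
    out = []
    for i, (region, entry, span_end) in enumerate(runs):
        exit_time = runs[i + 1][1] if i + 1 < len(runs) else span_end
        out.append((region, entry, exit_time))
    return out


def scan_path_durations(path):
    """One (region, duration_ms) per visit, regressive visits included."""
    return [
        (region, 1000.0 * (exit_time - entry))
        for region, entry, exit_time in _visits(path)
    ]


def _first_pass_visits(path):
    """Indices of visits that are first inspections entered from the left."""
    visits = _visits(path)
    seen = set()
    keep = []
    for i, (region, _, _) in enumerate(visits):
        from_left = i == 0 or visits[i - 1][0] < region
        if region not in seen and from_left:
            keep.append(i)
        seen.add(region)
    return visits, keep


def first_pass_durations(path):
    """Scan-path durations restricted to first visits entered from the left
    (record-initial entries count as leftward)."""
    visits, keep = _first_pass_visits(path)
    return [
        (visits[i][0], 1000.0 * (visits[i][2] - visits[i][1])) for i in keep
    ]


def go_past_durations(path, return_unresolved=False):
    """Go-past duration per region first entered from the left: time from
    that entry until first entry of any higher-indexed region, including
    all regressive fixation time.  Regions whose record ends before a
    rightward exit are excluded and reported as unresolved."""
    visits, keep = _first_pass_visits(path)
    out, unresolved = [], []
    for i in keep:
        region, entry, _ = visits[i]
        exit_time = None
        for j in range(i + 1, len(visits)):
            if visits[j][0] > region:
                exit_time = visits[j][1]
                break
        if exit_time is None:
            unresolved.append(region)
        else:
            out.append((region, 1000.0 * (exit_time - entry)))
    if return_unresolved:
        return out, unresolved
    return out


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion protocol.  None disables a rule.

    Defaults replicate common self-paced-reading bounds; eye-tracking
    protocols add saccade/blink/boundary rules through the metadata flags.
    """

    rt_min: float | None = 100.0  # ms
    rt_max: float | None = 3000.0  # ms
    max_saccade_len: int | None = None  # words
    exclude_sentence_boundary: bool = False
    exclude_screen_boundary: bool = False
    exclude_line_boundary: bool = False
    exclude_blinks: bool = False
    min_accuracy: float | None = None  # per-participant comprehension
    correct_only: bool = False
    min_rts_per_participant: int | None = None

    def __post_init__(self):
        if self.rt_min is not None and self.rt_max is not None:
            if not self.rt_min < self.rt_max:
                raise ValueError("rt_min must be below rt_max")
        if self.max_saccade_len is not None and self.max_saccade_len <= 0:
            raise ValueError("max_saccade_len must be positive")


_META_COLS = {
    "blink": "blink_flag",
    "saccade": "saccade_len",
    "sentence_boundary": "sentence_boundary",
    "screen_boundary": "screen_boundary",
    "line_boundary": "line_boundary",
    "accuracy": "accuracy",
    "correct": "correct",
}


def apply_filters(responses: pd.DataFrame, cfg: FilterConfig, metadata=None):
    """Apply the exclusion protocol to a response table.

    Rules fire in a fixed documented order - track quality (blink,
    outlier saccade), boundary adjacency, RT bounds, accuracy/correctness,
    per-participant minimum count - and each excluded response is
    attributed to the first matching rule.  Participant-level minima are
    evaluated on the counts remaining after the item-level rules.  Returns
    (kept responses, exclusion log with per-rule counts).  Only responses
    are filtered; event/predictor streams are never touched.
    """
    df = responses
    meta = metadata if metadata is not None else pd.DataFrame(index=df.index)

    def need(col, rule):
        if col in df.columns:
            return df[col]
        if col in meta.columns:
            return meta.loc[df.index, col]
        raise ValueError(f"rule {rule!r} requires missing metadata column {col!r}")

    excluded_by = pd.Series("", index=df.index, dtype=object)

    def mark(mask, rule):
        mask = mask & (excluded_by == "")
        excluded_by[mask] = rule

    if cfg.exclude_blinks:
        mark(need(_META_COLS["blink"], "blink").astype(bool), "blink")
    if cfg.max_saccade_len is not None:
        sac = need(_META_COLS["saccade"], "outlier_saccade").abs()
        mark(sac > cfg.max_saccade_len, "outlier_saccade")
    for flag, rule in (
        ("exclude_sentence_boundary", "sentence_boundary"),
        ("exclude_screen_boundary", "screen_boundary"),
        ("exclude_line_boundary", "line_boundary"),
    ):
        if getattr(cfg, flag):
            mark(need(_META_COLS[rule], rule).astype(bool), rule)
    if cfg.rt_min is not None:
        mark(df["duration_ms"] < cfg.rt_min, "rt_too_short")
    if cfg.rt_max is not None:
        mark(df["duration_ms"] > cfg.rt_max, "rt_too_long")
    if cfg.min_accuracy is not None:
        acc = need(_META_COLS["accuracy"], "low_accuracy")
        mark(acc < cfg.min_accuracy, "low_accuracy")
    if cfg.correct_only:
        mark(~need(_META_COLS["correct"], "incorrect_response").astype(bool), "incorrect_response")
    if cfg.min_rts_per_participant is not None:
        alive = excluded_by == ""
        counts = df.loc[alive, "participant_id"].value_counts()
        low = counts[counts < cfg.min_rts_per_participant].index
        mark(df["participant_id"].isin(low) & alive, "too_few_rts")

    kept = df[excluded_by == ""]
    log = {
        "order": [
            "blink", "outlier_saccade", "sentence_boundary", "screen_boundary",
            "line_boundary", "rt_too_short", "rt_too_long", "low_accuracy",
            "incorrect_response", "too_few_rts",
        ],
        "counts": excluded_by[excluded_by != ""].value_counts().to_dict(),
        "n_in": len(df),
        "n_kept": len(kept),
    }
    return kept, log


# ---------------------------------------------------------------------------
# partitioning


@dataclass(frozen=True)
class PartitionLabel:
    value: str  # train | validation | test
    split_index: int
    participant: int
    sentence: int


_SPLIT_OF_I = {0: "train", 1: "train", 2: "validation", 3: "test"}


def assign_partition(p: int, s: int) -> PartitionLabel:
    """Cycle datapoints into splits by i = (s + p) mod 4: train for
    i in {0, 1}, validation for i = 2, test for i = 3."""
    if p < 0 or s < 0:
        raise ValueError("participant and sentence indices must be >= 0")
    i = (s + p) % 4
    return PartitionLabel(_SPLIT_OF_I[i], i, p, s)


def assign_partitions(df: pd.DataFrame, participant_col="participant_id", sentence_col="sentence_index"):
    """Vectorized split column for a response/event table.

    Participant ids are ranked into 0..P-1 in first-appearance order;
    sentence indices are used as given.
    """
    codes, _ = pd.factorize(df[participant_col])
    s = df[sentence_col].to_numpy()
    if (s < 0).any():
        raise ValueError("sentence indices must be >= 0")
    i = (s + codes) % 4
    out = df.copy()
    out["split"] = np.array(["train", "train", "validation", "test"])[i]
    return out


def split_dataset(events: pd.DataFrame, responses: pd.DataFrame):
    """Partition responses by (sentence + participant) mod 4 and return
    {split: Dataset}.  The full event stream is retained for every split
    (predictor histories are never filtered)."""
    from .model import Dataset

    labeled = assign_partitions(responses)
    return {
        name: Dataset(events, labeled[labeled["split"] == name].drop(columns="split"))
        for name in ("train", "validation", "test")
    }
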