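"""Plain-text (TSV/YAML-free) table input/output.

Events and responses travel as TSV with fixed column sets so that
synthetic and real corpora share one on-disk format.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["write_events", "read_events", "write_responses", "read_responses"]

EVENT_KEYS = ["participant_id", "text_id", "sentence_index", "token_position", "time_s"]
RESPONSE_KEYS = EVENT_KEYS + ["duration_ms", "measure_name"]


def write_events(events: pd.DataFrame, path):
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_KEYS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    return df


def write_responses(responses: pd.DataFrame, path):
    responses.to_csv(path, sep="\t", index=False)


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESPONSE_KEYS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns {missing}")
    return df
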