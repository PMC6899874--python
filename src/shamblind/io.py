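"""Validated CSV readers/writers for the four tidy study tables.

Schemas
-------
``probes``   one row per detection probe: participant_id, condition,
             probe_index, time_s, answer (yes/no, blank if the response
             window lapsed), confidence (0-10, blank iff answer blank).
``trials``   one row per forced-choice trial: participant_id, condition,
             block (1-4), subblock (0 for baseline, 1-32 in-task), stimulus
             (diamond/square), response (left/right/none), correct, rt_ms.
``ratings``  one row per participant x condition with the five side-effect
             ratings (headache, tingling, itching, burning, pain), each 1-5.
``guesses``  one row per participant: end-of-study guess of which session
             was sham, whether it was correct, and guess confidence (1-10).

``read_table`` raises :class:`SchemaError` carrying row-level diagnostics
for every invariant violation rather than silently coercing.  Extra columns
(e.g. a ``session`` bookkeeping column) are preserved.  Lines starting with
``#`` are treated as comments, so provenance headers survive a round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "validate_table", "SCHEMAS"]

CONDITIONS = ("active", "sham")
RATING_SCALES = ("headache", "tingling", "itching", "burning", "pain")


class SchemaError(ValueError):
    """Raised when a table violates its schema; ``errors`` lists (row, message)."""

    def __init__(self, schema: str, errors: list[tuple[int | None, str]]):
        self.schema = schema
        self.errors = errors
        lines = [f"{schema}: {len(errors)} problem(s)"]
        for row, msg in errors[:20]:
            where = "header" if row is None else f"row {row}"
            lines.append(f"  {where}: {msg}")
        if len(errors) > 20:
            lines.append(f"  ... and {len(errors) - 20} more")
        super().__init__("\n".join(lines))


def _require(df: pd.DataFrame, cols: tuple[str, ...], errors) -> bool:
    missing = [c for c in cols if c not in df.columns]
    for c in missing:
        errors.append((None, f"missing required column '{c}'"))
    return not missing


def _check_condition(df, errors):
    bad = ~df["condition"].isin(CONDITIONS)
    for i in df.index[bad]:
        errors.append((int(i), f"unknown condition label {df.at[i, 'condition']!r}"))


def _validate_probes(df: pd.DataFrame, errors) -> pd.DataFrame:
    cols = ("participant_id", "condition", "probe_index", "time_s", "answer", "confidence")
    if not _require(df, cols, errors):
        return df
    df = df.copy()
    df["answer"] = df["answer"].astype("string").str.strip().replace({"": pd.NA, "missing": pd.NA})
    df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    _check_condition(df, errors)
    for i in df.index[~df["answer"].isin(["yes", "no"]) & df["answer"].notna()]:
        errors.append((int(i), f"answer must be yes/no/blank, got {df.at[i, 'answer']!r}"))
    conf = df["confidence"]
    for i in df.index[(conf < 0) | (conf > 10)]:
        errors.append((int(i), f"confidence {conf[i]} outside [0, 10]"))
    mismatch = df["answer"].isna() != conf.isna()
    for i in df.index[mismatch]:
        errors.append((int(i), "answer and confidence must be missing together"))
    idx = pd.to_numeric(df["probe_index"], errors="coerce")
    for i in df.index[idx.isna() | (idx < 1) | (idx != idx.round())]:
        errors.append((int(i), f"probe_index must be a positive integer, got {df.at[i, 'probe_index']!r}"))
    t = pd.to_numeric(df["time_s"], errors="coerce")
    for i in df.index[t.isna() | (t <= 0)]:
        errors.append((int(i), f"time_s must be positive, got {df.at[i, 'time_s']!r}"))
    if not errors:
        df["probe_index"] = idx.astype(int)
        df["time_s"] = t.astype(float)
    return df


def _validate_trials(df: pd.DataFrame, errors) -> pd.DataFrame:
    cols = ("participant_id", "condition", "block", "subblock",
            "stimulus", "response", "correct", "rt_ms")
    if not _require(df, cols, errors):
        return df
    df = df.copy()
    _check_condition(df, errors)
    for i in df.index[~df["block"].isin([1, 2, 3, 4])]:
        errors.append((int(i), f"block must be 1-4, got {df.at[i, 'block']!r}"))
    for i in df.index[~df["stimulus"].isin(["diamond", "square"])]:
        errors.append((int(i), f"unknown stimulus {df.at[i, 'stimulus']!r}"))
    for i in df.index[~df["response"].isin(["left", "right", "none"])]:
        errors.append((int(i), f"unknown response {df.at[i, 'response']!r}"))
    correct = df["correct"].map({True: True, False: False, "True": True, "False": False})
    for i in df.index[correct.isna()]:
        errors.append((int(i), f"correct must be boolean, got {df.at[i, 'correct']!r}"))
    # forced-choice mapping: diamond -> left button, square -> right button
    expected = ((df["stimulus"] == "diamond") & (df["response"] == "left")) | (
        (df["stimulus"] == "square") & (df["response"] == "right"))
    for i in df.index[correct.notna() & (correct != expected)]:
        errors.append((int(i), "correct flag inconsistent with stimulus/response mapping"))
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    for i in df.index[(rt <= 0)]:
        errors.append((int(i), f"rt_ms must be positive, got {rt[i]}"))
    none_resp = df["response"] == "none"
    for i in df.index[none_resp != rt.isna()]:
        errors.append((int(i), "rt_ms must be missing iff response is 'none'"))
    if not errors:
        df["correct"] = correct.astype(bool)
        df["rt_ms"] = rt
        df["block"] = df["block"].astype(int)
        df["subblock"] = df["subblock"].astype(int)
    return df


def _validate_ratings(df: pd.DataFrame, errors) -> pd.DataFrame:
    cols = ("participant_id", "condition") + RATING_SCALES
    if not _require(df, cols, errors):
        return df
    df = df.copy()
    _check_condition(df, errors)
    for scale in RATING_SCALES:
        v = pd.to_numeric(df[scale], errors="coerce")
        for i in df.index[v.isna() | (v < 1) | (v > 5) | (v != v.round())]:
            errors.append((int(i), f"{scale} rating must be an integer in 1..5, got {df.at[i, scale]!r}"))
        if not errors:
            df[scale] = v.astype(int)
    return df


def _validate_guesses(df: pd.DataFrame, errors) -> pd.DataFrame:
    cols = ("participant_id", "guessed_sham_session", "correct", "confidence")
    if not _require(df, cols, errors):
        return df
    df = df.copy()
    for i in df.index[~df["guessed_sham_session"].isin(["session1", "session2"])]:
        errors.append((int(i), f"guessed_sham_session must be session1/session2, "
                               f"got {df.at[i, 'guessed_sham_session']!r}"))
    correct = df["correct"].map({True: True, False: False, "True": True, "False": False})
    for i in df.index[correct.isna()]:
        errors.append((int(i), f"correct must be boolean, got {df.at[i, 'correct']!r}"))
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    for i in df.index[conf.isna() | (conf < 1) | (conf > 10)]:
        errors.append((int(i), f"confidence must be in [1, 10], got {df.at[i, 'confidence']!r}"))
    if not errors:
        df["correct"] = correct.astype(bool)
        df["confidence"] = conf.astype(float)
    return df


SCHEMAS = {
    "probes": _validate_probes,
    "trials": _validate_trials,
    "ratings": _validate_ratings,
    "guesses": _validate_guesses,
}


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Validate an in-memory table against ``schema``; raise :class:`SchemaError` on violations."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    errors: list[tuple[int | None, str]] = []
    out = SCHEMAS[schema](df.reset_index(drop=True), errors)
    if errors:
        raise SchemaError(schema, errors)
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one of the four study tables from CSV."""
    df = pd.read_csv(path, comment="#")
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a table as UTF-8 CSV; optional ``header_comment`` lines are '#'-prefixed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
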