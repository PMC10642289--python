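"""Trial-table schema, validation, and CSV round-tripping.

The canonical trial table is a tidy CSV with header
``participant,proximity,object,congruency,rt_ms,accuracy,status`` (any column
order; matching is by name).  RTs are in ms; ``rt_ms`` may be empty only for
nonresponse trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import (
    STATUS_NONRESPONSE,
    STATUS_OK,
    STATUS_TOO_FAST,
    STATUS_TOO_SLOW,
    TRIAL_COLUMNS,
)

__all__ = ["read_trials", "write_trials", "validate_trials", "TrialTableError"]

_VALID_STATUS = {STATUS_OK, STATUS_TOO_SLOW, STATUS_TOO_FAST, STATUS_NONRESPONSE}
_VALID_CONGRUENCY = {"congruent", "incongruent"}


class TrialTableError(ValueError):
    """Raised for malformed trial tables, naming the offending rows."""


def _bad_rows(msg: str, index) -> TrialTableError:
    rows = [int(i) + 2 for i in list(index)[:10]]  # 1-based + header line
    return TrialTableError(f"{msg} (file line(s) {rows}{'...' if len(index) > 10 else ''})")


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a trial table; raises ``TrialTableError``."""
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise TrialTableError(f"missing required columns: {sorted(missing)}")
    table = table[TRIAL_COLUMNS].copy()
    rt = pd.to_numeric(table["rt_ms"], errors="coerce")
    bad_rt = rt.isna() & (table["status"] != STATUS_NONRESPONSE)
    if bad_rt.any():
        raise _bad_rows("non-numeric rt_ms", table.index[bad_rt])
    nonpos = rt.notna() & (rt <= 0)
    if nonpos.any():
        raise _bad_rows("rt_ms must be positive", table.index[nonpos])
    table["rt_ms"] = rt
    acc = pd.to_numeric(table["accuracy"], errors="coerce")
    bad_acc = ~acc.isin([0, 1])
    if bad_acc.any():
        raise _bad_rows("accuracy must be 0 or 1", table.index[bad_acc])
    table["accuracy"] = acc.astype(np.int64)
    bad_status = ~table["status"].isin(_VALID_STATUS)
    if bad_status.any():
        raise _bad_rows(f"status must be one of {sorted(_VALID_STATUS)}", table.index[bad_status])
    bad_cong = ~table["congruency"].isin(_VALID_CONGRUENCY)
    if bad_cong.any():
        raise _bad_rows("unknown congruency level", table.index[bad_cong])
    return table


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV (schema by column name, order-free)."""
    table = pd.read_csv(path)
    return validate_trials(table)


def write_trials(table: pd.DataFrame, path) -> None:
    """Write a trial table as the canonical CSV."""
    table[TRIAL_COLUMNS].to_csv(path, index=False)
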