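"""Longitudinal total-score datasets.

Long format: one row per observation with subject ID, time in years, the
observed total score (DV), and named covariate columns (e.g. a 0/1
medication flag).  Validation enforces integer scores within the declared
scale range; rows with missing DV are dropped (and counted), mirroring the
missing-dependent-variable convention of NLME datasets.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TSDataset", "read_dataset"]

_CORE_COLS = ("ID", "TIME", "DV")


@dataclass
class TSDataset:
    """Validated long-format total-score dataset.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ID, TIME (years), DV (integer total score) plus covariates.
    ts_range : tuple or None
        Declared (min, max) total score; DV outside it is rejected.
    """

    frame: pd.DataFrame
    ts_range: tuple | None = None
    n_dropped: int = 0

    def __post_init__(self):
        df = self.frame
        missing = [c for c in _CORE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns {missing}")
        before = len(df)
        df = df.dropna(subset=["DV"]).reset_index(drop=True)
        dropped = before - len(df)
        if dropped:
            logger.info("dropped %d rows with missing DV", dropped)
        self.n_dropped += dropped
        if not np.all(np.isfinite(df["TIME"])):
            raise ValueError("non-finite TIME values")
        dv = np.asarray(df["DV"], dtype=float)
        if np.any(np.abs(dv - np.rint(dv)) > 1e-9):
            raise ValueError("DV must be integer-valued total scores")
        if self.ts_range is not None:
            lo, hi = self.ts_range
            bad = (dv < lo) | (dv > hi)
            if np.any(bad):
                rows = list(df.index[bad][:5])
                raise ValueError(
                    f"DV outside declared range [{lo}, {hi}] at rows {rows}"
                )
        dup = df.duplicated(subset=["ID", "TIME"])
        if dup.any() and "OCC" not in df.columns:
            raise ValueError(
                f"duplicate (ID, TIME) pairs at rows {list(df.index[dup][:5])} "
                "(add an OCC column to disambiguate)"
            )
        self.frame = df

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.frame["ID"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def covariate(self, name: str):
        if name not in self.frame.columns:
            return None
        return np.asarray(self.frame[name], dtype=float)

    def fingerprint(self) -> str:
        """Content hash, invariant to row and column ordering."""
        df = self.frame.copy()
        df = df[sorted(df.columns)]
        df = df.sort_values(list(df.columns)).reset_index(drop=True)
        text = df.to_csv(index=False, float_format="%.12g")
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def read_dataset(path, ts_range=None, delimiter=",") -> TSDataset:
    """Read a delimited long-format dataset and validate it."""
    try:
        df = pd.read_csv(path, delimiter=delimiter)
    except Exception as exc:  # pandas reports the offending line itself
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return TSDataset(frame=df, ts_range=ts_range)
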