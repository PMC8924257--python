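"""Statistics for the two screening readouts of a CRMAGE experiment.

* Killing rate — on a MacConkey-galactose colorimetric screen, white
  colonies are successful edits and red colonies are unedited wild type.
  The rate is white / (white + red) per biological replicate, summarized
  as mean +/- sample standard deviation (n - 1 denominator) across
  replicates.
* Indigoidine index — blue-pigment production quantified as the 615 nm
  absorbance normalized to the 800 nm absorbance, which cancels background
  turbidity and volume (pipetting) variation; the ratio is reported per
  sample with replicate mean/SD.  No blank subtraction is applied before
  the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ScreenStatsError(ValueError):
    pass


@dataclass(frozen=True)
class ColonyCount:
    replicate: str
    white: int
    red: int

    def __post_init__(self) -> None:
        if self.white < 0 or self.red < 0:
            raise ScreenStatsError(
                f"replicate {self.replicate!r}: negative colony count"
            )


@dataclass(frozen=True)
class AbsorbanceRecord:
    sample: str
    a615: float
    a800: float


@dataclass(frozen=True)
class ScreenSummary:
    """Per-sample values plus replicate mean and sample SD (None for n < 2)."""

    values: dict[str, float]
    mean: float
    sd: float | None
    excluded: tuple[str, ...] = field(default=())

    @property
    def n(self) -> int:
        return len(self.values)


def _summarize(values: dict[str, float], excluded: list[str]) -> ScreenSummary:
    if not values:
        raise ScreenStatsError("no usable replicates")
    arr = np.array(list(values.values()), dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) >= 2 else None
    return ScreenSummary(
        values=values, mean=float(arr.mean()), sd=sd, excluded=tuple(excluded)
    )


def killing_rate(counts: Sequence[ColonyCount]) -> ScreenSummary:
    """Fraction of colonies that are white (edited), per replicate.

    rate_i = white_i / (white_i + red_i).  Replicates with zero total are
    excluded with a warning; all excluded is an error.
    """
    values: dict[str, float] = {}
    excluded: list[str] = []
    for c in counts:
        total = c.white + c.red
        if total < 1:
            log.warning("replicate %r has zero colonies; excluded", c.replicate)
            excluded.append(c.replicate)
            continue
        values[c.replicate] = c.white / total
    return _summarize(values, excluded)


def indigoidine_index(records: Sequence[AbsorbanceRecord]) -> ScreenSummary:
    """A615 / A800 per sample; samples with A800 <= 0 are flagged and excluded."""
    values: dict[str, float] = {}
    excluded: list[str] = []
    for r in records:
        if not (r.a800 > 0) or math.isnan(r.a800):
            log.warning("sample %r has non-positive A800; excluded", r.sample)
            excluded.append(r.sample)
            continue
        values[r.sample] = r.a615 / r.a800
    return _summarize(values, excluded)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_colony_counts(path: str | Path) -> list[ColonyCount]:
    """Table with columns replicate, white, red (TSV or CSV by extension)."""
    table = _read_table(path)
    for col in ("replicate", "white", "red"):
        if col not in table.columns:
            raise ScreenStatsError(f"colony table missing column {col!r}")
    return [
        ColonyCount(str(r.replicate), int(r.white), int(r.red))
        for r in table.itertuples(index=False)
    ]


def read_absorbance(path: str | Path) -> list[AbsorbanceRecord]:
    """Table with columns sample, a615, a800 (TSV or CSV by extension)."""
    table = _read_table(path)
    for col in ("sample", "a615", "a800"):
        if col not in table.columns:
            raise ScreenStatsError(f"absorbance table missing column {col!r}")
    return [
        AbsorbanceRecord(str(r.sample), float(r.a615), float(r.a800))
        for r in table.itertuples(index=False)
    ]


def write_summary_tsv(summary: ScreenSummary, path: str | Path, value_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"id\t{value_name}\n")
        for sample, value in summary.values.items():
            fh.write(f"{sample}\t{value:.6g}\n")
        fh.write(f"__mean__\t{summary.mean:.6g}\n")
        fh.write(f"__sd__\t{'NA' if summary.sd is None else format(summary.sd, '.6g')}\n")
        for sample in summary.excluded:
            fh.write(f"{sample}\texcluded\n")
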