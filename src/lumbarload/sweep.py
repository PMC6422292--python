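"""Batch execution of the configuration sweep and table aggregation.

The unfiltered grid covers 4 lumbar types x 11 sacral slopes x 21 pelvic
incidences x 3 sagittal-balance conditions = 2772 standing configurations.
Results are collected long-form (one row per configuration) and aggregated
as median and (min-max) per output, lumbar type and SVA condition over the
SS x PI grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ModelConstants, default_constants
from .errors import LumbarLoadError
from .posture import SpinopelvicParams, enumerate_sweep
from .solver import LoadResult, simulate_configuration

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = ("fl4l5c", "fl4l5s", "fl5s1c", "fl5s1s",
                  "f_mf", "f_es", "f_ra", "ll_deg")


@dataclass(frozen=True)
class SweepResultTable:
    """Long-form per-configuration results with grid metadata."""

    results: tuple[LoadResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def __len__(self) -> int:
        return len(self.results)


def run_sweep(constants: ModelConstants | None = None,
              rts: tuple[str, ...] | None = None,
              ss_values: tuple[int, ...] | None = None,
              pi_values: tuple[int, ...] | None = None,
              sva_conditions: tuple[str, ...] | None = None,
              progress: Callable[[int, int], None] | None = None,
              ) -> SweepResultTable:
    """Simulate every configuration of the (optionally filtered) grid.

    The run is deterministic: configurations are visited in (RT, SS, PI,
    SVA) order and contain no randomness. Any configuration failure aborts
    the sweep, annotated with the offending parameter tuple.
    """
    constants = constants or default_constants()
    grid = enumerate_sweep(constants, rts=rts, ss_values=ss_values,
                           pi_values=pi_values, sva_conditions=sva_conditions)
    results = []
    for i, params in enumerate(grid):
        try:
            results.append(simulate_configuration(params, constants))
        except LumbarLoadError as exc:
            raise type(exc)(
                f"configuration (rt={params.rt}, ss={params.ss}, pi={params.pi}, "
                f"sva={params.sva_condition}) failed: {exc}"
            ) from exc
        if progress is not None:
            progress(i + 1, len(grid))
        elif (i + 1) % 500 == 0:
            logger.info("simulated %d / %d configurations", i + 1, len(grid))
    return SweepResultTable(results=tuple(results))


def aggregate(table: SweepResultTable) -> pd.DataFrame:
    """Median and range per (output, RT, SVA condition) over the SS x PI grid.

    The median of an even-count cell is the midpoint of the two central
    order statistics.
    """
    frame = table.to_frame()
    if frame.empty:
        raise LumbarLoadError("cannot aggregate an empty sweep table")
    rows = []
    for (rt, cond), cell in frame.groupby(["rt", "sva_condition"], sort=True):
        for output in OUTPUT_COLUMNS:
            values = cell[output].to_numpy()
            rows.append({
                "output": output, "rt": rt, "sva_condition": cond,
                "n": len(values),
                "median": float(np.median(values)),
                "min": float(np.min(values)),
                "max": float(np.max(values)),
            })
    return pd.DataFrame(rows)


def write_results(table: SweepResultTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, lineterminator="\r\n")


def write_aggregate(table: SweepResultTable, path: str | Path) -> None:
    aggregate(table).to_csv(path, index=False, lineterminator="\r\n")


__all__ = [
    "SweepResultTable",
    "run_sweep",
    "aggregate",
    "write_results",
    "write_aggregate",
    "OUTPUT_COLUMNS",
]
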