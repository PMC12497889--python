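"""Compositional stability of community time series.

The stability of a community at time t is its similarity to the
preceding time point, s_t = 1 - BrayCurtis(rel_t-1, rel_t), computed on
depth-aggregated relative abundances within each (lake, fraction) group;
the average stability index of a group is the arithmetic mean of its
s_t. Alternative similarity kernels (presence/absence Jaccard and a
rank-correlation variant) are selectable for sensitivity checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jaccard as _jaccard
from scipy.stats import spearmanr

from .core import AbundanceMatrix, aggregate_samples, bray_curtis, relative_abundance
from .exceptions import InvalidInputError

METHODS = ("braycurtis", "jaccard", "rank")


@dataclass
class StabilitySeries:
    """Stability values for consecutive transitions of one group."""

    group: str
    times: list[str]  # ordered time points, length = len(values) + 1
    values: np.ndarray  # s_t per transition, in [0, 1]

    @property
    def average_index(self) -> float:
        return float(np.mean(self.values))


def _similarity(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "braycurtis":
        return 1.0 - bray_curtis(x, y)
    if method == "jaccard":
        return 1.0 - float(_jaccard(x > 0, y > 0))
    if method == "rank":
        rho = spearmanr(x, y).statistic
        return float(np.clip(rho, 0.0, 1.0))  # clipped to the [0,1] convention
    raise InvalidInputError(f"unknown stability method {method!r}")


def stability_series(
    m: AbundanceMatrix,
    metadata: pd.DataFrame,
    group_keys=("lake", "fraction"),
    time_key: str = "month",
    method: str = "braycurtis",
) -> dict[str, StabilitySeries]:
    """Per-group stability series on depth-aggregated communities.

    Counts are summed over all samples sharing (group_keys, time point)
    — i.e. over depths — before computing consecutive similarities.
    Groups with fewer than 2 time points are skipped with a warning.
    """
    agg = aggregate_samples(m, metadata, list(group_keys) + [time_key])
    # aggregate IDs are "key1|key2|time"
    parts = pd.Series(agg.sample_ids).str.rsplit("|", n=1)
    groups = parts.str[0]
    times = parts.str[1]
    rel = relative_abundance(agg)
    out: dict[str, StabilitySeries] = {}
    for group in sorted(groups.unique()):
        idx = np.flatnonzero((groups == group).to_numpy())
        order = idx[np.argsort(times.iloc[idx].to_numpy())]
        if order.size < 2:
            warnings.warn(f"group {group!r} has fewer than 2 time points; skipped")
            continue
        vals = np.array(
            [
                _similarity(rel[a], rel[b], method)
                for a, b in zip(order[:-1], order[1:])
            ]
        )
        out[group] = StabilitySeries(group, list(times.iloc[order]), vals)
    if not out:
        raise InvalidInputError("no group had at least 2 time points")
    return out


def stability_at_samples(
    series: dict[str, StabilitySeries],
    metadata: pd.DataFrame,
    group_keys=("lake", "fraction"),
    time_key: str = "month",
) -> pd.Series:
    """Map each sample to the stability of its group's transition ending
    at its time point; samples at the first time point receive the first
    transition's value (declared convention)."""
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    values = {}
    for sid, row in md.iterrows():
        group = "|".join(str(row[k]) for k in group_keys)
        if group not in series:
            raise InvalidInputError(f"sample {sid!r}: no stability series for group {group!r}")
        ser = series[group]
        t = str(row[time_key])
        if t not in ser.times:
            raise InvalidInputError(f"sample {sid!r}: time {t!r} not in series for {group!r}")
        pos = ser.times.index(t)
        values[sid] = float(ser.values[max(pos - 1, 0)])
    return pd.Series(values, name="stability")


def write_series(series: dict[str, StabilitySeries], tsv_path, json_path=None) -> None:
    rows = []
    for ser in series.values():
        for t0, t1, s in zip(ser.times[:-1], ser.times[1:], ser.values):
            rows.append({"group": ser.group, "time_start": t0, "time_end": t1, "stability": s})
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({g: ser.average_index for g, ser in series.items()}, fh, indent=2)
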