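"""Chemical-shift-perturbation and peak-intensity interface mapping.

Titrating an unlabelled binder into an isotope-labelled histone sample moves
(fast exchange) or attenuates (exchange broadening) the resonances of
residues at or near the binding interface.  This module turns per-residue
shift or intensity tables into significance-classified perturbation tables:
values more than one (two) standard deviations beyond a one-sided trimmed
mean of the background are classed ``one_sd`` (``two_sd``).

Weighted CSPs combine the proton and heteronucleus shift changes as a
root-sum-of-squares with dimension weights reflecting the relative shift
dispersion of each nucleus: 1.0 for 1H and 0.15 (15N) or 0.32 (13C) for the
heavy dimension.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ShiftRecord",
    "SignificanceParams",
    "PerturbationTable",
    "weighted_csp",
    "trimmed_threshold",
    "classify_perturbations",
    "intensity_ratio_profile",
]

CLASS_NONE = "none"
CLASS_ONE = "one_sd"
CLASS_TWO = "two_sd"


@dataclasses.dataclass(frozen=True)
class ShiftRecord:
    """Shift change of one residue between two titration points."""

    residue: tuple[str, int]  # (molecule/histone label, author number)
    nucleus_pair: str  # "H-N" or "H-C"
    delta_h: float  # ppm, 1H dimension
    delta_x: float  # ppm, 15N or 13C dimension

    def __post_init__(self):
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_x)):
            raise ValueError("shift deltas must be finite")
        if self.nucleus_pair not in ("H-N", "H-C"):
            raise ValueError(f"unknown nucleus pair {self.nucleus_pair!r}")


@dataclasses.dataclass(frozen=True)
class SignificanceParams:
    """Weights and trimming parameters for significance classification.

    ``side`` selects the tail that carries the effect and is therefore
    excluded from the background estimate: ``high`` for CSPs (binding raises
    them), ``low`` for intensity ratios (binding attenuates peaks).
    """

    trim_fraction: float = 0.10
    side: str = "high"
    weight_hn: float = 0.15
    weight_hc: float = 0.32
    weight_h: float = 1.0
    trim_sd_on_trimmed: bool = False  # SD pool: full data (default) or trimmed set

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.side not in ("low", "high"):
            raise ValueError("side must be 'low' or 'high'")


class PerturbationTable:
    """Per-residue perturbation values with significance classes.

    Backed by a DataFrame with columns ``molecule``, ``residue_number``,
    ``value`` (CSP in ppm, or unitless intensity ratio), ``kind`` and
    ``significance_class``; missing data are NaN values and carry no class.
    """

    KINDS = ("csp", "intensity_ratio")

    def __init__(self, frame: pd.DataFrame, kind: str = "csp"):
        required = {"molecule", "residue_number", "value"}
        if not required <= set(frame.columns):
            raise ValueError(f"table needs columns {sorted(required)}")
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        frame = frame.copy()
        if frame.duplicated(["molecule", "residue_number"]).any():
            raise ValueError("each residue may appear at most once")
        if kind == "intensity_ratio":
            vals = frame["value"].to_numpy(float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValueError("intensity ratios must be non-negative")
        if "significance_class" not in frame.columns:
            frame["significance_class"] = CLASS_NONE
        frame.loc[~np.isfinite(frame["value"].to_numpy(float)), "significance_class"] = CLASS_NONE
        self.frame = frame.reset_index(drop=True)
        self.kind = kind

    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(float)

    def residues(self) -> list[tuple[str, int]]:
        return [
            (m, int(n))
            for m, n in zip(self.frame["molecule"], self.frame["residue_number"])
        ]

    def significant(self, min_class: str = CLASS_ONE) -> list[tuple[str, int]]:
        """Residues at or above a significance class."""
        order = {CLASS_NONE: 0, CLASS_ONE: 1, CLASS_TWO: 2}
        want = order[min_class]
        return [
            (m, int(n))
            for m, n, c in zip(
                self.frame["molecule"],
                self.frame["residue_number"],
                self.frame["significance_class"],
            )
            if order[c] >= want
        ]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "csp") -> "PerturbationTable":
        return cls(pd.read_csv(path, sep="\t"), kind=kind)


def weighted_csp(record: ShiftRecord, params: SignificanceParams | None = None) -> float:
    """Weighted CSP in ppm: sqrt((w_H dH)^2 + (w_X dX)^2).

    Symmetric in the sign of both deltas and homogeneous of degree one; zero
    iff both deltas are zero.
    """
    params = params or SignificanceParams()
    w_x = params.weight_hn if record.nucleus_pair == "H-N" else params.weight_hc
    return math.hypot(params.weight_h * record.delta_h, w_x * record.delta_x)


def trimmed_threshold(
    values: Iterable[float], params: SignificanceParams | None = None
) -> tuple[float, float, float, float]:
    """One-sided trimmed mean/SD background and the 1-SD / 2-SD cutoffs.

    The ``ceil(trim_fraction * n)`` most extreme values on ``params.side``
    are removed before estimating the background; with ``trim_fraction=0``
    this is the plain mean and SD.  Thresholds are ``mean + k*sd`` for the
    high side and ``mean - k*sd`` for the low side.
    """
    params = params or SignificanceParams()
    vals = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if len(vals) < 5:
        raise ValueError("need at least 5 non-missing values")
    n_trim = math.ceil(params.trim_fraction * len(vals))
    ordered = np.sort(vals)
    if n_trim > 0:
        kept = ordered[:-n_trim] if params.side == "high" else ordered[n_trim:]
    else:
        kept = ordered
    mean = float(kept.mean())
    sd_pool = kept if params.trim_sd_on_trimmed else vals
    sd = float(sd_pool.std(ddof=0))
    sign = 1.0 if params.side == "high" else -1.0
    return mean, sd, mean + sign * sd, mean + sign * 2.0 * sd


def classify_perturbations(
    table: PerturbationTable, params: SignificanceParams | None = None
) -> PerturbationTable:
    """Fill significance classes from the data-driven trimmed thresholds.

    CSP tables use high-side trimming/thresholds, intensity-ratio tables
    low-side; classification is invariant under multiplying all values by a
    positive constant because the thresholds scale with the data.
    """
    if params is None:
        params = SignificanceParams(side="high" if table.kind == "csp" else "low")
    vals = table.values()
    finite = np.isfinite(vals)
    _, _, thr1, thr2 = trimmed_threshold(vals[finite], params)
    classes = np.full(len(vals), CLASS_NONE, dtype=object)
    if params.side == "high":
        classes[finite & (vals > thr1)] = CLASS_ONE
        classes[finite & (vals > thr2)] = CLASS_TWO
    else:
        classes[finite & (vals < thr1)] = CLASS_ONE
        classes[finite & (vals < thr2)] = CLASS_TWO
    out = table.frame.copy()
    out["significance_class"] = classes
    return PerturbationTable(out, kind=table.kind)


def intensity_ratio_profile(
    bound: Mapping[tuple[str, int], float],
    free: Mapping[tuple[str, int], float],
    normalization: str = "median",
) -> PerturbationTable:
    """Per-residue bound/free peak-intensity ratios.

    Residues with zero or negative free intensity are marked missing with a
    warning; with median normalization all ratios are divided by the median
    ratio so a uniform dilution of the bound spectrum maps to 1.0.
    """
    if normalization not in ("median", "none"):
        raise ValueError("normalization must be 'median' or 'none'")
    rows = []
    for res in free:
        f = free[res]
        b = bound.get(res, np.nan)
        if not np.isfinite(f) or f <= 0:
            if np.isfinite(f):
                warnings.warn(f"non-positive free intensity for {res}; marked missing")
            ratio = np.nan
        elif not np.isfinite(b):
            ratio = np.nan
        else:
            ratio = b / f
        rows.append({"molecule": res[0], "residue_number": res[1], "value": ratio})
    frame = pd.DataFrame(rows)
    vals = frame["value"].to_numpy(float)
    if normalization == "median" and np.any(np.isfinite(vals)):
        med = np.nanmedian(vals)
        if med > 0:
            frame["value"] = vals / med
    return PerturbationTable(frame, kind="intensity_ratio")
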