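"""Summary-level MR data containers, IVW standardization and delimited-text IO.

The basic unit of data is one genetic variant (instrumental variable) with its
estimated associations to ``p`` exposures and ``q`` outcomes, each with a
standard error.  All downstream models consume these per-variant association
matrices; no individual-level data are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MODES = ("per_outcome", "joint_precision", "none")


class FormatError(ValueError):
    """A mandatory column is missing or the file layout is unusable."""


@dataclass
class SummaryData:
    """Per-variant genetic association estimates for p exposures and q outcomes.

    Attributes
    ----------
    variant_ids : list of str
        One identifier per variant (row).
    exposure_names, outcome_names : list of str
        Labels for the columns of the exposure / outcome blocks.
    beta_x, se_x : (n, p) ndarray
        Variant-exposure association estimates and their standard errors.
    beta_y, se_y : (n, q) ndarray
        Variant-outcome association estimates and their standard errors.
    """

    variant_ids: list
    exposure_names: list
    outcome_names: list
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.atleast_2d(np.asarray(self.beta_y, dtype=float))
        self.se_y = np.atleast_2d(np.asarray(self.se_y, dtype=float))
        n = len(self.variant_ids)
        for name, arr in (("beta_x", self.beta_x), ("se_x", self.se_x),
                          ("beta_y", self.beta_y), ("se_y", self.se_y)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if self.beta_x.shape != self.se_x.shape or self.beta_y.shape != self.se_y.shape:
            raise ValueError("beta and se blocks must have matching shapes")
        if self.beta_x.shape[1] != len(self.exposure_names):
            raise ValueError("exposure_names does not match beta_x columns")
        if self.beta_y.shape[1] != len(self.outcome_names):
            raise ValueError("outcome_names does not match beta_y columns")
        for name, arr in (("se_x", self.se_x), ("se_y", self.se_y)):
            if np.any(arr <= 0):
                bad = np.argwhere(arr <= 0)[0]
                raise ValueError(
                    f"{name} must be strictly positive; first offending row index "
                    f"{bad[0]} (variant {self.variant_ids[bad[0]]!r})")

    @property
    def n(self) -> int:
        return len(self.variant_ids)

    @property
    def p(self) -> int:
        return self.beta_x.shape[1]

    @property
    def q(self) -> int:
        return self.beta_y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical wide table (one row per variant)."""
        cols = {"variant": self.variant_ids}
        for j, name in enumerate(self.exposure_names):
            cols[f"beta_{name}"] = self.beta_x[:, j]
            cols[f"se_{name}"] = self.se_x[:, j]
        for k, name in enumerate(self.outcome_names):
            cols[f"beta_{name}"] = self.beta_y[:, k]
            cols[f"se_{name}"] = self.se_y[:, k]
        return pd.DataFrame(cols)


@dataclass
class StandardizedData:
    """IVW-standardized association matrices ready for model fitting.

    ``weights`` holds the per-variant scale v_i that was divided out; the
    ``standardized`` flag guards against applying the weighting twice.
    """

    beta_x_std: np.ndarray
    beta_y_std: np.ndarray
    weights: np.ndarray
    standardization_mode: str
    exposure_names: list = field(default_factory=list)
    outcome_names: list = field(default_factory=list)
    variant_ids: list = field(default_factory=list)
    standardized: bool = True

    def __post_init__(self):
        self.beta_x_std = np.atleast_2d(np.asarray(self.beta_x_std, dtype=float))
        self.beta_y_std = np.atleast_2d(np.asarray(self.beta_y_std, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.standardization_mode not in _MODES:
            raise ValueError(f"unknown mode {self.standardization_mode!r}")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and positive")

    @property
    def n(self) -> int:
        return self.beta_y_std.shape[0]

    @property
    def p(self) -> int:
        return self.beta_x_std.shape[1]

    @property
    def q(self) -> int:
        return self.beta_y_std.shape[1]


def ivw_standardize(data: SummaryData, mode: str = "joint_precision") -> StandardizedData:
    """Standardize summary statistics by inverse-variance (IVW) weights.

    ``joint_precision`` divides row i of both the outcome and exposure blocks
    by the per-variant scale

        v_i = (q^-1 sum_k se(beta_Yik)^-2)^(-1/2),

    the precision-averaged standard error across the q outcomes.  After the
    division the per-variant residual covariance of the multi-response model
    is (approximately) constant across variants, which is what the sampler
    assumes.  For a single outcome this reduces to the classical first-order
    IVW weighting by se(beta_Yi).

    ``per_outcome`` divides each outcome column by its own standard errors and
    is only defined for q=1 (with several outcomes it would apply a different
    row scaling per column, breaking the shared design matrix).  ``none``
    passes the data through with unit weights.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == "none":
        v = np.ones(data.n)
        return StandardizedData(data.beta_x, data.beta_y, v, mode,
                                data.exposure_names, data.outcome_names,
                                data.variant_ids)
    if mode == "per_outcome":
        if data.q != 1:
            raise ValueError(
                "per_outcome standardization is only supported for a single "
                f"outcome (q=1); got q={data.q}. Use joint_precision instead.")
        v = data.se_y[:, 0]
    else:  # joint_precision
        v = np.sqrt(1.0 / np.mean(data.se_y ** -2, axis=1))
    return StandardizedData(data.beta_x / v[:, None], data.beta_y / v[:, None],
                            v, mode, data.exposure_names, data.outcome_names,
                            data.variant_ids)


def _resolve_columns(columns, exposures, outcomes, column_map):
    column_map = column_map or {}

    def col(name):
        return column_map.get(name, name)

    if col("variant") not in columns:
        raise FormatError(f"mandatory column {col('variant')!r} not found")
    missing = []
    for name in exposures + outcomes:
        for prefix in ("beta", "se"):
            c = col(f"{prefix}_{name}")
            if c not in columns:
                missing.append(c)
    if missing:
        raise FormatError(f"mandatory columns missing: {missing}")
    return col


def _infer_trait_names(columns):
    """Pair beta_*/se_* columns; order of first appearance is preserved."""
    names = []
    for c in columns:
        if c.startswith("beta_") and f"se_{c[5:]}" in columns:
            names.append(c[5:])
    return names


def read_summary_data(path, exposure_names=None, outcome_names=None,
                      column_map=None, sep=None) -> SummaryData:
    """Read a delimited text file of per-variant summary statistics.

    The canonical layout has a header with a ``variant`` column and
    ``beta_<trait>`` / ``se_<trait>`` pairs for every exposure and outcome;
    ``column_map`` maps these canonical names to whatever the file uses.
    When ``exposure_names``/``outcome_names`` are omitted, every beta/se pair
    is treated as an exposure unless its name starts with ``"Y"`` (the
    convention the writer uses), in which case it is an outcome.

    Rows with any missing cell are dropped (complete-case per variant, since
    the model is variant-wise) and the count is logged.  Non-numeric values
    and non-positive standard errors raise with the offending row named.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if exposure_names is None or outcome_names is None:
        traits = _infer_trait_names(list(df.columns))
        if exposure_names is None and outcome_names is None:
            outcome_names = [t for t in traits if t.startswith("Y")]
            exposure_names = [t for t in traits if t not in outcome_names]
        elif exposure_names is None:
            exposure_names = [t for t in traits if t not in set(outcome_names)]
        else:
            outcome_names = [t for t in traits if t not in set(exposure_names)]
    if not exposure_names or not outcome_names:
        raise FormatError("could not identify both exposure and outcome columns")

    col = _resolve_columns(set(df.columns), list(exposure_names),
                           list(outcome_names), column_map)
    value_cols = []
    for name in list(exposure_names) + list(outcome_names):
        value_cols += [col(f"beta_{name}"), col(f"se_{name}")]
    sub = df[[col("variant")] + value_cols].copy()
    for c in value_cols:
        try:
            sub[c] = pd.to_numeric(sub[c], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(sub[c], errors="coerce")
            idx = int(np.argmax(bad.isna() & sub[c].notna()))
            raise ValueError(
                f"non-numeric value in column {c!r} at row {idx}") from exc
    keep = sub[value_cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d row(s) with missing values", n_dropped)
    sub = sub[keep]

    bx = np.column_stack([sub[col(f"beta_{n}")] for n in exposure_names])
    sx = np.column_stack([sub[col(f"se_{n}")] for n in exposure_names])
    by = np.column_stack([sub[col(f"beta_{n}")] for n in outcome_names])
    sy = np.column_stack([sub[col(f"se_{n}")] for n in outcome_names])
    return SummaryData(list(sub[col("variant")].astype(str)),
                       list(exposure_names), list(outcome_names), bx, sx, by, sy)


def write_summary_data(data: SummaryData, path, sep="\t") -> None:
    """Write the canonical wide table; round-trips with :func:`read_summary_data`."""
    data.to_frame().to_csv(path, sep=sep, index=False)
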