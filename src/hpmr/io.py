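"""Summarized genetic-association data: containers, validation and I/O.

Two-sample summary-data Mendelian randomization operates on one row per
(uncorrelated) genetic variant: the estimated per-allele association with
the risk factor (``beta_x``), the estimated association with the outcome
(``beta_y``) and the standard error of the latter (``se_y``).  The standard
error of ``beta_x`` may be present in input files and is carried along, but
the core estimators deliberately ignore uncertainty in the variant-risk
factor associations, which are typically far more precisely estimated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummarizedData",
    "RatioEstimates",
    "FormatError",
    "ValidationError",
    "read_summarized",
    "ratio_estimates",
    "write_result",
    "read_result",
    "make_fixture",
    "DEFAULT_COLUMNS",
]


class FormatError(ValueError):
    """Input file lacks a required column or cannot be parsed."""


class ValidationError(ValueError):
    """Input values violate a precondition; the message names the variants."""


#: default column names expected in delimited input files
DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant": "variant",
    "beta_x": "beta_x",
    "beta_y": "beta_y",
    "se_y": "se_y",
    "se_x": "se_x",
}


@dataclass(frozen=True)
class SummarizedData:
    """Per-variant summary associations for a two-sample MR analysis.

    Parameters
    ----------
    variant_ids
        Unique identifiers, one per variant.
    beta_x
        Association with the risk factor (risk-factor units per allele).
    beta_y
        Association with the outcome (outcome units or log odds per allele).
    se_y
        Standard error of ``beta_y``; strictly positive.
    se_x
        Optional standard error of ``beta_x``; stored but unused by the
        core estimators.
    """

    variant_ids: tuple
    beta_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    se_x: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(v) for v in self.variant_ids)
        object.__setattr__(self, "variant_ids", ids)
        for name in ("beta_x", "beta_y", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.se_x is not None:
            object.__setattr__(self, "se_x", np.asarray(self.se_x, dtype=float))
        self._validate()

    def _validate(self) -> None:
        J = len(self.variant_ids)
        if J < 2:
            raise ValidationError(f"need at least 2 variants, got {J}")
        for name in ("beta_x", "beta_y", "se_y"):
            arr = getattr(self, name)
            if arr.shape != (J,):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({J},)"
                )
            bad = [v for v, x in zip(self.variant_ids, arr) if not np.isfinite(x)]
            if bad:
                raise ValidationError(f"non-finite {name} for variants: {bad}")
        if self.se_x is not None and self.se_x.shape != (J,):
            raise ValidationError("se_x length does not match variant count")
        seen: set[str] = set()
        dups = [v for v in self.variant_ids if v in seen or seen.add(v)]
        if dups:
            raise ValidationError(f"duplicate variant ids: {sorted(set(dups))}")
        bad = [v for v, s in zip(self.variant_ids, self.se_y) if s <= 0]
        if bad:
            raise ValidationError(f"se_y must be > 0; offending variants: {bad}")
        bad = [v for v, b in zip(self.variant_ids, self.beta_x) if b == 0]
        if bad:
            raise ValidationError(
                f"beta_x must be nonzero (ratio estimate undefined): {bad}"
            )

    @property
    def J(self) -> int:
        """Number of genetic variants."""
        return len(self.variant_ids)

    def subset(self, mask: np.ndarray) -> "SummarizedData":
        """Restrict to the variants where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        ids = tuple(v for v, m in zip(self.variant_ids, mask) if m)
        return SummarizedData(
            variant_ids=ids,
            beta_x=self.beta_x[mask],
            beta_y=self.beta_y[mask],
            se_y=self.se_y[mask],
            se_x=None if self.se_x is None else self.se_x[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant": list(self.variant_ids),
                "beta_x": self.beta_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
            }
        )
        if self.se_x is not None:
            df.insert(2, "se_x", self.se_x)
        return df


@dataclass(frozen=True)
class RatioEstimates:
    """Variant-specific ratio (Wald) estimates theta_j = beta_y / beta_x.

    The standard error uses the leading-order delta-method term
    se(beta_y)/|beta_x|; the absolute value keeps it positive for variants
    oriented to a risk-factor-decreasing allele.
    """

    theta: np.ndarray
    se_theta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "se_theta", np.asarray(self.se_theta, dtype=float))
        if np.any(self.se_theta <= 0):
            raise ValidationError("se_theta must be strictly positive")


def ratio_estimates(data: SummarizedData) -> RatioEstimates:
    """Per-variant ratio estimates and delta-method standard errors."""
    return RatioEstimates(
        theta=data.beta_y / data.beta_x,
        se_theta=data.se_y / np.abs(data.beta_x),
    )


def read_summarized(
    path: str | Path,
    delimiter: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> SummarizedData:
    """Read a delimited summary-statistics file into :class:`SummarizedData`.

    Parameters
    ----------
    path
        CSV/TSV file with one header row.
    delimiter
        Field delimiter; sniffed from the file when ``None``.
    columns
        Mapping from the canonical names (``variant``, ``beta_x``,
        ``beta_y``, ``se_y``, optionally ``se_x``) to the column names used
        in the file.  Defaults to :data:`DEFAULT_COLUMNS`.

    Raises
    ------
    FormatError
        If a required column is absent.
    ValidationError
        If any row has a missing required field, ``se_y <= 0``,
        ``beta_x == 0`` or a duplicated variant id; the message names the
        offending variants.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    required = ["variant", "beta_x", "beta_y", "se_y"]
    missing = [cols[c] for c in required if cols[c] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    variant = df[cols["variant"]].astype(str)
    incomplete = df[[cols[c] for c in required[1:]]].isna().any(axis=1)
    if incomplete.any():
        raise ValidationError(
            f"rows with missing required fields: {sorted(variant[incomplete])}"
        )
    se_x = None
    if cols["se_x"] in df.columns and not df[cols["se_x"]].isna().any():
        se_x = df[cols["se_x"]].to_numpy(dtype=float)
    return SummarizedData(
        variant_ids=tuple(variant),
        beta_x=df[cols["beta_x"]].to_numpy(dtype=float),
        beta_y=df[cols["beta_y"]].to_numpy(dtype=float),
        se_y=df[cols["se_y"]].to_numpy(dtype=float),
        se_x=se_x,
    )


def write_result(result, path: str | Path, extra: Mapping | None = None) -> None:
    """Write an estimation result to ``path`` as JSON.

    ``result`` may be any dataclass with a ``to_dict`` method (the causal
    result of the model-averaging method) or a plain dataclass; ``extra``
    entries (e.g. the run configuration and seed) are merged at top level.
    """
    if hasattr(result, "to_dict"):
        payload = result.to_dict()
    elif dataclasses.is_dataclass(result):
        payload = dataclasses.asdict(result)
    else:
        payload = dict(result)
    if extra:
        payload = {**payload, **dict(extra)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_result(path: str | Path) -> dict:
    """Read back a JSON result written by :func:`write_result`."""
    with open(path) as fh:
        return json.load(fh)


def make_fixture(
    J: int,
    theta: float,
    invalid_spec: Sequence[float] | Mapping[int, float] | None = None,
    seed: int = 0,
    se_y: float | Sequence[float] = 0.05,
    beta_x_low: float = 0.2,
    beta_x_high: float = 0.6,
    noise: bool = True,
) -> SummarizedData:
    """Construct a small deterministic summary dataset for tests/examples.

    ``beta_x`` is drawn positive on ``[beta_x_low, beta_x_high]``;
    ``beta_y = theta * beta_x + offset + noise`` where the pleiotropic
    ``offset`` per variant comes from ``invalid_spec`` (a length-``J``
    sequence or an index->offset mapping; zero elsewhere) and the noise is
    N(0, se_y).  Distinct from the individual-level simulation model: this
    generator works directly on the summary-statistic scale.
    """
    if J < 2:
        raise ValidationError("fixture needs J >= 2")
    rng = np.random.default_rng(seed)
    offsets = np.zeros(J)
    if invalid_spec is not None:
        if isinstance(invalid_spec, Mapping):
            for idx, off in invalid_spec.items():
                offsets[int(idx)] = float(off)
        else:
            offsets = np.asarray(invalid_spec, dtype=float)
            if offsets.shape != (J,):
                raise ValidationError("invalid_spec length must equal J")
    se = np.broadcast_to(np.asarray(se_y, dtype=float), (J,)).copy()
    beta_x = rng.uniform(beta_x_low, beta_x_high, size=J)
    eps = rng.normal(0.0, se) if noise else np.zeros(J)
    beta_y = theta * beta_x + offsets + eps
    return SummarizedData(
        variant_ids=tuple(f"snp{j + 1}" for j in range(J)),
        beta_x=beta_x,
        beta_y=beta_y,
        se_y=se,
    )
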