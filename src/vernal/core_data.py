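"""Domain types and I/O for expression time-course data.

The central container is :class:`ExpressionDataset`: mean and standard
deviation of mRNA levels for the five flowering genes, at each sampled day,
in each of the four genotype x vernalization conditions.  Values are
dimensionless (normalized to a reference gene); no unit handling exists
anywhere in the package.

On-disk formats are a long CSV (columns ``gene, genotype, vernalized, day,
mean, sd``, one row per cell) and a JSON mirror with the same field names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GENES",
    "GENOTYPES",
    "CONDITIONS",
    "Condition",
    "ExpressionDataset",
    "FitResult",
    "DatasetSchemaError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "dataset_fingerprint",
]

#: Controlled vocabulary of gene identifiers (case-sensitive, fixed order).
GENES: Tuple[str, ...] = ("FTa1", "SOC1a", "SOC1b", "SOC1c", "PIM")

#: Controlled vocabulary of genotypes.
GENOTYPES: Tuple[str, ...] = ("WT", "fta1-1")

_VERN_LABEL = {True: "V+", False: "V-"}
_VERN_FROM_LABEL = {"V+": True, "V-": False}


class DatasetSchemaError(ValueError):
    """A table does not conform to the documented long-format schema."""


class DatasetValidationError(ValueError):
    """A structurally well-formed dataset violates a value invariant."""


@dataclass(frozen=True, order=True)
class Condition:
    """One experimental condition: genotype crossed with vernalization."""

    genotype: str
    vernalized: bool

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise DatasetSchemaError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if not isinstance(self.vernalized, (bool, np.bool_)):
            raise DatasetSchemaError("vernalized must be a boolean")

    @property
    def label(self) -> str:
        return f"{self.genotype}:{_VERN_LABEL[self.vernalized]}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        try:
            genotype, vern = label.split(":")
            return cls(genotype, _VERN_FROM_LABEL[vern])
        except (ValueError, KeyError):
            raise DatasetSchemaError(f"malformed condition label {label!r}") from None


#: The four possible conditions, in canonical order.
CONDITIONS: Tuple[Condition, ...] = (
    Condition("WT", True),
    Condition("WT", False),
    Condition("fta1-1", True),
    Condition("fta1-1", False),
)


class ExpressionDataset:
    """Mean +/- s.d. expression of the five genes over time in each condition.

    Parameters
    ----------
    timepoints
        Strictly increasing sampling days (at least two).
    mean, sd
        Mappings ``(gene, condition) -> sequence`` aligned with
        ``timepoints``.  Standard deviations must be strictly positive: they
        are used as weights (denominators) in the fitting cost.
    conditions
        Conditions present; defaults to all four.
    source
        Free-text provenance tag (``"synthetic"``, ``"digitized"``, ...).
        Not part of equality.
    """

    def __init__(
        self,
        timepoints: Sequence[float],
        mean: Mapping[Tuple[str, Condition], Sequence[float]],
        sd: Mapping[Tuple[str, Condition], Sequence[float]],
        conditions: Sequence[Condition] = CONDITIONS,
        source: str = "unspecified",
    ) -> None:
        self.timepoints: Tuple[float, ...] = tuple(float(t) for t in timepoints)
        self.genes: Tuple[str, ...] = GENES
        self.conditions: Tuple[Condition, ...] = tuple(conditions)
        self.source = source
        self._mean: Dict[Tuple[str, Condition], np.ndarray] = {
            k: np.asarray(v, dtype=float) for k, v in mean.items()
        }
        self._sd: Dict[Tuple[str, Condition], np.ndarray] = {
            k: np.asarray(v, dtype=float) for k, v in sd.items()
        }
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Check every dataset invariant; raise naming the offending cell."""
        if len(self.conditions) == 0:
            raise DatasetValidationError("dataset has no conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise DatasetValidationError("duplicate conditions")
        if len(self.timepoints) < 2:
            raise DatasetValidationError("need at least 2 timepoints")
        if not all(a < b for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise DatasetValidationError(
                f"timepoints must be strictly increasing, got {self.timepoints}"
            )
        n = len(self.timepoints)
        for gene in self.genes:
            for cond in self.conditions:
                key = (gene, cond)
                for name, table in (("mean", self._mean), ("sd", self._sd)):
                    if key not in table:
                        raise DatasetSchemaError(
                            f"missing {name} series for ({gene}, {cond.label})"
                        )
                    arr = table[key]
                    if arr.shape != (n,):
                        raise DatasetSchemaError(
                            f"{name} series for ({gene}, {cond.label}) has length "
                            f"{arr.shape}, expected {n}"
                        )
                    if not np.all(np.isfinite(arr)):
                        i = int(np.flatnonzero(~np.isfinite(arr))[0])
                        raise DatasetValidationError(
                            f"non-finite {name} at ({gene}, {cond.label}, "
                            f"day {self.timepoints[i]})"
                        )
                if np.any(self._mean[key] < 0):
                    i = int(np.flatnonzero(self._mean[key] < 0)[0])
                    raise DatasetValidationError(
                        f"negative mean at ({gene}, {cond.label}, "
                        f"day {self.timepoints[i]})"
                    )
                if np.any(self._sd[key] <= 0):
                    i = int(np.flatnonzero(self._sd[key] <= 0)[0])
                    raise DatasetValidationError(
                        f"sd <= 0 at ({gene}, {cond.label}, "
                        f"day {self.timepoints[i]})"
                    )
        extra = set(self._mean) - {(g, c) for g in self.genes for c in self.conditions}
        if extra:
            g, c = sorted(extra)[0][0], sorted(extra)[0][1]
            raise DatasetSchemaError(f"unexpected series ({g}, {c.label})")

    # -- accessors -------------------------------------------------------

    def mean(self, gene: str, condition: Condition) -> np.ndarray:
        """Mean series of `gene` in `condition`, aligned with `timepoints`."""
        return self._mean[self._key(gene, condition)].copy()

    def sd(self, gene: str, condition: Condition) -> np.ndarray:
        return self._sd[self._key(gene, condition)].copy()

    def value(self, gene: str, condition: Condition, day: float) -> float:
        """Mean at a single sampled day (exact match required)."""
        return float(self._mean[self._key(gene, condition)][self._day_index(day)])

    def _key(self, gene: str, condition: Condition) -> Tuple[str, Condition]:
        if gene not in self.genes:
            raise DatasetSchemaError(f"unknown gene {gene!r}")
        if condition not in self.conditions:
            raise DatasetSchemaError(f"condition {condition.label} not in dataset")
        return (gene, condition)

    def _day_index(self, day: float) -> int:
        try:
            return self.timepoints.index(float(day))
        except ValueError:
            raise DatasetSchemaError(f"day {day} not a sampled timepoint") from None

    # -- conversion ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, genotype, vernalized, day, mean, sd."""
        rows = []
        for gene in self.genes:
            for cond in self.conditions:
                m, s = self._mean[(gene, cond)], self._sd[(gene, cond)]
                for i, day in enumerate(self.timepoints):
                    rows.append(
                        {
                            "gene": gene,
                            "genotype": cond.genotype,
                            "vernalized": _VERN_LABEL[cond.vernalized],
                            "day": day,
                            "mean": m[i],
                            "sd": s[i],
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str = "unspecified") -> "ExpressionDataset":
        required = {"gene", "genotype", "vernalized", "day", "mean", "sd"}
        missing = required - set(frame.columns)
        if missing:
            raise DatasetSchemaError(f"missing columns: {sorted(missing)}")
        for v in frame["vernalized"].unique():
            if v not in _VERN_FROM_LABEL:
                raise DatasetSchemaError(
                    f"unknown vernalized label {v!r}; expected 'V+' or 'V-'"
                )
        for g in frame["gene"].unique():
            if g not in GENES:
                raise DatasetSchemaError(f"unknown gene {g!r}")

        timepoints = sorted(float(d) for d in frame["day"].unique())
        conditions = []
        for cond in CONDITIONS:
            sub = frame[
                (frame["genotype"] == cond.genotype)
                & (frame["vernalized"] == _VERN_LABEL[cond.vernalized])
            ]
            if len(sub):
                conditions.append(cond)
        mean: Dict[Tuple[str, Condition], list] = {}
        sd: Dict[Tuple[str, Condition], list] = {}
        for cond in conditions:
            sub = frame[
                (frame["genotype"] == cond.genotype)
                & (frame["vernalized"] == _VERN_LABEL[cond.vernalized])
            ]
            for gene in GENES:
                g = sub[sub["gene"] == gene].set_index("day")
                ms, ss = [], []
                for day in timepoints:
                    if day not in g.index:
                        raise DatasetSchemaError(
                            f"missing row for ({gene}, {cond.label}, day {day:g})"
                        )
                    ms.append(float(g.loc[day, "mean"]))
                    ss.append(float(g.loc[day, "sd"]))
                mean[(gene, cond)] = ms
                sd[(gene, cond)] = ss
        return cls(timepoints, mean, sd, conditions=conditions, source=source)

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        if self.timepoints != other.timepoints or set(self.conditions) != set(
            other.conditions
        ):
            return False
        return all(
            np.array_equal(self._mean[k], other._mean[k])
            and np.array_equal(self._sd[k], other._sd[k])
            for k in self._mean
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionDataset({len(self.genes)} genes x "
            f"{len(self.timepoints)} timepoints x {len(self.conditions)} conditions)"
        )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "json"):
            raise ValueError(f"unsupported format {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_dataset(path: str | Path, format: str | None = None) -> ExpressionDataset:
    """Read an :class:`ExpressionDataset` from long CSV or its JSON mirror."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    if fmt == "csv":
        frame = pd.read_csv(path, float_precision="round_trip")
    else:
        with open(path) as fh:
            payload = json.load(fh)
        if not isinstance(payload, dict) or "records" not in payload:
            raise DatasetSchemaError("JSON dataset must be {'records': [...]}")
        frame = pd.DataFrame(payload["records"])
    return ExpressionDataset.from_frame(frame)


def write_dataset(
    dataset: ExpressionDataset, path: str | Path, format: str | None = None
) -> None:
    """Write a dataset so that :func:`read_dataset` recovers it exactly."""
    dataset.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    frame = dataset.to_frame()
    if fmt == "csv":
        # str(float) round-trips exactly in Python 3; no precision is lost.
        frame.to_csv(path, index=False)
    else:
        records = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump({"records": records}, fh, indent=1)


def dataset_fingerprint(dataset: ExpressionDataset) -> str:
    """Stable content hash used to detect fits against different datasets."""
    h = hashlib.sha256()
    h.update(repr(dataset.timepoints).encode())
    for gene in dataset.genes:
        for cond in sorted(dataset.conditions):
            h.update(gene.encode())
            h.update(cond.label.encode())
            h.update(dataset.mean(gene, cond).tobytes())
            h.update(dataset.sd(gene, cond).tobytes())
    return h.hexdigest()


@dataclass
class FitResult:
    """Outcome of fitting one hypothesis model to a dataset.

    ``trajectories`` maps condition labels to ``{"t": ..., "pim": ...}``
    arrays on a dense grid.  ``v_min`` must equal the cost recomputed from
    ``params``; this is asserted by the fitting routine and re-checkable via
    :func:`vernal.fitting.cost`.
    """

    hypothesis: str
    params: Dict[str, float]
    v_min: float
    aicc: float
    trajectories: Dict[str, Dict[str, np.ndarray]]
    restarts_used: int
    seed: int
    polished: bool = False
    dataset_hash: str = ""
    m: int = 0

    def to_json(self) -> str:
        payload = {
            "hypothesis": self.hypothesis,
            "params": self.params,
            "v_min": self.v_min,
            "aicc": self.aicc,
            "trajectories": {
                label: {k: np.asarray(v).tolist() for k, v in tr.items()}
                for label, tr in self.trajectories.items()
            },
            "restarts_used": self.restarts_used,
            "seed": self.seed,
            "polished": self.polished,
            "dataset_hash": self.dataset_hash,
            "m": self.m,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        payload = json.loads(text)
        payload["trajectories"] = {
            label: {k: np.asarray(v, dtype=float) for k, v in tr.items()}
            for label, tr in payload["trajectories"].items()
        }
        return cls(**payload)
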