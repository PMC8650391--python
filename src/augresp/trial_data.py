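"""Data model, CSV ingestion and validation for composite-endpoint trials.

Input files are plain comma-separated text with columns identified strictly
by POSITION: subject ID, treatment arm (0/1), the continuous outcome(s), the
binary outcome (if any), then the baseline value(s) for the continuous
outcome(s).  An optional single header row may be present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EndpointSpec",
    "TrialDataset",
    "StructureError",
    "ValidationError",
    "MissingDataError",
    "read_dataset",
    "classify_responders",
    "write_dataset",
]


class StructureError(ValueError):
    """File layout (column count / order) does not match the endpoint."""


class ValidationError(ValueError):
    """Cell values violate the data contract (non-numeric, bad codes)."""


class MissingDataError(ValueError):
    """Dataset contains empty cells; rows with missing values are rejected."""


@dataclass(frozen=True)
class EndpointSpec:
    """Structure of the composite responder endpoint.

    Parameters
    ----------
    n_cont
        Number of continuous components (1 or 2).
    has_binary
        Whether a binary component is present.
    thresholds
        Responder threshold per continuous component, in clinical-scale
        units.  Values BELOW the threshold count as response.
    inclusive
        Per-component flag: whether a value exactly equal to the threshold
        counts as response in the observed classification.  Defaults to
        strict ``<`` comparison.  This only affects observed classification,
        never model-based probabilities.
    """

    n_cont: int
    has_binary: bool
    thresholds: tuple[float, ...]
    inclusive: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cont not in (1, 2):
            raise ValueError(f"n_cont must be 1 or 2, got {self.n_cont}")
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) != self.n_cont:
            raise ValueError(
                f"expected {self.n_cont} threshold(s), got {len(thr)}"
            )
        inc = tuple(bool(b) for b in self.inclusive)
        if not inc:
            inc = (False,) * self.n_cont
        if len(inc) != self.n_cont:
            raise ValueError(
                f"expected {self.n_cont} inclusive flag(s), got {len(inc)}"
            )
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "inclusive", inc)

    @property
    def n_components(self) -> int:
        """Total latent dimension: continuous components plus binary."""
        return self.n_cont + int(self.has_binary)

    @property
    def n_columns(self) -> int:
        """Expected CSV column count: id, arm, outcomes, baselines."""
        return 2 + self.n_cont + int(self.has_binary) + self.n_cont

    def column_layout(self) -> list[str]:
        cols = ["id", "arm"]
        cols += [f"y{j + 1}" for j in range(self.n_cont)]
        if self.has_binary:
            cols.append("y_bin")
        cols += [f"baseline{j + 1}" for j in range(self.n_cont)]
        return cols


@dataclass
class TrialDataset:
    """Validated patient-level composite-endpoint data.

    Attributes
    ----------
    subject_id : ndarray of object
        Opaque per-row identifier.
    arm : ndarray of int
        Treatment indicator, 0 = control, 1 = treatment.
    y_cont : ndarray, shape (n, n_cont)
        Continuous outcome(s) per subject.
    y_bin : ndarray of int or None
        Binary outcome, 1 = component response; None when absent.
    baselines : ndarray, shape (n, n_cont)
        Baseline value(s) matching the continuous outcomes.
    """

    subject_id: np.ndarray
    arm: np.ndarray
    y_cont: np.ndarray
    y_bin: np.ndarray | None
    baselines: np.ndarray

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.arm = np.asarray(self.arm)
        self.y_cont = np.atleast_2d(np.asarray(self.y_cont, dtype=float))
        if self.y_cont.shape[0] == 1 and len(self.subject_id) > 1:
            self.y_cont = self.y_cont.T
        self.baselines = np.atleast_2d(np.asarray(self.baselines, dtype=float))
        if self.baselines.shape[0] == 1 and len(self.subject_id) > 1:
            self.baselines = self.baselines.T
        if self.y_bin is not None:
            self.y_bin = np.asarray(self.y_bin)
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_id)

    @property
    def n_cont(self) -> int:
        return self.y_cont.shape[1]

    def validate(self) -> None:
        n = self.n_subjects
        if self.arm.shape != (n,):
            raise ValidationError("arm must be one value per subject")
        arm_vals = np.unique(self.arm)
        if not np.all(np.isin(arm_vals, [0, 1])):
            bad = sorted(set(arm_vals) - {0, 1})
            raise ValidationError(
                f"arm must be coded 0 (control) / 1 (treatment); found {bad}"
            )
        if self.y_cont.shape != (n, self.n_cont) or self.n_cont not in (1, 2):
            raise ValidationError("y_cont must be (n, 1) or (n, 2)")
        if self.baselines.shape != self.y_cont.shape:
            raise ValidationError("baselines must match y_cont in shape")
        for name, arr in (("y_cont", self.y_cont), ("baselines", self.baselines)):
            if not np.all(np.isfinite(arr)):
                raise MissingDataError(f"{name} contains missing/non-finite values")
        if self.y_bin is not None:
            if self.y_bin.shape != (n,):
                raise ValidationError("y_bin must be one value per subject")
            if not np.all(np.isin(np.unique(self.y_bin), [0, 1])):
                bad = sorted(set(np.unique(self.y_bin)) - {0, 1})
                raise ValidationError(f"y_bin must be coded 0/1; found {bad}")
        self.arm = self.arm.astype(int)
        if self.y_bin is not None:
            self.y_bin = self.y_bin.astype(int)

    def require_both_arms(self) -> None:
        if np.sum(self.arm == 0) == 0 or np.sum(self.arm == 1) == 0:
            raise ValidationError("both arms must be non-empty for analysis")

    def arm_mask(self, arm: int) -> np.ndarray:
        return self.arm == arm

    def subset(self, idx: np.ndarray) -> "TrialDataset":
        return TrialDataset(
            subject_id=self.subject_id[idx],
            arm=self.arm[idx],
            y_cont=self.y_cont[idx],
            y_bin=None if self.y_bin is None else self.y_bin[idx],
            baselines=self.baselines[idx],
        )


def _numeric_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"column {list(df.columns).index(col) + 2} contains "
                f"non-numeric values (is a header row present without "
                f"--header?): {exc}"
            ) from exc
    return out


def read_dataset(path, has_header: bool, spec: EndpointSpec) -> TrialDataset:
    """Read a positional-column CSV into a validated :class:`TrialDataset`.

    Columns are bound strictly by position in the order: id, arm,
    continuous outcome(s), binary outcome (if ``spec.has_binary``),
    baseline(s).
    """
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        skip_blank_lines=True,
        dtype=object,
    )
    expected = spec.n_columns
    if df.shape[1] != expected:
        raise StructureError(
            f"expected {expected} columns ({', '.join(spec.column_layout())}) "
            f"for n_cont={spec.n_cont}, has_binary={spec.has_binary}; "
            f"file has {df.shape[1]}"
        )
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise MissingDataError(
            f"missing values in data rows {rows}; rows with any empty cell "
            "are rejected"
        )
    subject_id = df.iloc[:, 0].to_numpy(dtype=object)
    body = _numeric_frame(df.iloc[:, 1:])
    vals = body.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        rows = np.nonzero(~np.all(np.isfinite(vals), axis=1))[0].tolist()
        raise MissingDataError(f"non-finite values in data rows {rows}")

    arm = vals[:, 0]
    if not np.all(np.isin(arm, [0.0, 1.0])):
        rows = np.nonzero(~np.isin(arm, [0.0, 1.0]))[0].tolist()
        raise ValidationError(
            f"arm column must be 0/1; offending rows (0-based): {rows}"
        )
    nc = spec.n_cont
    y_cont = vals[:, 1 : 1 + nc]
    col = 1 + nc
    y_bin = None
    if spec.has_binary:
        y_bin = vals[:, col]
        if not np.all(np.isin(y_bin, [0.0, 1.0])):
            rows = np.nonzero(~np.isin(y_bin, [0.0, 1.0]))[0].tolist()
            raise ValidationError(
                f"binary outcome column must be 0/1; offending rows "
                f"(0-based): {rows}"
            )
        col += 1
    baselines = vals[:, col : col + nc]
    return TrialDataset(
        subject_id=subject_id,
        arm=arm,
        y_cont=y_cont,
        y_bin=y_bin,
        baselines=baselines,
    )


def classify_responders(data: TrialDataset, spec: EndpointSpec) -> np.ndarray:
    """Collapse the composite outcome to a per-subject 0/1 responder vector.

    A subject responds iff every continuous component is below its threshold
    (boundary per ``spec.inclusive``) and, when present, the binary
    component equals 1.
    """
    if data.n_cont != spec.n_cont:
        raise ValidationError(
            f"dataset has {data.n_cont} continuous component(s), "
            f"spec expects {spec.n_cont}"
        )
    resp = np.ones(data.n_subjects, dtype=bool)
    for j in range(spec.n_cont):
        tau = spec.thresholds[j]
        if spec.inclusive[j]:
            resp &= data.y_cont[:, j] <= tau
        else:
            resp &= data.y_cont[:, j] < tau
    if spec.has_binary:
        if data.y_bin is None:
            raise ValidationError("spec expects a binary component; none in data")
        resp &= data.y_bin == 1
    return resp.astype(int)


def write_dataset(data: TrialDataset, path, spec: EndpointSpec) -> None:
    """Echo a validated dataset as TSV (audit trail for ingestion)."""
    cols: dict[str, np.ndarray] = {
        "id": data.subject_id,
        "arm": data.arm,
    }
    for j in range(data.n_cont):
        cols[f"y{j + 1}"] = data.y_cont[:, j]
    if data.y_bin is not None:
        cols["y_bin"] = data.y_bin
    for j in range(data.n_cont):
        cols[f"baseline{j + 1}"] = data.baselines[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
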