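"""Dataset and report I/O, plus the serializable run configuration.

Datasets are headered CSV/TSV files with columns ``t``, ``y``, ``x1..xd``
(``t`` in [0, 1], nondecreasing); fit and study summaries are JSON; curves
and ECDF/QQ tables are TSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .asymptotics import NormalityReport
from .dols import PLMData
from .wavelet_estimator import NonparametricFit

__all__ = [
    "RunConfig",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "write_fit_summary",
    "write_curve",
    "write_normality_report",
]


class DatasetFormatError(ValueError):
    """A dataset file violates the expected tabular layout."""


@dataclass
class RunConfig:
    """All knobs of one run; round-trips losslessly through JSON."""

    mode: str = "fit"
    dataset: str | None = None
    m: int = 3
    sequence: list[float] | None = None
    family: str = "daubechies-2"
    resolution: int | None = None
    lag: int | None = None
    n: int = 128
    reps: int = 1000
    seed: int = 0
    t_eval: float = 0.5
    center: bool = True
    out: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _separator(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(path) -> PLMData:
    """Read a (t, y, x1..xd) table and validate it as a PLM sample.

    Rows are reordered by ``t`` (with a warning) if the file is unsorted.
    Error messages cite 1-based data-row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_separator(path))
    cols = list(df.columns)
    for required in ("t", "y"):
        if required not in cols:
            raise DatasetFormatError(f"{path}: missing required column '{required}'")
    d = 1
    while f"x{d}" in cols:
        d += 1
    d -= 1
    if d == 0:
        raise DatasetFormatError(f"{path}: no covariate columns x1..xd found")
    use = ["t", "y"] + [f"x{j}" for j in range(1, d + 1)]
    for col in use:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise DatasetFormatError(
                f"{path}: non-numeric value in column '{col}' at data row {row}"
            )
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0]) + 1
            raise DatasetFormatError(f"{path}: missing value in column '{col}' at data row {row}")
    t = df["t"].to_numpy(dtype=float)
    out_of_range = (t < 0.0) | (t > 1.0)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 1
        raise DatasetFormatError(
            f"{path}: t = {t[out_of_range][0]} outside [0, 1] at data row {row}"
        )
    if np.any(np.diff(t) < 0):
        warnings.warn(f"{path}: t not sorted; reordering rows by t", stacklevel=2)
        df = df.sort_values("t", kind="stable").reset_index(drop=True)
        t = df["t"].to_numpy(dtype=float)
    X = df[[f"x{j}" for j in range(1, d + 1)]].to_numpy(dtype=float)
    return PLMData(y=df["y"].to_numpy(dtype=float), X=X, t=t)


def write_dataset(data: PLMData, path) -> None:
    """Write a PLM sample as a headered CSV/TSV (t, y, x1..xd)."""
    path = Path(path)
    cols = {"t": data.t, "y": data.y}
    for j in range(data.d):
        cols[f"x{j + 1}"] = data.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep=_separator(path), index=False, lineterminator="\n")


def write_fit_summary(path, beta_hat, se, method: str, lag: int, extra: dict | None = None) -> None:
    payload = {
        "beta_hat": np.atleast_1d(beta_hat).tolist(),
        "se": np.atleast_1d(se).tolist(),
        "tau2_method": method,
        "lag_truncation": int(lag),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_curve(fit: NonparametricFit, path, tau_t: np.ndarray | None = None) -> None:
    """Write the smooth-component curve as TSV (t, f_hat[, tau_t])."""
    cols = {"t": fit.grid, "f_hat": fit.f_hat}
    if tau_t is not None:
        cols["tau_t"] = np.asarray(tau_t, dtype=float)
    pd.DataFrame(cols).to_csv(Path(path), sep="\t", index=False, lineterminator="\n")


def write_normality_report(report: NormalityReport, out_dir, stem: str) -> dict:
    """Write a study report: summary JSON plus ECDF and QQ TSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = report.summary()
    (out_dir / f"{stem}.json").write_text(json.dumps(summary, indent=2) + "\n")
    pd.DataFrame({"x": report.ecdf_x, "F": report.ecdf_F}).to_csv(
        out_dir / f"{stem}_ecdf.tsv", sep="\t", index=False, lineterminator="\n"
    )
    pd.DataFrame(
        {"theoretical": report.qq_theoretical, "empirical": report.qq_empirical}
    ).to_csv(out_dir / f"{stem}_qq.tsv", sep="\t", index=False, lineterminator="\n")
    return summary
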