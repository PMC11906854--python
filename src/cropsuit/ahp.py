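"""Analytic Hierarchy Process: weight derivation and consistency checking.

The workflow is Saaty's classic one.  A pairwise comparison matrix ``A`` holds
judgments on the 1/9…9 scale (a_ij > 1 means criterion i matters more than
criterion j, and a_ji = 1/a_ij).  Weights come from column normalization:
divide each column by its sum and average each row of the normalized matrix.
The consistency check estimates the principal eigenvalue λ_max from the
consistency vector ``(A·w)_i / w_i`` and derives

    CI = (λ_max − n) / (n − 1)        CR = CI / RI(n)

where RI is the tabulated random consistency index.  A matrix is accepted
when CR < 0.1.

Three λ_max estimators are exposed via ``estimator=``:

``"max"`` (default)
    the maximum of the consistency-vector components — the convention this
    package standardizes on for spreadsheet-style AHP audits;
``"mean"``
    the mean of the components, Saaty's usual estimate;
``"eigen"``
    the exact principal eigenvalue from a dense eigensolver.

All three coincide (at n) for a perfectly consistent matrix and all satisfy
λ_max ≥ n on positive reciprocal matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MatrixValidationError

#: Saaty's random consistency index for matrix sizes 1..10.
RANDOM_INDEX = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.46, 1.49)

#: Relative tolerance for the reciprocity check.  Printed matrices carry
#: 2-decimal reciprocals (0.13 for 1/8), which must validate.
RECIPROCAL_RTOL = 0.05

ESTIMATORS = ("max", "mean", "eigen")


@dataclass(frozen=True)
class PairwiseMatrix:
    """An n×n positive reciprocal judgment matrix with criterion labels."""

    entries: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "labels", tuple(self.labels))
        self._validate()

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def _validate(self) -> None:
        a = self.entries
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise MatrixValidationError(f"matrix must be square, got shape {a.shape}")
        n = a.shape[0]
        if not 2 <= n <= 15:
            raise MatrixValidationError(f"matrix size {n} outside the supported range 2..15")
        if len(self.labels) != n:
            raise MatrixValidationError(f"{len(self.labels)} labels for a {n}x{n} matrix")
        bad = np.argwhere(~(a > 0))
        if bad.size:
            i, j = bad[0]
            raise MatrixValidationError(
                f"non-positive entry {a[i, j]!r} at ({self.labels[i]}, {self.labels[j]})"
            )
        if not np.allclose(np.diag(a), 1.0):
            raise MatrixValidationError("diagonal entries must equal 1")
        prod = a * a.T
        bad = np.argwhere(np.abs(prod - 1.0) > RECIPROCAL_RTOL)
        if bad.size:
            i, j = bad[0]
            raise MatrixValidationError(
                f"reciprocity violated at ({self.labels[i]}, {self.labels[j]}): "
                f"{a[i, j]} × {a[j, i]} = {prod[i, j]:.4f}, expected 1 ± {RECIPROCAL_RTOL}"
            )

    @classmethod
    def from_judgments(
        cls, upper: np.ndarray | Sequence[Sequence[float]], labels: Sequence[str]
    ) -> "PairwiseMatrix":
        """Build from an upper-triangular judgment array, filling reciprocals."""
        a = np.asarray(upper, dtype=float).copy()
        iu = np.triu_indices_from(a, k=1)
        a[(iu[1], iu[0])] = 1.0 / a[iu]
        np.fill_diagonal(a, 1.0)
        return cls(a, tuple(labels))

    @classmethod
    def from_csv(cls, path: str | Path, lower: str = "given") -> "PairwiseMatrix":
        """Read a labeled square CSV.

        ``lower="auto"`` treats the upper triangle as authoritative and fills
        the lower triangle with exact reciprocals.
        """
        df = pd.read_csv(path, index_col=0)
        labels = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != labels:
            raise MatrixValidationError("row labels must match column labels")
        a = df.to_numpy(dtype=float)
        if lower == "auto":
            return cls.from_judgments(a, labels)
        return cls(a, labels)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, index=self.labels, columns=self.labels).to_csv(path)


@dataclass(frozen=True)
class ConsistencyReport:
    """Weights plus the λ_max / CI / RI / CR audit for one matrix."""

    labels: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float
    ci: float
    ri: float
    cr: float
    accepted: bool
    estimator: str = "max"

    @property
    def n(self) -> int:
        return len(self.labels)

    def weights_by_label(self) -> dict[str, float]:
        return dict(zip(self.labels, self.weights.tolist()))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "weights": self.weights.tolist(),
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "accepted": self.accepted,
            "estimator": self.estimator,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __str__(self) -> str:
        lines = [f"{lbl:<24s} {w:8.4f}" for lbl, w in self.weights_by_label().items()]
        verdict = "accepted (CR < 0.1)" if self.accepted else "REJECTED (CR >= 0.1)"
        lines += [
            f"n = {self.n}",
            f"lambda_max = {self.lambda_max:.4f}  [{self.estimator}]",
            f"CI = {self.ci:.4f}   RI = {self.ri:.2f}   CR = {self.cr:.4f}  -> {verdict}",
        ]
        return "\n".join(lines)


def derive_weights(matrix: PairwiseMatrix) -> np.ndarray:
    """Column-normalization weights: normalize each column, average rows."""
    a = matrix.entries
    normalized = a / a.sum(axis=0, keepdims=True)
    w = normalized.mean(axis=1)
    return w / w.sum()  # exact renormalization against float drift


def principal_eigenvector(matrix: PairwiseMatrix, tol: float = 1e-12, max_iter: int = 10_000) -> np.ndarray:
    """Principal eigenvector by power iteration (exact-eigen weight option)."""
    a = matrix.entries
    w = np.full(matrix.n, 1.0 / matrix.n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            return nxt
        w = nxt
    return w


def lambda_max(
    matrix: PairwiseMatrix, weights: np.ndarray, estimator: str = "max"
) -> float:
    """Estimate the principal eigenvalue from the consistency vector."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (matrix.n,):
        raise ValueError(f"weights shape {w.shape} does not match matrix size {matrix.n}")
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if estimator == "eigen":
        eigvals = np.linalg.eigvals(matrix.entries)
        return float(np.max(eigvals.real))
    ratios = (matrix.entries @ w) / w
    return float(ratios.max() if estimator == "max" else ratios.mean())


def consistency_index(lam: float, n: int) -> float:
    """CI = (λ_max − n) / (n − 1)."""
    if n < 2:
        raise ValueError("CI is undefined for n < 2")
    if lam < n - 1e-9:
        raise ValueError(f"lambda_max {lam} below n = {n}; not a reciprocal-matrix eigenvalue")
    return (lam - n) / (n - 1)


def random_index(n: int) -> float:
    """Tabulated random consistency index for n = 1..10."""
    if not 1 <= n <= 10:
        raise ValueError(
            f"random index tabulated only for n = 1..10 (got {n}); supply a custom RI"
        )
    return RANDOM_INDEX[n - 1]


def consistency_ratio(ci: float, ri: float) -> float:
    """CR = CI / RI, defined as 0 when RI = 0 (n ≤ 2)."""
    if ci < -1e-9 or ri < 0:
        raise ValueError(f"CI and RI must be non-negative (got ci={ci}, ri={ri})")
    return 0.0 if ri == 0 else max(ci, 0.0) / ri


def analyze(
    matrix: PairwiseMatrix, estimator: str = "max", ri: float | None = None
) -> ConsistencyReport:
    """Full audit: weights, λ_max, CI, RI, CR, and the CR < 0.1 verdict.

    A rejected matrix still returns its numbers so callers can report them
    and refuse downstream use.
    """
    w = derive_weights(matrix)
    lam = lambda_max(matrix, w, estimator=estimator)
    ci = consistency_index(lam, matrix.n)
    ri_val = random_index(matrix.n) if ri is None else ri
    cr = consistency_ratio(max(ci, 0.0), ri_val)
    return ConsistencyReport(
        labels=matrix.labels,
        weights=w,
        lambda_max=lam,
        ci=ci,
        ri=ri_val,
        cr=cr,
        accepted=cr < 0.1,
        estimator=estimator,
    )
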