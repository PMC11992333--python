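"""Data containers, validation, and matrix file I/O.

The reciprocal graphical model consumes one of three input bundles:

* individual-level data — an instrument matrix ``X`` (n x k, e.g. SNP
  dosages) and a response matrix ``Y`` (n x p, e.g. expression levels);
* exact summary statistics — the cross-moment matrices ``Syy`` (p x p),
  ``Syx`` (p x k) and ``Sxx`` (k x k) together with the sample size ``n``;
* per-response regression summaries — no-intercept regression coefficients
  ``Beta`` (p x k) and mean square errors ``SigmaHat`` (p x k), plus ``Sxx``
  and ``n``, for settings where response cross-covariances were never
  observed jointly.

All summary matrices use the cross-product-over-n convention
(``Syy = Y'Y / n`` and so on); the likelihood multiplies by ``n``
internally.  Every bundle is accompanied by a binary instrument-assignment
matrix ``D`` (p x k) declaring which instrument is allowed to affect which
response.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InstrumentAssignment",
    "IndividualData",
    "SummaryStatistics",
    "RegressionSummaries",
    "ValidationReport",
    "IdentifiabilityError",
    "validate_instrument_assignment",
    "compute_summary_statistics",
    "reconstruct_summary",
    "read_matrix_file",
    "write_matrix_file",
    "write_fit_outputs",
]

_SYM_TOL = 1e-10


class IdentifiabilityError(ValueError):
    """Raised when D lacks a private instrument for some response on a path
    that cannot proceed without one."""

    def __init__(self, rows: list[int]):
        self.rows = list(rows)
        super().__init__(
            "instrument-assignment matrix is not identifiable: responses "
            f"{self.rows} have no instrument private to them (need at least "
            "one column with a single 1 in each row)"
        )


def _as_2d(name: str, M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {M.shape}")
    return M


@dataclass(frozen=True)
class InstrumentAssignment:
    """Binary p x k matrix; D[i, j] = 1 means instrument j targets response i."""

    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D)
        if D.ndim != 2:
            raise ValueError(f"D must be 2-D, got shape {D.shape}")
        if not np.isin(D, (0, 1)).all():
            raise ValueError("D must contain only 0/1 entries")
        p, k = D.shape
        if p < 2:
            raise ValueError("need at least two response variables (p >= 2)")
        if k < 1:
            raise ValueError("need at least one instrument (k >= 1)")
        object.__setattr__(self, "D", D.astype(np.int8))

    @property
    def p(self) -> int:
        return self.D.shape[0]

    @property
    def k(self) -> int:
        return self.D.shape[1]

    @property
    def identifiable(self) -> bool:
        return not self.rows_lacking_unique_instrument()

    def rows_lacking_unique_instrument(self) -> list[int]:
        """Rows with no private instrument (a column that is 1 in this row
        and 0 in all others)."""
        col_sums = self.D.sum(axis=0)
        private = (self.D == 1) & (col_sums == 1)
        return [int(i) for i in range(self.p) if not private[i].any()]


@dataclass(frozen=True)
class IndividualData:
    """Raw instrument matrix X (n x k) and response matrix Y (n x p)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        X = _as_2d("X", self.X)
        Y = _as_2d("Y", self.Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"X and Y must have equal row counts, got {X.shape[0]} and {Y.shape[0]}"
            )
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("X/Y must not contain missing values")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class SummaryStatistics:
    """Cross-moment matrices on the cross-product/n scale.

    ``missing_offdiag=True`` marks a bundle reconstructed from regression
    summaries, where the off-diagonal entries of ``Syy`` were never observed
    (stored as NaN and imputed with model-implied values at likelihood
    evaluation).  ``n = 0`` is permitted as a degenerate flat-likelihood
    input used for prior-predictive checks.
    """

    Syy: np.ndarray
    Syx: np.ndarray
    Sxx: np.ndarray
    n: int
    missing_offdiag: bool = False
    scale_convention: str = field(default="cross_product_over_n", repr=False)

    def __post_init__(self):
        Syy = _as_2d("Syy", self.Syy)
        Syx = _as_2d("Syx", self.Syx)
        Sxx = _as_2d("Sxx", self.Sxx)
        p, k = Syx.shape
        if Syy.shape != (p, p) or Sxx.shape != (k, k):
            raise ValueError(
                f"inconsistent shapes: Syy {Syy.shape}, Syx {Syx.shape}, Sxx {Sxx.shape}"
            )
        if self.n < 0:
            raise ValueError("sample size n must be nonnegative")
        if not self.missing_offdiag:
            if np.nanmax(np.abs(Syy - Syy.T), initial=0.0) > _SYM_TOL:
                raise ValueError("Syy must be symmetric (tolerance 1e-10)")
        if np.max(np.abs(Sxx - Sxx.T), initial=0.0) > _SYM_TOL:
            raise ValueError("Sxx must be symmetric (tolerance 1e-10)")
        w = np.linalg.eigvalsh((Sxx + Sxx.T) / 2.0)
        if w.size and w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise ValueError("Sxx must be positive semidefinite")
        object.__setattr__(self, "Syy", Syy)
        object.__setattr__(self, "Syx", Syx)
        object.__setattr__(self, "Sxx", Sxx)
        object.__setattr__(self, "n", int(self.n))

    @property
    def p(self) -> int:
        return self.Syy.shape[0]

    @property
    def k(self) -> int:
        return self.Sxx.shape[0]


@dataclass(frozen=True)
class RegressionSummaries:
    """Per-cell no-intercept regression summaries.

    ``Beta[i, j]`` and ``SigmaHat[i, j]`` are the coefficient and mean square
    error of the regression of response i on instrument j alone, without an
    intercept; only cells with D[i, j] = 1 are meaningful.  Mean square
    errors use denominator n, matching the cross-product/n scale.
    """

    Beta: np.ndarray
    SigmaHat: np.ndarray
    Sxx: np.ndarray
    n: int

    def __post_init__(self):
        Beta = _as_2d("Beta", self.Beta)
        SigmaHat = _as_2d("SigmaHat", self.SigmaHat)
        Sxx = _as_2d("Sxx", self.Sxx)
        if Beta.shape != SigmaHat.shape:
            raise ValueError("Beta and SigmaHat must have equal shapes")
        if Sxx.shape != (Beta.shape[1], Beta.shape[1]):
            raise ValueError("Sxx must be k x k with k = Beta.shape[1]")
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        object.__setattr__(self, "Beta", Beta)
        object.__setattr__(self, "SigmaHat", SigmaHat)
        object.__setattr__(self, "Sxx", Sxx)
        object.__setattr__(self, "n", int(self.n))

    @property
    def p(self) -> int:
        return self.Beta.shape[0]

    @property
    def k(self) -> int:
        return self.Beta.shape[1]


@dataclass(frozen=True)
class ValidationReport:
    identifiable: bool
    rows_lacking_unique_instrument: list[int]
    severity: str  # "ok" | "warn" | "error"

    def raise_or_warn(self):
        import warnings

        if self.severity == "error":
            raise IdentifiabilityError(self.rows_lacking_unique_instrument)
        if self.severity == "warn":
            warnings.warn(
                "instrument-assignment matrix is not identifiable (responses "
                f"{self.rows_lacking_unique_instrument} lack a private "
                "instrument); proceeding, but causal directions may not be "
                "uniquely determined",
                UserWarning,
                stacklevel=3,
            )


_INPUT_PATHS = ("individual", "exact_summary", "regression_summary")


def validate_instrument_assignment(
    D: InstrumentAssignment | np.ndarray, input_path: str
) -> ValidationReport:
    """Check the private-instrument identifiability condition.

    Every response must have at least one instrument that targets it alone
    (a column of D with a single 1, in that response's row).  A violation is
    an error on the regression-summary path — the reconstruction cannot
    proceed without private instruments — and a warning on the
    individual-level and exact-summary paths, where the fit proceeds but
    causal directions may not be uniquely determined.
    """
    if input_path not in _INPUT_PATHS:
        raise ValueError(f"input_path must be one of {_INPUT_PATHS}, got {input_path!r}")
    if not isinstance(D, InstrumentAssignment):
        D = InstrumentAssignment(D)
    bad = D.rows_lacking_unique_instrument()
    if not bad:
        severity = "ok"
    elif input_path == "regression_summary":
        severity = "error"
    else:
        severity = "warn"
    return ValidationReport(
        identifiable=not bad, rows_lacking_unique_instrument=bad, severity=severity
    )


def compute_summary_statistics(data: IndividualData) -> SummaryStatistics:
    """Reduce individual-level data to its sufficient cross-moment matrices.

    Returns Syy = Y'Y/n, Syx = Y'X/n, Sxx = X'X/n.  The model likelihood
    depends on (X, Y) only through these, so fits from individual data and
    from its exact summary coincide.
    """
    if not isinstance(data, IndividualData):
        raise TypeError("expected IndividualData")
    X, Y, n = data.X, data.Y, data.n
    if n < 1:
        raise ValueError("need at least one observation")
    Syy = Y.T @ Y / n
    Sxx = X.T @ X / n
    Syx = Y.T @ X / n
    # enforce exact symmetry against floating-point matmul asymmetry
    Syy = (Syy + Syy.T) / 2.0
    Sxx = (Sxx + Sxx.T) / 2.0
    return SummaryStatistics(Syy=Syy, Syx=Syx, Sxx=Sxx, n=n)


def reconstruct_summary(
    reg: RegressionSummaries, D: InstrumentAssignment | np.ndarray
) -> SummaryStatistics:
    """Rebuild approximate summary statistics from regression summaries.

    For a no-intercept simple regression of response i on instrument j,
    ``Beta[i, j] = Syx[i, j] / Sxx[j, j]`` and
    ``SigmaHat[i, j] = Syy[i, i] - Beta[i, j]^2 * Sxx[j, j]`` (MSE with
    denominator n).  Inverting these gives Syx on the D = 1 cells and the
    Syy diagonal; a response with several private instruments contributes
    one diagonal estimate per instrument, and these are averaged.  The Syy
    off-diagonals are unobservable from per-response regressions and are
    stored as NaN, to be imputed with model-implied values at likelihood
    evaluation.
    """
    if not isinstance(D, InstrumentAssignment):
        D = InstrumentAssignment(D)
    report = validate_instrument_assignment(D, "regression_summary")
    report.raise_or_warn()
    if reg.Beta.shape != (D.p, D.k):
        raise ValueError(
            f"Beta shape {reg.Beta.shape} does not match D shape {(D.p, D.k)}"
        )
    mask = D.D == 1
    if (reg.SigmaHat[mask] <= 0).any():
        bad = [tuple(map(int, ij)) for ij in np.argwhere(mask & (reg.SigmaHat <= 0))]
        raise ValueError(f"SigmaHat must be positive on D=1 cells; offending cells {bad}")
    sxx_diag = np.diag(reg.Sxx)
    Syx = np.where(mask, reg.Beta * sxx_diag[None, :], 0.0)
    Syy = np.full((D.p, D.p), np.nan)
    for i in range(D.p):
        js = np.nonzero(mask[i])[0]
        est = reg.SigmaHat[i, js] + reg.Beta[i, js] ** 2 * sxx_diag[js]
        Syy[i, i] = est.mean()
    return SummaryStatistics(
        Syy=Syy, Syx=Syx, Sxx=reg.Sxx, n=reg.n, missing_offdiag=True
    )


# ---------------------------------------------------------------------------
# matrix file I/O
# ---------------------------------------------------------------------------


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_matrix_file(path: str | os.PathLike, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a numeric matrix from a CSV/TSV file.

    The delimiter (comma or tab) is sniffed from the first line.  A header
    row and/or a leading row-name column are detected by non-numeric tokens
    and stripped; headerless files are fine.  Errors name the offending
    cell in the original file's 1-based row/column coordinates.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
        fh.seek(0)
        rows = [row for row in csv.reader(fh, delimiter=delim)]
    rows = [r for r in rows if any(tok.strip() for tok in r)]
    # header row detected when any token past the first is non-numeric
    # (the first token may be an empty corner cell above row names)
    header = not all(_is_number(tok) for tok in rows[0][1:]) or (
        len(rows[0]) == 1 and not _is_number(rows[0][0])
    )
    body = rows[1:] if header else rows
    if not body:
        raise ValueError(f"{path}: no data rows")
    rowname = not all(_is_number(r[0]) for r in body)
    width = len(body[0])
    out = []
    for ridx, r in enumerate(body):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row {ridx + 1 + header} has {len(r)} cells, expected {width}"
            )
        vals = []
        for cidx, tok in enumerate(r):
            if rowname and cidx == 0:
                continue
            try:
                vals.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {tok!r} at row {ridx + 1 + header}, "
                    f"column {cidx + 1}"
                ) from None
        out.append(vals)
    M = np.asarray(out, dtype=float)
    if expected_shape is not None and M.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: expected shape {tuple(expected_shape)}, got {M.shape}"
        )
    return M


def write_matrix_file(
    M: np.ndarray,
    path: str | os.PathLike,
    row_names: list[str] | None = None,
    col_names: list[str] | None = None,
) -> None:
    """Write a matrix as CSV with full round-trip precision (repr of floats)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if col_names is None:
        col_names = [f"v{j + 1}" for j in range(M.shape[1])]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(([""] if row_names else []) + list(col_names))
        for i, row in enumerate(M):
            prefix = [row_names[i]] if row_names else []
            w.writerow(prefix + [repr(float(v)) for v in row])


def write_fit_outputs(result, directory: str | os.PathLike) -> dict[str, str]:
    """Write a PosteriorResult to a directory of plain files.

    One CSV per matrix/vector output, a JSON file for scalar summaries and
    acceptance rates, an edge-list TSV of the reported causal graph, and
    the retained gamma sample stack (``.npy`` with a JSON sidecar) so that
    motif probabilities can be computed post hoc.  Returns the mapping from
    output name to file path.
    """
    os.makedirs(directory, exist_ok=True)
    written: dict[str, str] = {}

    def _mat(name, M):
        fp = os.path.join(directory, f"{name}.csv")
        write_matrix_file(np.atleast_2d(M), fp)
        written[name] = fp

    for name in (
        "AEst", "BEst", "A0Est", "B0Est", "GammaEst", "PhiEst",
        "TauEst", "EtaEst", "zAEst", "zBEst",
    ):
        _mat(name, getattr(result, name))
    _mat("SigmaEst", np.asarray(result.SigmaEst)[None, :])
    _mat("LLPst", np.asarray(result.LLPst)[None, :])

    scalars = {
        "RhoEst": result.RhoEst,
        "PsiEst": result.PsiEst,
        "tAEst": result.tAEst,
        "tBEst": result.tBEst,
        "AccptA": result.AccptA,
        "AccptB": result.AccptB,
        "AccpttA": result.AccpttA,
        "AccpttB": result.AccpttB,
        "n_retained": int(np.asarray(result.GammaPst).shape[0]),
    }
    fp = os.path.join(directory, "summary.json")
    with open(fp, "w") as fh:
        json.dump({k: (None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v))
                   for k, v in scalars.items()}, fh, indent=2)
    written["summary"] = fp

    fp = os.path.join(directory, "edges.tsv")
    with open(fp, "w") as fh:
        fh.write("source\ttarget\teffect\tinclusion_probability\n")
        for (src, tgt, eff, prob) in result.Graph:
            fh.write(f"{src}\t{tgt}\t{eff!r}\t{prob!r}\n")
    written["edges"] = fp

    gpst = np.asarray(result.GammaPst)
    fp = os.path.join(directory, "GammaPst.npy")
    np.save(fp, gpst.astype(np.int8))
    written["GammaPst"] = fp
    side = {"shape": list(gpst.shape), "dtype": "int8",
            "order": "samples x p x p", "seed": getattr(result, "seed", None)}
    fp = os.path.join(directory, "GammaPst.json")
    with open(fp, "w") as fh:
        json.dump(side, fh, indent=2)
    written["GammaPst_sidecar"] = fp
    return written
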