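"""Long-format longitudinal data and block-diagonal design construction.

A study records ``m`` subjects on up to ``R`` longitudinal markers; the
observation ``y_irj`` is visit ``j`` of marker ``r`` on subject ``i``.  Each
marker has its own fixed-effect design (``p_r`` columns) and random-effect
design (``q_r`` columns); per subject the marker designs are arranged
block-diagonally, so the joint coefficient vector is
``(beta_1, ..., beta_R, u_1, ..., u_m)`` with each ``u_i`` of length
``q = sum_r q_r`` holding that subject's random effects for every marker.

Rows are kept in canonical order: subject-major, then marker block, then
visit.  The reserved covariate name ``"intercept"`` resolves to a constant
column of ones and need not be present in the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import FamilySpec, get_family

__all__ = [
    "MarkerSpec",
    "PriorConfig",
    "LongitudinalDataset",
    "DesignSet",
    "read_long_table",
    "build_design",
    "ConfigurationError",
]

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"

SUBJECT_COL = "subject"
MARKER_COL = "marker"
RESPONSE_COL = "response"


class ConfigurationError(ValueError):
    """A marker/prior/fit configuration that cannot be honoured."""


@dataclass(frozen=True)
class MarkerSpec:
    """One marker: its response family and fixed/random design columns."""

    name: str
    family: FamilySpec
    fixed: tuple[str, ...]
    random: tuple[str, ...]

    def __post_init__(self):
        if isinstance(self.family, str):
            object.__setattr__(self, "family", get_family(self.family))
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))
        if len(self.fixed) < 1 or len(self.random) < 1:
            raise ConfigurationError(
                f"marker {self.name!r} needs at least one fixed and one random column"
            )

    @property
    def p_r(self) -> int:
        return len(self.fixed)

    @property
    def q_r(self) -> int:
        return len(self.random)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the weakly informative covariance priors.

    ``sigma2_beta`` is the fixed-effect prior variance; ``nu`` the
    degrees-of-freedom modifier of the inverse-Wishart prior on the joint
    random-effects covariance (``nu = 2`` gives Half-t(2) standard deviations
    and uniform correlations); ``a_k`` and ``a_eps`` are the Half-Cauchy-type
    scale hyperparameters of the auxiliary inverse-gamma variables.
    """

    sigma2_beta: float = 1e4
    nu: float = 2.0
    a_k: float | np.ndarray = 1e4
    a_eps: float | np.ndarray = 1e4

    def __post_init__(self):
        if self.sigma2_beta <= 0 or self.nu <= 0:
            raise ConfigurationError("sigma2_beta and nu must be strictly positive")
        if np.any(np.asarray(self.a_k) <= 0) or np.any(np.asarray(self.a_eps) <= 0):
            raise ConfigurationError("all auxiliary scales must be strictly positive")

    def a_k_vector(self, q: int) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.a_k, dtype=float), (q,))
        return np.array(a)

    def a_eps_vector(self, n_gaussian: int) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.a_eps, dtype=float), (n_gaussian,))
        return np.array(a)


@dataclass
class LongitudinalDataset:
    """Validated long-format data in canonical (subject, marker, visit) order."""

    table: pd.DataFrame
    marker_specs: tuple[MarkerSpec, ...]
    subjects: np.ndarray  # unique subject ids, canonical order
    n_dropped: int = 0

    @property
    def m(self) -> int:
        return len(self.subjects)

    @property
    def R(self) -> int:
        return len(self.marker_specs)

    @property
    def n_rows(self) -> int:
        return len(self.table)

    def counts(self) -> np.ndarray:
        """``(m, R)`` matrix of visit counts ``n_ir`` (zeros allowed)."""
        out = np.zeros((self.m, self.R), dtype=int)
        subj_pos = {s: i for i, s in enumerate(self.subjects)}
        marker_pos = {sp.name: r for r, sp in enumerate(self.marker_specs)}
        grp = self.table.groupby([SUBJECT_COL, MARKER_COL], sort=False).size()
        for (s, mk), n in grp.items():
            out[subj_pos[s], marker_pos[mk]] = n
        return out

    def y_ir(self, subject, marker_name: str) -> np.ndarray:
        t = self.table
        sel = (t[SUBJECT_COL] == subject) & (t[MARKER_COL] == marker_name)
        return t.loc[sel, RESPONSE_COL].to_numpy(dtype=float)


def read_long_table(
    table_source, marker_specs: list[MarkerSpec] | tuple[MarkerSpec, ...]
) -> LongitudinalDataset:
    """Load and validate a long-format table (path, file object or DataFrame).

    Rows with a missing response are dropped (the count is logged); marker
    names in the table must be a subset of the spec names; responses are
    checked against each marker's family support.  A subject may lack a
    marker entirely.
    """
    marker_specs = tuple(marker_specs)
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source)

    for col in (SUBJECT_COL, MARKER_COL, RESPONSE_COL):
        if col not in df.columns:
            raise ConfigurationError(f"input table is missing required column {col!r}")

    known = {sp.name for sp in marker_specs}
    present = set(df[MARKER_COL].unique())
    unknown = present - known
    if unknown:
        raise ConfigurationError(
            f"table contains markers not in the specification: {sorted(unknown)}"
        )

    n_before = len(df)
    df = df[df[RESPONSE_COL].notna()]
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing responses", n_dropped)

    for sp in marker_specs:
        y = df.loc[df[MARKER_COL] == sp.name, RESPONSE_COL].to_numpy(dtype=float)
        try:
            sp.family.validate_response(y)
        except ValueError as exc:
            raise ValueError(f"marker {sp.name!r}: {exc}") from exc

    # canonical sort: subject, marker block order, original (visit) order
    marker_order = {sp.name: r for r, sp in enumerate(marker_specs)}
    df = df.assign(
        _marker_pos=df[MARKER_COL].map(marker_order),
        _row=np.arange(len(df)),
    )
    df = df.sort_values([SUBJECT_COL, "_marker_pos", "_row"], kind="stable")
    df = df.drop(columns=["_marker_pos", "_row"]).reset_index(drop=True)

    subjects = np.array(sorted(df[SUBJECT_COL].unique(), key=_sort_key))
    return LongitudinalDataset(
        table=df, marker_specs=marker_specs, subjects=subjects, n_dropped=n_dropped
    )


def _sort_key(v):
    return (0, v) if isinstance(v, (int, float, np.integer, np.floating)) else (1, str(v))


@dataclass
class DesignSet:
    """Stacked designs in row-compressed form plus slicing metadata.

    ``X`` is the dense stacked fixed-effect design (``N x p``) with one
    non-zero marker block per row.  The full random-effect design is
    block-diagonal over subjects; it is stored row-compressed as ``Zrows``
    (``N x q``, the subject-local columns) together with ``subj_idx``.
    Rows are subject-major, marker-block minor; per-subject row spans are
    contiguous, recorded in ``subj_starts`` / ``subj_stops``.
    """

    dataset: LongitudinalDataset
    X: np.ndarray  # (N, p)
    Zrows: np.ndarray  # (N, q)
    y: np.ndarray  # (N,)
    subj_idx: np.ndarray  # (N,) int, subject index per row
    marker_idx: np.ndarray  # (N,) int, marker index per row
    subj_starts: np.ndarray  # (m,) first row of each subject
    subj_stops: np.ndarray  # (m,) one past last row of each subject
    beta_labels: tuple[str, ...]
    u_labels: tuple[str, ...]  # labels of the q subject-level coefficients
    n_ir: np.ndarray  # (m, R)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Zrows.shape[1]

    @property
    def m(self) -> int:
        return len(self.subj_starts)

    @property
    def R(self) -> int:
        return self.n_ir.shape[1]

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def marker_specs(self) -> tuple[MarkerSpec, ...]:
        return self.dataset.marker_specs

    def subject_slice(self, i: int) -> slice:
        return slice(self.subj_starts[i], self.subj_stops[i])

    def X_i(self, i: int) -> np.ndarray:
        return self.X[self.subject_slice(i)]

    def Z_i(self, i: int) -> np.ndarray:
        return self.Zrows[self.subject_slice(i)]

    def y_i(self, i: int) -> np.ndarray:
        return self.y[self.subject_slice(i)]

    def marker_rows(self, r: int) -> np.ndarray:
        return np.flatnonzero(self.marker_idx == r)

    def gaussian_markers(self) -> list[int]:
        return [
            r for r, sp in enumerate(self.marker_specs) if sp.family.family_tag == "gaussian"
        ]

    def family_tag(self) -> np.ndarray:
        """Per-row family tag array."""
        tags = np.array([sp.family.family_tag for sp in self.marker_specs])
        return tags[self.marker_idx]

    def beta_slice(self, r: int) -> slice:
        """Columns of ``X`` holding marker ``r``'s fixed effects."""
        p_off = np.concatenate([[0], np.cumsum([sp.p_r for sp in self.marker_specs])])
        return slice(p_off[r], p_off[r + 1])

    def u_slice(self, r: int) -> slice:
        """Subject-local columns of ``Zrows`` holding marker ``r``'s random effects."""
        q_off = np.concatenate([[0], np.cumsum([sp.q_r for sp in self.marker_specs])])
        return slice(q_off[r], q_off[r + 1])

    def full_C(self, guard: int = 2000) -> np.ndarray:
        """Assemble the dense ``N x (p + m q)`` matrix ``C = [X Z]``.

        Intended for the naive reference path and small problems only.
        """
        dim = self.p + self.m * self.q
        if dim > guard:
            raise ValueError(
                f"dense C would have {dim} columns, above the guard of {guard}"
            )
        C = np.zeros((self.n_rows, dim))
        C[:, : self.p] = self.X
        for i in range(self.m):
            sl = self.subject_slice(i)
            c0 = self.p + i * self.q
            C[sl, c0 : c0 + self.q] = self.Zrows[sl]
        return C


def _resolve_columns(df: pd.DataFrame, names: tuple[str, ...], n: int) -> np.ndarray:
    cols = []
    for name in names:
        if name == INTERCEPT and INTERCEPT not in df.columns:
            cols.append(np.ones(n))
        elif name in df.columns:
            cols.append(df[name].to_numpy(dtype=float))
        else:
            raise ConfigurationError(f"covariate column {name!r} absent from table")
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def build_design(dataset: LongitudinalDataset, marker_specs=None) -> DesignSet:
    """Construct the stacked block-diagonal designs from a validated dataset."""
    specs = tuple(marker_specs) if marker_specs is not None else dataset.marker_specs
    df = dataset.table
    n = len(df)
    p_sizes = [sp.p_r for sp in specs]
    q_sizes = [sp.q_r for sp in specs]
    p_off = np.concatenate([[0], np.cumsum(p_sizes)])
    q_off = np.concatenate([[0], np.cumsum(q_sizes)])
    p, q = int(p_off[-1]), int(q_off[-1])

    subj_pos = {s: i for i, s in enumerate(dataset.subjects)}
    marker_pos = {sp.name: r for r, sp in enumerate(specs)}
    subj_idx = df[SUBJECT_COL].map(subj_pos).to_numpy(dtype=int)
    marker_idx = df[MARKER_COL].map(marker_pos).to_numpy(dtype=int)

    X = np.zeros((n, p))
    Zrows = np.zeros((n, q))
    for r, sp in enumerate(specs):
        rows = marker_idx == r
        sub = df.loc[rows]
        X[np.ix_(rows, range(p_off[r], p_off[r + 1]))] = _resolve_columns(
            sub, sp.fixed, rows.sum()
        )
        Zrows[np.ix_(rows, range(q_off[r], q_off[r + 1]))] = _resolve_columns(
            sub, sp.random, rows.sum()
        )

    # contiguous subject spans (rows are canonically sorted)
    m = dataset.m
    starts = np.searchsorted(subj_idx, np.arange(m), side="left")
    stops = np.searchsorted(subj_idx, np.arange(m), side="right")

    n_ir = np.zeros((m, len(specs)), dtype=int)
    np.add.at(n_ir, (subj_idx, marker_idx), 1)

    beta_labels = tuple(f"{sp.name}:{c}" for sp in specs for c in sp.fixed)
    u_labels = tuple(f"{sp.name}:{c}" for sp in specs for c in sp.random)

    return DesignSet(
        dataset=dataset,
        X=X,
        Zrows=Zrows,
        y=df[RESPONSE_COL].to_numpy(dtype=float),
        subj_idx=subj_idx,
        marker_idx=marker_idx,
        subj_starts=starts,
        subj_stops=stops,
        beta_labels=beta_labels,
        u_labels=u_labels,
        n_ir=n_ir,
    )
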