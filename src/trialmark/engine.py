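"""Precomputed array views of a trial used by every model-fitting stage.

The screening, interaction and CATE stages enumerate thousands of small
regressions over the same patient strata, and the permutation adjustment
repeats that enumeration hundreds of times with only the treatment
vector changed.  :class:`TrialArrays` therefore extracts, once, the
numpy pieces every fit needs — the binary feature matrix, the covariate
design, one row mask per subtype level, and per-(endpoint, stratum)
row-index arrays pre-sorted by survival time so that Cox fits never
re-sort.  Treatment-label permutations pass an override vector;
bootstrap resamples rebuild the arrays by row indexing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .data import ENDPOINT_COLUMNS, TrialDataset
from .fitters import FitResult, cox_fit, logistic_fit

ALL_LEVEL = "ALL"
NO_SCHEME = "none"


@dataclass
class Context:
    """One analysed stratum: a subtype level, or the whole cohort."""

    scheme: str
    level: str
    mask: np.ndarray  # (n,) bool


@dataclass
class EndpointArrays:
    name: str
    kind: str  # "survival" | "binary"
    valid: np.ndarray  # (n,) bool — endpoint observed
    time: np.ndarray | None = None
    event: np.ndarray | None = None  # survival event flag, or binary response
    y: np.ndarray | None = None


def build_covariate_matrix(
    clinical: pd.DataFrame, covariate_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded covariate design (reference = most frequent level)."""
    columns: list[np.ndarray] = []
    names: list[str] = []
    for name in covariate_names:
        col = clinical[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            columns.append(col.to_numpy(dtype=np.float64))
            names.append(name)
        else:
            counts = col.value_counts()
            reference = counts.index[0]
            for level in sorted(lv for lv in counts.index if lv != reference):
                columns.append((col == level).to_numpy(dtype=np.float64))
                names.append(f"{name}[{level}]")
    if not columns:
        return np.empty((len(clinical), 0)), []
    return np.column_stack(columns), names


class TrialArrays:
    """Numpy snapshot of one trial, ready for repeated model fitting."""

    def __init__(
        self,
        dataset: TrialDataset,
        features: pd.DataFrame,
        feature_meta: pd.DataFrame,
        config: Config,
    ) -> None:
        self.config = config
        clinical = dataset.clinical
        self.n = len(clinical)
        self.treatment = clinical["treatment"].to_numpy(dtype=np.int8)
        self.feature_names: list[str] = list(features.columns)
        self.X = features.to_numpy(dtype=np.int8)
        self.module_members: dict[int, list[int]] = {}
        if "members" in feature_meta.columns:
            name_to_idx = {f: j for j, f in enumerate(self.feature_names)}
            for j, f in enumerate(self.feature_names):
                if f in feature_meta.index:
                    members = feature_meta.loc[f, "members"]
                    if isinstance(members, str) and members:
                        self.module_members[j] = [
                            name_to_idx[m] for m in members.split(";")
                        ]
        self.cov, self.cov_names = build_covariate_matrix(
            clinical, config.covariate_names
        )

        self.contexts: list[Context] = [
            Context(NO_SCHEME, ALL_LEVEL, np.ones(self.n, dtype=bool))
        ]
        for scheme in config.subtype_schemes:
            labels = clinical[scheme]
            levels = sorted(labels.dropna().unique().tolist())
            if len(levels) < 2:
                raise ValueError(f"scheme {scheme!r} has fewer than 2 levels")
            for level in levels:
                self.contexts.append(
                    Context(scheme, str(level), (labels == level).to_numpy())
                )

        self.endpoints: dict[str, EndpointArrays] = {}
        for ep in config.endpoints:
            cols = ENDPOINT_COLUMNS[ep]
            if not all(c in clinical.columns for c in cols):
                continue
            if ep == "ORR":
                y = clinical["orr"]
                valid = y.notna().to_numpy()
                self.endpoints[ep] = EndpointArrays(
                    ep, "binary", valid, y=y.fillna(0).to_numpy(dtype=np.float64)
                )
            else:
                tcol, ecol = cols
                t = clinical[tcol]
                e = clinical[ecol]
                valid = (t.notna() & e.notna()).to_numpy()
                self.endpoints[ep] = EndpointArrays(
                    ep,
                    "survival",
                    valid,
                    time=t.fillna(0).to_numpy(dtype=np.float64),
                    event=e.fillna(0).to_numpy(dtype=np.float64),
                )
        if not self.endpoints:
            raise ValueError("no configured endpoint has columns in the dataset")

        # per (endpoint, context): row indices, time-sorted for survival
        self.orders: dict[tuple[str, int], np.ndarray] = {}
        for ep_name, ep in self.endpoints.items():
            for ci, ctx in enumerate(self.contexts):
                rows = np.flatnonzero(ctx.mask & ep.valid)
                if ep.kind == "survival":
                    rows = rows[np.argsort(ep.time[rows], kind="stable")]
                self.orders[(ep_name, ci)] = rows

    # -- resampling support -------------------------------------------------

    def resample(self, idx: np.ndarray) -> "TrialArrays":
        """Row-resampled copy (bootstrap); all derived arrays rebuilt."""
        new = object.__new__(TrialArrays)
        new.config = self.config
        new.n = len(idx)
        new.treatment = self.treatment[idx]
        new.feature_names = self.feature_names
        new.X = self.X[idx]
        new.module_members = self.module_members
        new.cov = self.cov[idx]
        new.cov_names = self.cov_names
        new.contexts = [
            Context(c.scheme, c.level, c.mask[idx]) for c in self.contexts
        ]
        new.endpoints = {}
        for name, ep in self.endpoints.items():
            new.endpoints[name] = EndpointArrays(
                name,
                ep.kind,
                ep.valid[idx],
                time=None if ep.time is None else ep.time[idx],
                event=None if ep.event is None else ep.event[idx],
                y=None if ep.y is None else ep.y[idx],
            )
        new.orders = {}
        for ep_name, ep in new.endpoints.items():
            for ci, ctx in enumerate(new.contexts):
                rows = np.flatnonzero(ctx.mask & ep.valid)
                if ep.kind == "survival":
                    rows = rows[np.argsort(ep.time[rows], kind="stable")]
                new.orders[(ep_name, ci)] = rows
        return new

    # -- single-model fit ---------------------------------------------------

    def fit_rows(
        self,
        endpoint: str,
        rows: np.ndarray,
        design: np.ndarray,
    ) -> FitResult | None:
        """Fit the endpoint model on pre-selected rows.

        ``rows`` must already be time-sorted for survival endpoints (any
        subset of an ``orders`` array is).  Constant covariate columns
        are dropped — only leading design columns (feature/interaction
        terms) keep their positions, which is all downstream code reads.
        Returns None for a degenerate outcome.
        """
        ep = self.endpoints[endpoint]
        if ep.kind == "survival":
            event = ep.event[rows]
            if event.sum() == 0:
                return None
            return cox_fit(ep.time[rows], event, design, presorted=True)
        y = ep.y[rows]
        if y.sum() == 0 or y.sum() == len(y):
            return None
        return logistic_fit(y, design)

    def design_with_covariates(
        self, rows: np.ndarray, *lead_columns: np.ndarray
    ) -> np.ndarray:
        cov = self.cov[rows]
        if cov.shape[1]:
            keep = np.ptp(cov, axis=0) > 0  # constant in this stratum: drop
            cov = cov[:, keep]
        return np.column_stack([*lead_columns, cov]) if cov.shape[1] else (
            np.column_stack(lead_columns)
        )

    def module_redistribution_ok(self, j: int, stratum_rows: np.ndarray) -> bool:
        """Module filter: union must redistribute >= n_min patients over
        every single member within the stratum."""
        members = self.module_members.get(j)
        if not members:
            return True
        union = int(self.X[stratum_rows, j].sum())
        n_min = self.config.n_min
        return all(
            union - int(self.X[stratum_rows, m].sum()) >= n_min for m in members
        )


def coef_offset(kind: str) -> int:
    """Index of the first design coefficient (logistic fits prepend an
    intercept)."""
    return 1 if kind == "binary" else 0
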