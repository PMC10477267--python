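"""Trial data model: clinical table, binary alteration matrix, joined dataset.

The clinical table carries one row per patient with the treatment
indicator (0/1, 1 = experimental arm by convention), the time-to-event
endpoints (`os_time`/`os_event`, `pfs_time`/`pfs_event`, months), the
binary response endpoint `orr`, plus any covariate and subtype columns.
The alteration matrix is strictly binary, patients x features.  The two
are inner-joined on `patient_id`; patients present in only one table are
dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config, SURVIVAL_ENDPOINTS

logger = logging.getLogger(__name__)

CLINICAL_CORE = ("patient_id", "treatment")
ENDPOINT_COLUMNS = {
    "OS": ("os_time", "os_event"),
    "PFS": ("pfs_time", "pfs_event"),
    "ORR": ("orr",),
}
FEATURE_CLASSES = ("SV", "AMP", "DEL", "MSI", "MODULE", "CUSTOM")


class DataError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass
class TrialDataset:
    """Joined clinical + alteration data for one two-arm trial.

    `clinical` and `alterations` are row-aligned (same patient order,
    `patient_id` column / index respectively).  `feature_meta` maps each
    alteration column to a gene symbol and a feature class.
    """

    clinical: pd.DataFrame
    alterations: pd.DataFrame
    feature_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = default_feature_meta(list(self.alterations.columns))

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.clinical["patient_id"])

    @property
    def feature_names(self) -> list[str]:
        return list(self.alterations.columns)

    def subtype_levels(self, scheme: str) -> list[str]:
        labels = self.clinical[scheme].dropna()
        return sorted(labels.unique().tolist())

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        """Write clinical.tsv and alterations.tsv (round-trips via load_trial)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cpath = outdir / "clinical.tsv"
        apath = outdir / "alterations.tsv"
        self.clinical.to_csv(cpath, sep="\t", index=False)
        alt = self.alterations.copy()
        alt.insert(0, "patient_id", self.clinical["patient_id"].to_numpy())
        alt.to_csv(apath, sep="\t", index=False)
        return cpath, apath


def default_feature_meta(features: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature": features, "gene": features, "class": ["SV"] * len(features)}
    ).set_index("feature")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def validate_clinical(clinical: pd.DataFrame, config: Config) -> pd.DataFrame:
    clinical = clinical.copy()
    for col in CLINICAL_CORE:
        if col not in clinical.columns:
            raise DataError(f"clinical table missing required column {col!r}")
    if clinical["patient_id"].duplicated().any():
        dups = clinical.loc[clinical["patient_id"].duplicated(), "patient_id"].tolist()
        raise DataError(f"duplicate patient_id in clinical table: {dups[:5]}")
    if clinical["treatment"].isna().any():
        raise DataError("treatment must never be missing")
    treatment = clinical["treatment"]
    if not treatment.isin([0, 1]).all():
        bad = sorted(treatment[~treatment.isin([0, 1])].unique().tolist())
        raise DataError(f"treatment values outside {{0,1}}: {bad}")
    clinical["treatment"] = treatment.astype(np.int64)

    present = []
    for ep in config.endpoints:
        cols = ENDPOINT_COLUMNS[ep]
        if not all(c in clinical.columns for c in cols):
            continue
        present.append(ep)
        if ep in SURVIVAL_ENDPOINTS:
            tcol, ecol = cols
            if (clinical[tcol].dropna() < 0).any():
                raise DataError(f"{tcol} contains negative times")
            ev = clinical[ecol].dropna()
            if not ev.isin([0, 1]).all():
                raise DataError(f"{ecol} values must be 0/1")
        else:
            orr = clinical["orr"].dropna()
            if not orr.isin([0, 1]).all():
                raise DataError("orr values must be 0/1 (or missing)")
    if not present:
        raise DataError(
            f"none of the configured endpoints {config.endpoints} has its "
            "columns in the clinical table"
        )
    for name in config.covariate_names:
        if name not in clinical.columns:
            raise DataError(f"covariate column {name!r} not in clinical table")
    for scheme in config.subtype_schemes:
        if scheme not in clinical.columns:
            raise DataError(f"subtype scheme column {scheme!r} not in clinical table")
        n_missing = int(clinical[scheme].isna().sum())
        if n_missing:
            logger.info(
                "scheme %s: %d patients without a subtype label (kept "
                "unstratified, excluded from this scheme's strata)",
                scheme,
                n_missing,
            )
    return clinical


def validate_alterations(
    alterations: pd.DataFrame, config: Config, id_column: str = "patient_id"
) -> pd.DataFrame:
    if id_column not in alterations.columns:
        raise DataError(f"alteration matrix missing {id_column!r} column")
    alterations = alterations.set_index(id_column)
    if alterations.index.duplicated().any():
        raise DataError("duplicate patient_id in alteration matrix")
    if alterations.shape[1] < 1:
        raise DataError("alteration matrix has no feature columns")
    if pd.Index(alterations.columns).duplicated().any():
        raise DataError("duplicate feature names in alteration matrix")
    if alterations.isna().any().any():
        if config.missing_as == "zero":
            alterations = alterations.fillna(0)
        else:
            cell = next(
                (pid, col)
                for col in alterations.columns
                for pid in alterations.index[alterations[col].isna()]
            )
            raise DataError(
                f"missing alteration value at (patient {cell[0]}, feature "
                f"{cell[1]}); rerun with missing_as='zero' to impute 0"
            )
    values = alterations.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"non-binary alteration value {values[i, j]!r} at "
            f"(patient {alterations.index[i]}, feature {alterations.columns[j]})"
        )
    return alterations.astype(np.int8)


def load_trial(
    clinical_path: str | Path,
    alterations_path: str | Path,
    config: Config,
    transpose_alterations: bool = False,
    column_map: dict[str, str] | None = None,
) -> TrialDataset:
    """Read, validate and inner-join the two input tables.

    Parameters
    ----------
    transpose_alterations : bool
        Accept a genes-as-rows matrix (first column = feature name).
    column_map : dict
        Optional ``{file column -> canonical column}`` rename applied to
        the clinical table before validation.
    """
    clinical = _read_table(clinical_path)
    if column_map:
        clinical = clinical.rename(columns=column_map)
    alterations = _read_table(alterations_path)
    if transpose_alterations:
        alterations = alterations.set_index(alterations.columns[0]).T
        alterations.index.name = "patient_id"
        alterations = alterations.reset_index()

    clinical = validate_clinical(clinical, config)
    alterations = validate_alterations(alterations, config)

    clin_ids = pd.Index(clinical["patient_id"].astype(str))
    alt_ids = alterations.index.astype(str)
    alterations.index = alt_ids
    clinical = clinical.assign(patient_id=clin_ids)
    shared = clin_ids.intersection(alt_ids)
    dropped_clin = clin_ids.difference(alt_ids)
    dropped_alt = alt_ids.difference(clin_ids)
    if len(dropped_clin) or len(dropped_alt):
        logger.warning(
            "inner join dropped %d clinical-only patients %s and %d "
            "alteration-only patients %s",
            len(dropped_clin),
            list(dropped_clin[:5]),
            len(dropped_alt),
            list(dropped_alt[:5]),
        )
    if len(shared) == 0:
        raise DataError("no shared patient_id between clinical and alteration tables")

    # deterministic order: clinical file order restricted to the join
    clinical = clinical[clinical["patient_id"].isin(shared)].reset_index(drop=True)
    alterations = alterations.loc[clinical["patient_id"]].reset_index(drop=True)

    arms = clinical["treatment"].value_counts()
    if len(arms) < 2:
        raise DataError(f"both arms must be present, got {arms.to_dict()}")
    if arms.min() < 2:
        logger.warning(
            "an arm has fewer than 2 patients (%s); arm-specific models "
            "will be degenerate", arms.to_dict(),
        )
    return TrialDataset(clinical=clinical, alterations=alterations)
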