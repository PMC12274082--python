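"""Longitudinal panel data model for main-study / validation-study designs.

A :class:`Panel` holds long-format records (one row per individual-visit) for a
main study (MS), an internal validation study (IVS), or an external validation
study (EVS).  The main study observes the outcome ``Y``, the error-prone
surrogate exposure ``C``, and error-free covariates ``W`` at each visit; the
validation study additionally observes the gold-standard true exposure ``c``
(possibly at a subset of visits).  EVS individuals come from a separate sample
and need not carry an outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyRole",
    "Panel",
    "PanelFormatError",
    "read_panel_csv",
    "validate_panel",
    "split_by_role",
]

#: canonical internal column names
ID, TIME, OUTCOME, SURROGATE, TRUE, ROLE = "id", "time", "y", "C", "c", "role"


class StudyRole(str, Enum):
    """Study membership of an individual: main study or validation study."""

    MS = "MS"
    IVS = "IVS"
    EVS = "EVS"


class PanelFormatError(ValueError):
    """Raised when long-format input violates the panel contract."""


@dataclass(frozen=True)
class Panel:
    """Validated long-format longitudinal data.

    Parameters
    ----------
    data:
        DataFrame with canonical columns ``id, time, y, C, c, role`` plus the
        covariate columns named in ``covariates``.  Rows are sorted by
        ``(id, time)``.  ``y`` and ``c`` may contain NaN where unobserved.
    covariates:
        Names of the error-free covariate columns ``W`` (possibly empty).
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.data
        required = [ID, TIME, SURROGATE, ROLE]
        missing = [col for col in required if col not in df.columns]
        if missing:
            raise PanelFormatError(f"missing required columns: {missing}")
        for col in (OUTCOME, TRUE):
            if col not in df.columns:
                df = df.assign(**{col: np.nan})
        df = df.sort_values([ID, TIME], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=[ID, TIME])
        if dup.any():
            pair = df.loc[dup.idxmax(), [ID, TIME]].tolist()
            raise PanelFormatError(f"duplicate (id, time) pair: {pair}")
        if df[SURROGATE].isna().any():
            raise PanelFormatError("surrogate exposure C contains missing values")
        for w in self.covariates:
            if w not in df.columns:
                raise PanelFormatError(f"covariate column not found: {w}")
            if df[w].isna().any():
                raise PanelFormatError(f"covariate {w!r} contains missing values")
        bad_role = ~df[ROLE].isin([r.value for r in StudyRole])
        if bad_role.any():
            raise PanelFormatError(
                f"unknown role value: {df.loc[bad_role, ROLE].iloc[0]!r}"
            )
        ms_with_true = (df[ROLE] == StudyRole.MS.value) & df[TRUE].notna()
        if ms_with_true.any():
            raise PanelFormatError(
                "main-study rows must not carry the true exposure c "
                f"(individual {df.loc[ms_with_true.idxmax(), ID]!r})"
            )
        object.__setattr__(self, "data", df)

    # -- accessors ---------------------------------------------------------

    @property
    def ids(self) -> np.ndarray:
        """Unique individual ids, in sorted row order."""
        return self.data[ID].unique()

    @property
    def n_individuals(self) -> int:
        return self.data[ID].nunique()

    @property
    def roles(self) -> set[str]:
        return set(self.data[ROLE].unique())

    def cluster_sizes(self) -> pd.Series:
        return self.data.groupby(ID, sort=False).size()

    def with_column(self, name: str, values: np.ndarray | pd.Series) -> "Panel":
        """Return a copy with an extra per-visit column (row-aligned)."""
        df = self.data.copy()
        df[name] = np.asarray(values)
        return replace(self, data=df)

    def subset_ids(self, ids: Sequence) -> "Panel":
        df = self.data[self.data[ID].isin(ids)]
        return replace(self, data=df.reset_index(drop=True))

    def to_csv(self, path, column_map: dict | None = None) -> None:
        """Write long-format CSV using canonical (or mapped) column names."""
        df = self.data
        if column_map:
            df = df.rename(columns={v: k for k, v in _canonical_map(column_map).items()})
        df.to_csv(path, index=False)


def _canonical_map(column_map: dict) -> dict:
    """Map external column names -> canonical names from a config mapping."""
    out = {}
    keys = {"id": ID, "time": TIME, "outcome": OUTCOME, "surrogate": SURROGATE,
            "true": TRUE, "role": ROLE}
    for key, canon in keys.items():
        if key in column_map and column_map[key] is not None:
            out[column_map[key]] = canon
    return out


def read_panel_csv(path, column_map: dict | None = None) -> Panel:
    """Read a long-format CSV into a validated :class:`Panel`.

    ``column_map`` follows the config schema
    ``{id:…, time:…, outcome:…, surrogate:…, true:…, covariates:[…], role:…}``;
    omitted keys default to the canonical names.  Empty cells are the only
    missing-value sentinel and are permitted only in the true-exposure and
    (for EVS rows) outcome columns.
    """
    column_map = dict(column_map or {})
    covariates = tuple(column_map.pop("covariates", ()) or ())
    df = pd.read_csv(path)
    rename = _canonical_map(column_map)
    missing_src = [src for src in rename if src not in df.columns]
    if missing_src:
        raise PanelFormatError(f"mapped columns absent from CSV: {missing_src}")
    df = df.rename(columns=rename)
    for col in (ID, TIME, SURROGATE, ROLE):
        if col not in df.columns:
            raise PanelFormatError(f"required column missing: {col!r}")
    if OUTCOME in df.columns:
        need_y = df[ROLE].isin([StudyRole.MS.value, StudyRole.IVS.value])
        if df.loc[need_y, OUTCOME].isna().any():
            raise PanelFormatError("outcome missing on an MS/IVS row")
    elif df[ROLE].isin([StudyRole.MS.value, StudyRole.IVS.value]).any():
        raise PanelFormatError("outcome column required for MS/IVS rows")
    return Panel(df, covariates=covariates)


def validate_panel(panel: Panel, link: str = "logit") -> list[str]:
    """Check Panel invariants; return human-readable violations (no raising).

    For the logit link, observed outcomes must be 0/1.  EVS individuals may
    carry outcomes (they are ignored downstream).
    """
    violations: list[str] = []
    df = panel.data
    for iid, grp in df.groupby(ID, sort=False):
        t = grp[TIME].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            violations.append(f"individual {iid!r}: visit times not strictly increasing")
        role = grp[ROLE].iloc[0]
        if (grp[ROLE] != role).any():
            violations.append(f"individual {iid!r}: inconsistent role across visits")
        if role in (StudyRole.MS.value, StudyRole.IVS.value):
            y = grp[OUTCOME]
            if y.isna().any():
                violations.append(f"individual {iid!r}: missing outcome on {role} row")
            elif link == "logit":
                bad = ~y.isin([0.0, 1.0])
                if bad.any():
                    j = int(np.argmax(bad.to_numpy()))
                    violations.append(
                        f"individual {iid!r}, visit {j + 1}: outcome "
                        f"{y.iloc[j]!r} not in {{0,1}} under logit link"
                    )
        if role == StudyRole.MS.value and grp[TRUE].notna().any():
            violations.append(f"individual {iid!r}: MS row carries true exposure")
        if role in (StudyRole.IVS.value, StudyRole.EVS.value):
            # where c is observed, C must be observed at the same visit
            # (guaranteed by the no-missing-C invariant, checked for clarity)
            if grp.loc[grp[TRUE].notna(), SURROGATE].isna().any():
                violations.append(
                    f"individual {iid!r}: true exposure observed without surrogate"
                )
    return violations


@dataclass(frozen=True)
class SplitResult:
    main: Panel
    validation: Panel
    design: str  # "ms_evs" or "ms_ivs"

    def __iter__(self):
        return iter((self.main, self.validation, self.design))


def split_by_role(panel: Panel) -> SplitResult:
    """Split into main and validation panels and identify the design.

    Under MS/IVS the validation individuals are part of the main analysis set
    (analysis N = n1 + n2); under MS/EVS they are not (N = n1).  The returned
    ``main`` panel contains MS rows only — the caller assembles the MS/IVS
    analysis set from both parts.
    """
    roles = panel.roles
    if StudyRole.MS.value not in roles:
        raise PanelFormatError("panel contains no main-study (MS) rows")
    has_ivs = StudyRole.IVS.value in roles
    has_evs = StudyRole.EVS.value in roles
    if has_ivs and has_evs:
        raise PanelFormatError("both IVS and EVS present: unsupported design")
    if not (has_ivs or has_evs):
        raise PanelFormatError("no validation (IVS/EVS) rows present")
    df = panel.data
    main = Panel(df[df[ROLE] == StudyRole.MS.value].reset_index(drop=True),
                 covariates=panel.covariates)
    vrole = StudyRole.IVS.value if has_ivs else StudyRole.EVS.value
    validation = Panel(df[df[ROLE] == vrole].reset_index(drop=True),
                       covariates=panel.covariates)
    return SplitResult(main, validation, "ms_ivs" if has_ivs else "ms_evs")
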