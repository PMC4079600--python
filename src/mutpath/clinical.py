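"""Mutation–clinical-feature and survival association tests.

Binary clinical features are tested against per-sample mutation status of
a gene or pathway with the classical small-table rule: Fisher's exact test
when the 2x2 is sparse (minimum expected cell count <= 5, the Cochran
criterion), otherwise the chi-square test with Yates' continuity
correction.  Overall survival is contrasted between mutated and unmutated
arms with the log-rank test, alongside a univariate Cox hazard ratio and
Kaplan–Meier median OS per arm.  Raw (uncorrected) p-values are reported,
matching the screening style of small-cohort mutation studies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .annotations import fisher_exact_2x2
from .pathways import PathwayMutationMatrix

logger = logging.getLogger(__name__)

#: Binary clinical features carried by the clinical table.
BINARY_FEATURES = (
    "differentiation_poor",
    "metastasis",
    "cirrhosis",
    "hbsag_positive",
)

# textual encodings used in the clinical TSV
_FEATURE_CODES = {
    "differentiation_poor": ("differentiation", {"poor": True, "good": False}),
    "metastasis": ("metastasis", {"yes": True, "no": False}),
    "cirrhosis": ("cirrhosis", {"yes": True, "no": False}),
    "hbsag_positive": ("hbsag", {"pos": True, "neg": False}),
}


@dataclass
class ClinicalTable:
    """Per-sample binary clinical features and overall survival.

    ``data`` is indexed by sample label with nullable-boolean feature
    columns and float ``os_months`` / ``os_event`` columns; missing values
    are allowed per feature (dropped pairwise at test time).  ``os_event``
    is present exactly where ``os_months`` is.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        for col in BINARY_FEATURES:
            if col not in df.columns:
                df[col] = pd.array([pd.NA] * len(df), dtype="boolean")
            else:
                df[col] = df[col].astype("boolean")
        for col in ("os_months", "os_event"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if (df["os_months"].isna() != df["os_event"].isna()).any():
            raise ValueError("os_event must be present exactly where os_months is")
        if (df["os_months"].dropna() < 0).any():
            raise ValueError("os_months must be nonnegative")
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def feature(self, name: str) -> pd.Series:
        if name not in BINARY_FEATURES:
            raise KeyError(f"unknown clinical feature: {name}")
        return self.data[name]

    def write_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(index=self.data.index)
        out.index.name = "sample_id"
        for feat, (col, codes) in _FEATURE_CODES.items():
            inv = {v: k for k, v in codes.items()}
            out[col] = self.data[feat].map(lambda x: inv[x] if x is not pd.NA else "")
        out["os_months"] = self.data["os_months"]
        out["os_event"] = self.data["os_event"].map(
            lambda x: "" if pd.isna(x) else str(int(x))
        )
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ClinicalTable":
        raw = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
        df = pd.DataFrame(index=raw.index)
        for feat, (col, codes) in _FEATURE_CODES.items():
            if col in raw.columns:
                df[feat] = pd.array(
                    [
                        codes.get(str(v).strip()) if not _blank(v) else pd.NA
                        for v in raw[col]
                    ],
                    dtype="boolean",
                )
        for col in ("os_months", "os_event"):
            if col in raw.columns:
                df[col] = pd.to_numeric(raw[col], errors="coerce")
        return cls(df)


def _blank(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == ""


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one mutation-status association test.

    ``rate_positive`` / ``rate_negative`` are the mutation rates within
    feature-positive and feature-negative patients (for survival tests
    they are unused).  ``median_os`` entries of ``inf`` mean the arm's
    Kaplan–Meier median was not reached.
    """

    unit_id: str
    feature: str
    test_used: str  # fisher | chisq_yates | logrank
    p: float
    rate_positive: float | None = None
    rate_negative: float | None = None
    hazard_ratio: float | None = None
    median_os_mutated: float | None = None
    median_os_unmutated: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def binary_association(
    status: Sequence[bool],
    feature: Sequence,
    unit_id: str = "",
    feature_name: str = "",
    expected_rule: bool = True,
) -> AssociationResult:
    """Test mutation status against a binary clinical feature.

    Samples with a missing feature value are dropped.  With
    ``expected_rule=True`` (default) the branch is chosen by the Cochran
    criterion on expected counts: Fisher's exact test when the minimum
    expected cell count is <= 5, otherwise chi-square with Yates'
    continuity correction.  ``expected_rule=False`` applies the same cut to
    the minimum observed cell count instead.

    A feature arm left empty after dropping missing values is an error; a
    constant mutation-status vector gives p = 1 with a warning (no
    contrast).
    """
    status = np.asarray([bool(s) for s in status])
    feat = pd.array(list(feature), dtype="boolean")
    if len(status) != len(feat):
        raise ValueError("status and feature must have equal length")
    mask = ~pd.isna(feat)
    if not mask.any():
        raise ValueError("feature vector is entirely missing")
    s = status[np.asarray(mask)]
    f = feat[mask].to_numpy(dtype=bool)
    n_pos, n_neg = int(f.sum()), int((~f).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("a feature arm is empty after dropping missing values")
    rate_pos = float(s[f].mean())
    rate_neg = float(s[~f].mean())
    # 2x2: rows mutated/unmutated, columns feature-positive/negative
    a = int((s & f).sum())
    b = int((s & ~f).sum())
    c = int((~s & f).sum())
    d = int((~s & ~f).sum())
    if s.all() or not s.any():
        warnings.warn(
            f"degenerate table for {unit_id or 'unit'}: constant mutation status",
            stacklevel=2,
        )
        return AssociationResult(
            unit_id, feature_name, "fisher", 1.0, rate_pos, rate_neg, n=len(s)
        )
    table = np.array([[a, b], [c, d]], dtype=float)
    if expected_rule:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        small = expected.min() <= 5
    else:
        small = table.min() <= 5
    if small:
        p = fisher_exact_2x2(a, b, c, d)
        test = "fisher"
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        p = float(p)
        test = "chisq_yates"
    return AssociationResult(
        unit_id, feature_name, test, p, rate_pos, rate_neg, n=len(s)
    )


def survival_association(
    status: Sequence[bool],
    clinical: ClinicalTable,
    unit_id: str = "",
) -> AssociationResult:
    """Log-rank test of overall survival between mutated and unmutated arms.

    Also reports the univariate Cox proportional-hazards ratio for
    mutation status and the Kaplan–Meier median OS of each arm (``inf``
    when not reached).  Requires at least two samples with survival data
    per arm and at least one event overall.
    """
    status = np.asarray([bool(s) for s in status])
    if len(status) != len(clinical.samples):
        raise ValueError("status length does not match clinical table")
    df = clinical.data[["os_months", "os_event"]].copy()
    df["status"] = status
    df = df.dropna(subset=["os_months"])
    n_mut = int(df["status"].sum())
    n_unmut = len(df) - n_mut
    if n_mut < 2 or n_unmut < 2:
        raise ValueError("each arm needs >= 2 samples with survival data")
    if df["os_event"].sum() == 0:
        raise ValueError("no events observed; survival test undefined")
    mut = df[df["status"]]
    unmut = df[~df["status"]]
    lr = logrank_test(
        mut["os_months"], unmut["os_months"], mut["os_event"], unmut["os_event"]
    )
    p = float(lr.p_value)

    hr = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(
                df[["os_months", "os_event", "status"]].astype(float),
                duration_col="os_months",
                event_col="os_event",
            )
        hr = float(np.exp(cph.params_["status"]))
    except Exception as exc:  # noqa: BLE001 - Cox may fail on separable data
        logger.warning("Cox fit failed for %s: %s", unit_id or "unit", exc)

    medians = []
    for arm in (mut, unmut):
        km = KaplanMeierFitter()
        km.fit(arm["os_months"], arm["os_event"])
        medians.append(float(km.median_survival_time_))
    return AssociationResult(
        unit_id,
        "overall_survival",
        "logrank",
        p,
        hazard_ratio=hr,
        median_os_mutated=medians[0],
        median_os_unmutated=medians[1],
        n=len(df),
    )


def pathway_status(matrix: PathwayMutationMatrix, pathway_id: str) -> np.ndarray:
    """Per-sample coverage (Y row) of a pathway as a boolean vector."""
    return matrix.row(pathway_id).astype(bool)


def association_screen(
    units: Mapping[str, Sequence[bool]],
    clinical: ClinicalTable,
    alpha: float = 0.05,
    survival_alpha: float = 0.1,
    features: Iterable[str] = BINARY_FEATURES,
    include_survival: bool = True,
) -> pd.DataFrame:
    """Screen many status vectors against every clinical feature + survival.

    Units failing a test's preconditions (an empty arm, no events, ...)
    are skipped with a logged reason.  ``significant`` flags raw
    p <= ``alpha`` for binary features and p <= ``survival_alpha`` for the
    log-rank test; no multiplicity correction is applied.
    """
    rows = []
    for unit_id, status in units.items():
        for feat in features:
            try:
                res = binary_association(
                    status, clinical.feature(feat), unit_id, feat
                )
            except ValueError as exc:
                logger.info("skipping %s x %s: %s", unit_id, feat, exc)
                continue
            rows.append(_as_row(res, res.p <= alpha))
        if include_survival:
            try:
                res = survival_association(status, clinical, unit_id)
            except ValueError as exc:
                logger.info("skipping %s x survival: %s", unit_id, exc)
                continue
            rows.append(_as_row(res, res.p <= survival_alpha))
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id",
            "feature",
            "test_used",
            "p",
            "rate_positive",
            "rate_negative",
            "hazard_ratio",
            "median_os_mutated",
            "median_os_unmutated",
            "n",
            "significant",
        ],
    )


def _as_row(res: AssociationResult, significant: bool) -> dict:
    return {
        "unit_id": res.unit_id,
        "feature": res.feature,
        "test_used": res.test_used,
        "p": res.p,
        "rate_positive": res.rate_positive,
        "rate_negative": res.rate_negative,
        "hazard_ratio": res.hazard_ratio,
        "median_os_mutated": res.median_os_mutated,
        "median_os_unmutated": res.median_os_unmutated,
        "n": res.n,
        "significant": bool(significant),
    }
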