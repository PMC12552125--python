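"""Differential abundance testing, BH correction and PCA lipotypes.

Tests run on percent-of-total values.  The parametric/rank choice is
gated by Shapiro-Wilk normality at alpha = 0.05 (on each group for
unpaired comparisons, on the paired differences otherwise); a forced-test
override is available for reproducing specific analyses.  BH families are
corrected separately at class and species level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import (
    DomainError,
    InsufficientReplicatesError,
    InsufficientSamplesError,
)

__all__ = [
    "bh_adjust",
    "select_test",
    "DifferentialResult",
    "differential_test",
    "aggregate_replicates",
    "PcaResult",
    "pca_lipotypes",
]

_MIN_PER_GROUP = 3


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    Raises
    ------
    DomainError
        If any p-value is outside [0, 1] or non-finite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must be finite and within [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p; constant input cannot reject normality (p = 1)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def select_test(group_a, group_b, paired: bool = False,
                alpha: float = 0.05) -> str:
    """Choose the test: t / mwu (unpaired), paired-t / wilcoxon (paired).

    Unpaired: Shapiro-Wilk on each group; any rejection at ``alpha``
    selects the rank test.  Paired: Shapiro-Wilk on the differences.

    Raises
    ------
    InsufficientReplicatesError
        Fewer than 3 values per group (or fewer than 3 pairs).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise InsufficientReplicatesError("paired groups differ in length")
        if len(a) < _MIN_PER_GROUP:
            raise InsufficientReplicatesError(
                f"need >= {_MIN_PER_GROUP} pairs, got {len(a)}")
        normal = _shapiro_p(b - a) > alpha
        return "paired-t" if normal else "wilcoxon"
    if len(a) < _MIN_PER_GROUP or len(b) < _MIN_PER_GROUP:
        raise InsufficientReplicatesError(
            f"need >= {_MIN_PER_GROUP} values per group, "
            f"got {len(a)} and {len(b)}")
    normal = _shapiro_p(a) > alpha and _shapiro_p(b) > alpha
    return "t" if normal else "mwu"


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def _run_test(test: str, case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided p-value for the named test, with degenerate-data guards."""
    if test == "t":
        if np.ptp(case) == 0 and np.ptp(control) == 0:
            return 1.0 if case.mean() == control.mean() else 0.0
        res = sps.ttest_ind(case, control, equal_var=False)
        return float(res.pvalue)
    if test == "mwu":
        # exact null distribution for small tie-free samples, otherwise the
        # tie-corrected normal approximation
        if max(len(case), len(control)) <= 8 and not _has_ties(case, control):
            method = "exact"
        else:
            method = "asymptotic"
        res = sps.mannwhitneyu(case, control, alternative="two-sided",
                               method=method)
        return float(res.pvalue)
    diff = case - control
    if test == "paired-t":
        if np.ptp(diff) == 0:
            return 1.0 if diff.mean() == 0 else 0.0
        res = sps.ttest_rel(case, control)
        return float(res.pvalue)
    if test == "wilcoxon":
        if np.all(diff == 0):
            return 1.0
        res = sps.wilcoxon(case, control, alternative="two-sided")
        return float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class DifferentialResult:
    """Per-feature differential abundance results for one comparison.

    ``table`` columns: feature, n_case, n_control, mean_case, mean_control,
    log2fc, test, p, q, skipped, reason.  BH correction (``q``) is applied
    across the non-skipped features of this family only.
    """

    table: pd.DataFrame
    family: str
    case_group: str
    control_group: str
    paired: bool

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]


def differential_test(matrix: pd.DataFrame,
                      group_of: Mapping[str, str],
                      case_group: str,
                      control_group: str,
                      paired: bool = False,
                      pair_of: Mapping[str, str] | None = None,
                      family: str = "class",
                      test_override: str | None = None,
                      normality_alpha: float = 0.05) -> DifferentialResult:
    """Test every feature (row) of ``matrix`` between two groups.

    ``matrix`` holds percent-of-total values (features x samples);
    ``group_of`` maps sample id -> group label.  Missing values are
    dropped per feature; in paired mode (pairs keyed by ``pair_of``) a
    pair with a missing member is dropped entirely.  Features with fewer
    than 3 usable values per group are skipped and recorded.

    ``test_override`` forces ``"t"`` or ``"rank"`` instead of the
    Shapiro-Wilk gate (mapped to the paired variants when ``paired``).
    """
    case_ids = [s for s in matrix.columns if group_of.get(s) == case_group]
    control_ids = [s for s in matrix.columns if group_of.get(s) == control_group]
    if not case_ids or not control_ids:
        raise ValueError(
            f"groups {case_group!r} / {control_group!r} not found in design")
    if paired and pair_of is None:
        raise ValueError("paired mode requires pair_of (sample -> pairing key)")

    rows = []
    for feature, values in matrix.iterrows():
        a = values[case_ids].astype(float)
        b = values[control_ids].astype(float)
        if paired:
            by_key_a = {pair_of[s]: a[s] for s in case_ids if s in pair_of}
            by_key_b = {pair_of[s]: b[s] for s in control_ids if s in pair_of}
            keys = [k for k in by_key_a if k in by_key_b
                    and np.isfinite(by_key_a[k]) and np.isfinite(by_key_b[k])]
            case_v = np.array([by_key_a[k] for k in keys], dtype=float)
            control_v = np.array([by_key_b[k] for k in keys], dtype=float)
            n_case = n_control = len(keys)
        else:
            case_v = a.dropna().to_numpy(dtype=float)
            control_v = b.dropna().to_numpy(dtype=float)
            n_case, n_control = len(case_v), len(control_v)

        mean_case = float(case_v.mean()) if n_case else np.nan
        mean_control = float(control_v.mean()) if n_control else np.nan
        if mean_control and mean_control > 0 and mean_case > 0:
            log2fc = float(np.log2(mean_case / mean_control))
        else:
            log2fc = np.nan

        if n_case < _MIN_PER_GROUP or n_control < _MIN_PER_GROUP:
            rows.append(dict(feature=feature, n_case=n_case, n_control=n_control,
                             mean_case=mean_case, mean_control=mean_control,
                             log2fc=log2fc, test="", p=np.nan, q=np.nan,
                             skipped=True,
                             reason=f"<{_MIN_PER_GROUP} usable values per group"))
            continue

        if test_override is None:
            test = select_test(control_v, case_v, paired=paired,
                               alpha=normality_alpha)
        elif test_override in ("t", "paired-t"):
            test = "paired-t" if paired else "t"
        elif test_override in ("rank", "mwu", "wilcoxon"):
            test = "wilcoxon" if paired else "mwu"
        else:
            raise ValueError(f"unknown test_override {test_override!r}")

        p = _run_test(test, case_v, control_v)
        rows.append(dict(feature=feature, n_case=n_case, n_control=n_control,
                         mean_case=mean_case, mean_control=mean_control,
                         log2fc=log2fc, test=test, p=p, q=np.nan,
                         skipped=False, reason=""))

    table = pd.DataFrame(rows).set_index("feature")
    tested = ~table["skipped"]
    if tested.any():
        table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    return DifferentialResult(table=table, family=family,
                              case_group=case_group,
                              control_group=control_group, paired=paired)


def aggregate_replicates(matrix: pd.DataFrame,
                         replicate_of: Mapping[str, str],
                         group_of: Mapping[str, str] | None = None):
    """Average replicate wells into one column per (group, experiment).

    Returns ``(aggregated matrix, aggregated group_of)``; aggregated
    column names are ``<group>:<experiment>`` (or the experiment key alone
    when ``group_of`` is None).  Statistics on experiment means follow the
    convention of testing one value per independent experiment.
    """
    cols = [c for c in matrix.columns if c in replicate_of]
    key_of = {}
    for c in cols:
        if group_of is not None:
            key_of[c] = f"{group_of[c]}:{replicate_of[c]}"
        else:
            key_of[c] = str(replicate_of[c])
    agg = matrix[cols].T.groupby(pd.Series(key_of)).mean().T
    new_group_of = {}
    if group_of is not None:
        for c in cols:
            new_group_of[key_of[c]] = group_of[c]
    return agg, new_group_of


@dataclass
class PcaResult:
    """Sample scores, feature loadings and explained-variance fractions."""

    scores: pd.DataFrame                 # sample x component
    loadings: pd.DataFrame               # feature x component
    explained_variance_ratio: np.ndarray


def pca_lipotypes(matrix: pd.DataFrame, scale: bool = False,
                  n_components: int | None = None) -> PcaResult:
    """PCA of samples in species percent-of-total space.

    ``matrix`` is features x samples.  Features with any missing value are
    excluded (no imputation); features are centered and optionally
    unit-scaled.  Sign convention: per component, the feature with the
    largest absolute loading has a positive loading.
    """
    if matrix.shape[1] < 3:
        raise InsufficientSamplesError(
            f"PCA needs >= 3 samples, got {matrix.shape[1]}")
    complete = matrix.dropna(axis=0)
    if scale:
        sd = complete.std(axis=1, ddof=1)
        complete = complete.loc[sd > 0]
        complete = complete.div(sd[sd > 0], axis=0)
    if complete.shape[0] < 2:
        raise ValueError("PCA needs >= 2 complete features")

    X = complete.T.to_numpy(dtype=float)  # samples x features
    k = min(X.shape[0] - 1, X.shape[1])
    if n_components is not None:
        k = min(k, n_components)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x components

    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=complete.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
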