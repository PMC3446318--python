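"""Case/control differential expression calling.

A gene is called differentially expressed (DE) with a two-sided
pooled-variance Student's t-test at a configurable threshold, optionally
on Benjamini-Hochberg adjusted p-values.  An optional bead-array style
detection filter removes genes whose detection score falls below a
cutoff in every sample before testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Gene x sample expression intensities with case/control labels.

    ``values`` is a genes-by-samples DataFrame; ``groups`` maps each
    sample id to ``"case"`` or ``"control"``; ``detection`` is an
    optional gene x sample DataFrame of detection scores in [0, 1].
    """

    values: pd.DataFrame
    groups: pd.Series
    detection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in (CASE, CONTROL):
            if (self.groups == grp).sum() < 2:
                raise ValueError(f"group {grp!r} has fewer than 2 samples")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicated gene ids: {sorted(set(dups))[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.detection is not None:
            if not self.detection.index.equals(self.values.index) or not (
                self.detection.columns.equals(self.values.columns)
            ):
                raise ValueError("detection scores must align with values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])


def read_expression(
    values_path: str | Path,
    sample_sheet_path: str | Path,
    detection_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) plus a two-column
    sample sheet (sample id, group)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    sheet = pd.read_csv(
        sample_sheet_path, sep="\t", header=None, names=["sample", "group"]
    )
    groups = sheet.set_index("sample")["group"]
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, groups=groups, detection=detection)


def test_differential_expression(
    expr: ExpressionMatrix,
    threshold: float = 0.05,
    use_adjusted: bool = False,
    detection_cutoff: float | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided t-test (case vs control) with BH adjustment.

    Returns a DataFrame indexed by gene with columns ``t``, ``p_raw``,
    ``p_adj``, ``is_de`` and ``zero_variance``.  The t statistic is
    positive when cases are higher.  ``is_de`` compares ``p_raw`` (or
    ``p_adj`` when ``use_adjusted``) strictly below ``threshold``.

    Genes whose detection score is below ``detection_cutoff`` in *every*
    sample are removed before testing (and before BH adjustment).  Genes
    with zero variance in both groups are reported with ``t = 0`` and
    ``p = 1`` and flagged rather than erroring.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    values = expr.values
    if detection_cutoff is not None:
        if expr.detection is None:
            raise ValueError("detection_cutoff given but no detection scores")
        detected = (expr.detection >= detection_cutoff).any(axis=1)
        values = values.loc[detected]
    if values.shape[0] == 0:
        raise ValueError("no gene left after detection filtering")

    case = values[expr.case_samples].to_numpy(dtype=float)
    ctrl = values[expr.control_samples].to_numpy(dtype=float)

    zero_var = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate genes: no within-group variance -> no evidence either way
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    if np.isnan(p).any():
        raise AssertionError("unexpected NaN p-value from t-test")

    p_adj = multipletests(p, method="fdr_bh")[1]
    chosen = p_adj if use_adjusted else p
    out = pd.DataFrame(
        {
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "is_de": chosen < threshold,
            "zero_variance": zero_var,
        },
        index=values.index,
    )
    out.index.name = "gene"
    return out


def de_gene_set(de: pd.DataFrame) -> set[str]:
    """Gene ids flagged as differentially expressed."""
    return set(de.index[de["is_de"]])


def write_de_results(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t")
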