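"""Test-retest reproducibility of regional DVR values.

For each ROI with paired test/retest measurements the module computes the
signed relative difference ``100 * (retest - test) / test``, the mean and
sample SD of the absolute relative differences, and an intraclass
correlation coefficient of the form

    ICC = (BIMSS - WIMSS) / (BIMSS + WIMSS)

with BIMSS the between-individuals mean sum of squares of the pair means
and WIMSS the within-individual mean sum of squares of the pair
differences.  This ICC lies in [-1, 1]: 1 for perfect within-pair
agreement with any between-subject spread, -1 when all pair means
coincide but pairs disagree.

A five-patient, 11-ROI test-retest table of tau-PET DVR values is shipped
with the package (``load_study_table``); its printed per-subject % rows can
be consumed directly (``summarize_table(from_percents=True)``) since the
published relative differences were computed from unrounded DVRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TestRetestRecord:
    __test__ = False  # not a pytest collectable despite the name

    subject_id: str
    roi_name: str
    test_value: float
    retest_value: float

    def __post_init__(self):
        if self.test_value <= 0 or self.retest_value <= 0:
            raise ValueError("test and retest values must be positive")


@dataclass(frozen=True)
class TrtSummary:
    roi_name: str
    pct_differences: tuple[float, ...]
    mean_abs_pct: float
    sd_abs_pct: float
    icc: float | None  # None when only % rows (not raw pairs) are available


def relative_difference(test: float, retest: float) -> float:
    """Signed percent difference ``100 * (retest - test) / test``.

    Deliberately asymmetric: swapping the roles gives 100*(T-R)/R, not the
    negation.
    """
    if test <= 0:
        raise ValueError("test value must be positive")
    return 100.0 * (retest - test) / test


def icc(pairs: list[tuple[float, float]] | np.ndarray) -> float:
    """Intraclass correlation (BIMSS - WIMSS) / (BIMSS + WIMSS).

    BIMSS = 2 * sum_i (m_i - g)^2 / (n - 1) with m_i the pair mean and g
    the grand mean; WIMSS = sum_i d_i^2 / (2 n) with d_i = retest - test.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (test, retest) pairs")
    n = arr.shape[0]
    m = arr.mean(axis=1)
    d = arr[:, 1] - arr[:, 0]
    bimss = 2.0 * float(((m - m.mean()) ** 2).sum()) / (n - 1)
    wimss = float((d**2).sum()) / (2.0 * n)
    denom = bimss + wimss
    if denom == 0:
        raise ValueError("degenerate input: all values identical")
    return (bimss - wimss) / denom


def trt_summary(
    records: list[TestRetestRecord] | None = None,
    *,
    roi_name: str | None = None,
    pct_differences: list[float] | None = None,
) -> TrtSummary:
    """Summarise one ROI's test-retest agreement.

    Either pass paired ``records`` (signed % differences and the ICC are
    recomputed from the DVR values) or pass printed ``pct_differences``
    directly, in which case no ICC is available.
    """
    if records is not None:
        if len(records) < 2:
            raise ValueError("need at least 2 subjects")
        names = {r.roi_name for r in records}
        if len(names) != 1:
            raise ValueError(f"records span multiple ROIs: {sorted(names)}")
        roi_name = names.pop()
        pcts = [relative_difference(r.test_value, r.retest_value) for r in records]
        coeff = icc([(r.test_value, r.retest_value) for r in records])
    else:
        if pct_differences is None or roi_name is None:
            raise ValueError("pass records, or roi_name with pct_differences")
        if len(pct_differences) < 2:
            raise ValueError("need at least 2 subjects")
        pcts = [float(p) for p in pct_differences]
        coeff = None
    absd = np.abs(np.asarray(pcts, dtype=float))
    return TrtSummary(
        roi_name=roi_name,
        pct_differences=tuple(pcts),
        mean_abs_pct=float(absd.mean()),
        sd_abs_pct=float(absd.std(ddof=1)),
        icc=coeff,
    )


def load_study_table() -> pd.DataFrame:
    """The packaged five-patient tau-PET DVR test-retest table: columns
    subject_id, roi_name, test, retest, pct_difference (the published
    per-subject signed % rows)."""
    with resources.files("tauquant.data").joinpath(
        "thk5317_test_retest.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_table(df: pd.DataFrame, from_percents: bool = False) -> pd.DataFrame:
    """Per-ROI reproducibility summary of a tidy test-retest table.

    With ``from_percents=True`` the mean/SD of absolute differences are
    computed from the ``pct_difference`` column (the published rows, which
    derive from unrounded DVRs); otherwise % differences are recomputed
    from the test/retest values.  The ICC always uses the value pairs when
    present.  ROI order of the input is preserved.
    """
    rows = []
    for roi in df["roi_name"].drop_duplicates():
        sub = df[df["roi_name"] == roi]
        has_pairs = {"test", "retest"} <= set(sub.columns) and sub["test"].notna().all()
        if from_percents:
            s = trt_summary(roi_name=roi, pct_differences=sub["pct_difference"].tolist())
            coeff = icc(sub[["test", "retest"]].to_numpy()) if has_pairs else None
            s = TrtSummary(roi, s.pct_differences, s.mean_abs_pct, s.sd_abs_pct, coeff)
        else:
            recs = [
                TestRetestRecord(r.subject_id, roi, r.test, r.retest)
                for r in sub.itertuples()
            ]
            s = trt_summary(recs)
        rows.append(
            {
                "roi_name": s.roi_name,
                "n_subjects": len(s.pct_differences),
                "mean_abs_pct": s.mean_abs_pct,
                "sd_abs_pct": s.sd_abs_pct,
                "icc": s.icc,
            }
        )
    return pd.DataFrame(rows)
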