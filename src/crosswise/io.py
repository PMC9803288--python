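"""File formats, bundled study data, and report generation.

Count tables travel as CSV with one row per question
(``label,p1,n21,n11,n22,n12``); paired tables additionally carry
direct-question columns (``dq_yes,dq_no``) and a study id.  The observed
response frequencies of the three validation studies (two on controlled
substance use, one on COVID-19 lockdown compliance, ~6,000 respondents in
total) ship with the package, together with each study's randomizer
sequence length and control-question probability, so the full results
table can be regenerated offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .dq_compare import DirectCounts, compare_ecwm_dq, dq_estimate
from .mle import gof_test, interior_mle
from .model_core import (
    Z95,
    CrosswiseCounts,
    PrevalenceEstimate,
    RandomizationDesign,
    moment_pooled,
    pooled_variance,
)

__all__ = [
    "StudyFixture",
    "FixtureQuestion",
    "read_counts",
    "write_counts",
    "load_study_fixtures",
    "run_table2",
    "format_table2",
]

logger = logging.getLogger("crosswise")

COUNT_COLUMNS = ["label", "p1", "n21", "n11", "n22", "n12"]

#: Randomizer metadata per study: (sequence length, control-item probability).
STUDY_META = {
    "I": (15, 1),
    "II": (10, 1),
    "III": (5, 0),
}


@dataclass(frozen=True)
class FixtureQuestion:
    label: str
    counts: CrosswiseCounts
    dq: DirectCounts | None = None


@dataclass(frozen=True)
class StudyFixture:
    """All questions of one study condition, with design metadata."""

    study: str
    questions: tuple[FixtureQuestion, ...]
    sequence_length: int
    control_p: int


def read_counts(path) -> list[CrosswiseCounts]:
    """Read a count-table CSV (``label,p1,n21,n11,n22,n12``).

    Malformed rows raise with the offending row number; an empty file
    yields an empty list with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("%s: no count rows found", path)
        return []
    out = []
    for i, row in df.iterrows():
        try:
            design = RandomizationDesign(float(row["p1"]))
            out.append(
                CrosswiseCounts(
                    label=str(row["label"]),
                    n21=float(row["n21"]),
                    n11=float(row["n11"]),
                    n22=float(row["n22"]),
                    n12=float(row["n12"]),
                    design=design,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {i + 2}: {exc}") from exc
    return out


def write_counts(counts: list[CrosswiseCounts], path) -> None:
    """Write count tables in the canonical CSV schema (read_counts inverse)."""
    rows = [
        {
            "label": c.label,
            "p1": c.design.p1,
            "n21": c.n21,
            "n11": c.n11,
            "n22": c.n22,
            "n12": c.n12,
        }
        for c in counts
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, index=False)


def _fixture_frame() -> pd.DataFrame:
    with resources.files("crosswise.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_study_fixtures() -> list[StudyFixture]:
    """Load the bundled observed response frequencies of the three studies.

    Sub-sample 1 is the p = 1/5 arm throughout (the estimators are
    invariant to that labeling).  Direct-question counts are present for
    the second and third studies only; the first study ran no DQ condition.
    """
    df = _fixture_frame()
    fixtures = []
    for study, grp in df.groupby("study", sort=False):
        roman = study.split("-")[0]
        L, control_p = STUDY_META[roman]
        questions = []
        for _, row in grp.iterrows():
            counts = CrosswiseCounts(
                label=row["label"],
                n21=int(row["n21"]),
                n11=int(row["n11"]),
                n22=int(row["n22"]),
                n12=int(row["n12"]),
                design=RandomizationDesign(float(row["p1"])),
            )
            dq = None
            if not pd.isna(row["dq_yes"]):
                dq = DirectCounts(int(row["dq_yes"]), int(row["dq_no"]))
            questions.append(FixtureQuestion(row["label"], counts, dq))
        fixtures.append(StudyFixture(str(study), tuple(questions), L, control_p))
    return fixtures


def _mle_estimate(counts: CrosswiseCounts) -> PrevalenceEstimate:
    """Intercept-only ML point estimate with the pooled-moment variance.

    For interior solutions the ML and pooled moment estimates coincide
    exactly; the closed-form (clipped) maximizer is used directly and the
    interval is the Wald interval from the pooled variance, truncated to
    [0, 1].
    """
    est = moment_pooled(counts)
    pi = interior_mle(counts)
    boundary = not np.isclose(pi, est.pi_hat)
    var = pooled_variance(pi, counts.n, counts.design.p1)
    half = Z95 * var**0.5
    lo = min(max(pi - half, 0.0), 1.0)
    hi = min(max(pi + half, 0.0), 1.0)
    return PrevalenceEstimate(pi, var, lo, hi, method="mle", boundary=boundary)


def run_table2(fixtures: list[StudyFixture] | None = None) -> pd.DataFrame:
    """Regenerate the full per-question results table from count data.

    One row per question: direct-question estimate and CI (where that
    condition exists), ECWM estimate and CI, the 1-df goodness-of-fit G^2
    and p-value, and the ECWM-minus-DQ difference with its z test.
    Percentages are on the 0-100 scale at full precision; estimation
    errors in one row are logged and do not abort the batch.
    """
    if fixtures is None:
        fixtures = load_study_fixtures()
    rows = []
    for fx in fixtures:
        for q in fx.questions:
            row: dict = {"study": fx.study, "label": q.label}
            try:
                est = _mle_estimate(q.counts)
                gof = gof_test(q.counts)
                row.update(
                    ecwm_pct=100 * est.pi_hat,
                    ecwm_lo=100 * est.ci_low,
                    ecwm_hi=100 * est.ci_high,
                    g2=gof.g2_stat,
                    lr=gof.lr_stat,
                    g2_p=gof.p_value,
                    boundary=gof.boundary,
                )
                if q.dq is not None:
                    dq_est = dq_estimate(q.dq)
                    cmp_ = compare_ecwm_dq(est, dq_est)
                    row.update(
                        dq_pct=100 * dq_est.pi_hat,
                        dq_lo=100 * dq_est.ci_low,
                        dq_hi=100 * dq_est.ci_high,
                        delta_pct=100 * cmp_.delta,
                        z=cmp_.z,
                        z_p=cmp_.p_value,
                    )
            except Exception:
                logger.exception("estimation failed for %s; row skipped", q.label)
            rows.append(row)
    cols = [
        "study",
        "label",
        "dq_pct",
        "dq_lo",
        "dq_hi",
        "ecwm_pct",
        "ecwm_lo",
        "ecwm_hi",
        "g2",
        "lr",
        "g2_p",
        "boundary",
        "delta_pct",
        "z",
        "z_p",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def format_table2(table: pd.DataFrame) -> pd.DataFrame:
    """Render the results table with display rounding: percentages to one
    decimal, statistics to two, p-values to three."""
    out = pd.DataFrame({"label": table["label"]})

    def ci(prefix: str) -> pd.Series:
        return table.apply(
            lambda r: ""
            if pd.isna(r.get(f"{prefix}_pct"))
            else f"{r[f'{prefix}_pct']:.1f} ({r[f'{prefix}_lo']:.1f}, {r[f'{prefix}_hi']:.1f})",
            axis=1,
        )

    out["DQ"] = ci("dq")
    out["ECWM"] = ci("ecwm")
    out["G2"] = table["g2"].map(lambda v: f"{v:.2f}")
    out["p"] = table["g2_p"].map(lambda v: f"{v:.3f}")
    out["diff"] = table["delta_pct"].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out["z"] = table["z"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    out["z_p"] = table["z_p"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return out
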