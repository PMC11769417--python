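"""Test-retest reliability battery for subjects × sessions velocity tables.

Implements the standard sports-science reliability workup for a
two-session (familiarization + test) design:

* within-day and between-day coefficient of variation, CV% = 100·SD/M
  (sample SD, n−1 denominator);
* ICC(3,1), the two-way mixed-effects, single-measure, consistency
  intraclass correlation of Shrout & Fleiss, with its F-based 95% CI;
* SEM = sqrt(residual mean square) of the subjects × sessions repeated
  measures ANOVA, plus SEM% of the grand mean;
* Bland–Altman mean difference and 95% limits of agreement
  (MD ± 1.96·SD of the paired differences);
* a paired t-test for systematic bias.

All mean squares come from one two-way (subjects × sessions)
decomposition so that ICC and SEM are mutually consistent.  Differences
are oriented session2 − session1 throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ReliabilityTable:
    """A complete-case subjects × sessions matrix of velocities (m/s)."""

    subject_ids: list
    values: np.ndarray  # shape (n_subjects, n_sessions)
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x sessions) matrix")
        n, k = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match number of rows")
        if n < 3:
            raise ValueError(f"at least 3 subjects required, got {n}")
        if k < 2:
            raise ValueError(f"at least 2 sessions required, got {k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table must be complete-case (no missing cells)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.values.shape[1]


class AnovaMeanSquares(NamedTuple):
    """Two-way (subjects × sessions) mean squares without replication."""

    ms_subjects: float
    ms_sessions: float
    ms_error: float
    df_subjects: int
    df_sessions: int
    df_error: int
    grand_mean: float


class BlandAltman(NamedTuple):
    mean_difference: float
    loa_upper: float
    loa_lower: float


class PairedT(NamedTuple):
    t: float
    df: int
    p: float
    mean_difference: float


class IccResult(NamedTuple):
    icc: float
    ci_lower: float
    ci_upper: float


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, 100·SD/M, with the sample SD (n−1).

    Scale-invariant: multiplying every value by c > 0 leaves it
    unchanged.  Requires n ≥ 2 and a non-zero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = float(np.mean(arr))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(arr, ddof=1)) / mean


def between_day_cv(table: ReliabilityTable) -> tuple[np.ndarray, dict]:
    """Per-subject CV% over that subject's two session values.

    Returns the per-subject CVs (in subject order) and a min/mean/max
    summary across subjects.
    """
    if table.n_sessions != 2:
        raise ValueError("between-day CV is defined for exactly 2 sessions")
    cvs = np.array([cv_percent(row) for row in table.values])
    summary = {
        "min": float(np.min(cvs)),
        "mean": float(np.mean(cvs)),
        "max": float(np.max(cvs)),
    }
    return cvs, summary


def two_way_anova(table: ReliabilityTable) -> AnovaMeanSquares:
    """Two-way (subjects × sessions) decomposition, no replication.

    Partitions the total sum of squares into between-subjects,
    between-sessions and residual components; the residual mean square
    is the error term shared by ICC(3,1) and the SEM.
    """
    x = table.values
    n, k = x.shape
    grand = float(np.mean(x))
    row_means = np.mean(x, axis=1)
    col_means = np.mean(x, axis=0)
    ss_subjects = k * float(np.sum((row_means - grand) ** 2))
    ss_sessions = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_error = ss_total - ss_subjects - ss_sessions
    df_b, df_s, df_e = n - 1, k - 1, (n - 1) * (k - 1)
    return AnovaMeanSquares(
        ms_subjects=ss_subjects / df_b,
        ms_sessions=ss_sessions / df_s,
        ms_error=max(ss_error, 0.0) / df_e,  # guard tiny negative rounding
        df_subjects=df_b,
        df_sessions=df_s,
        df_error=df_e,
        grand_mean=grand,
    )


def icc_3_1(table: ReliabilityTable, alpha: float = 0.05) -> IccResult:
    """ICC(3,1): two-way mixed, single-measure, consistency ICC.

    ICC = (MS_B − MS_E) / (MS_B + (k−1)·MS_E), with the confidence
    interval from F = MS_B/MS_E on (n−1, (n−1)(k−1)) degrees of freedom
    (Shrout–Fleiss case 3, single measure):

        FL = F / F_{1−α/2}(df1, df2),  FU = F · F_{1−α/2}(df2, df1)
        CI = [(FL − 1)/(FL + k − 1), (FU − 1)/(FU + k − 1)]

    Session main effects cancel (consistency form), so a constant
    offset between sessions leaves ICC = 1.
    """
    ms = two_way_anova(table)
    k = table.n_sessions
    denom = ms.ms_subjects + (k - 1) * ms.ms_error
    if denom == 0:
        raise ValueError("ICC undefined: all table values identical")
    icc = (ms.ms_subjects - ms.ms_error) / denom
    if ms.ms_error == 0:
        return IccResult(icc=icc, ci_lower=icc, ci_upper=icc)
    f_obs = ms.ms_subjects / ms.ms_error
    df1, df2 = ms.df_subjects, ms.df_error
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lower = (f_l - 1) / (f_l + k - 1)
    upper = (f_u - 1) / (f_u + k - 1)
    return IccResult(icc=float(icc), ci_lower=float(lower), ci_upper=float(upper))


def sem_from_anova(table: ReliabilityTable) -> tuple[float, float]:
    """Standard error of measurement from the repeated measures ANOVA.

    SEM = sqrt(MS_error) of the subjects × sessions decomposition (the
    same error term as ICC(3,1)); SEM% = 100·SEM / grand mean.
    Translation-invariant in SEM, not in SEM%.
    """
    ms = two_way_anova(table)
    sem = math.sqrt(ms.ms_error)
    if ms.grand_mean == 0:
        raise ValueError("SEM%% undefined for zero grand mean")
    return sem, 100.0 * sem / ms.grand_mean


def sem_percent(sem: float, mean: float) -> float:
    """SEM expressed as a percentage of a population mean."""
    if mean == 0:
        raise ValueError("SEM% undefined for zero mean")
    return 100.0 * sem / mean


def bland_altman(table: ReliabilityTable) -> BlandAltman:
    """Mean difference and 95% limits of agreement (session2 − session1).

    LOA = MD ± 1.96·SD(d) with the sample SD of the paired differences,
    so LOA_upper + LOA_lower = 2·MD always.
    """
    if table.n_sessions != 2:
        raise ValueError("Bland-Altman is defined for exactly 2 sessions")
    d = table.values[:, 1] - table.values[:, 0]
    if d.size < 2:
        raise ValueError("Bland-Altman requires at least 2 subjects")
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(md, md + 1.96 * sd, md - 1.96 * sd)


def loa_lower_from(mean_difference: float, loa_upper: float) -> float:
    """Reconstruct the lower limit of agreement from MD and the upper LOA.

    Uses the identity LOA_upper + LOA_lower = 2·MD, which holds for any
    symmetric ±1.96·SD band around the mean difference.
    """
    return 2.0 * mean_difference - loa_upper


def paired_t(table: ReliabilityTable) -> PairedT:
    """Paired t-test on session2 − session1 differences.

    df = n − 1, two-sided p.  Zero-variance differences are handled
    explicitly: t = 0, p = 1 when MD = 0, else t = ±inf, p = 0
    (degenerate constant shift).
    """
    if table.n_sessions != 2:
        raise ValueError("paired t-test is defined for exactly 2 sessions")
    d = table.values[:, 1] - table.values[:, 0]
    n = d.size
    if n < 2:
        raise ValueError("paired t-test requires at least 2 subjects")
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        if md == 0:
            return PairedT(0.0, n - 1, 1.0, md)
        logger.warning("degenerate paired t-test: constant non-zero shift")
        return PairedT(math.copysign(math.inf, md), n - 1, 0.0, md)
    res = stats.ttest_rel(table.values[:, 1], table.values[:, 0])
    return PairedT(float(res.statistic), n - 1, float(res.pvalue), md)


@dataclass
class ReliabilityReport:
    """Complete reliability workup for one velocity metric."""

    metric_name: str
    n_subjects: int
    n_dropped: int
    between_day_cv_min: float
    between_day_cv_mean: float
    between_day_cv_max: float
    icc: float
    icc_ci_lower: float
    icc_ci_upper: float
    sem: float
    sem_percent: float
    mean_difference: float
    loa_upper: float
    loa_lower: float
    t: float
    df: int
    p: float
    per_subject_between_day_cv: dict = field(default_factory=dict)
    within_day_cv: dict = field(default_factory=dict)  # session label -> {min,mean,max}

    _SCALARS = (
        "n_subjects", "n_dropped",
        "between_day_cv_min", "between_day_cv_mean", "between_day_cv_max",
        "icc", "icc_ci_lower", "icc_ci_upper",
        "sem", "sem_percent",
        "mean_difference", "loa_upper", "loa_lower",
        "t", "df", "p",
    )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per metric, full precision."""
        rows = [("metric_name", self.metric_name)]
        rows += [(name, getattr(self, name)) for name in self._SCALARS]
        for sid, cv in self.per_subject_between_day_cv.items():
            rows.append((f"between_day_cv[{sid}]", cv))
        for session, summ in self.within_day_cv.items():
            for key, val in summ.items():
                rows.append((f"within_day_cv[{session}].{key}", val))
        return pd.DataFrame(rows, columns=["metric", "value"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReliabilityReport":
        mapping = dict(zip(frame["metric"], frame["value"]))
        kwargs = {"metric_name": str(mapping.pop("metric_name"))}
        for name in cls._SCALARS:
            kwargs[name] = float(mapping.pop(name))
        kwargs["n_subjects"] = int(kwargs["n_subjects"])
        kwargs["n_dropped"] = int(kwargs["n_dropped"])
        kwargs["df"] = int(kwargs["df"])
        per_subject = {}
        within = {}
        for key, val in mapping.items():
            if key.startswith("between_day_cv["):
                per_subject[key[len("between_day_cv["):-1]] = float(val)
            elif key.startswith("within_day_cv["):
                session, stat = key[len("within_day_cv["):].split("].")
                within.setdefault(session, {})[stat] = float(val)
        kwargs["per_subject_between_day_cv"] = per_subject
        kwargs["within_day_cv"] = within
        return cls(**kwargs)

    @classmethod
    def from_csv(cls, path) -> "ReliabilityReport":
        return cls.from_frame(pd.read_csv(path))

    def summary(self) -> str:
        """Human-readable report (ICC/SEM to 3 decimals, CV to 2)."""
        lines = [
            f"Test-retest reliability: {self.metric_name or '<unnamed metric>'}",
            "=" * 46,
            f"subjects (complete case): {self.n_subjects}"
            + (f"   dropped: {self.n_dropped}" if self.n_dropped else ""),
            "",
            f"between-day CV%   min {self.between_day_cv_min:.2f}"
            f"   mean {self.between_day_cv_mean:.2f}"
            f"   max {self.between_day_cv_max:.2f}",
        ]
        for session, summ in self.within_day_cv.items():
            lines.append(
                f"within-day CV% ({session})   min {summ['min']:.2f}"
                f"   mean {summ['mean']:.2f}   max {summ['max']:.2f}"
            )
        lines += [
            f"ICC(3,1) {self.icc:.3f}   95% CI"
            f" [{self.icc_ci_lower:.3f}, {self.icc_ci_upper:.3f}]",
            f"SEM {self.sem:.3f} m/s   ({self.sem_percent:.1f}% of mean)",
            f"Bland-Altman MD {self.mean_difference:.3f} m/s   95% LOA"
            f" [{self.loa_lower:.3f}, {self.loa_upper:.3f}]",
            f"paired t({self.df}) = {self.t:.3f}, p = {self.p:.3f}",
        ]
        return "\n".join(lines)


class TestRetestModel:
    """Reliability model for a subjects × sessions velocity table.

    statsmodels-style: construct from data, call fit() for results::

        model = TestRetestModel.from_sessions(s1, s2, metric_name="jab_avg")
        res = model.fit()
        print(res.summary())

    Parameters
    ----------
    table : ReliabilityTable
        Complete-case matrix, one row per subject, one column per
        session (k = 2 for the Bland–Altman / paired-t parts).
    per_strike : mapping, optional
        ``{session label: {subject_id: [strike velocities]}}`` used for
        within-day CVs; omitted when only session-level values exist.
    """

    def __init__(
        self,
        table: ReliabilityTable,
        per_strike: Optional[Mapping[str, Mapping]] = None,
        n_dropped: int = 0,
    ):
        self.table = table
        self.per_strike = per_strike or {}
        self.n_dropped = n_dropped

    @classmethod
    def from_sessions(
        cls,
        session1: Mapping,
        session2: Mapping,
        metric_name: str = "",
        per_strike: Optional[Mapping[str, Mapping]] = None,
    ) -> "TestRetestModel":
        """Build from two {subject_id: velocity} mappings.

        Subjects missing from either session are dropped (complete-case)
        with a logged count; fewer than 3 completers is an error.
        """
        common = [sid for sid in session1 if sid in session2]
        dropped = (len(session1) - len(common)) + (len(session2) - len(common))
        if dropped:
            logger.info("dropping %d incomplete subject-session records", dropped)
        if len(common) < 3:
            raise ValueError(
                f"at least 3 complete subjects required, got {len(common)}"
            )
        values = np.array([[session1[s], session2[s]] for s in common], dtype=float)
        table = ReliabilityTable(common, values, metric_name=metric_name)
        return cls(table, per_strike=per_strike, n_dropped=dropped)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, subject_col: str, session_cols: Sequence[str],
        metric_name: str = "",
    ) -> "TestRetestModel":
        values = frame[list(session_cols)].to_numpy(dtype=float)
        table = ReliabilityTable(
            list(frame[subject_col]), values, metric_name=metric_name
        )
        return cls(table)

    def fit(self, alpha: float = 0.05) -> "TestRetestResults":
        table = self.table
        cvs, cv_summary = between_day_cv(table)
        icc = icc_3_1(table, alpha=alpha)
        sem, semp = sem_from_anova(table)
        ba = bland_altman(table)
        tt = paired_t(table)
        within = {}
        for session, by_subject in self.per_strike.items():
            session_cvs = [cv_percent(v) for v in by_subject.values() if len(v) >= 2]
            if session_cvs:
                within[str(session)] = {
                    "min": float(np.min(session_cvs)),
                    "mean": float(np.mean(session_cvs)),
                    "max": float(np.max(session_cvs)),
                }
        report = ReliabilityReport(
            metric_name=table.metric_name,
            n_subjects=table.n_subjects,
            n_dropped=self.n_dropped,
            between_day_cv_min=cv_summary["min"],
            between_day_cv_mean=cv_summary["mean"],
            between_day_cv_max=cv_summary["max"],
            icc=icc.icc,
            icc_ci_lower=icc.ci_lower,
            icc_ci_upper=icc.ci_upper,
            sem=sem,
            sem_percent=semp,
            mean_difference=ba.mean_difference,
            loa_upper=ba.loa_upper,
            loa_lower=ba.loa_lower,
            t=tt.t,
            df=tt.df,
            p=tt.p,
            per_subject_between_day_cv=dict(zip(table.subject_ids, cvs)),
            within_day_cv=within,
        )
        return TestRetestResults(model=self, report=report, anova=two_way_anova(table))


@dataclass
class TestRetestResults:
    """Fitted reliability statistics plus the underlying ANOVA terms."""

    model: TestRetestModel
    report: ReliabilityReport
    anova: AnovaMeanSquares

    def summary(self) -> str:
        return self.report.summary()

    def plot_bland_altman(self, ax=None):
        """Bland–Altman scatter with MD and ±1.96 SD limits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.table.values
        means = x.mean(axis=1)
        diffs = x[:, 1] - x[:, 0]
        r = self.report
        ax.scatter(means, diffs, s=18, color="black")
        ax.axhline(r.mean_difference, color="tab:blue")
        ax.axhline(r.loa_upper, ls="--", color="grey")
        ax.axhline(r.loa_lower, ls="--", color="grey")
        ax.set_xlabel("mean of sessions (m/s)")
        ax.set_ylabel("session 2 - session 1 (m/s)")
        ax.set_title(self.model.table.metric_name)
        return ax


def full_report(
    session1: Mapping,
    session2: Mapping,
    per_strike: Optional[Mapping[str, Mapping]] = None,
    metric_name: str = "",
    alpha: float = 0.05,
) -> ReliabilityReport:
    """One-call reliability battery on two {subject: velocity} mappings."""
    model = TestRetestModel.from_sessions(
        session1, session2, metric_name=metric_name, per_strike=per_strike
    )
    return model.fit(alpha=alpha).report
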